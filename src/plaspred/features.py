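"""Fixed-length composition encodings of protein sequences.

Four encodings are provided, all producing values in [0, 1]:

``AC``
    Amino-acid composition: the fraction of each of the 20 residues,
    a 20-dimensional vector.
``DC``
    Dipeptide composition: the fraction of each of the 400 ordered
    adjacent residue pairs among the L-1 overlapping windows, capturing
    local sequence order.
``PSSM``
    Evolutionary-profile composition: per-position PSI-BLAST log-odds
    scores squashed through a logistic sigmoid and pooled per
    (sequence residue, profile column) pair into a 400-dim vector.
``HYBRID``
    Concatenation of AC and DC (420-dim).

Residues are ordered alphabetically by one-letter code and dipeptides
row-major (first residue major); this ordering is part of the on-disk
model contract.
"""

from __future__ import annotations

import subprocess
import tempfile
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .seqio import AMINO_ACIDS, LabeledDataset, ProteinSequence, ValidationError

#: PSI-BLAST writes PSSM columns in this residue order (not alphabetical).
PSIBLAST_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: Dipeptides in row-major alphabetical order: AA, AC, AD, ..., YY.
DIPEPTIDES = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
# column j (alphabetical) lives at PSI-BLAST position _ALPHA_TO_PSIBLAST[j]
_ALPHA_TO_PSIBLAST = np.array([PSIBLAST_COLUMNS.index(aa)
                               for aa in AMINO_ACIDS])

METHODS = ("AC", "DC", "PSSM", "HYBRID")
DIMENSIONS = {"AC": 20, "DC": 400, "PSSM": 400, "HYBRID": 420}


class ConfigurationError(RuntimeError):
    """A required external resource (profile, executable, path) is missing."""


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length composition encoding tagged by method."""

    method: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown feature method {self.method!r}")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (DIMENSIONS[self.method],):
            raise ValidationError(
                f"{self.method} vector must have length "
                f"{DIMENSIONS[self.method]}, got {v.shape}"
            )


@dataclass(frozen=True)
class PSSMProfile:
    """Per-position PSI-BLAST log-odds scores for one sequence.

    ``scores`` is an L x 20 integer matrix with columns in PSI-BLAST
    residue order (``ARNDCQEGHILKMFPSTWYV``); ``consensus`` is the
    query/consensus residue at each position.
    """

    sequence_id: str
    scores: np.ndarray
    consensus: str

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=int)
        object.__setattr__(self, "scores", s)
        if s.ndim != 2 or s.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.sequence_id!r} must be L x 20, got {s.shape}"
            )
        if len(self.consensus) != s.shape[0]:
            raise ValidationError(
                f"PSSM for {self.sequence_id!r}: consensus length "
                f"{len(self.consensus)} != row count {s.shape[0]}"
            )


def amino_acid_composition(seq: ProteinSequence) -> FeatureVector:
    """Fraction of each amino acid: count of residue i over sequence length."""
    counts = np.zeros(20)
    for ch in seq.residues:
        counts[_AA_INDEX[ch]] += 1
    return FeatureVector("AC", counts / len(seq))


def dipeptide_composition(seq: ProteinSequence) -> FeatureVector:
    """Fraction of each ordered adjacent pair over the L-1 windows."""
    if len(seq) < 2:
        raise ValidationError(
            f"sequence {seq.id!r} has length {len(seq)}; dipeptide "
            "composition needs length >= 2"
        )
    counts = np.zeros(400)
    r = seq.residues
    for a, b in zip(r, r[1:]):
        counts[20 * _AA_INDEX[a] + _AA_INDEX[b]] += 1
    return FeatureVector("DC", counts / (len(seq) - 1))


def hybrid_composition(seq: ProteinSequence) -> FeatureVector:
    """AC followed by DC, 420-dim."""
    ac = amino_acid_composition(seq).values
    dc = dipeptide_composition(seq).values
    return FeatureVector("HYBRID", np.concatenate([ac, dc]))


def pssm_composition(profile: PSSMProfile,
                     seq: ProteinSequence) -> FeatureVector:
    """Pool a per-position profile into a 400-dim composition vector.

    Each log-odds score s is normalised to sigma(s) = 1/(1+exp(-s));
    entry (a, b) is the sum of sigma(score at position p, column b) over
    positions p where the sequence residue is a, divided by the sequence
    length L.  Dividing by L (rather than per-residue counts) makes
    absent residues contribute exact zeros and keeps every entry in
    [0, 1].
    """
    if profile.scores.shape[0] != len(seq):
        raise ValidationError(
            f"profile for {profile.sequence_id!r} has "
            f"{profile.scores.shape[0]} rows but sequence {seq.id!r} has "
            f"length {len(seq)}"
        )
    sig = expit(profile.scores.astype(float))[:, _ALPHA_TO_PSIBLAST]
    out = np.zeros((20, 20))
    for p, ch in enumerate(seq.residues):
        out[_AA_INDEX[ch]] += sig[p]
    return FeatureVector("PSSM", out.ravel() / len(seq))


def parse_pssm(path: str | Path) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` dialect).

    Data rows carry a position index, the query residue, 20 log-odds
    integers and (usually) 20 weighted-percentage columns plus two
    trailing statistics; only the log-odds block is kept.
    """
    path = Path(path)
    rows: list[list[int]] = []
    consensus: list[str] = []
    expected_pos = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if len(tokens) < 2:
                if rows and not tokens:
                    break  # blank line after matrix: trailing statistics
                continue
            if not tokens[0].isdigit():
                continue  # header lines
            pos = int(tokens[0])
            if pos != expected_pos:
                continue  # numeric lines outside the matrix block
            if len(tokens[1]) != 1 or tokens[1] not in PSIBLAST_COLUMNS:
                raise ValidationError(
                    f"{path}:{lineno}: expected a residue code, "
                    f"got {tokens[1]!r}"
                )
            if len(tokens) < 22:
                raise ValidationError(
                    f"{path}:{lineno}: truncated PSSM row "
                    f"({len(tokens)} columns, need >= 22)"
                )
            try:
                rows.append([int(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer log-odds value ({exc})"
                ) from None
            consensus.append(tokens[1])
            expected_pos += 1
    if not rows:
        raise ValidationError(f"{path}: no PSSM matrix rows found")
    return PSSMProfile(sequence_id=path.stem, scores=np.array(rows, dtype=int),
                       consensus="".join(consensus))


def write_ascii_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect parse_pssm reads."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSIBLAST_COLUMNS) + "\n")
        for i, (res, row) in enumerate(zip(profile.consensus,
                                           profile.scores), 1):
            cells = " ".join(f"{v:3d}" for v in row)
            fh.write(f"{i:5d} {res}  {cells}\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")


def mock_pssm(seq: ProteinSequence, seed: int = 0) -> PSSMProfile:
    """Deterministic stand-in profile for offline testing.

    Base scores are uniform integers in [-5, 5] seeded from `seed` and
    the sequence content; the column of the sequence's own residue at
    each position gets +4, mimicking the self-conservation signal of a
    real profile.
    """
    key = zlib.crc32(f"{seq.id}:{seq.residues}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng((int(seed) & 0x7FFFFFFF, key))
    scores = rng.integers(-5, 6, size=(len(seq), 20))
    col_index = {aa: i for i, aa in enumerate(PSIBLAST_COLUMNS)}
    for p, ch in enumerate(seq.residues):
        scores[p, col_index[ch]] += 4
    return PSSMProfile(sequence_id=seq.id, scores=scores,
                       consensus=seq.residues)


def run_psiblast(seq: ProteinSequence, database: str,
                 executable: str = "psiblast", iterations: int = 3,
                 evalue: float = 0.001) -> PSSMProfile:
    """Shell out to PSI-BLAST and parse the resulting ASCII PSSM.

    Defaults follow common practice for profile construction: three
    iterations at an inclusion e-value of 0.001 against the given
    database (typically nr).
    """
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fasta"
        query.write_text(f">{seq.id}\n{seq.residues}\n")
        out_pssm = Path(tmp) / f"{seq.id}.pssm"
        cmd = [
            executable, "-query", str(query), "-db", database,
            "-num_iterations", str(iterations), "-evalue", str(evalue),
            "-out_ascii_pssm", str(out_pssm), "-out", str(Path(tmp) / "o"),
        ]
        try:
            subprocess.run(cmd, check=True, capture_output=True, text=True)
        except FileNotFoundError:
            raise ConfigurationError(
                f"PSI-BLAST executable {executable!r} not found; install "
                "BLAST+ or use mode='mock'/'precomputed'"
            ) from None
        except subprocess.CalledProcessError as exc:
            raise ConfigurationError(
                f"PSI-BLAST failed for {seq.id!r}: {exc.stderr.strip()}"
            ) from None
        if not out_pssm.exists():
            raise ConfigurationError(
                f"PSI-BLAST produced no PSSM for {seq.id!r} "
                "(no hits above inclusion threshold?)"
            )
        profile = parse_pssm(out_pssm)
    return PSSMProfile(sequence_id=seq.id, scores=profile.scores,
                       consensus=profile.consensus)


def pssm_provider(seq: ProteinSequence, mode: str = "mock", *,
                  profile_dir: str | Path | None = None,
                  database: str | None = None,
                  executable: str = "psiblast",
                  iterations: int = 3, evalue: float = 0.001,
                  seed: int = 0) -> PSSMProfile:
    """Obtain a PSSM profile for a sequence.

    Modes: ``precomputed`` looks up ``<profile_dir>/<id>.pssm``;
    ``external`` runs PSI-BLAST against `database`; ``mock`` builds a
    deterministic seeded profile so the full PSSM pipeline is testable
    offline.
    """
    if mode == "mock":
        return mock_pssm(seq, seed=seed)
    if mode == "precomputed":
        if profile_dir is None:
            raise ConfigurationError(
                "precomputed mode needs profile_dir=<directory of .pssm files>"
            )
        path = Path(profile_dir) / f"{seq.id}.pssm"
        if not path.exists():
            raise ConfigurationError(
                f"no precomputed profile for {seq.id!r}: {path} does not "
                "exist; generate it with PSI-BLAST or switch to mode='mock'"
            )
        prof = parse_pssm(path)
        return PSSMProfile(sequence_id=seq.id, scores=prof.scores,
                           consensus=prof.consensus)
    if mode == "external":
        if database is None:
            raise ConfigurationError(
                "external mode needs database=<path to BLAST database>"
            )
        return run_psiblast(seq, database, executable=executable,
                            iterations=iterations, evalue=evalue)
    raise ValueError(f"unknown pssm provider mode {mode!r}")


def encode(seq: ProteinSequence, method: str, *,
           profile: PSSMProfile | None = None,
           pssm_mode: str = "mock", pssm_seed: int = 0,
           profile_dir: str | Path | None = None,
           database: str | None = None) -> FeatureVector:
    """Encode one sequence with the given method.

    For PSSM, an explicit `profile` takes precedence; otherwise one is
    fetched through :func:`pssm_provider`.
    """
    if method == "AC":
        return amino_acid_composition(seq)
    if method == "DC":
        return dipeptide_composition(seq)
    if method == "HYBRID":
        return hybrid_composition(seq)
    if method == "PSSM":
        if profile is None:
            profile = pssm_provider(seq, mode=pssm_mode, seed=pssm_seed,
                                    profile_dir=profile_dir,
                                    database=database)
        return pssm_composition(profile, seq)
    raise ValidationError(f"unknown feature method {method!r}")


def encode_dataset(seqs: Sequence[ProteinSequence] | LabeledDataset,
                   method: str, **pssm_kwargs) -> np.ndarray:
    """Encode many sequences into an (n, d) feature matrix."""
    if isinstance(seqs, LabeledDataset):
        seqs = seqs.sequences
    return np.vstack([encode(s, method, **pssm_kwargs).values for s in seqs])


def write_feature_tsv(seqs: Sequence[ProteinSequence], matrix: np.ndarray,
                      method: str, path: str | Path) -> None:
    """Write an id + values feature table as TSV with a header row."""
    names = (list(AMINO_ACIDS) if method == "AC"
             else list(DIPEPTIDES) if method in ("DC", "PSSM")
             else list(AMINO_ACIDS) + list(DIPEPTIDES))
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for s, row in zip(seqs, matrix):
            fh.write(s.id + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_svmlight(matrix: np.ndarray, labels: Sequence[int],
                   path: str | Path) -> None:
    """Write features in SVM-light sparse format: label index:value ..."""
    with open(path, "w") as fh:
        for y, row in zip(labels, matrix):
            cells = " ".join(f"{i + 1}:{v:.6g}"
                             for i, v in enumerate(row) if v != 0)
            fh.write(f"{int(y):+d} {cells}\n")
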