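"""Protein sequence I/O, validation, statistics and redundancy reduction.

FASTA reading/writing goes through Biopython's ``SeqIO``; everything on
top (validation policies, a CD-HIT-style greedy identity filter, basic
physicochemical statistics) is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical by one-letter code.  All
#: feature encodings in this package index residues in this order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Mapping applied under the ``map`` validation policy: common ambiguity
#: and non-standard codes are replaced by the nearest standard residue
#: (B -> Asp, Z -> Glu, U selenocysteine -> Cys, J -> Leu,
#: O pyrrolysine -> Lys); fully unknown X is dropped.
AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C", "J": "L", "O": "K"}

#: Average (not monoisotopic) residue masses in daltons, Expasy values.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.0153


class ValidationError(ValueError):
    """Raised when a sequence or dataset violates an invariant."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    Parameters
    ----------
    id : str
        Accession-like identifier (first whitespace-delimited header
        token in FASTA).
    residues : str
        Sequence over the 20 standard one-letter codes.
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has empty body")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-standard residues "
                f"{sorted(bad)}; run validate_sequence first"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SeqStats:
    """Basic per-sequence statistics: mass, counts and composition."""

    molecular_weight: float
    residue_counts: dict[str, int]
    composition_percent: dict[str, float]


VALID_LABELS = ("SAK", "SK", "tPA", "UK", "NEG")
POSITIVE_LABELS = ("SAK", "SK", "tPA", "UK")


@dataclass
class LabeledDataset:
    """Sequences with one subfamily/negative label each.

    Labels are drawn from ``{SAK, SK, tPA, UK, NEG}``; NEG marks
    non-activator sequences.
    """

    sequences: list[ProteinSequence]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValidationError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        for lab in self.labels:
            if lab not in VALID_LABELS:
                raise ValidationError(
                    f"label {lab!r} not in {VALID_LABELS}"
                )
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValidationError(f"duplicate sequence id {dup!r} in dataset")

    def __len__(self) -> int:
        return len(self.sequences)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.sequences[i] for i in indices],
            [self.labels[i] for i in indices],
        )


def validate_sequence(raw: str, policy: str = "map") -> str:
    """Normalise a raw residue string to the 20-letter alphabet.

    Policies
    --------
    ``strict``
        Any character outside the standard alphabet raises.
    ``drop``
        Offending characters are silently removed.
    ``map``
        Ambiguity codes are resolved (B->D, Z->E, U->C, J->L, O->K) and
        X is dropped; anything else raises.
    """
    if not raw:
        raise ValidationError("empty sequence")
    up = raw.upper()
    if policy == "strict":
        for pos, ch in enumerate(up):
            if ch not in _AA_SET:
                raise ValidationError(
                    f"non-standard residue {ch!r} at position {pos}"
                )
        return up
    if policy == "drop":
        out = "".join(ch for ch in up if ch in _AA_SET)
    elif policy == "map":
        chars = []
        for pos, ch in enumerate(up):
            if ch in _AA_SET:
                chars.append(ch)
            elif ch in AMBIGUITY_MAP:
                chars.append(AMBIGUITY_MAP[ch])
            elif ch == "X":
                continue
            else:
                raise ValidationError(
                    f"unmappable character {ch!r} at position {pos}"
                )
        out = "".join(chars)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if not out:
        raise ValidationError("sequence empty after filtering")
    return out


def read_fasta(path: str | Path, policy: str = "map") -> list[ProteinSequence]:
    """Read a (multi-record) FASTA file into validated sequences.

    The header token before the first whitespace becomes the id; the
    remainder is kept as the description.  Residues are normalised with
    :func:`validate_sequence` under `policy`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    out: list[ProteinSequence] = []
    for rec in records:
        body = str(rec.seq)
        if not body:
            raise ValidationError(f"record {rec.id!r} in {path} has empty body")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(
            ProteinSequence(
                id=rec.id,
                residues=validate_sequence(body, policy=policy),
                description=desc,
            )
        )
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                width: int = 60) -> None:
    """Write sequences as FASTA, wrapping bodies at `width` columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sequence id, label) into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            out[parts[0]] = parts[1]
    return out


def write_manifest(dataset: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq, lab in zip(dataset.sequences, dataset.labels):
            fh.write(f"{seq.id}\t{lab}\n")


def load_dataset(fasta_path: str | Path, manifest_path: str | Path,
                 policy: str = "map") -> LabeledDataset:
    """Assemble a labelled dataset from a FASTA file and a label manifest.

    Every sequence must have a label; an id present in the manifest but
    missing from the FASTA is ignored.
    """
    seqs = read_fasta(fasta_path, policy=policy)
    manifest = read_manifest(manifest_path)
    labels = []
    for s in seqs:
        if s.id not in manifest:
            raise ValidationError(f"no label for sequence id {s.id!r}")
        labels.append(manifest[s.id])
    return LabeledDataset(seqs, labels)


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped identity between two sequences.

    The shorter sequence is slid along the longer one; at each offset the
    number of exact matches is counted, and the best offset's match count
    is divided by the shorter length (CD-HIT's denominator convention).
    """
    if len(a) > len(b):
        a, b = b, a
    sa = np.frombuffer(a.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.encode(), dtype=np.uint8)
    la, lb = len(sa), len(sb)
    best = 0
    for off in range(lb - la + 1):
        m = int(np.count_nonzero(sa == sb[off:off + la]))
        if m > best:
            best = m
            if best == la:
                break
    return best / la


def reduce_redundancy(seqs: Sequence[ProteinSequence],
                      identity_threshold: float = 0.90,
                      ) -> list[ProteinSequence]:
    """Greedy redundancy filter in the style of CD-HIT.

    Sequences are sorted longest first; each sequence is compared against
    the representatives retained so far and discarded if its pairwise
    identity with any of them reaches `identity_threshold`, otherwise it
    becomes a new representative.  The boundary is inclusive (CD-HIT's
    convention), so a threshold of 1.0 removes exactly the duplicates.
    The returned representatives keep the length-rank order.
    """
    if not 0 < identity_threshold <= 1:
        raise ValidationError("identity threshold must be in (0, 1]")
    ordered = sorted(seqs, key=lambda s: -len(s))
    reps: list[ProteinSequence] = []
    for s in ordered:
        for r in reps:
            if pairwise_identity(s.residues,
                                 r.residues) >= identity_threshold:
                break
        else:
            reps.append(s)
    return reps


def compute_stats(seq: ProteinSequence) -> SeqStats:
    """Molecular weight, residue counts and percent composition.

    Molecular weight is the sum of average residue masses plus one water
    (18.0153 Da) for the free termini.
    """
    counts = {aa: seq.residues.count(aa) for aa in AMINO_ACIDS}
    n = len(seq)
    mw = sum(RESIDUE_MASS[aa] * c for aa, c in counts.items()) + WATER_MASS
    comp = {aa: 100.0 * c / n for aa, c in counts.items()}
    return SeqStats(molecular_weight=mw, residue_counts=counts,
                    composition_percent=comp)
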