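"""Seeded synthetic protein families with controllable composition.

Real plasminogen-activator training data comes from curated sequence
databases and cannot be bundled; this module generates a stand-in
benchmark whose compositional structure mimics what is observed in the
real families: the prokaryotic activators (SAK, SK) are cysteine- and
tryptophan-free and lysine-rich, the eukaryotic ones (tPA, UK) contain
Cys/Trp and elevated Ala/Gly/Arg, and the negative class follows
background database-like residue frequencies.  Class sizes default to
the real dataset's (69 SAK, 167 SK, 11 tPA, 109 UK, 501 negatives) so
the severe tPA imbalance is exercised by everything downstream.

Sequences are drawn i.i.d. from a per-family residue distribution, or
from a first-order Markov chain when a transition matrix is given
(yielding a dipeptide signal beyond composition alone).  These are
compositional nulls, not evolved proteins: there is no homology, domain
structure or substitution model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .seqio import AMINO_ACIDS, LabeledDataset, ProteinSequence

#: SwissProt-like background residue frequencies, percent.
BACKGROUND_PERCENT = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.74, "G": 7.07, "H": 2.27, "I": 5.93,
    "L": 9.65, "K": 5.82, "M": 2.41, "F": 3.86, "P": 4.72,
    "S": 6.60, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.87,
}

#: Class sizes of the default benchmark (positives 69+167+11+109 = 356,
#: negatives 501).
DEFAULT_COUNTS = {"SAK": 69, "SK": 167, "tPA": 11, "UK": 109, "NEG": 501}


@dataclass(frozen=True)
class FamilyProfile:
    """Compositional recipe for one synthetic family."""

    name: str
    residue_probs: np.ndarray  # 20 probabilities, alphabetical order
    length_range: tuple[int, int]
    transition_matrix: np.ndarray | None = None  # 20x20 row-stochastic

    def __post_init__(self) -> None:
        p = np.asarray(self.residue_probs, dtype=float)
        object.__setattr__(self, "residue_probs", p)
        if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ValueError(
                f"profile {self.name!r}: residue_probs must be 20 "
                "non-negative values summing to 1"
            )
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError(
                f"profile {self.name!r}: length_range must satisfy "
                "2 <= min <= max"
            )
        if self.transition_matrix is not None:
            t = np.asarray(self.transition_matrix, dtype=float)
            object.__setattr__(self, "transition_matrix", t)
            if (t.shape != (20, 20) or np.any(t < 0)
                    or np.max(np.abs(t.sum(axis=1) - 1)) > 1e-9):
                raise ValueError(
                    f"profile {self.name!r}: transition matrix must be "
                    "20x20 row-stochastic"
                )


def _probs_from_percent(percent: Mapping[str, float],
                        overrides: Mapping[str, float] | None = None,
                        ) -> np.ndarray:
    """Build a probability vector, rescaling non-overridden residues so
    the total stays at 100%."""
    base = dict(percent)
    if overrides:
        fixed = sum(overrides.values())
        free = [aa for aa in AMINO_ACIDS if aa not in overrides]
        if free:
            free_total = sum(base[aa] for aa in free)
            scale = (100.0 - fixed) / free_total
            for aa in free:
                base[aa] *= scale
        base.update(overrides)
    p = np.array([base[aa] for aa in AMINO_ACIDS], dtype=float)
    return p / p.sum()


def succ_transition(probs: np.ndarray, boost: float) -> np.ndarray:
    """A row-stochastic matrix biased toward the alphabetical successor.

    Row for residue i is the family distribution with the probability of
    residue (i+1) mod 20 multiplied by (1 + boost), renormalised — a
    cheap way to plant a dipeptide-order signal on top of a composition.
    """
    t = np.tile(probs, (20, 1))
    for i in range(20):
        t[i, (i + 1) % 20] *= 1.0 + boost
        s = t[i].sum()
        if s > 0:
            t[i] /= s
    return t


def default_profiles() -> dict[str, FamilyProfile]:
    """The five shipped family profiles.

    SAK/SK: no Cys or Trp, strongly elevated Lys (plus family-specific
    shifts in Asn/Tyr for SAK and Glu/Asp/Ile for SK; SK additionally
    carries a Markov dipeptide signal).  tPA/UK: Cys and Trp present,
    elevated Ala/Gly/Arg (tPA) or Ser/Gly/Thr (UK).  NEG: background
    frequencies.  Length ranges bracket the real proteins (SAK ~136,
    SK ~414, tPA ~530, UK ~411 residues).
    """
    sak = _probs_from_percent(BACKGROUND_PERCENT, {
        "C": 0.0, "W": 0.0, "K": 15.0, "N": 7.5, "Y": 5.5})
    sk = _probs_from_percent(BACKGROUND_PERCENT, {
        "C": 0.0, "W": 0.0, "K": 12.0, "E": 10.0, "I": 8.0, "D": 7.5})
    tpa = _probs_from_percent(BACKGROUND_PERCENT, {
        "C": 4.0, "W": 2.5, "A": 11.5, "G": 10.5, "R": 8.5})
    uk = _probs_from_percent(BACKGROUND_PERCENT, {
        "C": 3.5, "W": 1.8, "S": 10.5, "G": 9.5, "T": 8.0, "D": 7.0})
    neg = _probs_from_percent(BACKGROUND_PERCENT)
    return {
        "SAK": FamilyProfile("SAK", sak, (120, 150)),
        "SK": FamilyProfile("SK", sk, (390, 440),
                            transition_matrix=succ_transition(sk, 4.0)),
        "tPA": FamilyProfile("tPA", tpa, (500, 560)),
        "UK": FamilyProfile("UK", uk, (380, 430)),
        "NEG": FamilyProfile("NEG", neg, (80, 600)),
    }


def sample_family(profile: FamilyProfile, n: int,
                  seed: int | np.random.SeedSequence | np.random.Generator,
                  ) -> list[ProteinSequence]:
    """Draw n sequences from a family profile, reproducibly from seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo, hi = profile.length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    out: list[ProteinSequence] = []
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    if profile.transition_matrix is not None:
        cum = np.cumsum(profile.transition_matrix, axis=1)
    for i, L in enumerate(lengths):
        L = int(L)
        if profile.transition_matrix is None:
            idx = rng.choice(20, size=L, p=profile.residue_probs)
        else:
            idx = np.empty(L, dtype=int)
            idx[0] = rng.choice(20, p=profile.residue_probs)
            u = rng.random(L - 1)
            for p in range(1, L):
                idx[p] = np.searchsorted(cum[idx[p - 1]], u[p - 1],
                                         side="right")
        residues = aa[idx].tobytes().decode()
        out.append(ProteinSequence(
            id=f"{profile.name}_{i:04d}", residues=residues,
            description=f"synthetic {profile.name} family member"))
    return out


def benchmark(profiles: Mapping[str, FamilyProfile],
              counts: Mapping[str, int], seed: int = 0) -> LabeledDataset:
    """Sample a labelled dataset with the given per-family counts."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(counts))
    seqs: list[ProteinSequence] = []
    labels: list[str] = []
    for (name, n), child in zip(counts.items(), children):
        fam = sample_family(profiles[name], n, child)
        seqs.extend(fam)
        labels.extend([name] * n)
    return LabeledDataset(seqs, labels)


def default_benchmark(seed: int = 0) -> LabeledDataset:
    """The standard synthetic benchmark: real-data class sizes with the
    shipped family profiles (356 activators + 501 negatives)."""
    return benchmark(default_profiles(), DEFAULT_COUNTS, seed=seed)


def load_profiles(path: str | Path,
                  ) -> tuple[dict[str, FamilyProfile], dict[str, int]]:
    """Read family profiles (and optional per-family counts) from YAML.

    Each top-level key is a family name mapping to::

        length_range: [min, max]
        residue_percent: {A: 8.25, C: 0.0, ...}   # omitted residues get
                                                  # rescaled background
        succ_boost: 4.0        # optional Markov dipeptide signal
        n: 167                 # optional sample count

    Returns (profiles, counts); counts fall back to the defaults for
    families that do not specify ``n``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    profiles: dict[str, FamilyProfile] = {}
    counts: dict[str, int] = {}
    for name, spec in raw.items():
        probs = _probs_from_percent(BACKGROUND_PERCENT,
                                    spec.get("residue_percent"))
        trans = None
        if spec.get("succ_boost"):
            trans = succ_transition(probs, float(spec["succ_boost"]))
        profiles[name] = FamilyProfile(
            name=name, residue_probs=probs,
            length_range=tuple(spec["length_range"]),
            transition_matrix=trans)
        counts[name] = int(spec.get("n", DEFAULT_COUNTS.get(name, 100)))
    return profiles, counts


def dump_default_profiles(path: str | Path) -> None:
    """Write the default profiles as an editable YAML config."""
    profs = default_profiles()
    doc = {}
    for name, prof in profs.items():
        doc[name] = {
            "length_range": [int(prof.length_range[0]),
                             int(prof.length_range[1])],
            "residue_percent": {
                aa: round(float(100 * p), 4)
                for aa, p in zip(AMINO_ACIDS, prof.residue_probs)},
            "n": DEFAULT_COUNTS[name],
        }
        if name == "SK":
            doc[name]["succ_boost"] = 4.0
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
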