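"""RBF-SVM training and two-stage hierarchical prediction.

The classifier is hierarchical, mirroring how the prediction problem is
posed: a level-1 gate decides whether a sequence is a plasminogen
activator at all (all four subfamilies pooled as positives against the
negative set), and four one-vs-rest subclass models — each trained with
one subfamily as positive and the other three as negatives, the
non-activator set excluded — assign gated sequences to SAK, SK, tPA or
UK by argmax of decision score.

The modelling surface follows the fit/results idiom:
:class:`PgActivatorModel` holds the data and configuration,
``fit()`` returns a :class:`PgActivatorResults` carrying the trained
bundle, training diagnostics, ``predict`` and ``summary``.

Kernel parameterisation is K(x, y) = exp(-gamma * ||x - y||^2), the
SVM-light convention, so the shipped per-model (gamma, C) defaults are
directly meaningful.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .seqio import (
    LabeledDataset,
    POSITIVE_LABELS,
    ProteinSequence,
    ValidationError,
)
from .features import (
    AMINO_ACIDS,
    DIPEPTIDES,
    DIMENSIONS,
    METHODS,
    FeatureVector,
    PSSMProfile,
    encode,
    encode_dataset,
)

LEVEL1 = "LEVEL1"

#: Optimised (gamma, C) per encoding for the activator-vs-non gate.
DEFAULT_LEVEL1_PARAMS: dict[str, tuple[float, float]] = {
    "AC": (25, 450), "DC": (3, 375), "PSSM": (3, 400), "HYBRID": (1, 450),
}

#: Optimised (gamma, C) per subfamily and encoding for the one-vs-rest
#: subclass models.
DEFAULT_SUBCLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "SAK": {"AC": (3, 300), "DC": (3, 75), "PSSM": (1, 300),
            "HYBRID": (1, 150)},
    "SK": {"AC": (3, 275), "DC": (10, 25), "PSSM": (1, 400),
           "HYBRID": (1, 250)},
    "tPA": {"AC": (50, 100), "DC": (15, 450), "PSSM": (4, 200),
            "HYBRID": (10, 450)},
    "UK": {"AC": (3, 300), "DC": (15, 500), "PSSM": (5, 9),
           "HYBRID": (1, 450)},
}

SUBCLASS_ORDER = ("SAK", "SK", "tPA", "UK")  # also the argmax tie order


def default_params(method: str) -> dict[str, tuple[float, float]]:
    """The shipped (gamma, C) defaults for all five models of a method."""
    out = {LEVEL1: DEFAULT_LEVEL1_PARAMS[method]}
    for sub in SUBCLASS_ORDER:
        out[sub] = DEFAULT_SUBCLASS_PARAMS[sub][method]
    return out


def feature_checksum(method: str) -> str:
    """Checksum of the feature ordering contract for bundle manifests."""
    spec = f"{method}|{AMINO_ACIDS}|{''.join(DIPEPTIDES)}"
    return f"{zlib.crc32(spec.encode()):08x}"


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters tied to a feature method."""

    gamma: float
    cost: float
    feature_method: str
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValidationError("gamma and cost must be positive")
        if self.feature_method not in METHODS:
            raise ValidationError(
                f"unknown feature method {self.feature_method!r}"
            )


@dataclass
class TrainedModel:
    """A fitted binary RBF-SVM with its configuration."""

    config: SVMConfig
    positive_class: str
    classifier: SVC

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Signed decision scores; positive side is the positive class."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != DIMENSIONS[self.config.feature_method]:
            raise ValidationError(
                f"model expects {DIMENSIONS[self.config.feature_method]}-dim "
                f"{self.config.feature_method} features, got {X.shape[1]}"
            )
        return self.classifier.decision_function(X)


@dataclass(frozen=True)
class PredictionResult:
    """Two-stage prediction outcome for one sequence.

    ``subclass_scores`` and ``subclass_call`` are populated only when
    the level-1 call is PG.
    """

    sequence_id: str
    level1_score: float
    level1_call: str  # "PG" | "NON_PG"
    subclass_scores: dict[str, float]
    subclass_call: str | None
    threshold: float

    def to_dict(self) -> dict:
        d = {"sequence_id": self.sequence_id,
             "level1_score": self.level1_score,
             "level1_call": self.level1_call,
             "threshold": self.threshold,
             "subclass_call": self.subclass_call}
        for sub in SUBCLASS_ORDER:
            d[f"score_{sub}"] = self.subclass_scores.get(sub)
        return d


def train(features: Sequence[FeatureVector] | np.ndarray,
          labels: Sequence[int], config: SVMConfig,
          positive_class: str = "+1") -> TrainedModel:
    """Fit a soft-margin RBF SVM on +/-1-labelled feature vectors."""
    if isinstance(features, np.ndarray):
        X = np.atleast_2d(features)
    else:
        methods = {f.method for f in features}
        if len(methods) > 1:
            raise ValidationError(f"mixed feature methods: {sorted(methods)}")
        if methods and methods != {config.feature_method}:
            raise ValidationError(
                f"features are {methods.pop()} but config says "
                f"{config.feature_method}"
            )
        X = np.vstack([f.values for f in features])
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValidationError(
            "training needs at least one example of each class"
        )
    clf = SVC(kernel="rbf", gamma=config.gamma, C=config.cost)
    clf.fit(X, y)
    return TrainedModel(config=config, positive_class=positive_class,
                        classifier=clf)


class PgActivatorModel:
    """Hierarchical plasminogen-activator classifier specification.

    Parameters
    ----------
    dataset : LabeledDataset
        Training sequences labelled SAK/SK/tPA/UK/NEG.
    method : str
        Feature encoding: AC, DC, PSSM or HYBRID.
    params : mapping, optional
        ``{model name: (gamma, C)}`` for LEVEL1 and each subclass;
        missing entries fall back to the shipped defaults.
    pssm_mode, pssm_seed, profile_dir, database
        PSSM acquisition settings, used only when ``method == "PSSM"``.
    """

    def __init__(self, dataset: LabeledDataset, method: str = "DC", *,
                 params: Mapping[str, tuple[float, float]] | None = None,
                 pssm_mode: str = "mock", pssm_seed: int = 0,
                 profile_dir: str | Path | None = None,
                 database: str | None = None) -> None:
        if method not in METHODS:
            raise ValidationError(f"unknown feature method {method!r}")
        self.dataset = dataset
        self.method = method
        self.params = dict(default_params(method))
        if params:
            self.params.update(params)
        self.pssm_kwargs = dict(pssm_mode=pssm_mode, pssm_seed=pssm_seed,
                                profile_dir=profile_dir, database=database)

    @classmethod
    def from_files(cls, fasta_path: str | Path, manifest_path: str | Path,
                   method: str = "DC", **kwargs) -> "PgActivatorModel":
        from .seqio import load_dataset
        return cls(load_dataset(fasta_path, manifest_path), method, **kwargs)

    def fit(self) -> "PgActivatorResults":
        """Train the level-1 gate and the four one-vs-rest subclass models."""
        ds = self.dataset
        labels = np.array(ds.labels)
        if "NEG" not in labels:
            raise ValidationError("dataset has no NEG examples for level 1")
        if not any(lab in labels for lab in POSITIVE_LABELS):
            raise ValidationError("dataset has no positive examples")
        X = encode_dataset(ds, self.method, **self.pssm_kwargs)

        models: dict[str, TrainedModel] = {}
        train_acc: dict[str, float] = {}
        train_n: dict[str, tuple[int, int]] = {}

        def _fit(name: str, mask_pos: np.ndarray, mask_neg: np.ndarray):
            gamma, cost = self.params[name]
            cfg = SVMConfig(gamma=gamma, cost=cost,
                            feature_method=self.method)
            sel = mask_pos | mask_neg
            y = np.where(mask_pos[sel], 1, -1)
            m = train(X[sel], y, cfg, positive_class=name)
            models[name] = m
            scores = m.decision(X[sel])
            train_acc[name] = float(np.mean(np.sign(scores) == y))
            train_n[name] = (int(mask_pos.sum()), int(mask_neg.sum()))

        is_pos = np.isin(labels, POSITIVE_LABELS)
        _fit(LEVEL1, is_pos, labels == "NEG")
        for sub in SUBCLASS_ORDER:
            mask_pos = labels == sub
            if not mask_pos.any():
                warnings.warn(
                    f"subclass {sub} absent from training data; its "
                    "one-vs-rest model is skipped", stacklevel=2)
                continue
            mask_neg = is_pos & ~mask_pos  # NEG excluded at level 2
            _fit(sub, mask_pos, mask_neg)

        return PgActivatorResults(
            method=self.method, models=models, params=dict(self.params),
            pssm_kwargs=dict(self.pssm_kwargs),
            training_accuracy=train_acc, training_counts=train_n,
            n_training=len(ds),
        )


@dataclass
class PgActivatorResults:
    """A fitted hierarchical classifier bundle.

    Carries the five trained SVMs (level-1 gate plus one-vs-rest
    subclass models), their hyperparameters, training diagnostics, and
    the prediction, persistence and reporting methods.
    """

    method: str
    models: dict[str, TrainedModel]
    params: dict[str, tuple[float, float]]
    pssm_kwargs: dict = field(default_factory=dict)
    training_accuracy: dict[str, float] = field(default_factory=dict)
    training_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_training: int = 0

    @property
    def subclasses(self) -> tuple[str, ...]:
        return tuple(s for s in SUBCLASS_ORDER if s in self.models)

    # -- prediction ----------------------------------------------------

    def decision_scores(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Raw decision scores of every model on an encoded matrix."""
        return {name: m.decision(X) for name, m in self.models.items()}

    def predict(self, seqs: Sequence[ProteinSequence],
                threshold: float = 0.0, *,
                profiles: Mapping[str, PSSMProfile] | None = None,
                ) -> list[PredictionResult]:
        """Two-stage prediction for a batch of sequences.

        A sequence is called PG when its level-1 score is >= `threshold`
        (default 0, the SVM margin); only then are the subclass scores
        computed and the argmax subfamily assigned, ties broken in the
        fixed order SAK < SK < tPA < UK.
        """
        kw = dict(self.pssm_kwargs)
        rows = []
        for s in seqs:
            prof = profiles.get(s.id) if profiles else None
            rows.append(encode(s, self.method, profile=prof, **{
                k: v for k, v in kw.items()
                if k in ("pssm_mode", "pssm_seed", "profile_dir", "database")
            }).values)
        X = np.vstack(rows)
        l1 = self.models[LEVEL1].decision(X)
        out: list[PredictionResult] = []
        for i, s in enumerate(seqs):
            score = float(l1[i])
            if score >= threshold:
                sub_scores = {
                    sub: float(self.models[sub].decision(X[i:i + 1])[0])
                    for sub in self.subclasses
                }
                call = None
                best = -math.inf
                for sub in SUBCLASS_ORDER:  # fixed tie order
                    if sub in sub_scores and sub_scores[sub] > best:
                        best = sub_scores[sub]
                        call = sub
                out.append(PredictionResult(
                    sequence_id=s.id, level1_score=score, level1_call="PG",
                    subclass_scores=sub_scores, subclass_call=call,
                    threshold=threshold))
            else:
                out.append(PredictionResult(
                    sequence_id=s.id, level1_score=score,
                    level1_call="NON_PG", subclass_scores={},
                    subclass_call=None, threshold=threshold))
        return out

    def predict_frame(self, seqs: Sequence[ProteinSequence],
                      threshold: float = 0.0, **kwargs):
        """Prediction results as a pandas DataFrame (one row per input)."""
        import pandas as pd

        return pd.DataFrame(
            [r.to_dict() for r in self.predict(seqs, threshold, **kwargs)]
        )

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Serialise as a bundle directory: one joblib file per model
        plus a JSON manifest recording the feature method, the ordering
        checksum and every model's hyperparameters."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "plaspred-bundle-v1",
            "method": self.method,
            "feature_checksum": feature_checksum(self.method),
            "n_training": self.n_training,
            "pssm": {k: (str(v) if isinstance(v, Path) else v)
                     for k, v in self.pssm_kwargs.items()},
            "models": {},
        }
        for name, m in self.models.items():
            fname = f"{name}.joblib"
            joblib.dump(m.classifier, directory / fname)
            manifest["models"][name] = {
                "file": fname,
                "gamma": m.config.gamma,
                "cost": m.config.cost,
                "positive_class": m.positive_class,
                "training_accuracy": self.training_accuracy.get(name),
                "n_pos": self.training_counts.get(name, (None, None))[0],
                "n_neg": self.training_counts.get(name, (None, None))[1],
            }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "PgActivatorResults":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        method = manifest["method"]
        if manifest["feature_checksum"] != feature_checksum(method):
            raise ValidationError(
                "bundle feature ordering does not match this library "
                "version; refusing to predict with mismatched features"
            )
        models: dict[str, TrainedModel] = {}
        params: dict[str, tuple[float, float]] = {}
        acc: dict[str, float] = {}
        counts: dict[str, tuple[int, int]] = {}
        for name, meta in manifest["models"].items():
            clf = joblib.load(directory / meta["file"])
            cfg = SVMConfig(gamma=meta["gamma"], cost=meta["cost"],
                            feature_method=method)
            models[name] = TrainedModel(config=cfg,
                                        positive_class=meta["positive_class"],
                                        classifier=clf)
            params[name] = (meta["gamma"], meta["cost"])
            if meta.get("training_accuracy") is not None:
                acc[name] = meta["training_accuracy"]
            counts[name] = (meta.get("n_pos"), meta.get("n_neg"))
        return cls(method=method, models=models, params=params,
                   pssm_kwargs=manifest.get("pssm", {}),
                   training_accuracy=acc, training_counts=counts,
                   n_training=manifest.get("n_training", 0))

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fitted bundle."""
        lines = [
            "Plasminogen-activator SVM bundle",
            "=" * 64,
            f"feature method: {self.method}   "
            f"dimension: {DIMENSIONS[self.method]}   "
            f"training sequences: {self.n_training}",
            "-" * 64,
            f"{'model':<8}{'gamma':>8}{'C':>8}{'n_pos':>8}{'n_neg':>8}"
            f"{'train acc':>12}",
        ]
        for name in (LEVEL1,) + tuple(SUBCLASS_ORDER):
            if name not in self.models:
                continue
            g, c = self.params[name]
            npos, nneg = self.training_counts.get(name, ("", ""))
            a = self.training_accuracy.get(name)
            acc = f"{100 * a:.2f}%" if a is not None else ""
            lines.append(
                f"{name:<8}{g:>8g}{c:>8g}{npos:>8}{nneg:>8}{acc:>12}")
        lines.append("=" * 64)
        return "\n".join(lines)


def train_suite(dataset: LabeledDataset, method: str = "DC",
                params: Mapping[str, tuple[float, float]] | None = None,
                **pssm_kwargs) -> PgActivatorResults:
    """Train the five-model bundle (functional wrapper over the class)."""
    return PgActivatorModel(dataset, method, params=params,
                            **pssm_kwargs).fit()


def predict(bundle: PgActivatorResults, seq: ProteinSequence,
            threshold: float = 0.0, *,
            profile: PSSMProfile | None = None) -> PredictionResult:
    """Two-stage prediction for a single sequence."""
    profiles = {seq.id: profile} if profile is not None else None
    return bundle.predict([seq], threshold=threshold, profiles=profiles)[0]
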