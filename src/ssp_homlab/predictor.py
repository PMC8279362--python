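"""Windowed-feature SSP predictor: bootstrapped voting ensembles.

Every residue is encoded from a 5-residue window; each window slot carries
the 20 profile probabilities, a 20-dim amino-acid one-hot and a terminus
pad flag (41 values, 205 features in total for the default window).  The
model is a "random forest" in the loose sense: ``n_members`` base learners
(neural network, decision tree or support-vector machine), each trained on
a bootstrap resample of residues and a random subset of features, combining
predictions by majority vote with ties broken toward coil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .profile import ProfileMatrix
from .seq import LabeledSequence

WINDOW_DEFAULT = 5
SLOT_WIDTH = 41  # 20 profile probs + 20 one-hot + 1 pad flag

BASE_LEARNERS = ("neural-network", "decision-tree", "support-vector")


def encode_features(
    seq: LabeledSequence, profile: ProfileMatrix, window: int = WINDOW_DEFAULT
) -> np.ndarray:
    """Per-residue feature matrix of shape (L, window * 41)."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be odd and positive")
    if profile.length != seq.length:
        raise ValueError(
            f"profile length {profile.length} != sequence length {seq.length}"
        )
    length = seq.length
    half = window // 2
    # float32: what the tree/net backends use internally, at half the
    # memory traffic; probabilities and one-hots lose nothing.
    slot = np.zeros((length, SLOT_WIDTH), dtype=np.float32)
    slot[:, :20] = profile.probs
    slot[np.arange(length), 20 + seq.codes] = 1.0
    padded = np.zeros((length + 2 * half, SLOT_WIDTH), dtype=np.float32)
    padded[:, 40] = 1.0  # pad flag everywhere, overwritten by real slots
    padded[half:half + length] = slot
    out = np.empty((length, window * SLOT_WIDTH), dtype=np.float32)
    for w in range(window):
        out[:, w * SLOT_WIDTH:(w + 1) * SLOT_WIDTH] = padded[w:w + length]
    return out


@dataclass
class EnsembleConfig:
    """Training-time knobs of the voting ensemble."""

    base_learner: str = "neural-network"
    n_members: int = 60
    sample_fraction: float = 1.0
    bootstrap: bool = True
    feature_fraction: float = 0.7
    hidden_units: int = 30
    max_iter: int = 200
    dt_max_depth: Optional[int] = 12
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.base_learner not in BASE_LEARNERS:
            raise ValueError(f"unknown base learner {self.base_learner!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0 < self.sample_fraction <= 1 or not 0 < self.feature_fraction <= 1:
            raise ValueError("sample and feature fractions must be in (0, 1]")


def make_base_learner(config: EnsembleConfig, seed: int):
    if config.base_learner == "neural-network":
        return MLPClassifier(
            hidden_layer_sizes=(config.hidden_units,),
            max_iter=config.max_iter,
            early_stopping=True,
            n_iter_no_change=5,
            random_state=seed,
        )
    if config.base_learner == "decision-tree":
        return DecisionTreeClassifier(max_depth=config.dt_max_depth, random_state=seed)
    return SVC(C=config.svm_c, kernel="rbf", random_state=seed)


@dataclass
class EnsembleModel:
    """Trained voting ensemble; members carry their feature subsets."""

    config: EnsembleConfig
    classes: tuple
    n_features: int
    members: list = field(default_factory=list)          # fitted estimators
    feature_subsets: list = field(default_factory=list)  # column indices per member
    member_seeds: list = field(default_factory=list)
    member_weights: list = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "EnsembleModel":
        return joblib.load(path)


def train_ensemble(
    features: np.ndarray,
    labels: Sequence[str],
    config: Optional[EnsembleConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> EnsembleModel:
    """Train the bootstrapped ensemble; deterministic given the generator."""
    config = config or EnsembleConfig()
    rng = rng or np.random.default_rng(0)
    X = np.asarray(features)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training set is degenerate: a single class present")
    n, d = X.shape
    n_feat = max(1, int(round(config.feature_fraction * d)))
    n_rows = max(1, int(round(config.sample_fraction * n)))
    model = EnsembleModel(config=config, classes=classes, n_features=d)
    for _ in range(config.n_members):
        seed = int(rng.integers(2**31 - 1))
        cols = (
            np.arange(d)
            if n_feat == d
            else np.sort(rng.choice(d, size=n_feat, replace=False))
        )
        if config.bootstrap:
            rows = rng.integers(0, n, size=n_rows)
        else:
            rows = (
                np.arange(n)
                if n_rows == n
                else rng.choice(n, size=n_rows, replace=False)
            )
        if len(set(y[rows])) < 2:  # resample once if a draw is degenerate
            rows = rng.integers(0, n, size=n_rows) if config.bootstrap else rows
        learner = make_base_learner(config, seed)
        learner.fit(X[rows][:, cols], y[rows])
        model.members.append(learner)
        model.feature_subsets.append(cols)
        model.member_seeds.append(seed)
        model.member_weights.append(1.0)
    return model


def _vote(model: EnsembleModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted vote counts (n_samples, n_classes) and the class order."""
    classes = np.asarray(model.classes)
    class_index = {c: i for i, c in enumerate(model.classes)}
    votes = np.zeros((X.shape[0], len(classes)))
    for learner, cols, weight in zip(
        model.members, model.feature_subsets, model.member_weights
    ):
        pred = learner.predict(X[:, cols])
        idx = np.fromiter((class_index[p] for p in pred), dtype=int, count=len(pred))
        votes[np.arange(len(pred)), idx] += weight
    return votes, classes


def predict(model: EnsembleModel, features: np.ndarray) -> str:
    """Majority-vote labels as a string; ties break toward coil (C)."""
    X = np.asarray(features)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"training width {model.n_features}"
        )
    votes, classes = _vote(model, X)
    best = votes.max(axis=1, keepdims=True)
    tied = votes >= best - 1e-9
    out = []
    coil = np.where(classes == "C")[0]
    for i in range(X.shape[0]):
        if coil.size and tied[i, coil[0]]:
            out.append("C")
        else:
            out.append(classes[np.argmax(votes[i])])
    return "".join(out)


def vote_fractions(model: EnsembleModel, features: np.ndarray) -> np.ndarray:
    """Per-class vote fractions, useful for PSIPRED-style output."""
    votes, _ = _vote(model, np.asarray(features))
    return votes / votes.sum(axis=1, keepdims=True)


def combine_ensembles(
    models: Sequence[EnsembleModel], weights: Optional[Sequence[float]] = None
) -> EnsembleModel:
    """Pool members of several ensembles into one jointly-voting forest."""
    if not models:
        raise ValueError("no models to combine")
    first = models[0]
    if weights is None:
        weights = [1.0] * len(models)
    if len(weights) != len(models):
        raise ValueError("one weight per model required")
    combined = EnsembleModel(
        config=first.config,
        classes=first.classes,
        n_features=first.n_features,
    )
    for model, weight in zip(models, weights):
        if model.classes != first.classes or model.n_features != first.n_features:
            raise ValueError("models must share class alphabet and feature width")
        combined.members.extend(model.members)
        combined.feature_subsets.extend(model.feature_subsets)
        combined.member_seeds.extend(model.member_seeds)
        combined.member_weights.extend(w * weight for w in model.member_weights)
    return combined


def write_predictions(path, seq: LabeledSequence, predicted: str,
                      fractions: Optional[np.ndarray] = None,
                      classes: Sequence[str] = ("C", "E", "H")) -> None:
    """Vertical per-residue prediction listing (PSIPRED-like)."""
    with open(path, "w") as fh:
        fh.write(f"# {seq.id}\n")
        for i, (aa, state) in enumerate(zip(seq.residues, predicted)):
            frac = (
                " ".join(f"{v:.3f}" for v in fractions[i]) if fractions is not None else ""
            )
            fh.write(f"{i + 1:5d} {aa} {state} {frac}".rstrip() + "\n")
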