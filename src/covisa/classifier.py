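"""Four-class attention decoder: six pairwise linear SVMs with majority vote.

One soft-margin linear C-SVM (C = 1) is trained for each unordered pair of
the classes {RIGHT, LEFT, UP, CENTER} on the detrended, normalized localizer
feature vectors. A volume is assigned the class winning the majority of the
six pairwise votes; any tie for first place is resolved to CENTER, so the
robot never acts on an ambiguous volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from covisa.simulate import ALL_DIRECTIONS, CueSchedule, Direction


@dataclass(frozen=True)
class SvmConfig:
    c_param: float = 1.0
    label_lag_volumes: int = 2

    def __post_init__(self) -> None:
        if self.c_param <= 0:
            raise ValueError("c_param must be > 0")
        if self.label_lag_volumes < 0:
            raise ValueError("label_lag_volumes must be >= 0")


@dataclass(frozen=True)
class PairSvm:
    """One binary decision function: votes ``pos`` if w.x + b > 0 else ``neg``."""

    pos: Direction
    neg: Direction
    weights: np.ndarray
    bias: float

    def vote(self, x: np.ndarray) -> Direction:
        return self.pos if float(self.weights @ x + self.bias) > 0 else self.neg


@dataclass(frozen=True)
class AttnClassifier:
    """Six pairwise linear decision functions over a fixed feature space."""

    pairs: tuple[PairSvm, ...]
    feature_dim: int

    def __post_init__(self) -> None:
        if len(self.pairs) != len(list(combinations(ALL_DIRECTIONS, 2))):
            raise ValueError("a 4-class one-against-one model needs 6 pairs")
        for p in self.pairs:
            if p.weights.shape != (self.feature_dim,):
                raise ValueError("pair weight dimension must equal feature_dim")

    def decision_values(self, x: np.ndarray) -> dict[tuple[Direction, Direction], float]:
        return {(p.pos, p.neg): float(p.weights @ x + p.bias) for p in self.pairs}


def build_training_set(
    schedule: CueSchedule,
    features: np.ndarray,
    config: SvmConfig = SvmConfig(),
) -> tuple[np.ndarray, list[Direction]]:
    """Label localizer feature vectors with hemodynamically lagged cues.

    Volume v is labeled with the trial direction that was cued
    ``label_lag_volumes`` earlier; the first ``lag`` volumes (whose lagged
    time precedes the first trial) are dropped. With lag 0 the labels are
    the schedule's own per-volume directions.
    """
    X = np.asarray(features, dtype=float)
    states = schedule.states()
    if X.shape[0] < len(states):
        raise ValueError("features must cover the localizer phase")
    lag = config.label_lag_volumes
    rows, labels = [], []
    for v in range(len(states)):
        if v - lag < 0:
            continue
        rows.append(v)
        labels.append(states[v - lag])
    if not rows:
        raise ValueError("no labeled volumes remain after lagging")
    return X[rows], labels


def train(
    examples: tuple[np.ndarray, list[Direction]],
    config: SvmConfig = SvmConfig(),
) -> AttnClassifier:
    """Fit the six pairwise linear C-SVMs (one-against-one).

    Deterministic for a fixed example order. Raises if any class has fewer
    than two examples.
    """
    X, labels = examples
    y = np.asarray([d.value for d in labels])
    for d in ALL_DIRECTIONS:
        if int((y == d.value).sum()) < 2:
            raise ValueError(f"need >= 2 examples of class {d.value}")
    pairs: list[PairSvm] = []
    for a, b in combinations(ALL_DIRECTIONS, 2):
        sel = (y == a.value) | (y == b.value)
        Xp, yp = X[sel], (y[sel] == a.value).astype(int)  # 1 = class a
        svc = SVC(kernel="linear", C=config.c_param)
        svc.fit(Xp, yp)
        # decision_function > 0 predicts class 1 (= a)
        pairs.append(
            PairSvm(
                pos=a,
                neg=b,
                weights=np.asarray(svc.coef_).ravel().copy(),
                bias=float(svc.intercept_[0]),
            )
        )
    return AttnClassifier(pairs=tuple(pairs), feature_dim=X.shape[1])


def tally_votes(votes: list[Direction]) -> Direction:
    """Majority vote over pairwise winners; any tie for first -> CENTER."""
    counts = {d: 0 for d in ALL_DIRECTIONS}
    for v in votes:
        counts[v] += 1
    best = max(counts.values())
    winners = [d for d in ALL_DIRECTIONS if counts[d] == best]
    return winners[0] if len(winners) == 1 else Direction.CENTER


def classify(model: AttnClassifier, feature_vector: np.ndarray) -> Direction:
    """Decode one volume's attention state from its feature vector."""
    x = np.asarray(feature_vector, dtype=float).ravel()
    if x.shape != (model.feature_dim,):
        raise ValueError(
            f"feature vector has dim {x.shape[0]}, model expects {model.feature_dim}"
        )
    return tally_votes([p.vote(x) for p in model.pairs])


def save_model(model: AttnClassifier, path) -> None:
    """Write the model as a self-describing flat text file."""
    with open(path, "w") as fh:
        fh.write(f"# covisa one-against-one linear SVM, dim={model.feature_dim}\n")
        for p in model.pairs:
            w = "\t".join(f"{v:.17g}" for v in p.weights)
            fh.write(f"{p.pos.value}\t{p.neg.value}\t{p.bias:.17g}\t{w}\n")


def load_model(path) -> AttnClassifier:
    pairs = []
    dim = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            pos, neg, bias = Direction(parts[0]), Direction(parts[1]), float(parts[2])
            w = np.array([float(v) for v in parts[3:]])
            dim = w.size
            pairs.append(PairSvm(pos, neg, w, bias))
    return AttnClassifier(pairs=tuple(pairs), feature_dim=int(dim))
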