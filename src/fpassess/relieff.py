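"""ReliefF feature ranking over movement-minus-rest FAU differences.

Relief-family algorithms weight each feature by how well it separates
nearest neighbours of the same class ("hits") from nearest neighbours of
a different class ("misses"): features that differ across a class
boundary but agree within a class get positive weight.

This implementation is the binary one-movement-versus-rest variant used
to identify the units most engaged by each facial movement: for every
instance, the k nearest hits and k nearest misses are found by Manhattan
distance on range-normalised features, and

    W[f] = sum_i [ sum_miss diff(f, x_i, miss) - sum_hit diff(f, x_i, hit) ] / (m k)

with diff the normalised absolute difference. Every instance is used
once (no subsampling), so the procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import faus
from .errors import ValidationError


@dataclass(frozen=True)
class DifferenceVector:
    """Movement-minus-rest differences of all 17 units, with a class label."""

    values: dict[str, float]
    label: str

    def __post_init__(self) -> None:
        missing = set(faus.DESCRIPTORS) - set(self.values)
        if missing:
            raise ValidationError(
                f"difference vector missing descriptors: {sorted(missing)}"
            )
        if not np.all(np.isfinite(list(self.values.values()))):
            raise ValidationError("difference vector contains non-finite values")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[d] for d in faus.DESCRIPTORS], dtype=float)


@dataclass(frozen=True)
class FeatureWeights:
    """ReliefF weights for one movement-versus-rest problem."""

    weights: dict[str, float]
    movement: str
    k_neighbors: int
    n_samples_used: int


def relieff_weights(
    X: np.ndarray, y: np.ndarray, k: int = 10
) -> np.ndarray:
    """Core binary ReliefF on a feature matrix.

    Parameters
    ----------
    X
        (n_samples, n_features) raw feature matrix.
    y
        Boolean or binary array; the two values are the two classes.
    k
        Number of nearest hits and nearest misses per instance. Both
        classes must contain at least k+1 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 classes, got {len(classes)}")
    for c in classes:
        n_c = int(np.sum(y == c))
        if n_c < k + 1:
            raise ValidationError(
                f"class {c!r} has {n_c} samples; need at least k+1 = {k + 1}"
            )

    rng_span = X.max(axis=0) - X.min(axis=0)
    # a constant feature carries no information: define its diff as 0
    safe = np.where(rng_span > 0, rng_span, 1.0)
    Z = X / safe
    Z[:, rng_span == 0] = 0.0

    n, p = Z.shape
    # pairwise Manhattan distances on normalised features
    D = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    W = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        # stable sort → deterministic neighbour choice under ties
        hits = same[np.argsort(D[i, same], kind="stable")[:k]]
        misses = other[np.argsort(D[i, other], kind="stable")[:k]]
        diffs_hit = np.abs(Z[hits] - Z[i]).sum(axis=0)
        diffs_miss = np.abs(Z[misses] - Z[i]).sum(axis=0)
        W += diffs_miss - diffs_hit
    return W / (n * k)


def relieff(
    samples: list[DifferenceVector],
    target_movement: str,
    k: int = 10,
) -> FeatureWeights:
    """Rank the 17 difference features for one movement versus rest.

    Samples with labels other than ``target_movement`` and ``rest`` are
    ignored, so a full six-class dataset can be passed directly.
    """
    if target_movement not in faus.VOLUNTARY_MOVEMENTS:
        raise ValidationError(
            f"target_movement must be a voluntary movement, got {target_movement!r}"
        )
    used = [s for s in samples if s.label in (target_movement, faus.REST)]
    if not used:
        raise ValidationError("no samples for the target movement or rest")
    X = np.stack([s.as_array() for s in used])
    y = np.array([s.label == target_movement for s in used])
    W = relieff_weights(X, y, k=k)
    return FeatureWeights(
        weights={d: float(w) for d, w in zip(faus.DESCRIPTORS, W)},
        movement=target_movement,
        k_neighbors=k,
        n_samples_used=len(used),
    )


def top_features(weights: FeatureWeights, n: int) -> list[str]:
    """The n highest-weighted descriptors; ties break by canonical order."""
    if n > len(faus.DESCRIPTORS):
        raise ValidationError(f"n must be <= 17, got {n}")
    ranked = sorted(
        faus.DESCRIPTORS,
        key=lambda d: (-weights.weights[d], faus.DESCRIPTOR_INDEX[d]),
    )
    return ranked[:n]


def aggregate_ranking(
    per_movement_weights: list[FeatureWeights], n: int = 9
) -> list[str]:
    """Consensus ranking: descriptors by mean ReliefF weight across movements.

    Averaging the weights themselves (rather than per-movement ranks)
    keeps a unit that is strongly informative for even one movement above
    units that are informative for none: uninformative features have
    near-zero weight in every movement, so their mean stays near zero,
    whereas per-movement *ranks* among such features are arbitrary. Ties
    break by canonical descriptor order. The top-n list is the default
    classifier feature set and can be overridden by the user.
    """
    present = {w.movement for w in per_movement_weights}
    missing = set(faus.VOLUNTARY_MOVEMENTS) - present
    if missing:
        raise ValidationError(
            f"weights missing for movements: {sorted(missing)}"
        )
    mean_w = {
        d: sum(w.weights[d] for w in per_movement_weights)
        / len(per_movement_weights)
        for d in faus.DESCRIPTORS
    }
    ranked = sorted(
        faus.DESCRIPTORS,
        key=lambda d: (-mean_w[d], faus.DESCRIPTOR_INDEX[d]),
    )
    return ranked[:n]
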