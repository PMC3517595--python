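"""The centroid distance-spectrum comparison algorithm.

Two equal-size atom sets are compared by (1) computing each set's centroid
(unweighted mean of coordinates), (2) listing each atom's Euclidean
distance to its own centroid, (3) sorting each list ascending into the
spectra V1 and V2, and (4) summing position-weighted absolute differences:

    score(A, B) = sum_i  w_i * |V1_i - V2_i|        (optionally / n)

The score is zero for identical spectra, symmetric, and invariant under
rigid motion, reflection, and atom-order permutation of either input.
Reflection invariance means the score is chirality-blind: a structure and
its mirror image score 0 although no proper superposition maps one onto
the other — a documented limitation, with Kabsch superposition RMSD
available as the chirality-aware cross-check.

Weights: because the spectra are sorted ascending, giving atoms *far* from
the centroid more significance means weights must grow with position; the
default scheme is ``rank_proportional`` (w_i = i/n).  ``inverse_rank``
(w_i = 1/i) and ``uniform`` are available for sensitivity checks.  Scores
are only comparable — and only compared to thresholds — under a single
weight scheme; mixing schemes raises.

The division by n (normalization) makes scores comparable across segments
with different atom counts and is enabled by default.

A binary decision compares the score to a threshold epsilon: match iff
score <= epsilon (the boundary is inclusive: only a score *exceeding*
epsilon is a no-match).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import SizeMismatchError, WeightSchemeMismatchError
from .structure_io import SegmentCoordinates

_WEIGHT_KINDS = ("rank_proportional", "inverse_rank", "uniform")


@dataclass(frozen=True)
class WeightScheme:
    """Position weights w_i for i = 1..n over the sorted spectrum.

    kind:
      - ``rank_proportional``: w_i = i/n — atoms farther from the centroid
        gain significance (the default).
      - ``inverse_rank``: w_i = 1/i — the literal reading of "inversely
        proportional to position".
      - ``uniform``: w_i = 1.
    """

    kind: str = "rank_proportional"

    def __post_init__(self):
        if self.kind not in _WEIGHT_KINDS:
            raise ValueError(f"unknown weight scheme {self.kind!r}; "
                             f"choose from {_WEIGHT_KINDS}")

    def weights(self, n: int) -> np.ndarray:
        i = np.arange(1, n + 1, dtype=float)
        if self.kind == "rank_proportional":
            return i / n
        if self.kind == "inverse_rank":
            return 1.0 / i
        return np.ones(n)


DEFAULT_WEIGHTS = WeightScheme("rank_proportional")


@dataclass(frozen=True)
class DistanceSpectrum:
    """Sorted (ascending) centroid-distance values of one atom set, in Å."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("spectrum must be a nonempty 1-D array")
        if (v < 0).any() or (np.diff(v) < 0).any():
            raise ValueError("spectrum must be nonnegative and sorted")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CentroidScore:
    value: float
    normalized: bool
    atom_count: int
    weight_scheme: str = "rank_proportional"

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("centroid score is nonnegative by construction")


@dataclass(frozen=True)
class MatchThreshold:
    """The decision threshold epsilon, in the same score units/scheme as
    the scores it will be compared with."""

    epsilon: float
    weight_scheme: str | None = None
    normalized: bool | None = None

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")


def _coords(seg) -> np.ndarray:
    if isinstance(seg, SegmentCoordinates):
        return seg.coordinates
    arr = np.asarray(seg, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected SegmentCoordinates or an (n, 3) array")
    return arr


def distance_spectrum(segment) -> DistanceSpectrum:
    """Sorted centroid-distance spectrum of a segment.

    The centroid is the unweighted mean of the coordinates; distances are
    Euclidean; the result is rigid-motion invariant by construction.
    """
    xyz = _coords(segment)
    if len(xyz) == 0:
        raise ValueError("cannot take the spectrum of an empty segment")
    centroid = xyz.mean(axis=0)
    d = np.linalg.norm(xyz - centroid, axis=1)
    d.sort()
    return DistanceSpectrum(values=d)


def centroid_score(a, b, weights: WeightScheme = DEFAULT_WEIGHTS,
                   normalize: bool = True) -> CentroidScore:
    """Weighted sum of absolute spectrum differences between two segments.

    Raises :class:`SizeMismatchError` on unequal atom counts — there is no
    implicit truncation.
    """
    va = distance_spectrum(a).values
    vb = distance_spectrum(b).values
    if len(va) != len(vb):
        raise SizeMismatchError(
            f"atom counts differ ({len(va)} vs {len(vb)}); segments must "
            "have equal atom counts")
    n = len(va)
    value = float(np.sum(weights.weights(n) * np.abs(va - vb)))
    if normalize:
        value /= n
    return CentroidScore(value=value, normalized=normalize, atom_count=n,
                         weight_scheme=weights.kind)


def match_decision(score: CentroidScore, threshold: MatchThreshold) -> bool:
    """True (match) iff score.value <= threshold.epsilon.

    Scores and thresholds must come from the same weight scheme and
    normalization; comparing across schemes raises.
    """
    if (threshold.weight_scheme is not None
            and threshold.weight_scheme != score.weight_scheme):
        raise WeightSchemeMismatchError(
            f"score uses {score.weight_scheme!r} but threshold was derived "
            f"under {threshold.weight_scheme!r}")
    if (threshold.normalized is not None
            and threshold.normalized != score.normalized):
        raise WeightSchemeMismatchError(
            "score and threshold differ in normalization")
    return score.value <= threshold.epsilon


def pairwise_max_score(segments, weights: WeightScheme = DEFAULT_WEIGHTS,
                       normalize: bool = True) -> float:
    """Maximum centroid score over all unordered pairs of segments.

    This is the "limit of variation" of a set of examples of one
    structural category: the worst within-set disagreement.
    """
    segments = list(segments)
    if len(segments) < 2:
        raise ValueError("need at least 2 segments for a pairwise maximum")
    return max(
        centroid_score(a, b, weights, normalize).value
        for a, b in itertools.combinations(segments, 2)
    )


def inflate_threshold(limit: float, inflation: float = 0.10,
                      weight_scheme: str | None = None,
                      normalized: bool | None = None) -> MatchThreshold:
    """Threshold set a safety margin above the observed score limit.

    epsilon = limit * (1 + inflation), unrounded.  The default 10%
    inflation widens the acceptance region so borderline true positives
    are not missed.
    """
    if limit < 0:
        raise ValueError("limit must be nonnegative")
    if inflation < 0:
        raise ValueError("inflation must be nonnegative")
    return MatchThreshold(epsilon=limit * (1.0 + inflation),
                          weight_scheme=weight_scheme, normalized=normalized)


@dataclass(frozen=True)
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray     # (3, 3) proper rotation, det = +1
    translation: np.ndarray  # applied after rotation


def kabsch_superpose_rmsd(a, b) -> SuperpositionResult:
    """Least-squares optimal proper superposition of b onto a.

    Returns the RMSD after the optimal rotation (det = +1; mirror images
    do NOT superpose to zero) and translation.  Fewer than 3 atoms or a
    degenerate (collinear) configuration triggers a conditioning warning.
    """
    xa, xb = _coords(a), _coords(b)
    if len(xa) != len(xb):
        raise SizeMismatchError(
            f"atom counts differ ({len(xa)} vs {len(xb)})")
    n = len(xa)
    ca, cb = xa.mean(axis=0), xb.mean(axis=0)
    ya, yb = xa - ca, xb - cb
    if n < 3 or np.linalg.matrix_rank(ya, tol=1e-8) < 2:
        warnings.warn("superposition of < 3 atoms or a collinear "
                      "configuration is poorly conditioned", stacklevel=2)
    # Rotation.align_vectors gives the proper rotation minimizing
    # sum |ya_i - R yb_i|^2 (classic Kabsch via SVD).
    rot, rssd = Rotation.align_vectors(ya, yb)
    R = rot.as_matrix()
    rmsd = float(rssd) / np.sqrt(n)
    translation = ca - R @ cb
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=translation)
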