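"""Data-driven FiO2 cut-point derivation with a single-feature decision tree.

The graded oxygen item needs three cut-points splitting [0.21, 1.0] into
four bands of increasing risk. They are found by growing a binary
classification tree on the single feature (calculated FiO2) against the
observation-level event label: best-first greedy growth, Gini impurity,
each step splitting whichever current leaf offers the largest total
impurity decrease, until ``max_cut_points`` internal splits exist or the
minimum-leaf-size constraint binds. The split thresholds, sorted
ascending, become the band edges; weights 0/1/2/3 are assigned in
ascending FiO2 order (risk is expected, but not forced, to increase with
the inspired fraction — a diagnostic flags non-monotone band event rates
rather than re-ranking them).

Determinism: candidate thresholds are midpoints between adjacent distinct
feature values; ties in impurity gain break toward the lower FiO2 cut, so
the derivation needs no random seed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import LabeledObservation
from .scoring import FiO2Bands

__all__ = [
    "TreeConfig",
    "DerivationError",
    "DerivedBands",
    "BandReport",
    "derive_fio2_bands",
    "derive_cuts_from_arrays",
    "band_report",
]


class DerivationError(ValueError):
    """The labeled data cannot support the requested banding."""


@dataclass(frozen=True)
class TreeConfig:
    """Growth controls for the single-feature tree."""

    impurity: str = "gini"
    max_cut_points: int = 3
    min_leaf_fraction: float = 0.01
    rounding: int = 1  # decimal places for reported percent thresholds
    seed: int = 0  # unused by the deterministic tie-break; kept for config parity

    def __post_init__(self) -> None:
        if self.impurity != "gini":
            raise ValueError("only gini impurity is supported")
        if self.max_cut_points < 1:
            raise ValueError("max_cut_points must be >= 1")
        if not 0 < self.min_leaf_fraction < 0.5:
            raise ValueError("min_leaf_fraction must be in (0, 0.5)")


@dataclass
class DerivedBands:
    """Cut-points recovered by the tree plus per-band diagnostics."""

    cut_points: tuple[float, ...]
    weights: tuple[int, ...]
    band_counts: tuple[int, ...]
    band_event_counts: tuple[int, ...]
    gains: tuple[float, ...]  # impurity decrease of each accepted split, in order taken
    monotone_event_rates: bool
    rounding: int = 1

    @property
    def band_event_rates(self) -> tuple[float, ...]:
        return tuple(e / c if c else math.nan
                     for e, c in zip(self.band_event_counts, self.band_counts))

    @property
    def total_gain(self) -> float:
        return float(sum(self.gains))

    def cut_points_percent(self) -> tuple[float, ...]:
        """Thresholds rounded to the reporting precision, percent scale."""
        return tuple(round(100.0 * c, self.rounding) for c in self.cut_points)

    def as_fio2_bands(self) -> FiO2Bands:
        if len(self.cut_points) != 3:
            raise DerivationError(
                f"{len(self.cut_points)} cut-point(s) derived; a scoring band set needs 3"
            )
        return FiO2Bands(tuple(self.cut_points))


def _leaf_best_split(pos_cum: np.ndarray, s: int, e: int, boundaries: np.ndarray,
                     min_leaf: int) -> tuple[float, int] | None:
    """Best admissible split of sorted-range [s, e) by Gini decrease.

    ``boundaries`` are the sorted positions b (s < b < e) where the feature
    value changes; a split at b puts [s, b) left and [b, e) right.
    Returns (gain, boundary) or None; ties prefer the smaller boundary.
    """
    b = boundaries[(boundaries > s) & (boundaries < e)]
    if b.size == 0:
        return None
    n = e - s
    pos = pos_cum[e] - pos_cum[s]
    nl = b - s
    nr = e - b
    ok = (nl >= min_leaf) & (nr >= min_leaf)
    if not ok.any():
        return None
    b, nl, nr = b[ok], nl[ok], nr[ok]
    pl = pos_cum[b] - pos_cum[s]
    pr = pos - pl
    # impurity decrease in count units: n*G(parent) - nl*G(left) - nr*G(right)
    parent = n * _gini(pos, n)
    children = nl * _gini_vec(pl, nl) + nr * _gini_vec(pr, nr)
    gains = parent - children
    best = int(np.argmax(gains))
    # break exact/near ties toward the lower-FiO2 boundary
    tol = 1e-9 * max(1.0, abs(float(gains[best])))
    first = int(np.argmax(gains >= gains[best] - tol))
    return float(gains[first]), int(b[first])


def _gini(pos: float, n: float) -> float:
    p = pos / n
    return 2.0 * p * (1.0 - p)


def _gini_vec(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    p = pos / n
    return 2.0 * p * (1.0 - p)


def derive_cuts_from_arrays(
    fio2: np.ndarray,
    labels: np.ndarray,
    config: TreeConfig = TreeConfig(),
) -> tuple[list[float], list[float]]:
    """Grow the tree on raw arrays; return (cut_values, gains in split order)."""
    fio2 = np.asarray(fio2, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if fio2.shape != labels.shape or fio2.ndim != 1:
        raise ValueError("fio2 and labels must be equal-length 1-d arrays")
    n = fio2.size
    if n == 0 or labels.all() or not labels.any():
        raise DerivationError("labels must contain both classes")
    order = np.argsort(fio2, kind="mergesort")
    x = fio2[order]
    y = labels[order]
    distinct = np.unique(x)
    if distinct.size < config.max_cut_points + 1:
        raise DerivationError(
            f"{distinct.size} distinct fio2 value(s) cannot yield "
            f"{config.max_cut_points} cut-point(s)"
        )
    boundaries = np.flatnonzero(np.diff(x)) + 1  # positions where value changes
    pos_cum = np.concatenate([[0], np.cumsum(y)])
    min_leaf = max(1, math.ceil(config.min_leaf_fraction * n))

    # best-first growth: a max-heap of candidate splits, one per leaf
    heap: list[tuple[float, float, int, int, int]] = []

    def push(s: int, e: int) -> None:
        found = _leaf_best_split(pos_cum, s, e, boundaries, min_leaf)
        if found is not None:
            gain, b = found
            # heapq is a min-heap: order by (-gain, cut value) for the tie-break
            heapq.heappush(heap, (-gain, float(x[b - 1] + x[b]) / 2.0, s, e, b))

    push(0, n)
    cuts: list[float] = []
    gains: list[float] = []
    while heap and len(cuts) < config.max_cut_points:
        neg_gain, cut, s, e, b = heapq.heappop(heap)
        if -neg_gain <= 0:
            break  # no impurity decrease left anywhere
        cuts.append(cut)
        gains.append(-neg_gain)
        push(s, b)
        push(b, e)
    return sorted(cuts), gains


def derive_fio2_bands(
    labeled: Sequence[LabeledObservation],
    config: TreeConfig = TreeConfig(),
) -> DerivedBands:
    """Derive FiO2 scoring bands from labeled observations.

    Raises :class:`DerivationError` on single-class labels or too few
    distinct FiO2 values. The returned diagnostics carry per-band
    observation and event counts and whether event rates ascend across
    bands (checked, not enforced).
    """
    fio2 = np.array([lo.calculated_fio2 for lo in labeled], dtype=float)
    labels = np.array([lo.label for lo in labeled], dtype=bool)
    cuts, gains = derive_cuts_from_arrays(fio2, labels, config)

    idx = np.searchsorted(np.asarray(cuts), fio2, side="left")
    k = len(cuts) + 1
    counts = np.bincount(idx, minlength=k)
    events = np.bincount(idx, weights=labels.astype(float), minlength=k).astype(int)
    rates = [e / c if c else math.nan for e, c in zip(events, counts)]
    finite = [r for r in rates if not math.isnan(r)]
    monotone = all(a <= b for a, b in zip(finite, finite[1:]))
    return DerivedBands(
        cut_points=tuple(cuts),
        weights=tuple(range(k)),
        band_counts=tuple(int(c) for c in counts),
        band_event_counts=tuple(int(e) for e in events),
        gains=tuple(gains),
        monotone_event_rates=monotone,
        rounding=config.rounding,
    )


# --------------------------------------------------------------------------
# band occupancy reporting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandReport:
    """Per-band observation and event tallies for a fixed band set.

    ``counts[i]`` / ``event_counts[i]`` tally the observations whose
    calculated FiO2 fell in the band carrying weight ``i``.
    """

    counts: tuple[int, ...]
    event_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.event_counts):
            raise ValueError("counts and event_counts must align")
        if any(c < 0 for c in self.counts) or any(e < 0 for e in self.event_counts):
            raise ValueError("tallies must be non-negative")
        if any(e > c for c, e in zip(self.counts, self.event_counts)):
            raise ValueError("event count cannot exceed band count")

    @property
    def n_total(self) -> int:
        return int(sum(self.counts))

    @property
    def n_events(self) -> int:
        return int(sum(self.event_counts))

    def share_percent(self, weights: Sequence[int], decimals: int = 1) -> float:
        """Percentage of all observations falling in the given weight bands."""
        if self.n_total == 0:
            raise ValueError("empty report has no shares")
        sub = sum(self.counts[w] for w in weights)
        return round(100.0 * sub / self.n_total, decimals)


def band_report(
    labeled: Sequence[LabeledObservation],
    bands: FiO2Bands,
) -> BandReport:
    """Tally observations and events per scoring band (conserving totals)."""
    k = len(bands.cut_points) + 1
    counts = [0] * k
    events = [0] * k
    for lo in labeled:
        w = bands.assign(lo.calculated_fio2)
        counts[w] += 1
        if lo.label:
            events[w] += 1
    return BandReport(tuple(counts), tuple(events))
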