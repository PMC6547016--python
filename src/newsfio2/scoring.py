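"""NEWS and NEWS-FiO2 score computation.

An early warning score sums integer sub-scores (weights 0-3) assigned to
bands of each vital sign. The standard chart scores oxygen in a binary
manner: 0 on room air, 2 on any supplemental oxygen regardless of dose.
The FiO2 variant replaces that binary item with a four-level graded item:
the calculated inspired oxygen fraction is banded by three ascending
cut-points into weights 0/1/2/3, so escalations in oxygen therapy move
the score while the rest of the chart is untouched.

Band-edge semantics are right-closed: with cut-points c1 < c2 < c3 the
bands are [0.21, c1], (c1, c2], (c2, c3], (c3, 1.0]. With the default
cut-points 0.22/0.37/0.53 this reproduces one-decimal percent banding
(21-22 / 22.1-37 / 37.1-53 / >53) without gaps.

Charts are data, not code: they serialise to YAML so a ship chart can be
audited and swapped without touching the package.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .cohort import gcs_to_avpu
from .data_model import ObservationSet

__all__ = [
    "VitalBands",
    "ScoreChart",
    "FiO2Bands",
    "ScoreResult",
    "DEFAULT_CHART",
    "DEFAULT_FIO2_BANDS",
    "assign_band",
    "score_news",
    "score_news_fio2",
    "load_chart",
    "save_chart",
    "load_fio2_bands",
    "save_fio2_bands",
]


@dataclass(frozen=True)
class VitalBands:
    """Right-closed scoring bands for one vital sign.

    ``cuts`` are the interior band edges (ascending); ``weights`` has one
    more entry than ``cuts``. A value v falls in band i where i is the
    number of cuts strictly below v, i.e. intervals
    (-inf, cuts[0]], (cuts[0], cuts[1]], ..., (cuts[-1], +inf).
    """

    cuts: tuple[float, ...]
    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.cuts) + 1:
            raise ValueError("need exactly one more weight than cut")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError(f"cuts must be strictly ascending: {self.cuts}")
        if any(not (0 <= w <= 3 and int(w) == w) for w in self.weights):
            raise ValueError(f"weights must be integers in 0..3: {self.weights}")

    def assign(self, value: float) -> int:
        return int(self.weights[bisect.bisect_left(self.cuts, value)])

    @property
    def max_weight(self) -> int:
        return max(self.weights)


@dataclass(frozen=True)
class FiO2Bands:
    """Three ascending FiO2 cut-points partitioning [0.21, 1.0] into weights 0-3."""

    cut_points: tuple[float, float, float] = (0.22, 0.37, 0.53)
    weights: tuple[int, int, int, int] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        if len(self.cut_points) != 3:
            raise ValueError("exactly three cut-points required")
        cp = self.cut_points
        if not (0.21 < cp[0] < cp[1] < cp[2] < 1.0):
            raise ValueError(f"cut-points must be strictly ascending in (0.21, 1.0): {cp}")
        if tuple(self.weights) != (0, 1, 2, 3):
            raise ValueError("weights must ascend 0,1,2,3")

    def assign(self, fio2: float) -> int:
        return assign_band(fio2, self)

    def cut_points_percent(self, decimals: int = 1) -> tuple[float, ...]:
        """Cut-points on the percentage scale used in reports."""
        return tuple(round(100.0 * c, decimals) for c in self.cut_points)


DEFAULT_FIO2_BANDS = FiO2Bands()

#: The published 2012 RCP National Early Warning Score chart. These bands come
#: from the RCP publication and are configuration: verify against the chart in
#: force locally before operational use.
DEFAULT_CHART_SPEC: dict[str, tuple[tuple[float, ...], tuple[int, ...]]] = {
    "rr": ((8, 11, 20, 24), (3, 1, 0, 2, 3)),
    "spo2": ((91, 93, 95), (3, 2, 1, 0)),
    "temp": ((35.0, 36.0, 38.0, 39.0), (3, 1, 0, 1, 2)),
    "sbp": ((90, 100, 110, 219), (3, 2, 1, 0, 3)),
    "hr": ((40, 50, 90, 110, 130), (3, 1, 0, 1, 2, 3)),
}


@dataclass(frozen=True)
class ScoreChart:
    """Per-vital scoring bands plus the consciousness and oxygen rules.

    The consciousness rule is fixed by the chart family: Alert scores 0,
    any of V/P/U scores 3. The oxygen item is binary (0 room air / 2 any
    supplement) in the standard variant; the FiO2 variant swaps it for a
    graded :class:`FiO2Bands` item at scoring time.
    """

    vitals: Mapping[str, VitalBands] = field(
        default_factory=lambda: {
            name: VitalBands(cuts, weights)
            for name, (cuts, weights) in DEFAULT_CHART_SPEC.items()
        }
    )
    oxygen_supplement_weight: int = 2

    def __post_init__(self) -> None:
        missing = {"rr", "spo2", "temp", "sbp", "hr"} - set(self.vitals)
        if missing:
            raise ValueError(f"chart missing vital(s): {sorted(missing)}")

    def consciousness_weight(self, avpu: str) -> int:
        return 0 if avpu == "A" else 3

    def structural_max(self, graded_oxygen: bool) -> int:
        """Largest attainable total under this chart."""
        vit = sum(b.max_weight for b in self.vitals.values())
        return vit + 3 + (3 if graded_oxygen else self.oxygen_supplement_weight)


DEFAULT_CHART = ScoreChart()


@dataclass(frozen=True)
class ScoreResult:
    """Per-component sub-scores and their total for one observation set."""

    components: Mapping[str, int]
    total: int
    variant: str  # "news" | "news_fio2"

    def __post_init__(self) -> None:
        if self.total != sum(self.components.values()):
            raise ValueError("total must equal the sum of sub-scores")


def assign_band(fio2: float, bands: FiO2Bands) -> int:
    """Weight of the band containing ``fio2`` under right-closed semantics."""
    if not 0.21 <= fio2 <= 1.0:
        raise ValueError(f"fio2 {fio2} outside [0.21, 1.0]")
    return int(bands.weights[bisect.bisect_left(bands.cut_points, fio2)])


def _consciousness(obs: ObservationSet, chart: ScoreChart) -> int:
    avpu = obs.avpu if obs.avpu is not None else gcs_to_avpu(obs.gcs)
    return chart.consciousness_weight(avpu)


def _vital_components(obs: ObservationSet, chart: ScoreChart) -> dict[str, int]:
    comps = {name: bands.assign(getattr(obs, name)) for name, bands in chart.vitals.items()}
    comps["consciousness"] = _consciousness(obs, chart)
    return comps


def score_news(obs: ObservationSet, chart: ScoreChart = DEFAULT_CHART) -> ScoreResult:
    """Standard score: binary oxygen item (0 room air, 2 any supplement)."""
    if not obs.is_complete():
        raise ValueError("observation set is incomplete; cannot score")
    comps = _vital_components(obs, chart)
    comps["oxygen"] = 0 if obs.on_room_air else chart.oxygen_supplement_weight
    return ScoreResult(comps, sum(comps.values()), "news")


def score_news_fio2(
    obs: ObservationSet,
    calculated_fio2: float,
    chart: ScoreChart = DEFAULT_CHART,
    bands: FiO2Bands = DEFAULT_FIO2_BANDS,
) -> ScoreResult:
    """FiO2-graded score: the binary oxygen item is replaced by the band weight."""
    if not obs.is_complete():
        raise ValueError("observation set is incomplete; cannot score")
    comps = _vital_components(obs, chart)
    comps["oxygen"] = assign_band(calculated_fio2, bands)
    return ScoreResult(comps, sum(comps.values()), "news_fio2")


# --------------------------------------------------------------------------
# configuration round-trip
# --------------------------------------------------------------------------

def save_chart(chart: ScoreChart, path: str | Path) -> None:
    payload = {
        "vitals": {
            name: {"cuts": list(b.cuts), "weights": list(b.weights)}
            for name, b in chart.vitals.items()
        },
        "oxygen_supplement_weight": chart.oxygen_supplement_weight,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_chart(path: str | Path) -> ScoreChart:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    vitals = {
        name: VitalBands(tuple(v["cuts"]), tuple(v["weights"]))
        for name, v in payload["vitals"].items()
    }
    return ScoreChart(vitals, int(payload.get("oxygen_supplement_weight", 2)))


def save_fio2_bands(bands: FiO2Bands, path: str | Path) -> None:
    payload = {"cut_points": [float(c) for c in bands.cut_points],
               "weights": list(bands.weights)}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_fio2_bands(path: str | Path) -> FiO2Bands:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return FiO2Bands(tuple(payload["cut_points"]), tuple(payload.get("weights", (0, 1, 2, 3))))
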