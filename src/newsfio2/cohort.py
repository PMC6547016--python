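"""Eligibility filtering and observation-level outcome labeling.

The unit of analysis is the individual hospital admission (repeat
admissions of one patient are independent). Eligible admissions are adult
(>= 16 years at admission), stayed at least 24 hours unless the stay ended
in the adverse event, did not reach the ward via ICU, and contributed at
least one complete vital-sign observation set.

The composite adverse event is in-hospital death or unplanned ICU
admission; when an ICU admission is followed by death, the ICU admission
is the event and defines the event time. Every complete observation taken
in the look-back window before the event (default 24 h, boundary
inclusive) is labeled positive with its time-to-event; observations at or
after the event are dropped; everything else is a negative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .data_model import Admission, LabeledObservation, ObservationSet
from .fio2 import estimate_fio2

__all__ = [
    "CohortConfig",
    "DEFAULT_GCS_TO_AVPU",
    "EligibilityResult",
    "filter_eligible",
    "tag_events",
    "gcs_to_avpu",
    "completeness_filter",
    "summarize_cohort",
    "rate_percent",
]

#: (gcs_low, gcs_high, avpu) ranges covering 3-15 without gaps. This is a
#: commonly used correspondence; site conversion tables vary and the map is
#: fully configurable.
DEFAULT_GCS_TO_AVPU: tuple[tuple[int, int, str], ...] = (
    (15, 15, "A"),
    (9, 14, "V"),
    (4, 8, "P"),
    (3, 3, "U"),
)


@dataclass(frozen=True)
class CohortConfig:
    min_age_years: int = 16
    min_stay_hours: float = 24.0
    lookback_window_hours: float = 24.0
    gcs_to_avpu_map: tuple[tuple[int, int, str], ...] = DEFAULT_GCS_TO_AVPU
    window_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.lookback_window_hours <= 0:
            raise ValueError("lookback_window_hours must be > 0")
        covered = sorted(r for lo, hi, _ in self.gcs_to_avpu_map for r in range(lo, hi + 1))
        if covered != list(range(3, 16)):
            raise ValueError("gcs_to_avpu_map must cover 3-15 exactly once")


def gcs_to_avpu(gcs: int, mapping: Sequence[tuple[int, int, str]] = DEFAULT_GCS_TO_AVPU) -> str:
    """Convert a Glasgow Coma Scale total to an AVPU level via a range map."""
    if not 3 <= gcs <= 15:
        raise ValueError(f"gcs {gcs} outside [3, 15]")
    for lo, hi, avpu in mapping:
        if lo <= gcs <= hi:
            return avpu
    raise ValueError(f"gcs {gcs} not covered by map")  # pragma: no cover - config validated


def completeness_filter(
    observations: Iterable[ObservationSet],
) -> tuple[list[ObservationSet], int]:
    """Keep complete observation sets; return them with the count removed."""
    complete, incomplete = [], 0
    for obs in observations:
        if obs.is_complete():
            complete.append(obs)
        else:
            incomplete += 1
    return complete, incomplete


@dataclass
class EligibilityResult:
    """Eligible admissions/observations plus a flowchart-style exclusion tally."""

    admissions: list[Admission]
    observations: list[ObservationSet]
    exclusions: Counter = field(default_factory=Counter)
    #: non-excluding flowchart tallies (e.g. events with no recent observation)
    notes: Counter = field(default_factory=Counter)
    diagnostics: list[str] = field(default_factory=list)
    n_incomplete_observations: int = 0

    @property
    def n_input_admissions(self) -> int:
        return len(self.admissions) + sum(self.exclusions.values())


def filter_eligible(
    admissions: Sequence[Admission],
    observations: Sequence[ObservationSet],
    config: CohortConfig = CohortConfig(),
) -> EligibilityResult:
    """Apply the admission-level eligibility filters.

    Exclusion categories (each admission tallied once, in this order):
    ``under_age``, ``short_stay`` (discharged event-free in under
    ``min_stay_hours``), ``post_icu_ward`` (ward period reached via ICU),
    ``no_complete_observations``. Admissions whose event has no complete
    observation in the look-back window stay eligible but are tallied
    under ``event_without_recent_observation`` for the flowchart.
    Orphan observations (no matching admission) are reported, not dropped
    silently.
    """
    by_adm: dict[str, list[ObservationSet]] = {}
    diagnostics: list[str] = []
    known = {a.admission_id for a in admissions}
    for obs in observations:
        if obs.admission_id not in known:
            diagnostics.append(f"orphan observation for unknown admission {obs.admission_id}")
            continue
        by_adm.setdefault(obs.admission_id, []).append(obs)

    exclusions: Counter = Counter()
    kept_adm: list[Admission] = []
    kept_obs: list[ObservationSet] = []
    n_incomplete = 0
    for adm in admissions:
        if adm.age_years < config.min_age_years:
            exclusions["under_age"] += 1
            continue
        if adm.stay_hours < config.min_stay_hours and not adm.has_event:
            exclusions["short_stay"] += 1
            continue
        if adm.planned_icu_before_ward:
            exclusions["post_icu_ward"] += 1
            continue
        complete, inc = completeness_filter(by_adm.get(adm.admission_id, []))
        n_incomplete += inc
        if not complete:
            exclusions["no_complete_observations"] += 1
            continue
        kept_adm.append(adm)
        kept_obs.extend(complete)

    result = EligibilityResult(
        kept_adm, kept_obs, exclusions,
        diagnostics=diagnostics, n_incomplete_observations=n_incomplete,
    )

    w = config.lookback_window_hours
    for adm in kept_adm:
        if not adm.has_event:
            continue
        gaps = [
            (adm.event_time - o.timestamp).total_seconds() / 3600.0
            for o in by_adm.get(adm.admission_id, [])
            if o.is_complete()
        ]
        in_window = [g for g in gaps if 0 < g and (g <= w if config.window_inclusive else g < w)]
        if not in_window:
            result.notes["event_without_recent_observation"] += 1
            diagnostics.append(
                f"admission {adm.admission_id}: event with no complete observation "
                f"in the prior {w:g} h; contributes no positives"
            )
    return result


def tag_events(
    observations: Sequence[ObservationSet],
    admissions: Sequence[Admission],
    config: CohortConfig = CohortConfig(),
    device_table: Mapping[str, str] | None = None,
) -> tuple[list[LabeledObservation], list[str]]:
    """Label each complete observation against its admission's adverse event.

    The event time is the admission's (already-composite) event time — the
    earliest of unplanned ICU admission or death. Observations at or after
    the event are dropped. An observation is positive when the gap to the
    event lies in (0, window] (right boundary open when
    ``window_inclusive`` is false). The calculated FiO2 is attached to
    every labeled observation. Idempotent: relabeling the same inputs
    yields identical output.
    """
    adm_by_id = {a.admission_id: a for a in admissions}
    w = config.lookback_window_hours
    labeled: list[LabeledObservation] = []
    diagnostics: list[str] = []
    first_obs: dict[str, ObservationSet] = {}
    for obs in sorted(observations, key=lambda o: (o.admission_id, o.timestamp)):
        first_obs.setdefault(obs.admission_id, obs)

    for obs in observations:
        adm = adm_by_id.get(obs.admission_id)
        if adm is None:
            diagnostics.append(f"orphan observation for unknown admission {obs.admission_id}")
            continue
        if not obs.is_complete():
            continue
        fio2 = estimate_fio2(obs, device_table).fio2
        if adm.has_event:
            gap_h = (adm.event_time - obs.timestamp).total_seconds() / 3600.0
            if gap_h <= 0:
                continue  # post-event ward observations are not analysed
            positive = gap_h <= w if config.window_inclusive else gap_h < w
            if positive:
                labeled.append(LabeledObservation(obs, True, fio2, time_to_event_h=gap_h))
                continue
        labeled.append(LabeledObservation(obs, False, fio2))

    for adm in adm_by_id.values():
        if adm.has_event and adm.admission_id in first_obs:
            if adm.event_time < first_obs[adm.admission_id].timestamp:
                diagnostics.append(
                    f"admission {adm.admission_id}: event precedes first observation; "
                    "contributes only negatives"
                )
    return labeled, diagnostics


def rate_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage share rounded to the reporting precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def summarize_cohort(
    admissions: Sequence[Admission],
    oxygen_admission_ids: set[str] | None = None,
    decimals: int = 1,
) -> dict[str, float | int]:
    """Admission-level cohort summary: event and oxygen-cohort shares.

    Returns counts plus the percentages a demographics table reports: the
    event-admission share of the whole cohort, the oxygen cohort's share
    of admissions, and the event share within the oxygen cohort.
    """
    n = len(admissions)
    n_event = sum(1 for a in admissions if a.has_event)
    out: dict[str, float | int] = {
        "n_admissions": n,
        "n_event_admissions": n_event,
        "event_admission_percent": rate_percent(n_event, n, decimals) if n else 0.0,
    }
    if oxygen_admission_ids is not None:
        oxy = [a for a in admissions if a.admission_id in oxygen_admission_ids]
        n_oxy = len(oxy)
        n_oxy_event = sum(1 for a in oxy if a.has_event)
        out.update({
            "n_oxygen_admissions": n_oxy,
            "oxygen_admission_percent": rate_percent(n_oxy, n, decimals) if n else 0.0,
            "n_oxygen_event_admissions": n_oxy_event,
            "oxygen_event_percent": rate_percent(n_oxy_event, n_oxy, decimals) if n_oxy else 0.0,
        })
    return out
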