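"""Synthetic ward cohorts for exercising the full scoring pipeline.

The generator emulates the structure of an acute-ward vital-signs
database: admissions with stay intervals and a composite adverse-event
outcome, and timestamped observation sets with vitals drawn from
truncated-normal marginals (oxygen-cohort means/SDs: HR 84 (18) bpm,
RR 18 (4) /min, SBP 125 (23) mmHg, temp 36.7 (0.6) C, FiO2 47 (15) %).
About 38% of admissions receive oxygen; the admission-level adverse-event
rate is ~4% overall and higher in the oxygen cohort because the event
hazard rises with the inspired fraction through three planted FiO2
cut-points (defaults 0.22/0.37/0.53). In the final 24 h before an event
the vitals drift (rising RR/HR and FiO2, falling SBP/SpO2) so scores
climb as the event approaches.

Vitals are independent apart from the drift mechanism; real
between-vital covariance, diurnal observation cadence and disease-specific
physiology are deliberately out of scope. Oxygen device and flow are
chosen to be exactly consistent with the target FiO2 under the dilution
formula, so estimation round-trips the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping

import numpy as np

from .data_model import Admission, LabeledObservation, ObservationSet
from .fio2 import DEFAULT_TIDAL_VOLUME_L, ROOM_AIR_FIO2

__all__ = ["SimConfig", "generate_cohort", "generate_banded_fio2_labels"]

_EPOCH = datetime(2015, 1, 1)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the generator (defaults are the conditions)."""

    n_admissions: int = 2000
    oxygen_fraction: float = 0.38
    admission_event_rate: float = 0.04
    obs_per_admission: float = 25.0
    #: per-vital (mean, sd); fio2_percent applies within the oxygen cohort
    vital_marginals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hr": (84.0, 18.0),
            "rr": (18.0, 4.0),
            "sbp": (125.0, 23.0),
            "temp": (36.7, 0.6),
            "fio2_percent": (47.0, 15.0),
        }
    )
    planted_fio2_cuts: tuple[float, float, float] = (0.22, 0.37, 0.53)
    #: per-observation event-window probability by planted band
    band_event_probs: tuple[float, float, float, float] = (0.005, 0.02, 0.05, 0.12)
    drift_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be >= 1")
        if self.obs_per_admission < 1:
            raise ValueError("obs_per_admission must be >= 1")
        for p in (self.oxygen_fraction, self.admission_event_rate, *self.band_event_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if list(self.planted_fio2_cuts) != sorted(self.planted_fio2_cuts):
            raise ValueError("planted cuts must ascend")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-free truncated normal via clipped resampling (adequate tails)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    for _ in range(8):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.clip(out, lo, hi)


def _band_index(fio2: float, cuts: tuple[float, ...]) -> int:
    i = 0
    for c in cuts:
        if fio2 > c:
            i += 1
    return i


def _device_for(fio2: float, rr: float, rng: np.random.Generator):
    """Pick a delivery device and flow exactly consistent with the target FiO2."""
    if fio2 <= ROOM_AIR_FIO2:
        return "room_air", None, None
    if fio2 > 0.95:
        dev = "high_flow_nasal" if rng.random() < 0.5 else "niv"
        return dev, None, None
    if rng.random() < 0.10:  # charted Venturi masks carry the prescribed fraction
        return "fixed_performance_mask", None, round(float(fio2), 3)
    mv = rr * DEFAULT_TIDAL_VOLUME_L
    flow = mv * (fio2 - ROOM_AIR_FIO2) / (1.0 - ROOM_AIR_FIO2)
    if flow <= 6.0:
        dev = "nasal_cannula"
    elif flow <= 10.0:
        dev = "simple_mask"
    else:
        dev = "reservoir_mask"
    return dev, float(flow), None


def generate_cohort(config: SimConfig) -> tuple[list[Admission], list[ObservationSet]]:
    """Generate admissions and observation sets; reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    vm = config.vital_marginals
    cuts = config.planted_fio2_cuts
    probs = np.asarray(config.band_event_probs)
    # scale admission event probability by the relative band hazard of the
    # admission's baseline FiO2 so risk rises through the planted cuts
    rel = probs / probs.mean() if probs.mean() > 0 else np.ones(4)

    admissions: list[Admission] = []
    observations: list[ObservationSet] = []
    for i in range(config.n_admissions):
        aid = f"A{i:06d}"
        pid = f"P{i:06d}"
        age = int(np.clip(rng.normal(66, 18), 16, 105))
        on_oxygen = rng.random() < config.oxygen_fraction
        if on_oxygen:
            base_fio2 = float(np.clip(
                rng.normal(vm["fio2_percent"][0], vm["fio2_percent"][1]) / 100.0,
                0.215, 1.0))
        else:
            base_fio2 = ROOM_AIR_FIO2

        p_event = min(1.0, config.admission_event_rate * float(rel[_band_index(base_fio2, cuts)]))
        has_event = rng.random() < p_event
        stay_h = float(np.clip(rng.lognormal(math.log(110.0), 0.6), 30.0, 1200.0))
        admit = _EPOCH + timedelta(hours=float(rng.uniform(0, 24 * 365)))
        discharge = admit + timedelta(hours=stay_h)
        event_time = None
        outcome = "none"
        if has_event:
            outcome = "death" if rng.random() < 0.6 else "unplanned_icu"
            event_time = admit + timedelta(hours=float(rng.uniform(26.0, stay_h)))

        n_obs = max(1, int(rng.poisson(config.obs_per_admission)))
        end = event_time if event_time is not None else discharge
        span_h = (end - admit).total_seconds() / 3600.0
        times = np.sort(rng.uniform(0.0, span_h, n_obs))

        hr = _trunc_normal(rng, *vm["hr"], 30, 220, n_obs)
        rr = np.round(_trunc_normal(rng, *vm["rr"], 5, 60, n_obs))
        sbp = _trunc_normal(rng, *vm["sbp"], 50, 260, n_obs)
        temp = _trunc_normal(rng, *vm["temp"], 33.0, 41.5, n_obs)
        spo2 = np.clip(100.0 - rng.gamma(2.0, 1.5, n_obs), 70.0, 100.0)
        fio2 = np.clip(base_fio2 + rng.normal(0, 0.03, n_obs), ROOM_AIR_FIO2, 1.0) \
            if on_oxygen else np.full(n_obs, ROOM_AIR_FIO2)

        if has_event:
            tte = span_h - times
            prox = np.clip(1.0 - tte / 24.0, 0.0, 1.0) * config.drift_strength
            hr = np.clip(hr + 20.0 * prox, 30, 220)
            rr = np.clip(np.round(rr + 8.0 * prox), 5, 60)
            sbp = np.clip(sbp - 20.0 * prox, 50, 260)
            spo2 = np.clip(spo2 - 4.0 * prox, 70, 100)
            if on_oxygen:
                fio2 = np.clip(fio2 + 0.30 * prox, ROOM_AIR_FIO2, 1.0)

        avpu_draw = rng.random(n_obs)
        for j in range(n_obs):
            ts = admit + timedelta(hours=float(times[j]))
            f = float(fio2[j])
            device, flow, prescribed = _device_for(f, float(rr[j]), rng) \
                if on_oxygen else ("room_air", None, None)
            avpu = "A" if avpu_draw[j] < 0.97 else ("V" if avpu_draw[j] < 0.99 else "P")
            observations.append(ObservationSet(
                admission_id=aid,
                timestamp=ts,
                hr=round(float(hr[j]), 1),
                rr=float(rr[j]),
                sbp=round(float(sbp[j]), 1),
                spo2=round(float(spo2[j]), 1),
                temp=round(float(temp[j]), 1),
                avpu=avpu,
                device=device,
                o2_flow_lpm=None if flow is None else round(flow, 4),
                prescribed_fio2=prescribed,
            ))
        admissions.append(Admission(
            admission_id=aid,
            patient_id=pid,
            age_years=age,
            admit_time=admit,
            discharge_time=discharge,
            outcome=outcome,
            event_time=event_time,
        ))
    return admissions, observations


def generate_banded_fio2_labels(
    config: SimConfig,
    n_observations: int | None = None,
) -> list[LabeledObservation]:
    """Labeled observations with a pure planted band-hazard structure.

    FiO2 is drawn from the oxygen-cohort marginal (truncated normal on the
    percent scale, default mean 47 / SD 15, clipped to [21, 100]) and the
    event label follows the per-band probabilities through the planted
    cuts; positives get a uniform time-to-event within 24 h. This is the
    fixture for cut-point recovery: the banding signal is exact, with no
    vital-sign confounding, and the marginal keeps every band populated
    well enough for its cut to be identifiable.
    """
    rng = np.random.default_rng(config.seed)
    n = int(n_observations if n_observations is not None
            else config.n_admissions * config.obs_per_admission)
    mean_pct, sd_pct = config.vital_marginals["fio2_percent"]
    fio2 = np.clip(rng.normal(mean_pct, sd_pct, n) / 100.0, ROOM_AIR_FIO2, 1.0)
    band = np.searchsorted(np.asarray(config.planted_fio2_cuts), fio2, side="left")
    p = np.asarray(config.band_event_probs)[band]
    labels = rng.random(n) < p
    tte = rng.uniform(0.0, 24.0, n)
    base = ObservationSet(
        admission_id="synthetic", timestamp=_EPOCH, hr=80.0, rr=18.0,
        sbp=120.0, spo2=96.0, temp=36.8, avpu="A", device="room_air",
    )
    out: list[LabeledObservation] = []
    for j in range(n):
        obs = replace(base, timestamp=_EPOCH + timedelta(minutes=j))
        if labels[j]:
            out.append(LabeledObservation(obs, True, float(fio2[j]),
                                          time_to_event_h=float(tte[j])))
        else:
            out.append(LabeledObservation(obs, False, float(fio2[j])))
    return out
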