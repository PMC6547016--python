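"""Inspired-oxygen-fraction estimation from oxygen-delivery observations.

For variable-performance devices (nasal cannula, simple and reservoir
masks) the inspired fraction is the oxygen volume fraction of the inhaled
gas mixture under a fixed-tidal-volume assumption:

    FiO2 = (flow + 0.21 * (MV - flow)) / MV,      MV = rr * Vt

with tidal volume Vt = 0.45 L per breath by default, so that minute volume
MV is proportional to the respiratory rate. Fixed-performance (Venturi)
masks deliver their prescribed fraction; high-flow nasal oxygen and
non-invasive ventilation are assigned the ceiling value 1.0. Room air is
0.21. Raw formula values above 1.0 (flow exceeding minute volume) are
clamped to 1.0 and flagged.

The per-device behaviour is configuration, not code: ship charts differ,
so the mapping from device category to behaviour class should be aligned
with the local observation chart via :func:`load_device_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .data_model import ObservationSet

__all__ = [
    "ROOM_AIR_FIO2",
    "DEFAULT_TIDAL_VOLUME_L",
    "DEFAULT_DEVICE_TABLE",
    "DEFAULT_VT_GRID",
    "Fio2Estimate",
    "minute_volume",
    "estimate_fio2",
    "tidal_volume_sensitivity",
    "load_device_table",
]

ROOM_AIR_FIO2 = 0.21
DEFAULT_TIDAL_VOLUME_L = 0.45

#: device category -> behaviour class. "formula" uses the dilution formula,
#: "prescribed" takes the charted fraction, "max" saturates at 1.0.
DEFAULT_DEVICE_TABLE: dict[str, str] = {
    "room_air": "room_air",
    "nasal_cannula": "formula",
    "simple_mask": "formula",
    "reservoir_mask": "formula",
    "fixed_performance_mask": "prescribed",
    "high_flow_nasal": "max",
    "niv": "max",
}

#: default tidal-volume grid (L) for the fixed-Vt sensitivity analysis.
DEFAULT_VT_GRID: tuple[float, ...] = tuple(round(0.30 + 0.05 * i, 2) for i in range(9))


@dataclass(frozen=True)
class Fio2Estimate:
    """An estimated inspired oxygen fraction and how it was obtained."""

    fio2: float
    method: str  # formula | prescribed | saturated_max | room_air
    clamped: bool = False

    def __post_init__(self) -> None:
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValueError(f"fio2 {self.fio2} outside [0.21, 1.0]")
        if self.method == "room_air" and self.fio2 != ROOM_AIR_FIO2:
            raise ValueError("room_air estimates must be 0.21")

    @property
    def percent(self) -> float:
        return 100.0 * self.fio2


def minute_volume(rr: float, tidal_volume_l: float = DEFAULT_TIDAL_VOLUME_L) -> float:
    """Minute volume (L/min) = respiratory rate x tidal volume."""
    if rr <= 0:
        raise ValueError(f"respiratory rate must be > 0, got {rr}")
    if tidal_volume_l <= 0:
        raise ValueError(f"tidal volume must be > 0, got {tidal_volume_l}")
    return rr * tidal_volume_l


def load_device_table(path: str | Path) -> dict[str, str]:
    """Load a device -> behaviour mapping from a YAML file and sanity-check it."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, Mapping):
        raise ValueError(f"device table {path} must be a mapping")
    bad = {d: b for d, b in table.items()
           if b not in {"room_air", "formula", "prescribed", "max"}}
    if bad:
        raise ValueError(f"unknown behaviour class(es): {bad}")
    return {str(d): str(b) for d, b in table.items()}


def estimate_fio2(
    obs: ObservationSet,
    device_table: Mapping[str, str] | None = None,
    tidal_volume_l: float = DEFAULT_TIDAL_VOLUME_L,
) -> Fio2Estimate:
    """Estimate the inspired oxygen fraction for one observation set.

    Dispatch is by the behaviour class of ``obs.device`` in ``device_table``:
    room air gives 0.21, fixed-performance masks return the prescribed
    fraction, saturating modes (high-flow nasal, NIV) return 1.0, and every
    other device goes through the dilution formula with the observation's
    respiratory rate. The result is clamped to [0.21, 1.0] with the
    ``clamped`` flag set whenever the raw formula value fell outside.
    """
    table = DEFAULT_DEVICE_TABLE if device_table is None else device_table
    if obs.device not in table:
        raise ValueError(f"device {obs.device!r} not in device table")
    behaviour = table[obs.device]

    if behaviour == "room_air":
        return Fio2Estimate(ROOM_AIR_FIO2, "room_air")
    if behaviour == "prescribed":
        if obs.prescribed_fio2 is None:
            raise ValueError(f"device {obs.device} requires prescribed_fio2")
        return Fio2Estimate(float(obs.prescribed_fio2), "prescribed")
    if behaviour == "max":
        return Fio2Estimate(1.0, "saturated_max")

    # formula device
    if obs.o2_flow_lpm is None:
        raise ValueError(f"device {obs.device} requires o2_flow_lpm")
    mv = minute_volume(obs.rr, tidal_volume_l)
    flow = float(obs.o2_flow_lpm)
    raw = (flow + ROOM_AIR_FIO2 * (mv - flow)) / mv
    clamped = not ROOM_AIR_FIO2 <= raw <= 1.0
    return Fio2Estimate(min(1.0, max(ROOM_AIR_FIO2, raw)), "formula", clamped=clamped)


def tidal_volume_sensitivity(
    obs: ObservationSet,
    device_table: Mapping[str, str] | None = None,
    vt_grid: Sequence[float] = DEFAULT_VT_GRID,
) -> list[tuple[float, Fio2Estimate]]:
    """Recompute the FiO2 estimate across a tidal-volume grid.

    Quantifies the sensitivity of the fixed-Vt assumption: for formula
    devices at fixed flow the estimate decreases as the assumed tidal
    volume (hence minute volume) grows; non-formula devices are flat.
    """
    if not vt_grid:
        raise ValueError("vt_grid must be non-empty")
    if any(vt <= 0 for vt in vt_grid):
        raise ValueError("all tidal volumes must be positive")
    return [(vt, estimate_fio2(obs, device_table, tidal_volume_l=vt)) for vt in vt_grid]
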