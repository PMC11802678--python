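"""Electrolyte-leakage (EL) injury indices.

The EL assay quantifies cell-membrane damage in needle tissue: conductivity
of the soaking solution is read before and after the membranes are fully
destroyed in an autoclave (121 °C, 20 min), each against an ultrapure-water
blank.  The injury index is the blank-corrected relative conductivity

    INX = 100 * (c_fresh - c_blank_fresh) / (c_auto - c_blank_auto)   [%]

i.e. the fraction of the total leachable electrolyte pool already released
by the (ozone-) injured tissue before autoclaving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError, ValidationError

log = logging.getLogger(__name__)

#: Ratios below this are treated as measurement noise and clipped to 0;
#: anything more negative is rejected as a bad measurement.
NEGATIVE_TOLERANCE_PCT = -0.5

CSV_COLUMNS = ["sample_id", "species", "zone", "series_index",
               "c_blank_fresh", "c_fresh", "c_blank_auto", "c_auto"]


@dataclass(frozen=True)
class ConductivityMeasurement:
    """One EL assay (conductivities in µS cm⁻¹)."""

    sample_id: str
    species: str
    zone: str
    series_index: int
    c_blank_fresh: float
    c_fresh: float
    c_blank_auto: float
    c_auto: float

    def __post_init__(self) -> None:
        vals = (self.c_blank_fresh, self.c_fresh, self.c_blank_auto, self.c_auto)
        if any(v < 0 for v in vals):
            raise ValidationError(
                f"sample {self.sample_id!r}: negative raw conductivity {vals}")
        if not 1 <= self.series_index <= 6:
            raise ValidationError(
                f"sample {self.sample_id!r}: series_index must be in 1..6")


@dataclass(frozen=True)
class InjuryIndex:
    species: str
    zone: str
    series_index: int  # 0 denotes the modelled zero-ozone baseline
    inx: float  # percent, in [0, 100]

    def __post_init__(self) -> None:
        if not 0.0 <= self.inx <= 100.0:
            raise ValidationError(f"inx {self.inx} outside [0, 100]")


def compute_injury_index(m: ConductivityMeasurement) -> InjuryIndex:
    """Blank-corrected relative EL conductivity of one measurement.

    Raises
    ------
    InvalidMeasurementError
        If the post-autoclave denominator is not positive.
    ValidationError
        If the numerator is more negative than measurement noise allows.
    """
    denom = m.c_auto - m.c_blank_auto
    if denom <= 0:
        raise InvalidMeasurementError(
            f"sample {m.sample_id!r}: c_auto - c_blank_auto = {denom} <= 0")
    inx = 100.0 * (m.c_fresh - m.c_blank_fresh) / denom
    if inx < 0:
        if inx < NEGATIVE_TOLERANCE_PCT:
            raise ValidationError(
                f"sample {m.sample_id!r}: injury index {inx:.3f}% is negative "
                "beyond measurement tolerance")
        log.warning("sample %r: tiny negative injury index %.3f%% clipped to 0",
                    m.sample_id, inx)
        inx = 0.0
    inx = min(inx, 100.0)
    return InjuryIndex(m.species, m.zone, m.series_index, inx)


def mean_injury_index(measurements: list[ConductivityMeasurement]
                      ) -> tuple[InjuryIndex, float]:
    """Average replicate measurements after per-replicate computation.

    Returns the mean index and the (population-free, ddof=1) standard
    deviation of the replicate indices; sd is 0.0 for a single replicate.
    """
    if not measurements:
        raise ValidationError("no measurements to average")
    keys = {(m.species, m.zone, m.series_index) for m in measurements}
    if len(keys) > 1:
        raise ValidationError(f"replicates mix several series: {sorted(keys)}")
    values = [compute_injury_index(m).inx for m in measurements]
    species, zone, n = keys.pop()
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return InjuryIndex(species, zone, n, float(np.mean(values))), sd


def read_conductivity_csv(path) -> list[ConductivityMeasurement]:
    """Read the EL assay table (UTF-8, decimal point, header required)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        ConductivityMeasurement(
            sample_id=str(r.sample_id), species=str(r.species), zone=str(r.zone),
            series_index=int(r.series_index),
            c_blank_fresh=float(r.c_blank_fresh), c_fresh=float(r.c_fresh),
            c_blank_auto=float(r.c_blank_auto), c_auto=float(r.c_auto))
        for r in df.itertuples()
    ]


def injury_table(measurements: list[ConductivityMeasurement]) -> pd.DataFrame:
    """Replicate-averaged injury indices, one row per (species, zone, series)."""
    groups: dict[tuple, list[ConductivityMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.zone, m.species, m.series_index), []).append(m)
    rows = []
    for (zone, species, n), ms in sorted(groups.items()):
        idx, sd = mean_injury_index(ms)
        rows.append({"zone": zone, "species": species, "series_index": n,
                     "inx_pct": idx.inx, "inx_sd": sd, "n_replicates": len(ms)})
    return pd.DataFrame(rows)
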