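"""Longitudinal electrode-impedance bookkeeping.

Impedance telemetry is the day-to-day health check of a chronically
implanted intracochlear array: values below 1 kOhm indicate a short
("closed-circuit"), values above 20 kOhm a broken lead or air gap
("open-circuit"); anything in the 1-20 kOhm range is a functional contact.
Logs are kept as tidy pandas DataFrames with one row per measurement and
columns ``animal, ear, electrode, day, mode, kohm``, where ``mode`` is the
reference configuration: common-ground (CG, referenced against the other
intracochlear electrodes) or monopolar (MP, referenced against the
extracochlear ball electrode).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

#: Intracochlear electrode positions, apical (AE1) to basal (AE7).
ELECTRODES: tuple[str, ...] = tuple(f"AE{i}" for i in range(1, 8))

LOG_COLUMNS: tuple[str, ...] = ("animal", "ear", "electrode", "day", "mode", "kohm")

#: Functional impedance window in kOhm (inclusive at both ends).
CLOSED_CIRCUIT_KOHM: float = 1.0
OPEN_CIRCUIT_KOHM: float = 20.0


class Status(str, Enum):
    CLOSED = "closed-circuit"
    FUNCTIONAL = "functional"
    OPEN = "open-circuit"


class Mode(str, Enum):
    CG = "CG"
    MP = "MP"


@dataclass(frozen=True)
class EpochSummary:
    mean_kohm: float
    sd_kohm: float
    n: int


def classify(impedance_kohm: float) -> Status:
    """Classify a single impedance measurement.

    Strictly below 1 kOhm is closed-circuit, strictly above 20 kOhm is
    open-circuit; the boundary values themselves count as functional.
    Every positive impedance maps to exactly one status.
    """
    z = float(impedance_kohm)
    if z <= 0:
        raise ValueError("impedance must be positive")
    if z < CLOSED_CIRCUIT_KOHM:
        return Status.CLOSED
    if z > OPEN_CIRCUIT_KOHM:
        return Status.OPEN
    return Status.FUNCTIONAL


def validate_log(log: pd.DataFrame) -> pd.DataFrame:
    """Check schema and uniqueness of an impedance log."""
    missing = [c for c in LOG_COLUMNS if c not in log.columns]
    if missing:
        raise ValueError(f"impedance log missing column(s): {', '.join(missing)}")
    if log.empty:
        raise ValueError("impedance log is empty")
    if (log["kohm"] <= 0).any():
        raise ValueError("impedances must be positive")
    if (log["day"] < 0).any():
        raise ValueError("post-operative days must be non-negative")
    key = ["animal", "ear", "electrode", "day", "mode"]
    if log.duplicated(subset=key).any():
        raise ValueError("duplicate (animal, ear, electrode, day, mode) records")
    return log


def classify_log(log: pd.DataFrame) -> pd.Series:
    """Vectorized classification; returns a Status-valued series aligned to the log."""
    validate_log(log)
    return log["kohm"].map(lambda z: classify(z))


def epoch_summary(
    log: pd.DataFrame,
    day_range: tuple[int, int],
    mode: Mode | str | None = None,
) -> EpochSummary:
    """Mean and sample (n-1) SD of impedance over an inclusive day range.

    Open- and closed-circuit measurements are excluded from the statistics
    (they reflect hardware failure, not tissue impedance). A single-record
    selection reports sd 0 with n = 1 so the caller can flag it.
    """
    validate_log(log)
    d0, d1 = day_range
    sel = log[(log["day"] >= d0) & (log["day"] <= d1)]
    if mode is not None:
        sel = sel[sel["mode"] == (mode.value if isinstance(mode, Mode) else mode)]
    sel = sel[sel["kohm"].map(lambda z: classify(z) is Status.FUNCTIONAL)]
    if sel.empty:
        raise ValueError(f"no functional records in days [{d0}, {d1}]")
    vals = sel["kohm"].to_numpy(dtype=float)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return EpochSummary(mean_kohm=float(np.mean(vals)), sd_kohm=sd, n=int(vals.size))


def functional_fraction(log: pd.DataFrame) -> dict[str, float]:
    """Percentage of electrode positions that stayed functional throughout.

    A position is one (animal, ear, electrode) triple; it counts as
    functional only if *every* one of its measurements classifies as
    functional. The position-level percentage is the primary statistic;
    the measurement-level percentage (fraction of individual records in
    range) is reported alongside it.
    """
    validate_log(log)
    ok = log["kohm"].map(lambda z: classify(z) is Status.FUNCTIONAL)
    by_pos = ok.groupby([log["animal"], log["ear"], log["electrode"]]).all()
    return {
        "position_percent": float(100.0 * by_pos.mean()),
        "measurement_percent": float(100.0 * ok.mean()),
        "n_positions": int(by_pos.size),
        "n_failed_positions": int((~by_pos).sum()),
    }


def per_position_profile(
    log: pd.DataFrame,
    mode: Mode | str | None = None,
) -> pd.DataFrame:
    """Mean +- sd impedance per electrode position AE1-AE7.

    Pools over animals, ears and days; open/closed measurements are
    excluded. Positions with no (functional) data are absent from the
    result rather than reported as zero.
    """
    validate_log(log)
    sel = log
    if mode is not None:
        sel = sel[sel["mode"] == (mode.value if isinstance(mode, Mode) else mode)]
    sel = sel[sel["kohm"].map(lambda z: classify(z) is Status.FUNCTIONAL)]
    if sel.empty:
        raise ValueError("no functional records for the requested mode")
    grouped = sel.groupby("electrode")["kohm"]
    prof = pd.DataFrame(
        {
            "mean_kohm": grouped.mean(),
            "sd_kohm": grouped.std(ddof=1).fillna(0.0),
            "n": grouped.size(),
        }
    )
    # keep canonical apical-to-basal ordering for the positions present
    order = [e for e in ELECTRODES if e in prof.index]
    extra = [e for e in prof.index if e not in ELECTRODES]
    return prof.loc[order + extra]
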