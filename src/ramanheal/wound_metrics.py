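"""Wound morphometry and light-dose arithmetic.

The wound is treated as an ellipse measured by two caliper diameters A and
B (mm): S = A*B*pi/4.  Closure on a given day is the fraction of the day-0
area that has disappeared, [(S0 - S)/S0] * 100; a wound that grew reports a
negative closure (never clipped).  Continuous-wave light doses scale
linearly with exposure time at constant irradiance, so 4 J/cm^2 delivered
at the irradiance that gives 1 J/cm^2 in 3 min 45 s takes 15 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .band_analysis import ttest_two_sample

__all__ = [
    "WoundRecord",
    "DosePlan",
    "wound_area",
    "closure_percent",
    "exposure_time",
    "closure_curve",
]


def wound_area(A: float, B: float) -> float:
    """Elliptical wound area S = A*B*pi/4 from two caliper diameters (mm)."""
    if A < 0 or B < 0:
        raise ValueError(f"diameters must be >= 0, got A={A}, B={B}")
    return A * B * np.pi / 4.0


def closure_percent(S0: float, S: float) -> float:
    """Percentage of the day-0 wound area closed: [(S0 - S)/S0] * 100."""
    if S0 <= 0:
        raise ValueError(f"day-0 area must be > 0, got {S0}")
    if S < 0:
        raise ValueError(f"wound area must be >= 0, got {S}")
    return (S0 - S) / S0 * 100.0


def exposure_time(dose: float, reference_dose: float, reference_time: float) -> float:
    """Exposure time (s) for a CW dose at the irradiance of a reference dose."""
    if dose <= 0 or reference_dose <= 0 or reference_time <= 0:
        raise ValueError("dose, reference dose and reference time must be > 0")
    return reference_time * dose / reference_dose


@dataclass(frozen=True)
class WoundRecord:
    """One caliper measurement with its day-0 baseline area."""

    A: float
    B: float
    day: int
    S0: float

    def __post_init__(self) -> None:
        if self.B > self.A:
            raise ValueError("A must be the major diameter (A >= B)")
        wound_area(self.A, self.B)  # validates signs

    @property
    def S(self) -> float:
        return wound_area(self.A, self.B)

    @property
    def closure(self) -> float:
        return closure_percent(self.S0, self.S)


@dataclass(frozen=True)
class DosePlan:
    """CW exposure plan at the irradiance implied by a reference pair."""

    dose: float
    reference_dose: float = 1.0
    reference_time: float = 225.0  # 3 min 45 s for 1 J/cm^2

    @property
    def time(self) -> float:
        return exposure_time(self.dose, self.reference_dose, self.reference_time)


def closure_curve(records: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Per-(group, day) mean +/- SD closure %, with t-tests versus control.

    ``records`` needs columns group, day, mouse_id, A, B and must contain a
    day-0 row per (group, mouse) defining S0.  Returns one row per
    (group, day > 0) with n, mean/SD closure, and the p-value of a pooled
    two-sample t-test against the control group on the same day (NaN where
    no test applies, e.g. for the control row itself or degenerate samples).
    """
    req = {"group", "day", "mouse_id", "A", "B"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    df = records.copy()
    df["S"] = [wound_area(a, b) for a, b in zip(df["A"], df["B"])]

    s0 = df[df["day"] == 0].set_index(["group", "mouse_id"])["S"]
    closures = []
    for _, row in df[df["day"] > 0].iterrows():
        key = (row["group"], row["mouse_id"])
        if key not in s0.index:
            raise ValueError(f"no day-0 record for group/mouse {key}")
        closures.append(
            {
                "group": row["group"],
                "day": int(row["day"]),
                "closure": closure_percent(float(s0.loc[key]), float(row["S"])),
            }
        )
    cl = pd.DataFrame(closures)

    rows = []
    for (group, day), sub in cl.groupby(["group", "day"], sort=True):
        vals = sub["closure"].to_numpy()
        p = np.nan
        if group != control_group:
            ctrl = cl[(cl["group"] == control_group) & (cl["day"] == day)]["closure"]
            if len(vals) >= 2 and len(ctrl) >= 2:
                try:
                    p = ttest_two_sample(vals, ctrl.to_numpy()).p
                except ValueError:
                    p = np.nan
        rows.append(
            {
                "group": group,
                "day": int(day),
                "n": len(vals),
                "mean_closure": float(vals.mean()),
                "sd_closure": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "p_vs_control": p,
            }
        )
    return pd.DataFrame(rows)
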