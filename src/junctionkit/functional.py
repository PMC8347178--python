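"""Functional barrier assays: TER normalization and dextran-flux quantification.

Transendothelial electrical resistance (TER) of a monolayer on a porous
filter insert is obtained by subtracting the blank-filter resistance and
multiplying by the effective filter area (0.33 cm² for a 12-well insert):

    TER = (R_raw − R_blank) · A        [Ω·cm²]

Treatment effects are expressed as fold changes TER_t / TER_initial,
normalized to the same ratio in medium-only controls.  Paracellular flux
of FITC-dextran is read off a linear fluorescence calibration curve and
reported as percent of control.  Conditions are compared with a classical
two-sample (equal-variance) Student t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TERMeasurement",
    "CalibrationCurve",
    "FluxMeasurement",
    "ComparisonResult",
    "compute_ter",
    "ter_fold_change",
    "fit_calibration",
    "calibrate_and_quantify_flux",
    "compare_conditions",
    "recover_ter_fold_changes",
    "recover_flux_percent",
]

DEFAULT_AREA_CM2 = 0.33


@dataclass(frozen=True)
class TERMeasurement:
    raw_ohm: float
    blank_ohm: float
    area_cm2: float = DEFAULT_AREA_CM2
    timepoint_h: float = 0.0
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.raw_ohm < 0:
            raise ValueError("raw_ohm must be >= 0")
        if self.area_cm2 <= 0:
            raise ValueError("area_cm2 must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, fluorescence_au: float | np.ndarray) -> np.ndarray:
        """Invert the line AU = slope·conc + intercept; clip negatives to 0."""
        conc = (np.asarray(fluorescence_au, dtype=float) - self.intercept) / self.slope
        if np.any(conc < 0):
            warnings.warn("negative inferred concentration clipped to 0", stacklevel=2)
            conc = np.clip(conc, 0.0, None)
        return conc


@dataclass(frozen=True)
class FluxMeasurement:
    fluorescence_au: float
    condition: str
    compartment: str = "basolateral"
    timepoint_h: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.fluorescence_au < 0:
            raise ValueError("fluorescence_au must be >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    flagged: bool = False


def compute_ter(m: TERMeasurement) -> float:
    """Blank-subtracted, area-normalized resistance in Ω·cm².

    A raw resistance below the blank yields a negative TER; it is returned
    (not silently clipped) with a warning so the measurement can be flagged.
    """
    ter = (m.raw_ohm - m.blank_ohm) * m.area_cm2
    if m.raw_ohm < m.blank_ohm:
        warnings.warn(
            f"raw resistance {m.raw_ohm} below blank {m.blank_ohm}: negative TER",
            stacklevel=2,
        )
    return ter


def ter_fold_change(ter_t: float, ter_initial: float, control_ratio: float = 1.0) -> float:
    """Treated TER_t / TER_initial ratio normalized to the control ratio."""
    if ter_initial <= 0 or control_ratio <= 0:
        raise ValueError("ter_initial and control_ratio must be > 0")
    return (ter_t / ter_initial) / control_ratio


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Unweighted OLS line AU = slope·conc + intercept through the standards."""
    conc = np.asarray([s[0] for s in standards], dtype=float)
    au = np.asarray([s[1] for s in standards], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct standard concentrations")
    res = stats.linregress(conc, au)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def calibrate_and_quantify_flux(
    standards: Sequence[tuple[float, float]],
    samples: Sequence[FluxMeasurement],
    control_condition: str = "control",
) -> tuple[pd.DataFrame, float, CalibrationCurve]:
    """Per-sample dextran concentrations and flux as percent of control.

    Returns (per-sample table with a ``conc`` column, percent_of_control,
    fitted calibration curve) where
    ``percent_of_control = 100 · mean(treated conc) / mean(control conc)``.
    """
    curve = fit_calibration(standards)
    table = pd.DataFrame(
        dict(
            condition=[s.condition for s in samples],
            replicate=[s.replicate for s in samples],
            fluorescence_au=[s.fluorescence_au for s in samples],
        )
    )
    table["conc"] = curve.concentration(table["fluorescence_au"].to_numpy())
    control = table.loc[table.condition == control_condition, "conc"]
    treated = table.loc[table.condition != control_condition, "conc"]
    if control.empty or treated.empty:
        raise ValueError("need both control and treated samples")
    percent = 100.0 * treated.mean() / control.mean()
    return table, float(percent), curve


def compare_conditions(a: Sequence[float], b: Sequence[float]) -> ComparisonResult:
    """Classical equal-variance two-sample t-test with group summaries.

    Degenerate cases: zero pooled variance with equal means gives t=0, p=1;
    zero pooled variance with unequal means gives p=0 and a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return ComparisonResult(mean_a, sd_a, mean_b, sd_b, 0.0, 1.0)
        return ComparisonResult(
            mean_a, sd_a, mean_b, sd_b,
            t_statistic=np.inf if mean_a > mean_b else -np.inf,
            p_value=0.0, flagged=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(mean_a, sd_a, mean_b, sd_b, float(t), float(p))


# ---------------------------------------------------------------------------
# recovery from tabular records (generator or instrument export)
# ---------------------------------------------------------------------------


def recover_ter_fold_changes(
    ter_table: pd.DataFrame,
    treated_condition: str = "treated",
    control_condition: str = "control",
    baseline_timepoint: float = 0.0,
) -> pd.DataFrame:
    """Fold changes TER_t/TER_0 per replicate, normalized to the control mean.

    Expects columns condition, replicate, timepoint_h, raw_ohm, blank_ohm,
    area_cm2.  Returns one row per (timepoint, replicate) with the
    normalized fold change of the treated condition.
    """
    df = ter_table.copy()
    df["ter"] = [
        compute_ter(TERMeasurement(r.raw_ohm, r.blank_ohm, r.area_cm2))
        for r in df.itertuples()
    ]
    wide = df.pivot_table(
        index=["condition", "replicate"], columns="timepoint_h", values="ter"
    )
    base = wide[baseline_timepoint]
    out_rows = []
    for t in [c for c in wide.columns if c != baseline_timepoint]:
        ratio = wide[t] / base
        control_ratio = ratio.loc[control_condition].mean()
        for rep, r in ratio.loc[treated_condition].items():
            out_rows.append(
                dict(
                    timepoint_h=t,
                    replicate=rep,
                    fold_change=ter_fold_change(r, 1.0, control_ratio),
                )
            )
    return pd.DataFrame(out_rows)


def recover_flux_percent(
    flux_table: pd.DataFrame,
    standards_table: pd.DataFrame,
    control_condition: str = "control",
) -> float:
    """Percent-of-control dextran flux from generator-format tables."""
    standards = list(
        zip(standards_table["conc_mg_ml"], standards_table["fluorescence_au"])
    )
    samples = [
        FluxMeasurement(
            fluorescence_au=r.fluorescence_au,
            condition=r.condition,
            compartment=getattr(r, "compartment", "basolateral"),
            replicate=getattr(r, "replicate", 0),
        )
        for r in flux_table.itertuples()
    ]
    _, percent, _ = calibrate_and_quantify_flux(
        standards, samples, control_condition=control_condition
    )
    return percent
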