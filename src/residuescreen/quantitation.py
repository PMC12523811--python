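"""Matrix-matched quantitation and method-validation arithmetic.

Calibration is an ordinary unweighted least-squares line through
(concentration, peak area) points of matrix-matched standards; samples are
back-calculated through the inverse line. Validation statistics follow the
conventions of multi-residue method validation: recovery as measured/spiked
x 100 with a relative standard deviation over replicates, matrix effect as
the matrix/solvent area ratio x 100 banded into negligible / moderate /
strong, a gravimetric co-extract removal rate, a recovery- and
precision-gated limit of quantification, and in-range fraction summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "QuantResult",
    "RecoveryResult",
    "ValidationSummary",
    "fit_calibration",
    "quantify",
    "recovery_stats",
    "matrix_effect",
    "classify_me",
    "removal_rate",
    "determine_loq",
    "range_fraction",
    "RECOVERY_BAND",
    "RSD_MAX",
]

RECOVERY_BAND = (60.0, 120.0)  # acceptance band for LOQ gating, %
RSD_MAX = 20.0                 # precision gate, %


def _round1(x: float) -> float:
    return float(round(x, 1))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted matrix-matched line ``area = slope * conc + intercept``."""

    compound: str
    slope: float
    intercept: float
    r2: float
    level_range: tuple[float, float]     # ug/kg
    points: tuple[tuple[float, float], ...] = ()

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


@dataclass(frozen=True)
class QuantResult:
    concentration: float  # ug/kg
    below_curve: bool = False
    extrapolated: bool = False


@dataclass(frozen=True)
class RecoveryResult:
    compound: str
    level: float            # spiked, ug/kg
    mean_recovery: float    # %
    rsd: float | None       # %, None for n < 2
    n: int


@dataclass(frozen=True)
class ValidationSummary:
    """Per-compound method-validation record (one report row)."""

    compound: str
    sdl: float | None             # ug/kg
    loq: float | None             # ug/kg
    curve: CalibrationCurve | None
    recoveries: tuple[RecoveryResult, ...]  # at LOQ, 2xLOQ, 20xLOQ
    me: float | None              # %
    me_band: str | None


def fit_calibration(
    points: Sequence[tuple[float, float]], compound: str = ""
) -> CalibrationCurve:
    """Unweighted OLS of peak area on concentration.

    Requires at least three distinct non-negative concentration levels.
    """
    conc = np.array([p[0] for p in points], dtype=float)
    area = np.array([p[1] for p in points], dtype=float)
    if conc.size and conc.min() < 0:
        raise ValueError("concentrations must be >= 0")
    if len(np.unique(conc)) < 3:
        raise ValueError("calibration needs at least 3 distinct concentration levels")
    fit = stats.linregress(conc, area)
    return CalibrationCurve(
        compound=compound,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        level_range=(float(conc.min()), float(conc.max())),
        points=tuple((float(c), float(a)) for c, a in zip(conc, area)),
    )


def quantify(area: float, curve: CalibrationCurve) -> QuantResult:
    """Back-calculate a concentration; flags instead of suppression.

    Areas below the intercept report 0 with ``below_curve`` set; values
    outside the calibrated range are flagged ``extrapolated`` but returned
    as-is (real samples can legitimately exceed the top standard).
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    conc = (area - curve.intercept) / curve.slope
    lo, hi = curve.level_range
    if conc < 0:
        return QuantResult(0.0, below_curve=True, extrapolated=False)
    return QuantResult(conc, below_curve=False, extrapolated=not lo <= conc <= hi)


def recovery_stats(
    measured: Sequence[float], spiked: float, compound: str = ""
) -> RecoveryResult:
    """Mean recovery (%) and RSD (%) of replicate measured concentrations.

    RSD is the sample standard deviation (n-1) of the per-replicate
    recoveries over their mean, x100; undefined (None) for one replicate.
    """
    if spiked <= 0:
        raise ValueError("spiked concentration must be positive")
    if not measured:
        raise ValueError("no replicates")
    rec = 100.0 * np.asarray(measured, dtype=float) / spiked
    mean = float(rec.mean())
    rsd = None
    if rec.size >= 2 and mean != 0:
        rsd = float(100.0 * rec.std(ddof=1) / mean)
    return RecoveryResult(compound, spiked, mean, rsd, int(rec.size))


def matrix_effect(area_matrix: float, area_solvent: float) -> float:
    """ME(%) = matrix-matched area / solvent area x 100."""
    if area_solvent <= 0:
        raise ValueError("solvent-standard area must be positive")
    return 100.0 * area_matrix / area_solvent


def classify_me(me: float) -> str:
    """Band a matrix effect: negligible 80-120, moderate 50-80 / 120-150, else strong.

    Boundaries are closed on the negligible side (80 and 120 are
    negligible); 50 and 150 are moderate; strictly beyond is strong.
    """
    if me < 0:
        raise ValueError("matrix effect must be >= 0")
    if 80.0 <= me <= 120.0:
        return "negligible"
    if 50.0 <= me < 80.0 or 120.0 < me <= 150.0:
        return "moderate"
    return "strong"


def removal_rate(w_unpurified: float, w_purified: float) -> float:
    """Gravimetric co-extract removal (%), reported at one decimal."""
    if w_unpurified <= 0:
        raise ValueError("unpurified co-extract weight must be positive")
    if w_purified < 0:
        raise ValueError("weights must be >= 0")
    return _round1(100.0 * (w_unpurified - w_purified) / w_unpurified)


def determine_loq(
    level_data: Sequence[tuple[float, bool, Sequence[float]]],
    recovery_band: tuple[float, float] = RECOVERY_BAND,
    rsd_max: float = RSD_MAX,
) -> float | None:
    """Lowest level passing confirmation, recovery and precision gates.

    ``level_data`` holds ``(level, confirmed, measured concentrations)``
    tuples; each level needs at least three replicates. A level passes when
    the compound is confirmed there, the mean recovery falls inside
    ``recovery_band`` and the RSD does not exceed ``rsd_max``.
    """
    for level, confirmed, measured in sorted(level_data, key=lambda t: t[0]):
        if len(measured) < 3:
            raise ValueError(f"level {level}: LOQ gating needs >= 3 replicates")
        if not confirmed:
            continue
        res = recovery_stats(measured, level)
        if res.rsd is None:
            continue
        if recovery_band[0] <= res.mean_recovery <= recovery_band[1] and res.rsd <= rsd_max:
            return level
    return None


def range_fraction(
    values: Sequence[float], lo: float, hi: float
) -> tuple[int, float]:
    """Count and percentage (one decimal) of values inside [lo, hi]."""
    if len(values) == 0:
        return 0, 0.0
    count = int(sum(1 for v in values if lo <= v <= hi))
    return count, _round1(100.0 * count / len(values))
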