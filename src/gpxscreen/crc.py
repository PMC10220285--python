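"""Concentration-response curve fitting, classification and quality calls.

Responses are % remaining enzyme activity (100 = uninhibited); the
four-parameter logistic (4PL)

    y(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

descends from ``top`` toward ``bottom`` as concentration increases, so
``ic50`` is the inflection (relative IC50) of the fitted curve. Fitting is
multi-start bounded least squares; the concentration axis is log10 molar.

Curve classes follow the qHTS taxonomy: -1.1/-1.2 complete curves
(both asymptotes observed) with high/partial efficacy, -2.1/-2.2
incomplete curves, -3 activity only at the single top concentration,
4 inactive. Active-quality categories combine curve class with maximal
response and an IC50 <= 20 uM ceiling.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .plates import DoseSeries

__all__ = [
    "CurveClass",
    "Quality",
    "DoseResponseSeries",
    "CRCFit",
    "fit_4pl",
    "compute_auc",
    "classify_curve",
    "quality_category",
    "fit_and_classify",
    "series_from_table",
    "fits_to_frame",
]

IC50_CEILING = 20e-6  # molar; active-quality compounds must be at least this potent


class CurveClass(float, enum.Enum):
    """qHTS concentration-response curve classes (negative = inhibition)."""

    complete_high = -1.1
    complete_partial = -1.2
    incomplete_high = -2.1
    incomplete_partial = -2.2
    single_top_dose = -3.0
    inactive = 4.0


class Quality(str, enum.Enum):
    high = "high"
    low = "low"
    inconclusive = "inconclusive"
    inactive = "inactive"


@dataclass(frozen=True)
class DoseResponseSeries:
    """Per-compound (concentration, % activity) observations, replicates
    included as individual points."""

    compound_id: str
    assay: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise ValidationError("concentrations and responses differ in length")
        if any(c <= 0 for c in self.concentrations):
            raise ValidationError("concentrations must be > 0")

    @property
    def tested_range(self) -> tuple[float, float]:
        return min(self.concentrations), max(self.concentrations)

    def per_concentration_means(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.concentrations)
        y = np.asarray(self.responses)
        uniq = np.unique(c)
        means = np.array([y[c == u].mean() for u in uniq])
        return uniq, means


@dataclass
class CRCFit:
    compound_id: str
    assay: str
    top: float
    bottom: float
    ic50: float | None
    hill: float
    rss: float
    r2: float
    max_response: float  # fitted % remaining activity at top tested conc
    auc: float = math.nan
    curve_class: CurveClass | None = None
    quality: Quality | None = None
    tested_range: tuple[float, float] = (math.nan, math.nan)
    fold: float = 3.0
    converged: bool = True

    @property
    def efficacy(self) -> float:
        """% inhibition at the top tested concentration (fitted)."""
        return 100.0 - self.max_response

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if self.ic50 is None:
            return np.full_like(conc, self.top)
        return _model4pl(conc, self.top, self.bottom, self.ic50, self.hill)


def _model4pl(c, top, bottom, ic50, hill):
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_4pl(series: DoseResponseSeries, fold: float = 3.0) -> CRCFit:
    """Bounded multi-start least-squares 4PL fit.

    Starts span a grid of log10 IC50 over the tested range crossed with
    Hill slopes {0.5, 1, 2}; bounds are top in [50, 150], bottom in
    [-20, 100], hill in [0.3, 5], IC50 within the tested range extended one
    dilution step either side. The best start by residual sum of squares
    wins.
    """
    c = np.asarray(series.concentrations, dtype=float)
    y = np.asarray(series.responses, dtype=float)
    if np.unique(c).size < 4:
        raise FitError(
            f"{series.compound_id}: need >= 4 distinct concentrations, "
            f"have {np.unique(c).size}"
        )
    logc = np.log10(c)
    lo, hi = logc.min(), logc.max()
    step = math.log10(fold)
    ln10 = math.log(10.0)

    def resid(theta):
        top, bottom, logic50, hill = theta
        u = 10.0 ** (hill * (logc - logic50))
        return bottom + (top - bottom) / (1.0 + u) - y

    def jac(theta):
        top, bottom, logic50, hill = theta
        x = logc - logic50
        u = 10.0 ** (hill * x)
        inv = 1.0 / (1.0 + u)
        w = (top - bottom) * u * inv * inv  # (top-bottom) u / (1+u)^2
        return np.column_stack(
            (inv, 1.0 - inv, w * hill * ln10, -w * ln10 * x)
        )

    bounds = (
        np.array([50.0, -20.0, lo - step, 0.3]),
        np.array([150.0, 100.0, hi + step, 5.0]),
    )
    top0 = float(np.clip(y.max(), 50.0, 150.0))
    bot0 = float(np.clip(y.min(), -20.0, 100.0))
    if bot0 >= top0:
        bot0 = top0 - 1.0
    starts = []
    n_grid = 7
    for logic50 in np.linspace(lo - step / 2, hi + step / 2, n_grid):
        for hill0 in (0.5, 1.0, 2.0):
            theta0 = np.clip(
                [top0, bot0, logic50, hill0], bounds[0] + 1e-12, bounds[1] - 1e-12
            )
            starts.append((float(np.sum(resid(theta0) ** 2)), theta0))
    # polish the most promising grid starts; best final RSS wins
    starts.sort(key=lambda s: s[0])
    best = None
    for _rss0, theta0 in starts[:5]:
        try:
            sol = least_squares(
                resid, theta0, jac=jac, bounds=bounds, method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, sol)
        if rss <= 1e-16 * max(1.0, float(np.sum(y**2))):
            break
    if best is None:
        return CRCFit(
            compound_id=series.compound_id,
            assay=series.assay,
            top=float(np.mean(y)),
            bottom=float(np.mean(y)),
            ic50=None,
            hill=1.0,
            rss=float(np.sum((y - y.mean()) ** 2)),
            r2=0.0,
            max_response=float(np.mean(y)),
            quality=Quality.inconclusive,
            tested_range=series.tested_range,
            fold=fold,
            converged=False,
        )
    rss, sol = best
    top, bottom, logic50, hill = sol.x
    ic50 = 10.0**logic50
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    max_resp = float(_model4pl(c.max(), top, bottom, ic50, hill))
    return CRCFit(
        compound_id=series.compound_id,
        assay=series.assay,
        top=float(top),
        bottom=float(bottom),
        ic50=float(ic50),
        hill=float(hill),
        rss=rss,
        r2=float(r2),
        max_response=max_resp,
        tested_range=series.tested_range,
        fold=fold,
    )


def compute_auc(fit: CRCFit, series: DoseSeries | None = None, n_grid: int = 512) -> float:
    """Normalized area under the inhibition curve over the tested range.

    Trapezoidal integral of fitted percent inhibition (100 - y) over log10
    concentration, divided by the log-range: a curve fully inhibited at
    every tested concentration scores 100, a flat 100%-activity curve 0.
    """
    if series is not None:
        cmin, cmax = series.bottom, series.top
    else:
        cmin, cmax = fit.tested_range
    if not (cmin > 0 and cmax > cmin):
        raise ValidationError("invalid concentration range for AUC")
    grid = np.logspace(math.log10(cmin), math.log10(cmax), n_grid)
    inhibition = 100.0 - fit.predict(grid)
    auc = np.trapezoid(inhibition, np.log10(grid)) / (
        math.log10(cmax) - math.log10(cmin)
    )
    return float(auc)


# classification thresholds; the qHTS curve-class algorithm itself is not
# public, so this is a documented approximation keyed to its verbal
# definitions (see docs/methods.md)
EFFICACY_HIGH = 80.0  # % inhibition for a .1 subclass
EFFICACY_MIN = 30.0  # below this a curve is inactive
R2_MIN = 0.3
PLATEAU_TOL = 0.10  # fraction of (top - bottom)
TOP_ONLY_OTHERS_MAX = 10.0  # % inhibition allowed off the top dose for class -3


def classify_curve(fit: CRCFit, series: DoseResponseSeries | None = None) -> CurveClass:
    """Assign the qHTS curve class; total on every fitted curve.

    Order of rules: single-top-dose activity (-3, judged on the observed
    per-concentration means) first, then inactive (efficacy < 30% or
    r2 < 0.3), then complete (-1.x) vs incomplete (-2.x) with the .1/.2
    split at 80% inhibition. "Complete" requires the fitted IC50 to sit at
    least one dilution step inside both ends of the tested range and the
    response at the top tested concentration to be within 10% of
    (top - bottom) of the lower asymptote.
    """
    if series is not None:
        uniq, means = series.per_concentration_means()
        if uniq.size >= 2:
            inhib = 100.0 - means
            if inhib[-1] >= EFFICACY_MIN and np.all(
                inhib[:-1] < TOP_ONLY_OTHERS_MAX
            ):
                return CurveClass.single_top_dose
    if not fit.converged or fit.ic50 is None:
        return CurveClass.inactive
    if fit.efficacy < EFFICACY_MIN or fit.r2 < R2_MIN:
        return CurveClass.inactive
    cmin, cmax = fit.tested_range
    step = math.log10(fit.fold)
    log_ic50 = math.log10(fit.ic50)
    inside = (
        log_ic50 >= math.log10(cmin) + step
        and log_ic50 <= math.log10(cmax) - step
    )
    span = fit.top - fit.bottom
    plateau = (
        span > 0 and abs(fit.max_response - fit.bottom) <= PLATEAU_TOL * span
    )
    complete = inside and plateau
    high = fit.efficacy >= EFFICACY_HIGH
    if complete:
        return CurveClass.complete_high if high else CurveClass.complete_partial
    return CurveClass.incomplete_high if high else CurveClass.incomplete_partial


class QualityVariant(str, enum.Enum):
    """Which printed active-quality definition to apply.

    ``triage``: high-quality requires a complete curve class, <= 25%
    remaining activity and IC50 <= 20 uM. ``primary``: the primary-screen
    hit definition -- > 50% reduction in activity, IC50 <= 20 uM and a
    complete curve.
    """

    triage = "triage"
    primary = "primary"


def quality_category(
    fit: CRCFit, variant: QualityVariant | str = QualityVariant.triage
) -> Quality:
    """Map a classified fit to {high, low, inactive, inconclusive}."""
    variant = QualityVariant(variant)
    if fit.curve_class is None:
        raise ValidationError("classify_curve must run before quality_category")
    if not fit.converged:
        return Quality.inconclusive
    cc = fit.curve_class
    complete = cc in (CurveClass.complete_high, CurveClass.complete_partial)
    curve_ok = complete or cc in (
        CurveClass.incomplete_high,
        CurveClass.incomplete_partial,
    )
    potent = fit.ic50 is not None and fit.ic50 <= IC50_CEILING
    if variant == QualityVariant.primary:
        if complete and fit.max_response <= 50.0 and potent:
            return Quality.high
    else:
        if complete and fit.max_response <= 25.0 and potent:
            return Quality.high
    if curve_ok and fit.max_response <= 50.0 and potent:
        return Quality.low
    return Quality.inactive


def fit_and_classify(
    series: DoseResponseSeries,
    fold: float = 3.0,
    variant: QualityVariant | str = QualityVariant.triage,
) -> CRCFit:
    """Fit, compute AUC, classify and grade one series in a single call."""
    fit = fit_4pl(series, fold=fold)
    if fit.converged:
        fit.auc = compute_auc(fit)
    fit.curve_class = classify_curve(fit, series)
    if not fit.converged:
        fit.quality = Quality.inconclusive
        return fit
    if fit.curve_class == CurveClass.inactive and fit.efficacy < EFFICACY_MIN:
        fit.ic50 = None  # a flat curve carries no meaningful IC50
    fit.quality = quality_category(fit, variant)
    return fit


def series_from_table(
    wells: pd.DataFrame, assay: str | None = None
) -> list[DoseResponseSeries]:
    """Group a normalized-well table into per-compound dose series.

    Expects columns compound, concentration_molar, percent_activity and
    (optionally) assay; control wells (no compound) are skipped.
    """
    df = wells[wells["compound"].notna() & (wells["compound"] != "")]
    if assay is not None:
        df = df[df["assay"] == assay]
    out = []
    group_cols = ["compound"] + (["assay"] if "assay" in df.columns else [])
    for key, grp in df.groupby(group_cols, sort=True):
        compound = key[0] if isinstance(key, tuple) else key
        a = key[1] if isinstance(key, tuple) and len(key) > 1 else (assay or "")
        out.append(
            DoseResponseSeries(
                compound_id=str(compound),
                assay=str(a),
                concentrations=tuple(grp["concentration_molar"].astype(float)),
                responses=tuple(grp["percent_activity"].astype(float)),
            )
        )
    return out


def fits_to_frame(fits: Sequence[CRCFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "compound": f.compound_id,
                "assay": f.assay,
                "top": f.top,
                "bottom": f.bottom,
                "ic50_molar": f.ic50,
                "hill": f.hill,
                "auc": f.auc,
                "rss": f.rss,
                "r2": f.r2,
                "max_response": f.max_response,
                "curve_class": f.curve_class.value if f.curve_class else None,
                "quality": f.quality.value if f.quality else None,
            }
        )
    return pd.DataFrame(rows)
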