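"""Melting-temperature extraction from nanoDSF ratio curves.

nanoDSF tracks intrinsic tryptophan fluorescence at 330 and 350 nm during
a thermal ramp (30-90 C); unfolding shifts the emission ratio F350/F330,
and the melting temperature Tm is the inflection of the ratio curve --
located here as a peak of the smoothed first derivative d(ratio)/dT. Up to
two transitions are reported (ligand-bound subpopulations can melt
separately); Delta-Tm statistics across replicate capillaries use Welch's
unequal-variance two-tailed t-test with the conventional significance
bands (* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import ttest_ind

from .errors import DataError, ValidationError

__all__ = [
    "MeltCurve",
    "TmResult",
    "DeltaTmResult",
    "detect_tm",
    "delta_tm",
    "significance_band",
    "welch_t",
    "read_melt_csv",
    "write_melt_csv",
]


@dataclass
class MeltCurve:
    capillary_id: str
    condition: str
    temperatures: np.ndarray  # degrees C, strictly increasing, within [30, 90]
    f330: np.ndarray
    f350: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        t = self.temperatures
        if t.size != self.f330.size or t.size != self.f350.size:
            raise ValidationError("temperature and fluorescence arrays differ")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if t.size and (t[0] < 30.0 - 1e-9 or t[-1] > 90.0 + 1e-9):
            raise ValidationError("temperatures must lie within [30, 90] C")
        if np.any(self.f330 <= 0):
            raise ValidationError("f330 must be > 0 wherever the ratio is defined")

    @property
    def ratio(self) -> np.ndarray:
        return self.f350 / self.f330


@dataclass
class TmResult:
    capillary_id: str
    tm_list: tuple[float, ...]  # ascending, at most 2
    prominences: tuple[float, ...] = ()
    no_transition: bool = False
    condition: str = ""


@dataclass(frozen=True)
class DeltaTmResult:
    """Per-transition Tm shift of a treated group vs its control group."""

    delta_tm: float
    p_value: float
    band: str
    n_treated: int
    n_control: int
    transition_mismatch: bool = False


def detect_tm(
    curve: MeltCurve,
    smooth_window_c: float = 2.0,
    prominence_frac: float = 0.2,
    max_transitions: int = 2,
) -> TmResult:
    """Locate up to two unfolding transitions from the ratio derivative.

    The ratio is smoothed with a Savitzky-Golay filter (window
    ``smooth_window_c`` degrees, cubic; the instrument's own algorithm is
    proprietary, so the window is a tunable), differentiated, and derivative
    peaks above ``prominence_frac`` of the maximum derivative are kept.
    Each peak temperature is refined by local quadratic interpolation, so
    Tm resolution is finer than the temperature grid. Ties and extra peaks
    resolve toward lower temperature (ascending report order, at most
    ``max_transitions`` kept by prominence).
    """
    t = curve.temperatures
    if t.size < 50:
        raise DataError(
            f"{curve.capillary_id}: need >= 50 temperature points, have {t.size}"
        )
    step = float(np.median(np.diff(t)))
    window = max(5, int(round(smooth_window_c / step)) | 1)
    window = min(window, t.size - 1 if (t.size - 1) % 2 else t.size - 2)
    smoothed = savgol_filter(curve.ratio, window_length=window, polyorder=3)
    deriv = np.gradient(smoothed, t)
    dmax = float(np.max(np.abs(deriv)))
    if dmax <= 0 or not math.isfinite(dmax):
        return TmResult(curve.capillary_id, (), no_transition=True,
                        condition=curve.condition)
    peaks, props = find_peaks(deriv, prominence=prominence_frac * dmax)
    if peaks.size == 0:
        return TmResult(curve.capillary_id, (), no_transition=True,
                        condition=curve.condition)
    prom = props["prominences"]
    # keep the most prominent peaks; equal prominence -> lower temperature
    order = np.lexsort((peaks, -prom))
    keep = np.sort(order[:max_transitions])
    tms, proms = [], []
    half = max(1, window // 4)
    for k in keep:
        i = peaks[k]
        lo_i, hi_i = max(0, i - half), min(t.size, i + half + 1)
        if hi_i - lo_i >= 3:
            # local quadratic least-squares around the peak; vertex = Tm
            coef = np.polyfit(t[lo_i:hi_i] - t[i], deriv[lo_i:hi_i], 2)
            if coef[0] < 0:
                offset = float(
                    np.clip(-coef[1] / (2 * coef[0]), -half * step, half * step)
                )
            else:
                offset = 0.0
            tms.append(float(t[i] + offset))
        else:
            tms.append(float(t[i]))
        proms.append(float(prom[k]))
    order2 = np.argsort(tms)
    return TmResult(
        capillary_id=curve.capillary_id,
        tm_list=tuple(np.asarray(tms)[order2]),
        prominences=tuple(np.asarray(proms)[order2]),
        condition=curve.condition,
    )


def significance_band(p: float) -> str:
    """Map a p-value to the conventional star band (strict thresholds)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance two-tailed t-test; returns (t, p).

    Degenerate case: if every value in both groups is identical, the
    difference is exactly zero with no evidence against it -> (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 replicates per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def delta_tm(
    treated: Sequence[TmResult], control: Sequence[TmResult]
) -> list[DeltaTmResult]:
    """Tm shift (treated - control) per transition with Welch statistics.

    Transitions are matched between groups by nearest mean temperature;
    when the groups report different transition counts the extra
    transitions are matched to the nearest control transition and flagged.
    """
    if len(treated) < 2 or len(control) < 2:
        raise ValidationError("need >= 2 replicate TmResults per group")
    n_t = max((len(r.tm_list) for r in treated), default=0)
    n_c = max((len(r.tm_list) for r in control), default=0)
    if n_t == 0 or n_c == 0:
        raise DataError("a group reports no transitions; no Delta-Tm defined")
    mismatch = n_t != n_c

    def group_matrix(results: Sequence[TmResult], n: int) -> np.ndarray:
        rows = []
        for r in results:
            if len(r.tm_list) == 0:
                continue
            row = list(r.tm_list) + [r.tm_list[-1]] * (n - len(r.tm_list))
            rows.append(row[:n])
        return np.asarray(rows)

    tmat = group_matrix(treated, n_t)
    cmat = group_matrix(control, n_c)
    c_means = cmat.mean(axis=0)
    out = []
    for j in range(n_t):
        t_vals = tmat[:, j]
        jc = int(np.argmin(np.abs(c_means - t_vals.mean())))
        c_vals = cmat[:, jc]
        _t, p = welch_t(t_vals, c_vals)
        out.append(
            DeltaTmResult(
                delta_tm=float(t_vals.mean() - c_vals.mean()),
                p_value=p,
                band=significance_band(p),
                n_treated=int(t_vals.size),
                n_control=int(c_vals.size),
                transition_mismatch=mismatch,
            )
        )
    return out


MELT_CSV_COLUMNS = ["capillary_id", "condition", "temperature_c", "f330", "f350"]


def write_melt_csv(curves: Sequence[MeltCurve], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(MELT_CSV_COLUMNS + ["ratio"])
        for c in curves:
            ratio = c.ratio
            for i in range(c.temperatures.size):
                w.writerow(
                    [
                        c.capillary_id,
                        c.condition,
                        repr(float(c.temperatures[i])),
                        repr(float(c.f330[i])),
                        repr(float(c.f350[i])),
                        repr(float(ratio[i])),
                    ]
                )


def read_melt_csv(path) -> list[MeltCurve]:
    by_cap: dict[str, dict[str, list]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(MELT_CSV_COLUMNS) <= set(
            reader.fieldnames
        ):
            raise DataError(
                f"{path}: expected columns {', '.join(MELT_CSV_COLUMNS)}"
            )
        for row in reader:
            d = by_cap.setdefault(
                row["capillary_id"],
                {"condition": row.get("condition", ""), "t": [], "f330": [], "f350": []},
            )
            d["t"].append(float(row["temperature_c"]))
            d["f330"].append(float(row["f330"]))
            d["f350"].append(float(row["f350"]))
    return [
        MeltCurve(
            capillary_id=cap,
            condition=d["condition"],
            temperatures=np.asarray(d["t"]),
            f330=np.asarray(d["f330"]),
            f350=np.asarray(d["f350"]),
        )
        for cap, d in by_cap.items()
    ]
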