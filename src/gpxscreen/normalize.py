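"""Delta-RFU computation, percent-activity normalization and plate QC.

Percent activity anchors each well between the plate's own DMSO-treated
controls: the median delta-RFU of enzyme controls defines 100% and that of
no-enzyme controls defines 0%. Values are deliberately not clipped to
[0, 100]; downstream curve fitting sees raw normalized responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, QCError
from .plates import Assay, Channel, PlateRecord, WellRecord, WellRole

__all__ = [
    "NormalizedWell",
    "PlateQC",
    "delta_rfu",
    "percent_activity",
    "plate_qc",
    "normalize_plate",
    "normalize_plates",
]


@dataclass(frozen=True)
class NormalizedWell:
    plate_id: str
    well: str
    role: WellRole
    compound_id: str | None
    concentration: float | None
    delta_rfu: float
    percent_activity: float

    @property
    def percent_remaining(self) -> float:
        """Alias: % activity is % remaining enzyme activity."""
        return self.percent_activity


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    zprime: float
    signal_to_background: float
    n_pos: int
    n_neg: int
    pos_median: float
    neg_median: float
    pos_sd: float
    neg_sd: float
    passed: bool


def delta_rfu(well: WellRecord, channel: Channel) -> float:
    """Signed signal change between the t=0 and endpoint reads.

    NADPH-consumption assays report the *decrease* in fluorescence
    (t0 - endpoint), the mBBr endpoint assay the *increase*
    (endpoint - t0): each is the direction in which the assay's signal
    develops over the read window.
    """
    reads = well.reads_on(channel)
    if len(reads) < 2:
        raise DataError(
            f"well {well.plate_id}/{well.well}: need t0 and endpoint reads "
            f"on {channel.value}, found {len(reads)}"
        )
    first, last = reads[0], reads[-1]
    if channel == Channel.mbbr_394_490:
        return last.rfu - first.rfu
    return first.rfu - last.rfu


def percent_activity(delta: float, pos_median: float, neg_median: float) -> float:
    """100 * (delta - neg) / (pos - neg); may leave [0, 100] for noisy wells."""
    if pos_median == neg_median:
        raise QCError("degenerate controls: pos and neg medians are equal")
    return 100.0 * (delta - neg_median) / (pos_median - neg_median)


def _control_deltas(
    plate: PlateRecord,
    channel: Channel,
    role: WellRole,
    mask_outliers: bool,
) -> np.ndarray:
    vals = np.array(
        [delta_rfu(w, channel) for w in plate.wells_by_role(role)], dtype=float
    )
    if mask_outliers and vals.size >= 4:
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        # floor the cut so a lone bad dispense is still masked when the
        # remaining controls are (near-)identical
        cut = 5.0 * mad if mad > 0 else 1e-9 * max(1.0, abs(med))
        vals = vals[np.abs(vals - med) <= cut]
    return vals


def plate_qc(
    plate: PlateRecord,
    channel: Channel | None = None,
    zprime_threshold: float = 0.5,
    mask_outliers: bool = True,
) -> PlateQC:
    """Z'-factor and signal:background from the plate's control wells.

    Z' = 1 - 3 (sd_pos + sd_neg) / |median_pos - median_neg| and
    S/B = median_pos / median_neg, both on control delta-RFU. Controls more
    than 5 MAD from their group median are masked before the statistics
    (configurable), since a single dispense failure should not sink a plate.
    """
    if channel is None:
        channel = plate.assay.channel
    pos = _control_deltas(plate, channel, WellRole.pos_control, mask_outliers)
    neg = _control_deltas(plate, channel, WellRole.neg_control, mask_outliers)
    if pos.size < 4 or neg.size < 4:
        raise QCError(
            f"plate {plate.plate_id}: need >= 4 usable controls per group, "
            f"have {pos.size} pos / {neg.size} neg"
        )
    pos_median = float(np.median(pos))
    neg_median = float(np.median(neg))
    pos_sd = float(np.std(pos, ddof=1))
    neg_sd = float(np.std(neg, ddof=1))
    sep = abs(pos_median - neg_median)
    if sep == 0:
        raise QCError(f"plate {plate.plate_id}: degenerate controls")
    zprime = 1.0 - 3.0 * (pos_sd + neg_sd) / sep
    sb = pos_median / neg_median if neg_median != 0 else np.inf
    return PlateQC(
        plate_id=plate.plate_id,
        zprime=zprime,
        signal_to_background=float(sb),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        pos_median=pos_median,
        neg_median=neg_median,
        pos_sd=pos_sd,
        neg_sd=neg_sd,
        passed=bool(zprime >= zprime_threshold),
    )


def normalize_plate(
    plate: PlateRecord,
    channel: Channel | None = None,
    zprime_threshold: float = 0.5,
    mask_outliers: bool = True,
) -> tuple[list[NormalizedWell], PlateQC]:
    """Normalize every readable well of a plate against its own controls."""
    if channel is None:
        channel = plate.assay.channel
    qc = plate_qc(
        plate,
        channel,
        zprime_threshold=zprime_threshold,
        mask_outliers=mask_outliers,
    )
    out = []
    for w in plate.wells:
        if w.role == WellRole.empty or len(w.reads_on(channel)) < 2:
            continue
        d = delta_rfu(w, channel)
        out.append(
            NormalizedWell(
                plate_id=plate.plate_id,
                well=w.well,
                role=w.role,
                compound_id=w.compound_id,
                concentration=w.concentration,
                delta_rfu=d,
                percent_activity=percent_activity(d, qc.pos_median, qc.neg_median),
            )
        )
    return out, qc


def normalize_plates(
    plates, zprime_threshold: float = 0.5, mask_outliers: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a collection of plates into tidy DataFrames.

    Returns (wells, qc): one row per normalized well with plate/assay
    context, and one row per plate with QC statistics. Failing plates are
    kept but flagged; callers decide whether to gate on them.
    """
    well_rows, qc_rows = [], []
    for plate in plates:
        wells, qc = normalize_plate(
            plate,
            zprime_threshold=zprime_threshold,
            mask_outliers=mask_outliers,
        )
        qc_rows.append(
            {
                "plate": qc.plate_id,
                "assay": plate.assay.value,
                "zprime": qc.zprime,
                "signal_to_background": qc.signal_to_background,
                "n_pos": qc.n_pos,
                "n_neg": qc.n_neg,
                "pos_median": qc.pos_median,
                "neg_median": qc.neg_median,
                "pos_sd": qc.pos_sd,
                "neg_sd": qc.neg_sd,
                "passed": qc.passed,
            }
        )
        for nw in wells:
            well_rows.append(
                {
                    "plate": nw.plate_id,
                    "assay": plate.assay.value,
                    "well": nw.well,
                    "role": nw.role.value,
                    "compound": nw.compound_id,
                    "concentration_molar": nw.concentration,
                    "delta_rfu": nw.delta_rfu,
                    "percent_activity": nw.percent_activity,
                }
            )
    return pd.DataFrame(well_rows), pd.DataFrame(qc_rows)
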