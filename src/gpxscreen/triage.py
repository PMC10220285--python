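"""The hit-triage decision tree.

Primary-screen actives are reconfirmed in 11-point dose response, weak
(top-dose-only) actives removed, coupling-enzyme (GR) inhibitors excluded
as false positives, and the survivors placed into specificity categories
using the TXNRD1 and GPX2 counter/isoform assays:

* pan_selenoprotein  - inhibits GPX1, GPX4 and TXNRD1 but not GR
* pan_gpx            - inhibits GPX1 and GPX4, not TXNRD1
* sec_cross_reactive - inhibits a GPX and TXNRD1 (not GR), e.g. the
                       auranofin profile (GPX1/GPX2 + TXNRD1, GPX4 inactive)
* gpx1_gpx2_specific - GPX1 active, GPX4 inactive (GPX2 activity is
                       recorded, not exclusionary: every GPX1 inhibitor of
                       the screen also inhibited GPX2)
* gpx4_specific      - GPX4 active, GPX1/GPX2 inactive

"Active" in a counter- or isoform assay means meeting the low-quality-or-
better activity bar: curve class -1.x/-2.x, <= 50% remaining activity and
IC50 <= 20 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .crc import CRCFit, CurveClass, Quality, QualityVariant, quality_category
from .errors import TriageError, ValidationError
from .simulate import SpecificityCategory

__all__ = [
    "CompoundPanelProfile",
    "TriageOutcome",
    "ScreenSummary",
    "is_active",
    "call_primary_hits",
    "reconfirm",
    "apply_counterscreens",
    "classify_specificity",
    "summarize_screen",
    "export_profile_matrix",
    "run_triage",
    "cross_activity_percent",
]

PRIMARY_ASSAYS = ("gpx1", "gpx4")
NOT_TESTED = "NT"


def is_active(fit: CRCFit | None, level: Quality = Quality.low) -> bool:
    """Does a fit meet the activity bar (low-quality-or-better by default)?"""
    if fit is None:
        return False
    q = quality_category(fit, QualityVariant.triage)
    if level == Quality.high:
        return q == Quality.high
    return q in (Quality.high, Quality.low)


@dataclass
class CompoundPanelProfile:
    """One compound's fits across the assay panel plus triage stage flags."""

    compound_id: str
    fits: dict[str, CRCFit] = field(default_factory=dict)
    stage_flags: set[str] = field(default_factory=set)

    def fit(self, assay: str) -> CRCFit | None:
        return self.fits.get(assay)

    def tested(self, assay: str) -> bool:
        return assay in self.fits


@dataclass(frozen=True)
class TriageOutcome:
    compound_id: str
    category: SpecificityCategory
    rationale: tuple[str, ...]


@dataclass(frozen=True)
class ScreenSummary:
    """Stage-by-stage attrition counts and the screen's headline rates."""

    n_screened: int
    n_primary_hits_gpx1: int
    n_primary_hits_gpx4: int
    n_initial_hits: int
    n_reconfirmed: int
    n_top_dose_only: int
    n_confirmed: int
    n_gr_active: int
    n_after_gr: int
    n_txnrd1_active: int
    hit_rate_gpx1: float
    hit_rate_gpx4: float
    cross_activity: dict[str, float] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def from_counts(
        n_screened: int,
        n_primary_hits_gpx1: int,
        n_primary_hits_gpx4: int,
        n_reconfirmed: int,
        n_top_dose_only: int,
        n_gr_active: int,
        n_txnrd1_active: int,
        n_initial_hits: int | None = None,
        cross_counts: Mapping[str, tuple[int, int]] | None = None,
        category_counts: Mapping[str, int] | None = None,
    ) -> "ScreenSummary":
        """Build a summary from stage counts alone.

        ``cross_counts`` maps a label to (|A intersect B|, |A|) pairs and is
        reported as rounded whole percentages.
        """
        if n_screened <= 0:
            raise ValidationError("n_screened must be > 0")
        cross = {
            label: cross_activity_percent(k, n)
            for label, (k, n) in (cross_counts or {}).items()
        }
        return ScreenSummary(
            n_screened=n_screened,
            n_primary_hits_gpx1=n_primary_hits_gpx1,
            n_primary_hits_gpx4=n_primary_hits_gpx4,
            n_initial_hits=(
                n_initial_hits
                if n_initial_hits is not None
                else n_primary_hits_gpx1 + n_primary_hits_gpx4
            ),
            n_reconfirmed=n_reconfirmed,
            n_top_dose_only=n_top_dose_only,
            n_confirmed=n_reconfirmed - n_top_dose_only,
            n_gr_active=n_gr_active,
            n_after_gr=n_reconfirmed - n_top_dose_only - n_gr_active,
            n_txnrd1_active=n_txnrd1_active,
            hit_rate_gpx1=round(100.0 * n_primary_hits_gpx1 / n_screened, 1),
            hit_rate_gpx4=round(100.0 * n_primary_hits_gpx4 / n_screened, 1),
            cross_activity=cross,
            category_counts=dict(category_counts or {}),
        )

    def to_dict(self) -> dict:
        return {
            "n_screened": self.n_screened,
            "n_primary_hits_gpx1": self.n_primary_hits_gpx1,
            "n_primary_hits_gpx4": self.n_primary_hits_gpx4,
            "n_initial_hits": self.n_initial_hits,
            "n_reconfirmed": self.n_reconfirmed,
            "n_top_dose_only": self.n_top_dose_only,
            "n_confirmed": self.n_confirmed,
            "n_gr_active": self.n_gr_active,
            "n_after_gr": self.n_after_gr,
            "n_txnrd1_active": self.n_txnrd1_active,
            "hit_rate_gpx1": self.hit_rate_gpx1,
            "hit_rate_gpx4": self.hit_rate_gpx4,
            "cross_activity": dict(self.cross_activity),
            "category_counts": dict(self.category_counts),
        }


def cross_activity_percent(n_cross: int, n_total: int) -> float:
    """100 * |A intersect B| / |A|, rounded to a whole percent."""
    if n_total <= 0:
        raise ValidationError("cross-activity denominator must be > 0")
    return float(round(100.0 * n_cross / n_total))


def call_primary_hits(
    primary_fits: Mapping[str, Mapping[str, CRCFit]],
) -> dict[str, set[str]]:
    """High-quality hit sets per primary assay.

    The primary-screen hit definition: > 50% reduction in activity,
    IC50 <= 20 uM and a complete curve. Also returns the pan-active
    intersection under key ``"pan"``.
    """
    hits: dict[str, set[str]] = {}
    for assay, fits in primary_fits.items():
        hits[assay] = {
            cid
            for cid, fit in fits.items()
            if quality_category(fit, QualityVariant.primary) == Quality.high
        }
    sets = [hits[a] for a in hits]
    hits["pan"] = set.intersection(*sets) if sets else set()
    return hits


def call_initial_hits(
    primary_fits: Mapping[str, Mapping[str, CRCFit]],
) -> dict[str, set[str]]:
    """Initial (follow-up-eligible) hit sets: low-quality-or-better.

    The screen carried forward more compounds than the high-quality count
    -- anything with a credible curve (class -1.x/-2.x, <= 50% remaining,
    IC50 <= 20 uM) was reacquired for 11-point confirmation; weak and
    partial actives are then culled by reconfirmation, not at this stage.
    """
    hits: dict[str, set[str]] = {}
    for assay, fits in primary_fits.items():
        hits[assay] = {cid for cid, fit in fits.items() if is_active(fit)}
    sets = [hits[a] for a in hits]
    hits["pan"] = set.intersection(*sets) if sets else set()
    return hits


def reconfirm(
    profiles: Mapping[str, CompoundPanelProfile],
    primary_hits: Iterable[str],
    followup_assays: Sequence[str] = PRIMARY_ASSAYS,
) -> None:
    """Flag reconfirmation of primary hits from 11-point follow-up fits.

    ``reconfirmed`` means the follow-up shows activity (low-quality-or-
    better, or single-top-dose class); ``top_dose_only`` marks the class -3
    weak actives that are excluded downstream. Hits with no follow-up fit
    at all are flagged ``inconclusive`` rather than silently dropped.
    """
    for cid in primary_hits:
        profile = profiles.get(cid)
        if profile is None or not any(profile.tested(a) for a in followup_assays):
            if profile is not None:
                profile.stage_flags.add("inconclusive")
            continue
        active = False
        top_only = False
        for a in followup_assays:
            fit = profile.fit(a)
            if fit is None:
                continue
            if is_active(fit):
                active = True
            if fit.curve_class == CurveClass.single_top_dose:
                top_only = True
        if active or top_only:
            profile.stage_flags.add("reconfirmed")
        if top_only and not active:
            profile.stage_flags.add("top_dose_only")


def apply_counterscreens(profiles: Mapping[str, CompoundPanelProfile]) -> None:
    """Record counter-/isoform-assay activity flags on each profile."""
    for profile in profiles.values():
        if is_active(profile.fit("gr_counter")):
            profile.stage_flags.add("gr_active")
        if is_active(profile.fit("txnrd1")):
            profile.stage_flags.add("txnrd1_active")
        if is_active(profile.fit("gpx2")):
            profile.stage_flags.add("gpx2_active")
        mbbr_fits = [
            profile.fit(a)
            for a in ("mbbr_gpx1", "mbbr_gpx4")
            if profile.tested(a)
        ]
        if mbbr_fits and any(is_active(f) for f in mbbr_fits):
            profile.stage_flags.add("orthogonal_confirmed")


def classify_specificity(profile: CompoundPanelProfile) -> TriageOutcome:
    """Place one compound in exactly one specificity category.

    Rule order: excluded stages (not reconfirmed, weak top-dose-only,
    GR false positive) before specificity; then pan_selenoprotein >
    pan_gpx > sec_cross_reactive > gpx1_gpx2_specific > gpx4_specific >
    inactive.
    """
    flags = profile.stage_flags
    rationale: list[str] = []

    def done(cat: SpecificityCategory) -> TriageOutcome:
        if cat != SpecificityCategory.inactive and not rationale:
            raise TriageError(
                f"{profile.compound_id}: category {cat.value} with empty "
                f"rationale; flags={sorted(flags)}"
            )
        return TriageOutcome(profile.compound_id, cat, tuple(rationale))

    if not flags & {"primary_hit_gpx1", "primary_hit_gpx4"}:
        return done(SpecificityCategory.inactive)
    rationale.append(
        "primary hit in "
        + "/".join(
            a for a in PRIMARY_ASSAYS if f"primary_hit_{a}" in flags
        )
    )
    if "reconfirmed" not in flags:
        rationale.append("did not reconfirm in 11-point follow-up")
        return done(SpecificityCategory.not_reconfirmed)
    if "top_dose_only" in flags:
        rationale.append("follow-up activity only at the top concentration")
        return done(SpecificityCategory.weak_top_dose_only)
    if "gr_active" in flags:
        rationale.append("inhibits the coupling enzyme GR")
        return done(SpecificityCategory.gr_false_positive)

    gpx1a = is_active(profile.fit("gpx1"))
    gpx4a = is_active(profile.fit("gpx4"))
    gpx2a = "gpx2_active" in flags
    txa = "txnrd1_active" in flags
    if gpx1a and gpx4a and txa:
        rationale.append("inhibits GPX1, GPX4 and TXNRD1; GR inactive")
        return done(SpecificityCategory.pan_selenoprotein)
    if gpx1a and gpx4a:
        rationale.append("inhibits GPX1 and GPX4; TXNRD1 and GR inactive")
        return done(SpecificityCategory.pan_gpx)
    if (gpx1a or gpx4a) and txa:
        rationale.append("GPX activity shared with TXNRD1 (Sec cross-reactive)")
        return done(SpecificityCategory.sec_cross_reactive)
    if gpx1a:
        rationale.append(
            "GPX1 active, GPX4 inactive"
            + ("; GPX2 co-inhibited" if gpx2a else "")
        )
        return done(SpecificityCategory.gpx1_gpx2_specific)
    if gpx4a:
        rationale.append("GPX4 active, GPX1/GPX2 inactive")
        return done(SpecificityCategory.gpx4_specific)
    rationale.append("reconfirmed but no follow-up GPX activity")
    return done(SpecificityCategory.not_reconfirmed)


def run_triage(
    profiles: Mapping[str, CompoundPanelProfile],
    primary_fits: Mapping[str, Mapping[str, CRCFit]],
) -> dict[str, TriageOutcome]:
    """Run the full decision tree over a profile collection.

    Stage order follows the screen's published flow: primary hit calling,
    11-point reconfirmation with weak-active removal, GR counter-screen
    exclusion, then TXNRD1/GPX2 specificity assignment. Outcomes are
    independent of compound input order.
    """
    initial = call_initial_hits(primary_fits)
    hq = call_primary_hits(primary_fits)
    for assay in PRIMARY_ASSAYS:
        for cid in initial.get(assay, ()):
            if cid in profiles:
                profiles[cid].stage_flags.add(f"primary_hit_{assay}")
        for cid in hq.get(assay, ()):
            if cid in profiles:
                profiles[cid].stage_flags.add(f"primary_hq_{assay}")
    all_hits = set().union(*(initial.get(a, set()) for a in PRIMARY_ASSAYS))
    reconfirm(profiles, all_hits)
    apply_counterscreens(profiles)
    return {
        cid: classify_specificity(profile)
        for cid, profile in sorted(profiles.items())
    }


def summarize_screen(
    profiles: Mapping[str, CompoundPanelProfile],
    outcomes: Mapping[str, TriageOutcome],
    n_screened: int,
) -> ScreenSummary:
    """Stage counts, hit rates and cross-activity percentages from triage."""
    if n_screened <= 0:
        raise ValidationError("n_screened must be > 0")
    # hit rates report the high-quality definition; attrition tracks the
    # broader initial-hit set that actually entered follow-up
    hits1 = {c for c, p in profiles.items() if "primary_hq_gpx1" in p.stage_flags}
    hits4 = {c for c, p in profiles.items() if "primary_hq_gpx4" in p.stage_flags}
    initial = {
        c
        for c, p in profiles.items()
        if p.stage_flags & {"primary_hit_gpx1", "primary_hit_gpx4"}
    }
    reconfirmed = {
        c for c, p in profiles.items() if "reconfirmed" in p.stage_flags
    }
    top_only = {
        c for c, p in profiles.items() if "top_dose_only" in p.stage_flags
    }
    confirmed = reconfirmed - top_only
    gr_active = {c for c in confirmed if "gr_active" in profiles[c].stage_flags}
    after_gr = confirmed - gr_active
    tx_active = {
        c for c in after_gr if "txnrd1_active" in profiles[c].stage_flags
    }
    gpx1_after = {c for c in after_gr if is_active(profiles[c].fit("gpx1"))}
    gpx4_after = {
        c
        for c in after_gr
        if is_active(profiles[c].fit("gpx4")) and c not in gpx1_after
    }
    cross: dict[str, float] = {}
    conf1 = {c for c in confirmed if is_active(profiles[c].fit("gpx1"))}
    conf4 = {c for c in confirmed if is_active(profiles[c].fit("gpx4"))}
    if conf1:
        cross["gpx1_gr_pct"] = cross_activity_percent(
            len(conf1 & gr_active), len(conf1)
        )
    if conf4:
        cross["gpx4_gr_pct"] = cross_activity_percent(
            len(conf4 & gr_active), len(conf4)
        )
    if gpx1_after:
        cross["gpx1_txnrd1_pct"] = cross_activity_percent(
            len(gpx1_after & tx_active), len(gpx1_after)
        )
    if gpx4_after:
        cross["gpx4_txnrd1_pct"] = cross_activity_percent(
            len(gpx4_after & tx_active), len(gpx4_after)
        )
    cat_counts: dict[str, int] = {}
    for out in outcomes.values():
        cat_counts[out.category.value] = cat_counts.get(out.category.value, 0) + 1
    return ScreenSummary(
        n_screened=n_screened,
        n_primary_hits_gpx1=len(hits1),
        n_primary_hits_gpx4=len(hits4),
        n_initial_hits=len(initial),
        n_reconfirmed=len(reconfirmed),
        n_top_dose_only=len(top_only),
        n_confirmed=len(confirmed),
        n_gr_active=len(gr_active),
        n_after_gr=len(after_gr),
        n_txnrd1_active=len(tx_active),
        hit_rate_gpx1=round(100.0 * len(hits1) / n_screened, 1),
        hit_rate_gpx4=round(100.0 * len(hits4) / n_screened, 1),
        cross_activity=cross,
        category_counts=cat_counts,
    )


def export_profile_matrix(
    profiles: Mapping[str, CompoundPanelProfile],
    assays: Sequence[str] = ("gpx1", "gpx2", "gpx4", "gr_counter", "txnrd1"),
) -> pd.DataFrame:
    """Compounds x assays matrix of mean % remaining activity at the top
    tested concentration.

    Untested cells carry NaN (written as the explicit sentinel ``NT`` in
    CSV exports, never 0). Rows are ordered by average-linkage hierarchical
    clustering on Euclidean distance between profiles, so identical
    profiles end up adjacent.
    """
    compounds = sorted(profiles)
    data = np.full((len(compounds), len(assays)), np.nan)
    for i, cid in enumerate(compounds):
        for j, assay in enumerate(assays):
            fit = profiles[cid].fit(assay)
            if fit is not None:
                data[i, j] = fit.max_response
    df = pd.DataFrame(data, index=compounds, columns=list(assays))
    if len(compounds) > 2:
        filled = df.to_numpy(copy=True)
        col_means = np.array(
            [
                np.nanmean(col) if np.isfinite(col).any() else 100.0
                for col in filled.T
            ]
        )
        idx = np.where(np.isnan(filled))
        filled[idx] = np.take(col_means, idx[1])
        order = leaves_list(linkage(filled, method="average", metric="euclidean"))
        df = df.iloc[order]
    return df


def write_profile_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, na_rep=NOT_TESTED)
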