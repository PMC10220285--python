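import numpy as np
import pytest

from gpxscreen.crc import CRCFit, CurveClass, Quality
from gpxscreen.simulate import SpecificityCategory
from gpxscreen.triage import (
    CompoundPanelProfile,
    ScreenSummary,
    apply_counterscreens,
    call_initial_hits,
    call_primary_hits,
    classify_specificity,
    cross_activity_percent,
    export_profile_matrix,
    reconfirm,
    run_triage,
    summarize_screen,
)


def _fit(
    cid,
    assay,
    active=True,
    curve_class=CurveClass.complete_high,
    max_response=10.0,
    ic50=2e-6,
):
    """A classified fit; ``active=False`` gives a flat inactive curve."""
    if not active:
        curve_class, max_response, ic50 = CurveClass.inactive, 100.0, None
    return CRCFit(
        compound_id=cid,
        assay=assay,
        top=100.0,
        bottom=max_response,
        ic50=ic50,
        hill=1.0,
        rss=1.0,
        r2=0.98,
        max_response=max_response,
        curve_class=curve_class,
        tested_range=(842.5e-12, 49.8e-6),
    )


def _profile(cid, actives, inactives=(), flags=()):
    p = CompoundPanelProfile(compound_id=cid)
    for a in actives:
        p.fits[a] = _fit(cid, a, active=True)
    for a in inactives:
        p.fits[a] = _fit(cid, a, active=False)
    p.stage_flags |= set(flags)
    return p


BASE_FLAGS = {"primary_hit_gpx1", "primary_hit_gpx4", "reconfirmed"}


class TestPrimaryHitCalling:
    def test_hit_definition(self):
        fits = {
            "gpx1": {
                "strong": _fit("strong", "gpx1", max_response=40.0, ic50=5e-6),
                "incomplete": _fit(
                    "incomplete",
                    "gpx1",
                    curve_class=CurveClass.incomplete_partial,
                    max_response=40.0,
                ),
                "weakresp": _fit("weakresp", "gpx1", max_response=60.0),
                "flat": _fit("flat", "gpx1", active=False),
            }
        }
        hits = call_primary_hits(fits)
        # >50% reduction + IC50 <= 20 uM + complete CRC
        assert hits["gpx1"] == {"strong"}
        # initial (follow-up) set additionally carries incomplete curves
        assert call_initial_hits(fits)["gpx1"] == {"strong", "incomplete"}

    def test_pan_active_intersection(self):
        fits = {
            "gpx1": {"a": _fit("a", "gpx1"), "b": _fit("b", "gpx1")},
            "gpx4": {"a": _fit("a", "gpx4"), "b": _fit("b", "gpx4", active=False)},
        }
        assert call_primary_hits(fits)["pan"] == {"a"}


class TestReconfirmation:
    def test_top_dose_only_flagged_and_counted(self):
        profiles = {
            "ok": _profile("ok", ["gpx1"]),
            "weak": _profile("weak", [], inactives=[]),
            "gone": _profile("gone", [], inactives=["gpx1"]),
        }
        profiles["weak"].fits["gpx1"] = _fit(
            "weak", "gpx1", curve_class=CurveClass.single_top_dose,
            max_response=60.0, ic50=None,
        )
        reconfirm(profiles, ["ok", "weak", "gone"])
        assert "reconfirmed" in profiles["ok"].stage_flags
        assert {"reconfirmed", "top_dose_only"} <= profiles["weak"].stage_flags
        assert "reconfirmed" not in profiles["gone"].stage_flags

    def test_missing_followup_marked_inconclusive(self):
        profiles = {"lost": CompoundPanelProfile("lost")}
        reconfirm(profiles, ["lost"])
        assert "inconclusive" in profiles["lost"].stage_flags
        assert "reconfirmed" not in profiles["lost"].stage_flags

    def test_attrition_bookkeeping_matches_screen_arithmetic(self):
        """215 reconfirmed minus 44 weak actives leaves 171 confirmed."""
        s = ScreenSummary.from_counts(
            n_screened=11_892,
            n_primary_hits_gpx1=180,
            n_primary_hits_gpx4=318,
            n_reconfirmed=215,
            n_top_dose_only=44,
            n_gr_active=94,
            n_txnrd1_active=30,
        )
        assert s.n_confirmed == 171
        assert s.n_reconfirmed - s.n_top_dose_only == s.n_confirmed


class TestCounterscreens:
    def test_gr_activity_flags_false_positive(self):
        p = _profile(
            "fp", ["gpx1", "gr_counter"], inactives=["gpx4"], flags=BASE_FLAGS
        )
        apply_counterscreens({"fp": p})
        assert "gr_active" in p.stage_flags
        out = classify_specificity(p)
        assert out.category == SpecificityCategory.gr_false_positive
        assert out.rationale

    def test_txnrd1_cross_reactivity(self):
        p = _profile(
            "x", ["gpx1", "gpx2", "txnrd1"], inactives=["gpx4", "gr_counter"],
            flags=BASE_FLAGS,
        )
        apply_counterscreens({"x": p})
        assert "txnrd1_active" in p.stage_flags
        assert (
            classify_specificity(p).category
            == SpecificityCategory.sec_cross_reactive
        )

    def test_clean_profile_gains_no_flags(self):
        p = _profile("clean", ["gpx1"], inactives=["gr_counter", "txnrd1", "gpx2"])
        before = set(p.stage_flags)
        apply_counterscreens({"clean": p})
        assert p.stage_flags == before


class TestSpecificityExemplars:
    """The screen's published exemplar activity profiles."""

    def _classify(self, actives, inactives):
        p = _profile("c", actives, inactives=inactives, flags=BASE_FLAGS)
        apply_counterscreens({"c": p})
        return classify_specificity(p).category

    def test_auranofin_like_profile(self):
        # GPX1+, GPX2+, GPX4-, TXNRD1+, GR- -> Sec cross-reactive
        cat = self._classify(
            ["gpx1", "gpx2", "txnrd1"], ["gpx4", "gr_counter"]
        )
        assert cat == SpecificityCategory.sec_cross_reactive

    def test_metamizole_like_profile(self):
        # all GPXs+, TXNRD1-, GR- -> pan-GPX
        cat = self._classify(
            ["gpx1", "gpx2", "gpx4"], ["txnrd1", "gr_counter"]
        )
        assert cat == SpecificityCategory.pan_gpx

    def test_dimercaptopropanesulfonate_like_profile(self):
        # all GPXs+ and TXNRD1+, GR- -> pan-selenoprotein
        cat = self._classify(
            ["gpx1", "gpx2", "gpx4", "txnrd1"], ["gr_counter"]
        )
        assert cat == SpecificityCategory.pan_selenoprotein

    def test_venetoclax_like_profile(self):
        # GPX4 only -> GPX4-specific
        cat = self._classify(
            ["gpx4"], ["gpx1", "gpx2", "txnrd1", "gr_counter"]
        )
        assert cat == SpecificityCategory.gpx4_specific

    def test_gpx1_branch_with_gpx2_coactivity(self):
        cat = self._classify(
            ["gpx1", "gpx2"], ["gpx4", "txnrd1", "gr_counter"]
        )
        assert cat == SpecificityCategory.gpx1_gpx2_specific

    def test_all_inactive(self):
        p = _profile("dud", [], inactives=["gpx1", "gpx4"])
        assert (
            classify_specificity(p).category == SpecificityCategory.inactive
        )


class TestPartitionAndOrderInvariance:
    def test_every_compound_gets_exactly_one_category(self):
        rng = np.random.default_rng(12)
        assays = ["gpx1", "gpx2", "gpx4", "gr_counter", "txnrd1"]
        profiles = {}
        primary = {"gpx1": {}, "gpx4": {}}
        for i in range(40):
            cid = f"r{i}"
            actives = [a for a in assays if rng.random() < 0.5]
            inactives = [a for a in assays if a not in actives]
            profiles[cid] = _profile(cid, actives, inactives=inactives)
            for a in ("gpx1", "gpx4"):
                primary[a][cid] = profiles[cid].fits[a]
        outcomes = run_triage(profiles, primary)
        assert set(outcomes) == set(profiles)
        for out in outcomes.values():
            assert isinstance(out.category, SpecificityCategory)

    def test_input_order_never_changes_outcomes(self):
        def build(order):
            profiles = {}
            primary = {"gpx1": {}, "gpx4": {}}
            for cid, actives, inactives in order:
                profiles[cid] = _profile(cid, actives, inactives=inactives)
                for a in ("gpx1", "gpx4"):
                    primary[a][cid] = profiles[cid].fits[a]
            return {
                c: o.category
                for c, o in run_triage(profiles, primary).items()
            }

        spec = [
            ("a", ["gpx1", "gpx2"], ["gpx4", "gr_counter", "txnrd1"]),
            ("b", ["gpx4"], ["gpx1", "gpx2", "gr_counter", "txnrd1"]),
            ("c", ["gpx1", "gpx4", "gr_counter"], ["gpx2", "txnrd1"]),
        ]
        assert build(spec) == build(spec[::-1])


class TestScreenSummary:
    def test_published_arithmetic(self):
        s = ScreenSummary.from_counts(
            n_screened=11_892,
            n_primary_hits_gpx1=180,
            n_primary_hits_gpx4=318,
            n_reconfirmed=215,
            n_top_dose_only=44,
            n_gr_active=94,
            n_txnrd1_active=30,
            cross_counts={
                "gpx1_gr_pct": (24, 49),
                "gpx4_gr_pct": (54, 132),
                "gpx1_txnrd1_pct": (14, 20),
                "gpx4_txnrd1_pct": (11, 42),
            },
        )
        assert s.hit_rate_gpx4 == 2.7
        assert s.n_confirmed == 171
        assert s.cross_activity == {
            "gpx1_gr_pct": 49.0,
            "gpx4_gr_pct": 41.0,
            "gpx1_txnrd1_pct": 70.0,
            "gpx4_txnrd1_pct": 26.0,
        }

    def test_zero_hits(self):
        s = ScreenSummary.from_counts(100, 0, 0, 0, 0, 0, 0)
        assert s.hit_rate_gpx1 == 0.0 and s.hit_rate_gpx4 == 0.0

    def test_cross_activity_percent_rounding(self):
        assert cross_activity_percent(14, 20) == 70.0
        assert cross_activity_percent(11, 42) == 26.0
        assert cross_activity_percent(0, 10) == 0.0

    def test_summarize_from_profiles_consistent(self):
        profiles = {
            "hit": _profile(
                "hit",
                ["gpx1"],
                inactives=["gpx4", "gpx2", "gr_counter", "txnrd1"],
                flags={"primary_hit_gpx1", "primary_hq_gpx1", "reconfirmed"},
            ),
            "fp": _profile(
                "fp",
                ["gpx1", "gr_counter"],
                inactives=["gpx4"],
                flags={"primary_hit_gpx1", "reconfirmed", "gr_active"},
            ),
            "dud": _profile("dud", [], inactives=["gpx1", "gpx4"]),
        }
        outcomes = {
            c: classify_specificity(p) for c, p in profiles.items()
        }
        s = summarize_screen(profiles, outcomes, n_screened=50)
        assert s.n_primary_hits_gpx1 == 1
        assert s.n_initial_hits == 2
        assert s.n_reconfirmed == 2
        assert s.n_gr_active == 1
        assert s.n_after_gr == 1
        assert s.category_counts["gr_false_positive"] == 1


class TestProfileMatrix:
    def test_untested_cell_uses_sentinel(self, tmp_path):
        from gpxscreen.triage import write_profile_matrix

        profiles = {
            "a": _profile("a", ["gpx1"], inactives=["gpx4"]),
            "b": _profile("b", ["gpx1", "gpx2"], inactives=["gpx4"]),
        }
        df = export_profile_matrix(profiles)
        assert np.isnan(df.loc["a", "gpx2"])
        path = tmp_path / "m.csv"
        write_profile_matrix(df, path)
        text = path.read_text()
        assert "NT" in text and ",0," not in text.replace(".0,", ",")

    def test_identical_profiles_adjacent_after_ordering(self):
        profiles = {}
        for cid, resp in (
            ("a", 10.0),
            ("odd", 95.0),
            ("b", 10.0),
            ("c", 55.0),
        ):
            profiles[cid] = _profile(cid, [])
            for assay in ("gpx1", "gpx2", "gpx4"):
                profiles[cid].fits[assay] = _fit(cid, assay, max_response=resp)
        order = list(export_profile_matrix(profiles).index)
        assert abs(order.index("a") - order.index("b")) == 1

    def test_matrix_values_match_fit_max_response(self):
        profiles = {"a": _profile("a", ["gpx1"])}
        df = export_profile_matrix(profiles)
        assert df.loc["a", "gpx1"] == profiles["a"].fits["gpx1"].max_response
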