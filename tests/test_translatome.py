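"""Translation-change computation, S/R/I calling, percentiles, coordination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polytome import translatome
from polytome.exceptions import ConfigurationError, PolytomeError
from polytome.translatome import ClassThresholds


def _entries(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "te_control", "te_stress", "delta_a"])
    df["delta_te"] = df["te_stress"] - df["te_control"]
    df["a_control"] = 5.0
    df["a_stress"] = 5.0 + df["delta_a"]
    df["class_label"] = "U"
    return df


class TestComputeTranslationChange:
    def _expr(self, genes, m):
        return pd.DataFrame({"gene_id": genes, "M": m, "A": 5.0, "n_probes": 1})

    def test_delta_is_stress_minus_control(self):
        out = translatome.compute_translation_change(
            self._expr(["g"], [1.0]), self._expr(["g"], [0.2])
        )
        assert out.loc[0, "delta_te"] == pytest.approx(-0.8)

    def test_gene_missing_in_stress_dropped(self):
        out = translatome.compute_translation_change(
            self._expr(["g1", "g2"], [1.0, 2.0]), self._expr(["g1"], [0.5])
        )
        assert list(out["gene_id"]) == ["g1"]

    def test_identical_conditions_give_zero_delta(self):
        out = translatome.compute_translation_change(
            self._expr(["g"], [1.3]), self._expr(["g"], [1.3])
        )
        assert out.loc[0, "delta_te"] == 0.0


class TestClassifyTranslation:
    @pytest.mark.parametrize(
        "tc,ts,expected",
        [
            (0.9, 1.0, "R"),    # maintained high engagement
            (-1.0, 0.5, "I"),   # low control TE, gain 1.5
            (1.5, 0.3, "S"),    # drop 1.2
            (0.5, 0.4, "U"),    # no rule fires
            (3.0, 1.0, "R"),    # drop 2.0 but still >= 0.8 both: R beats S
            (0.0, 1.0, "I"),    # boundary: control at i_control_max, gain exactly 1
            (0.8, 0.8, "R"),    # boundary: both exactly at r_level
            (1.0, 0.2, "S"),    # boundary: drop exactly 0.8
        ],
    )
    def test_rule_examples(self, tc, ts, expected):
        assert translatome.classify_translation(tc, ts) == expected

    def test_vectorised_assignment_matches_scalar(self, rng):
        entries = _entries(
            [(f"g{i}", tc, ts, 0.0)
             for i, (tc, ts) in enumerate(rng.normal(0, 2, (500, 2)))]
        )
        out = translatome.assign_classes(entries)
        scalar = [
            translatome.classify_translation(r.te_control, r.te_stress)
            for r in entries.itertuples()
        ]
        assert list(out["class_label"]) == scalar

    @given(
        tc=st.floats(-5, 5), ts=st.floats(-5, 5),
        s_delta=st.floats(-3, -0.1), r_level=st.floats(0.1, 3),
        i_delta=st.floats(0.1, 3), i_gap=st.floats(0.0, 2),
    )
    def test_total_and_inducible_resistant_disjoint(
        self, tc, ts, s_delta, r_level, i_delta, i_gap
    ):
        """Every entry gets exactly one label; I and R cannot both fire
        whenever i_control_max < r_level."""
        thr = ClassThresholds(
            s_delta=s_delta, r_level=r_level,
            i_control_max=r_level - i_gap - 1e-6, i_delta=i_delta,
        )
        label = translatome.classify_translation(tc, ts, thr)
        assert label in translatome.CLASS_LABELS
        i_fires = tc <= thr.i_control_max and (ts - tc) >= thr.i_delta
        r_fires = tc >= thr.r_level and ts >= thr.r_level
        assert not (i_fires and r_fires)

    def test_thresholds_validated(self):
        with pytest.raises(ConfigurationError):
            ClassThresholds(s_delta=0.5)
        with pytest.raises(ConfigurationError):
            ClassThresholds(i_control_max=2.0, r_level=1.0)


class TestPercentilePlacement:
    def test_median_of_odd_distribution_is_50(self):
        te = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        assert translatome.percentile_placement(te, ["c"])["c"] == pytest.approx(50.0)

    def test_top_of_1_to_100_is_99_5(self):
        te = pd.Series(np.arange(1.0, 101.0), index=[f"g{i}" for i in range(100)])
        assert translatome.percentile_placement(te, ["g99"])["g99"] == pytest.approx(99.5)

    def test_full_tie_places_everything_at_50(self):
        te = pd.Series([2.0] * 7, index=[f"g{i}" for i in range(7)])
        placements = translatome.percentile_placement(te, ["g0", "g6"])
        assert placements == {"g0": pytest.approx(50.0), "g6": pytest.approx(50.0)}

    def test_missing_marker_reported_not_raised(self):
        te = pd.Series([1.0], index=["a"])
        assert translatome.percentile_placement(te, ["zz"])["zz"] is None


class TestCoordinationAnalysis:
    def test_ten_gene_set_matches_exhaustive_enumeration(self):
        rows = [
            ("g0", 0.0, 1.5, 1.2),   # I; translation & abundance changed
            ("g1", 1.0, 1.2, 0.0),   # R; neither changed
            ("g2", 2.0, 0.5, -1.5),  # S by delta -1.5; both changed
            ("g3", 0.5, 0.4, 0.0),   # U; neither
            ("g4", -0.5, 0.6, 2.0),  # I; both
            ("g5", 1.0, 0.1, 0.5),   # S; translation only
            ("g6", 0.9, 0.9, 1.0),   # R; abundance only
            ("g7", 0.3, 0.2, -1.0),  # U; abundance only
            ("g8", 2.5, 2.5, 0.0),   # R; neither
            ("g9", -2.0, -0.9, 0.9), # I (gain 1.1); translation only
        ]
        report = translatome.coordination_analysis(_entries(rows))
        # brute-force over the same ten genes
        thr = ClassThresholds()
        t_ch = [abs(r[2] - r[1]) >= thr.venn_translation_delta for r in rows]
        a_ch = [abs(r[3]) >= thr.abundance_delta for r in rows]
        assert report["venn"]["translation_only"] == sum(t and not a for t, a in zip(t_ch, a_ch))
        assert report["venn"]["abundance_only"] == sum(a and not t for t, a in zip(t_ch, a_ch))
        assert report["venn"]["both"] == sum(t and a for t, a in zip(t_ch, a_ch))
        labels = [translatome.classify_translation(r[1], r[2]) for r in rows]
        for cls in "SRI":
            members = [i for i, l in enumerate(labels) if l == cls]
            up = sum(rows[i][3] >= thr.abundance_delta for i in members)
            assert report["classes"][cls]["n"] == len(members)
            assert report["classes"][cls]["abundance_up"] == up
        n_up = sum(r[3] >= thr.abundance_delta for r in rows)
        tr_up = sum(r[3] >= 1 and (r[2] - r[1]) >= thr.i_delta for r in rows)
        assert report["abundance_up"]["n"] == n_up
        assert report["abundance_up"]["pct_translation_up"] == pytest.approx(100 * tr_up / n_up)

    def test_no_gene_over_threshold_gives_zero_counts(self):
        rows = [(f"g{i}", 0.1, 0.2, 0.3) for i in range(5)]
        report = translatome.coordination_analysis(_entries(rows))
        assert report["venn"] == {"translation_only": 0, "abundance_only": 0, "both": 0}

    def test_every_gene_over_both_thresholds_is_pure_overlap(self):
        rows = [(f"g{i}", 0.0, 2.0, 3.0) for i in range(6)]
        report = translatome.coordination_analysis(_entries(rows))
        assert report["venn"] == {"translation_only": 0, "abundance_only": 0, "both": 6}

    def test_counts_conserve_and_ignore_order(self, rng):
        rows = [
            (f"g{i}", tc, ts, da)
            for i, (tc, ts, da) in enumerate(rng.normal(0, 1.5, (200, 3)))
        ]
        entries = _entries(rows)
        a = translatome.coordination_analysis(entries)
        b = translatome.coordination_analysis(
            entries.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        assert a == b
        t_changed = (entries["delta_te"].abs() >= 1.0).sum()
        assert a["venn"]["translation_only"] + a["venn"]["both"] == t_changed


class TestSubsetSummary:
    def test_constant_subset_has_zero_sd(self):
        entries = _entries([(f"g{i}", 2.0, 2.0, 0.0) for i in range(3)])
        stats = translatome.subset_summary(entries, ["g0", "g1", "g2"])
        assert stats["te_control"] == {"mean": pytest.approx(2.0), "sd": 0.0}

    def test_two_point_subset_sd_is_sqrt2(self):
        entries = _entries([("g0", 1.0, 0.0, 0.0), ("g1", 3.0, 0.0, 0.0)])
        stats = translatome.subset_summary(entries, ["g0", "g1"])
        assert stats["te_control"]["mean"] == pytest.approx(2.0)
        assert stats["te_control"]["sd"] == pytest.approx(np.sqrt(2))

    def test_disjoint_subset_raises(self):
        entries = _entries([("g0", 1.0, 0.0, 0.0)])
        with pytest.raises(PolytomeError, match="no overlap"):
            translatome.subset_summary(entries, ["zz"])
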