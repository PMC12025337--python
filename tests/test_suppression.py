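"""Suppression indices and the statistical reporting chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from normatt.nma import ConfigurationError
from normatt.suppression import (
    one_sample_t_vs_zero,
    paired_t,
    rm_anova_2x2,
    si_behavioral,
    si_fmri,
    si_table_from_betas,
    si_table_from_thresholds,
    stats_report,
)


def _si_table_from_matrix(Y):
    """Long-format SI table from an (n, attention, direction) array."""
    rows = []
    for s in range(Y.shape[0]):
        for i, attn in enumerate(("narrow", "wide")):
            for j, direction in enumerate(("same", "opposite")):
                rows.append((f"P{s:02d}", attn, direction, Y[s, i, j], "fmri"))
    return pd.DataFrame(rows, columns=["participant", "attention", "direction", "si", "modality"])


class TestSuppressionIndices:
    @pytest.mark.parametrize("t_c,t_cs,expected", [
        (50.0, 50.0, 0.0),
        (50.0, 100.0, 1.0),
        (50.0, 25.0, -0.5),  # facilitation: surround lowers the threshold
    ])
    def test_behavioral_si(self, t_c, t_cs, expected):
        assert si_behavioral(t_c, t_cs) == pytest.approx(expected)

    @pytest.mark.parametrize("b_c,b_cs,expected", [
        (0.8, 0.8, 0.0), (1.0, 0.7, 0.3), (0.7, 1.0, -0.3),
    ])
    def test_fmri_si(self, b_c, b_cs, expected):
        assert si_fmri(b_c, b_cs) == pytest.approx(expected)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            si_behavioral(0.0, 50.0)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ConfigurationError):
            si_fmri(np.nan, 1.0)

    @given(t_c=st.floats(1.0, 1e4), t_cs=st.floats(1.0, 1e4))
    def test_behavioral_si_exact_arithmetic(self, t_c, t_cs):
        # the index is exact arithmetic: reconstructing the center+surround
        # threshold from the SI reproduces it bit-for-bit-scale
        si = si_behavioral(t_c, t_cs)
        assert si > -1.0
        assert t_c * (1.0 + si) == pytest.approx(t_cs, rel=1e-12)

    def test_si_tables_share_center_baseline(self):
        df = pd.DataFrame({
            "participant": ["a"] * 5,
            "condition": ["center_only", "narrow_same", "narrow_opp", "wide_same", "wide_opp"],
            "threshold_ms": [50.0, 75.0, 50.0, 100.0, 55.0],
        })
        si = si_table_from_thresholds(df).set_index(["attention", "direction"])["si"]
        assert si[("narrow", "same")] == pytest.approx(0.5)
        assert si[("wide", "same")] == pytest.approx(1.0)
        assert si[("wide", "opposite")] == pytest.approx(0.1)

    def test_missing_center_only_rejected(self):
        df = pd.DataFrame({
            "participant": ["a"] * 4,
            "condition": ["narrow_same", "narrow_opp", "wide_same", "wide_opp"],
            "beta": [1.0, 2.0, 3.0, 4.0],
        })
        with pytest.raises(ConfigurationError):
            si_table_from_betas(df)


class TestOneSampleT:
    def test_known_small_sample(self):
        # mean 2, sd 1, n 3: t = 2 / (1/sqrt(3))
        res = one_sample_t_vs_zero([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3), rel=1e-12)
        assert res.df == 2

    def test_all_zero_is_exact_null(self):
        res = one_sample_t_vs_zero([0.0, 0.0, 0.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_zero_variance_nonzero_mean_flagged(self):
        res = one_sample_t_vs_zero([1.0, 1.0, 1.0, 1.0])
        assert np.isinf(res.t) and res.p == 0.0 and res.degenerate

    def test_single_observation_rejected(self):
        with pytest.raises(ConfigurationError):
            one_sample_t_vs_zero([1.0])


class TestPairedT:
    def test_identical_pairs_are_null(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            paired_t([1.0, 2.0], [1.0])

    @settings(deadline=None, max_examples=50)
    @given(arrays(float, (2, 8), elements=st.floats(-10, 10)))
    def test_reduces_to_one_sample_on_differences(self, ab):
        a, b = ab
        pt = paired_t(a, b)
        os = one_sample_t_vs_zero(a - b, alpha_corrected=pt.alpha)
        if pt.degenerate:
            assert os.degenerate and pt.t == os.t
        else:
            assert pt.t == pytest.approx(os.t, rel=1e-12, abs=1e-12)
            assert pt.p == pytest.approx(os.p, rel=1e-12, abs=1e-12)


class TestRmAnova:
    def test_additive_data_have_zero_interaction(self):
        n = 8
        subj = np.arange(n)[:, None, None] * 0.1
        attn = np.array([0.0, 0.5])[None, :, None]
        direction = np.array([0.0, 1.0])[None, None, :]
        Y = 1.0 + subj + attn + direction
        res = rm_anova_2x2(_si_table_from_matrix(Y))
        assert res["interaction"].F == pytest.approx(0.0, abs=1e-18)

    def test_degrees_of_freedom_track_sample_size(self):
        rng = np.random.default_rng(0)
        res = rm_anova_2x2(_si_table_from_matrix(rng.normal(size=(10, 2, 2))))
        for eff in res.values():
            assert (eff.df1, eff.df2) == (1, 9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(123)
        table = _si_table_from_matrix(rng.normal(0.3, 1.0, size=(10, 2, 2)))
        mine = rm_anova_2x2(table)
        theirs = pg.rm_anova(data=table, dv="si", within=["attention", "direction"],
                             subject="participant", detailed=True, effsize="np2")
        by_src = {str(r["Source"]).lower(): r for _, r in theirs.iterrows()}
        pairs = [("attention", "attention"), ("direction", "direction"),
                 ("interaction", "attention * direction")]
        for mine_key, pg_key in pairs:
            assert mine[mine_key].F == pytest.approx(by_src[pg_key]["F"], rel=1e-9)
            assert mine[mine_key].p == pytest.approx(by_src[pg_key]["p_unc"], rel=1e-9)
            assert mine[mine_key].partial_eta_sq == pytest.approx(by_src[pg_key]["np2"], rel=1e-9)

    def test_main_effects_invariant_to_factor_relabeling(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(9, 2, 2))
        res = rm_anova_2x2(_si_table_from_matrix(Y))
        flipped = rm_anova_2x2(_si_table_from_matrix(Y[:, :, ::-1]))
        assert res["attention"].F == pytest.approx(flipped["attention"].F, rel=1e-12)
        swapped = rm_anova_2x2(_si_table_from_matrix(Y[:, ::-1, :]))
        assert res["direction"].F == pytest.approx(swapped["direction"].F, rel=1e-12)

    def test_missing_cell_rejected(self):
        table = _si_table_from_matrix(np.zeros((5, 2, 2)))
        with pytest.raises(ConfigurationError):
            rm_anova_2x2(table[~((table.attention == "wide") & (table.direction == "same"))])

    def test_interaction_test_has_power_against_true_interaction(self):
        # generator with a built-in attention x direction interaction is
        # rejected far more often than a no-interaction generator (n = 10)
        rng = np.random.default_rng(2024)
        n_sims, n = 1000, 10
        hits = {True: 0, False: 0}
        for with_interaction in (True, False):
            for _ in range(n_sims):
                Y = rng.normal(0.0, 0.5, size=(n, 2, 2))
                Y += rng.normal(0.0, 0.3, size=(n, 1, 1))  # subject offsets
                if with_interaction:
                    Y[:, 1, 0] += 0.8  # extra suppression: wide x same only
                res = rm_anova_2x2(_si_table_from_matrix(Y))
                hits[with_interaction] += res["interaction"].p < 0.05
        assert hits[True] / n_sims > 0.4
        assert hits[False] / n_sims < 0.10
        assert hits[True] > hits[False]


class TestStatsReport:
    def test_full_chain_on_structured_data(self):
        # strong same-direction suppression, stronger under wide attention
        rng = np.random.default_rng(77)
        Y = rng.normal(0.0, 0.05, size=(10, 2, 2))
        Y[:, :, 0] += 0.4   # same-direction suppression
        Y[:, 1, 0] += 0.3   # extra suppression under wide attention
        report = stats_report(_si_table_from_matrix(Y))
        assert report.one_sample["narrow_same"].significant
        assert report.one_sample["wide_same"].significant
        assert not report.one_sample["narrow_opposite"].significant
        assert report.anova["interaction"].p < 0.05
        assert report.posthoc["wide_vs_narrow_same"].significant
        assert not report.posthoc["wide_vs_narrow_opposite"].significant
        # corrected alphas: 0.05/4 for the four cells, 0.05/2 post hoc
        assert report.one_sample["narrow_same"].alpha == pytest.approx(0.0125)
        assert report.posthoc["wide_vs_narrow_same"].alpha == pytest.approx(0.025)

    def test_report_serializes(self):
        rng = np.random.default_rng(3)
        report = stats_report(_si_table_from_matrix(rng.normal(size=(6, 2, 2))))
        d = report.to_dict()
        assert set(d) == {"one_sample", "anova", "posthoc"}
        assert d["anova"]["attention"]["df2"] == 5
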