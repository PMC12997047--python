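"""Mixed ANOVA reduction, ART ANOVA, BH adjustment, gating, comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lipocurve as lc
from lipocurve.stats import (
    EFFECTS,
    art_anova,
    assumption_gate,
    bh_adjust,
    compare_approaches,
    mixed_anova,
    run_differential,
)


def _one_group_design(n):
    rows = [
        {"subject": f"S{i}", "timepoint": tp, "group": "G"}
        for i in range(n)
        for tp in ("baseline", "acute")
    ]
    return pd.DataFrame(rows)


def _y_from_pairs(design, baseline, diff):
    """Assemble observations so subject i has the given baseline and
    acute-baseline difference."""
    y = np.empty(len(design))
    for i, (_, row) in enumerate(design.iterrows()):
        s = int(row["subject"][1:])
        y[i] = baseline[s] + (diff[s] if row["timepoint"] == "acute" else 0.0)
    return y


class TestMixedAnova:
    def test_one_group_differences_1_2_3_give_f_twelve(self):
        design = _one_group_design(3)
        y = _y_from_pairs(design, [5.0, 7.0, 2.0], [1.0, 2.0, 3.0])
        res = mixed_anova(y, design)
        assert res["F_time"] == pytest.approx(12.0, abs=1e-10)
        t = sps.ttest_rel(
            y[design["timepoint"] == "acute"][np.argsort(
                design.loc[design["timepoint"] == "acute", "subject"])],
            y[design["timepoint"] == "baseline"][np.argsort(
                design.loc[design["timepoint"] == "baseline", "subject"])],
        )
        assert res["F_time"] == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert res["p_time"] == pytest.approx(t.pvalue, abs=1e-12)

    def test_f_time_equals_paired_t_squared_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            design = _one_group_design(n)
            y = rng.normal(size=len(design))
            res = mixed_anova(y, design)
            a = y[(design["timepoint"] == "acute").to_numpy()]
            b = y[(design["timepoint"] == "baseline").to_numpy()]
            # rows alternate baseline/acute per subject in construction order
            t = sps.ttest_rel(a, b)
            assert res["F_time"] == pytest.approx(t.statistic ** 2, abs=1e-10)

    def test_identical_timepoints_give_zero_f_unit_p(self):
        design = _one_group_design(4)
        y = _y_from_pairs(design, [1.0, 2.0, 3.0, 4.0], [0.0] * 4)
        res = mixed_anova(y, design)
        assert res["F_time"] == 0.0 and res["p_time"] == 1.0

    def test_matches_pingouin_on_balanced_three_group_design(
            self, balanced_design):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(balanced_design)) \
            + (balanced_design["timepoint"] == "acute") * 0.4 \
            + (balanced_design["group"] == "COX") * 0.6
        res = mixed_anova(y.to_numpy(), balanced_design)
        df = balanced_design.assign(y=y)
        ref = pg.mixed_anova(data=df, dv="y", within="timepoint",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        assert res["F_group"] == pytest.approx(ref.loc["group", "F"])
        assert res["F_time"] == pytest.approx(ref.loc["timepoint", "F"])
        assert res["F_interaction"] == pytest.approx(
            ref.loc["Interaction", "F"])
        assert res["p_time"] == pytest.approx(ref.loc["timepoint", "p_unc"])

    def test_unpaired_subject_is_an_error(self):
        design = _one_group_design(3).drop(index=0)
        with pytest.raises(lc.ValidationError, match="paired"):
            mixed_anova(np.arange(5.0), design)

    def test_group_null_p_uniform(self, balanced_design):
        """Shuffled group labels under a pure time effect: p_group is
        uniform (KS test at 1% over 400 replicates)."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(400):
            y = rng.normal(size=len(balanced_design)) \
                + (balanced_design["timepoint"] == "acute") * 0.5
            design = balanced_design.copy()
            perm = rng.permutation(design["group"].unique())
            relabel = dict(zip(design["group"].unique(), perm))
            design["group"] = design["group"].map(relabel)
            pvals.append(mixed_anova(y.to_numpy(), design)["p_group"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestArtAnova:
    def test_pure_time_effect_degenerates_other_effects(self, balanced_design):
        y = (balanced_design["timepoint"] == "acute").to_numpy(float) * 10.0
        res = art_anova(y, balanced_design)
        assert res["p_group"] == 1.0 and res["p_interaction"] == 1.0
        assert res["p_time"] < 1e-10

    def test_balanced_2x2_matches_align_and_rank_oracle(self):
        """8-value 2x2 fixture: alignment and mid-ranks recomputed
        explicitly, then pushed through the same reduced F formulas via an
        independent engine (pingouin)."""
        pg = pytest.importorskip("pingouin")
        rows = [
            {"subject": f"{g}{i}", "timepoint": tp, "group": g}
            for g in ("A", "B")
            for i in range(2)
            for tp in ("baseline", "acute")
        ]
        design = pd.DataFrame(rows)
        y = np.array([3.0, 7.0, 1.0, 5.0, 10.0, 12.0, 8.0, 14.0])
        res = art_anova(y, design)

        df = design.assign(y=y)
        cell = df.groupby(["group", "timepoint"])["y"].mean()
        grand = cell.mean()
        a_t = cell.groupby("timepoint").mean() - grand
        b_g = cell.groupby("group").mean() - grand
        resid = y - df.apply(
            lambda r: cell[(r["group"], r["timepoint"])], axis=1
        ).to_numpy()
        comps = {
            "time": df["timepoint"].map(a_t).to_numpy(),
            "group": df["group"].map(b_g).to_numpy(),
            "interaction": df.apply(
                lambda r: cell[(r["group"], r["timepoint"])]
                - grand - a_t[r["timepoint"]] - b_g[r["group"]],
                axis=1,
            ).to_numpy(),
        }
        for effect, comp in comps.items():
            ranked = sps.rankdata(resid + comp)
            ref = pg.mixed_anova(data=design.assign(y=ranked), dv="y",
                                 within="timepoint", subject="subject",
                                 between="group").set_index("Source")
            key = {"time": "timepoint", "group": "group",
                   "interaction": "Interaction"}[effect]
            assert res[f"F_{effect}"] == pytest.approx(ref.loc[key, "F"],
                                                       abs=1e-10)

    def test_effect_ordering_concordant_with_mixed_on_gaussian_data(
            self, balanced_design):
        """On data meeting the parametric assumptions, ART and the mixed
        ANOVA order the evidence the same way (rank corr of -log p >= 0.9)."""
        rng = np.random.default_rng(23)
        logp_mixed, logp_art = [], []
        for _ in range(120):
            fc = rng.uniform(0, 0.8)
            y = rng.normal(size=len(balanced_design)) \
                + (balanced_design["timepoint"] == "acute") * fc
            logp_mixed.append(-math.log10(
                mixed_anova(y.to_numpy(), balanced_design)["p_time"]))
            logp_art.append(-math.log10(
                art_anova(y.to_numpy(), balanced_design)["p_time"]))
        rho = sps.spearmanr(logp_mixed, logp_art).statistic
        assert rho >= 0.9


class TestAssumptionGate:
    def test_gaussian_residuals_route_parametric(self, balanced_design):
        rng = np.random.default_rng(42)
        y = rng.normal(size=len(balanced_design))
        assert assumption_gate(y, balanced_design) == "mixed_anova"

    def test_heavy_tailed_residuals_route_nonparametric(self, balanced_design):
        rng = np.random.default_rng(42)
        y = rng.lognormal(0, 2.5, size=len(balanced_design))
        assert assumption_gate(y, balanced_design) == "art_anova"

    def test_alpha_zero_disables_the_gate(self, balanced_design):
        rng = np.random.default_rng(42)
        y = rng.lognormal(0, 2.5, size=len(balanced_design))
        assert assumption_gate(y, balanced_design, alpha=0.0) == "mixed_anova"

    def test_tiny_cells_error(self):
        design = _one_group_design(1)
        with pytest.raises(lc.ValidationError, match=">= 2"):
            assumption_gate(np.array([1.0, 2.0]), design)


class TestBH:
    def test_closed_form_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]).tolist() == [0.123]

    def test_order_invariance_and_dominates_p(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert (adj >= p).all()
        perm = rng.permutation(200)
        assert np.allclose(bh_adjust(p[perm]), adj[perm])

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(32)
        p = rng.uniform(size=150)
        ref = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(lc.ValidationError):
            bh_adjust([0.5, 1.5])


class TestRunDifferential:
    def test_null_experiment_time_p_uniform(self):
        """No planted effect: downstream p_time over signals is uniform."""
        cfg = lc.SimConfig.hmvec_experiment(
            seed=3, planted_time_fc=1.0, frac_affected=0.0,
            n_cell_signals=150, n_background_signals=0, n_media_signals=0,
            lod=0.0, n_batches=1, batch_scale=1.0,
        )
        m, s, t = lc.simulate_experiment(cfg)
        res = run_differential(m, s)
        ks = sps.kstest(res.table["p_time"], "uniform")
        assert ks.pvalue > 0.01
        assert len(res.significant_ids("time")) <= 0.05 * m.k

    def test_shrinking_the_tested_set_helps_top_ranked_signals(self):
        """BH is monotone in m for a signal keeping its rank position:
        restricting testing to a selected subset can flip padj below the
        threshold but never above it for the top-ranked p."""
        p = np.array([0.001, 0.06, 0.2, 0.5, 0.8, 0.9, 0.95, 0.99])
        full = bh_adjust(p)
        subset = bh_adjust(p[:3])
        assert (subset <= full[:3]).all()
        # constructed flip: padj crosses the 0.2 threshold only in the subset
        assert full[1] > 0.2 > subset[1]

    def test_identical_inputs_give_empty_venn_margins(self, hmvec):
        ids = hmvec["selection"].selected_ids
        res = run_differential(
            hmvec["qa_matrix"].subset_signals(ids), hmvec["samples"]
        )
        venn = compare_approaches(res, res, ids)
        for effect in list(EFFECTS) + ["any"]:
            assert venn[effect]["standard_only"] == []
            assert venn[effect]["correlation_only"] == []
            assert venn[effect]["shared"] == sorted(
                res.any_significant_ids()
            ) if effect == "any" else True

    def test_mismatched_universes_rejected(self, hmvec):
        ids = hmvec["selection"].selected_ids
        res_cor = run_differential(
            hmvec["qa_matrix"].subset_signals(ids), hmvec["samples"]
        )
        with pytest.raises(lc.ValidationError, match="subset"):
            compare_approaches(res_cor, res_cor.__class__(
                res_cor.table.rename(index={ids[0]: "ghost"})
            ), ids)

    def test_routes_are_assumption_driven(self, hmvec):
        res = run_differential(
            hmvec["qa_matrix"].subset_signals(
                hmvec["selection"].selected_ids),
            hmvec["samples"],
        )
        assert set(res.table["route"]) <= {"mixed_anova", "art_anova"}
        res.validate()
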