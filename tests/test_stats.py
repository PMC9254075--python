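"""Two-way ANOVA decomposition, Tukey-Kramer comparisons, trait reports."""

import numpy as np
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from paceshape.simulate import paper_like_config, simulate_cohort
from paceshape.stats import (
    trait_comparison,
    tukey_kramer,
    two_way_anova,
)


def _balanced_2x2(effects=(0.0, 0.0, 0.0), noise=None):
    """2 species x 2 blocks x 4 replicates with additive effects."""
    species = ["S1"] * 8 + ["S2"] * 8
    block = (["B1"] * 4 + ["B2"] * 4) * 2
    sp_eff, bl_eff, inter = effects
    y = []
    for s, b in zip(species, block):
        v = (sp_eff if s == "S2" else 0) + (bl_eff if b == "B2" else 0)
        if s == "S2" and b == "B2":
            v += inter
        y.append(v)
    y = np.asarray(y, dtype=float)
    if noise is not None:
        y = y + noise
    return y, species, block


class TestTwoWayAnova:
    def test_identical_values_give_zero_ss_everywhere(self):
        y, s, b = _balanced_2x2()
        res = two_way_anova(y + 3.0, s, b)
        assert np.allclose(res.table["SS"].iloc[:-2], 0.0)

    def test_balanced_design_matches_hand_projection(self):
        """SS from explicit group-mean projections on a balanced 2x2."""
        rng = np.random.default_rng(3)
        noise = rng.normal(scale=0.5, size=16)
        y, s, b = _balanced_2x2(effects=(2.0, 1.0, 0.5), noise=noise)
        res = two_way_anova(y, s, b)
        y = np.asarray(y)
        s_arr, b_arr = np.asarray(s), np.asarray(b)
        grand = y.mean()
        ss_sp = sum(
            (y[s_arr == lv].size) * (y[s_arr == lv].mean() - grand) ** 2
            for lv in ("S1", "S2")
        )
        ss_bl = sum(
            (y[b_arr == lv].size) * (y[b_arr == lv].mean() - grand) ** 2
            for lv in ("B1", "B2")
        )
        cell_means = {
            (sv, bv): y[(s_arr == sv) & (b_arr == bv)].mean()
            for sv in ("S1", "S2")
            for bv in ("B1", "B2")
        }
        ss_cells = sum(
            4 * (cell_means[k] - grand) ** 2 for k in cell_means
        )
        ss_int = ss_cells - ss_sp - ss_bl
        t = res.table.set_index("Source")
        assert t.loc["Species", "SS"] == pytest.approx(ss_sp, rel=1e-10)
        assert t.loc["Block", "SS"] == pytest.approx(ss_bl, rel=1e-10)
        assert t.loc["Species x Block", "SS"] == pytest.approx(ss_int, rel=1e-8)

    def test_ss_decomposition_is_exact(self, paper_cohort):
        fronds = paper_cohort.included()
        y = np.log([f.death_age for f in fronds])
        res = two_way_anova(
            y, [f.species for f in fronds], [f.block for f in fronds]
        )
        t = res.table.set_index("Source")
        parts = t.drop("Total")["SS"].sum()
        assert parts == pytest.approx(t.loc["Total", "SS"], rel=1e-8)

    def test_balanced_type1_ss_invariant_to_entry_order(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(size=16)
        y, s, b = _balanced_2x2(effects=(1.0, 2.0, 0.0), noise=noise)
        res_sp_first = two_way_anova(y, s, b)
        res_bl_first = two_way_anova(y, b, s)  # factors swapped
        t1 = res_sp_first.table.set_index("Source")
        t2 = res_bl_first.table.set_index("Source")
        assert t1.loc["Species", "SS"] == pytest.approx(
            t2.loc["Block", "SS"], rel=1e-10
        )
        assert t1.loc["Block", "SS"] == pytest.approx(
            t2.loc["Species", "SS"], rel=1e-10
        )

    def test_cell_level_shape_design_df_structure(self):
        """12 values over 3 species x 4 blocks, no interaction: df 2/3/6/11."""
        rng = np.random.default_rng(6)
        species = [s for s in ("A", "B", "C") for _ in range(4)]
        blocks = ["B1", "B2", "B3", "B4"] * 3
        res = two_way_anova(rng.normal(size=12), species, blocks, interaction=False)
        t = res.table.set_index("Source")
        assert t["df"].to_dict() == {
            "Species": 2, "Block": 3, "Residual": 6, "Total": 11,
        }

    def test_single_factor_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            two_way_anova([1.0, 2.0], ["A", "A"], ["B1", "B2"])


class TestTukeyKramer:
    def test_identical_group_means_share_one_letter(self):
        values = [1.0, 1.1, 0.9] * 3
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = tukey_kramer(values, labels, mse=0.5, df_resid=20)
        assert len(set(res.letters.values())) == 1

    def test_shifted_group_gets_its_own_letter(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.normal(0, 0.3, 10), rng.normal(0, 0.3, 10), rng.normal(5, 0.3, 10)]
        )
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        mse = float(
            np.mean([values[i * 10 : (i + 1) * 10].var(ddof=1) for i in range(3)])
        )
        res = tukey_kramer(values, labels, mse=mse, df_resid=27)
        assert res.letters["A"] == res.letters["B"]
        assert res.letters["C"] not in (res.letters["A"], res.letters["B"])
        # q for the shifted pair, by the definitional formula
        row = res.pairwise.set_index(["group1", "group2"]).loc[("A", "C")]
        means = {g: values[np.array(labels) == g].mean() for g in "AC"}
        q_hand = abs(means["A"] - means["C"]) / np.sqrt(mse / 2 * (1 / 10 + 1 / 10))
        assert row["q"] == pytest.approx(q_hand, rel=1e-12)

    def test_equal_n_reduces_to_tukey_hsd_oracle(self):
        """With equal group sizes our p-values equal statsmodels' HSD."""
        rng = np.random.default_rng(9)
        values = np.concatenate(
            [rng.normal(0, 1, 12), rng.normal(1, 1, 12), rng.normal(1.5, 1, 12)]
        )
        labels = np.array(["A"] * 12 + ["B"] * 12 + ["C"] * 12)
        # one-way error variance so both routes share the error term
        groups = [values[labels == g] for g in "ABC"]
        mse = float(np.mean([g.var(ddof=1) for g in groups]))
        ours = tukey_kramer(values, labels, mse=mse, df_resid=33)
        ref = pairwise_tukeyhsd(values, labels)
        assert np.allclose(
            ours.pairwise["p_adj"].to_numpy(), ref.pvalues, atol=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            tukey_kramer([1, 2], ["A", "B"], mse=1.0, df_resid=0)
        with pytest.raises(ValueError):
            tukey_kramer([1, 2], ["A", "B"], mse=0.0, df_resid=5)


class TestTraitComparison:
    def test_paper_like_cohort_df_structure(self, paper_cohort):
        report = trait_comparison(paper_cohort)
        assert set(report) >= {
            "log(lifespan)", "shape_mortality", "total_offspring", "shape_fecundity",
        }
        t = report["log(lifespan)"].anova.table.set_index("Source")
        assert t.loc["Species", "df"] == 2
        assert t.loc["Block", "df"] == 3
        assert t.loc["Species x Block", "df"] == 6
        sm_t = report["shape_mortality"].anova.table.set_index("Source")
        assert sm_t.loc["Residual", "df"] == 6
        assert sm_t.loc["Total", "df"] == 11

    def test_size_traits_present_yields_six_analyses(self, paper_cohort):
        report = trait_comparison(paper_cohort)
        assert len(report) == 6
        assert "log(surface_area)" in report and "log(perimeter)" in report

    def test_size_traits_absent_skips_those_analyses(self, paper_cohort):
        import copy

        stripped = copy.deepcopy(paper_cohort)
        for f in stripped.fronds:
            f.surface_area = None
            f.perimeter = None
        report = trait_comparison(stripped)
        assert len(report) == 4
        assert "log(surface_area)" not in report

    def test_large_pace_gap_separates_letters(self):
        """Species with a much slower pace gets its own lifespan letter."""
        hits = 0
        for rep in range(20):
            cfg = paper_like_config(seed=100 + rep, n_per_cell=12)
            slow = cfg.species_params["LG"]
            # stretch LG's time axis far beyond the others
            cfg.species_params["LG"] = type(slow)(
                mortality_model=slow.mortality_model,
                mortality_params=(slow.mortality_params[0] / 20,
                                  slow.mortality_params[1] / 2,
                                  slow.mortality_params[2]),
                repro_latency=slow.repro_latency,
                repro_intercept=slow.repro_intercept,
                repro_slope=slow.repro_slope / 3,
                serial_corr=slow.serial_corr,
                twin_prob=slow.twin_prob,
            )
            cohort = simulate_cohort(cfg)
            report = trait_comparison(cohort)
            tk = report["log(lifespan)"].tukey
            if tk is not None and tk.letters["LG"] != tk.letters["LM"]:
                hits += 1
        assert hits >= 18
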