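import numpy as np
import pandas as pd
import pytest
from scipy import stats

from punctaflux.stats_flux import (
    assess_flux,
    fold_change,
    fold_change_p62,
    group_summary,
    one_way_anova_tukey,
    sem,
    sidak_adjust,
    two_way_anova_sidak,
    unpaired_t,
)
from punctaflux.synthetic import sample_density_records


def frame(groups: dict[str, list[float]], value="y") -> pd.DataFrame:
    rows = [{"group": g, value: v} for g, vals in groups.items() for v in vals]
    return pd.DataFrame(rows)


def anova_oracle(groups: list[np.ndarray]):
    """One-way ANOVA and Tukey HSD from first principles.

    Sums of squares by definition; Tukey p from the studentized range
    distribution of |mean_i - mean_j| / sqrt(MSE/n) (balanced case).
    """
    grand = np.concatenate(groups).mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    df_b, df_w = k - 1, n_tot - k
    f_stat = (ss_b / df_b) / (ss_w / df_w)
    p = stats.f.sf(f_stat, df_b, df_w)
    mse = ss_w / df_w
    tukey_p = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
            q = abs(groups[j].mean() - groups[i].mean()) / se
            tukey_p[(i, j)] = stats.studentized_range.sf(q, k, df_w)
    return ss_b, ss_w, f_stat, p, tukey_p


class TestOneWayAnovaTukey:
    FIXTURE = {
        "a": [24.0, 28.0, 37.0, 30.0, 31.0],
        "b": [37.0, 44.0, 31.0, 35.0, 41.0],
        "c": [42.0, 47.0, 52.0, 38.0, 49.0],
    }

    def test_matches_by_definition_oracle(self):
        table = one_way_anova_tukey(frame(self.FIXTURE), "y", "group")
        groups = [np.array(v) for v in self.FIXTURE.values()]
        ss_b, ss_w, f_stat, p, tukey_p = anova_oracle(groups)
        omn = table.omnibus.set_index("term")
        assert omn.loc["group", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert omn.loc["residual", "sum_sq"] == pytest.approx(ss_w, rel=1e-9)
        assert omn.loc["group", "F"] == pytest.approx(f_stat, rel=1e-9)
        assert omn.loc["group", "p"] == pytest.approx(p, rel=1e-9)
        expected = {("a", "b"): tukey_p[(0, 1)], ("a", "c"): tukey_p[(0, 2)], ("b", "c"): tukey_p[(1, 2)]}
        for _, row in table.contrasts.iterrows():
            hi, lo = row["contrast"].split(" - ")
            assert row["p_adj"] == pytest.approx(expected[(lo, hi)], abs=1e-3)

    def test_ss_decomposition(self):
        table = one_way_anova_tukey(frame(self.FIXTURE), "y", "group")
        total = np.concatenate([np.array(v) for v in self.FIXTURE.values()])
        ss_total = ((total - total.mean()) ** 2).sum()
        assert table.omnibus["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_identical_groups_f_zero(self):
        table = one_way_anova_tukey(
            frame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]}), "y", "group"
        )
        assert table.omnibus.set_index("term").loc["group", "F"] == pytest.approx(0.0, abs=1e-12)
        assert (table.contrasts["p_adj"] > 0.99).all()

    def test_requires_two_groups_with_two_obs(self):
        with pytest.raises(ValueError, match="two groups"):
            one_way_anova_tukey(frame({"a": [1, 2, 3]}), "y", "group")
        with pytest.raises(ValueError, match="two observations"):
            one_way_anova_tukey(frame({"a": [1.0], "b": [2.0, 3.0]}), "y", "group")

    def test_null_type1_error_calibrated(self):
        """Omnibus rejection rate under the null sits near the nominal 5%."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            data = frame({g: rng.normal(0, 1, 30).tolist() for g in "abc"})
            table = one_way_anova_tukey(data, "y", "group", posthoc=False)
            if table.omnibus.set_index("term").loc["group", "p"] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07


def two_way_frame(effects, n=6, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (g, t), mu in effects.items():
        for _ in range(n):
            rows.append({"group": g, "treatment": t, "y": mu + noise * rng.normal()})
    return pd.DataFrame(rows)


class TestTwoWayAnovaSidak:
    def test_sidak_formula(self):
        assert sidak_adjust(0.02, 3) == pytest.approx(0.058808, abs=1e-6)
        assert sidak_adjust(0.0, 5) == 0.0
        assert float(sidak_adjust(1.0, 10)) == 1.0
        assert float(sidak_adjust(0.9, 10)) == pytest.approx(1.0, abs=1e-9)

    def test_additive_effects_have_zero_interaction(self):
        effects = {
            ("A", "none"): 1.0,
            ("A", "chloroquine"): 3.0,
            ("B", "none"): 2.0,
            ("B", "chloroquine"): 4.0,
        }
        data = two_way_frame(effects, noise=0.3, seed=4)
        # impose exact additivity of cell means on top of noise
        for (g, t), mu in effects.items():
            sel = (data.group == g) & (data.treatment == t)
            data.loc[sel, "y"] += mu - data.loc[sel, "y"].mean()
        table = two_way_anova_sidak(data, "y")
        omn = table.omnibus.set_index("term")
        inter = [t for t in omn.index if ":" in str(t)][0]
        assert omn.loc[inter, "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_adjusted_never_below_unadjusted(self):
        data = two_way_frame(
            {("A", "none"): 1, ("A", "chloroquine"): 1.4, ("B", "none"): 1, ("B", "chloroquine"): 1.1},
            n=8,
            noise=0.5,
            seed=7,
        )
        table = two_way_anova_sidak(data, "y")
        assert (table.contrasts["p_adj"] >= table.contrasts["p_unadj"] - 1e-12).all()

    def test_contrast_estimates_are_cell_mean_differences(self):
        data = two_way_frame(
            {("A", "none"): 2, ("A", "chloroquine"): 5, ("B", "none"): 1, ("B", "chloroquine"): 1},
            n=5,
            noise=0.2,
            seed=11,
        )
        table = two_way_anova_sidak(data, "y")
        for _, row in table.contrasts.iterrows():
            g = row["group"]
            delta = (
                data.loc[(data.group == g) & (data.treatment == "chloroquine"), "y"].mean()
                - data.loc[(data.group == g) & (data.treatment == "none"), "y"].mean()
            )
            assert row["estimate"] == pytest.approx(delta, rel=1e-9)

    def test_empty_cell_rejected(self):
        data = two_way_frame(
            {("A", "none"): 1, ("A", "chloroquine"): 2, ("B", "none"): 1}, n=4, noise=0.1
        )
        with pytest.raises(ValueError, match="missing one treatment arm|empty cell"):
            two_way_anova_sidak(data, "y")


class TestUnpairedT:
    def test_identical_samples(self):
        t, p = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_pooled_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        p_expected = 2 * stats.t.sf(abs(t_expected), len(a) + len(b) - 2)
        t, p = unpaired_t(a, b)
        assert t == pytest.approx(t_expected, rel=1e-12)
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_zero_variance_convention(self):
        assert unpaired_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = unpaired_t([3.0, 3.0], [2.0, 2.0])
        assert t == np.inf and p == 0.0

    def test_power_at_one_sigma_shift(self):
        rng = np.random.default_rng(5)
        hits = sum(
            unpaired_t(rng.normal(0, 1, 50), rng.normal(1, 1, 50))[1] < 0.05 for _ in range(200)
        )
        assert hits / 200 >= 0.9

    def test_needs_two_per_sample(self):
        with pytest.raises(ValueError):
            unpaired_t([1.0], [1.0, 2.0])


class TestFoldChange:
    def _records(self, means, n=10, seed=3, value="density_p62_per_um2"):
        return sample_density_records(means, n, seed, value=value)

    def test_fold_of_one_when_cq_equals_baseline_mean(self):
        base = pd.DataFrame({"group": ["A"] * 3, "v": [1.0, 2.0, 3.0]})
        cq = pd.DataFrame({"group": ["A"] * 2, "v": [2.0, 2.0]})
        out = fold_change(base, cq, "v")
        assert out["fold"].tolist() == pytest.approx([1.0, 1.0])

    def test_fold_arithmetic(self):
        base = pd.DataFrame({"group": ["A"] * 2, "v": [1.5, 2.5]})  # mean 2.0
        cq = pd.DataFrame({"group": ["A"], "v": [5.0]})
        assert fold_change(base, cq, "v")["fold"].iloc[0] == pytest.approx(2.5)

    def test_zero_baseline_flagged_undefined(self):
        base = pd.DataFrame({"group": ["A"] * 2, "v": [0.0, 0.0]})
        cq = pd.DataFrame({"group": ["A"], "v": [5.0]})
        assert np.isnan(fold_change(base, cq, "v")["fold"].iloc[0])

    def test_flux_intact_group_doubles(self):
        base = self._records({("NOR", "none"): 1.0}, n=20, seed=31)
        cq = self._records({("NOR", "chloroquine"): 2.0}, n=20, seed=32)
        out = fold_change_p62(base, cq)
        assert 1.8 <= out["fold_mean"].iloc[0] <= 2.2


class TestAssessFlux:
    def scenario(self, seed=42, n=15):
        return sample_density_records(
            {
                ("A", "none"): 1.0,
                ("A", "chloroquine"): 2.0,
                ("B", "none"): 1.0,
                ("B", "chloroquine"): 1.0,
            },
            n,
            seed,
        )

    def test_doubling_group_intact_flat_group_impaired(self):
        calls = {c.group: c.call for c in assess_flux(self.scenario(), "density_lc3_per_um2")}
        assert calls == {"A": "intact", "B": "impaired"}

    def test_all_zero_densities_degenerate_impaired(self):
        data = self.scenario()
        data["density_lc3_per_um2"] = 0.0
        calls = assess_flux(data, "density_lc3_per_um2")
        assert all(c.call == "impaired" and c.flag_degenerate for c in calls)

    def test_alpha_one_any_positive_delta_is_intact(self):
        calls = {
            c.group: c.call
            for c in assess_flux(self.scenario(seed=7), "density_lc3_per_um2", alpha=1.0)
        }
        assert calls["A"] == "intact"

    def test_insufficient_arm_rejected(self):
        data = self.scenario(n=1)
        with pytest.raises(ValueError, match="insufficient"):
            assess_flux(data, "density_lc3_per_um2")


class TestSummaries:
    def test_sem_matches_definition(self):
        v = [0.0, 1.0, 2.0]
        assert sem(v) == pytest.approx(np.std(v, ddof=1) / np.sqrt(3))

    def test_group_summary_means(self):
        data = frame({"a": [1.0, 2.0], "b": [4.0, 8.0]})
        out = group_summary(data, "y", ["group"]).set_index("group")
        assert out.loc["a", "mean"] == pytest.approx(1.5)
        assert out.loc["b", "mean"] == pytest.approx(6.0)
        assert out.loc["b", "n"] == 2
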