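"""Mixed-model machinery: REML against dense-matrix and classical-ANOVA
oracles, heritability/breeding-value arithmetic, selection rules and the
monthly series."""

import numpy as np
import pandas as pd
import pytest
from numpy.linalg import slogdet

from pine_phenomics import genetics as g
from pine_phenomics.synthetic_orchard import (GeneticConfig, LayoutConfig,
                                              default_genetics, make_layout,
                                              plant_superior_families,
                                              simulate_traits)


def dense_reml_loglik(vf, vb, ve, y, design):
    """Independent dense-matrix restricted likelihood (n x n algebra)."""
    X = design.fixed_design()
    Zb = design.incidence("block")
    Zf = design.incidence("family")
    n, p = X.shape
    V = ve * np.eye(n) + vb * Zb @ Zb.T + vf * Zf @ Zf.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    return -0.5 * (slogdet(V)[1] + slogdet(XtViX)[1] + resid @ Vi @ resid
                   + (n - p) * np.log(2 * np.pi))


def simulate_vector(design_cfg, gen_cfg, seed, month="Jul"):
    lay = make_layout(design_cfg, seed=seed)
    tr = simulate_traits(lay, {"N": gen_cfg}, months=[month])
    return tr["value"].to_numpy(), g.PedigreeDesign.from_frame(tr), tr


SMALL = LayoutConfig(sites=("S1", "S2"), blocks_per_site=3, trees_per_block=8,
                     n_families=8, block_cols=2)
GCFG = GeneticConfig(var_family=0.3, var_block=0.2, var_residual=0.5,
                     monthly_means={"Jul": 2.0},
                     site_effects={"S1": 0.0, "S2": 0.3}, seed=5)


class TestDesign:
    def test_incidence_shapes(self):
        y, des, _ = simulate_vector(SMALL, GCFG, seed=1)
        n = 2 * 3 * 8  # sites x blocks x trees per block
        assert des.fixed_design().shape == (n, 2)
        assert des.incidence("block").shape == (n, 6)
        assert des.incidence("family").shape == (n, 8)
        assert des.incidence("family").sum() == n

    def test_too_few_families_rejected(self):
        with pytest.raises(ValueError, match="families"):
            g.PedigreeDesign(site=["S1"] * 4, block=["B1", "B2"] * 2,
                             family=["F1"] * 4)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            g.PedigreeDesign(site=["S1"] * 3, block=["B1"] * 2, family=["F1"] * 3)


class TestRemlLoglik:
    def test_agrees_with_dense_oracle(self):
        y, des, _ = simulate_vector(
            LayoutConfig(sites=("S1",), blocks_per_site=2, trees_per_block=6,
                         n_families=6, block_cols=2), GCFG, seed=2)
        assert len(y) <= 50
        for vf, vb, ve in [(0.3, 0.2, 0.5), (0.01, 0.5, 1.0), (1.0, 0.0, 0.2)]:
            assert g.reml_loglik((vf, vb, ve), y, des) == pytest.approx(
                dense_reml_loglik(vf, vb, ve, y, des), abs=1e-8)

    def test_invariant_to_intercept_shift(self):
        y, des, _ = simulate_vector(SMALL, GCFG, seed=3)
        a = g.reml_loglik((0.2, 0.1, 0.6), y, des)
        b = g.reml_loglik((0.2, 0.1, 0.6), y + 7.5, des)
        assert a == pytest.approx(b, abs=1e-8)

    def test_scale_equivariance(self):
        y, des, _ = simulate_vector(SMALL, GCFG, seed=4)
        c = 3.0
        fit1 = g.reml_fit(y, des)
        fit2 = g.reml_fit(c * y, des)
        assert fit2.var_family == pytest.approx(c ** 2 * fit1.var_family, rel=1e-3, abs=1e-8)
        assert fit2.var_block == pytest.approx(c ** 2 * fit1.var_block, rel=1e-3, abs=1e-8)
        assert fit2.var_residual == pytest.approx(c ** 2 * fit1.var_residual, rel=1e-4)
        n, p = des.n, des.fixed_design().shape[1]
        assert fit2.loglik == pytest.approx(fit1.loglik - (n - p) * np.log(c),
                                            abs=1e-4)

    def test_zero_residual_rejected(self):
        y, des, _ = simulate_vector(SMALL, GCFG, seed=5)
        with pytest.raises(ValueError, match="residual"):
            g.reml_loglik((0.1, 0.1, 0.0), y, des)


class TestRemlFit:
    def test_balanced_one_way_matches_anova_estimators(self):
        """On a balanced single-site, single-block family design the REML
        estimates equal the classical ANOVA moment estimators
        sf2 = (MS_family - MS_within)/m, se2 = MS_within when positive."""
        rng = np.random.default_rng(3)
        k, m = 8, 10
        fam = np.repeat([f"F{i}" for i in range(k)], m)
        y = rng.normal(0, 1, k * m) + np.repeat(rng.normal(0, 0.7, k), m)
        des = g.PedigreeDesign(site=np.repeat("S1", k * m),
                               block=np.repeat("B1", k * m), family=fam)
        fit = g.reml_fit(y, des)
        ybar = y.reshape(k, m).mean(axis=1)
        ms_f = m * np.sum((ybar - y.mean()) ** 2) / (k - 1)
        ms_w = np.sum((y.reshape(k, m) - ybar[:, None]) ** 2) / (k * (m - 1))
        assert fit.var_family == pytest.approx((ms_f - ms_w) / m, rel=1e-5)
        assert fit.var_residual == pytest.approx(ms_w, rel=1e-5)
        assert "block" in fit.boundary

    def test_optimum_beats_lattice_search(self):
        """Optimizer log-likelihood dominates a brute-force lattice over
        variance triples on a tiny instance (3 families x 2 blocks)."""
        y, des, _ = simulate_vector(
            LayoutConfig(sites=("S1",), blocks_per_site=2, trees_per_block=3,
                         n_families=3, block_cols=3),
            GeneticConfig(var_family=0.2, var_block=0.2, var_residual=0.6,
                          monthly_means={"Jul": 1.0}, seed=8), seed=8)
        assert len(y) == 6  # 2 blocks x 3 trees
        fit = g.reml_fit(y, des)
        grid = np.geomspace(1e-4, 5.0, 18)
        best = -np.inf
        for vf in np.concatenate([[0.0], grid]):
            for vb in np.concatenate([[0.0], grid]):
                for ve in grid:
                    best = max(best, g.reml_loglik((vf, vb, ve), y, des))
        assert fit.loglik >= best - 1e-4

    def test_matches_lme4_reference(self, tmp_path):
        """Cross-check variance components against R/lme4 on one
        simulated instance."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        y, des, tr = simulate_vector(SMALL, GCFG, seed=12)
        csv = tmp_path / "d.csv"
        tr.to_csv(csv, index=False)
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- lmer(value ~ site + (1|block) + (1|family), data=d, REML=TRUE);"
            "v <- as.data.frame(VarCorr(m));"
            "cat(v$vcov[v$grp=='family'], v$vcov[v$grp=='block'],"
            "    v$vcov[v$grp=='Residual'], REMLcrit(m)/-2)")
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        vf, vb, ve, ll = map(float, out.stdout.split())
        fit = g.reml_fit(y, des)
        assert fit.var_family == pytest.approx(vf, rel=1e-3, abs=1e-6)
        assert fit.var_block == pytest.approx(vb, rel=1e-3, abs=1e-6)
        assert fit.var_residual == pytest.approx(ve, rel=1e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_zero_family_variance_recovered_at_boundary(self, paper_layout):
        """With no genetic signal the family component collapses to the
        boundary in nearly all replicates."""
        hits = 0
        reps = 15
        for rep in range(reps):
            cfg = GeneticConfig(var_family=0.0, var_block=0.1, var_residual=0.9,
                                monthly_means={"Jul": 2.0}, seed=600 + rep)
            tr = simulate_traits(paper_layout, {"N": cfg}, months=["Jul"])
            fit = g.reml_fit(tr["value"].to_numpy(),
                             g.PedigreeDesign.from_frame(tr))
            hits += fit.var_family <= 0.01 * fit.var_residual
        assert hits >= 0.9 * reps

    def test_interior_truth_recovered_at_scale(self, paper_layout):
        """Variance-component bias stays within 10% of an interior truth
        at the 800-tree trial scale (averaged over seeds)."""
        truth = dict(var_family=0.10, var_block=0.10, var_residual=0.80)
        fits = []
        for rep in range(50):
            cfg = GeneticConfig(**truth, monthly_means={"Jul": 2.0},
                                seed=700 + rep)
            tr = simulate_traits(paper_layout, {"N": cfg}, months=["Jul"])
            fits.append(g.reml_fit(tr["value"].to_numpy(),
                                   g.PedigreeDesign.from_frame(tr)))
        for name in truth:
            vals = [getattr(f, name) for f in fits]
            # 10% bias band plus the Monte-Carlo error of the mean itself
            mc_err = 2 * np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - truth[name]) <= 0.10 * truth[name] + mc_err

    def test_permutation_null_concentrates_at_zero(self, paper_layout):
        """Shuffling family labels destroys the genetic signal: the
        permuted h2 distribution has median ~0."""
        cfg = default_genetics(seed=3)["N"]
        tr = simulate_traits(paper_layout, {"N": cfg}, months=["Jul"])
        y = tr["value"].to_numpy()
        rng = np.random.default_rng(19)
        fam = tr["family"].to_numpy()
        h2s = []
        for _ in range(100):
            des = g.PedigreeDesign(site=tr["site"].to_numpy(),
                                   block=tr["block"].to_numpy(),
                                   family=rng.permutation(fam))
            fit = g.reml_fit(y, des)
            h2s.append(g.heritability(fit))
        assert np.median(h2s) <= 0.05


class TestArithmetic:
    def test_heritability_worked_case(self):
        vc = g.VarianceComponents(0.2, 0.3, 0.5, {}, 0.0, True)
        assert g.heritability(vc) == pytest.approx(0.5, abs=1e-12)

    def test_zero_family_variance_gives_zero(self):
        vc = g.VarianceComponents(0.0, 0.3, 0.5, {}, 0.0, True)
        assert g.heritability(vc) == 0.0

    def test_h2_above_one_warned_not_truncated(self):
        vc = g.VarianceComponents(0.6, 0.2, 0.2, {}, 0.0, True)
        with pytest.warns(UserWarning, match="exceeds 1"):
            assert g.heritability(vc) == pytest.approx(1.5, abs=1e-12)

    def test_all_zero_variances_rejected(self):
        vc = g.VarianceComponents(0.0, 0.0, 0.0, {}, 0.0, True)
        with pytest.raises(ValueError, match="undefined"):
            g.heritability(vc)

    def test_breeding_value_worked_case(self):
        bv = g.breeding_values(0.49, pd.Series({"F1": 2.1, "F2": 2.0}), 2.0)
        assert bv["F1"] == pytest.approx(0.049, abs=1e-12)
        assert bv["F2"] == 0.0

    def test_weighted_breeding_values_sum_to_zero(self):
        rng = np.random.default_rng(2)
        sizes = pd.Series({f"F{i}": int(s) for i, s in
                           enumerate(rng.integers(10, 50, 8))})
        means = pd.Series({f: rng.normal(2, 0.3) for f in sizes.index})
        mu = float((means * sizes).sum() / sizes.sum())
        bv = g.breeding_values(0.3, means, mu)
        assert float((bv * sizes).sum()) == pytest.approx(0.0, abs=1e-10)


class TestSelection:
    @staticmethod
    def _bv_table(values_by_trait, month="Jul"):
        rows = []
        for trait, vals in values_by_trait.items():
            for fam, v in vals.items():
                rows.append({"family": fam, "month": month, "trait": trait,
                             "breeding_value": v})
        return pd.DataFrame(rows)

    def test_dominant_family_selected_first(self):
        bv = self._bv_table({"N": {"F1": 0.5, "F2": 0.0, "F3": -0.5},
                             "NSC": {"F1": 0.4, "F2": 0.1, "F3": -0.5}})
        assert g.select_families(bv, ["Jul"])[0] == "F1"

    def test_identical_families_select_nothing(self):
        bv = self._bv_table({"N": {"F1": 0.1, "F2": 0.1},
                             "NSC": {"F1": 0.1, "F2": 0.1}})
        assert g.select_families(bv, ["Jul"]) == []

    def test_empty_month_set_rejected(self):
        bv = self._bv_table({"N": {"F1": 0.1, "F2": 0.0}})
        with pytest.raises(ValueError, match="month"):
            g.select_families(bv, [])

    def test_planted_superior_families_recovered(self, paper_layout):
        planted = ["F03", "F07", "F11", "F15", "F19"]
        gen = plant_superior_families(default_genetics(seed=91), planted)
        tr = simulate_traits(paper_layout, gen, months=["Jul"])
        series = g.monthly_genetic_series(tr, months=["Jul"])
        bv = pd.DataFrame([
            {"trait": s.trait, "month": s.month, "family": f, "breeding_value": b}
            for s in series for f, b in s.breeding_values.items()])
        assert set(planted) <= set(g.select_families(bv, ["Jul"]))


class TestMonthlySeries:
    def test_one_h2_per_trait_month(self):
        lay = make_layout(SMALL, seed=21)
        tr = simulate_traits(lay, default_genetics(seed=22))
        series = g.monthly_genetic_series(tr)
        assert len(series) == 2 * 11
        for s in series:
            assert s.error is None
            assert s.h2 >= 0

    def test_zero_signal_month_isolated(self, paper_layout):
        """A month simulated without family variance shows h2 ~ 0 while
        the surrounding months keep their genetic signal."""
        strong = GeneticConfig(var_family=0.3, var_block=0.05, var_residual=0.65,
                               monthly_means={"Jun": 2.0, "Aug": 2.0}, seed=31)
        null = GeneticConfig(var_family=0.0, var_block=0.05, var_residual=0.95,
                             monthly_means={"Jul": 2.0}, seed=32)
        tr = pd.concat([
            simulate_traits(paper_layout, {"N": strong}, months=["Jun", "Aug"]),
            simulate_traits(paper_layout, {"N": null}, months=["Jul"])],
            ignore_index=True)
        series = {s.month: s for s in g.monthly_genetic_series(
            tr, months=["Jun", "Jul", "Aug"])}
        assert series["Jul"].h2 <= 0.05
        assert series["Jun"].h2 >= 0.3
        assert series["Aug"].h2 >= 0.3

    def test_failed_month_recorded_not_fatal(self):
        lay = make_layout(SMALL, seed=33)
        tr = simulate_traits(lay, default_genetics(seed=34), months=["Jun", "Jul"])
        # one family only in July -> design error for that month
        tr.loc[(tr["month"] == "Jul"), "family"] = "F01"
        series = g.monthly_genetic_series(tr, months=["Jun", "Jul"])
        by_month = {(s.trait, s.month): s for s in series}
        assert by_month[("N", "Jun")].error is None
        assert by_month[("N", "Jul")].error is not None
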