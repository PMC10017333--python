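"""REML variance components, narrow-sense heritability and family
breeding values for an open-pollinated progeny trial.

Model (one trait, one month):

    y = X m + Z1 b + Z2 f + e,
    b ~ N(0, s2_b I),  f ~ N(0, s2_f I),  e ~ N(0, s2_e I),

with fixed effects m = intercept + site contrasts and random block and
family effects.  Heritability uses the open-pollinated family
relationship: h2 = 2.5 * s2_f / (s2_f + s2_b + s2_e); the 2.5 (rather
than 4) reflects a presumed mix of half- and full-sibs among
open-pollinated progeny.  Family breeding values are a_i = h2 * (ybar_i
- mu), mu being the trait's grand mean.

The REML criterion is maximized on the log scale of the variance
*ratios* (block/residual, family/residual) with the residual variance
profiled out in closed form; the n x n covariance inverse and
determinant use the Woodbury/determinant-lemma identities through the
q-dimensional random-effect cross-products, so one likelihood
evaluation costs O(q^3) after an O(n q^2) setup.  Optimization is
Nelder-Mead from 3 starts, followed by explicit boundary refits with
each random term dropped, so zero variance components are estimated
exactly rather than floored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = ["PedigreeDesign", "VarianceComponents", "GeneticSummary",
           "reml_fit", "reml_loglik", "heritability", "breeding_values",
           "select_families", "monthly_genetic_series",
           "HERITABILITY_COEF"]

#: numerator coefficient of the open-pollinated family h2 formula.
HERITABILITY_COEF = 2.5

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class PedigreeDesign:
    """Incidence structure aligned to a trait vector.

    Built from per-tree site/block/family labels; exposes the fixed
    design X (intercept + site contrasts) and the random-effect
    incidence matrices for block and family.
    """

    site: np.ndarray
    block: np.ndarray
    family: np.ndarray
    site_levels: tuple[str, ...] = field(init=False)
    block_levels: tuple[str, ...] = field(init=False)
    family_levels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.site = np.asarray(self.site)
        self.block = np.asarray(self.block)
        self.family = np.asarray(self.family)
        n = len(self.site)
        if not (len(self.block) == len(self.family) == n):
            raise ValueError("site/block/family labels must have equal length")
        self.site_levels = tuple(sorted(pd.unique(self.site)))
        self.block_levels = tuple(sorted(pd.unique(self.block)))
        self.family_levels = tuple(sorted(pd.unique(self.family)))
        if len(self.family_levels) < 2:
            raise ValueError("need at least 2 families")
        # a single block level is tolerated: its variance is confounded
        # with the intercept under REML, so the block term is dropped
        # (reported as a boundary estimate of zero)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeDesign":
        return cls(site=df["site"].to_numpy(), block=df["block"].to_numpy(),
                   family=df["family"].to_numpy())

    @property
    def n(self) -> int:
        return len(self.site)

    def fixed_design(self) -> np.ndarray:
        X = [np.ones(self.n)]
        for lvl in self.site_levels[1:]:
            X.append((self.site == lvl).astype(float))
        return np.column_stack(X)

    def incidence(self, which: str) -> np.ndarray:
        labels = getattr(self, which)
        levels = getattr(self, f"{which}_levels")
        codes = pd.Categorical(labels, categories=levels).codes
        Z = np.zeros((self.n, len(levels)))
        Z[np.arange(self.n), codes] = 1.0
        return Z


@dataclass
class VarianceComponents:
    var_family: float
    var_block: float
    var_residual: float
    fixed_effects: dict[str, float]
    loglik: float
    converged: bool
    boundary: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return self.var_family + self.var_block + self.var_residual


@dataclass
class GeneticSummary:
    """Per trait-month genetic evaluation."""

    trait: str
    month: str
    components: VarianceComponents | None
    h2: float | None
    population_mean: float | None
    family_means: pd.Series | None
    breeding_values: pd.Series | None
    error: str | None = None


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _RemlWork:
    """Cross-products for fast profiled-REML evaluation."""

    def __init__(self, y: np.ndarray, design: PedigreeDesign):
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(y) != design.n:
            raise ValueError("y must be a vector aligned to the design")
        X = design.fixed_design()
        n, p = X.shape
        if n < p + 2:
            raise ValueError(f"n={n} too small for {p} fixed effects")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("singular fixed-effects design")
        self.y, self.X, self.n, self.p = y, X, n, p
        self.Zb = design.incidence("block")
        self.Zf = design.incidence("family")
        self.nb = self.Zb.shape[1]
        self.nf = self.Zf.shape[1]
        Z = np.hstack([self.Zb, self.Zf])
        self.Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def profiled(self, gamma_b: float, gamma_f: float):
        """Profiled REML: given variance ratios, concentrate out s2_e.

        Returns (loglik, s2_e, beta) at the profiled optimum.
        """
        n, p = self.n, self.p
        g = np.concatenate([np.full(self.nb, gamma_b), np.full(self.nf, gamma_f)])
        active = g > 0
        if active.any():
            s = np.sqrt(g[active])
            W = np.eye(int(active.sum())) + (s[:, None] * self.ZtZ[np.ix_(active, active)]) * s[None, :]
            cw = cho_factor(W, lower=True)
            logdet_h = 2.0 * np.sum(np.log(np.diag(cw[0])))
            U_x = s[:, None] * self.ZtX[active]         # q_a x p
            u_y = s * self.Zty[active]                  # q_a
            XtHiX = self.XtX - U_x.T @ cho_solve(cw, U_x)
            XtHiy = self.Xty - U_x.T @ cho_solve(cw, u_y)
            ytHiy = self.yty - float(u_y @ cho_solve(cw, u_y))
        else:
            logdet_h = 0.0
            XtHiX, XtHiy, ytHiy = self.XtX, self.Xty, self.yty
        cx = cho_factor(XtHiX, lower=True)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        beta = cho_solve(cx, XtHiy)
        r = ytHiy - float(beta @ XtHiy)
        r = max(r, 1e-300)
        s2e = r / (n - p)
        ll = -0.5 * ((n - p) * (math.log(s2e) + _LOG2PI + 1.0)
                     + logdet_h + logdet_x)
        return ll, s2e, beta

    def loglik_at(self, var_block: float, var_family: float, var_residual: float) -> float:
        """REML log-likelihood at explicit variance components."""
        if min(var_block, var_family, var_residual) < 0:
            raise ValueError("variances must be nonnegative")
        if var_residual <= 0:
            raise ValueError("residual variance must be positive (singular covariance)")
        n, p = self.n, self.p
        s2e = var_residual
        g = np.concatenate([np.full(self.nb, var_block / s2e),
                            np.full(self.nf, var_family / s2e)])
        active = g > 0
        if active.any():
            s = np.sqrt(g[active])
            W = np.eye(int(active.sum())) + (s[:, None] * self.ZtZ[np.ix_(active, active)]) * s[None, :]
            cw = cho_factor(W, lower=True)
            logdet_h = 2.0 * np.sum(np.log(np.diag(cw[0])))
            U_x = s[:, None] * self.ZtX[active]
            u_y = s * self.Zty[active]
            XtHiX = self.XtX - U_x.T @ cho_solve(cw, U_x)
            XtHiy = self.Xty - U_x.T @ cho_solve(cw, u_y)
            ytHiy = self.yty - float(u_y @ cho_solve(cw, u_y))
        else:
            logdet_h = 0.0
            XtHiX, XtHiy, ytHiy = self.XtX, self.Xty, self.yty
        cx = cho_factor(XtHiX, lower=True)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        beta = cho_solve(cx, XtHiy)
        r = (ytHiy - float(beta @ XtHiy)) / s2e
        # log|V| = n log s2e + log|H|; log|X'V^-1X| = log|X'H^-1X| - p log s2e
        return -0.5 * ((n - p) * (math.log(s2e) + _LOG2PI)
                       + logdet_h + logdet_x + r)

    def beta_dict(self, beta, design: PedigreeDesign) -> dict[str, float]:
        names = ["intercept"] + [f"site[{lvl}]" for lvl in design.site_levels[1:]]
        return {k: float(v) for k, v in zip(names, beta)}


def reml_loglik(components: VarianceComponents | Sequence[float],
                y: np.ndarray, design: PedigreeDesign) -> float:
    """REML log-likelihood of (s2_f, s2_b, s2_e) for y under the design.

    Deterministic; exposed so the optimizer can be audited against dense
    restricted-likelihood computations.
    """
    if isinstance(components, VarianceComponents):
        vf, vb, ve = (components.var_family, components.var_block,
                      components.var_residual)
    else:
        vf, vb, ve = components
    return _RemlWork(y, design).loglik_at(vb, vf, ve)


_STARTS = ((math.log(0.1), math.log(0.1)),
           (0.0, 0.0),
           (math.log(0.01), math.log(0.5)))


def reml_fit(y: np.ndarray, design: PedigreeDesign) -> VarianceComponents:
    """Maximize the REML criterion over the nonnegative variance orthant.

    Nelder-Mead on log variance ratios from 3 starts, then explicit
    refits with block and/or family variance fixed at zero; the best
    criterion value wins, and components estimated at zero are reported
    in ``boundary``.
    """
    work = _RemlWork(y, design)
    block_estimable = work.nb >= 2

    def negll(theta):
        gb, gf = math.exp(theta[0]), math.exp(theta[1])
        if max(gb, gf) > 1e8:
            return 1e12
        try:
            return -work.profiled(gb, gf)[0]
        except np.linalg.LinAlgError:
            return 1e12

    candidates = []
    converged = True
    if block_estimable:
        best = None
        converged = False
        for start in _STARTS:
            res = optimize.minimize(negll, start, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-9,
                                             "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        gb, gf = math.exp(best.x[0]), math.exp(best.x[1])
        candidates.append((gb, gf, ()))

    # boundary refits: drop each random term and re-profile
    def refit_1d(fixed_zero: str):
        def neg1(t):
            g = math.exp(t[0])
            if g > 1e8:
                return 1e12
            gb_, gf_ = (0.0, g) if fixed_zero == "block" else (g, 0.0)
            return -work.profiled(gb_, gf_)[0]
        r = optimize.minimize_scalar(lambda t: neg1([t]), bounds=(-20, 18),
                                     method="bounded")
        g = math.exp(r.x)
        return (0.0, g, ("block",)) if fixed_zero == "block" else (g, 0.0, ("family",))

    candidates.append(refit_1d("block"))
    if block_estimable:
        candidates.append(refit_1d("family"))
    candidates.append((0.0, 0.0, ("block", "family")))

    best_ll, best_cand = -np.inf, None
    for gb_, gf_, bound in candidates:
        try:
            ll, s2e, beta = work.profiled(gb_, gf_)
        except np.linalg.LinAlgError:
            continue
        if ll > best_ll:
            best_ll, best_cand = ll, (gb_, gf_, bound, s2e, beta)
    if best_cand is None:
        raise RuntimeError("REML optimization failed to evaluate any candidate")
    gb_, gf_, bound, s2e, beta = best_cand
    # tiny interior ratios are boundary estimates in all but name
    extra = []
    if gb_ > 0 and gb_ < 1e-8:
        gb_, extra = 0.0, extra + ["block"]
    if gf_ > 0 and gf_ < 1e-8:
        gf_, extra = 0.0, extra + ["family"]
    if extra:
        best_ll, s2e, beta = work.profiled(gb_, gf_)
        bound = tuple(sorted(set(bound) | set(extra)))
    if not converged:
        warnings.warn("REML optimizer did not report convergence; "
                      "returning best point found")
    return VarianceComponents(
        var_family=gf_ * s2e, var_block=gb_ * s2e, var_residual=s2e,
        fixed_effects=work.beta_dict(beta, design),
        loglik=float(best_ll), converged=converged, boundary=tuple(bound))


# ---------------------------------------------------------------------------
# heritability, breeding values, selection
# ---------------------------------------------------------------------------

def heritability(components: VarianceComponents,
                 coefficient: float = HERITABILITY_COEF) -> float:
    """Narrow-sense h2 = coef * s2_f / (s2_f + s2_b + s2_e).

    The open-pollinated coefficient can push h2 above 1; such values are
    reported with a warning rather than truncated.
    """
    denom = components.total
    if denom <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    h2 = coefficient * components.var_family / denom
    if h2 > 1.0:
        warnings.warn(f"h2 = {h2:.3f} exceeds 1 (open-pollinated coefficient)")
    return h2


def breeding_values(h2: float, family_means: pd.Series,
                    population_mean: float) -> pd.Series:
    """Family breeding values a_i = h2 * (ybar_i - mu)."""
    if len(family_means) < 2:
        raise ValueError("need at least 2 families")
    bv = h2 * (family_means - population_mean)
    bv.name = "breeding_value"
    return bv


def select_families(bv: pd.DataFrame, months: Sequence[str],
                    rule: str = "both above mean",
                    k: int | None = None) -> list[str]:
    """Bivariate quadrant selection on N and NSC breeding values.

    A family is selected when its breeding value strictly exceeds the
    across-family mean for *both* traits in *every* month of ``months``.
    Selected ids are ordered by the sum of standardized breeding values
    over the selection months (ties by family id); ``k`` truncates.
    """
    if rule != "both above mean":
        raise ValueError(f"unknown selection rule {rule!r}")
    months = list(months)
    if not months:
        raise ValueError("empty month set")
    needed = {"family", "month", "trait", "breeding_value"}
    if not needed <= set(bv.columns):
        raise ValueError(f"breeding-value table needs columns {sorted(needed)}")
    sub = bv[bv["month"].isin(months)]
    traits = sorted(sub["trait"].unique())
    families = sorted(sub["family"].unique())
    ok = pd.Series(True, index=families)
    score = pd.Series(0.0, index=families)
    for month in months:
        for trait in traits:
            cell = sub[(sub["month"] == month) & (sub["trait"] == trait)]
            if set(cell["family"]) != set(families):
                missing = sorted(set(families) - set(cell["family"]))
                raise ValueError(f"{trait}/{month}: missing breeding values for {missing}")
            vals = cell.set_index("family")["breeding_value"].reindex(families)
            ok &= vals > vals.mean()
            sd = vals.std(ddof=0)
            score += (vals - vals.mean()) / sd if sd > 0 else 0.0
    chosen = sorted((f for f in families if ok[f]),
                    key=lambda f: (-score[f], f))
    return chosen[:k] if k is not None else chosen


def monthly_genetic_series(traits: pd.DataFrame,
                           months: Sequence[str] | None = None,
                           coefficient: float = HERITABILITY_COEF,
                           ) -> list[GeneticSummary]:
    """Independent univariate REML evaluation per trait-month.

    ``traits`` is the long table (tree_id, month, trait, value, family,
    block, site).  A month whose fit fails is recorded with its error
    and the series continues.
    """
    out: list[GeneticSummary] = []
    trait_names = sorted(traits["trait"].unique())
    month_order = [m for m in
                   (months if months is not None else pd.unique(traits["month"]))]
    for trait in trait_names:
        for month in month_order:
            sub = traits[(traits["trait"] == trait) & (traits["month"] == month)]
            if sub.empty:
                out.append(GeneticSummary(trait, month, None, None, None, None,
                                          None, error="no data"))
                continue
            try:
                design = PedigreeDesign.from_frame(sub)
                y = sub["value"].to_numpy(dtype=float)
                vc = reml_fit(y, design)
                h2 = heritability(vc, coefficient=coefficient)
                mu = float(y.mean())
                fam_means = sub.groupby("family")["value"].mean()
                bv = breeding_values(h2, fam_means, mu)
                out.append(GeneticSummary(trait, month, vc, h2, mu, fam_means, bv))
            except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                out.append(GeneticSummary(trait, month, None, None, None, None,
                                          None, error=str(exc)))
    return out
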