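"""Treatment-effect and trait-relationship statistics.

Each trait y_ij of tree j in plot i is modeled with a nested two-level
linear mixed-effects model fitted by REML:

    y = beta_1 T_1 + ... + beta_7 T_7 + a_site + c_plot(site) + eps

with cell-means (no-intercept) coding of the seven thinning treatments, a
random intercept per study site, a random intercept per plot nested in
site, and independent residuals.  Pairwise treatment differences are tested
with Tukey's honest significance test (studentized-range distribution on
the fitted fixed-effect covariance).  Trait-SAHMC relationships are screened
with Pearson and Spearman correlations and with single-predictor mixed
models that keep the same nested random structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

REQUIRED_KEYS = ("site", "plot", "treatment")


@dataclass
class LMMFit:
    trait: str
    treatments: list[str]
    fixed_effects: pd.Series      # one estimate per treatment (cell means)
    fixed_se: pd.Series
    fixed_cov: pd.DataFrame
    var_site: float
    var_plot: float
    var_resid: float
    loglike: float
    converged: bool
    n_obs: int
    n_plots: int
    n_sites: int


@dataclass
class TukeyResult:
    contrasts: pd.DataFrame  # columns: a, b, estimate, se, q, p_adj, significant
    alpha: float = 0.05

    def pvalue(self, a: str, b: str) -> float:
        c = self.contrasts
        row = c[((c.a == a) & (c.b == b)) | ((c.a == b) & (c.b == a))]
        if row.empty:
            raise KeyError(f"no contrast between {a!r} and {b!r}")
        return float(row.p_adj.iloc[0])


def _validate_nesting(table: pd.DataFrame) -> None:
    for key in REQUIRED_KEYS:
        if key not in table.columns:
            raise ValueError(f"trait table lacks required column {key!r}")
    # plot labels are interpreted within their site (composite key), so
    # nesting holds by construction; remaining checks guard degenerate sizes
    n_sites = table["site"].nunique()
    if n_sites < 2:
        raise ValueError("need >= 2 study sites")
    plots_per_site = table.groupby("site")["plot"].nunique()
    if (plots_per_site < 2).any():
        bad = plots_per_site[plots_per_site < 2].index.tolist()
        raise ValueError(f"sites with a single plot break the nesting: {bad}")
    trees_per_plot = table.groupby(["site", "plot"]).size()
    if (trees_per_plot < 2).any():
        bad = trees_per_plot[trees_per_plot < 2].index.tolist()
        raise ValueError(f"plots with fewer than 2 trees: {bad}")


def fit_nested_lmm(table: pd.DataFrame, trait: str,
                   predictor: str | None = None) -> LMMFit:
    """REML fit of the nested two-level model for one trait.

    With ``predictor=None`` the fixed part is the cell-means treatment
    coding (one beta per treatment, no intercept); with a predictor name it
    is an intercept plus that single covariate (the trait-screen variant).
    Non-convergence is flagged on the result, not raised.
    """
    _validate_nesting(table)
    if trait not in table.columns:
        raise ValueError(f"trait {trait!r} not in table")
    df = table.reset_index(drop=True)
    df["_plot"] = df["site"].astype(str) + "/" + df["plot"].astype(str)

    if predictor is None:
        formula = f"Q('{trait}') ~ 0 + C(treatment)"
    else:
        formula = f"Q('{trait}') ~ Q('{predictor}')"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups="site",
                            re_formula="1", vc_formula={"plot": "0 + C(_plot)"})
        res = None
        converged = False
        for method in (None, "cg", "powell"):
            try:
                cand = model.fit(reml=True, **({} if method is None else {"method": method}))
            except Exception:
                continue
            res = cand
            if bool(cand.converged):
                converged = True
                break
        if res is None:
            res = model.fit(reml=True, method="nm", maxiter=500)
            converged = False

    fe = res.fe_params.copy()
    if predictor is None:
        def _level(name: str) -> str:
            lvl = name.split("[", 1)[1][:-1]
            return lvl[2:] if lvl.startswith("T.") else lvl
        fe.index = [_level(n) for n in fe.index]

    var_site = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_plot = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    var_resid = float(res.scale)
    # GLS fixed-effect covariance from the estimated variance components:
    # finite even when a variance estimate sits on the boundary, where the
    # Hessian-based covariance is not.
    X = np.asarray(model.exog)
    # jitter keeps V invertible when the residual variance degenerates to 0
    # (e.g. an exactly collinear predictor)
    eps = 1e-10 * max(var_site + var_plot + var_resid, 1e-8)
    cov_inv = np.zeros((X.shape[1], X.shape[1]))
    for _, sub in df.groupby("site", sort=False):
        idx = df.index.get_indexer(sub.index)
        Xg = X[idx]
        n_g = len(idx)
        V = np.full((n_g, n_g), var_site)
        plots = sub["_plot"].to_numpy()
        same_plot = plots[:, None] == plots[None, :]
        V[same_plot] += var_plot
        V[np.diag_indices(n_g)] += var_resid + eps
        cov_inv += Xg.T @ np.linalg.solve(V, Xg)
    cov_arr = np.linalg.pinv(cov_inv)
    se = pd.Series(np.sqrt(np.diag(cov_arr)), index=fe.index)
    cov = pd.DataFrame(cov_arr, index=fe.index, columns=fe.index)
    return LMMFit(
        trait=trait,
        treatments=list(fe.index) if predictor is None else [],
        fixed_effects=fe,
        fixed_se=se,
        fixed_cov=cov,
        var_site=var_site,
        var_plot=var_plot,
        var_resid=var_resid,
        loglike=float(res.llf),
        converged=converged,
        n_obs=int(res.nobs),
        n_plots=int(df["_plot"].nunique()),
        n_sites=int(df["site"].nunique()),
    )


def tukey_contrasts(fit: LMMFit, alpha: float = 0.05) -> TukeyResult:
    """All pairwise treatment contrasts with Tukey family-wise adjustment.

    The studentized-range statistic uses the fitted model's fixed-effect
    covariance; the denominator degrees of freedom follow the containment
    rule at the plot level (treatment is a plot-level factor):
    df = n_plots - n_treatments.
    """
    if not fit.converged:
        raise ValueError("cannot build Tukey contrasts from a non-converged fit")
    k = len(fit.fixed_effects)
    if k < 2:
        raise ValueError("need >= 2 treatment levels")
    df_denom = max(fit.n_plots - k, 1)
    rows = []
    for a, b in itertools.combinations(fit.fixed_effects.index, 2):
        est = float(fit.fixed_effects[a] - fit.fixed_effects[b])
        se = float(np.sqrt(fit.fixed_cov.loc[a, a] + fit.fixed_cov.loc[b, b]
                           - 2 * fit.fixed_cov.loc[a, b]))
        q = abs(est) / se * np.sqrt(2) if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_denom))
        rows.append(dict(a=a, b=b, estimate=est, se=se, q=q, p_adj=min(p, 1.0),
                         significant=p < alpha))
    return TukeyResult(pd.DataFrame(rows), alpha=alpha)


def trait_screen(table: pd.DataFrame, traits: list[str],
                 response: str = "sahmc_cm2") -> pd.DataFrame:
    """Per-trait association with SAHMC.

    Reports Pearson and Spearman correlations (two-sided p) and the slope of
    a single-predictor nested mixed model of SAHMC on the trait.  Traits
    with zero variance are reported with NaN coefficients.
    """
    rows = []
    for trait in traits:
        sub = table[[*REQUIRED_KEYS, trait, response]].dropna()
        x = sub[trait].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        row: dict = {"trait": trait, "n": len(sub)}
        if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
            row.update(pearson_r=np.nan, pearson_p=np.nan,
                       spearman_rho=np.nan, spearman_p=np.nan,
                       lmm_slope=np.nan, lmm_slope_se=np.nan, lmm_slope_p=np.nan,
                       converged=False)
            rows.append(row)
            continue
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        row.update(pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
                   spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue))
        fit = fit_nested_lmm(sub, response, predictor=trait)
        slope_name = fit.fixed_effects.index[-1]
        slope = float(fit.fixed_effects[slope_name])
        se = float(fit.fixed_se[slope_name])
        zval = slope / se if se > 0 else np.inf
        row.update(lmm_slope=slope, lmm_slope_se=se,
                   lmm_slope_p=float(2 * stats.norm.sf(abs(zval))),
                   converged=fit.converged)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_nested_dataset(
    betas: dict[str, float],
    n_sites: int = 3,
    plots_per_site: int = 9,
    trees_per_plot: int = 25,
    var_site: float = 1.0,
    var_plot: float = 0.5,
    var_resid: float = 4.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Draw a trait table directly from the nested model (simulation oracle).

    Treatments are assigned to plots in rotation so every level appears;
    used for parameter-recovery, Tukey-null and power simulations.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    treatments = list(betas)
    rows = []
    t = 0
    for s in range(n_sites):
        a = rng.normal(0, np.sqrt(var_site))
        for p in range(plots_per_site):
            c = rng.normal(0, np.sqrt(var_plot))
            treatment = treatments[t % len(treatments)]
            t += 1
            mu = betas[treatment] + a + c
            for _ in range(trees_per_plot):
                rows.append(dict(site=f"s{s}", plot=f"s{s}p{p}", treatment=treatment,
                                 y=mu + rng.normal(0, np.sqrt(var_resid))))
    return pd.DataFrame(rows)
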