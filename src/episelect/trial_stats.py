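"""Per-trait trial models and line-vs-check contrasts.

The workhorse model is ``value ~ genotype + block`` with genotype fixed and
block random (REML), fitted per trait.  Count traits use a Poisson GLM with
log link and flowering time a Gamma GLM with log link, each with block as a
fixed covariate.  Least-squares means are marginal over blocks.  Also hosts
the 2x2 Fisher exact test, reversion frequencies, and moisture
standardization of plot yields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._util import DataError, round_half_up

FAMILIES = ("gaussian-mixed", "poisson-log", "gamma")


@dataclass(frozen=True)
class TraitModelSpec:
    """Which model to fit for a trait.

    ``family`` is one of ``gaussian-mixed`` (linear mixed model, block
    random), ``poisson-log`` (counts) or ``gamma`` (positive continuous,
    log link).
    """

    trait: str
    family: str = "gaussian-mixed"
    fixed: str = "genotype"
    random: str = "block"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


# Model family defaults per trait, mirroring the analysis plan.
DEFAULT_TRAIT_FAMILIES = {
    "yield_g": "gaussian-mixed",
    "yield_kg_ha_std": "gaussian-mixed",
    "height_cm": "gaussian-mixed",
    "tiller_count": "poisson-log",
    "days_to_flowering": "gamma",
}


@dataclass
class TraitModelFit:
    """Fitted per-trait model: genotype LS-means plus variance components."""

    spec: TraitModelSpec
    reference: str
    ls_means: pd.Series
    block_var: float
    resid_var: float
    converged: bool
    n_obs: int
    n_blocks: int
    diagnostics: dict = field(default_factory=dict)
    # link-scale contrast (level - reference), its SE and Wald p, per non-reference level
    _coef: pd.Series = field(default_factory=pd.Series, repr=False)
    _bse: pd.Series = field(default_factory=pd.Series, repr=False)
    _pvalues: pd.Series = field(default_factory=pd.Series, repr=False)


@dataclass(frozen=True)
class ContrastResult:
    line_id: str
    trait: str
    ls_mean: float
    wt_ls_mean: float
    difference: float
    p_value: float
    direction: str  # higher | lower | ns


def _level_from_term(term: str) -> str:
    # patsy names treatment terms like C(genotype, Treatment('WT'))[T.L001]
    return term.split("[T.", 1)[1].rstrip("]")


def fit_trait_model(
    records: pd.DataFrame,
    spec: TraitModelSpec,
    reference: str = "WT",
) -> TraitModelFit:
    """Fit the per-trait model and return LS-means and variance components.

    ``records`` must have columns ``genotype``, ``block`` and ``spec.trait``.
    With fewer than two blocks the random term is dropped and a fixed-effects
    model is fitted instead (with a warning).  Non-convergence is flagged on
    the result, never silently replaced.
    """
    for col in ("genotype", "block", spec.trait):
        if col not in records.columns:
            raise DataError(f"missing required column {col!r}")
    df = records[["genotype", "block", spec.trait]].dropna().copy()
    df["genotype"] = df["genotype"].astype(str)
    levels = df["genotype"].unique()
    if len(levels) < 2:
        raise DataError("need at least 2 genotype levels")
    if reference not in set(levels):
        raise DataError(f"reference level {reference!r} absent from data")
    n_blocks = df["block"].nunique()

    fixed = f"Q('{spec.trait}') ~ C(genotype, Treatment('{reference}'))"
    if spec.family == "gaussian-mixed":
        if n_blocks >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = smf.mixedlm(fixed, df, groups=df["block"]).fit(reml=True)
            converged = bool(res.converged)
            block_var = float(np.asarray(res.cov_re)[0, 0])
            resid_var = float(res.scale)
        else:
            warnings.warn(
                "fewer than 2 blocks: degrading to fixed-effects model", stacklevel=2
            )
            res = smf.ols(fixed, df).fit()
            converged = True
            block_var = 0.0
            resid_var = float(res.scale)
        params, bse, pvals = res.params, res.bse, res.pvalues
        coef = pd.Series(
            {_level_from_term(t): params[t] for t in params.index if "[T." in t}
        )
        se = pd.Series({_level_from_term(t): bse[t] for t in bse.index if "[T." in t})
        pv = pd.Series(
            {_level_from_term(t): pvals[t] for t in pvals.index if "[T." in t}
        )
        intercept = float(params["Intercept"])
        ls_means = pd.Series(
            {reference: intercept, **{lv: intercept + coef[lv] for lv in coef.index}}
        )
        diagnostics = {
            "method": "MixedLM-REML" if n_blocks >= 2 else "OLS",
            "df_resid": float(res.df_resid),
        }
    else:
        family = (
            sm.families.Poisson()
            if spec.family == "poisson-log"
            else sm.families.Gamma(link=sm.families.links.Log())
        )
        formula = fixed + (" + C(block)" if n_blocks >= 2 else "")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.glm(formula, df, family=family).fit()
        converged = bool(res.converged)
        block_var = float("nan")
        resid_var = float(res.scale)
        params, bse, pvals = res.params, res.bse, res.pvalues
        geno_terms = [t for t in params.index if "genotype" in t and "[T." in t]
        coef = pd.Series({_level_from_term(t): params[t] for t in geno_terms})
        se = pd.Series({_level_from_term(t): bse[t] for t in geno_terms})
        pv = pd.Series({_level_from_term(t): pvals[t] for t in geno_terms})
        # LS-mean on the response scale, averaged over observed block levels.
        blocks = sorted(df["block"].unique())
        grid = pd.DataFrame(
            [(g, b) for g in levels for b in blocks], columns=["genotype", "block"]
        )
        grid[spec.trait] = 0.0
        pred = res.predict(grid)
        grid["_mu"] = np.asarray(pred)
        ls_means = grid.groupby("genotype")["_mu"].mean()
        ls_means = pd.Series(ls_means.to_dict())
        diagnostics = {"method": f"GLM-{spec.family}"}
    if not converged:
        diagnostics["warning"] = "model did not converge; estimates are unreliable"

    return TraitModelFit(
        spec=spec,
        reference=reference,
        ls_means=ls_means,
        block_var=block_var,
        resid_var=resid_var,
        converged=converged,
        n_obs=len(df),
        n_blocks=n_blocks,
        diagnostics=diagnostics,
        _coef=coef,
        _bse=se,
        _pvalues=pv,
    )


def contrast_lines_vs_wt(
    fit: TraitModelFit,
    alpha: float | None = None,
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """One contrast per line vs the reference (wild-type) level.

    Direction is ``higher``/``lower`` when the Wald p-value is below
    ``alpha``, else ``ns``.  Contrasting the reference with itself yields a
    zero difference with p = 1 by convention.
    """
    alpha = fit.spec.alpha if alpha is None else alpha
    if levels is None:
        levels = [lv for lv in fit.ls_means.index if lv != fit.reference]
    wt_mean = float(fit.ls_means[fit.reference])
    rows = []
    for lv in levels:
        if lv == fit.reference:
            rows.append(
                ContrastResult(lv, fit.spec.trait, wt_mean, wt_mean, 0.0, 1.0, "ns")
            )
            continue
        if lv not in fit.ls_means.index:
            raise DataError(f"unknown genotype level {lv!r}")
        diff = float(fit.ls_means[lv]) - wt_mean
        p = float(fit._pvalues[lv])
        if p < alpha:
            direction = "higher" if diff > 0 else "lower"
        else:
            direction = "ns"
        rows.append(
            ContrastResult(
                lv, fit.spec.trait, float(fit.ls_means[lv]), wt_mean, diff, p, direction
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def variance_component_intervals(fit: TraitModelFit, level: float = 0.95) -> dict:
    """Approximate confidence intervals for the variance components.

    The residual variance gets an exact chi-square interval on its degrees
    of freedom.  The block variance uses a chi-square interval for the
    block-mean variance (df = n_blocks - 1) with the residual contribution
    subtracted; lower bounds are clipped at zero.  Only defined for the
    gaussian-mixed family.
    """
    if fit.spec.family != "gaussian-mixed":
        raise DataError("variance intervals are defined for the gaussian-mixed family")
    a = 1.0 - level
    df_resid = float(fit.diagnostics.get("df_resid", fit.n_obs - 1))
    r_lo = df_resid * fit.resid_var / scipy.stats.chi2.ppf(1 - a / 2, df_resid)
    r_hi = df_resid * fit.resid_var / scipy.stats.chi2.ppf(a / 2, df_resid)
    out = {"resid_var": (r_lo, r_hi)}
    if fit.n_blocks >= 2:
        m = fit.n_obs / fit.n_blocks  # mean plots per block
        v = fit.block_var + fit.resid_var / m
        dfb = fit.n_blocks - 1
        b_lo = max(0.0, dfb * v / scipy.stats.chi2.ppf(1 - a / 2, dfb) - fit.resid_var / m)
        b_hi = max(0.0, dfb * v / scipy.stats.chi2.ppf(a / 2, dfb) - fit.resid_var / m)
        out["block_var"] = (b_lo, b_hi)
    return out


def _validate_counts(table: np.ndarray) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise DataError("counts must be non-negative integers")
    return arr.astype(np.int64)


def fisher_reversion_test(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Two-sided by the point-probability method: the p-value sums the
    probabilities of all tables (same margins) no more likely than the
    observed one.
    """
    arr = _validate_counts(table)
    return float(scipy.stats.fisher_exact(arr, alternative="two-sided")[1])


def fisher_pvalues_for_margins(row1_total: int, col1_total: int, total: int) -> np.ndarray:
    """Two-sided Fisher p-values for every table with the given margins.

    Returns p[a] for a = 0..min(row1_total, col1_total), where ``a`` is the
    top-left cell.  Vectorized over the hypergeometric support; used for
    exhaustive sweeps where per-table calls would be too slow.
    """
    r, c, n = int(row1_total), int(col1_total), int(total)
    if not (0 <= r <= n and 0 <= c <= n):
        raise DataError("margins must satisfy 0 <= row1, col1 <= total")
    lo, hi = max(0, r + c - n), min(r, c)
    support = np.arange(lo, hi + 1)
    pmf = scipy.stats.hypergeom.pmf(support, n, r, c)
    # p[a] = sum of pmf over tables no more probable than a (relative slack
    # for float ties, as in the standard implementations)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    pos = np.searchsorted(pmf[order], pmf * (1.0 + 1e-7), side="right")
    out = np.full(min(r, c) + 1, np.nan)
    out[lo : hi + 1] = np.minimum(csum[pos - 1], 1.0)
    return out


def reversion_frequency(n_revertants: int, n_total: int, ndigits: int | None = None) -> float:
    """Percent revertants: 100 * k / n, optionally rounded half-up."""
    if n_total <= 0:
        raise DataError("n_total must be positive")
    if not 0 <= n_revertants <= n_total:
        raise DataError("need 0 <= n_revertants <= n_total")
    pct = 100.0 * n_revertants / n_total
    return round_half_up(pct, ndigits) if ndigits is not None else pct


def standardize_yield(raw_weight_kg, moisture_g_per_kg, plot_area_m2, target_moisture: float = 140.0):
    """Plot yield in kg/ha standardized to a reference grain moisture.

    Dry matter is preserved: ``raw * (1000 - moisture) / (1000 - target)``
    then scaled from the plot area to one hectare.  Accepts scalars or
    arrays.
    """
    moisture = np.asarray(moisture_g_per_kg, dtype=float)
    area = np.asarray(plot_area_m2, dtype=float)
    raw = np.asarray(raw_weight_kg, dtype=float)
    if np.any(moisture >= 1000) or np.any(moisture < 0):
        raise DataError("moisture must be in [0, 1000) g/kg")
    if np.any(area <= 0):
        raise DataError("plot area must be positive")
    out = raw * (1000.0 - moisture) / (1000.0 - target_moisture) * (10_000.0 / area)
    return float(out) if out.ndim == 0 else out
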