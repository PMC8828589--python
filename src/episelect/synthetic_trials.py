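"""Synthetic field-trial generator.

Emulates the statistical structure the downstream analysis assumes: an
augmented incomplete-block single-location trial at the plant level
(epi-F2-style), a two-location lattice trial at the plot level
(epi-F3-style) with category effects and line-specific GxE sensitivity, a
cold-vs-standard emergence experiment, and revertant counts.  Everything is
deterministic given the root seed; each operation draws from its own
derived stream.

Generative model
----------------
Per-line epi effects follow a three-component mixture (up / null / down)
constant across plants within a line.  Plant yield is

    yield = env_mean + epi_effect + line_effect + block_effect + residual

with Gaussian line/block/residual components.  Tiller counts come from a
Gaussian copula shared with the yield residual: the latent correlation is
inflated analytically so that the *observed* plant-level tiller-yield
correlation matches the requested target despite count discretization and
between-line variance.  Low-input GxE is a line-specific multiplicative
sensitivity applied in the lowest-mean environment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from ._util import (
    STREAM_EMERGENCE,
    STREAM_F2,
    STREAM_F3,
    STREAM_REVERSION,
    ParameterError,
    stream,
)
from .emergence_analysis import DEFAULT_DAY_GRID, EmergenceSeries
from .selection_engine import COMBINED_CATEGORIES, CategoryLabel

PLANT_COLUMNS = [
    "line_id", "family_id", "cohort", "environment_id", "replication", "block",
    "yield_g", "height_cm", "tiller_count", "days_to_flowering", "revertant",
]
PLOT_COLUMNS = [
    "line_id", "cohort", "environment_id", "replication", "block",
    "raw_grain_weight", "moisture_g_per_kg", "plot_area_m2", "yield_kg_ha_std",
]

MOISTURE_TARGET = 140.0
PLOT_AREA_M2 = 10.0


@dataclass(frozen=True)
class EpiMixture:
    """Three-component per-line epi-effect mixture (trait units)."""

    fraction_up: float
    fraction_down: float
    fraction_null: float
    mean_up: float = 0.0
    mean_down: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.fraction_up, self.fraction_down, self.fraction_null)
        if any(f < 0 for f in fracs):
            raise ParameterError("mixture fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ParameterError(f"mixture fractions must sum to 1, got {sum(fracs)}")
        if self.mean_up < 0 or self.mean_down < 0:
            raise ParameterError("mixture effect magnitudes must be non-negative")

    def moments(self) -> tuple[float, float]:
        """(mean, variance) of the line epi effect."""
        m = self.fraction_up * self.mean_up - self.fraction_down * self.mean_down
        m2 = self.fraction_up * self.mean_up**2 + self.fraction_down * self.mean_down**2
        return m, m2 - m * m


NULL_MIXTURE = EpiMixture(0.0, 0.0, 1.0)


@dataclass(frozen=True)
class SimParams:
    """Variance components and design counts for the generators."""

    wt_mean_by_env: dict
    line_var: float = 0.0
    block_var: float = 0.0
    resid_var: float = 1.0
    epi_mixture: EpiMixture = NULL_MIXTURE
    gxe_scale: float = 0.0
    tiller_yield_rho: float = 0.52
    tiller_mean: float = 3.0
    tiller_effect_logfc: float = 0.0  # log-scale tiller shift for up/down lines
    reversion_rate: float = 0.0015
    n_epi_lines: int = 100
    n_wt_lines: int = 19
    plants_or_plots_per_line_per_rep: int = 15
    n_reps_by_env: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.wt_mean_by_env:
            raise ParameterError("wt_mean_by_env must name at least one environment")
        for name, value in (("line_var", self.line_var), ("block_var", self.block_var),
                            ("resid_var", self.resid_var)):
            if value < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not -1.0 <= self.tiller_yield_rho <= 1.0:
            raise ParameterError("tiller_yield_rho must be in [-1, 1]")
        if not 0.0 <= self.reversion_rate <= 1.0:
            raise ParameterError("reversion_rate must be in [0, 1]")
        if self.gxe_scale < 0:
            raise ParameterError("gxe_scale must be >= 0")
        if self.tiller_mean <= 0:
            raise ParameterError("tiller_mean must be positive")
        for name, value in (("n_epi_lines", self.n_epi_lines),
                            ("n_wt_lines", self.n_wt_lines),
                            ("plants_or_plots_per_line_per_rep",
                             self.plants_or_plots_per_line_per_rep)):
            if value < 1:
                raise ParameterError(f"{name} must be >= 1")
        reps = self.n_reps_by_env or {env: 1 for env in self.wt_mean_by_env}
        object.__setattr__(self, "n_reps_by_env", dict(reps))
        unknown = set(self.n_reps_by_env) - set(self.wt_mean_by_env)
        if unknown:
            raise ParameterError(f"n_reps_by_env names unknown environment(s): {sorted(unknown)}")
        if any(r < 1 for r in self.n_reps_by_env.values()):
            raise ParameterError("replication counts must be >= 1")


def _count_corr_moment(lam: float) -> float:
    """E[z * T(z)] for z ~ N(0,1), T the Poisson(lam) quantile transform.

    Measures how much latent-Gaussian correlation survives discretization to
    counts; computed by dense quadrature.
    """
    z = np.linspace(-8.0, 8.0, 4001)
    t = scipy.stats.poisson.ppf(scipy.stats.norm.cdf(z), lam)
    w = scipy.stats.norm.pdf(z)
    return float(np.trapezoid(z * t * w, z))


def _latent_rho(params: SimParams) -> float:
    """Latent residual-level correlation needed so that the observed
    plant-level tiller-yield correlation hits the target.

    Solves  rho_target * sd_y * sd_t = cov_between(epi, lambda)
                                       + sqrt(resid_var) * r * E[z T(z)]
    and clips r into (-1, 1) with a warning when the target is unreachable.
    """
    mix = params.epi_mixture
    e_mean, e_var = mix.moments()
    sd_y = math.sqrt(e_var + params.line_var + params.block_var + params.resid_var)
    lam0 = params.tiller_mean
    s = params.tiller_effect_logfc
    # lambda per mixture component
    lam_up, lam_dn = lam0 * math.exp(s), lam0 * math.exp(-s)
    probs = np.array([mix.fraction_up, mix.fraction_down, mix.fraction_null])
    lams = np.array([lam_up, lam_dn, lam0])
    effs = np.array([mix.mean_up, -mix.mean_down, 0.0])
    e_lam = float(probs @ lams)
    var_lam = float(probs @ (lams - e_lam) ** 2)
    cov_between = float(probs @ (effs * lams)) - e_mean * e_lam
    sd_t = math.sqrt(e_lam + var_lam)
    if sd_y == 0 or sd_t == 0:
        return 0.0
    target_cov = params.tiller_yield_rho * sd_y * sd_t
    within = target_cov - cov_between
    denom = math.sqrt(params.resid_var) * _count_corr_moment(e_lam)
    if denom == 0:
        if abs(within) > 1e-12:
            warnings.warn("zero residual variance: tiller-yield correlation target unreachable",
                          stacklevel=2)
        return 0.0
    r = within / denom
    if abs(r) > 0.999:
        warnings.warn(f"tiller-yield correlation target requires latent r={r:.3f}; clipping",
                      stacklevel=2)
        r = math.copysign(0.999, r)
    return r


def _draw_epi_effects(mix: EpiMixture, n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[mix.fraction_up, mix.fraction_down, mix.fraction_null])
    return np.where(comp == 0, mix.mean_up, np.where(comp == 1, -mix.mean_down, 0.0))


def simulate_epiF2_trial(params: SimParams, block_size: int = 10) -> pd.DataFrame:
    """Plant-level single-location trial with wild-type checks in every block.

    Returns one row per plant with the PlantRecord columns.  The trial is run
    in the first environment of ``wt_mean_by_env``; each epi family appears
    once per replication, grouped into incomplete blocks of ``block_size``
    families plus one wild-type check entry.
    """
    rng = stream(params.seed, STREAM_F2)
    env = next(iter(params.wt_mean_by_env))
    env_mean = float(params.wt_mean_by_env[env])
    n_reps = params.n_reps_by_env[env]
    n_plants = params.plants_or_plots_per_line_per_rep

    lines = [f"EP{i + 1:03d}" for i in range(params.n_epi_lines)]
    epi_effect = dict(zip(lines, _draw_epi_effects(params.epi_mixture, len(lines), rng)))
    line_re = dict(zip(lines, rng.normal(0.0, math.sqrt(params.line_var), len(lines))))
    # modest line-to-line spread in the side traits, independent of yield
    height_line = dict(zip(lines, rng.normal(0.0, 6.0, len(lines))))
    flower_line = dict(zip(lines, rng.normal(0.0, 0.04, len(lines))))
    for wt in ("WT",):
        epi_effect[wt] = 0.0
        line_re[wt] = 0.0
        height_line[wt] = 0.0
        flower_line[wt] = 0.0

    s = params.tiller_effect_logfc
    lam_of = {
        line: params.tiller_mean
        * math.exp(s if epi_effect[line] > 0 else (-s if epi_effect[line] < 0 else 0.0))
        for line in epi_effect
    }
    r = _latent_rho(params)
    sd_resid = math.sqrt(params.resid_var)

    rows = []
    for rep in range(1, n_reps + 1):
        order = list(lines)
        rng.shuffle(order)
        n_blocks = math.ceil(len(order) / block_size)
        for b in range(n_blocks):
            members = order[b * block_size : (b + 1) * block_size] + ["WT"]
            block_id = f"{env}-r{rep}-b{b + 1:02d}"
            block_eff = rng.normal(0.0, math.sqrt(params.block_var))
            for line in members:
                z1 = rng.standard_normal(n_plants)
                z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_plants)
                yields = np.maximum(
                    0.0,
                    env_mean + epi_effect[line] + line_re[line] + block_eff + sd_resid * z1,
                )
                tillers = scipy.stats.poisson.ppf(
                    scipy.stats.norm.cdf(z2), lam_of[line]
                ).astype(int)
                heights = np.maximum(
                    0.0, 120.0 + height_line[line] + rng.normal(0.0, 8.0, n_plants)
                )
                mean_dtf = 70.0 * math.exp(flower_line[line])
                shape = 60.0
                dtf = np.maximum(
                    1, np.round(rng.gamma(shape, mean_dtf / shape, n_plants))
                ).astype(int)
                revert = rng.random(n_plants) < params.reversion_rate
                cohort = "WT" if line == "WT" else "epiF2"
                for j in range(n_plants):
                    rows.append(
                        (line, line, cohort, env, rep, block_id,
                         float(yields[j]), float(heights[j]), int(tillers[j]),
                         int(dtf[j]), bool(revert[j]))
                    )
    return pd.DataFrame(rows, columns=PLANT_COLUMNS)


def default_category_assignment(params: SimParams) -> dict[str, CategoryLabel]:
    """Cycle the nine combined categories over the epi-F3 line ids."""
    return {
        f"F3-{i + 1:03d}": CategoryLabel.parse(COMBINED_CATEGORIES[i % len(COMBINED_CATEGORIES)])
        for i in range(params.n_epi_lines)
    }


def simulate_epiF3_multienv_trial(
    params: SimParams,
    category_effects: dict | None = None,
    category_of_line: dict[str, CategoryLabel] | None = None,
    block_size: int = 13,
) -> pd.DataFrame:
    """Plot-level multi-location lattice trial with category effects and GxE.

    ``category_effects`` maps a category label to a fractional yield shift,
    either a scalar (all environments) or a per-environment mapping whose
    keys must be known environments.  Line-specific GxE sensitivity scaled
    by ``gxe_scale`` is applied multiplicatively to epi lines in the
    environment with the lowest wild-type mean.
    """
    rng = stream(params.seed, STREAM_F3)
    envs = list(params.wt_mean_by_env)
    low_env = min(envs, key=lambda e: params.wt_mean_by_env[e]) if len(envs) > 1 else None

    effects: dict[str, dict[str, float]] = {}
    for key, val in (category_effects or {}).items():
        label = key.render() if isinstance(key, CategoryLabel) else str(key)
        if label not in COMBINED_CATEGORIES and label not in ("LL", "ML", "HL"):
            raise ParameterError(f"unknown category label {label!r}")
        if isinstance(val, dict):
            unknown = set(val) - set(envs)
            if unknown:
                raise ParameterError(f"unknown environment id(s) in category_effects: {sorted(unknown)}")
            effects[label] = {str(e): float(v) for e, v in val.items()}
        else:
            effects[label] = {e: float(val) for e in envs}

    cats = category_of_line or default_category_assignment(params)
    cats = {str(k): (v if isinstance(v, CategoryLabel) else CategoryLabel.parse(str(v)))
            for k, v in cats.items()}
    epi_lines = sorted(cats)
    wt_lines = [f"WT-{i + 1:02d}" for i in range(params.n_wt_lines)]

    line_re = dict(zip(epi_lines + wt_lines,
                       rng.normal(0.0, math.sqrt(params.line_var), len(epi_lines) + len(wt_lines))))
    sens = {line: max(0.0, 1.0 + params.gxe_scale * g)
            for line, g in zip(epi_lines, rng.standard_normal(len(epi_lines)))}

    rows = []
    for env in envs:
        wt_mean = float(params.wt_mean_by_env[env])
        for rep in range(1, params.n_reps_by_env[env] + 1):
            order = epi_lines + wt_lines
            rng.shuffle(order)
            n_blocks = math.ceil(len(order) / block_size)
            block_effs = rng.normal(0.0, math.sqrt(params.block_var), n_blocks)
            for b in range(n_blocks):
                members = order[b * block_size : (b + 1) * block_size]
                block_id = f"{env}-r{rep}-b{b + 1:02d}"
                wt_set = set(wt_lines)
                for line in members:
                    is_wt = line in wt_set
                    if is_wt:
                        base = wt_mean + line_re[line]
                    else:
                        label = cats[line]
                        frac = 0.0
                        for key in (label.render(), f"{label.line_class}L"):
                            if key in effects:
                                frac = effects[key].get(env, 0.0)
                                break
                        base = wt_mean * (1.0 + frac) + line_re[line]
                        if env == low_env:
                            base *= sens[line]
                    for _ in range(params.plants_or_plots_per_line_per_rep):
                        value = max(
                            0.0,
                            base + block_effs[b] + rng.normal(0.0, math.sqrt(params.resid_var)),
                        )
                        moisture = float(np.clip(rng.normal(MOISTURE_TARGET, 15.0), 60.0, 300.0))
                        raw = value * (1000.0 - MOISTURE_TARGET) / (1000.0 - moisture) \
                            * PLOT_AREA_M2 / 10_000.0
                        rows.append(
                            (line, "WT" if is_wt else "epiF3", env, rep, block_id,
                             raw, moisture, PLOT_AREA_M2, value)
                        )
    return pd.DataFrame(rows, columns=PLOT_COLUMNS)


def simulate_emergence(
    params: SimParams,
    stress_delay_by_line: dict[str, float],
    days: tuple = DEFAULT_DAY_GRID,
    final_count: int = 30,
    t50: float = 6.0,
    spread: float = 1.5,
) -> list[EmergenceSeries]:
    """Early (cold) and standard cumulative emergence series per line.

    Emergence follows a logistic time course reaching ``final_count``;
    cold stress shifts the curve by the line's delay (infinite delay means
    no emergence at all).  Counts are rounded to whole plants, hence
    non-decreasing in day.
    """
    d = np.asarray(days, dtype=float)
    if d.size < 2 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
        raise ParameterError("days must be a strictly increasing positive sequence")

    def curve(delay: float) -> tuple:
        if math.isinf(delay):
            return tuple(int(0) for _ in d)
        frac = 1.0 / (1.0 + np.exp(-(d - t50 - delay) / spread))
        return tuple(int(c) for c in np.round(final_count * frac))

    out = []
    for line, delay in sorted(stress_delay_by_line.items()):
        if delay < 0:
            raise ParameterError(f"negative stress delay for line {line!r}")
        out.append(EmergenceSeries(str(line), "standard", tuple(int(x) for x in d), curve(0.0)))
        out.append(EmergenceSeries(str(line), "early", tuple(int(x) for x in d), curve(float(delay))))
    return out


def simulate_reversion_counts(n_plants: int, rate: float, seed: int) -> int:
    """Binomial(n_plants, rate) revertant count, deterministic given seed."""
    if n_plants < 1:
        raise ParameterError("n_plants must be >= 1")
    if not 0.0 <= rate <= 1.0:
        raise ParameterError("rate must be in [0, 1]")
    return int(stream(seed, STREAM_REVERSION).binomial(n_plants, rate))
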