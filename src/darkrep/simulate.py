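"""Synthetic transcriptome generator with planted light/dark/inhibitor structure.

The generator emulates the experimental design the analysis assumes: ~2,515
genes, two replicate experiments, samples at 0/30/60 minutes after a stimulus
added at time 0, under light, dark and inhibitor conditions.  Effects are
planted as per-gene fold-changes relative to the light time-0 state:

* a majority of genes (default 65 %) is dark-*repressed*, with heterogeneous
  per-gene depths rescaled so that the noise-free total mRNA pool under dark
  at 60 min hits the target ratio (default 0.50) exactly;
* a small subset (default 5 %) is dark-*induced* with fold-changes drawn
  log-uniformly from a configurable range; induced genes are planted with
  reduced light baselines (dark-induced genes are weakly expressed in
  light — and without this the pool target is arithmetically unreachable);
* inhibitors applied in the light reproduce the dark effect scaled by a
  per-gene concordance factor (stronger for DBMIB than DCMU);
* under dark+DBMIB a fixed fraction of the regulated genes (default 60 %)
  has its dark effect attenuated, with the attenuation strength solved so
  the noise-free 60-min pool hits its target ratio (default 0.80) exactly;
  dark+DBMIB+rifampicin carries the same planted effects with independent
  noise.

Noise is multiplicative log-normal, independent across genes and samples,
with unit mean.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import (
    DARK,
    DARK_DBMIB,
    DARK_DBMIB_RIF,
    DEFAULT_CONDITIONS,
    LIGHT,
    LIGHT_DBMIB,
    LIGHT_DCMU,
    SignalMatrix,
    make_sample_id,
)
from .errors import ConfigurationError

REPRESSED = "repressed"
INDUCED = "induced"
UNREGULATED = "unregulated"


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study design.

    Pool-ratio targets are exact constraints on the noise-free data; all
    other effect parameters are distributional.
    """

    n_genes: int = 2515
    n_experiments: int = 2
    time_points_min: tuple = (0, 30, 60)
    conditions: tuple = DEFAULT_CONDITIONS
    frac_induced: float = 0.05
    frac_repressed: float = 0.65
    frac_attenuated: float = 0.60
    pool_ratio_dark_60: float = 0.5
    pool_ratio_darkDBMIB_60: float = 0.8
    induction_fold_range: tuple = (2.0, 10.0)
    #: effect share retained by attenuated genes under dark+DBMIB;
    #: None = solve so the noise-free pool hits pool_ratio_darkDBMIB_60.
    attenuation_factor: float | None = None
    cv_noise: float = 0.1
    # light time-0 baseline intensities: log-normal across genes
    baseline_median: float = 100.0
    baseline_log_sd: float = 0.3
    #: per-experiment global scale spread (log-sd) of the raw intensities
    experiment_scale_log_sd: float = 0.2
    #: induced genes are weakly expressed in the light: their baseline is
    #: scaled by this factor (needed for the dark pool target to be
    #: reachable at all with folds of 2-10 on 5 % of genes)
    induced_baseline_scale: float = 0.35
    #: mean concordance of inhibitor-in-light effects with the dark effect
    dcmu_concordance: float = 0.8
    dbmib_concordance: float = 0.95
    concordance_concentration: float = 60.0
    #: fraction of the full (60-min) log-effect realised at 30 min is
    #: (30/60)**time_progress_exponent ~ 0.7 — most change happens early
    time_progress_exponent: float = 0.515
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_experiments < 1:
            raise ConfigurationError("n_experiments must be >= 1")
        if not (0 <= self.frac_induced <= 1 and 0 <= self.frac_repressed <= 1):
            raise ConfigurationError("frac_induced/frac_repressed must lie in [0, 1]")
        if self.frac_induced + self.frac_repressed > 1 + 1e-12:
            raise ConfigurationError("frac_induced + frac_repressed must be <= 1")
        if not (0 <= self.frac_attenuated <= 1):
            raise ConfigurationError("frac_attenuated must lie in [0, 1]")
        if 0 not in self.time_points_min:
            raise ConfigurationError("time_points_min must contain 0")
        if len(set(self.time_points_min)) != len(self.time_points_min):
            raise ConfigurationError("time_points_min contains duplicates")
        if LIGHT not in self.conditions:
            raise ConfigurationError("conditions must include the light control")
        for target in ("pool_ratio_dark_60", "pool_ratio_darkDBMIB_60",
                       "baseline_median", "induced_baseline_scale"):
            if getattr(self, target) <= 0:
                raise ConfigurationError(f"{target} must be strictly positive")
        if self.cv_noise < 0:
            raise ConfigurationError("cv_noise must be >= 0")
        lo, hi = self.induction_fold_range
        if not (0 < lo <= hi):
            raise ConfigurationError("induction_fold_range must be 0 < lo <= hi")
        if self.attenuation_factor is not None and not (
                0 <= self.attenuation_factor <= 1):
            raise ConfigurationError("attenuation_factor must lie in [0, 1]")
        if self.pool_ratio_darkDBMIB_60 < self.pool_ratio_dark_60:
            raise ConfigurationError(
                "pool_ratio_darkDBMIB_60 must be >= pool_ratio_dark_60")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown SyntheticSpec fields: {sorted(unknown)}")
        spec = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        spec.validate()
        return spec


@dataclass
class TruthTable:
    """Planted ground truth: per-gene class, per (gene, condition, time)
    noise-free fold-change relative to light time 0, and the dark+DBMIB
    attenuation membership."""

    classes: pd.Series
    fold: pd.DataFrame  # columns: MultiIndex (condition, time_min)
    attenuated: pd.Series

    def regulated_genes(self) -> pd.Index:
        return self.classes.index[self.classes != UNREGULATED]


@dataclass
class _EffectPlan:
    baselines: np.ndarray
    classes: np.ndarray
    logfold: dict          # condition -> (n_genes,) log fold at full progress
    attenuated: np.ndarray  # bool mask
    attenuation_phi: float | None


def _time_progress(t: float, t_max: float, gamma: float) -> float:
    if t == 0:
        return 0.0
    return (t / t_max) ** gamma


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _solve_repression_exponent(b, base_depth, rep_mask, other_pool, target_pool):
    """Exponent lam such that repressed folds (1-d0)**lam give the target
    noise-free pool exactly."""
    brep = b[rep_mask]
    surv = 1.0 - base_depth  # per-gene survival at lam=1

    def pool(lam):
        return other_pool + float(brep @ np.power(surv, lam))

    limit = other_pool  # lam -> inf
    if target_pool <= limit:
        raise ConfigurationError(
            "pool_ratio_dark_60 unreachable: even complete repression leaves "
            f"a pool of {limit:.3g} > target {target_pool:.3g}; lower "
            "frac_induced / induction folds or raise the target")
    hi = 1.0
    while pool(hi) > target_pool:
        hi *= 2.0
        if hi > 1e6:
            raise ConfigurationError("repression-depth solve failed to bracket")
    if pool(0.0) < target_pool:
        raise ConfigurationError(
            "pool_ratio_dark_60 above the unrepressed pool; nothing to solve")
    return brentq(lambda lam: pool(lam) - target_pool, 0.0, hi,
                  xtol=1e-13, rtol=8.9e-16)


def _select_attenuated(rng, b, fold60, reg_idx, k, need):
    """Choose k regulated genes whose complete de-repression restores at
    least `need` pool units; deterministic swaps fix random shortfalls."""
    gains = b * (1.0 - fold60)  # pool restored per gene at full attenuation
    subset = set(rng.choice(reg_idx, size=k, replace=False).tolist())
    rest = [g for g in reg_idx if g not in subset]
    total = sum(gains[g] for g in subset)
    if total >= need:
        return subset
    inside = sorted(subset, key=lambda g: gains[g])          # weakest first
    outside = sorted(rest, key=lambda g: gains[g], reverse=True)  # strongest first
    i = 0
    while total < need and i < min(len(inside), len(outside)):
        g_out, g_in = inside[i], outside[i]
        if gains[g_in] <= gains[g_out]:
            break
        subset.remove(g_out)
        subset.add(g_in)
        total += gains[g_in] - gains[g_out]
        i += 1
    if total < need - 1e-12:
        raise ConfigurationError(
            "pool_ratio_darkDBMIB_60 unreachable with frac_attenuated "
            f"{k}/{len(reg_idx)} regulated genes")
    return subset


def _plan(spec: SyntheticSpec, rng: np.random.Generator,
          solve_targets: bool = True) -> _EffectPlan:
    n = spec.n_genes
    sigma_b = spec.baseline_log_sd
    b = spec.baseline_median * np.exp(rng.normal(0.0, sigma_b, size=n))

    n_ind = int(round(spec.frac_induced * n))
    n_rep = int(round(spec.frac_repressed * n))
    n_rep = min(n_rep, n - n_ind)

    classes = np.full(n, UNREGULATED, dtype=object)
    induced_idx = (rng.choice(n, size=n_ind, replace=False)
                   if n_ind else np.empty(0, dtype=int))
    classes[induced_idx] = INDUCED
    b[induced_idx] *= spec.induced_baseline_scale
    remaining = np.setdiff1d(np.arange(n), induced_idx)
    repressed_idx = (rng.choice(remaining, size=n_rep, replace=False)
                     if n_rep else np.empty(0, dtype=int))
    classes[repressed_idx] = REPRESSED

    rep_mask = classes == REPRESSED
    ind_mask = classes == INDUCED

    # per-gene base repression depths in [0.5, 0.85]; rescaled by the solve
    base_depth = 0.5 + 0.35 * rng.beta(2.0, 2.0, size=int(rep_mask.sum()))
    lo, hi = spec.induction_fold_range
    ind_fold = np.exp(rng.uniform(np.log(lo), np.log(hi), size=int(ind_mask.sum())))

    total = float(b.sum())
    logfold_dark = np.zeros(n)
    if rep_mask.any():
        other_pool = float(b[~rep_mask].sum()
                           - b[ind_mask].sum() + b[ind_mask] @ ind_fold)
        if solve_targets:
            lam = _solve_repression_exponent(
                b, base_depth, rep_mask, other_pool,
                spec.pool_ratio_dark_60 * total)
        else:
            lam = 1.0
        logfold_dark[rep_mask] = lam * np.log1p(-base_depth)
    elif ind_mask.any() and solve_targets and spec.pool_ratio_dark_60 < 1.0:
        raise ConfigurationError(
            "pool_ratio_dark_60 < 1 requires repressed genes (frac_repressed > 0)")
    logfold_dark[ind_mask] = np.log(ind_fold)

    reg_mask = rep_mask | ind_mask
    n_reg = int(reg_mask.sum())

    kd_a, kd_b = _beta_params(spec.dcmu_concordance, spec.concordance_concentration)
    kb_a, kb_b = _beta_params(spec.dbmib_concordance, spec.concordance_concentration)
    kappa_dcmu = rng.beta(kd_a, kd_b, size=n)
    kappa_dbmib = rng.beta(kb_a, kb_b, size=n)

    attenuated = np.zeros(n, dtype=bool)
    att_logfold = logfold_dark.copy()
    phi: float | None = None
    if n_reg and (DARK_DBMIB in spec.conditions or DARK_DBMIB_RIF in spec.conditions):
        reg_idx = np.flatnonzero(reg_mask)
        k = int(round(spec.frac_attenuated * n_reg))
        fold60 = np.exp(logfold_dark)
        if spec.attenuation_factor is not None or not solve_targets:
            phi = spec.attenuation_factor if spec.attenuation_factor is not None else 1.0
            subset = set(rng.choice(reg_idx, size=k, replace=False).tolist()) if k else set()
        else:
            dark_pool = float(b @ fold60)
            need = spec.pool_ratio_darkDBMIB_60 * total - dark_pool
            subset = _select_attenuated(rng, b, fold60, reg_idx, k, max(need, 0.0))

            sub = np.fromiter(sorted(subset), dtype=int) if subset else np.empty(0, int)
            fixed = dark_pool - float(b[sub] @ fold60[sub])

            def pool(p):
                return fixed + float(b[sub] @ np.exp(p * logfold_dark[sub]))

            target = spec.pool_ratio_darkDBMIB_60 * total
            if abs(pool(1.0) - target) < 1e-9 * total or not len(sub):
                phi = 1.0
            else:
                phi = brentq(lambda p: pool(p) - target, 0.0, 1.0,
                             xtol=1e-15, rtol=8.9e-16)
        sub_arr = np.fromiter(sorted(subset), dtype=int) if subset else np.empty(0, int)
        att_logfold[sub_arr] = phi * logfold_dark[sub_arr]
        if phi < 1.0:
            attenuated[sub_arr] = True

    logfold = {LIGHT: np.zeros(n)}
    for cond in spec.conditions:
        if cond == LIGHT:
            continue
        if cond == DARK:
            logfold[cond] = logfold_dark
        elif cond == LIGHT_DCMU:
            logfold[cond] = kappa_dcmu * logfold_dark
        elif cond == LIGHT_DBMIB:
            logfold[cond] = kappa_dbmib * logfold_dark
        elif cond in (DARK_DBMIB, DARK_DBMIB_RIF):
            logfold[cond] = att_logfold
        else:
            raise ConfigurationError(f"unknown condition label {cond!r}")

    return _EffectPlan(baselines=b, classes=classes, logfold=logfold,
                       attenuated=attenuated, attenuation_phi=phi)


def _fold_table(spec: SyntheticSpec, plan: _EffectPlan, genes: pd.Index) -> pd.DataFrame:
    t_max = max(spec.time_points_min)
    cols = pd.MultiIndex.from_product(
        [list(spec.conditions), list(spec.time_points_min)],
        names=["condition", "time_min"])
    data = np.empty((spec.n_genes, len(cols)))
    for j, (cond, t) in enumerate(cols):
        p = _time_progress(t, t_max, spec.time_progress_exponent)
        data[:, j] = np.exp(plan.logfold[cond] * p)
    return pd.DataFrame(data, index=genes, columns=cols)


def generate_dataset(spec: SyntheticSpec) -> tuple[SignalMatrix, TruthTable]:
    """Generate one synthetic dataset plus its ground truth.

    Deterministic for a fixed spec and seed.  The noise-free (cv_noise=0)
    dark 60-min pool equals ``pool_ratio_dark_60`` times the light pool to
    within solver precision, and likewise for dark+DBMIB.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plan = _plan(spec, rng)

    width = len(str(spec.n_genes))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(1, spec.n_genes + 1)],
                     name="gene")
    fold = _fold_table(spec, plan, genes)

    sigma = float(np.sqrt(np.log1p(spec.cv_noise ** 2)))
    experiments = list(range(1, spec.n_experiments + 1))
    scales = {n: float(np.exp(rng.normal(0.0, spec.experiment_scale_log_sd)))
              for n in experiments}

    columns, meta_rows = [], []
    values = {}
    for n in experiments:
        for cond in spec.conditions:
            for t in spec.time_points_min:
                sid = make_sample_id(cond, t, n)
                noise = (np.exp(rng.normal(0.0, sigma, size=spec.n_genes)
                                - 0.5 * sigma ** 2)
                         if sigma > 0 else 1.0)
                values[sid] = (plan.baselines * fold[(cond, t)].to_numpy()
                               * scales[n] * noise)
                columns.append(sid)
                meta_rows.append((sid, cond, t, n))

    vdf = pd.DataFrame(values, index=genes, columns=columns)
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition",
                                            "time_min", "experiment"]
                        ).set_index("sample_id")
    truth = TruthTable(
        classes=pd.Series(plan.classes, index=genes, name="class"),
        fold=fold,
        attenuated=pd.Series(plan.attenuated, index=genes, name="attenuated"),
    )
    return SignalMatrix(vdf, meta), truth


def null_dataset(spec: SyntheticSpec) -> tuple[SignalMatrix, TruthTable]:
    """Same sampling scheme with no planted effects (noise only); used for
    FDR calibration."""
    null_spec = dataclasses.replace(spec, frac_induced=0.0, frac_repressed=0.0)
    return generate_dataset(null_spec)
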