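"""Modified Dunnett multiple-comparison test with Monte-Carlo permutation FDR.

For gene g and contrast (condition c, time t) the statistic is

    score = (|mean(dx_test) - mean(dx_ctrl)| - m) / (SE + t)

where dx_test are the replicate differences dx(g, c, t, n), dx_ctrl the
control replicates dx(g, l, t, n) at the same time, m >= 0 a minimal-
difference offset, t >= 0 an additive standard-error stabiliser, and SE the
Dunnett-style standard error of the mean difference, with the residual
variance pooled across the test and control groups of all the gene's
contrasts.  A contrast is *significant* when the score exceeds a fixed
critical cut (default sqrt(2)), i.e. when

    |mean difference| > m + critical * (SE + t);

a pure minimal-difference rule (critical = 0) is expressible but degenerate:
high-variance genes then keep large |differences| under permutation as well
and the estimated FDR acquires a floor, which defeats the FDR-constrained
parameter search.  A gene is *regulated* under condition c when at least one
of its time points is significant, with the direction taken from the sign of
the mean difference at the most significant time point.

The false discovery rate is estimated by Monte Carlo: replicate labels are
reassigned between the test and control groups of each contrast (the same
reassignment for every gene, preserving gene-gene correlation; independent
across contrasts), the score — including its pooled SE — is recomputed from
the reassigned groups, and

    FDR = mean over permutations of (#significant genes under permuted
          labels) / max(1, #significant genes observed).

Reassignments equivalent to the identity or to the full group swap are
excluded from the null space — they reproduce the observed groups exactly
and carry no information about the null.  With n experiments the space per
contrast has C(2n, n) - 2 elements; when the joint space over contrasts is
smaller than the requested number of permutations it is enumerated
exhaustively instead (with a :class:`CoarsePermutationWarning`).

``mul_opt`` performs the FDR-constrained grid search: among (m, t) pairs
whose estimated FDR is below the threshold it returns the one with the
maximal significant-gene count, ties broken toward larger m then larger t.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LIGHT, DiffMatrix
from .errors import (
    ConfigurationError,
    CoarsePermutationWarning,
    InsufficientReplicationError,
    NoFeasibleParametersError,
    StructuralError,
)

logger = logging.getLogger(__name__)

MIN_PERMUTATIONS = 100
DEFAULT_CRITICAL = float(np.sqrt(2.0))


@dataclass(frozen=True)
class MulcomParams:
    """Test parameters: offset m and stabiliser t (normalized signal units),
    the critical score cut, permutation count, FDR threshold, RNG seed."""

    m: float = 0.0
    t: float = 0.0
    critical: float = DEFAULT_CRITICAL
    n_permutations: int = 1000
    fdr_threshold: float = 0.003
    seed: int = 0

    def validate(self) -> None:
        if self.m < 0 or self.t < 0:
            raise ConfigurationError("m and t must be >= 0")
        if self.critical < 0:
            raise ConfigurationError("critical must be >= 0")
        if self.n_permutations < MIN_PERMUTATIONS:
            raise ConfigurationError(
                f"n_permutations must be >= {MIN_PERMUTATIONS}")
        if not (0 < self.fdr_threshold < 1):
            raise ConfigurationError("fdr_threshold must lie in (0, 1)")


def mulcom_score(dx_test, dx_ctrl, params: MulcomParams) -> float:
    """Standalone two-group score; the pooled SD uses the two groups given.

    With m = 0 and t = 0 this is the classic |pooled-variance two-sample t|.
    """
    a = np.asarray(dx_test, dtype=float)
    b = np.asarray(dx_ctrl, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicationError("need >= 2 replicates per group")
    diff = abs(a.mean() - b.mean())
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    s2 = ss / (a.size + b.size - 2)
    se = np.sqrt(s2 * (1.0 / a.size + 1.0 / b.size))
    return float((diff - params.m) / (se + params.t))


# ---------------------------------------------------------------------------
# contrast extraction


@dataclass
class _ContrastFrame:
    genes: pd.Index
    contrasts: list          # [(condition, time_min), ...] test cells
    test: np.ndarray         # (n_contrasts, n_genes, n_exp)
    ctrl: np.ndarray         # (n_contrasts, n_genes, n_exp)
    n_exp: int
    control_condition: str

    @property
    def dof(self) -> int:
        return 2 * len(self.contrasts) * (self.n_exp - 1)

    def pooled_se(self) -> np.ndarray:
        """Dunnett-style SE of a mean difference, residual variance pooled
        over the test and control groups of every contrast."""
        ss = (_group_ss(self.test) + _group_ss(self.ctrl)).sum(axis=0)
        return np.sqrt(ss / self.dof) * np.sqrt(2.0 / self.n_exp)

    def absdiff(self) -> np.ndarray:
        """(n_contrasts, n_genes) absolute mean differences."""
        return np.abs(self.test.mean(axis=2) - self.ctrl.mean(axis=2))


def _group_ss(arr: np.ndarray) -> np.ndarray:
    return ((arr - arr.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)


def _contrast_frame(dx: DiffMatrix, test_conditions, control_condition=LIGHT,
                    times=None) -> _ContrastFrame:
    experiments = dx.experiments
    n_exp = len(experiments)
    if n_exp < 2:
        raise InsufficientReplicationError(
            "the test needs >= 2 replicate experiments")
    if times is None:
        times = [t for t in dx.times if t != 0]
    contrasts = []
    test_stacks, ctrl_stacks = [], []
    cells = {}

    def cell(cond, t):
        key = (cond, t)
        if key not in cells:
            try:
                cols = [dx.sample_id(cond, t, n) for n in experiments]
            except KeyError:
                raise StructuralError(
                    f"missing sample ({cond!r}, t={t}) in some experiment"
                ) from None
            cells[key] = dx.values[cols].to_numpy()
        return cells[key]

    for cond in test_conditions:
        for t in times:
            contrasts.append((cond, t))
            test_stacks.append(cell(cond, t))
            ctrl_stacks.append(cell(control_condition, t))
    if not contrasts:
        raise StructuralError("no contrasts requested")

    return _ContrastFrame(
        genes=dx.genes, contrasts=contrasts,
        test=np.stack(test_stacks), ctrl=np.stack(ctrl_stacks),
        n_exp=n_exp, control_condition=control_condition)


def _significant(absdiff_max, se, params: MulcomParams) -> np.ndarray:
    """score > critical, vectorised over genes (and permutations)."""
    score = (absdiff_max - params.m) / (se + params.t)
    return score > params.critical


# ---------------------------------------------------------------------------
# permutation machinery


def _assignments(n_exp: int) -> list[tuple[int, ...]]:
    """Group reassignments of the pooled 2n replicate values, excluding the
    identity and the full swap."""
    idx = tuple(range(2 * n_exp))
    identity = tuple(range(n_exp))
    swap = tuple(range(n_exp, 2 * n_exp))
    return [a for a in itertools.combinations(idx, n_exp)
            if a != identity and a != swap]


@dataclass
class _PermCache:
    absdiff_max: np.ndarray  # (P, n_genes) max |mean difference| over contrasts
    se: np.ndarray           # (P, n_genes) pooled SE of the permuted groups
    exhaustive: bool
    n_permutations: int


def _perm_cache(cf: _ContrastFrame, params: MulcomParams) -> _PermCache:
    pooled = np.concatenate([cf.test, cf.ctrl], axis=2)  # (C, G, 2n)
    opts = _assignments(cf.n_exp)
    n_contrasts, n_genes = pooled.shape[0], pooled.shape[1]
    n_opt = len(opts)
    all_idx = set(range(2 * cf.n_exp))
    absopt = np.empty((n_contrasts, n_opt, n_genes))
    ssopt = np.empty((n_contrasts, n_opt, n_genes))
    for j, a in enumerate(opts):
        rest = sorted(all_idx - set(a))
        g1, g2 = pooled[:, :, list(a)], pooled[:, :, rest]
        absopt[:, j, :] = np.abs(g1.mean(axis=2) - g2.mean(axis=2))
        ssopt[:, j, :] = _group_ss(g1) + _group_ss(g2)

    space = n_opt ** n_contrasts
    if space <= params.n_permutations:
        warnings.warn(
            f"permutation space ({space}) smaller than requested "
            f"n_permutations ({params.n_permutations}); enumerating it "
            "exhaustively", CoarsePermutationWarning, stacklevel=3)
        combos = np.array(list(itertools.product(range(n_opt),
                                                 repeat=n_contrasts)))
        exhaustive = True
    else:
        rng = np.random.default_rng(params.seed)
        combos = rng.integers(0, n_opt, size=(params.n_permutations,
                                              n_contrasts))
        exhaustive = False

    A = np.zeros((combos.shape[0], n_genes))
    SS = np.zeros((combos.shape[0], n_genes))
    for c in range(n_contrasts):
        np.maximum(A, absopt[c, combos[:, c], :], out=A)
        SS += ssopt[c, combos[:, c], :]
    se = np.sqrt(SS / cf.dof) * np.sqrt(2.0 / cf.n_exp)
    return _PermCache(absdiff_max=A, se=se, exhaustive=exhaustive,
                      n_permutations=combos.shape[0])


@dataclass
class FdrEstimate:
    fdr: float
    n_significant: int
    perm_call_counts: np.ndarray
    exhaustive: bool
    params: MulcomParams

    @property
    def monte_carlo_se(self) -> float:
        """Standard deviation of the per-permutation call counts (the
        draw-level Monte-Carlo scale of the estimate)."""
        return float(self.perm_call_counts.std(ddof=1)) if len(
            self.perm_call_counts) > 1 else 0.0


def permutation_fdr(dx: DiffMatrix, params: MulcomParams,
                    test_conditions=("dark",), control_condition=LIGHT,
                    times=None) -> FdrEstimate:
    """Estimate the FDR of the gene-level calls at the given (m, t)."""
    params.validate()
    cf = _contrast_frame(dx, test_conditions, control_condition, times)
    n_sig = int(_significant(cf.absdiff().max(axis=0), cf.pooled_se(),
                             params).sum())
    cache = _perm_cache(cf, params)
    counts = _significant(cache.absdiff_max, cache.se, params).sum(axis=1)
    fdr = float(counts.mean() / max(1, n_sig))
    return FdrEstimate(fdr=fdr, n_significant=n_sig,
                       perm_call_counts=counts, exhaustive=cache.exhaustive,
                       params=params)


def mul_opt(dx: DiffMatrix, grid_m, grid_t, params: MulcomParams,
            test_conditions=("dark",), control_condition=LIGHT,
            times=None) -> MulcomParams:
    """FDR-constrained (m, t) search over the given grids.

    Equivalent to exhaustively calling :func:`permutation_fdr` at every grid
    point (the permutations are generated from the same seed, so the two
    routes agree bit for bit); among feasible points the significant-gene
    count is maximised, ties broken toward larger m then larger t.
    """
    params.validate()
    grid_m, grid_t = list(grid_m), list(grid_t)
    if not grid_m or not grid_t:
        raise ConfigurationError("grid_m and grid_t must be non-empty")
    cf = _contrast_frame(dx, test_conditions, control_condition, times)
    obs_stat = cf.absdiff().max(axis=0)
    obs_se = cf.pooled_se()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CoarsePermutationWarning)
        cache = _perm_cache(cf, params)
    best = None
    for m in grid_m:
        for t in grid_t:
            trial = dataclasses.replace(params, m=float(m), t=float(t))
            n_sig = int(_significant(obs_stat, obs_se, trial).sum())
            perm = _significant(cache.absdiff_max, cache.se, trial).sum(axis=1)
            fdr = float(perm.mean() / max(1, n_sig))
            if fdr >= params.fdr_threshold:
                continue
            key = (n_sig, m, t)
            if best is None or key > best:
                best = key
    if best is None:
        raise NoFeasibleParametersError(
            f"no (m, t) grid point reaches FDR < {params.fdr_threshold}")
    n_sig, m, t = best
    logger.info("mul_opt: m=%g t=%g -> %d significant genes", m, t, n_sig)
    return dataclasses.replace(params, m=float(m), t=float(t))


# ---------------------------------------------------------------------------
# gene-level calls


@dataclass
class MulcomResult:
    """Per-contrast scores and per-gene regulation calls.

    ``contrasts``: long table (gene, condition, time_min, mean_test,
    mean_ctrl, diff, se, score, significant).
    ``calls``: one row per gene x condition with ``regulated``, ``direction``
    ('up'/'down', defined only for regulated genes), ``best_time`` and
    ``best_score``.
    """

    contrasts: pd.DataFrame
    calls: pd.DataFrame
    params: MulcomParams
    control_condition: str

    def regulated(self, condition: str) -> pd.DataFrame:
        if condition not in set(self.calls["condition"]):
            raise KeyError(f"condition {condition!r} was not tested")
        return self.calls[(self.calls["condition"] == condition)
                          & self.calls["regulated"]]


def call_regulated(dx: DiffMatrix, conditions, params: MulcomParams,
                   control_condition=LIGHT, times=None) -> MulcomResult:
    """Score every (gene, condition, time) contrast and call a gene
    regulated under a condition when >= 1 time point is significant."""
    params.validate()
    conditions = list(conditions)
    cf = _contrast_frame(dx, conditions, control_condition, times)
    mean_test = cf.test.mean(axis=2)
    mean_ctrl = cf.ctrl.mean(axis=2)
    diff = mean_test - mean_ctrl
    se = cf.pooled_se()
    score = (np.abs(diff) - params.m) / (se[None, :] + params.t)
    significant = score > params.critical

    n_genes = len(cf.genes)
    rows = []
    for i, (cond, t) in enumerate(cf.contrasts):
        rows.append(pd.DataFrame({
            "gene": cf.genes, "condition": cond, "time_min": t,
            "mean_test": mean_test[i], "mean_ctrl": mean_ctrl[i],
            "diff": diff[i], "se": se, "score": score[i],
            "significant": significant[i]}))
    contrasts = pd.concat(rows, ignore_index=True)

    call_rows = []
    for cond in conditions:
        idx = [i for i, (c, _) in enumerate(cf.contrasts) if c == cond]
        sc = score[idx]           # (n_times, n_genes)
        sig = significant[idx]
        dfc = diff[idx]
        best = np.argmax(sc, axis=0)
        cols = np.arange(n_genes)
        regulated = sig.any(axis=0)
        best_diff = dfc[best, cols]
        direction = np.where(best_diff > 0, "up", "down")
        call_rows.append(pd.DataFrame({
            "gene": cf.genes, "condition": cond, "regulated": regulated,
            "direction": np.where(regulated, direction, None),
            "best_time": [cf.contrasts[idx[b]][1] for b in best],
            "best_score": sc[best, cols],
            "best_diff": best_diff,
            "best_ctrl_mean": mean_ctrl[idx][best, cols],
        }))
    calls = pd.concat(call_rows, ignore_index=True)
    return MulcomResult(contrasts=contrasts, calls=calls, params=params,
                        control_condition=control_condition)
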