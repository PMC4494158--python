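"""Expression-profile comparison: correlation-matrix PCA and induction-ratio
scatter correlations.

A *profile* is the vector of normalized expression over all genes for one
(condition, time), averaged over replicate experiments.  Profiles are the
entities being scored by the PCA; genes are the dimensions.  The PCA is an
eigendecomposition of the profile x profile Pearson correlation matrix:
scores are eigenvectors scaled by the square root of their eigenvalue, and
variance-explained fractions are eigenvalues over the trace.  The first
component separates illuminated from dark-acclimated profiles when the
planted dark structure dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LIGHT, SignalMatrix
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


def build_profiles(matrix: SignalMatrix, conditions=None, times=None) -> pd.DataFrame:
    """Gene x profile table, profiles keyed by (condition, time_min) and
    averaged over experiments."""
    conditions = list(conditions) if conditions is not None else matrix.conditions
    times = list(times) if times is not None else matrix.times
    cols = {}
    for cond in conditions:
        for t in times:
            reps = [matrix.column(cond, t, n).to_numpy()
                    for n in matrix.experiments if matrix.has_sample(cond, t, n)]
            if not reps:
                continue
            if len(reps) < len(matrix.experiments):
                logger.warning("profile (%s, t=%d) present in only %d/%d "
                               "experiments", cond, t, len(reps),
                               len(matrix.experiments))
            cols[(cond, t)] = np.mean(reps, axis=0)
    out = pd.DataFrame(cols, index=matrix.genes)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["condition", "time_min"])
    return out


def standard_profile_set(matrix: SignalMatrix, conditions=None) -> pd.DataFrame:
    """The profile set the PCA operates on: the light control at every time
    point plus each treated condition at the post-stimulus times only.

    The stimulus is added at time 0, so every condition's time-0 sample is
    the same light state; keeping one time-0 profile (light) avoids filling
    the light-like block with replicates of a single state.
    """
    conditions = list(conditions) if conditions is not None else matrix.conditions
    prof = build_profiles(matrix, conditions=conditions)
    keep = [(c, t) for c, t in prof.columns if c == LIGHT or t > 0]
    return prof[keep]


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of profile vectors."""
    if profiles.shape[1] < 2:
        raise DegenerateInputError("need at least two profiles")
    sd = profiles.std(axis=0, ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise DegenerateInputError(
            f"zero-variance profile(s): {list(zero.index)}")
    corr = np.corrcoef(profiles.to_numpy(), rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=profiles.columns, columns=profiles.columns)


@dataclass
class PCAResult:
    """Eigendecomposition of a correlation matrix.

    ``scores``: profile x component DataFrame, each column an eigenvector
    scaled by sqrt(eigenvalue); ``eigenvalues`` non-negative and
    non-increasing; ``variance_ratio`` sums to 1.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    variance_ratio: np.ndarray


def pca(corr: pd.DataFrame, reference=None) -> PCAResult:
    """PCA of a symmetric unit-diagonal correlation matrix.

    The sign of each component is fixed by requiring a non-negative loading
    for the reference profile (default: the light time-0 profile if present,
    else the first profile; if that loading is zero, the first profile with
    a nonzero loading).
    """
    mat = np.asarray(corr, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DegenerateInputError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise DegenerateInputError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise DegenerateInputError("correlation matrix diagonal is not 1")

    labels = list(corr.index) if isinstance(corr, pd.DataFrame) else list(
        range(mat.shape[0]))
    eigval, eigvec = np.linalg.eigh(mat)
    order = np.argsort(-eigval, kind="stable")
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)  # round-off can yield tiny negatives

    if reference is None:
        ref_idx = labels.index((LIGHT, 0)) if (LIGHT, 0) in labels else 0
    else:
        ref_idx = labels.index(reference)
    for j in range(eigvec.shape[1]):
        pivot = eigvec[ref_idx, j]
        if pivot == 0:
            nz = np.flatnonzero(eigvec[:, j])
            pivot = eigvec[nz[0], j] if len(nz) else 1.0
        if pivot < 0:
            eigvec[:, j] = -eigvec[:, j]

    scores = eigvec * np.sqrt(eigval)
    trace = float(np.trace(mat))
    comp_names = [f"PC{k + 1}" for k in range(len(eigval))]
    idx = corr.index if isinstance(corr, pd.DataFrame) else pd.RangeIndex(len(labels))
    return PCAResult(
        scores=pd.DataFrame(scores, index=idx, columns=comp_names),
        eigenvalues=eigval,
        variance_ratio=eigval / trace,
    )


def pc1_projection(result: PCAResult) -> pd.Series:
    """The PC1 score of each profile, in stable profile order."""
    return result.scores["PC1"].copy()


def induction_ratio_correlation(matrix: SignalMatrix, cond_a: str, cond_b: str,
                                time_min: int) -> float:
    """Pearson correlation of per-gene log2 induction ratios between two
    conditions at one time point.

    The induction ratio of gene g under condition c is
    x(g, c, t, n) / x(g, l, 0, n), averaged over experiments; genes with a
    zero reference in any experiment are excluded (count logged).
    """
    ratios = {}
    valid = np.ones(len(matrix.genes), dtype=bool)
    per_cond = {}
    for cond in (cond_a, cond_b):
        reps = []
        for n in matrix.experiments:
            ref = matrix.column(LIGHT, 0, n).to_numpy()
            num = matrix.column(cond, time_min, n).to_numpy()
            ok = ref > 0
            valid &= ok & (num > 0)  # log-ratio undefined at zero signal
            r = np.full(len(ref), np.nan)
            r[ok] = num[ok] / ref[ok]
            reps.append(r)
        per_cond[cond] = np.mean(reps, axis=0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("induction_ratio_correlation: %d gene(s) with zero "
                       "light time-0 reference excluded", n_excluded)
    ratios = {c: np.log2(per_cond[c][valid]) for c in (cond_a, cond_b)}
    return float(np.corrcoef(ratios[cond_a], ratios[cond_b])[0, 1])
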