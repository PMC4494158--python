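"""The normalization chain and derived quantities.

Three steps, applied in this fixed order on the linear scale:

1. **Total-signal normalization.**  For each experiment *n* a factor
   ``Y(n) = sum_g x(g, l, 0, n) / 1000`` rescales the experiment so that the
   total RNA signal of the light time-0 sample equals 1,000.
2. **Per-gene cross-experiment equalisation.**  ``Z(g, n) = x(g, l, 0, n) /
   mean_n x(g, l, 0, n)`` makes each gene's light time-0 value identical
   across experiments (equal to the cross-experiment mean).  Genes whose
   cross-experiment mean at light time 0 is zero are excluded with a logged
   warning.
3. **Differences.**  ``dx(g, c, t, n) = x(g, c, t, n) - x(g, l, 0, n)`` is
   the quantity the differential test operates on; it is exactly zero at
   (light, 0) by construction.

The *total mRNA pool* of a condition/time is the gene sum of the normalized
signals, reported per experiment and as the cross-experiment mean; the light
time-0 pool is 1,000 by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LIGHT, DiffMatrix, NormalizationFactors, SignalMatrix
from .errors import DegenerateInputError, StructuralError

logger = logging.getLogger(__name__)


def compute_total_factor(matrix: SignalMatrix, experiment: int) -> float:
    """Y(n) = (sum over genes of the light time-0 signal) / 1000."""
    try:
        col = matrix.column(LIGHT, 0, experiment)
    except KeyError:
        raise StructuralError(
            f"experiment {experiment} lacks a light time-0 sample") from None
    total = float(np.sum(col.to_numpy()))  # pairwise summation
    if total <= 0:
        raise DegenerateInputError(
            f"light time-0 total of experiment {experiment} is not positive")
    return total / 1000.0


def apply_total_normalization(matrix: SignalMatrix) -> SignalMatrix:
    """Divide every sample of experiment n by Y(n)."""
    out = matrix.values.copy()
    for n in matrix.experiments:
        y = compute_total_factor(matrix, n)
        cols = matrix.experiment_columns(n)
        out[cols] = out[cols] / y
    return SignalMatrix(out, matrix.samples.copy())


def compute_per_gene_factor(matrix: SignalMatrix) -> NormalizationFactors:
    """Z(g, n) = x(g, l, 0, n) / cross-experiment mean of x(g, l, 0, ·).

    Genes with a zero cross-experiment mean (or a zero value in any single
    experiment, which would make the factor zero) are flagged for exclusion.
    """
    experiments = matrix.experiments
    t0 = pd.DataFrame(
        {n: matrix.column(LIGHT, 0, n).to_numpy() for n in experiments},
        index=matrix.genes)
    mean = t0.mean(axis=1)
    bad = (t0 <= 0).any(axis=1) | (mean <= 0)
    excluded = list(matrix.genes[bad])
    if excluded:
        logger.warning(
            "%d gene(s) with zero light time-0 intensity excluded from "
            "per-gene normalization: %s%s", len(excluded),
            ", ".join(map(str, excluded[:5])), "..." if len(excluded) > 5 else "")
    z = t0.loc[~bad].div(mean.loc[~bad], axis=0)
    return NormalizationFactors(Z=z, excluded_genes=excluded)


def apply_per_gene_normalization(
        matrix: SignalMatrix,
        factors: NormalizationFactors | None = None) -> SignalMatrix:
    """Divide each gene's values in experiment n by Z(g, n); excluded genes
    are dropped from the output."""
    if factors is None:
        factors = compute_per_gene_factor(matrix)
    keep = factors.Z.index
    out = matrix.values.loc[keep].copy()
    for n in matrix.experiments:
        cols = matrix.experiment_columns(n)
        out[cols] = out[cols].div(factors.Z[n], axis=0)
    return SignalMatrix(out, matrix.samples.copy())


def normalize(matrix: SignalMatrix) -> tuple[SignalMatrix, NormalizationFactors]:
    """Full chain: Y then Z (fixed order).  Returns the normalized matrix and
    the factors (Y per experiment, Z per gene x experiment)."""
    y = pd.Series({n: compute_total_factor(matrix, n) for n in matrix.experiments},
                  name="Y")
    totaled = apply_total_normalization(matrix)
    factors = compute_per_gene_factor(totaled)
    factors.Y = y
    return apply_per_gene_normalization(totaled, factors), factors


def compute_dx(matrix: SignalMatrix) -> DiffMatrix:
    """dx(g, c, t, n) = x(g, c, t, n) - x(g, l, 0, n), per experiment."""
    out = matrix.values.copy()
    for n in matrix.experiments:
        try:
            ref = matrix.column(LIGHT, 0, n).to_numpy()
        except KeyError:
            raise StructuralError(
                f"experiment {n} lacks a light time-0 reference") from None
        cols = matrix.experiment_columns(n)
        out[cols] = out[cols].sub(ref, axis=0)
        out[matrix.sample_id(LIGHT, 0, n)] = 0.0  # exact, not just round-off
    return DiffMatrix(out, matrix.samples.copy())


@dataclass
class PoolEstimate:
    """Total mRNA pool of one (condition, time): per-experiment sums of the
    normalized signals plus their cross-experiment mean."""

    condition: str
    time_min: int
    per_experiment: pd.Series
    mean: float


def total_pool(matrix: SignalMatrix, condition: str, time_min: int) -> PoolEstimate:
    sums = {}
    for n in matrix.experiments:
        if matrix.has_sample(condition, time_min, n):
            sums[n] = float(np.sum(matrix.column(condition, time_min, n).to_numpy()))
    if not sums:
        raise KeyError(f"no samples for ({condition!r}, t={time_min})")
    per = pd.Series(sums, name="pool")
    return PoolEstimate(condition, time_min, per, float(per.mean()))


def pool_table(matrix: SignalMatrix) -> pd.DataFrame:
    """Pool estimates for every (condition, time) present in the matrix."""
    rows = []
    seen = set()
    for _, row in matrix.samples.iterrows():
        key = (row["condition"], int(row["time_min"]))
        if key in seen:
            continue
        seen.add(key)
        est = total_pool(matrix, *key)
        rec = {"condition": key[0], "time_min": key[1], "mean": est.mean}
        for n, v in est.per_experiment.items():
            rec[f"experiment_{n}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)


def normalize_to_reference_mean(series: pd.Series, reference) -> pd.Series:
    """Divide a single-gene series by the mean over the designated reference
    samples; the output's mean over the reference set is 1."""
    reference = list(reference)
    if not reference:
        raise DegenerateInputError("reference sample set is empty")
    missing = [r for r in reference if r not in series.index]
    if missing:
        raise KeyError(f"reference samples not in series: {missing}")
    ref_mean = float(series.loc[reference].mean())
    if ref_mean <= 0:
        raise DegenerateInputError(
            f"reference mean is not positive ({ref_mean})")
    return series / ref_mean
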