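"""Normalization chain: Y(n), Z(g,n), dx, pools, reference-mean scaling."""

import numpy as np
import pandas as pd
import pytest

from darkrep import (
    SignalMatrix,
    SyntheticSpec,
    apply_per_gene_normalization,
    apply_total_normalization,
    compute_dx,
    compute_per_gene_factor,
    compute_total_factor,
    generate_dataset,
    normalize,
    normalize_to_reference_mean,
    total_pool,
)
from darkrep.containers import DARK, DARK_DBMIB, LIGHT, make_sample_id
from darkrep.errors import DegenerateInputError, StructuralError

from conftest import random_signal_matrix


def _matrix_from_t0(t0_by_exp, extra=None):
    """Small matrix with specified light time-0 columns (genes x 1 each)."""
    n_genes = len(next(iter(t0_by_exp.values())))
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene")
    cols, meta = {}, []
    for n, vals in t0_by_exp.items():
        sid = make_sample_id(LIGHT, 0, n)
        cols[sid] = np.asarray(vals, float)
        meta.append((sid, LIGHT, 0, n))
        if extra is not None:
            sid2 = make_sample_id(DARK, 30, n)
            cols[sid2] = np.asarray(extra[n], float)
            meta.append((sid2, DARK, 30, n))
    values = pd.DataFrame(cols, index=genes)
    samples = pd.DataFrame(meta, columns=["sample_id", "condition",
                                          "time_min", "experiment"]
                           ).set_index("sample_id")
    return SignalMatrix(values, samples)


class TestTotalFactor:
    def test_forced_by_definition(self):
        sm = _matrix_from_t0({1: [500.0, 1500.0]})
        assert compute_total_factor(sm, 1) == pytest.approx(2.0, rel=1e-15)

    def test_resummation_returns_1000(self, rng):
        for _ in range(10):
            sm = random_signal_matrix(rng)
            out = apply_total_normalization(sm)
            for n in out.experiments:
                pool = out.column(LIGHT, 0, n).sum()
                assert pool == pytest.approx(1000.0, rel=1e-9)

    def test_idempotent(self, rng):
        sm = random_signal_matrix(rng)
        once = apply_total_normalization(sm)
        twice = apply_total_normalization(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), rtol=1e-12)

    def test_different_raw_scales_converge(self):
        sm = _matrix_from_t0({1: [100.0, 300.0], 2: [1000.0, 3000.0]})
        out = apply_total_normalization(sm)
        for n in (1, 2):
            assert out.column(LIGHT, 0, n).sum() == pytest.approx(1000.0)
        # per-gene proportions preserved
        np.testing.assert_allclose(out.column(LIGHT, 0, 1).to_numpy(),
                                   out.column(LIGHT, 0, 2).to_numpy())

    def test_zero_total_degenerate(self):
        sm = _matrix_from_t0({1: [0.0, 0.0]})
        with pytest.raises(DegenerateInputError):
            compute_total_factor(sm, 1)

    def test_missing_light_t0_structural(self, rng):
        sm = random_signal_matrix(rng)
        with pytest.raises(StructuralError):
            compute_total_factor(sm, 99)


class TestPerGeneFactor:
    def test_direct_arithmetic(self):
        sm = _matrix_from_t0({1: [4.0, 10.0], 2: [6.0, 10.0]})
        fac = compute_per_gene_factor(sm)
        assert fac.Z.loc["g0", 1] == pytest.approx(0.8)
        assert fac.Z.loc["g0", 2] == pytest.approx(1.2)
        out = apply_per_gene_normalization(sm, fac)
        assert out.column(LIGHT, 0, 1)["g0"] == pytest.approx(5.0)
        assert out.column(LIGHT, 0, 2)["g0"] == pytest.approx(5.0)

    def test_single_experiment_all_ones(self):
        sm = _matrix_from_t0({1: [4.0, 7.0, 2.0]})
        fac = compute_per_gene_factor(sm)
        np.testing.assert_allclose(fac.Z.to_numpy(), 1.0)

    def test_cross_experiment_variance_zero_and_mean_preserved(self, rng):
        for _ in range(5):
            sm = random_signal_matrix(rng)
            before = pd.DataFrame({n: sm.column(LIGHT, 0, n)
                                   for n in sm.experiments})
            out = apply_per_gene_normalization(sm)
            after = pd.DataFrame({n: out.column(LIGHT, 0, n)
                                  for n in out.experiments})
            np.testing.assert_allclose(after.var(axis=1, ddof=0), 0.0,
                                       atol=1e-18)
            np.testing.assert_allclose(after.mean(axis=1),
                                       before.mean(axis=1), rtol=1e-12)

    def test_zero_baseline_gene_excluded_with_warning(self, caplog):
        sm = _matrix_from_t0({1: [0.0, 10.0], 2: [5.0, 10.0]})
        with caplog.at_level("WARNING"):
            fac = compute_per_gene_factor(sm)
        assert fac.excluded_genes == ["g0"]
        assert "excluded" in caplog.text
        out = apply_per_gene_normalization(sm, fac)
        assert "g0" not in out.genes


class TestDx:
    def test_forced_arithmetic(self):
        sm = _matrix_from_t0({1: [10.0, 20.0]}, extra={1: [7.0, 25.0]})
        dx = compute_dx(sm)
        assert dx.values[dx.sample_id(DARK, 30, 1)]["g0"] == pytest.approx(-3.0)
        assert dx.values[dx.sample_id(DARK, 30, 1)]["g1"] == pytest.approx(5.0)

    def test_light_t0_exactly_zero(self, rng):
        for _ in range(5):
            dx = compute_dx(random_signal_matrix(rng))
            for n in dx.experiments:
                col = dx.values[dx.sample_id(LIGHT, 0, n)]
                assert (col == 0.0).all()

    def test_unregulated_gene_zero_dx_noise_free(self):
        spec = SyntheticSpec(n_genes=120, cv_noise=0.0, seed=8)
        sm, truth = generate_dataset(spec)
        norm, _ = normalize(sm)
        dx = compute_dx(norm)
        unreg = truth.classes[truth.classes == "unregulated"].index
        unreg = [g for g in unreg if g in dx.genes]
        np.testing.assert_allclose(dx.values.loc[unreg].to_numpy(), 0.0,
                                   atol=1e-9)


class TestTotalPool:
    def test_light_t0_is_1000(self, rng):
        sm, _ = normalize(random_signal_matrix(rng))
        est = total_pool(sm, LIGHT, 0)
        assert est.mean == pytest.approx(1000.0, rel=1e-9)

    def test_noise_free_synthetic_pools(self):
        spec = SyntheticSpec(cv_noise=0.0, seed=2)
        sm, _ = generate_dataset(spec)
        norm, _ = normalize(sm)
        dark = total_pool(norm, DARK, 60)
        dbmib = total_pool(norm, DARK_DBMIB, 60)
        assert dark.mean == pytest.approx(500.0, rel=1e-8)
        assert dbmib.mean == pytest.approx(800.0, rel=1e-8)
        for v in dark.per_experiment:
            assert v == pytest.approx(500.0, rel=1e-8)

    def test_unknown_condition_lookup_error(self, rng):
        sm = random_signal_matrix(rng)
        with pytest.raises(KeyError):
            total_pool(sm, "no-such-condition", 0)


class TestReferenceMean:
    def test_arithmetic_oracle(self):
        series = pd.Series({"a": 2.0, "b": 4.0, "c": 6.0})
        out = normalize_to_reference_mean(series, ["a", "b"])
        np.testing.assert_allclose(out.to_numpy(),
                                   [2 / 3, 4 / 3, 2.0], rtol=1e-12)

    def test_constant_series_all_ones(self):
        series = pd.Series({"a": 5.0, "b": 5.0})
        out = normalize_to_reference_mean(series, ["a", "b"])
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_reference_mean_of_output_is_one(self, rng):
        for _ in range(20):
            vals = rng.gamma(2.0, 10.0, size=8) + 1e-6
            series = pd.Series(vals, index=[f"s{i}" for i in range(8)])
            ref = list(series.index[: int(rng.integers(1, 8))])
            out = normalize_to_reference_mean(series, ref)
            assert out.loc[ref].mean() == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_reference(self):
        series = pd.Series({"a": 0.0, "b": 1.0})
        with pytest.raises(DegenerateInputError):
            normalize_to_reference_mean(series, ["a"])
        with pytest.raises(DegenerateInputError):
            normalize_to_reference_mean(series, [])
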