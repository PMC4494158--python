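"""Modified-Dunnett score, permutation FDR, mulOpt and regulation calls."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from darkrep import (
    MulcomParams,
    SyntheticSpec,
    call_regulated,
    compute_dx,
    generate_dataset,
    mul_opt,
    mulcom_score,
    normalize,
    null_dataset,
    permutation_fdr,
)
from darkrep.containers import DARK, LIGHT, LIGHT_DBMIB, LIGHT_DCMU
from darkrep.errors import (
    ConfigurationError,
    CoarsePermutationWarning,
    InsufficientReplicationError,
    NoFeasibleParametersError,
    StructuralError,
)
from darkrep.mulcom import _assignments


def _dx(spec):
    sm, truth = generate_dataset(spec)
    norm, _ = normalize(sm)
    return compute_dx(norm), truth


@pytest.fixture(scope="module")
def planted_dx():
    return _dx(SyntheticSpec(n_genes=400, seed=7))


class TestScore:
    def test_formula_oracle(self):
        # means 5 and 3, pooled SE exactly 1 -> score (|2| - m) / (1 + t)
        d = np.sqrt(0.5)
        test, ctrl = [5 - d, 5 + d], [3 - d, 3 + d]
        assert mulcom_score(test, ctrl, MulcomParams()) == pytest.approx(2.0)
        assert mulcom_score(test, ctrl, MulcomParams(m=1.0, t=1.0)
                            ) == pytest.approx(0.5)

    def test_difference_equal_to_m_scores_zero(self):
        p = MulcomParams(m=2.0, t=0.3)
        assert mulcom_score([5.0, 5.2], [3.0, 3.2], p) == pytest.approx(0.0)

    def test_equal_groups_nonpositive(self, rng):
        vals = rng.normal(size=3)
        p = MulcomParams(m=0.5)
        assert mulcom_score(vals, vals, p) <= 0

    def test_monotone_decreasing_in_m_and_t(self, rng):
        # larger m always lowers the score; larger t shrinks its magnitude
        # (so it lowers any non-negative score)
        for _ in range(20):
            a, b = rng.normal(size=4), rng.normal(size=4)
            s1 = mulcom_score(a, b, MulcomParams(m=0.1, t=0.1))
            s2 = mulcom_score(a, b, MulcomParams(m=0.3, t=0.1))
            s3 = mulcom_score(a, b, MulcomParams(m=0.1, t=0.4))
            assert s2 <= s1
            if s1 >= 0:
                assert s3 <= s1

    def test_reduces_to_two_group_t(self, rng):
        p0 = MulcomParams(m=0.0, t=0.0)
        for _ in range(25):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a, b = rng.normal(size=n1), rng.normal(1.0, 2.0, size=n2)
            t_stat = stats.ttest_ind(a, b, equal_var=True).statistic
            assert mulcom_score(a, b, p0) == pytest.approx(abs(t_stat),
                                                           abs=1e-10)

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            mulcom_score([1.0], [2.0, 3.0], MulcomParams())


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(m=-1.0), dict(t=-0.1), dict(n_permutations=10),
        dict(fdr_threshold=0.0), dict(fdr_threshold=1.0), dict(critical=-1.0),
    ])
    def test_validation(self, bad):
        with pytest.raises(ConfigurationError):
            MulcomParams(**bad).validate()


class TestPermutationFdr:
    def test_assignment_space_excludes_identity_and_swap(self):
        opts = _assignments(2)
        assert len(opts) == 4  # C(4,2) - 2
        assert (0, 1) not in opts and (2, 3) not in opts

    def test_exhaustive_enumeration_warns(self, planted_dx):
        dx, _ = planted_dx
        with pytest.warns(CoarsePermutationWarning):
            est = permutation_fdr(dx, MulcomParams(m=0.2, seed=3))
        assert est.exhaustive
        assert len(est.perm_call_counts) == 16  # 4 options ^ 2 contrasts

    def test_same_seed_bit_identical(self, planted_dx):
        dx, _ = planted_dx
        # three test conditions -> 4^6 joint space -> sampled path
        p = MulcomParams(m=0.2, n_permutations=500, seed=11)
        conds = (DARK, LIGHT_DCMU, LIGHT_DBMIB)
        a = permutation_fdr(dx, p, test_conditions=conds)
        b = permutation_fdr(dx, p, test_conditions=conds)
        assert not a.exhaustive
        assert a.fdr == b.fdr
        np.testing.assert_array_equal(a.perm_call_counts, b.perm_call_counts)

    def test_strong_effects_drive_fdr_to_zero(self):
        spec = SyntheticSpec(n_genes=300, frac_repressed=0.9, frac_induced=0.0,
                             cv_noise=0.02, seed=21)
        dx, _ = _dx(spec)
        est = permutation_fdr(dx, MulcomParams(m=0.05, seed=1))
        assert est.n_significant > 200
        assert est.fdr < 0.02

    def test_scale_invariance_at_m0_t0(self, planted_dx):
        dx, _ = planted_dx
        p = MulcomParams(m=0.0, t=0.0, seed=5)
        est1 = permutation_fdr(dx, p)
        scaled = dataclasses.replace(dx, values=dx.values * 37.5)
        est2 = permutation_fdr(scaled, p)
        assert est1.fdr == pytest.approx(est2.fdr, rel=1e-12)
        assert est1.n_significant == est2.n_significant

    def test_gene_relabelling_invariance(self, planted_dx):
        dx, _ = planted_dx
        p = MulcomParams(m=0.2, seed=5)
        est1 = permutation_fdr(dx, p)
        perm = np.random.default_rng(0).permutation(len(dx.genes))
        shuffled = dataclasses.replace(dx, values=dx.values.iloc[perm])
        est2 = permutation_fdr(shuffled, p)
        assert est1.fdr == pytest.approx(est2.fdr, rel=1e-12)

    def test_too_few_permutations_rejected(self, planted_dx):
        dx, _ = planted_dx
        with pytest.raises(ConfigurationError):
            permutation_fdr(dx, MulcomParams(n_permutations=50))


class TestMulOpt:
    def test_matches_exhaustive_grid_oracle(self, planted_dx):
        dx, _ = planted_dx
        base = MulcomParams(seed=9)
        grid_m, grid_t = [0.3, 0.9, 2.0], [0.0, 0.05, 0.1]
        chosen = mul_opt(dx, grid_m, grid_t, base)
        # oracle: independent FDR evaluation at all 9 points
        best = None
        for m in grid_m:
            for t in grid_t:
                p = dataclasses.replace(base, m=m, t=t)
                est = permutation_fdr(dx, p)
                if est.fdr < base.fdr_threshold:
                    key = (est.n_significant, m, t)
                    if best is None or key > best:
                        best = key
        assert best is not None
        assert (chosen.m, chosen.t) == (best[1], best[2])

    def test_single_feasible_point_returned(self, planted_dx):
        dx, _ = planted_dx
        base = MulcomParams(seed=9)
        feasible_m = 1.2
        chosen = mul_opt(dx, [1e-6, feasible_m], [0.0], base)
        assert chosen.m == feasible_m

    def test_no_feasible_point_raises(self):
        dx, _ = _dx(dataclasses.replace(SyntheticSpec(n_genes=300, seed=3),
                                        frac_induced=0.0, frac_repressed=0.0))
        base = MulcomParams(seed=2, fdr_threshold=0.003)
        with pytest.raises(NoFeasibleParametersError):
            mul_opt(dx, [0.0, 0.001], [0.0], base)

    def test_empty_grid_rejected(self, planted_dx):
        dx, _ = planted_dx
        with pytest.raises(ConfigurationError):
            mul_opt(dx, [], [0.0], MulcomParams())


class TestCallRegulated:
    def test_planted_induced_gene_called_up(self):
        spec = SyntheticSpec(n_genes=300, cv_noise=0.05, seed=17)
        dx, truth = _dx(spec)
        res = call_regulated(dx, [DARK], MulcomParams(m=0.1))
        induced = truth.classes[truth.classes == "induced"].index
        fold5 = truth.fold.loc[induced, (DARK, 60)]
        gene = fold5.idxmax()
        row = res.calls[(res.calls["gene"] == gene)
                        & (res.calls["condition"] == DARK)].iloc[0]
        assert row["regulated"]
        assert row["direction"] == "up"

    def test_unregulated_noise_free_gene_never_called(self):
        spec = SyntheticSpec(n_genes=200, cv_noise=0.0, seed=4)
        dx, truth = _dx(spec)
        res = call_regulated(dx, [DARK], MulcomParams(m=0.01, t=0.01))
        unreg = set(truth.classes[truth.classes == "unregulated"].index)
        called = set(res.calls[res.calls["regulated"]]["gene"])
        assert not (called & unreg)

    def test_direction_consistent_with_mean_difference(self, planted_dx):
        dx, _ = planted_dx
        res = call_regulated(dx, [DARK], MulcomParams(m=0.15))
        reg = res.calls[res.calls["regulated"]]
        assert ((reg["best_diff"] > 0) == (reg["direction"] == "up")).all()
        assert res.calls.loc[~res.calls["regulated"], "direction"].isna().all()

    def test_missing_control_time_structural_error(self, planted_dx):
        dx, _ = planted_dx
        drop = [c for c in dx.values.columns
                if dx.samples.loc[c, "condition"] == LIGHT
                and dx.samples.loc[c, "time_min"] == 30]
        crippled = dataclasses.replace(
            dx, values=dx.values.drop(columns=drop),
            samples=dx.samples.drop(index=drop))
        with pytest.raises(StructuralError):
            call_regulated(crippled, [DARK], MulcomParams())
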