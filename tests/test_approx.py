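import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

import apyrel as a
from apyrel.approx import effective_record_weights

from conftest import random_pd_matrix, small_population


def make_apy(n, nc, rng, ids=None):
    G = random_pd_matrix(n, rng)
    ids = np.arange(n) if ids is None else ids
    part = a.CorePartition(core_ids=ids[:nc], noncore_ids=ids[nc:])
    grm = a.GRM(ids=ids, G=G, blend_weights=(1, 0))
    return grm, a.build_apy_inverse(grm, part)


class TestReverseReliabilityWeights:
    def test_zero_and_half(self):
        params = a.ModelParams.from_heritability(0.1)  # lambda = 9
        w = a.reverse_reliability_weights(
            pd.Series([0.0, 0.5], index=[1, 2]), params
        )
        assert w.weights[1] == 0.0
        assert w.weights[2] == pytest.approx(9.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e5))
    def test_round_trip(self, d):
        """d -> rel = d/(d+lambda) -> d recovers the input."""
        params = a.ModelParams.from_heritability(0.3)
        rel = d / (d + params.lam)
        w = a.reverse_reliability_weights(pd.Series([rel], index=[0]), params)
        assert w.weights[0] == pytest.approx(d, rel=1e-9)

    def test_out_of_range_rejected(self):
        params = a.ModelParams.from_heritability(0.3)
        with pytest.raises(ValueError):
            a.reverse_reliability_weights(pd.Series([1.5]), params)

    def test_cap_prevents_infinite_weight(self):
        params = a.ModelParams.from_heritability(0.3)
        w = a.reverse_reliability_weights(pd.Series([1.0]), params)
        assert np.isfinite(w.weights.iloc[0])


class TestEffectiveRecordWeights:
    def test_reproduces_target_reliabilities(self, rng):
        """The fitted diagonal D must reproduce reliabilities that are
        achievable through the genotyped-only system lambda*A22^-1 + D."""
        n = 40
        A22 = random_pd_matrix(n, rng, jitter=0.3)
        d = np.diag(A22).copy()
        A22 = A22 / np.sqrt(np.outer(d, d))  # correlation-like, diag 1
        params = a.ModelParams.from_heritability(0.3)
        A22inv = sla.inv(A22)
        d_true = rng.uniform(0.0, 4.0, n)
        K_true = params.lam * A22inv + np.diag(d_true)
        target = pd.Series(
            1 - params.lam * np.diag(sla.inv(K_true)) / np.diag(A22),
            index=np.arange(n),
        )
        w = effective_record_weights(target, A22, params, tol=1e-6, max_iter=300)
        K = params.lam * A22inv + np.diag(w.weights.to_numpy())
        rel = 1 - params.lam * np.diag(sla.inv(K)) / np.diag(A22)
        assert np.abs(rel - target.to_numpy()).max() < 1e-4

    def test_unrelated_animals_equal_closed_form(self):
        """With A22 = I the relationship-consistent weights reduce to the
        single-animal reversal."""
        params = a.ModelParams.from_heritability(0.25)
        target = pd.Series([0.1, 0.4, 0.6])
        w = effective_record_weights(target, np.eye(3), params, tol=1e-10)
        closed = a.reverse_reliability_weights(target, params)
        assert np.abs(w.weights.to_numpy() - closed.weights.to_numpy()).max() < 1e-6


class TestBlockDiagInverse:
    def test_full_core_no_weights_gives_grm_diagonal(self, rng):
        grm, apy = make_apy(20, 20, rng)
        params = a.ModelParams.from_heritability(0.5)  # lambda = 1
        w = a.WeightVector(pd.Series(0.0, index=np.arange(20)))
        diag = a.apy_block_diag_inverse(apy, w, params)
        assert np.abs(diag.to_numpy() - np.diag(grm.G)).max() < 1e-10

    def test_matches_dense_inverse(self, rng):
        nc, nn = 50, 400
        grm, apy = make_apy(nc + nn, nc, rng)
        params = a.ModelParams.from_heritability(0.042)
        w = a.WeightVector(
            pd.Series(rng.uniform(0, 5, nc + nn), index=np.arange(nc + nn))
        )
        diag = a.apy_block_diag_inverse(apy, w, params)
        K = params.lam * apy.to_sparse().toarray() + np.diag(
            w.reindex(apy.partition.all_ids)
        )
        oracle = np.diag(sla.inv(K))
        assert np.abs(diag.to_numpy() - oracle).max() < 1e-10

    def test_information_saturation(self, rng):
        n, nc = 30, 10
        grm, apy = make_apy(n, nc, rng)
        params = a.ModelParams.from_heritability(0.3)
        d = np.zeros(n)
        d[-1] = 1e12  # huge pseudo-record count for one noncore animal
        w = a.WeightVector(pd.Series(d, index=np.arange(n)))
        diag = a.apy_block_diag_inverse(apy, w, params)
        assert diag.iloc[-1] < 1e-11


class TestGenomicReliabilities:
    def test_no_information_limit(self, rng):
        grm, apy = make_apy(15, 15, rng)
        params = a.ModelParams.from_heritability(0.3)
        w = a.WeightVector(pd.Series(0.0, index=np.arange(15)))
        rel = a.genomic_reliabilities(apy, grm.diagonal(), w, params)
        assert np.abs(rel.to_numpy()).max() < 1e-10

    def test_saturation_limit(self, rng):
        grm, apy = make_apy(15, 5, rng)
        params = a.ModelParams.from_heritability(0.3)
        w = a.WeightVector(pd.Series(1e12, index=np.arange(15)))
        rel = a.genomic_reliabilities(apy, grm.diagonal(), w, params)
        assert np.all(rel > 1 - 1e-6)

    def test_small_instance_dense_oracle(self, rng):
        nc, nn = 20, 100
        grm, apy = make_apy(nc + nn, nc, rng)
        params = a.ModelParams.from_heritability(0.042)
        w = a.WeightVector(
            pd.Series(rng.uniform(0, 3, nc + nn), index=np.arange(nc + nn))
        )
        rel = a.genomic_reliabilities(apy, grm.diagonal(), w, params)
        K = params.lam * apy.to_sparse().toarray() + np.diag(
            w.reindex(apy.partition.all_ids)
        )
        g = grm.diagonal().reindex(apy.partition.all_ids).to_numpy()
        oracle = np.clip(1 - params.lam * np.diag(sla.inv(K)) / g, 0, 1)
        got = rel.reindex(apy.partition.all_ids).to_numpy()
        assert np.abs(got - oracle).max() < 1e-10


class TestPropagation:
    def _setup(self, seed=41):
        pop = small_population(seed=seed)
        params, numrel, ped = pop["params"], pop["numrel"], pop["ped"]
        system = a.assemble_mme(pop["phen"], numrel.A_inverse, ped.ids, params)
        rel_ped = a.exact_reliabilities(system, params, numrel.inbreeding, "ped")
        return pop, system, rel_ped

    def test_no_genomic_gain_returns_pedigree(self):
        pop, system, rel_ped = self._setup()
        gids = pop["gids"]
        grel = rel_ped.series().reindex(gids)
        res = a.propagate_to_pedigree(
            rel_ped, grel, pop["params"], system, pop["numrel"].inbreeding
        )
        assert np.abs(
            res.final_reliability - rel_ped.series()
        ).max() < 1e-9

    def test_parent_reliability_increases(self):
        pop, system, rel_ped = self._setup()
        ped, gids = pop["ped"], pop["gids"]
        # pick a genotyped animal with a known nongenotyped parent
        target, parent = None, None
        gset = set(gids.tolist())
        for i in ped.index_of(gids):
            s = ped.sire[i]
            if s >= 0 and ped.ids[s] not in gset:
                target, parent = ped.ids[i], ped.ids[s]
                break
        assert target is not None
        grel = rel_ped.series().reindex(gids).copy()
        grel[target] = 0.95  # large genomic gain for one animal
        res = a.propagate_to_pedigree(
            rel_ped, grel, pop["params"], system, pop["numrel"].inbreeding
        )
        assert res.final_reliability[parent] > rel_ped.series()[parent] + 1e-6
        assert res.final_reliability[target] > rel_ped.series()[target]

    def test_end_to_end_correlation_with_exact(self):
        """Benchmark-core approximation tracks the exact MME reliabilities."""
        pop, system, rel_ped = self._setup(seed=42)
        gids, grm, params = pop["gids"], pop["grm"], pop["params"]
        hinv = a.build_H_inverse(pop["numrel"], sla.inv(grm.G), gids, params)
        sys_ss = a.assemble_mme(pop["phen"], hinv, pop["ped"].ids, params)
        rel_ex = a.exact_reliabilities(sys_ss, params, pop["numrel"].inbreeding)
        k99 = a.choose_core_size(pop["geno"].subset(gids), 0.99)
        part = a.select_nested_cores(gids, [k99], seed=42)[0]
        apy = a.build_apy_inverse(grm, part)
        w = effective_record_weights(
            pd.Series(rel_ped.series().reindex(gids).to_numpy(), index=gids),
            pop["A22"], params,
        )
        grel = a.genomic_reliabilities(apy, grm.diagonal(), w, params)
        res = a.propagate_to_pedigree(
            rel_ped, grel, params, system, pop["numrel"].inbreeding
        )
        r = np.corrcoef(res.final_reliability, rel_ex.series())[0, 1]
        assert r > 0.85  # small instance; the desk-scale study asserts more


class TestRandomizedMatmul:
    def test_full_k_is_exact(self, rng):
        A, B = rng.normal(size=(10, 50)), rng.normal(size=(50, 10))
        est = a.randomized_matmul(A, B, a.SketchConfig(k=50, seed=3))
        assert np.abs(est - A @ B).max() < 1e-12

    def test_zero_matrix(self, rng):
        A = rng.normal(size=(5, 20))
        est = a.randomized_matmul(A, np.zeros((20, 5)), a.SketchConfig(k=4, seed=0))
        assert np.all(est == 0)

    def test_deterministic_under_seed(self, rng):
        A, B = rng.normal(size=(8, 40)), rng.normal(size=(40, 8))
        s = a.SketchConfig(k=10, seed=5)
        assert np.array_equal(
            a.randomized_matmul(A, B, s), a.randomized_matmul(A, B, s)
        )

    def test_error_monotone_in_k(self, rng):
        A, B = rng.normal(size=(30, 300)), rng.normal(size=(300, 30))
        exact = A @ B
        means = []
        for k in (30, 150, 270):
            errs = [
                np.linalg.norm(
                    a.randomized_matmul(A, B, a.SketchConfig(k=k, seed=s)) - exact
                )
                for s in range(60)
            ]
            means.append(np.mean(errs))
        assert means[0] > means[1] > means[2]

    def test_k_out_of_range(self, rng):
        A, B = rng.normal(size=(4, 6)), rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            a.randomized_matmul(A, B, a.SketchConfig(k=7, seed=0))


class TestSketchedPath:
    def test_sketched_diagonal_diverges_from_exact(self, rng):
        """Column-sampling the two expensive products visibly perturbs the
        inverse diagonal (the mechanism behind sketched reliabilities
        decoupling from the benchmark)."""
        nc, nn = 30, 200
        grm, apy = make_apy(nc + nn, nc, rng)
        params = a.ModelParams.from_heritability(0.3)
        w = a.WeightVector(
            pd.Series(rng.uniform(0, 3, nc + nn), index=np.arange(nc + nn))
        )
        exact = a.apy_block_diag_inverse(apy, w, params)
        sk = a.apy_block_diag_inverse(
            apy, w, params, sketch=a.SketchConfig(k=nn // 2, seed=1)
        )
        rel_err = np.abs(sk - exact).max() / np.abs(exact).max()
        assert rel_err > 0.01
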