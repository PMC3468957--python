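"""Parallel ICA: pair selection, coupling behavior, repeat consistency."""

import itertools

import numpy as np
import pytest

from rsnfuse.ica import infomax, match_components, pca_reduce
from rsnfuse.parallel import (
    ParaIcaConfig,
    para_ica_fit,
    repeat_consistency,
    select_constrained_pairs,
)
from rsnfuse.synthetic import LinkedSimulationSpec, generate_linked_dataset


def _brute_force_selection(A1, A2, r_th, max_pairs):
    Z1 = (A1 - A1.mean(0)) / A1.std(0)
    Z2 = (A2 - A2.mean(0)) / A2.std(0)
    R = Z1.T @ Z2 / A1.shape[0]
    cand = [
        (i, j)
        for i in range(R.shape[0])
        for j in range(R.shape[1])
        if abs(R[i, j]) > r_th
    ]
    best = (0.0, frozenset())
    for size in range(1, max_pairs + 1):
        for combo in itertools.combinations(cand, size):
            if len({c[0] for c in combo}) < size or len({c[1] for c in combo}) < size:
                continue
            score = sum(abs(R[c]) for c in combo)
            if score > best[0] + 1e-12:
                best = (score, frozenset(combo))
    return best[1]


class TestSelectConstrainedPairs:
    def test_all_subthreshold_gives_empty(self):
        rng = np.random.default_rng(0)
        A1 = rng.standard_normal((500, 4))
        A2 = rng.standard_normal((500, 4))
        assert select_constrained_pairs(A1, A2, r_th=0.3) == []

    def test_duplicated_column_forces_that_pair(self):
        rng = np.random.default_rng(1)
        A1 = rng.standard_normal((50, 3))
        A2 = rng.standard_normal((50, 3))
        A2[:, 1] = A1[:, 2]
        links = select_constrained_pairs(A1, A2, r_th=0.95, max_pairs=3)
        assert [(l.comp1, l.comp2) for l in links] == [(2, 1)]
        assert links[0].r == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_selection_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        A1 = rng.standard_normal((24, 10))
        A2 = rng.standard_normal((24, 10))
        got = {(l.comp1, l.comp2) for l in select_constrained_pairs(A1, A2, 0.3, 3)}
        assert got == set(_brute_force_selection(A1, A2, 0.3, 3))

    def test_zero_variance_column_rejected(self):
        A1 = np.random.default_rng(2).standard_normal((20, 3))
        A2 = A1.copy()
        A2[:, 0] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            select_constrained_pairs(A1, A2)

    def test_cap_respected(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(40)
        A1 = np.column_stack([base + 0.1 * rng.standard_normal(40) for _ in range(6)])
        A2 = np.column_stack([base + 0.1 * rng.standard_normal(40) for _ in range(6)])
        links = select_constrained_pairs(A1, A2, r_th=0.3, max_pairs=3)
        assert len(links) <= 3


class TestParaIcaFit:
    def test_disabled_constraint_equals_two_plain_icas_bitwise(self, linked_dataset):
        ds, _ = linked_dataset
        cfg = ParaIcaConfig(k1=8, k2=4, r_th=1.1)
        res = para_ica_fit(ds.X1, ds.X2, cfg, seed=11)
        ss = np.random.SeedSequence(11)
        c1, c2 = ss.spawn(2)
        wh1, Z1 = pca_reduce(ds.X1, 8)
        wh2, Z2 = pca_reduce(ds.X2, 4)
        p = cfg.infomax_params()
        r1 = infomax(Z1, params=p, seed=c1, whitening=wh1)
        r2 = infomax(Z2, params=p, seed=c2, whitening=wh2)
        assert np.array_equal(res.result1.unmixing, r1.unmixing)
        assert np.array_equal(res.result2.unmixing, r2.unmixing)
        assert res.constraint_fire_count == 0
        assert res.links == []

    def test_planted_link_recovered(self, linked_dataset):
        ds, truth = linked_dataset
        res = para_ica_fit(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seed=11)
        perm, _, _ = match_components(res.result1.sources, truth.true_sources_1)
        i = perm[0]
        A1, A2 = res.result1.loadings, res.result2.loadings
        derived = max(
            abs(np.corrcoef(A1[:, i], A2[:, j])[0, 1]) for j in range(A2.shape[1])
        )
        assert derived == pytest.approx(abs(truth.link_corrs[0][2]), abs=0.1)

    def test_zscaled_loading_columns(self, linked_dataset):
        ds, _ = linked_dataset
        res = para_ica_fit(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seed=1)
        for z in (res.loadings_z1, res.loadings_z2):
            assert np.abs(z.mean(axis=0)).max() < 1e-10
            assert np.abs(z.std(axis=0) - 1).max() < 1e-10

    def test_links_capped_at_max_pairs(self, linked_dataset):
        ds, _ = linked_dataset
        res = para_ica_fit(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seed=2)
        assert len(res.links) <= 3
        # pairing is one-to-one
        assert len({l.comp1 for l in res.links}) == len(res.links)
        assert len({l.comp2 for l in res.links}) == len(res.links)

    def test_sample_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            para_ica_fit(np.zeros((10, 5)), np.zeros((11, 5)))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="endurance"):
            para_ica_fit(
                np.zeros((10, 5)),
                np.zeros((10, 5)),
                ParaIcaConfig(endurance=0.1),
            )

    def test_deterministic_per_seed(self, linked_dataset):
        ds, _ = linked_dataset
        a = para_ica_fit(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seed=4)
        b = para_ica_fit(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seed=4)
        assert np.array_equal(a.result1.unmixing, b.result1.unmixing)
        assert a.constraint_fire_count == b.constraint_fire_count


class TestConstraintBehavior:
    def test_constraint_fires_only_with_suprathreshold_natural_pairs(self):
        # oracle: scan the unconstrained solution's loading correlations
        for seed in range(6):
            spec = LinkedSimulationSpec(n_feat1=500)
            ds, _ = generate_linked_dataset(spec, seed)
            on = para_ica_fit(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seed=100 + seed)
            off = para_ica_fit(
                ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4, r_th=1.1), seed=100 + seed
            )
            R = np.abs(
                np.corrcoef(off.result1.loadings.T, off.result2.loadings.T)[:8, 8:]
            )
            if R.max() < 0.3:
                assert on.constraint_fire_count == 0
                assert np.array_equal(on.result1.unmixing, off.result1.unmixing)

    def test_near_threshold_enhancement_bias(self):
        # constrained recovery should not fall below unconstrained on
        # average for links near the firing threshold
        con, unc = [], []
        for seed in range(6):
            spec = LinkedSimulationSpec(n_feat1=500, links=[(0, 0, 0.3)])
            ds, truth = generate_linked_dataset(spec, 40 + seed)
            for cfg, acc in (
                (ParaIcaConfig(k1=8, k2=4), con),
                (ParaIcaConfig(k1=8, k2=4, r_th=1.1), unc),
            ):
                res = para_ica_fit(ds.X1, ds.X2, cfg, seed=200 + seed)
                perm, _, _ = match_components(
                    res.result1.sources, truth.true_sources_1
                )
                i = perm[0]
                A1, A2 = res.result1.loadings, res.result2.loadings
                acc.append(
                    max(
                        abs(np.corrcoef(A1[:, i], A2[:, j])[0, 1])
                        for j in range(A2.shape[1])
                    )
                )
        assert np.mean(con) >= np.mean(unc) - 0.02


class TestRepeatConsistency:
    def test_identical_seeds_give_unit_similarity(self, linked_dataset):
        ds, _ = linked_dataset
        cfg = ParaIcaConfig(k1=8, k2=4)
        cons, table = repeat_consistency(ds.X1, ds.X2, cfg, seeds=[3, 3])
        single = para_ica_fit(ds.X1, ds.X2, cfg, seed=3)
        assert np.array_equal(cons.result1.unmixing, single.result1.unmixing)
        for row in table:
            assert row["reproducibility"] == 1.0

    def test_planted_link_reproducible_across_repeats(self, linked_dataset):
        ds, truth = linked_dataset
        cfg = ParaIcaConfig(k1=8, k2=4)
        cons, table = repeat_consistency(ds.X1, ds.X2, cfg, seeds=list(range(5)))
        # the strongest consensus link should be reproducible in most repeats
        best = max(cons.links, key=lambda l: abs(l.r))
        rows = [
            r
            for r in table
            if (r["comp1"], r["comp2"]) == (best.comp1, best.comp2)
        ]
        assert rows and rows[0]["reproducibility"] >= 0.8

    def test_requires_two_repeats(self, linked_dataset):
        ds, _ = linked_dataset
        with pytest.raises(ValueError):
            repeat_consistency(ds.X1, ds.X2, ParaIcaConfig(k1=8, k2=4), seeds=[1])
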