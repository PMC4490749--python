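"""Penalties, stepwise model search, support intervals, variance, refinement."""

import numpy as np
import pytest

from boneqtl.crosssim import PlantedQTL, simulate_cross
from boneqtl.qtl import (PenaltySet, derive_penalties, estimate_heritability,
                         fit_model, genotype_probabilities, lod_support_interval,
                         refine_positions, stepwise_model_search,
                         variance_explained)
from boneqtl.qtl.model import LocusStore, QTLModel


@pytest.fixture(scope="module")
def two_qtl_cross():
    cross = simulate_cross(n_f2=755,
                           qtl=[PlantedQTL("3", 40.0, additive=0.8),
                                PlantedQTL("9", 30.0, additive=0.8)],
                           env_sd=1.0, sex_effect=0.5, seed=7)
    probs = genotype_probabilities(cross, step_cM=2.0)
    return cross, probs


@pytest.fixture(scope="module")
def penalties(two_qtl_cross):
    cross, probs = two_qtl_cross
    y = cross.phenotypes_f2.phenotype.to_numpy()
    return derive_penalties(probs, y, cross.sex, n_perm=64, seed=13)


class TestPenalties:
    def test_ordering_and_range(self, penalties):
        assert penalties.T_heavy >= penalties.T_light >= 0
        # genome-wide single-locus threshold for a scan of this size
        assert 3.0 <= penalties.T_main <= 4.5
        assert penalties.scaled_down

    def test_reproducible(self, two_qtl_cross):
        cross, probs = two_qtl_cross
        y = cross.phenotypes_f2.phenotype.to_numpy()
        a = derive_penalties(probs, y, cross.sex, n_perm=16, seed=21)
        b = derive_penalties(probs, y, cross.sex, n_perm=16, seed=21)
        assert (a.T_main, a.T_heavy, a.T_light) == (b.T_main, b.T_heavy, b.T_light)

    def test_validation(self):
        with pytest.raises(ValueError):
            PenaltySet(T_main=0.0, T_heavy=1.0, T_light=0.5)
        with pytest.raises(ValueError):
            PenaltySet(T_main=3.0, T_heavy=0.5, T_light=1.0)


class TestStepwise:
    def test_two_planted_qtl_recovered(self, two_qtl_cross, penalties):
        cross, probs = two_qtl_cross
        y = cross.phenotypes_f2.phenotype.to_numpy()
        model = stepwise_model_search(probs, y, cross.sex, penalties, max_qtl=6)
        assert model.n_loci == 2
        found = sorted(model.loci)
        assert found[0][0] == "3" and abs(found[0][1] - 40.0) <= 15
        assert found[1][0] == "9" and abs(found[1][1] - 30.0) <= 15
        for a in model.additive:
            assert a == pytest.approx(0.8, abs=0.2)

    def test_null_phenotype_gives_empty_model(self, two_qtl_cross, penalties):
        cross, probs = two_qtl_cross
        rng = np.random.default_rng(0)
        empty = 0
        for rep in range(10):
            y = rng.normal(size=755)
            model = stepwise_model_search(probs, y, cross.sex, penalties,
                                          max_qtl=3)
            empty += model.n_loci == 0
        assert empty >= 9

    def test_epistatic_pair_interaction_retained(self):
        cross = simulate_cross(n_f2=755,
                               qtl=[PlantedQTL("2", 50.0, additive=0.5),
                                    PlantedQTL("7", 30.0, additive=0.5)],
                               interactions=[(0, 1, 1.0)], env_sd=1.0, seed=17)
        probs = genotype_probabilities(cross, step_cM=2.0)
        y = cross.phenotypes_f2.phenotype.to_numpy()
        pen = derive_penalties(probs, y, cross.sex, n_perm=48, seed=18)
        model = stepwise_model_search(probs, y, cross.sex, pen, max_qtl=6)
        assert model.n_loci >= 2
        assert len(model.interactions) >= 1


class TestSupportInterval:
    def test_symmetric_peak(self):
        pos = np.arange(0.0, 101.0)
        lod = np.clip(6.0 - np.abs(pos - 50.0) * (1.5 / 8.0), 0, None)
        lo, hi = lod_support_interval(pos, lod, drop=1.5)
        assert lo == pytest.approx(42.0, abs=1.0)
        assert hi == pytest.approx(58.0, abs=1.0)

    def test_monotone_curve_clipped_at_end(self):
        pos = np.arange(0.0, 51.0)
        lod = pos / 10.0
        lo, hi = lod_support_interval(pos, lod)
        assert hi == 50.0
        assert lo == pytest.approx(35.0, abs=1.0)

    def test_flat_zero_whole_chromosome(self):
        pos = np.arange(0.0, 21.0)
        with pytest.warns(UserWarning, match="whole chromosome"):
            lo, hi = lod_support_interval(pos, np.zeros_like(pos))
        assert (lo, hi) == (0.0, 20.0)


class TestVariance:
    def test_single_locus_pct_var_is_marginal_r2(self, two_qtl_cross):
        cross, probs = two_qtl_cross
        y = cross.phenotypes_f2.phenotype.to_numpy()
        store = LocusStore(probs)
        model = QTLModel(loci=[("3", 40.0)])
        terms = variance_explained(model, store, y, sex=None)
        xz = store.get("3", 40.0)
        X = np.column_stack([np.ones(len(y)), xz])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 100 * (1 - ((y - X @ beta) ** 2).sum() / tss)
        assert terms.pct_var.iloc[0] == pytest.approx(r2, abs=1e-9)

    def test_unlinked_loci_variance_adds(self):
        # Monte-Carlo: loci on different chromosomes are orthogonal in
        # expectation, so per-term %var sums to the full-model %var
        devs = []
        for seed in (7, 8, 9):
            cross = simulate_cross(n_f2=2000,
                                   qtl=[PlantedQTL("3", 40.0, additive=0.8),
                                        PlantedQTL("9", 30.0, additive=0.8)],
                                   env_sd=1.0, sex_effect=0.5, seed=seed)
            y = cross.phenotypes_f2.phenotype.to_numpy()
            probs = genotype_probabilities(cross, step_cM=2.0)
            store = LocusStore(probs)
            model = QTLModel(loci=[("3", 40.0), ("9", 30.0)])
            terms = variance_explained(model, store, y, cross.sex)
            _, _, rss_full = fit_model(store, model, y, cross.sex)
            tss = ((y - y.mean()) ** 2).sum()
            B = np.column_stack([np.ones(len(y)), cross.sex])
            base_rss = ((y - B @ np.linalg.lstsq(B, y, rcond=None)[0]) ** 2).sum()
            devs.append(terms.pct_var.sum() - 100 * (base_rss - rss_full) / tss)
        assert abs(np.mean(devs)) <= 0.5

    def test_empty_model_rejected(self, two_qtl_cross):
        cross, probs = two_qtl_cross
        with pytest.raises(ValueError, match="empty"):
            variance_explained(QTLModel(), probs,
                               cross.phenotypes_f2.phenotype.to_numpy())


class TestRefine:
    def test_refinement_improves_and_is_idempotent(self, two_qtl_cross, penalties):
        cross, probs = two_qtl_cross
        y = cross.phenotypes_f2.phenotype.to_numpy()
        model = stepwise_model_search(probs, y, cross.sex, penalties, max_qtl=4)
        refined = refine_positions(model, cross, y, cross.sex, probs=probs)
        assert refined.lod >= model.lod - 1e-9
        # refined position sits at the dense-grid argmax of its own curve
        for i, (c, p) in enumerate(refined.loci):
            pos, lods = refined.lod_curves[i]
            assert abs(pos[np.argmax(lods)] - p) <= 0.1 + 1e-9
        again = refine_positions(refined, cross, y, cross.sex, probs=probs)
        for (c1, p1), (c2, p2) in zip(refined.loci, again.loci):
            assert c1 == c2 and abs(p1 - p2) <= 0.1 + 1e-9
        # support intervals contain their loci
        for (lo, hi), (_, p) in zip(refined.support_intervals, refined.loci):
            assert lo <= p <= hi


class TestHeritability:
    def test_criterion_is_strict(self):
        rng = np.random.default_rng(3)
        f1 = rng.normal(size=100000) * np.sqrt(0.6)
        f2 = rng.normal(size=100000) * 1.0
        h2 = estimate_heritability(f1, f2)
        assert h2 == pytest.approx(40.0, abs=1.5)
        from boneqtl.qtl import select_phenotypes
        import pandas as pd
        tbl = select_phenotypes(pd.DataFrame({"p": [0., 1., 2.]}),
                                pd.DataFrame({"p": [0., 1., 2.]}))
        assert not tbl.selected.iloc[0]  # identical cohorts: H2 = 0

    def test_identical_cohorts_zero(self):
        v = np.arange(10.0)
        assert estimate_heritability(v, v) == 0.0

    def test_zero_f2_variance_errors(self):
        with pytest.raises(ValueError, match="zero F2"):
            estimate_heritability(np.arange(4.0), np.ones(5))

    def test_negative_estimates_clamped(self):
        rng = np.random.default_rng(4)
        f1 = rng.normal(size=500) * 2.0
        f2 = rng.normal(size=500)
        assert estimate_heritability(f1, f2) == 0.0
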