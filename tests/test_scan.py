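"""Haley–Knott scans: oracles, calibration plumbing and edge cases."""

import numpy as np
import pytest

from boneqtl.crosssim import PlantedQTL, simulate_cross
from boneqtl.qtl import (genotype_probabilities, lod_to_odds,
                         permutation_threshold, scan_one_ehk,
                         single_gene_interval_cm)


@pytest.fixture(scope="module")
def planted_cross():
    cross = simulate_cross(n_f2=755, qtl=[PlantedQTL("1", 49.0, additive=0.8)],
                           env_sd=1.0, sex_effect=0.4, seed=5)
    probs = genotype_probabilities(cross, step_cM=2.0, error_rate=0.0)
    return cross, probs


def anova_lod(y, g):
    """Three-group ANOVA LOD at a fully typed marker: (n/2)·log10(RSS0/RSS1)."""
    rss0 = np.sum((y - y.mean()) ** 2)
    rss1 = sum(((y[g == k] - y[g == k].mean()) ** 2).sum() for k in (0, 1, 2))
    return len(y) / 2 * np.log10(rss0 / rss1)


def test_lod_odds_and_gene_resolution_conversions():
    assert lod_to_odds(3.0) == 1000.0
    assert single_gene_interval_cm(16.0) == 0.0625


@pytest.mark.parametrize("method", ["hk", "ehk"])
def test_scan_equals_anova_oracle_at_typed_marker(planted_cross, method):
    cross, probs = planted_cross
    y = cross.phenotypes_f2.phenotype.to_numpy()
    res = scan_one_ehk(probs, y, sex=None, mode="additive-covariate", method=method)
    chr1 = cross.map.chromosomes[0]
    pos, lod = res.chromosome("1")
    for j, mpos in enumerate(chr1.marker_pos):
        jj = int(np.argmin(np.abs(pos - mpos)))
        assert lod[jj] == pytest.approx(anova_lod(y, cross.genotypes[:, j]),
                                        abs=1e-6)


def test_lod_nonnegative_on_null_scan():
    cross = simulate_cross(n_f2=300, qtl=[], env_sd=1.0, seed=6)
    probs = genotype_probabilities(cross, step_cM=4.0)
    res = scan_one_ehk(probs, cross.phenotypes_f2.phenotype, cross.sex)
    assert np.all(res.lod >= 0)


def test_peak_near_planted_qtl(planted_cross):
    cross, probs = planted_cross
    res = scan_one_ehk(probs, cross.phenotypes_f2.phenotype, cross.sex)
    chrom, pos, lod = res.max()
    assert chrom == "1"
    assert abs(pos - 49.0) <= 10.0
    assert lod > 5.0


def test_constant_phenotype_rejected(planted_cross):
    _, probs = planted_cross
    with pytest.raises(ValueError, match="constant"):
        scan_one_ehk(probs, np.ones(755))


def test_constant_sex_falls_back_to_additive(planted_cross):
    cross, probs = planted_cross
    y = cross.phenotypes_f2.phenotype.to_numpy()
    with pytest.warns(UserWarning, match="additive"):
        res = scan_one_ehk(probs, y, sex=np.zeros(755, int),
                           mode="interactive-covariate")
    assert res.mode == "additive-covariate"


def test_permutation_threshold_reproducible(planted_cross):
    cross, probs = planted_cross
    y = cross.phenotypes_f2.phenotype.to_numpy()
    t1 = permutation_threshold(probs, y, cross.sex, n_perm=25, seed=11)
    t2 = permutation_threshold(probs, y, cross.sex, n_perm=25, seed=11)
    assert t1 == t2
    assert 2.0 < t1 < 6.0


def test_alpha_one_gives_minimum_permuted_max(planted_cross):
    cross, probs = planted_cross
    y = cross.phenotypes_f2.phenotype.to_numpy()
    thr, maxes = permutation_threshold(probs, y, cross.sex, n_perm=10, alpha=1.0,
                                       seed=12, return_max_lods=True)
    assert thr == pytest.approx(maxes.min())


def test_zero_permutations_rejected(planted_cross):
    cross, probs = planted_cross
    with pytest.raises(ValueError, match="n_perm"):
        permutation_threshold(probs, cross.phenotypes_f2.phenotype, cross.sex,
                              n_perm=0)


def test_additive_effect_recovered_with_correct_sign():
    """Planted additive effects recovered within 3 standard errors."""
    from boneqtl.crosssim import default_map

    gmap = default_map()
    chrom = gmap.chromosomes[1]
    target = chrom.marker_pos[len(chrom.marker_pos) // 2]  # plant at a marker
    j = len(gmap.chromosomes[0].marker_pos) + len(chrom.marker_pos) // 2
    hits = 0
    for rep in range(10):
        cross = simulate_cross(gmap=gmap, n_f2=755,
                               qtl=[PlantedQTL("2", target, additive=0.6)],
                               env_sd=1.0, seed=100 + rep)
        y = cross.phenotypes_f2.phenotype.to_numpy()
        g = cross.genotypes[:, j]
        x = g - 1.0
        z = (g == 1).astype(float)
        X = np.column_stack([np.ones_like(x), x, z])
        beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res_ss[0] / (len(y) - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        if beta[1] > 0 and abs(beta[1] - 0.6) <= 3 * se:
            hits += 1
    assert hits >= 9
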