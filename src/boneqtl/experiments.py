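"""Validation experiments: calibration, recovery and analytic-geometry checks.

These are the package's own end-to-end correctness experiments, shared by
the test suite and the acceptance script.  Every experiment regenerates its
inputs from a seed and runs the public pipeline operations — nothing is
precomputed.

Problem sizes are desk-scale by design: the calibration experiment uses 200
individuals on the 19-autosome/98-marker map with a 10 cM scan grid, and
the recovery experiment uses the full 755-animal cohort with a 2 cM grid;
both are documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .crosssim import MISSING, Chromosome, GeneticMap, PlantedQTL, default_map, simulate_cross
from .morphometry import (assemble_phenotypes, object_shape_metrics,
                          radial_cortical_thickness)
from .phantom import PhantomSpec, generate_phantom
from .qtl import (derive_penalties, enumerate_posterior, genotype_probabilities,
                  permutation_threshold, scan_one_ehk, stepwise_model_search,
                  variance_explained)
from .qtl.model import LocusStore, QTLModel
from .qtl.scan import _base_matrix, ehk_lod_engine, genotype_scores
from .segmentation import PhaseSegmentation, PoreComponent, label_components, segment_phases


# --- HMM vs enumeration --------------------------------------------------------

def hmm_enumeration_error(seed: int = 0, n_individuals: int = 8) -> float:
    """Worst |forward–backward − exhaustive enumeration| on a 3-marker
    chromosome, over individuals and grid positions."""
    gmap = GeneticMap((Chromosome("1", 30.0, (0.0, 12.0, 30.0),
                                  ("m1", "m2", "m3")),))
    cross = simulate_cross(gmap=gmap, n_f2=n_individuals, seed=seed,
                           missing_rate=0.25)
    probs = genotype_probabilities(cross, step_cM=2.0, error_rate=1e-3)
    cp = probs.chromosomes[0]
    mpos = np.array([0.0, 12.0, 30.0])
    worst = 0.0
    for i in range(n_individuals):
        for j, q in enumerate(cp.positions):
            pos = np.unique(np.concatenate([mpos, [q]]))
            obs = np.full(len(pos), MISSING)
            obs[np.searchsorted(pos, mpos)] = cross.genotypes[i]
            oracle = enumerate_posterior(pos, obs, error_rate=1e-3)
            qi = int(np.searchsorted(pos, q))
            worst = max(worst, float(np.abs(oracle[qi] - cp.probs[i, j]).max()))
    return worst


# --- Haley–Knott vs ANOVA oracle -----------------------------------------------

def hk_anova_difference(seed: int = 0, n_f2: int = 755) -> float:
    """Worst |scan LOD − three-group ANOVA LOD| over the fully typed markers
    of one chromosome, for both the plain and extended scan."""
    cross = simulate_cross(n_f2=n_f2, qtl=[PlantedQTL("1", 49.0, additive=0.8)],
                           env_sd=1.0, seed=seed)
    probs = genotype_probabilities(cross, step_cM=2.0, error_rate=0.0)
    y = cross.phenotypes_f2.phenotype.to_numpy()
    chr1 = cross.map.chromosomes[0]
    worst = 0.0
    for method in ("hk", "ehk"):
        res = scan_one_ehk(probs, y, sex=None, mode="additive-covariate",
                           method=method)
        pos, lod = res.chromosome("1")
        for j, mpos in enumerate(chr1.marker_pos):
            g = cross.genotypes[:, j]
            rss0 = np.sum((y - y.mean()) ** 2)
            rss1 = sum(((y[g == k] - y[g == k].mean()) ** 2).sum()
                       for k in (0, 1, 2))
            oracle = len(y) / 2 * np.log10(rss0 / rss1)
            jj = int(np.argmin(np.abs(pos - mpos)))
            worst = max(worst, abs(float(lod[jj]) - oracle))
    return worst


# --- permutation-threshold calibration -----------------------------------------

def calibration_type1_error(
    n_trials: int = 400,
    n_perm: int = 100,
    n_individuals: int = 200,
    alpha: float = 0.05,
    step_cM: float = 10.0,
    seed: int = 0,
) -> float:
    """Empirical genome-wide type-I error of permutation thresholds.

    One F2 cross fixes the genotypes; each trial draws a fresh null
    phenotype, derives its own ``n_perm``-permutation threshold and scans it
    genome-wide; the exceedance rate estimates the realized alpha.
    """
    rng = np.random.default_rng(seed)
    cross = simulate_cross(gmap=default_map(), n_f2=n_individuals, qtl=[],
                           env_sd=1.0, seed=int(rng.integers(2**31)))
    probs = genotype_probabilities(cross, step_cM=step_cM)
    xz, V, _ = genotype_scores(probs)
    sex = cross.sex
    base = _base_matrix(n_individuals, sex)
    exceed = 0
    for _ in range(n_trials):
        y = rng.normal(size=n_individuals)
        thr = permutation_threshold(probs, y, sex, n_perm=n_perm, alpha=alpha,
                                    seed=rng)
        lod = ehk_lod_engine(y[None], base, xz, V, sex=sex, interactive=True,
                             method="hk")[0]
        exceed += float(lod.max()) > thr
    return exceed / n_trials


# --- planted-QTL recovery ------------------------------------------------------

def two_qtl_recovery(
    n_reps: int = 100,
    n_f2: int = 755,
    additive: float = 0.8,
    env_sd: float = 1.0,
    tol_cM: float = 15.0,
    n_perm_penalties: int = 256,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which a two-QTL model search finds exactly
    the two planted loci (each within ``tol_cM``, no spurious locus).

    Penalties are derived once from the first replicate's permutations and
    reused — they describe the null of the shared study design.  256
    permutations keep the 95% quantile's own sampling noise (which shifts
    every replicate's spurious-locus rate together) below the level of the
    search's intrinsic error rate.
    """
    rng = np.random.default_rng(seed)
    truth = [PlantedQTL("3", 40.0, additive=additive),
             PlantedQTL("9", 30.0, additive=additive)]
    gmap = default_map()
    pen = None
    hits = 0
    for rep in range(n_reps):
        cross = simulate_cross(gmap=gmap, n_f2=n_f2, qtl=truth, env_sd=env_sd,
                               sex_effect=0.3, seed=int(rng.integers(2**31)))
        y = cross.phenotypes_f2.phenotype.to_numpy()
        probs = genotype_probabilities(cross, step_cM=2.0)
        if pen is None:
            pen = derive_penalties(probs, y, cross.sex,
                                   n_perm=n_perm_penalties,
                                   seed=int(rng.integers(2**31)))
        model = stepwise_model_search(probs, y, cross.sex, pen, max_qtl=5)
        if model.n_loci != 2:
            continue
        found = sorted(model.loci)
        ok = (found[0][0] == "3" and abs(found[0][1] - 40.0) <= tol_cM
              and found[1][0] == "9" and abs(found[1][1] - 30.0) <= tol_cM)
        hits += ok
    return hits / n_reps


def planted_variance_recovery(n_f2: int = 2000, additive: float = 1.0,
                              env_sd: float = 1.0, n_reps: int = 5,
                              seed: int = 0) -> float:
    """% variance attributed to a planted locus (truth: a²/2 / (a²/2 + σ²)).

    The QTL sits on a typed marker — between markers the expected-genotype
    regressor is attenuated by construction and the attributed variance
    would measure map geometry rather than the estimator.  The estimate is
    averaged over ``n_reps`` independent crosses (a single cross of 2000
    animals leaves ~2.3 points of sampling noise on a 33-point quantity).
    """
    rng = np.random.default_rng(seed)
    gmap = default_map()
    chrom = gmap.chromosomes[4]
    target = chrom.marker_pos[len(chrom.marker_pos) // 2]
    out = []
    for _ in range(n_reps):
        cross = simulate_cross(gmap=gmap, n_f2=n_f2,
                               qtl=[PlantedQTL(chrom.name, target,
                                               additive=additive)],
                               env_sd=env_sd, seed=int(rng.integers(2**31)))
        y = cross.phenotypes_f2.phenotype.to_numpy()
        probs = genotype_probabilities(cross, step_cM=2.0)
        res = scan_one_ehk(probs, y, sex=None, mode="additive-covariate",
                           method="hk")
        cname, pos, _ = res.max()
        store = LocusStore(probs)
        terms = variance_explained(QTLModel(loci=[(cname, pos)]), store, y,
                                   sex=None)
        out.append(float(terms.pct_var.iloc[0]))
    return float(np.mean(out))


# --- analytic morphometry ------------------------------------------------------

def digital_ellipsoid_stretch(semi_axes: tuple[float, float, float]) -> float:
    """Stretch of a rasterized solid ellipsoid (voxel-center inclusion)."""
    a = max(semi_axes)
    n = int(2 * a + 6)
    zz, yy, xx = np.meshgrid(*[np.arange(n) + 0.5] * 3, indexing="ij")
    c = n / 2
    m = ((zz - c) / semi_axes[0]) ** 2 + ((yy - c) / semi_axes[1]) ** 2 \
        + ((xx - c) / semi_axes[2]) ** 2 <= 1
    comp = PoreComponent(id=1, cls="lacuna", voxels=np.argwhere(m),
                         border_touching=False)
    return object_shape_metrics(comp, 1.0).stretch


def cylinder_thickness_voxels(outer: float = 40.0, inner: float = 30.0) -> tuple[float, float]:
    """(mean, sd) radial thickness of a concentric shell, in voxels."""
    spec = PhantomSpec(outer_radius=outer, inner_radius=inner, height=20,
                       n_lacunae=0, n_canals=0, seed=0)
    seg = segment_phases(generate_phantom(spec), 110)
    mean, sd = radial_cortical_thickness(seg)
    return mean / spec.voxel_size_um, sd / spec.voxel_size_um


def lattice_oblateness_signs() -> tuple[float, float]:
    """(prolate-spacing Ob, oblate-spacing Ob) on planted lattices."""
    from .morphometry import distribution_oblateness

    def lattice(sp, n=8):
        g = np.meshgrid(*[np.arange(n) * s for s in sp], indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1).astype(float)

    prolate = distribution_oblateness(lattice((10, 2, 2))).value
    oblate = distribution_oblateness(lattice((2, 10, 10))).value
    return float(prolate), float(oblate)


# --- end-to-end conservation ---------------------------------------------------

def _ground_truth_segmentation(volume) -> PhaseSegmentation:
    gt = volume.ground_truth
    shape = np.array(gt.phase_labels.shape)
    comps = []
    for _, o in gt.objects.iterrows():
        coords = np.argwhere(gt.object_labels == o.id)
        border = bool((coords == 0).any() or (coords == shape - 1).any())
        comps.append(PoreComponent(id=int(o.id), cls=o.cls, voxels=coords,
                                   border_touching=border))
    return PhaseSegmentation(phase_labels=gt.phase_labels,
                             voxel_size_um=volume.voxel_size_um,
                             components=comps)


def end_to_end_phenotype_errors(seed: int = 1) -> dict[str, float]:
    """Relative error of each pipeline phenotype against phantom ground truth.

    A noise-free phantom is measured twice: once through the full
    segment→label→morphometry pipeline, once with the ground-truth labels
    fed to the same morphometry.  Oblateness, which lives on a [−1, 1]
    scale, is compared by absolute difference.
    """
    vol = generate_phantom(PhantomSpec(seed=seed))
    pipe = assemble_phenotypes(label_components(segment_phases(vol, "otsu")))
    truth = assemble_phenotypes(_ground_truth_segmentation(vol))
    errors = {}
    for name in ("ct_th_r_um", "ct_th_r_sd_um", "ca_dn_per_mm3",
                 "lc_dn_per_mm3", "lc_v_um3", "lc_st"):
        errors[name] = abs(pipe[name] - truth[name]) / abs(truth[name])
    errors["lc_dt_ob"] = abs(pipe["lc_dt_ob"] - truth["lc_dt_ob"])
    return errors
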