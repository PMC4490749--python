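"""Multiple-QTL model selection with permutation-derived penalties.

The model space is the set of loci on the genotype-probability grid with
additive + dominance effects per locus, pairwise QTL×QTL interactions
("heavy") and QTL×sex interactions ("light").  Models are compared by the
penalized LOD

    pLOD = LOD − T_main·(#loci) − T_heavy·(#QTL×QTL) − T_light·(#QTL×sex),

with the penalties taken from the null distribution of two-locus
permutation scans: T_main is the 1−α quantile of the genome-wide maximum
single-locus LOD, T_heavy of (max full two-locus LOD − max single LOD), and
T_light of (max full − max additive two-locus LOD).  A forward/backward
search over this criterion returns the best model visited, or the empty
model when nothing beats pLOD = 0.

Multiple-QTL model fits use Haley–Knott regression on the expected genotype
scores; the extended (variance-inflation) form is used for the single-locus
scans that feed the search.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..crosssim import CrossData
from .hmm import GenotypeProbabilities, genotype_probabilities
from .scan import (_base_matrix, _solve_batched, _stratified_permutations,
                   ehk_lod_engine, genotype_scores)

_LN10 = np.log(10.0)


@dataclass
class PenaltySet:
    T_main: float
    T_heavy: float
    T_light: float
    alpha: float = 0.05
    n_perm: int = 0
    scaled_down: bool = False  # n_perm below the reference 1000

    def __post_init__(self):
        if self.T_main <= 0:
            raise ValueError("T_main must be > 0")
        if not (self.T_heavy >= self.T_light >= 0):
            raise ValueError("penalties must satisfy T_heavy >= T_light >= 0")


@dataclass
class QTLModel:
    """A multiple-QTL model: loci, effects, interactions and fit summaries."""

    loci: list[tuple[str, float]] = field(default_factory=list)
    additive: list[float] = field(default_factory=list)
    dominance: list[float] = field(default_factory=list)
    interactions: list[tuple[int, int]] = field(default_factory=list)
    sex_interactions: list[int] = field(default_factory=list)
    lod: float = 0.0
    penalized_lod: float = 0.0
    terms: pd.DataFrame | None = None          # per-term %var and dropped LOD
    support_intervals: list[tuple[float, float]] = field(default_factory=list)
    lod_curves: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    store: "LocusStore | None" = None          # genotype scores incl. refined positions

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, (c, p) in enumerate(self.loci):
            rows.append(dict(
                chromosome=c, position_cM=p,
                additive=self.additive[i] if self.additive else np.nan,
                dominance=self.dominance[i] if self.dominance else np.nan,
                ci_lo=self.support_intervals[i][0] if self.support_intervals else np.nan,
                ci_hi=self.support_intervals[i][1] if self.support_intervals else np.nan,
            ))
        return pd.DataFrame(rows)


class LocusStore:
    """Expected genotype scores x̂, ẑ at grid (and refined) positions."""

    def __init__(self, probs: GenotypeProbabilities):
        self.probs = probs
        xz, V, labels = genotype_scores(probs)
        self.xz, self.V, self.labels = xz, V, labels
        self._index = {(c, round(p, 4)): i for i, (c, p) in enumerate(labels)}
        self._extra: dict[tuple[str, float], np.ndarray] = {}

    def add(self, chrom: str, pos: float, xz: np.ndarray) -> None:
        self._extra[(chrom, round(pos, 4))] = xz

    def get(self, chrom: str, pos: float) -> np.ndarray:
        key = (chrom, round(pos, 4))
        if key in self._extra:
            return self._extra[key]
        i = self._index.get(key)
        if i is None:
            raise KeyError(f"no genotype probabilities at chr {chrom} {pos} cM")
        return self.xz[i]  # (n, 2)


def _model_design(store: LocusStore, model: QTLModel, sex: np.ndarray | None,
                  n: int, positions: list[tuple[str, float]] | None = None):
    """(n, p) design for a model; ``positions`` overrides the locus list."""
    base = _base_matrix(n, sex)
    cols = [base]
    loci = positions if positions is not None else model.loci
    locus_xz = [store.get(c, p) for c, p in loci]
    for xz in locus_xz:
        cols.append(xz)
    for (i, j) in model.interactions:
        xi, zi = locus_xz[i][:, 0], locus_xz[i][:, 1]
        xj, zj = locus_xz[j][:, 0], locus_xz[j][:, 1]
        cols.append(np.column_stack([xi * xj, xi * zj, zi * xj, zi * zj]))
    for i in model.sex_interactions:
        cols.append(locus_xz[i] * np.asarray(sex, float)[:, None])
    return np.concatenate(cols, axis=1)


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(max(r @ r, 1e-300))


def fit_model(store: LocusStore, model: QTLModel, y: np.ndarray,
              sex: np.ndarray | None) -> tuple[float, np.ndarray, float]:
    """(LOD, coefficients, RSS) of a multiple-QTL Haley–Knott fit."""
    n = len(y)
    base = _base_matrix(n, sex)
    rss0 = _ols_rss(base, y)
    if model.n_loci == 0:
        return 0.0, np.zeros(base.shape[1]), rss0
    X = _model_design(store, model, sex, n)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(max(((y - X @ beta) ** 2).sum(), 1e-300))
    lod = 0.5 * n * np.log10(rss0 / rss)
    return float(lod), beta, rss


def penalized_lod(lod: float, model: QTLModel, pen: PenaltySet) -> float:
    return (lod - pen.T_main * model.n_loci
            - pen.T_heavy * len(model.interactions)
            - pen.T_light * len(model.sex_interactions))


# --- penalties from two-locus permutations ------------------------------------

def _coarse_indices(probs: GenotypeProbabilities, grid_step: float) -> np.ndarray:
    """Indices into the stacked positions nearest multiples of grid_step."""
    idx = []
    offset = 0
    for c in probs.chromosomes:
        pos = c.positions
        if len(pos) < 2:
            raise ValueError(f"grid too coarse on chromosome {c.name}: "
                             "need >= 2 positions per chromosome")
        targets = np.arange(0.0, pos[-1] + grid_step / 2, grid_step)
        near = np.unique(np.searchsorted(pos, targets).clip(0, len(pos) - 1))
        idx.extend(offset + near)
        offset += len(pos)
    return np.unique(np.array(idx, dtype=int))


def derive_penalties(
    probs: GenotypeProbabilities,
    phenotype: np.ndarray,
    sex: np.ndarray | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    grid_step_cM: float = 10.0,
    pair_chunk: int = 1024,
) -> PenaltySet:
    """Main-effect and interaction penalties from two-locus null scans.

    Each permutation (stratified by sex) is scanned over all cross-chromosome
    position pairs of a ``grid_step_cM`` coarse grid, recording the maxima of
    the full (interacting), additive and single-locus LODs; the penalties are
    the 1−alpha quantiles described in the module docstring.  Two-locus fits
    use plain Haley–Knott regression.
    """
    if len({c.name for c in probs.chromosomes}) < 2:
        raise ValueError("penalties require at least 2 chromosomes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, float)
    n = len(y)
    base = _base_matrix(n, sex)
    qb = base.shape[1]
    xz_all, V_all, labels = genotype_scores(probs)
    cid = _coarse_indices(probs, grid_step_cM)
    xz = xz_all[cid]
    chrom_of = np.array([labels[i][0] for i in cid])

    perms = _stratified_permutations(y, sex, n_perm, rng)
    # single-locus maxima on the coarse grid (plain HK, same fits as the 2D scan)
    lod1 = ehk_lod_engine(perms, base, xz, V_all[cid], sex=sex, interactive=False,
                          method="hk")
    max_single = lod1.max(axis=1)

    Q, _ = np.linalg.qr(base)
    rss0 = np.maximum(((perms - (perms @ Q) @ Q.T) ** 2).sum(axis=1), 1e-300)
    yy_proj = perms  # alias for clarity below

    pairs = [(i, j) for i, j in itertools.combinations(range(len(cid)), 2)
             if chrom_of[i] != chrom_of[j]]
    pairs = np.array(pairs)
    max_full = np.zeros(n_perm)
    max_add = np.zeros(n_perm)
    for s0 in range(0, len(pairs), pair_chunk):
        pi = pairs[s0:s0 + pair_chunk]
        C = len(pi)
        Xf = np.empty((C, n, qb + 8))
        Xf[:, :, :qb] = base[None]
        xi, xj = xz[pi[:, 0]], xz[pi[:, 1]]  # (C, n, 2)
        Xf[:, :, qb:qb + 2] = xi
        Xf[:, :, qb + 2:qb + 4] = xj
        Xf[:, :, qb + 4] = xi[:, :, 0] * xj[:, :, 0]
        Xf[:, :, qb + 5] = xi[:, :, 0] * xj[:, :, 1]
        Xf[:, :, qb + 6] = xi[:, :, 1] * xj[:, :, 0]
        Xf[:, :, qb + 7] = xi[:, :, 1] * xj[:, :, 1]
        for cols, acc in ((qb + 8, max_full), (qb + 4, max_add)):
            Xs = Xf[:, :, :cols]
            XtX = np.einsum("cnk,cnl->ckl", Xs, Xs, optimize=True)
            XtY = np.einsum("cnk,mn->mck", Xs, yy_proj, optimize=True)
            beta = _solve_batched(XtX[None], XtY)
            rss = np.maximum((perms**2).sum(axis=1)[:, None]
                             - np.einsum("mck,mck->mc", beta, XtY), 1e-300)
            lod = 0.5 * n * np.log10(rss0[:, None] / rss)
            np.maximum(acc, lod.max(axis=1), out=acc)

    q = lambda v: float(np.quantile(v, 1.0 - alpha, method="linear"))
    return PenaltySet(
        T_main=q(max_single),
        T_heavy=max(q(max_full - max_single), 0.0),
        T_light=min(max(q(max_full - max_add), 0.0), max(q(max_full - max_single), 0.0)),
        alpha=alpha, n_perm=n_perm, scaled_down=n_perm < 1000,
    )


# --- stepwise search -----------------------------------------------------------

def _clone(model: QTLModel) -> QTLModel:
    return QTLModel(loci=list(model.loci), interactions=list(model.interactions),
                    sex_interactions=list(model.sex_interactions))


def stepwise_model_search(
    probs: GenotypeProbabilities,
    phenotype: np.ndarray,
    sex: np.ndarray | None = None,
    penalties: PenaltySet | None = None,
    max_qtl: int = 10,
    consider_interactions: bool = True,
) -> QTLModel:
    """Forward/backward search maximizing the penalized LOD.

    Forward steps greedily add the best locus (a fresh genome scan with the
    current model as covariates) or the best pairwise/sex interaction until
    ``max_qtl`` loci; backward steps then delete the least useful term down
    to the empty model.  The best model visited anywhere is returned; when
    nothing beats pLOD = 0 the empty model is returned.
    """
    if penalties is None:
        raise ValueError("penalties are required")
    y = np.asarray(phenotype, float)
    n = len(y)
    store = LocusStore(probs)
    base = _base_matrix(n, sex)

    best = QTLModel()
    best_plod = 0.0
    model = QTLModel()
    model_lod = 0.0

    def consider(cand: QTLModel) -> tuple[float, float]:
        lod, _, _ = fit_model(store, cand, y, sex)
        return lod, penalized_lod(lod, cand, penalties)

    # forward
    while model.n_loci < max_qtl:
        cands: list[tuple[float, float, QTLModel]] = []
        # add a locus: scan with current model as covariates
        covar = (_model_design(store, model, sex, n) if model.n_loci
                 else base)
        delta = ehk_lod_engine(y[None], covar, store.xz, store.V, sex=sex,
                               interactive=False, method="hk")[0]
        i_best = int(np.argmax(delta))
        c_new, p_new = store.labels[i_best]
        cand = _clone(model)
        cand.loci.append((c_new, p_new))
        lod, plod = consider(cand)
        cands.append((plod, lod, cand))
        if consider_interactions:
            for (i, j) in itertools.combinations(range(model.n_loci), 2):
                if (i, j) in model.interactions:
                    continue
                cand = _clone(model)
                cand.interactions.append((i, j))
                lod, plod = consider(cand)
                cands.append((plod, lod, cand))
            if sex is not None and np.ptp(sex) > 0:
                for i in range(model.n_loci):
                    if i in model.sex_interactions:
                        continue
                    cand = _clone(model)
                    cand.sex_interactions.append(i)
                    lod, plod = consider(cand)
                    cands.append((plod, lod, cand))
        plod, model_lod, model = max(cands, key=lambda t: t[0])
        if plod > best_plod:
            best, best_plod = _clone(model), plod
        if plod < best_plod - 2 * penalties.T_main:
            break  # far below the best: adding more will not recover

    # backward
    while model.n_loci > 0 or model.interactions or model.sex_interactions:
        cands = []
        for k in range(len(model.interactions)):
            cand = _clone(model)
            cand.interactions.pop(k)
            lod, plod = consider(cand)
            cands.append((plod, lod, cand))
        for k in range(len(model.sex_interactions)):
            cand = _clone(model)
            cand.sex_interactions.pop(k)
            lod, plod = consider(cand)
            cands.append((plod, lod, cand))
        for i in range(model.n_loci):
            cand = QTLModel(
                loci=[l for k, l in enumerate(model.loci) if k != i],
                interactions=[(a - (a > i), b - (b > i))
                              for a, b in model.interactions if i not in (a, b)],
                sex_interactions=[a - (a > i) for a in model.sex_interactions
                                  if a != i],
            )
            lod, plod = consider(cand)
            cands.append((plod, lod, cand))
        if not cands:
            break
        plod, model_lod, model = max(cands, key=lambda t: t[0])
        if plod > best_plod:
            best, best_plod = _clone(model), plod

    if best_plod <= 0.0:
        return QTLModel()
    lod, beta, _ = fit_model(store, best, y, sex)
    best.lod = lod
    best.penalized_lod = best_plod
    qb = base.shape[1]
    best.additive = [float(beta[qb + 2 * i]) for i in range(best.n_loci)]
    best.dominance = [float(beta[qb + 2 * i + 1]) for i in range(best.n_loci)]
    return best


# --- support intervals, variance attribution, refinement -----------------------

def lod_support_interval(positions_cM: np.ndarray, lod: np.ndarray,
                         drop: float = 1.5) -> tuple[float, float]:
    """Positions spanning all grid points with LOD within ``drop`` of the peak.

    The standard approximate 95% confidence region for QTL location in an
    intercross uses drop = 1.5.  A flat zero curve returns the whole
    chromosome with a warning.
    """
    positions_cM = np.asarray(positions_cM, float)
    lod = np.asarray(lod, float)
    peak = lod.max()
    if peak <= 0:
        warnings.warn("flat zero LOD curve: support interval is the whole chromosome",
                      stacklevel=2)
        return float(positions_cM[0]), float(positions_cM[-1])
    keep = np.flatnonzero(lod >= peak - drop)
    return float(positions_cM[keep[0]]), float(positions_cM[keep[-1]])


def variance_explained(
    model: QTLModel,
    probs: GenotypeProbabilities | LocusStore,
    phenotype: np.ndarray,
    sex: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-term % variance explained and dropped LOD.

    Each locus (with any interaction involving it) and each interaction term
    is removed in turn and the model refit; %var = 100·(RSS_red − RSS_full)/TSS
    and dropped LOD = LOD_full − LOD_reduced, the convention used when
    reporting per-locus contributions of a multiple-QTL model.
    """
    if model.n_loci == 0:
        raise ValueError("model is empty")
    if isinstance(probs, LocusStore):
        store = probs
    elif model.store is not None:
        store = model.store
    else:
        store = LocusStore(probs)
    y = np.asarray(phenotype, float)
    tss = float(((y - y.mean()) ** 2).sum())
    lod_full, _, rss_full = fit_model(store, model, y, sex)
    rows = []
    for i, (c, p) in enumerate(model.loci):
        red = QTLModel(
            loci=[l for k, l in enumerate(model.loci) if k != i],
            interactions=[(a - (a > i), b - (b > i))
                          for a, b in model.interactions if i not in (a, b)],
            sex_interactions=[a - (a > i) for a in model.sex_interactions if a != i],
        )
        lod_red, _, rss_red = fit_model(store, red, y, sex)
        rows.append(dict(term=f"{c}@{p:g}", kind="locus",
                         pct_var=100.0 * (rss_red - rss_full) / tss,
                         dropped_lod=lod_full - lod_red))
    for k, (a, b) in enumerate(model.interactions):
        red = _clone(model)
        red.interactions.pop(k)
        lod_red, _, rss_red = fit_model(store, red, y, sex)
        rows.append(dict(term=f"{model.loci[a][0]}@{model.loci[a][1]:g}:"
                              f"{model.loci[b][0]}@{model.loci[b][1]:g}",
                         kind="interaction",
                         pct_var=100.0 * (rss_red - rss_full) / tss,
                         dropped_lod=lod_full - lod_red))
    df = pd.DataFrame(rows)
    model.terms = df
    return df


def refine_positions(
    model: QTLModel,
    cross: CrossData,
    phenotype: np.ndarray,
    sex: np.ndarray | None = None,
    probs: GenotypeProbabilities | None = None,
    step_cM: float = 0.1,
    window_cM: float = 15.0,
    drop: float = 1.5,
) -> QTLModel:
    """Re-optimize each locus position on a ``step_cM`` grid near its locus.

    Holding the other loci fixed, the model LOD is profiled over a dense
    position grid within ``window_cM`` of each locus (one pass over loci, in
    order); the refined model, per-locus LOD curves and drop-based support
    intervals are returned.  Refinement never decreases the model LOD.
    """
    if model.n_loci == 0:
        raise ValueError("model is empty")
    y = np.asarray(phenotype, float)
    n = len(y)
    if probs is None:
        probs = genotype_probabilities(cross)
    store = model.store if model.store is not None else LocusStore(probs)
    base = _base_matrix(n, sex)
    rss0 = _ols_rss(base, y)

    refined = _clone(model)
    curves: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    intervals: list[tuple[float, float]] = []
    for i, (cname, pos) in enumerate(refined.loci):
        chrom = next(c for c in cross.map.chromosomes if c.name == cname)
        lo = max(0.0, pos - window_cM)
        hi = min(chrom.length_cM, pos + window_cM)
        dense = np.round(np.arange(lo, hi + step_cM / 2, step_cM), 6)
        dprobs = genotype_probabilities(cross, step_cM=probs.step_cM,
                                        error_rate=probs.error_rate,
                                        positions={cname: dense})
        cp = next(c for c in dprobs.chromosomes if c.name == cname)
        pAA, pAB, pBB = cp.probs[..., 0], cp.probs[..., 1], cp.probs[..., 2]
        xz_dense = np.stack([pBB - pAA, pAB], axis=-1).transpose(1, 0, 2)
        for j, q in enumerate(cp.positions):
            store.add(cname, float(q), xz_dense[j])

        lods = np.empty(len(cp.positions))
        for j, q in enumerate(cp.positions):
            cand_loci = list(refined.loci)
            cand_loci[i] = (cname, float(q))
            X = _model_design(store, refined, sex, n, positions=cand_loci)
            rss = _ols_rss(X, y)
            lods[j] = 0.5 * n * np.log10(rss0 / rss)
        j_best = int(np.argmax(lods))
        cur_j = int(np.argmin(np.abs(cp.positions - pos)))
        if lods[j_best] >= lods[cur_j]:
            refined.loci[i] = (cname, float(cp.positions[j_best]))
        curves[i] = (cp.positions.copy(), lods)
        intervals.append(lod_support_interval(cp.positions, lods, drop=drop))

    lod, beta, _ = fit_model(store, refined, y, sex)
    refined.lod = lod
    qb = base.shape[1]
    refined.additive = [float(beta[qb + 2 * k]) for k in range(refined.n_loci)]
    refined.dominance = [float(beta[qb + 2 * k + 1]) for k in range(refined.n_loci)]
    refined.lod_curves = curves
    refined.support_intervals = intervals
    refined.penalized_lod = model.penalized_lod + (lod - model.lod)
    refined.store = store
    return refined
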