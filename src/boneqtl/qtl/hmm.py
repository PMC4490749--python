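"""Hidden-Markov genotype probabilities for an F2 intercross.

At any point of a grid laid over each chromosome, the genotype of an F2
individual is a hidden state in {AA, AB, BB} with prior (1/4, 1/2, 1/4).
Adjacent points d cM apart are linked by the two-gamete transition matrix
built from the Haldane recombination fraction r(d); marker observations
enter through an emission model with a symmetric genotyping-error rate.
Forward–backward gives the marginal posterior triple at every grid point;
posterior path sampling provides imputation draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..crosssim import AA, AB, BB, MISSING, CrossData, GeneticMap, haldane_r

F2_PRIOR = np.array([0.25, 0.5, 0.25])


def f2_transition(r: float) -> np.ndarray:
    """3×3 genotype transition matrix for recombination fraction r.

    The two gametes recombine independently, so e.g.
    P(AA→AA) = (1−r)², P(AA→AB) = 2r(1−r), P(AB→AB) = (1−r)² + r².
    """
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


def _emission(obs: np.ndarray, error_rate: float) -> np.ndarray:
    """(n, 3) emission likelihoods for observed codes (MISSING → uniform)."""
    n = len(obs)
    em = np.full((n, 3), 1.0)
    typed = obs != MISSING
    em[typed] = error_rate / 2.0
    em[typed, obs[typed]] = 1.0 - error_rate
    return em


@dataclass
class ChromosomeProbs:
    name: str
    positions: np.ndarray          # grid positions in cM (markers included)
    probs: np.ndarray              # (n_individuals, n_positions, 3)
    marker_index: np.ndarray       # indices of map markers within positions


@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on a cM grid, per chromosome."""

    chromosomes: list[ChromosomeProbs]
    step_cM: float
    error_rate: float

    def stacked(self) -> tuple[np.ndarray, list[tuple[str, float]]]:
        """All positions genome-wide: ((n, P, 3) array, [(chrom, cM), ...])."""
        arrs, labels = [], []
        for c in self.chromosomes:
            arrs.append(c.probs)
            labels += [(c.name, float(p)) for p in c.positions]
        return np.concatenate(arrs, axis=1), labels


def grid_positions(length_cM: float, marker_pos: np.ndarray, step_cM: float) -> np.ndarray:
    """Union of an even step grid over [0, length] with the marker positions."""
    grid = np.arange(0.0, length_cM + step_cM / 2, step_cM)
    grid = grid[grid <= length_cM]
    return np.unique(np.round(np.concatenate([grid, marker_pos]), 6))


def genotype_probabilities(
    cross: CrossData,
    step_cM: float = 2.0,
    error_rate: float = 1e-4,
    positions: dict[str, np.ndarray] | None = None,
) -> GenotypeProbabilities:
    """Forward–backward posteriors at every grid point of every chromosome.

    ``positions`` overrides the grid per chromosome (used by the 0.1 cM
    refinement stage); map markers are always included in the grid.
    """
    chroms = []
    col0 = 0
    for chrom in cross.map.chromosomes:
        mpos = np.asarray(chrom.marker_pos, float)
        if np.any(np.diff(mpos) <= 0):
            raise ValueError(f"non-increasing marker positions on chr {chrom.name}")
        ncols = len(mpos)
        obs = cross.genotypes[:, col0:col0 + ncols]
        col0 += ncols
        if positions is not None and chrom.name in positions:
            pos = np.unique(np.round(np.concatenate([positions[chrom.name], mpos]), 6))
        else:
            pos = grid_positions(chrom.length_cM, mpos, step_cM)
        probs, midx = _chromosome_posteriors(pos, mpos, obs, error_rate)
        chroms.append(ChromosomeProbs(name=chrom.name, positions=pos,
                                      probs=probs, marker_index=midx))
    return GenotypeProbabilities(chromosomes=chroms, step_cM=step_cM,
                                 error_rate=error_rate)


def _position_emissions(pos, marker_pos, obs, error_rate):
    """(n, P, 3) per-position emissions (uniform at non-marker positions)."""
    n = obs.shape[0]
    P = len(pos)
    em = np.ones((n, P, 3))
    midx = np.searchsorted(pos, np.round(marker_pos, 6))
    for j, mj in enumerate(midx):
        em[:, mj, :] = _emission(obs[:, j], error_rate)
    return em, midx


def _chromosome_posteriors(pos, marker_pos, obs, error_rate):
    """Vectorized forward–backward over individuals for one chromosome."""
    em, midx = _position_emissions(pos, marker_pos, obs, error_rate)
    n, P, _ = em.shape
    trans = [f2_transition(float(haldane_r(d))) for d in np.diff(pos)]

    fwd = np.empty((n, P, 3))
    a = F2_PRIOR[None, :] * em[:, 0]
    norm = a.sum(axis=1, keepdims=True)
    fwd[:, 0] = a / norm
    for j in range(1, P):
        a = (fwd[:, j - 1] @ trans[j - 1]) * em[:, j]
        a /= a.sum(axis=1, keepdims=True)
        fwd[:, j] = a

    bwd = np.empty((n, P, 3))
    bwd[:, P - 1] = 1.0
    for j in range(P - 2, -1, -1):
        b = (bwd[:, j + 1] * em[:, j + 1]) @ trans[j].T
        b /= b.sum(axis=1, keepdims=True)
        bwd[:, j] = b

    post = fwd * bwd
    post /= post.sum(axis=2, keepdims=True)
    return post, midx


def posterior_draws(
    cross: CrossData,
    probs: GenotypeProbabilities,
    n_draws: int = 128,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Sample genotype paths from the joint posterior (backward sampling).

    Returns per chromosome an (n_draws, n_individuals, n_positions) int8
    array of genotype codes.  Draws are used for imputation-style scanning;
    their empirical frequencies converge to the forward–backward marginals.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    col0 = 0
    for chrom, cp in zip(cross.map.chromosomes, probs.chromosomes):
        mpos = np.asarray(chrom.marker_pos, float)
        ncols = len(mpos)
        obs = cross.genotypes[:, col0:col0 + ncols]
        col0 += ncols
        em, _ = _position_emissions(cp.positions, mpos, obs, probs.error_rate)
        n, P, _ = em.shape
        trans = [f2_transition(float(haldane_r(d))) for d in np.diff(cp.positions)]

        fwd = np.empty((n, P, 3))
        a = F2_PRIOR[None, :] * em[:, 0]
        fwd[:, 0] = a / a.sum(axis=1, keepdims=True)
        for j in range(1, P):
            a = (fwd[:, j - 1] @ trans[j - 1]) * em[:, j]
            fwd[:, j] = a / a.sum(axis=1, keepdims=True)

        draws = np.empty((n_draws, n, P), dtype=np.int8)
        u = rng.random((n_draws, n, P))
        # sample last position from the filtered marginal
        cdf = np.cumsum(fwd[:, P - 1], axis=1)
        draws[:, :, P - 1] = (u[:, :, P - 1, None] > cdf[None, :, :]).sum(axis=2)
        for j in range(P - 2, -1, -1):
            # P(state_j | state_{j+1}, data) ∝ fwd_j * trans[:, next]
            w = fwd[:, j][None, :, :] * trans[j].T[draws[:, :, j + 1]]
            w /= w.sum(axis=2, keepdims=True)
            cdf = np.cumsum(w, axis=2)
            draws[:, :, j] = (u[:, :, j, None] > cdf).sum(axis=2)
        out[cp.name] = draws
    return out


# --- independent oracle --------------------------------------------------------

def enumerate_posterior(
    positions_cM: np.ndarray,
    observed: np.ndarray,
    error_rate: float = 0.0,
) -> np.ndarray:
    """Brute-force posterior by enumerating both gametes' allele patterns.

    For one individual and one chromosome with positions ``positions_cM``
    and observed codes ``observed`` (MISSING allowed), enumerate all
    2^M × 2^M gamete configurations under the Haldane Markov chain, apply
    the emission model, and return the (M, 3) posterior.  Exponential in M:
    intended as an oracle for chromosomes with few positions.
    """
    positions_cM = np.asarray(positions_cM, float)
    M = len(positions_cM)
    r = haldane_r(np.diff(positions_cM))
    patterns = np.array(np.meshgrid(*[[0, 1]] * M, indexing="ij")).reshape(M, -1).T

    def gamete_prob(pat):
        p = 0.5
        for j in range(M - 1):
            p *= r[j] if pat[j] != pat[j + 1] else 1 - r[j]
        return p

    gp = np.array([gamete_prob(p) for p in patterns])
    post = np.zeros((M, 3))
    for i1, g1 in enumerate(patterns):
        for i2, g2 in enumerate(patterns):
            geno = g1 + g2
            like = gp[i1] * gp[i2]
            for j in range(M):
                if observed[j] == MISSING:
                    continue
                like *= (1 - error_rate) if geno[j] == observed[j] else error_rate / 2
            for j in range(M):
                post[j, geno[j]] += like
    return post / post.sum(axis=1, keepdims=True)
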