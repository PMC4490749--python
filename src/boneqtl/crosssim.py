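"""Simulation of an F2 intercross between two inbred strains.

Provides the genetic ground truth for the mapping machinery: a genetic map
(by default 19 mouse-like autosomes carrying 98 microsatellite-style
markers), F2 genotypes simulated as two independent gametes per individual
with Haldane (no-interference) recombination, phenotypes built from planted
QTL with additive/dominance/epistatic effects plus a sex effect, and an F1
cohort of genetically identical animals whose variance is purely
environmental.  Genotype codes follow the usual intercross convention
AA/AB/BB with AA homozygous for the first parental strain.

Default cohort sizes are 755 F2 and 12 F1 animals, the analyzed cohort of
the study design this package emulates; sex is Bernoulli with P(male)=0.47.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# integer genotype codes used internally; -1 = missing
AA, AB, BB, MISSING = 0, 1, 2, -1
GENO_STR = {AA: "AA", AB: "AB", BB: "BB", MISSING: "-"}
STR_GENO = {v: k for k, v in GENO_STR.items()}


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for distance d in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_cM: float
    marker_pos: tuple[float, ...]
    marker_names: tuple[str, ...]

    def __post_init__(self):
        pos = np.asarray(self.marker_pos)
        if len(pos) and (np.any(np.diff(pos) <= 0) or pos[0] < 0 or pos[-1] > self.length_cM):
            raise ValueError(f"marker positions on {self.name} must be strictly "
                             "increasing and within [0, length]")


@dataclass(frozen=True)
class GeneticMap:
    chromosomes: tuple[Chromosome, ...]

    @property
    def n_markers(self) -> int:
        return sum(len(c.marker_pos) for c in self.chromosomes)

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.marker_names]

    def total_length_cM(self) -> float:
        return sum(c.length_cM for c in self.chromosomes)


@dataclass(frozen=True)
class PlantedQTL:
    chromosome: str
    position_cM: float
    additive: float = 0.0   # half the AA-BB phenotype difference, sign = BB higher
    dominance: float = 0.0  # deviation of AB from the homozygote midpoint


@dataclass
class CrossData:
    """An F2 cross: map, genotypes, sex, phenotypes and (if simulated) truth."""

    map: GeneticMap
    genotypes: np.ndarray  # (n_f2, n_markers) int codes, -1 missing
    sex: np.ndarray        # (n_f2,) 0 = female, 1 = male
    phenotypes_f2: pd.DataFrame
    phenotypes_f1: pd.DataFrame
    truth: dict = field(default_factory=dict)


# --- default study map: 19 autosomes, 98 markers ------------------------------

_MOUSE_LENGTHS = [98, 103, 82, 88, 90, 79, 89, 76, 75, 77,
                  88, 64, 67, 66, 59, 57, 61, 59, 57]  # cM, mouse-like autosomes


def default_map(n_markers: int = 98, seed: int | None = None) -> GeneticMap:
    """19 autosomes with ``n_markers`` roughly evenly spaced markers.

    Markers are placed deterministically (equal spacing per chromosome with
    chromosomes receiving markers proportionally to length); a seed adds
    uniform jitter to emulate an irregular microsatellite panel.
    """
    lengths = np.asarray(_MOUSE_LENGTHS, dtype=float)
    alloc = np.maximum(2, np.round(n_markers * lengths / lengths.sum()).astype(int))
    while alloc.sum() > n_markers:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_markers:
        alloc[np.argmin(alloc)] += 1
    rng = np.random.default_rng(seed) if seed is not None else None
    chroms = []
    for i, (L, k) in enumerate(zip(lengths, alloc), start=1):
        pos = np.linspace(0, L, k)
        if rng is not None and k > 2:
            jitter = rng.uniform(-0.25, 0.25, size=k - 2) * (L / (k - 1))
            pos[1:-1] = np.sort(pos[1:-1] + jitter)
        names = tuple(f"D{i}M{j + 1}" for j in range(k))
        chroms.append(Chromosome(name=str(i), length_cM=float(L),
                                 marker_pos=tuple(np.round(pos, 3)), marker_names=names))
    return GeneticMap(chromosomes=tuple(chroms))


# --- genotype simulation -------------------------------------------------------

def _simulate_gametes(positions_cM: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Alleles (0/1) carried by n gametes at the given positions (one chromosome).

    Each gamete is a Markov chain along the chromosome: the allele switches
    between adjacent positions with the Haldane recombination fraction.
    """
    m = len(positions_cM)
    out = np.empty((n, m), dtype=np.int8)
    out[:, 0] = rng.integers(0, 2, size=n)
    r = haldane_r(np.diff(positions_cM))
    for j in range(1, m):
        swap = rng.random(n) < r[j - 1]
        out[:, j] = np.where(swap, 1 - out[:, j - 1], out[:, j - 1])
    return out


def simulate_f2_genotypes(
    gmap: GeneticMap,
    n_individuals: int,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    extra_positions: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Simulate F2 genotypes at the map markers (plus optional extra loci).

    Returns ``(observed, hidden)``: the marker genotype matrix with entries
    masked at ``missing_rate``, and a dict of the complete (unmasked) true
    genotypes per chromosome including ``extra_positions`` (used to plant
    off-marker QTL).  Each individual is the union of two independent
    gametes, each a Haldane Markov walk.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    extra_positions = extra_positions or {}
    observed_cols = []
    hidden: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        extra = np.asarray(extra_positions.get(chrom.name, []), dtype=float)
        allpos = np.union1d(np.asarray(chrom.marker_pos, float), extra)
        g = (_simulate_gametes(allpos, n_individuals, rng)
             + _simulate_gametes(allpos, n_individuals, rng)).astype(np.int8)
        hidden[chrom.name] = np.vstack([allpos, g])  # row 0: positions
        marker_idx = np.searchsorted(allpos, np.asarray(chrom.marker_pos, float))
        observed_cols.append(g[:, marker_idx])
    observed = np.concatenate(observed_cols, axis=1)
    if missing_rate > 0:
        mask = rng.random(observed.shape) < missing_rate
        observed = observed.copy()
        observed[mask] = MISSING
    return observed, hidden


def genotype_at(hidden: dict[str, np.ndarray], chromosome: str, position_cM: float) -> np.ndarray:
    """True simulated genotype codes at a (possibly off-marker) position."""
    block = hidden[chromosome]
    pos, g = block[0], block[1:]
    j = int(np.argmin(np.abs(pos - position_cM)))
    if abs(pos[j] - position_cM) > 1e-6:
        raise KeyError(f"position {position_cM} cM not simulated on chr {chromosome}")
    return g[:, j].astype(int)


# --- phenotype simulation ------------------------------------------------------

def simulate_phenotypes(
    hidden: dict[str, np.ndarray],
    n_individuals: int,
    qtl: list[PlantedQTL],
    env_sd: float = 1.0,
    sex_effect: float = 0.0,
    interactions: list[tuple[int, int, float]] | None = None,
    n_f1: int = 12,
    intercept: float = 0.0,
    p_male: float = 0.47,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Build F2 and F1 phenotypes from planted QTL.

    y = Σ_q (a_q x_q + d_q z_q) + Σ interactions + sex_effect·male + ε with
    x ∈ {−1, 0, +1} for {AA, AB, BB}, z = 1(AB), ε ~ N(0, env_sd²).
    Interactions are ``(i, j, gamma)`` adding ``gamma·x_i·x_j``.  F1 animals
    are genetically identical: intercept + ε only.  Returns
    ``(phenotypes_f2, phenotypes_f1, sex)``.
    """
    if env_sd <= 0:
        raise ValueError("env_sd must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sex = (rng.random(n_individuals) < p_male).astype(int)
    y = np.full(n_individuals, float(intercept))
    xs = []
    for q in qtl:
        g = genotype_at(hidden, q.chromosome, q.position_cM)
        x = g - 1.0          # AA=-1, AB=0, BB=+1
        z = (g == AB).astype(float)
        y += q.additive * x + q.dominance * z
        xs.append(x)
    for (i, j, gamma) in interactions or []:
        y += gamma * xs[i] * xs[j]
    y += sex_effect * sex + rng.normal(0, env_sd, n_individuals)
    y_f1 = intercept + rng.normal(0, env_sd, n_f1)
    return (pd.DataFrame({"phenotype": y}),
            pd.DataFrame({"phenotype": y_f1}),
            sex)


def simulate_cross(
    gmap: GeneticMap | None = None,
    n_f2: int = 755,
    n_f1: int = 12,
    qtl: list[PlantedQTL] | None = None,
    env_sd: float = 1.0,
    sex_effect: float = 0.0,
    interactions: list[tuple[int, int, float]] | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> CrossData:
    """One-call simulation of a complete F2 study (map, genotypes, phenotypes)."""
    rng = np.random.default_rng(seed)
    gmap = gmap or default_map()
    qtl = qtl or []
    extra = {}
    for q in qtl:
        chrom = next(c for c in gmap.chromosomes if c.name == q.chromosome)
        if q.position_cM not in chrom.marker_pos:
            extra.setdefault(q.chromosome, []).append(q.position_cM)
    extra = {k: np.asarray(v) for k, v in extra.items()}
    observed, hidden = simulate_f2_genotypes(gmap, n_f2, missing_rate, rng, extra)
    ph_f2, ph_f1, sex = simulate_phenotypes(hidden, n_f2, qtl, env_sd, sex_effect,
                                            interactions, n_f1=n_f1, seed=rng)
    return CrossData(map=gmap, genotypes=observed, sex=sex,
                     phenotypes_f2=ph_f2, phenotypes_f1=ph_f1,
                     truth=dict(qtl=qtl, env_sd=env_sd, sex_effect=sex_effect,
                                interactions=interactions or [], hidden=hidden))


# --- cross CSV dialect ---------------------------------------------------------

def write_cross_csv(path: str | Path, cross: CrossData) -> None:
    """Write the de-facto intercross CSV: row 1 column names (phenotype and
    sex first, then markers), row 2 chromosome, row 3 cM position, then one
    row per individual."""
    markers = cross.map.marker_names
    chroms = [c.name for c in cross.map.chromosomes for _ in c.marker_pos]
    pos = [p for c in cross.map.chromosomes for p in c.marker_pos]
    pheno_cols = list(cross.phenotypes_f2.columns)
    header = pheno_cols + ["sex"] + markers
    row_chr = [""] * (len(pheno_cols) + 1) + chroms
    row_pos = [""] * (len(pheno_cols) + 1) + [f"{p:g}" for p in pos]
    lines = [",".join(header), ",".join(row_chr), ",".join(row_pos)]
    geno_str = np.vectorize(GENO_STR.get)(cross.genotypes)
    for i in range(len(cross.genotypes)):
        vals = [f"{cross.phenotypes_f2[c].iloc[i]:.17g}" for c in pheno_cols]
        vals.append("M" if cross.sex[i] else "F")
        lines.append(",".join(vals + list(geno_str[i])))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cross_csv(path: str | Path) -> CrossData:
    """Read the cross CSV written by :func:`write_cross_csv`.

    The F1 cohort is not part of the genotype file; ``phenotypes_f1`` comes
    back empty and can be attached separately.
    """
    text = Path(path).read_text().strip().split("\n")
    header = text[0].split(",")
    row_chr = text[1].split(",")
    row_pos = text[2].split(",")
    n_lead = sum(1 for c in row_chr if c == "")
    markers = header[n_lead:]
    chroms_col = row_chr[n_lead:]
    pos_col = np.array([float(p) for p in row_pos[n_lead:]])
    chrom_objs = []
    for name in dict.fromkeys(chroms_col):
        idx = [i for i, c in enumerate(chroms_col) if c == name]
        cpos = pos_col[idx]
        chrom_objs.append(Chromosome(name=name, length_cM=float(cpos[-1]),
                                     marker_pos=tuple(cpos),
                                     marker_names=tuple(markers[i] for i in idx)))
    gmap = GeneticMap(chromosomes=tuple(chrom_objs))
    body = [ln.split(",") for ln in text[3:]]
    pheno_cols = header[: n_lead - 1]
    phen = pd.DataFrame({c: [float(row[j]) for row in body]
                         for j, c in enumerate(pheno_cols)})
    sex = np.array([1 if row[n_lead - 1].upper().startswith("M") else 0 for row in body])
    geno = np.array([[STR_GENO.get(v, MISSING) for v in row[n_lead:]] for row in body],
                    dtype=np.int8)
    return CrossData(map=gmap, genotypes=geno, sex=sex, phenotypes_f2=phen,
                     phenotypes_f1=pd.DataFrame(columns=pheno_cols))
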