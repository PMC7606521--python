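"""Synthetic data with the statistical structure the pipeline assumes.

Generates, from a single parameter set and seed: stationary-model tile
frequencies, Hardy-Weinberg diploid (or inbred haploid) epigenotypes,
noisy tile methylation levels as a three-component mixture around
0 / 0.5 / 1, per-cytosine bisulfite reports with negative-binomial
coverage, SNP tables with tunable correlation to the methylation
calls, and interval sets with controlled overlap. Every generator is a
pure function of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import CallMatrix
from .intervals import IntervalSet
from .io import SnpTable, TileMatrix
from .model import ModelParams, StationaryDensity

_EPS = 1e-12


@dataclass(frozen=True)
class LevelNoise:
    """Beta-shaped tile-level noise around the class centers 0, 0.5, 1.

    Unmethylated levels ~ Beta(1, conc_unmeth) (mode at 0),
    heterozygous ~ Beta(conc_het/2, conc_het/2) (mean 0.5, sd
    0.5/sqrt(conc_het+1)), methylated ~ Beta(conc_meth, 1) (mode at 1).
    The beta family respects the [0, 1] support of methylation levels;
    ``family="normal"`` instead draws clipped normals with
    sd = 1/sqrt(conc) around the exact centers, matching the mixture
    the state caller assumes.
    """

    conc_unmeth: float = 50.0
    conc_het: float = 100.0
    conc_meth: float = 50.0
    family: str = "beta"

    def __post_init__(self):
        if min(self.conc_unmeth, self.conc_het, self.conc_meth) <= 0:
            raise ValueError("concentrations must be positive")
        if self.family not in ("beta", "normal"):
            raise ValueError("family must be 'beta' or 'normal'")


@dataclass(frozen=True)
class CoverageModel:
    """Negative-binomial read depth per cytosine site.

    Defaults (mean 20, dispersion 5) emulate ~20x whole-genome
    bisulfite coverage with realistic overdispersion.
    """

    mean_depth: float = 20.0
    dispersion: float = 5.0

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        p = self.dispersion / (self.dispersion + self.mean_depth)
        return rng.negative_binomial(self.dispersion, p, size=size)


@dataclass(frozen=True)
class SimConfig:
    params: ModelParams = field(
        default_factory=lambda: ModelParams.from_scaled(0.72, 0.036, 8.0,
                                                        50_000))
    n_tiles: int = 5000
    n_individuals: int = 20
    ploidy_mode: str = "outbred"
    noise: LevelNoise = LevelNoise()
    coverage: CoverageModel = CoverageModel()
    sites_per_tile: int = 10
    tile_size: int = 100
    context: str = "CG"
    chrom: str = "sim1"
    seed: int = 0


def simulate_tile_frequencies(params: ModelParams, n_tiles: int,
                              seed: int, grid_order: int = 2048) -> np.ndarray:
    """Draw methylated-epiallele frequencies from the stationary density.

    Sampling is by inverse CDF on the Gauss-Jacobi quadrature grid of
    the normalized density; the grid resolves the endpoint
    singularities, and returned values lie strictly inside (0, 1).
    """
    rng = np.random.default_rng(seed)
    dens = StationaryDensity(params)
    nodes, cdf = dens.cdf_grid(order=grid_order)
    u = rng.random(n_tiles)
    q = np.interp(u, cdf, nodes)
    return np.clip(q, _EPS, 1 - _EPS)


def simulate_genotypes(q: np.ndarray, n_individuals: int,
                       ploidy_mode: str = "outbred", seed: int = 0,
                       tile_size: int = 100,
                       chrom: str = "sim1") -> CallMatrix:
    """True epigenotypes under Hardy-Weinberg (outbred, Binomial(2, q))
    or haploid inbred sampling (Bernoulli(q))."""
    rng = np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    n_draw = 2 if ploidy_mode == "outbred" else 1
    calls = rng.binomial(n_draw, q[:, None],
                         size=(len(q), n_individuals)).astype(float)
    tiles = [(chrom, i * tile_size) for i in range(len(q))]
    individuals = [f"ind{j:03d}" for j in range(n_individuals)]
    return CallMatrix(tiles, individuals, calls, ploidy_mode)


def simulate_tile_levels(true_states: CallMatrix,
                         noise: LevelNoise = LevelNoise(),
                         seed: int = 0, tile_size: int = 100,
                         context: str = "CG") -> TileMatrix:
    """Noisy tile methylation levels given true epigenotypes."""
    rng = np.random.default_rng(seed)
    calls = true_states.calls
    frac = calls / true_states.alleles_per_individual  # 0, 0.5 or 1
    levels = np.full(calls.shape, np.nan)
    if noise.family == "beta":
        shapes = {
            0.0: (1.0, noise.conc_unmeth),
            0.5: (noise.conc_het / 2, noise.conc_het / 2),
            1.0: (noise.conc_meth, 1.0),
        }
        for center, (a, b) in shapes.items():
            mask = frac == center
            levels[mask] = rng.beta(a, b, size=int(mask.sum()))
    else:
        sds = {0.0: noise.conc_unmeth, 0.5: noise.conc_het,
               1.0: noise.conc_meth}
        for center, conc in sds.items():
            mask = frac == center
            draw = rng.normal(center, 1 / np.sqrt(conc), size=int(mask.sum()))
            levels[mask] = np.clip(draw, 0.0, 1.0)
    n_sites = np.where(np.isfinite(levels), 1, 0)
    return TileMatrix(true_states.tiles, tile_size, context,
                      true_states.individuals, levels, n_sites)


def simulate_cytosine_report(levels: TileMatrix, individual: str,
                             sites_per_tile: int = 10,
                             coverage: CoverageModel = CoverageModel(),
                             seed: int = 0, path=None):
    """Per-cytosine Bismark-style report lines for one individual.

    Each tile carries ``sites_per_tile`` evenly spaced cytosines; site
    depth is negative-binomial and methylated reads are
    Binomial(depth, tile level). Zero-depth sites are omitted (a
    cytosine report only lists covered positions). Returns the rows as
    a list of tuples, or writes a TSV when ``path`` is given.
    """
    rng = np.random.default_rng(seed)
    col = levels.individuals.index(individual)
    rows = []
    offsets = ((np.arange(sites_per_tile) + 0.5)
               * levels.tile_size / sites_per_tile).astype(int)
    for i, (chrom, start) in enumerate(levels.tiles):
        lvl = levels.levels[i, col]
        if not np.isfinite(lvl):
            continue
        depths = coverage.sample(sites_per_tile, rng)
        meths = rng.binomial(depths, lvl)
        for off, d, mcount in zip(offsets, depths, meths):
            if d == 0:
                continue
            rows.append((chrom, start + int(off) + 1, "+", int(mcount),
                         int(d - mcount), levels.context))
    if path is not None:
        with open(path, "w") as fh:
            for r in rows:
                fh.write("\t".join(map(str, r)) + "\n")
    return rows


def simulate_snps_and_intervals(calls: CallMatrix, r2_target: float,
                                seed: int = 0, snps_per_tile: int = 5,
                                flank: int = 1000,
                                n_dmrs: int = 200, dmr_len: int = 500,
                                overlap_frac: float = 0.5,
                                sweep_len: int = 5000,
                                universe_len: int = 10_000_000):
    """SNPs in LD with methylation calls plus interval sets with
    controlled overlap.

    Each tile receives ``snps_per_tile`` SNPs within ``flank`` bp whose
    genotypes copy the tile's methylation calls with probability
    sqrt(r2_target) per individual and are otherwise drawn from the
    permuted call vector, giving expected squared correlation
    ~ r2_target. Interval sets: ``n_dmrs`` DMRs placed uniformly
    without overlap in a mappable universe of ``universe_len`` bp, and
    sweep intervals constructed to overlap each DMR independently with
    probability ``overlap_frac`` (plus background sweeps elsewhere).

    Returns (SnpTable, {"dmrs": ..., "sweeps": ..., "universe": ...}).
    """
    if not 0 <= r2_target <= 1:
        raise ValueError("r2_target must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rho = np.sqrt(r2_target)
    cm = calls.calls
    n_tiles, n_ind = cm.shape
    scale = 1 if calls.ploidy_mode == "outbred" else 2  # genotypes 0/2 inbred
    chroms, positions, geno_rows = [], [], []
    for i, (chrom, start) in enumerate(calls.tiles):
        c = cm[i]
        pool = c[np.isfinite(c)]
        if pool.size == 0:
            continue
        for jsnp in range(snps_per_tile):
            copy = rng.random(n_ind) < rho
            alt_src = rng.choice(pool, size=n_ind)
            g = np.where(copy, c, alt_src) * scale
            g = np.where(np.isfinite(g), g, -1)
            chroms.append(chrom)
            offset = int(rng.integers(-flank, flank + 100))
            positions.append(max(1, start + 50 + offset))
            geno_rows.append(g.astype(np.int8))
    snps = SnpTable(
        np.array(chroms, dtype=object), np.array(positions, dtype=np.int64),
        np.array(["A"] * len(chroms), dtype=object),
        np.array(["G"] * len(chroms), dtype=object),
        list(calls.individuals), np.array(geno_rows, dtype=np.int8),
    )

    # non-overlapping DMRs on a regular lattice with random jitter
    slot = universe_len // n_dmrs
    if slot <= dmr_len + sweep_len:
        raise ValueError("universe too small for the requested intervals")
    dmr_starts = (np.arange(n_dmrs) * slot
                  + rng.integers(0, slot - dmr_len, size=n_dmrs))
    dmrs = IntervalSet("dmrs", np.array(["simU"] * n_dmrs, dtype=object),
                       dmr_starts, dmr_starts + dmr_len)
    sweep_tuples = []
    hit = rng.random(n_dmrs) < overlap_frac
    for i in range(n_dmrs):
        if hit[i]:  # sweep overlapping this DMR
            s = int(dmr_starts[i] + rng.integers(-sweep_len // 2, dmr_len))
            s = max(0, s)
            sweep_tuples.append(("simU", s, s + sweep_len))
        else:  # background sweep inside the slot but clear of the DMR
            gap_start = int(dmr_starts[i] + dmr_len + 1)
            gap_end = int((i + 1) * slot - sweep_len)
            if gap_end > gap_start:
                s = int(rng.integers(gap_start, gap_end))
                sweep_tuples.append(("simU", s, s + sweep_len))
    sweeps = IntervalSet.from_tuples("sweeps", sweep_tuples)
    universe = IntervalSet.from_tuples("universe", [("simU", 0, universe_len)])
    return snps, {"dmrs": dmrs, "sweeps": sweeps, "universe": universe}


def simulate_dataset(config: SimConfig = SimConfig()) -> dict:
    """End-to-end simulation: frequencies -> genotypes -> levels.

    Returns a dict with the true q vector, the true CallMatrix and the
    noisy TileMatrix, using seeds derived deterministically from
    ``config.seed``.
    """
    q = simulate_tile_frequencies(config.params, config.n_tiles, config.seed)
    geno = simulate_genotypes(q, config.n_individuals, config.ploidy_mode,
                              config.seed + 1, config.tile_size, config.chrom)
    levels = simulate_tile_levels(geno, config.noise, config.seed + 2,
                                  config.tile_size, config.context)
    return {"q": q, "genotypes": geno, "levels": levels, "config": config}
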