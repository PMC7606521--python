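import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from epimsfs import (CallMatrix, ModelParams, TileMatrix,
                     simulate_genotypes, simulate_tile_frequencies,
                     simulate_tile_levels)

CG_PARAMS = ModelParams(3.6e-6, 1.8e-7, 4.0e-5, 50_000)  # alpha .72 beta .036 gamma 8
CHG_PARAMS = ModelParams(7.6e-6, 3.0e-7, 4.4e-5, 50_000)  # alpha 1.52 beta .06 gamma 8.8


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def cg_params():
    return CG_PARAMS


@pytest.fixture
def chg_params():
    return CHG_PARAMS


@pytest.fixture
def small_population():
    """Low-noise synthetic population: 800 tiles x 20 outbred individuals."""
    q = simulate_tile_frequencies(CG_PARAMS, 800, seed=5)
    geno = simulate_genotypes(q, 20, "outbred", seed=6)
    levels = simulate_tile_levels(geno, seed=7)
    return q, geno, levels


def make_call_matrix(calls, ploidy_mode="outbred", chrom="chr1"):
    calls = np.atleast_2d(np.asarray(calls, dtype=float))
    tiles = [(chrom, i * 100) for i in range(calls.shape[0])]
    individuals = [f"i{j}" for j in range(calls.shape[1])]
    return CallMatrix(tiles, individuals, calls, ploidy_mode)


def make_tile_matrix(levels, chrom="chr1", context="CG"):
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    tiles = [(chrom, i * 100) for i in range(levels.shape[0])]
    individuals = [f"i{j}" for j in range(levels.shape[1])]
    return TileMatrix(tiles, 100, context, individuals, levels,
                      np.ones_like(levels, dtype=np.int64))
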