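"""Interval and association statistics: sweep-window outlier merging,
overlap permutation tests, DMR-SNP linkage tests and candidate-gene
enrichment.

All permutation p-values use the add-one rule
p = (1 + #{perm >= observed}) / (n_perm + 1), so the smallest
attainable p with 999 permutations is 0.001 and p is never zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .intervals import IntervalSet


@dataclass
class PermutationResult:
    observed: float
    perm_stats: np.ndarray
    p_value: float
    enrichment_ratio: float
    n_perm: int
    seed: int


def merge_outlier_windows(windows: IntervalSet, tail_frac: float = 0.10,
                          outlier_frac: float = 0.005) -> IntervalSet:
    """Selective-sweep calling from scored sliding windows.

    Windows whose score reaches the upper ``tail_frac`` quantile are
    merged when overlapping or book-ended; each merged region carries
    the maximum score of its windows. Merged regions whose score
    reaches the upper ``outlier_frac`` quantile of the original window
    scores are returned as the targets of selection.
    """
    if windows.scores is None:
        raise ValueError("windows must carry scores")
    scores = windows.scores
    if not np.all(np.isfinite(scores)):
        raise ValueError("window scores must be finite")
    if np.ptp(scores) == 0:
        warnings.warn("all window scores equal; no tail is defined")
        return IntervalSet(windows.name + "_outliers", [], [], [],
                           np.array([]))
    tail_cut = np.quantile(scores, 1 - tail_frac)
    outlier_cut = np.quantile(scores, 1 - outlier_frac)
    keep = scores >= tail_cut
    tail = IntervalSet(windows.name + "_tail", windows.chroms[keep],
                       windows.starts[keep], windows.ends[keep],
                       scores[keep])
    merged = tail.merge(keep_max_score=True)
    sel = merged.scores >= outlier_cut
    return IntervalSet(windows.name + "_outliers", merged.chroms[sel],
                       merged.starts[sel], merged.ends[sel],
                       merged.scores[sel])


def overlap_permutation_test(query: IntervalSet, target: IntervalSet,
                             universe: IntervalSet, n_perm: int = 999,
                             seed: int = 0, mode: str = "within_chrom",
                             max_tries: int = 100) -> PermutationResult:
    """One-sided permutation test for interval-set overlap.

    The statistic is the number of query intervals overlapping at
    least 1 bp of the target. Under the null, query intervals are
    re-placed uniformly at random within the (merged) universe
    segments, preserving their lengths — within their own chromosome
    by default (``mode="genome"`` shuffles genome-wide). Placed
    intervals are kept non-overlapping by rejection (up to
    ``max_tries`` resamples each). The reported enrichment ratio is
    observed / mean(permuted).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    uni = universe.merge()
    segs_by_chrom: dict = {}
    for c, s, e in uni:
        segs_by_chrom.setdefault(str(c), []).append((s, e))
    # merged target arrays per chromosome for fast overlap lookups
    tmerged = target.merge()
    tgt: dict = {}
    for c in np.unique(tmerged.chroms.astype(str)):
        m = tmerged.chroms.astype(str) == c
        tgt[c] = (tmerged.starts[m], tmerged.ends[m])

    def hits_target(chrom, start, end) -> bool:
        if chrom not in tgt:
            return False
        ts, te = tgt[chrom]
        j = np.searchsorted(te, start, side="right")
        return j < len(ts) and ts[j] < end

    observed = int(query.overlaps_point_set(target).sum())

    # candidate segments and placement weights per query interval
    # (fixed across permutations: lengths are preserved)
    placements = []
    for i in range(len(query)):
        length = int(query.ends[i] - query.starts[i])
        if mode == "within_chrom":
            segs = [(str(query.chroms[i]), s, e)
                    for (s, e) in segs_by_chrom.get(str(query.chroms[i]), [])]
        else:
            segs = [(c, s, e) for c, lst in segs_by_chrom.items()
                    for (s, e) in lst]
        fits = [(c, s, e) for (c, s, e) in segs if e - s >= length]
        if not fits:
            raise ValueError(f"query interval of length {length} does not "
                             "fit in any universe segment")
        w = np.array([e - s - length + 1 for (_, s, e) in fits], dtype=float)
        placements.append((length, fits, w / w.sum()))

    perm_stats = np.empty(n_perm)
    for b in range(n_perm):
        placed: list = []
        count = 0
        for length, fits, w in placements:
            for attempt in range(max_tries + 1):
                c, s, e = fits[0] if len(fits) == 1 else \
                    fits[rng.choice(len(fits), p=w)]
                start = int(rng.integers(s, e - length + 1))
                clash = any(c == pc and start < pe and ps < start + length
                            for (pc, ps, pe) in placed)
                if not clash or attempt == max_tries:
                    placed.append((c, start, start + length))
                    count += hits_target(c, start, start + length)
                    break
        perm_stats[b] = count
    p = (1 + np.sum(perm_stats >= observed)) / (n_perm + 1)
    mean_perm = perm_stats.mean()
    ratio = observed / mean_perm if mean_perm > 0 else np.inf
    return PermutationResult(observed, perm_stats, float(p), float(ratio),
                             n_perm, seed)


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either vector is constant."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def dmr_snp_ld_test(dmr_states: np.ndarray, genotypes: np.ndarray,
                    n_perm: int = 999, min_sig: int = 3,
                    alpha: float = 0.01, seed: int = 0):
    """LD test between a DMR's methylation states and its local SNPs.

    ``dmr_states`` is the per-individual methylation call vector;
    ``genotypes`` is (n_snps, n_individuals) with -1/NaN as missing.
    Per SNP the statistic is the squared Pearson correlation across
    individuals with both values present; its one-sided p-value comes
    from permuting the state vector, with the same permutation stream
    shared across the DMR's SNPs so per-SNP p-values are comparable.
    Monomorphic SNPs (or a monomorphic state vector) carry no
    information and get p = 1. The DMR is flagged ``in_LD`` when at
    least ``min_sig`` SNPs reach p < ``alpha``.

    Returns (p_values array, in_LD flag).
    """
    rng = np.random.default_rng(seed)
    states = np.asarray(dmr_states, dtype=float)
    geno = np.asarray(genotypes, dtype=float)
    geno = np.where(geno < 0, np.nan, geno)
    n_snps, n_ind = geno.shape
    if len(states) != n_ind:
        raise ValueError("state vector and genotypes disagree on individuals")
    perms = np.array([rng.permutation(n_ind) for _ in range(n_perm)])
    p_values = np.ones(n_snps)
    for i in range(n_snps):
        mask = np.isfinite(geno[i]) & np.isfinite(states)
        g, st = geno[i, mask], states[mask]
        if mask.sum() < 3 or np.ptp(g) == 0 or np.ptp(st) == 0:
            p_values[i] = 1.0
            continue
        obs = _r2(g, st)
        perm_states = states[perms][:, mask]
        gc = g - g.mean()
        sc = perm_states - perm_states.mean(axis=1, keepdims=True)
        num = sc @ gc
        denom = (gc @ gc) * (sc * sc).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            perm_r2 = np.where(denom > 0, num * num / denom, 0.0)
        p_values[i] = (1 + int(np.sum(perm_r2 >= obs))) / (n_perm + 1)
    in_ld = bool(np.sum(p_values < alpha) >= min_sig)
    return p_values, in_ld


def candidate_enrichment(hits: set, candidates: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value for candidate-set overlap.

    Probability of drawing at least ``|hits & candidates|`` candidate
    genes when ``|hits|`` genes are drawn from the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    hits, candidates = set(hits) & universe, set(candidates) & universe
    overlap = len(hits & candidates)
    return float(hypergeom.sf(overlap - 1, len(universe), len(candidates),
                              len(hits)))
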