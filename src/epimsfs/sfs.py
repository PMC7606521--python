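"""Methylome site frequency spectra (mSFS) and tile stratification.

The mSFS counts, across 100-bp tiles, how many of the m sampled
epialleles (2 per outbred individual, 1 per inbred line) carry the
methylated state. It is the data summary the population-epigenetic
model is fitted to.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .calling import CallMatrix

TILE_CATEGORIES = (
    "invariant_unmethylated",
    "rarely_methylated",
    "high_frequency_variable",
    "rarely_unmethylated",
    "invariant_methylated",
)


@dataclass
class MSFS:
    """Methylated-epiallele count spectrum over k = 0..m."""

    m: int
    counts: np.ndarray
    context: str = "CG"
    label: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.m + 1:
            raise ValueError("counts must have length m + 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_tiles(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "m": self.m, "counts": self.counts.tolist(),
            "context": self.context, "label": self.label,
        })
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "MSFS":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(d["m"], np.array(d["counts"]), d.get("context", "CG"),
                   d.get("label", ""))


def build_msfs(calls: CallMatrix, missing_policy: str = "drop",
               target_m: int | None = None, context: str = "CG",
               label: str = "") -> MSFS:
    """Build the mSFS from an epigenotype call matrix.

    Per tile the methylated-allele count k is the sum of calls
    (heterozygous outbred calls contribute one methylated and one
    unmethylated allele). ``missing_policy="drop"`` excludes tiles with
    any missing call; ``"project"`` downsamples each tile's (k, m_obs)
    hypergeometrically to ``target_m`` alleles and accumulates expected
    counts, which rescues tiles with partial missingness.
    """
    a = calls.alleles_per_individual
    m_full = a * len(calls.individuals)
    cm = calls.calls
    obs = np.isfinite(cm)
    k_per_tile = np.nansum(cm, axis=1)
    m_obs = a * obs.sum(axis=1)

    if missing_policy == "drop":
        complete = obs.all(axis=1)
        counts = np.bincount(k_per_tile[complete].astype(int), minlength=m_full + 1)
        return MSFS(m_full, counts.astype(float), context, label)
    if missing_policy == "project":
        if target_m is None:
            raise ValueError("projection requires target_m")
        usable = m_obs >= 1
        if target_m > int(m_obs[usable].min() if usable.any() else 0):
            raise ValueError(
                f"target_m={target_m} exceeds the minimum observed allele "
                f"count {int(m_obs[usable].min()) if usable.any() else 0}")
        counts = np.zeros(target_m + 1)
        j = np.arange(target_m + 1)
        for k, mo in zip(k_per_tile.astype(int), m_obs.astype(int)):
            if mo < target_m:
                continue
            counts += hypergeom.pmf(j, mo, k, target_m)
        return MSFS(target_m, counts, context, label)
    raise ValueError("missing_policy must be 'drop' or 'project'")


def classify_tiles(freqs) -> tuple[np.ndarray, dict]:
    """Partition tiles by methylated-epiallele frequency.

    Exactly 0 -> invariant_unmethylated; (0, 0.1) -> rarely_methylated;
    [0.1, 0.9] -> high_frequency_variable; (0.9, 1) -> rarely_unmethylated;
    exactly 1 -> invariant_methylated. Returns the per-tile category
    array and the fraction of tiles in each category.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    cats = np.empty(len(f), dtype=object)
    cats[f == 0] = "invariant_unmethylated"
    cats[(f > 0) & (f < 0.1)] = "rarely_methylated"
    cats[(f >= 0.1) & (f <= 0.9)] = "high_frequency_variable"
    cats[(f > 0.9) & (f < 1)] = "rarely_unmethylated"
    cats[f == 1] = "invariant_methylated"
    fractions = {c: float((cats == c).mean()) if len(f) else 0.0
                 for c in TILE_CATEGORIES}
    return cats, fractions


def stratify_by_feature(tiles, tile_size: int, annotations: dict,
                        precedence: tuple = ("exon", "intron", "up5k",
                                             "down5k", "TE")) -> dict:
    """Assign each tile to a genomic feature class.

    A tile belongs to the first feature in ``precedence`` whose
    intervals cover at least 50% of the tile; tiles matching nothing
    fall into ``intergenic``. ``annotations`` maps feature name to an
    IntervalSet in the same coordinate system as the tiles.
    """
    strata: dict = {feat: [] for feat in precedence}
    strata["intergenic"] = []
    for idx, (chrom, start) in enumerate(tiles):
        assigned = False
        for feat in precedence:
            iv = annotations.get(feat)
            if iv is None:
                continue
            if iv.overlap_bp(chrom, start, start + tile_size) >= 0.5 * tile_size:
                strata[feat].append(idx)
                assigned = True
                break
        if not assigned:
            strata["intergenic"].append(idx)
    return strata


def polarize_by_ancestral_state(calls_teosinte: CallMatrix) -> np.ndarray:
    """Per-tile ancestral-state stratum from the wild-progenitor sample.

    The majority epiallele in teosinte defines the ancestral state:
    more methylated than unmethylated alleles -> ``ancestral_hyper``,
    fewer -> ``ancestral_hypo``; exact ties and all-missing tiles are
    ``ambiguous`` (and excluded from polarized fits). Heterozygous
    calls contribute one allele of each kind.
    """
    a = calls_teosinte.alleles_per_individual
    cm = calls_teosinte.calls
    obs = np.isfinite(cm)
    meth = np.nansum(cm, axis=1)
    total = a * obs.sum(axis=1)
    unmeth = total - meth
    out = np.where(meth > unmeth, "ancestral_hyper",
                   np.where(meth < unmeth, "ancestral_hypo", "ambiguous"))
    out[total == 0] = "ambiguous"
    return out.astype(object)
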