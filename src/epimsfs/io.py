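"""Reading and writing of methylome data: Bismark-style cytosine reports,
BED interval sets, FASTA pseudo-references, SNP tables and tile matrices.

Coordinates follow each format's native convention: cytosine reports and
SNP tables are 1-based, BED and tile coordinates are 0-based half-open.
Tiles are anchored to the reference (multiples of ``tile_size`` from 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine site from a bisulfite cytosine report."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.n_meth < 0 or self.n_total <= 0:
            raise ValueError("read counts must be non-negative, total positive")
        if self.n_meth > self.n_total:
            raise ValueError("n_meth exceeds n_total")

    @property
    def level(self) -> float:
        """Per-site methylation level: methylated reads / total reads."""
        return self.n_meth / self.n_total


@dataclass
class TileMatrix:
    """Tile x individual methylation levels for one sequence context.

    ``levels`` holds values in [0, 1] with NaN for missing tiles;
    ``n_sites`` counts the covered cytosines behind each entry. CHH is
    rejected: only CG and CHG enter population-genetic analysis (the
    vast majority of CHH sites are unmethylated).
    """

    tiles: list  # [(chrom, start0), ...] sorted
    tile_size: int
    context: str
    individuals: list
    levels: np.ndarray  # (n_tiles, n_ind) float, NaN = missing
    n_sites: np.ndarray  # (n_tiles, n_ind) int

    def __post_init__(self):
        if self.context not in ("CG", "CHG"):
            raise ValueError("TileMatrix context must be CG or CHG")
        self.levels = np.atleast_2d(np.asarray(self.levels, dtype=float))
        self.n_sites = np.atleast_2d(np.asarray(self.n_sites, dtype=np.int64))
        ok = np.isnan(self.levels) | ((self.levels >= 0) & (self.levels <= 1))
        if not ok.all():
            raise ValueError("tile levels must lie in [0, 1] or be NaN")
        if sorted(self.tiles) != list(self.tiles):
            raise ValueError("tiles must be sorted by (chrom, start)")

    @property
    def n_tiles(self) -> int:
        return self.levels.shape[0]


@dataclass
class SnpTable:
    """Biallelic SNPs with per-individual genotypes in {0, 1, 2, -1=missing}."""

    chroms: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    individuals: list
    genotypes: np.ndarray  # (n_snps, n_ind) int8, -1 missing

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        for r, a in zip(self.ref, self.alt):
            if len(r) != 1 or len(a) != 1:
                raise ValueError("only single-nucleotide alleles allowed")
            if r == a:
                raise ValueError("ref and alt allele identical")

    def __len__(self) -> int:
        return len(self.pos)


def read_cytosine_report(
    path,
    min_total: int = 4,
    counts: str = "meth_unmeth",
) -> list[CytosineRecord]:
    """Parse a Bismark-style cytosine report and apply the coverage filter.

    Expected columns: chrom, pos (1-based), strand, count_a, count_b,
    context [, trinucleotide]. With ``counts="meth_unmeth"`` (the Bismark
    dialect) columns 4/5 are methylated and unmethylated read counts;
    with ``counts="meth_total"`` they are methylated and total. Sites
    with total coverage below ``min_total`` are dropped — the default of
    4 keeps sites with more than three mapped reads.

    Raises ``ValueError`` naming the 1-based line number for malformed
    rows (wrong column count, negative counts, methylated > total).
    """
    if counts not in ("meth_unmeth", "meth_total"):
        raise ValueError("counts must be 'meth_unmeth' or 'meth_total'")
    records: list[CytosineRecord] = []
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"line {lineno}: expected >= 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            chrom, pos_s, strand, a_s, b_s, context = parts[:6]
            try:
                pos, a, b = int(pos_s), int(a_s), int(b_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer field ({exc})") from None
            n_meth = a
            n_total = a + b if counts == "meth_unmeth" else b
            if a < 0 or b < 0:
                raise ValueError(f"line {lineno}: negative read count")
            if n_meth > n_total:
                raise ValueError(f"line {lineno}: n_meth > n_total")
            if n_total < min_total:
                continue
            try:
                records.append(
                    CytosineRecord(chrom, pos, strand, context, n_meth, n_total)
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    return records


def aggregate_tiles(
    records,
    tile_size: int = 100,
    min_sites: int = 3,
    context: str = "CG",
    individual: str = "sample",
    weighted: bool = False,
) -> TileMatrix:
    """Aggregate per-cytosine levels into tile methylation levels.

    Each tile spans ``[k*tile_size, (k+1)*tile_size)`` on the reference.
    The tile level is the unweighted mean of the per-site levels
    n_meth/n_total of its covered cytosines (``weighted=True`` instead
    pools reads: sum n_meth / sum n_total). Tiles with fewer than
    ``min_sites`` covered cytosines are set to NaN.
    """
    recs = [r for r in records if r.context == context]
    buckets: dict[tuple, list[CytosineRecord]] = {}
    for r in recs:
        key = (r.chrom, ((r.pos - 1) // tile_size) * tile_size)
        buckets.setdefault(key, []).append(r)
    tiles = sorted(buckets)
    levels = np.full((len(tiles), 1), np.nan)
    n_sites = np.zeros((len(tiles), 1), dtype=np.int64)
    for i, key in enumerate(tiles):
        sites = buckets[key]
        n_sites[i, 0] = len(sites)
        if len(sites) < min_sites:
            continue
        if weighted:
            levels[i, 0] = sum(s.n_meth for s in sites) / sum(s.n_total for s in sites)
        else:
            levels[i, 0] = float(np.mean([s.level for s in sites]))
    return TileMatrix(tiles, tile_size, context, [individual], levels, n_sites)


def merge_tile_matrices(matrices: list[TileMatrix]) -> TileMatrix:
    """Outer-join single-individual tile matrices on tile coordinates."""
    if not matrices:
        raise ValueError("no matrices to merge")
    tile_size = matrices[0].tile_size
    context = matrices[0].context
    all_tiles = sorted({t for m in matrices for t in m.tiles})
    index = {t: i for i, t in enumerate(all_tiles)}
    n_ind = sum(len(m.individuals) for m in matrices)
    levels = np.full((len(all_tiles), n_ind), np.nan)
    n_sites = np.zeros((len(all_tiles), n_ind), dtype=np.int64)
    individuals, col = [], 0
    for m in matrices:
        if m.tile_size != tile_size or m.context != context:
            raise ValueError("tile_size/context mismatch across matrices")
        rows = [index[t] for t in m.tiles]
        k = len(m.individuals)
        levels[rows, col:col + k] = m.levels
        n_sites[rows, col:col + k] = m.n_sites
        individuals.extend(m.individuals)
        col += k
    return TileMatrix(all_tiles, tile_size, context, individuals, levels, n_sites)


def build_pseudo_reference(reference: dict, snps: SnpTable, individual: str) -> dict:
    """Substitute homozygous-alt SNP alleles into a reference genome.

    ``reference`` maps chromosome name to sequence string. Positions
    where ``individual`` is homozygous alt (genotype 2) receive the alt
    base; heterozygous and missing genotypes keep the reference base (a
    single output sequence cannot encode both alleles without IUPAC
    codes, which would break downstream bisulfite logic). Raises on any
    SNP whose stated ref allele disagrees with the reference sequence.
    """
    try:
        col = snps.individuals.index(individual)
    except ValueError:
        raise KeyError(f"individual {individual!r} not in SNP table") from None
    seqs = {c: np.frombuffer(s.upper().encode(), dtype="S1").copy()
            for c, s in reference.items()}
    mismatches = []
    for i in range(len(snps)):
        chrom, pos = str(snps.chroms[i]), int(snps.pos[i])
        if chrom not in seqs:
            raise KeyError(f"SNP chromosome {chrom!r} absent from reference")
        if pos > len(seqs[chrom]):
            raise ValueError(f"SNP position {chrom}:{pos} beyond chromosome end")
        ref_base = seqs[chrom][pos - 1].decode()
        if ref_base != str(snps.ref[i]).upper():
            mismatches.append(f"{chrom}:{pos} ref={snps.ref[i]} genome={ref_base}")
    if mismatches:
        raise ValueError("ref allele mismatch at " + "; ".join(mismatches))
    for i in range(len(snps)):
        if snps.genotypes[i, col] == 2:
            chrom, pos = str(snps.chroms[i]), int(snps.pos[i])
            seqs[chrom][pos - 1] = str(snps.alt[i]).upper().encode()
    return {c: a.tobytes().decode() for c, a in seqs.items()}


def read_fasta(path) -> dict:
    """Load a FASTA file into {name: sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(seqs: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path, name: str | None = None) -> IntervalSet:
    """Read BED3/BED6 (0-based, half-open); column 5 becomes the score."""
    chroms, starts, ends, scores = [], [], [], []
    has_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 columns")
            chroms.append(parts[0])
            starts.append(int(parts[1]))
            ends.append(int(parts[2]))
            if len(parts) >= 5:
                has_score = True
                scores.append(float(parts[4]))
            else:
                scores.append(np.nan)
    return IntervalSet(
        name or str(path), np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64),
        np.array(scores) if has_score else None,
    )


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(intervals)):
            row = [str(intervals.chroms[i]), str(int(intervals.starts[i])),
                   str(int(intervals.ends[i]))]
            if intervals.scores is not None:
                row += [intervals.name, f"{intervals.scores[i]:g}"]
            fh.write("\t".join(row) + "\n")


def write_tile_matrix(tiles: TileMatrix, path) -> None:
    """TSV with chrom, start, end then one level column per individual."""
    df = pd.DataFrame({
        "chrom": [t[0] for t in tiles.tiles],
        "start": [t[1] for t in tiles.tiles],
        "end": [t[1] + tiles.tile_size for t in tiles.tiles],
    })
    for j, ind in enumerate(tiles.individuals):
        df[ind] = tiles.levels[:, j]
    df.attrs["context"] = tiles.context
    with open(path, "w") as fh:
        fh.write(f"#context={tiles.context}\ttile_size={tiles.tile_size}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_tile_matrix(path) -> TileMatrix:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("#").split())
        df = pd.read_csv(fh, sep="\t", na_values="NA")
    individuals = [c for c in df.columns if c not in ("chrom", "start", "end")]
    tiles = list(zip(df["chrom"], df["start"].astype(int)))
    levels = df[individuals].to_numpy(dtype=float)
    return TileMatrix(
        tiles, int(meta["tile_size"]), meta["context"], individuals,
        levels, np.zeros_like(levels, dtype=np.int64),
    )


def write_snp_table(snps: SnpTable, path) -> None:
    df = pd.DataFrame({
        "chrom": snps.chroms, "pos": snps.pos,
        "ref": snps.ref, "alt": snps.alt,
    })
    for j, ind in enumerate(snps.individuals):
        df[ind] = snps.genotypes[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_snp_table(path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    individuals = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    return SnpTable(
        df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(),
        df["ref"].to_numpy(dtype=object), df["alt"].to_numpy(dtype=object),
        individuals, df[individuals].to_numpy(dtype=np.int8),
    )
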