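"""Copy-number segment post-processing.

The module starts from per-sample segment tables (chrom, start, end, copy
number) as produced by a read-depth CNV caller whose smallest bin is 1200 bp,
and implements the downstream steps: recentring copy numbers by a fixed
summand (so that the callers' 1.8 "normal" level maps to 2.0), assigning
copy numbers to exons with per-segment overlap lengths, summarizing the
deleted exonic base pairs per copy-number level, slicing the genome into
fixed-width bins to form per-bin cross-sample CNV vectors, clustering
samples on those vectors with bootstrap support, and joining gene-level copy
number with expression.

Coordinates are 0-based half-open throughout; a converter is provided for
1-based closed input.  Allosomes (X, Y) are excluded from exon assignment
and vector building because their normal copy number is one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError
from .trees import ClusterTree, bootstrap_tree, euclidean_condensed

ALLOSOMES = {"X", "Y", "chrX", "chrY"}
SEGMENT_COLUMNS = ["chrom", "start", "end", "cn"]


@dataclass
class SegmentTable:
    """Non-overlapping copy-number segments of one sample."""

    sample: str
    segments: pd.DataFrame  # chrom, start, end, cn

    def __post_init__(self) -> None:
        df = self.segments.reset_index(drop=True)
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ContractError(f"segment table missing columns {missing}")
        df = df[SEGMENT_COLUMNS].astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "cn": float}
        )
        if (df["end"] <= df["start"]).any():
            raise ContractError("segment end must exceed start")
        if (df["cn"] < 0).any():
            raise ContractError("copy numbers must be non-negative")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
        if np.any(same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])):
            raise ContractError(f"overlapping segments in sample {self.sample!r}")
        self.segments = df


def from_one_based_closed(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based closed (start, end) columns to 0-based half-open."""
    out = df.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    return out


def read_segment_tables(path: str | Path) -> list[SegmentTable]:
    """Read a TSV with header ``sample chrom start end cn`` into one
    :class:`SegmentTable` per sample (input order preserved)."""
    df = pd.read_csv(path, sep="\t", header=0)
    expected = ["sample", *SEGMENT_COLUMNS]
    if list(df.columns[:5]) != expected:
        raise FormatError(f"{path}: expected header {expected!r}, got {list(df.columns)!r}")
    out = []
    for sample in df["sample"].astype(str).unique():
        sub = df[df["sample"].astype(str) == sample]
        out.append(SegmentTable(sample, sub[SEGMENT_COLUMNS]))
    return out


def write_segment_tables(tables: Sequence[SegmentTable], path: str | Path) -> None:
    rows = []
    for st in tables:
        sub = st.segments.copy()
        sub.insert(0, "sample", st.sample)
        rows.append(sub)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False, lineterminator="\n")


def recenter_cn(st: SegmentTable, summand: float = 0.2) -> SegmentTable:
    """Add a fixed recentring summand to every copy number (1.8 -> 2.0 at
    the default), correcting the caller's depressed normal level."""
    df = st.segments.copy()
    df["cn"] = df["cn"] + summand
    return SegmentTable(st.sample, df)


# ---------------------------------------------------------------------------
# exon assignment and deletion burden


@dataclass
class ExonCn:
    """Copy number(s) assigned to one exon, with the covered length per
    segment when the exon crosses a segment boundary."""

    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    pieces: list[tuple[float, int]] = field(default_factory=list)  # (cn, covered_bp)

    def __post_init__(self) -> None:
        if not self.pieces:
            raise ContractError("ExonCn needs at least one (cn, covered_bp) entry")
        if sum(bp for _, bp in self.pieces) > self.end - self.start:
            raise ContractError("covered base pairs exceed exon length")

    @property
    def covered_bp(self) -> int:
        return sum(bp for _, bp in self.pieces)


EXON_COLUMNS = ["exon_id", "gene_id", "chrom", "start", "end"]


def read_exon_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in EXON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: exon table missing columns {missing}")
    return df[EXON_COLUMNS].astype(
        {"exon_id": str, "gene_id": str, "chrom": str, "start": np.int64, "end": np.int64}
    )


def exons_from_gff(path: str | Path, biotype: str = "protein_coding") -> pd.DataFrame:
    """Extract exons of protein-coding genes from a GFF3/GTF file into the
    exon-table format (0-based half-open coordinates)."""
    import gffutils

    rows = []
    k = 0
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        bt = (attrs.get("gene_biotype") or attrs.get("gene_type") or [None])[0]
        if biotype and bt != biotype:
            continue
        gene = (attrs.get("gene_id") or attrs.get("Parent") or ["?"])[0]
        exon = (attrs.get("exon_id") or attrs.get("ID") or [f"exon_{k}"])[0]
        k += 1
        rows.append((exon, gene, feat.seqid, feat.start - 1, feat.end))
    return pd.DataFrame(rows, columns=EXON_COLUMNS)


def _chrom_segments(st: SegmentTable) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in st.segments.groupby("chrom", sort=False):
        out[str(chrom)] = (
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            sub["cn"].to_numpy(),
        )
    return out


def _overlap_pieces(
    start: int, end: int, segs: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> list[tuple[float, int]]:
    starts, ends, cns = segs
    i0 = int(np.searchsorted(ends, start, side="right"))
    pieces = []
    for i in range(i0, len(starts)):
        if starts[i] >= end:
            break
        ov = min(end, ends[i]) - max(start, starts[i])
        if ov > 0:
            pieces.append((float(cns[i]), int(ov)))
    return pieces


def assign_exon_cn(
    st: SegmentTable, exons: pd.DataFrame
) -> tuple[list[ExonCn], int]:
    """Assign segment copy numbers to autosomal exons.

    An exon fully inside one segment gets that segment's copy number with
    the full exon length; an exon crossing k segments gets k (cn, overlap)
    entries.  Exons overlapping no segment are omitted; their count is the
    second return value.  Exons on chromosomes X/Y are excluded.
    """
    if (exons["end"] <= exons["start"]).any():
        raise ContractError("exon end must exceed start")
    segs = _chrom_segments(st)
    out: list[ExonCn] = []
    omitted = 0
    for row in exons.itertuples(index=False):
        if row.chrom in ALLOSOMES:
            continue
        chrom_segs = segs.get(str(row.chrom))
        pieces = _overlap_pieces(int(row.start), int(row.end), chrom_segs) if chrom_segs else []
        if not pieces:
            omitted += 1
            continue
        out.append(ExonCn(str(row.exon_id), str(row.gene_id), str(row.chrom),
                          int(row.start), int(row.end), pieces))
    return out, omitted


def deletion_burden(
    exon_cns: Iterable[ExonCn], normal_cn: float = 2.0, decimals: int = 1
) -> pd.DataFrame:
    """Affected exonic base pairs per (rounded) copy-number level below
    normal: a per-sample summary of how much coding sequence is deleted."""
    acc: dict[float, int] = {}
    for ec in exon_cns:
        for cn, bp in ec.pieces:
            level = round(cn, decimals)
            if level < normal_cn:
                acc[level] = acc.get(level, 0) + bp
    rows = sorted(acc.items())
    return pd.DataFrame(rows, columns=["cn", "affected_bp"])


# ---------------------------------------------------------------------------
# genome binning and CNV vectors


def bin_genome(chrom_sizes: Mapping[str, int], width: int = 1200) -> pd.DataFrame:
    """Slice each chromosome into fixed-width bins (last bin truncated)."""
    if width < 1:
        raise ContractError("bin width must be >= 1")
    rows = []
    for chrom, size in chrom_sizes.items():
        size = int(size)
        if size <= 0:
            raise ContractError(f"chromosome {chrom!r} has non-positive size")
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": str(chrom), "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class CnvVectors:
    """Per-bin cross-sample copy-number vectors retained for clustering."""

    bins: pd.DataFrame           # chrom, start, end of kept (unique) bins
    matrix: np.ndarray           # (n_kept_vectors, n_samples)
    samples: list[str]
    n_candidate_bins: int = 0    # bins passing the threshold filter pre-dedupe

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.samples):
            raise ContractError("vector width must equal the sample count")
        if len(self.bins) != self.matrix.shape[0]:
            raise ContractError("bin table inconsistent with vector matrix")

    @property
    def n_vectors(self) -> int:
        return self.matrix.shape[0]


def _bins_overlap_mask(bins: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """True for bins intersecting any exclusion interval."""
    mask = np.zeros(len(bins), dtype=bool)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sel = bins["chrom"].to_numpy() == str(chrom)
        if not sel.any():
            continue
        bstart = bins["start"].to_numpy()[sel]
        bend = bins["end"].to_numpy()[sel]
        hit = np.zeros(len(bstart), dtype=bool)
        for iv in sub.itertuples(index=False):
            hit |= (bstart < int(iv.end)) & (bend > int(iv.start))
        mask[np.flatnonzero(sel)[hit]] = True
    return mask


def build_cnv_vectors(
    tables: Sequence[SegmentTable],
    bins: pd.DataFrame,
    low: float = 1.6,
    high: float = 2.3,
    exclude: pd.DataFrame | None = None,
    mode: str = "any",
    dedupe_decimals: int | None = None,
) -> CnvVectors:
    """Per-bin copy-number vectors across samples, filtered for clear events.

    A bin is kept iff its vector shows a clear deletion or amplification
    (cn < ``low`` or cn > ``high``) in any sample (``mode="any"``, default)
    or in all samples (``mode="all"``).  Bins on allosomes or intersecting
    the exclusion intervals (e.g. centromere-containing bins) are dropped
    first; identical vectors are then deduplicated (first occurrence kept).
    Every sample must cover every remaining bin.
    """
    if mode not in ("any", "all"):
        raise ContractError(f"unknown filter mode {mode!r}")
    keep = ~bins["chrom"].isin(ALLOSOMES).to_numpy()
    if exclude is not None and len(exclude):
        keep &= ~_bins_overlap_mask(bins, exclude)
    bins = bins.loc[keep].reset_index(drop=True)
    n_bins = len(bins)
    samples = [st.sample for st in tables]
    matrix = np.empty((n_bins, len(tables)))
    for j, st in enumerate(tables):
        segs = _chrom_segments(st)
        col = np.empty(n_bins)
        pos = 0
        for chrom, sub in bins.groupby("chrom", sort=False):
            bstart = sub["start"].to_numpy()
            bend = sub["end"].to_numpy()
            k = len(bstart)
            chrom_segs = segs.get(str(chrom))
            if chrom_segs is None:
                raise ContractError(
                    f"sample {st.sample!r} has no segments on {chrom!r} (bin {int(bstart[0])})"
                )
            starts, ends, cns = chrom_segs
            idx = np.searchsorted(ends, bstart, side="right")
            inside = (idx < len(starts)) & (starts[np.minimum(idx, len(starts) - 1)] <= bstart)
            inside &= ends[np.minimum(idx, len(ends) - 1)] >= bend
            vals = np.empty(k)
            vals[inside] = cns[idx[inside]]
            for i in np.flatnonzero(~inside):  # bins split across segments, or gaps
                pieces = _overlap_pieces(int(bstart[i]), int(bend[i]), chrom_segs)
                covered = sum(bp for _, bp in pieces)
                if covered < bend[i] - bstart[i]:
                    raise ContractError(
                        f"sample {st.sample!r} does not cover bin "
                        f"{chrom}:{int(bstart[i])}-{int(bend[i])}"
                    )
                vals[i] = sum(cn * bp for cn, bp in pieces) / covered
            col[pos : pos + k] = vals
            pos += k
        matrix[:, j] = col
    extreme = (matrix < low) | (matrix > high)
    kept = extreme.any(axis=1) if mode == "any" else extreme.all(axis=1)
    bins = bins.loc[kept].reset_index(drop=True)
    matrix = matrix[kept]
    n_candidate = matrix.shape[0]
    key = matrix if dedupe_decimals is None else np.round(matrix, dedupe_decimals)
    unique = ~pd.DataFrame(key).duplicated().to_numpy()
    return CnvVectors(
        bins.loc[unique].reset_index(drop=True), matrix[unique], samples, n_candidate
    )


def cnv_similarity_tree(
    vectors: CnvVectors, nboot: int = 1000, seed: int = 0
) -> ClusterTree:
    """Ward.D2 sample tree on Euclidean distances between the samples'
    CNV-vector columns, with ordinary-bootstrap support over vectors."""
    if len(vectors.samples) < 2:
        raise ContractError("need at least two samples")
    if vectors.n_vectors < 2:
        warnings.warn("fewer than two CNV vectors: tree is degenerate")
    return bootstrap_tree(
        vectors.matrix.T, list(vectors.samples), euclidean_condensed, nboot=nboot, seed=seed
    )


# ---------------------------------------------------------------------------
# copy number vs expression


def cn_expression_join(
    exon_cns: Iterable[ExonCn],
    expression: Mapping[str, float] | pd.Series,
    cap_percent: float = 2000.0,
    cn_max: float = 6.0,
) -> pd.DataFrame:
    """Join gene-level copy number with relative expression.

    Gene copy number is the length-weighted mean over its exons' pieces;
    genes whose exons carry more than one distinct copy number (a break
    point within the gene) are excluded, as are genes outside [0, cn_max].
    Relative expression is 100 * gene mean / overall mean, capped at
    ``cap_percent``.  Genes absent from the expression table are skipped;
    the skip count is stored in ``df.attrs["skipped_no_expression"]``.
    """
    expr = pd.Series(expression, dtype=float)
    if len(expr) == 0 or expr.mean() == 0:
        raise ContractError("expression table empty or all-zero")
    overall = float(expr.mean())
    per_gene: dict[str, list[tuple[float, int]]] = {}
    for ec in exon_cns:
        per_gene.setdefault(ec.gene_id, []).extend(ec.pieces)
    rows = []
    skipped = 0
    breakpoints = 0
    for gene, pieces in per_gene.items():
        cns = {cn for cn, _ in pieces}
        if len(cns) > 1:
            breakpoints += 1
            continue
        total_bp = sum(bp for _, bp in pieces)
        cn = sum(cn * bp for cn, bp in pieces) / total_bp
        if not (0.0 <= cn <= cn_max):
            continue
        if gene not in expr.index:
            skipped += 1
            continue
        rel = min(100.0 * float(expr[gene]) / overall, cap_percent)
        rows.append((gene, cn, rel))
    df = pd.DataFrame(rows, columns=["gene", "cn", "relative_expression"])
    df.attrs["skipped_no_expression"] = skipped
    df.attrs["excluded_breakpoint"] = breakpoints
    return df
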