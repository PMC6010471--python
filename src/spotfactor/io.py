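"""Text I/O for spatial transcriptomics (ST) count matrices and annotations.

The canonical on-disk format is a dense UTF-8 TSV whose first column holds
spot tokens in the ST ``XxY`` array-coordinate convention (0-based integer
column ``x`` and row ``y``) and whose header names the genes.  Both
orientations (spots as rows, genes as rows) are supported because array
producers differ.  A sparse triplet variant with sidecar id lists is
available for large simulations.  Physical coordinates (the ~200 micron
center-to-center pitch of the array) are metadata and are not stored; all
geometry is in array space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

_SPOT_TOKEN = re.compile(r"^(\d+)x(\d+)$")


@dataclass(frozen=True, order=True)
class SpotId:
    """One barcoded capture spot, addressed by array coordinates.

    ``section`` labels the tissue section the spot belongs to, so that
    multi-section datasets can share a gene axis while keeping spots
    distinct.  ``(section, x, y)`` is the identity of a spot.
    """

    section: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ContractError(f"spot coordinates must be non-negative, got {self.x}x{self.y}")

    @property
    def token(self) -> str:
        return f"{self.x}x{self.y}"


def parse_spot_id(token: str, section: str = "") -> SpotId:
    """Parse an ``XxY`` spot token into a :class:`SpotId`."""
    m = _SPOT_TOKEN.match(token.strip())
    if m is None:
        raise FormatError(f"malformed spot token {token!r}: expected '<int>x<int>'")
    return SpotId(section=section, x=int(m.group(1)), y=int(m.group(2)))


@dataclass
class CountMatrix:
    """Spots x genes matrix of non-negative integer transcript counts."""

    genes: list[str]
    spots: list[SpotId]
    counts: np.ndarray  # (n_spots, n_genes) integer

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.spots = list(self.spots)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (len(self.spots), len(self.genes)):
            raise ContractError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.spots)} spots x {len(self.genes)} genes"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ContractError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ContractError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise ContractError("gene identifiers must be unique")
        if len(set(self.spots)) != len(self.spots):
            raise ContractError("spot identifiers must be unique")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def sections(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spots:
            seen.setdefault(s.section, None)
        return list(seen)

    def spot_index(self) -> dict[SpotId, int]:
        return {s: i for i, s in enumerate(self.spots)}

    def select_spots(self, indices: Sequence[int] | np.ndarray) -> "CountMatrix":
        idx = np.asarray(indices, dtype=int)
        return CountMatrix([*self.genes], [self.spots[i] for i in idx], self.counts[idx])

    def select_genes(self, indices: Sequence[int] | np.ndarray) -> "CountMatrix":
        idx = np.asarray(indices, dtype=int)
        return CountMatrix([self.genes[i] for i in idx], [*self.spots], self.counts[:, idx])

    def section_subset(self, section: str) -> "CountMatrix":
        idx = [i for i, s in enumerate(self.spots) if s.section == section]
        if not idx:
            raise ContractError(f"no spots in section {section!r}")
        return self.select_spots(idx)


def concatenate(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Stack sections sharing an identical gene axis into one matrix."""
    if not matrices:
        raise ContractError("need at least one matrix")
    genes = matrices[0].genes
    for cm in matrices[1:]:
        if cm.genes != genes:
            raise ContractError("matrices must share an identical gene axis")
    spots = [s for cm in matrices for s in cm.spots]
    counts = np.vstack([cm.counts for cm in matrices])
    return CountMatrix(list(genes), spots, counts)


def _validate_count_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    arr = numeric.to_numpy()
    if np.any(arr != np.floor(arr)):
        r, c = np.argwhere(arr != np.floor(arr))[0]
        raise FormatError(f"{path}: non-integer cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    if arr.size and arr.min() < 0:
        r, c = np.argwhere(arr < 0)[0]
        raise FormatError(f"{path}: negative cell at row {df.index[r]!r}, column {df.columns[c]!r}")
    return arr.astype(np.int64)


def read_counts(
    path: str | Path,
    orientation: str = "spots-as-rows",
    section: str = "",
    fmt: str = "dense",
) -> CountMatrix:
    """Read a count TSV (or triplet file set) into a :class:`CountMatrix`.

    ``orientation`` selects whether file rows are spots (default) or genes.
    With ``fmt="triplet"`` the file holds ``spot_index<TAB>gene_index<TAB>count``
    rows and sidecar files ``<path>.spots`` / ``<path>.genes`` list the ids.
    """
    path = Path(path)
    if fmt == "triplet":
        return _read_counts_triplet(path, section)
    if fmt != "dense":
        raise ContractError(f"unknown format {fmt!r}")
    if orientation not in ("spots-as-rows", "genes-as-rows"):
        raise ContractError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    counts = _validate_count_frame(df, str(path))
    if orientation == "genes-as-rows":
        genes = [str(g) for g in df.index]
        tokens = [str(t) for t in df.columns]
        counts = counts.T
    else:
        genes = [str(g) for g in df.columns]
        tokens = [str(t) for t in df.index]
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate gene identifiers")
    if len(set(tokens)) != len(tokens):
        raise FormatError(f"{path}: duplicate spot tokens")
    spots = [parse_spot_id(t, section) for t in tokens]
    return CountMatrix(genes, spots, counts)


def _read_counts_triplet(path: Path, section: str) -> CountMatrix:
    spots_file = path.with_name(path.name + ".spots")
    genes_file = path.with_name(path.name + ".genes")
    for f in (spots_file, genes_file):
        if not f.exists():
            raise FormatError(f"triplet sidecar file missing: {f}")
    tokens = [ln.strip() for ln in spots_file.read_text().splitlines() if ln.strip()]
    genes = [ln.strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
    spots = [parse_spot_id(t, section) for t in tokens]
    trip = pd.read_csv(path, sep="\t", header=None, names=["s", "g", "x"])
    counts = np.zeros((len(spots), len(genes)), dtype=np.int64)
    si = trip["s"].to_numpy(dtype=int)
    gi = trip["g"].to_numpy(dtype=int)
    x = trip["x"].to_numpy()
    if np.any(x != np.floor(x)) or (x.size and x.min() < 0):
        raise FormatError(f"{path}: triplet counts must be non-negative integers")
    if si.size and (si.min() < 0 or si.max() >= len(spots) or gi.min() < 0 or gi.max() >= len(genes)):
        raise FormatError(f"{path}: triplet index out of range")
    counts[si, gi] = x.astype(np.int64)
    return CountMatrix(genes, spots, counts)


def write_counts(
    cm: CountMatrix,
    path: str | Path,
    orientation: str = "spots-as-rows",
    fmt: str = "dense",
) -> None:
    """Write a :class:`CountMatrix` as TSV, losslessly re-readable."""
    path = Path(path)
    if fmt == "triplet":
        _write_counts_triplet(cm, path)
        return
    if fmt != "dense":
        raise ContractError(f"unknown format {fmt!r}")
    tokens = [s.token for s in cm.spots]
    if orientation == "spots-as-rows":
        df = pd.DataFrame(cm.counts, index=pd.Index(tokens, name="spot"), columns=cm.genes)
    elif orientation == "genes-as-rows":
        df = pd.DataFrame(cm.counts.T, index=pd.Index(cm.genes, name="gene"), columns=tokens)
    else:
        raise ContractError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", lineterminator="\n")


def _write_counts_triplet(cm: CountMatrix, path: Path) -> None:
    si, gi = np.nonzero(cm.counts)
    trip = pd.DataFrame({"s": si, "g": gi, "x": cm.counts[si, gi]})
    trip.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")
    path.with_name(path.name + ".spots").write_text("".join(s.token + "\n" for s in cm.spots))
    path.with_name(path.name + ".genes").write_text("".join(g + "\n" for g in cm.genes))


@dataclass
class SpotSelection:
    """Labelled spot subsets (e.g. tumor ``center`` vs ``periphery``)."""

    entries: dict[SpotId, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for spot, label in self.entries.items():
            if not label:
                raise ContractError(f"empty label for spot {spot}")

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.entries.values():
            seen.setdefault(lab, None)
        return list(seen)

    def spots_with(self, label: str) -> list[SpotId]:
        return [s for s, lab in self.entries.items() if lab == label]

    def resolve(self, cm: CountMatrix, label: str) -> np.ndarray:
        """Indices into ``cm.spots`` carrying ``label``; all must resolve."""
        index = cm.spot_index()
        out = []
        for spot in self.spots_with(label):
            if spot not in index:
                raise ContractError(f"selection spot {spot.section}:{spot.token} absent from matrix")
            out.append(index[spot])
        return np.asarray(out, dtype=int)


def read_spot_selection(path: str | Path) -> SpotSelection:
    """Read a selection TSV with header ``section<TAB>spot<TAB>label``."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    expected = ["section", "spot", "label"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: expected header {expected!r}, got {list(df.columns)!r}")
    entries: dict[SpotId, str] = {}
    for _, row in df.iterrows():
        section = "" if pd.isna(row["section"]) else str(row["section"])
        spot = parse_spot_id(str(row["spot"]), section)
        label = str(row["label"])
        if spot in entries and entries[spot] != label:
            raise FormatError(
                f"{path}: conflicting labels {entries[spot]!r} and {label!r} "
                f"for spot {section}:{spot.token}"
            )
        entries[spot] = label
    return SpotSelection(entries)


def write_spot_selection(sel: SpotSelection, path: str | Path) -> None:
    rows = [(s.section, s.token, lab) for s, lab in sel.entries.items()]
    df = pd.DataFrame(rows, columns=["section", "spot", "label"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Uniform TSV writer for result tables (newline-terminated)."""
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
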