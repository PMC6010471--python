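"""Seeded synthetic datasets with the structure the analyses assume.

Spatial expression data are generated from the package's own gamma-Poisson
factorization model: sparse gamma gene profiles with planted marker genes,
smooth region-structured factor activities built from Gaussian bumps on the
spot array (emulating glandular/stromal regions), log-normal per-spot depth
scaling, and Poisson counts with the latent factor split retained so
recovery can be scored exactly.  Copy-number segment tables are generated
with cluster-shared deletions and amplifications over a 1200-bp-aligned
grid, so the CNV vector filter and similarity tree can be exercised without
real sequencing data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as st_io
from .cnv import SegmentTable
from .errors import ContractError
from .io import CountMatrix, SpotId
from .model import FactorModel, LatentAllocation, PriorSpec, sample_counts


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions of a synthetic ST dataset.

    The defaults describe a desk-scale array: a 20 x 20 spot grid (one
    section), T = 3 factors over 200 genes, 20 marker genes per factor
    boosted 10x, two activity regions (Gaussian bumps of width 3 array
    units) per factor, a mean library of ~2000 counts per spot and mild
    log-normal depth dispersion.
    """

    grid_rows: int = 20
    grid_cols: int = 20
    sections: int = 1
    n_factors: int = 3
    n_genes: int = 200
    markers_per_factor: int = 20
    marker_boost: float = 10.0
    blobs_per_factor: int = 2
    blob_width: float = 3.0
    mean_library_size: float = 2000.0
    scaling_dispersion: float = 0.15
    profile_shape: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "grid_rows", "grid_cols", "sections", "n_factors", "n_genes",
            "markers_per_factor", "blobs_per_factor",
        ):
            if getattr(self, name) < 1:
                raise ContractError(f"{name} must be >= 1")
        if self.marker_boost < 1:
            raise ContractError("marker_boost must be >= 1 (1 disables planting)")
        if self.markers_per_factor * self.n_factors > self.n_genes:
            raise ContractError("more marker genes than genes")
        if self.mean_library_size <= 0 or self.blob_width <= 0:
            raise ContractError("mean_library_size and blob_width must be positive")
        if self.scaling_dispersion < 0:
            raise ContractError("scaling_dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth model with its spot/gene ids and planted marker lists."""

    model: FactorModel
    spots: list[SpotId]
    genes: list[str]
    markers: dict[int, list[str]]
    spec: SimulationSpec


def make_truth(spec: SimulationSpec) -> SyntheticTruth:
    """Draw a ground-truth factor model for the given study conditions.

    Profiles are Gamma(shape, 1) draws; each factor's marker genes have
    their entry in that factor raised to ``marker_boost`` times the gene's
    largest background value, guaranteeing the planted contrast (with
    boost = 1 profiles are left exchangeable).  Activities are sums of
    Gaussian bumps at distinct centers, per section, globally scaled so the
    expected library size matches the target.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    G, T = spec.n_genes, spec.n_factors
    phi = rng.gamma(spec.profile_shape, 1.0, size=(G, T))
    markers: dict[int, list[str]] = {}
    genes = [f"gene_{g:05d}" for g in range(G)]
    m = spec.markers_per_factor
    for t in range(T):
        ids = list(range(t * m, (t + 1) * m))
        markers[t] = [genes[g] for g in ids]
        if spec.marker_boost > 1:
            phi[ids, t] = spec.marker_boost * phi[ids, :].max(axis=1)

    spots: list[SpotId] = []
    theta_cols = []
    xs, ys = np.meshgrid(np.arange(spec.grid_cols), np.arange(spec.grid_rows))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    for sec in range(spec.sections):
        label = str(sec + 1)
        spots.extend(SpotId(label, int(x), int(y)) for x, y in coords.astype(int))
        n_centers = T * spec.blobs_per_factor
        if n_centers > len(coords):
            raise ContractError("more activity bumps than grid cells")
        centers = coords[rng.choice(len(coords), size=n_centers, replace=False)]
        theta = np.zeros((T, len(coords)))
        for t in range(T):
            own = centers[t * spec.blobs_per_factor : (t + 1) * spec.blobs_per_factor]
            d2 = ((coords[None, :, :] - own[:, None, :]) ** 2).sum(axis=2)
            theta[t] = np.exp(-d2 / (2.0 * spec.blob_width**2)).sum(axis=0)
        theta_cols.append(theta)
    theta = np.concatenate(theta_cols, axis=1)
    sigma = rng.lognormal(0.0, spec.scaling_dispersion, size=theta.shape[1])
    expected_lib = sigma * (phi.sum(axis=0) @ theta)
    theta *= spec.mean_library_size / expected_lib.mean()
    model = FactorModel(phi, theta, sigma, PriorSpec())
    return SyntheticTruth(model, spots, genes, markers, spec)


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    allocation: LatentAllocation
    truth: SyntheticTruth


def simulate_dataset(
    truth: SyntheticTruth,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> SimulatedDataset:
    """Sample counts from the truth model; optionally write everything out.

    When ``outdir`` is given, one count TSV per section is written together
    with the truth profiles/activities/scaling, the marker lists and a
    manifest.  The sampling seed defaults to a stream derived from the
    spec's seed so truth and counts stay jointly reproducible.
    """
    rng = np.random.default_rng([truth.spec.seed, 1] if seed is None else seed)
    counts, alloc = sample_counts(truth.model, rng, spots=truth.spots, genes=truth.genes)
    ds = SimulatedDataset(counts, alloc, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sections = counts.sections
        for sec in sections:
            st_io.write_counts(counts.section_subset(sec), outdir / f"counts_{sec}.tsv")
        m = truth.model
        pd.DataFrame(m.profiles, index=truth.genes,
                     columns=[f"factor_{t}" for t in range(m.n_factors)]).to_csv(
            outdir / "truth_profiles.tsv", sep="\t", index_label="gene", lineterminator="\n")
        pd.DataFrame(m.activities.T, index=[f"{s.section}:{s.token}" for s in truth.spots],
                     columns=[f"factor_{t}" for t in range(m.n_factors)]).to_csv(
            outdir / "truth_activities.tsv", sep="\t", index_label="spot", lineterminator="\n")
        pd.DataFrame({"spot": [f"{s.section}:{s.token}" for s in truth.spots],
                      "sigma": m.scaling}).to_csv(
            outdir / "truth_scaling.tsv", sep="\t", index=False, lineterminator="\n")
        rows = [(t, g) for t, gs in truth.markers.items() for g in gs]
        pd.DataFrame(rows, columns=["factor", "gene"]).to_csv(
            outdir / "truth_markers.tsv", sep="\t", index=False, lineterminator="\n")
        manifest = {"spec": asdict(truth.spec), "sections": sections,
                    "files": sorted(p.name for p in outdir.iterdir())}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ds


# ---------------------------------------------------------------------------
# copy-number segment simulation


DEFAULT_CHROM_SIZES: dict[str, int] = {"chr1": 1_200_000, "chr2": 1_200_000}


@dataclass
class SegmentSimulation:
    tables: list[SegmentTable]
    clusters: list[int]          # cluster index per sample
    events: pd.DataFrame         # cluster, kind, chrom, start, end, cn


def simulate_segments(
    n_samples: int = 12,
    clusters: Sequence[int] | int = 4,
    chrom_sizes: Mapping[str, int] | None = None,
    events_per_cluster: int = 2,
    event_width: int = 60_000,
    deletion_cn: float = 0.5,
    amplification_cn: float = 3.5,
    noise_sd: float = 0.05,
    private_events: int = 0,
    seed: int = 0,
) -> SegmentSimulation:
    """Simulate per-sample segment tables with planted cluster structure.

    The genome is segmented into ``event_width`` slots aligned to the
    1200-bp grid; every sample's background copy number is 2.0 plus
    N(0, noise_sd) noise per slot.  Each cluster receives
    ``events_per_cluster`` shared deletion (cn ``deletion_cn``) and as many
    shared amplification (cn ``amplification_cn``) slots, disjoint across
    clusters; optional private events are planted per sample.  Planted
    levels fall well outside the 1.6/2.3 clear-event window, so the
    downstream vector filter retains them.  Deterministic given the seed.
    """
    if events_per_cluster < 1:
        raise ContractError("events_per_cluster must be >= 1")
    if event_width % 1200 != 0:
        raise ContractError("event_width must be a multiple of the 1200 bp grid")
    if isinstance(clusters, int):
        cluster_of = [i % clusters for i in range(n_samples)]
    else:
        cluster_of = list(clusters)
        if len(cluster_of) != n_samples:
            raise ContractError("cluster assignment length must equal n_samples")
    n_clusters = len(set(cluster_of))
    sizes = dict(chrom_sizes) if chrom_sizes is not None else dict(DEFAULT_CHROM_SIZES)
    slots: list[tuple[str, int, int]] = []
    for chrom, size in sizes.items():
        size = int(size)
        if size < event_width:
            raise ContractError(f"chromosome {chrom!r} shorter than one event slot")
        for start in range(0, size - event_width + 1, event_width):
            slots.append((str(chrom), start, start + event_width))
        if size % event_width:
            tail = size - size % event_width
            slots.append((str(chrom), tail, size))
    needed = n_clusters * 2 * events_per_cluster + n_samples * private_events
    if needed > len(slots):
        raise ContractError(f"need {needed} event slots but genome has only {len(slots)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slots))
    cursor = 0
    event_rows = []
    slot_cn: dict[int, dict[int, float]] = {i: {} for i in range(len(slots))}  # slot -> cluster -> cn
    for c in sorted(set(cluster_of)):
        for kind, cn in (("deletion", deletion_cn), ("amplification", amplification_cn)):
            for _ in range(events_per_cluster):
                si = int(order[cursor])
                cursor += 1
                slot_cn[si][c] = cn
                chrom, start, end = slots[si]
                event_rows.append((c, kind, chrom, start, end, cn))
    private: dict[int, dict[int, float]] = {i: {} for i in range(len(slots))}  # slot -> sample -> cn
    for j in range(n_samples):
        for _ in range(private_events):
            si = int(order[cursor])
            cursor += 1
            cn = deletion_cn if rng.uniform() < 0.5 else amplification_cn
            private[si][j] = cn
            chrom, start, end = slots[si]
            event_rows.append((-1 - j, "private", chrom, start, end, cn))
    tables = []
    for j in range(n_samples):
        base = np.full(len(slots), 2.0)
        for si, by_cluster in slot_cn.items():
            if cluster_of[j] in by_cluster:
                base[si] = by_cluster[cluster_of[j]]
        for si, by_sample in private.items():
            if j in by_sample:
                base[si] = by_sample[j]
        noisy = np.clip(base + rng.normal(0.0, noise_sd, size=len(slots)), 0.0, None)
        df = pd.DataFrame(
            {
                "chrom": [s[0] for s in slots],
                "start": [s[1] for s in slots],
                "end": [s[2] for s in slots],
                "cn": noisy,
            }
        )
        tables.append(SegmentTable(f"sample_{j:02d}", df))
    events = pd.DataFrame(
        event_rows, columns=["cluster", "kind", "chrom", "start", "end", "cn"]
    )
    return SegmentSimulation(tables, cluster_of, events)
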