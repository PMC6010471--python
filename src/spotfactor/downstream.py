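"""Post-deconvolution statistics for ST data.

Covers spot/gene quality control, library-size and pooled-size-factor
normalization, variable-gene selection and PCA, factor similarity trees on
the quantitative Jaccard (Ruzicka) distance, per-factor marker (outlier)
genes via z-scores gated by a Kolmogorov-Smirnov normality check, tumor
center-vs-periphery differential expression, and 3-D t-SNE color summaries
of spot-level matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .io import CountMatrix, SpotId, SpotSelection
from .trees import ClusterTree, bootstrap_tree

MAD_NORMAL_CONSTANT = 1.4826  # consistency constant for a normal distribution


@dataclass
class NormalizedMatrix:
    """Spots x genes matrix of normalized expression values."""

    values: np.ndarray
    genes: list[str]
    spots: list[SpotId]
    method: str  # "cpm" or "pooled-size-factor"
    size_factors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.spots), len(self.genes)):
            raise ContractError("normalized values inconsistent with spot/gene ids")
        if self.values.size and self.values.min() < 0:
            raise ContractError("normalized values must be non-negative")
        if self.method not in ("cpm", "pooled-size-factor"):
            raise ContractError(f"unknown normalization method {self.method!r}")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def spot_index(self) -> dict[SpotId, int]:
        return {s: i for i, s in enumerate(self.spots)}


# ---------------------------------------------------------------------------
# quality control


def qc_filter_spots(cm: CountMatrix, nmads: float = 3.0) -> CountMatrix:
    """Drop spots whose log library size falls more than ``nmads`` median
    absolute deviations (normal-consistent, natural log) below the median."""
    if cm.n_spots < 1:
        raise ContractError("need at least one spot")
    with np.errstate(divide="ignore"):
        log_lib = np.log(cm.library_sizes.astype(float))
    med = np.median(log_lib)
    mad = MAD_NORMAL_CONSTANT * np.median(np.abs(log_lib - med))
    keep = ~(log_lib < med - nmads * mad)  # strict inequality removes
    if not keep.any():
        warnings.warn("spot QC removed every spot")
    return cm.select_spots(np.flatnonzero(keep))


def filter_genes(cm: CountMatrix, min_total: int = 1) -> CountMatrix:
    """Drop low-abundance genes with total count below ``min_total``."""
    totals = cm.counts.sum(axis=0)
    return cm.select_genes(np.flatnonzero(totals >= min_total))


# ---------------------------------------------------------------------------
# normalization


def normalize_cpm(cm: CountMatrix) -> NormalizedMatrix:
    """Counts per million: count * 1e6 / spot library size."""
    lib = cm.library_sizes.astype(float)
    if np.any(lib == 0):
        bad = cm.spots[int(np.flatnonzero(lib == 0)[0])]
        raise ContractError(f"zero library size at spot {bad.section}:{bad.token}")
    values = cm.counts * (1e6 / lib)[:, None]
    return NormalizedMatrix(values, list(cm.genes), list(cm.spots), "cpm")


def pooled_size_factors(cm: CountMatrix, pool_sizes: tuple[int, ...] = (21, 41)) -> np.ndarray:
    """Per-spot size factors from sliding pools of spots.

    Spots are ordered by library size on a ring; for every window of each
    pool size, the pooled count profile is compared to the average profile
    by a median ratio, giving one linear equation (the sum of the member
    factors equals the pooled ratio) under the assumption that most genes
    are not differentially expressed.  The stacked system is solved by least
    squares and the factors scaled to mean one.  Falls back to library-size
    factors (with a warning) if the solution is not strictly positive.
    """
    S = cm.n_spots
    counts = cm.counts.astype(float)
    lib = counts.sum(axis=1)
    if np.any(lib == 0):
        bad = cm.spots[int(np.flatnonzero(lib == 0)[0])]
        raise ContractError(f"zero library size at spot {bad.section}:{bad.token}")
    sizes = sorted({min(int(k), S) for k in pool_sizes if k >= 1})
    if not sizes:
        raise ContractError("need at least one pool size >= 1")
    order = np.argsort(lib, kind="stable")
    ref = counts.mean(axis=0)
    informative = ref > 0
    rows: list[np.ndarray] = []
    rhs: list[float] = []
    for k in sizes:
        for i in range(S):
            members = order[(i + np.arange(k)) % S]
            pooled = counts[members].sum(axis=0)
            ratio = float(np.median(pooled[informative] / ref[informative]))
            row = np.zeros(S)
            row[members] = 1.0
            rows.append(row)
            rhs.append(ratio)
    A = np.vstack(rows)
    b = np.asarray(rhs)
    factors, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < S or np.any(factors <= 0):
        warnings.warn("pooled size-factor system degenerate; using library-size factors")
        factors = lib.copy()
    factors = factors / factors.mean()
    return factors


def normalize_size_factors(cm: CountMatrix, factors: np.ndarray) -> NormalizedMatrix:
    """Divide each spot's counts by its (positive, mean-one) size factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (cm.n_spots,) or np.any(factors <= 0):
        raise ContractError("size factors must be positive, one per spot")
    values = cm.counts / factors[:, None]
    return NormalizedMatrix(
        values, list(cm.genes), list(cm.spots), "pooled-size-factor", size_factors=factors
    )


# ---------------------------------------------------------------------------
# variable genes and PCA


def top_variable_genes(nm: NormalizedMatrix, n: int = 500) -> list[str]:
    """Genes ranked by descending sample variance of log1p values; ties
    broken by gene id."""
    if n > len(nm.genes):
        raise ContractError(f"requested {n} genes but only {len(nm.genes)} available")
    logged = np.log1p(nm.values)
    var = logged.var(axis=0, ddof=1) if nm.n_spots > 1 else np.zeros(len(nm.genes))
    order = np.lexsort((np.asarray(nm.genes), -var))
    return [nm.genes[i] for i in order[:n]]


def pca_scores(data: NormalizedMatrix | np.ndarray, n_components: int = 2) -> np.ndarray:
    """Centered SVD principal-component scores of spots.

    A :class:`NormalizedMatrix` is log1p-transformed first (the package's
    variance-stabilizing stand-in for regularized-log values); raw arrays
    are used as given.  Component signs are fixed by making each loading
    vector's largest-magnitude entry positive.
    """
    if isinstance(data, NormalizedMatrix):
        X = np.log1p(data.values)
    else:
        X = np.asarray(data, dtype=float)
    if n_components > min(X.shape):
        raise ContractError("n_components exceeds matrix rank bound")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for c in range(n_components):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            U[:, c] = -U[:, c]
            Vt[c] = -Vt[c]
    return U[:, :n_components] * s[:n_components]


# ---------------------------------------------------------------------------
# factor trees


def ruzicka_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Quantitative Jaccard distance 1 - sum(min)/sum(max) on non-negative
    vectors; two all-zero vectors are at distance 0 by convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ContractError("Ruzicka distance requires non-negative vectors")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        warnings.warn("two all-zero profiles: distance 0 by convention")
        return 0.0
    return 1.0 - float(np.minimum(x, y).sum()) / float(denom)


def ruzicka_condensed(items: np.ndarray) -> np.ndarray:
    n = items.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(ruzicka_distance(items[i], items[j]))
    return np.asarray(out)


def jaccard_binary_condensed(items: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(items > 0, metric="jaccard")


def factor_tree(
    profiles: np.ndarray,
    labels: list[str] | None = None,
    distance: str = "ruzicka",
    nboot: int = 0,
    seed: int = 0,
) -> ClusterTree:
    """Ward.D2 dendrogram of factors from their (genes x T) expression
    profiles, with optional gene-bootstrap clade supports."""
    profiles = np.asarray(profiles, dtype=float)
    T = profiles.shape[1]
    if T < 2:
        raise ContractError("need at least two factors")
    if labels is None:
        labels = [f"factor_{t}" for t in range(T)]
    fn = {"ruzicka": ruzicka_condensed, "jaccard": ruzicka_condensed,
          "jaccard-binary": jaccard_binary_condensed}.get(distance)
    if fn is None:
        raise ContractError(f"unknown distance {distance!r}")
    return bootstrap_tree(profiles.T, labels, fn, nboot=nboot, seed=seed)


# ---------------------------------------------------------------------------
# marker (outlier) genes


def _ks_normal_pvalues(values: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Row-wise one-sample KS p-values against Normal(mean, sd).

    Vectorized version of the exact two-sided KS test for small samples
    (the same kstwo survival function scipy's kstest uses)."""
    n = values.shape[1]
    sorted_vals = np.sort(values, axis=1)
    with np.errstate(invalid="ignore"):
        cdf = stats.norm.cdf(sorted_vals, loc=mean[:, None], scale=sd[:, None])
    grid = np.arange(1, n + 1) / n
    d_plus = (grid[None, :] - cdf).max(axis=1)
    d_minus = (cdf - (np.arange(n) / n)[None, :]).max(axis=1)
    d = np.maximum(d_plus, d_minus)
    return stats.kstwo.sf(np.clip(d, 0, 1), n)


def outlier_genes(
    profiles: np.ndarray,
    gene_ids: list[str] | None = None,
    z_threshold: float = 2.5,
    alpha: float = 0.05,
) -> dict[int, list[str]]:
    """Per-factor outlier genes from cross-factor z-scores.

    Profiles are first normalized per factor (column sums one).  For gene g
    and factor t a normal distribution is fitted to the gene's values in the
    other factors; g is reported for t iff its z-score exceeds
    ``z_threshold`` and the other-factor values pass the KS normality test
    at level ``alpha`` (p >= alpha).  Genes whose other-factor values are
    constant are skipped for that factor.
    """
    phi = np.asarray(profiles, dtype=float)
    G, T = phi.shape
    if T < 4:
        raise ContractError("need at least 4 factors (3 reference values per test)")
    if gene_ids is None:
        gene_ids = [f"gene_{g}" for g in range(G)]
    colsum = phi.sum(axis=0)
    phi = phi / np.where(colsum > 0, colsum, 1.0)
    out: dict[int, list[str]] = {}
    for t in range(T):
        others = np.delete(phi, t, axis=1)  # (G, T-1)
        mu = others.mean(axis=1)
        sd = others.std(axis=1, ddof=1)
        ok = sd > 0
        z = np.full(G, -np.inf)
        z[ok] = (phi[ok, t] - mu[ok]) / sd[ok]
        candidates = np.flatnonzero(ok & (z > z_threshold))
        flagged: list[str] = []
        if candidates.size:
            pks = _ks_normal_pvalues(others[candidates], mu[candidates], sd[candidates])
            flagged = [gene_ids[g] for g, p in zip(candidates, pks) if p >= alpha]
        out[t] = sorted(flagged)
    return out


def top_genes_per_factor(
    profiles: np.ndarray, gene_ids: list[str] | None = None, n: int = 200
) -> dict[int, list[str]]:
    """Top-n genes per factor by normalized profile weight; ties by id."""
    phi = np.asarray(profiles, dtype=float)
    G, T = phi.shape
    if n > G:
        raise ContractError(f"requested {n} genes but only {G} available")
    if gene_ids is None:
        gene_ids = [f"gene_{g}" for g in range(G)]
    colsum = phi.sum(axis=0)
    phi = phi / np.where(colsum > 0, colsum, 1.0)
    ids = np.asarray(gene_ids)
    out: dict[int, list[str]] = {}
    for t in range(T):
        order = np.lexsort((ids, -phi[:, t]))
        out[t] = [gene_ids[i] for i in order[:n]]
    return out


# ---------------------------------------------------------------------------
# center vs periphery differential expression


def de_center_periphery(
    nm: NormalizedMatrix,
    sel: SpotSelection,
    center_label: str = "center",
    periphery_label: str = "periphery",
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-gene fold change (center mean / periphery mean) and Welch
    two-sample t-test on normalized values.

    Genes with zero variance in both groups get p = 0 when the means differ
    and p = 1 when they agree, with ``zero_variance`` set.  A zero periphery
    mean yields an infinite fold change, flagged via ``infinite_fold``.
    """
    index = nm.spot_index()
    groups = {}
    for label in (center_label, periphery_label):
        spots = sel.spots_with(label)
        if len(spots) < 2:
            raise ContractError(f"group {label!r} needs at least two selected spots")
        rows = []
        for s in spots:
            if s not in index:
                raise ContractError(f"selection spot {s.section}:{s.token} absent from matrix")
            rows.append(index[s])
        groups[label] = nm.values[np.asarray(rows, dtype=int)]
    a = groups[center_label]
    b = groups[periphery_label]
    mean_c = a.mean(axis=0)
    mean_p = b.mean(axis=0)
    var_c = a.var(axis=0, ddof=1)
    var_p = b.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pvals = stats.ttest_ind(a, b, axis=0, equal_var=False).pvalue
    zero_var = (var_c == 0) & (var_p == 0)
    pvals = np.where(zero_var, np.where(mean_c == mean_p, 1.0, 0.0), pvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_p > 0, mean_c / np.where(mean_p > 0, mean_p, 1.0), np.inf)
        fold = np.where((mean_p == 0) & (mean_c == 0), 1.0, fold)
    return pd.DataFrame(
        {
            "gene": nm.genes,
            "mean_center": mean_c,
            "mean_periphery": mean_p,
            "fold_change": fold,
            "p_value": pvals,
            "significant": pvals < p_cut,
            "zero_variance": zero_var,
            "infinite_fold": np.isinf(fold),
        }
    )


# ---------------------------------------------------------------------------
# t-SNE color summaries


def tsne_colors(matrix: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """Embed spots into three t-SNE dimensions scaled to [0, 1] as RGB.

    Similar rows (spots with similar expression or factor activity) receive
    similar colors.  The perplexity is capped at (rows - 1) / 3 with a
    warning when the matrix is small.  Deterministic given ``seed``.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ContractError("t-SNE coloring needs at least 4 spots")
    cap = (n - 1) / 3.0
    if perplexity > cap:
        warnings.warn(f"perplexity {perplexity} too large for {n} rows; reduced to {cap:.2f}")
        perplexity = cap
    emb = TSNE(
        n_components=3,
        perplexity=perplexity,
        method="exact",
        init="pca",
        random_state=seed,
    ).fit_transform(X)
    lo = emb.min(axis=0)
    span = emb.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    return (emb - lo) / span
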