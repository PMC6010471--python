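"""Gamma-Poisson factorization model for spatial count data.

The observed count x_gs for gene g in spot s is the sum over T latent
factors of independent Poisson contributions::

    x_gs = sum_t x_gts,   x_gts ~ Pois(mu_gts),   mu_gts = phi_gt * theta_ts * sigma_s

where ``phi_gt`` is the expression of gene g in factor t (spot-independent),
``theta_ts`` the spatial activity of factor t in spot s (gene-independent),
and ``sigma_s`` a spot-dependent scaling variable absorbing library-depth
differences.  Marginally x_gs ~ Pois(sigma_s * sum_t phi_gt theta_ts), so the
expected count matrix is the product of the profile and activity matrices
scaled per spot.  Setting sigma = 1 recovers the core model without depth
correction.

Priors are independent Gamma(shape, rate) on every phi, theta and sigma
entry, chosen for conjugacy with the Poisson likelihood; the defaults
(shape 0.5, rate 0.5) are mildly sparsity-inducing with prior mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .errors import ContractError
from .io import CountMatrix, SpotId


@dataclass(frozen=True)
class PriorSpec:
    """Gamma shape/rate pairs for profiles (a,b), activities (c,d) and
    scaling (e,f), plus the spatial-smoothing strength ``smoothing``
    (lambda >= 0; 0 disables the Markov-random-field penalty)."""

    a: float = 0.5
    b: float = 0.5
    c: float = 0.5
    d: float = 0.5
    e: float = 0.5
    f: float = 0.5
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        for name in "abcdef":
            if getattr(self, name) <= 0:
                raise ContractError(f"prior {name} must be > 0")
        if self.smoothing < 0:
            raise ContractError("smoothing must be >= 0")


@dataclass
class FactorModel:
    """Parameters of the factorization: Phi (genes x T), Theta (T x spots),
    sigma (spots,)."""

    profiles: np.ndarray   # phi, (G, T)
    activities: np.ndarray  # theta, (T, S)
    scaling: np.ndarray    # sigma, (S,)
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        self.scaling = np.asarray(self.scaling, dtype=float)
        if self.profiles.ndim != 2 or self.activities.ndim != 2 or self.scaling.ndim != 1:
            raise ContractError("profiles must be 2-D, activities 2-D, scaling 1-D")
        if self.profiles.shape[1] != self.activities.shape[0]:
            raise ContractError(
                f"factor count mismatch: profiles T={self.profiles.shape[1]}, "
                f"activities T={self.activities.shape[0]}"
            )
        if self.activities.shape[1] != self.scaling.shape[0]:
            raise ContractError("activities and scaling disagree on the number of spots")
        if self.n_factors < 1:
            raise ContractError("need at least one factor")
        if np.any(self.profiles < 0) or np.any(self.activities < 0):
            raise ContractError("profiles and activities must be non-negative")
        if np.any(self.scaling <= 0):
            raise ContractError("scaling must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.profiles.shape[0]

    @property
    def n_factors(self) -> int:
        return self.profiles.shape[1]

    @property
    def n_spots(self) -> int:
        return self.activities.shape[1]

    @property
    def scaled_activities(self) -> np.ndarray:
        """Identifiable activity maps sigma_s * theta_ts: the expected mRNA a
        factor contributes per spot.  Theta and sigma share a per-spot scale
        that the likelihood cannot separate, so recovery is evaluated on this
        product rather than on theta alone."""
        return self.activities * self.scaling[None, :]

    def copy(self) -> "FactorModel":
        return FactorModel(
            self.profiles.copy(), self.activities.copy(), self.scaling.copy(), self.priors
        )

    def with_priors(self, priors: PriorSpec) -> "FactorModel":
        return replace(self.copy(), priors=priors)


@dataclass
class LatentAllocation:
    """Per-(gene, spot) split of observed counts into factor contributions.

    Stored sparsely over the nonzero observed entries: ``spot_idx[k]``,
    ``gene_idx[k]`` locate entry k and ``counts[k, t]`` is x_gts.  The factor
    sums reproduce the observed counts exactly (integer identity).
    """

    spot_idx: np.ndarray   # (nnz,)
    gene_idx: np.ndarray   # (nnz,)
    counts: np.ndarray     # (nnz, T) integer
    shape: tuple[int, int]  # (n_spots, n_genes)

    def __post_init__(self) -> None:
        if not (len(self.spot_idx) == len(self.gene_idx) == len(self.counts)):
            raise ContractError("allocation arrays must share their first dimension")
        if self.counts.size and self.counts.min() < 0:
            raise ContractError("allocated counts must be non-negative")

    @property
    def n_factors(self) -> int:
        return self.counts.shape[1]

    def observed(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def totals_by_gene(self, n_genes: int | None = None) -> np.ndarray:
        """Sum_s x_gts as a (G, T) array."""
        G = n_genes if n_genes is not None else self.shape[1]
        out = np.zeros((G, self.n_factors))
        for t in range(self.n_factors):
            out[:, t] = np.bincount(self.gene_idx, weights=self.counts[:, t], minlength=G)
        return out

    def totals_by_spot(self, n_spots: int | None = None) -> np.ndarray:
        """Sum_g x_gts as a (T, S) array."""
        S = n_spots if n_spots is not None else self.shape[0]
        out = np.zeros((self.n_factors, S))
        for t in range(self.n_factors):
            out[t] = np.bincount(self.spot_idx, weights=self.counts[:, t], minlength=S)
        return out

    def to_dense(self) -> np.ndarray:
        """(T, S, G) dense array of x_gts; for small problems only."""
        S, G = self.shape
        dense = np.zeros((self.n_factors, S, G), dtype=np.int64)
        dense[:, self.spot_idx, self.gene_idx] = self.counts.T
        return dense


def expected_counts(m: FactorModel) -> np.ndarray:
    """E[X] as a (spots, genes) matrix: sigma_s * sum_t phi_gt theta_ts."""
    return (m.activities.T @ m.profiles.T) * m.scaling[:, None]


def log_likelihood(m: FactorModel, cm: CountMatrix) -> float:
    """Poisson log-likelihood of the observed counts under the model.

    Returns -inf (with a warning) if some mu_gs = 0 where x_gs > 0.
    """
    if (m.n_genes, m.n_spots) != (cm.n_genes, cm.n_spots):
        raise ContractError(
            f"model is {m.n_genes} genes x {m.n_spots} spots but matrix is "
            f"{cm.n_genes} x {cm.n_spots}"
        )
    x = cm.counts
    mu = expected_counts(m)
    pos = x > 0
    if np.any(mu[pos] == 0):
        warnings.warn("zero expected count where observations are positive; log-likelihood is -inf")
        return float("-inf")
    ll = -mu.sum() - gammaln(x + 1.0).sum()
    ll += float(np.sum(x[pos] * np.log(mu[pos])))
    return float(ll)


def _default_spots(n_spots: int, section: str = "sim") -> list[SpotId]:
    side = int(np.ceil(np.sqrt(n_spots)))
    return [SpotId(section, i % side, i // side) for i in range(n_spots)]


def sample_counts(
    m: FactorModel,
    seed: int | np.random.Generator,
    spots: list[SpotId] | None = None,
    genes: list[str] | None = None,
) -> tuple[CountMatrix, LatentAllocation]:
    """Draw a dataset from the generative model.

    Each latent contribution x_gts ~ Pois(phi_gt * theta_ts * sigma_s) is
    drawn independently; the returned counts are the factor sums and the
    allocation retains the per-factor split, so conservation
    sum_t x_gts = x_gs holds by construction.  Deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G, T, S = m.n_genes, m.n_factors, m.n_spots
    if spots is None:
        spots = _default_spots(S)
    if genes is None:
        genes = [f"gene_{g:05d}" for g in range(G)]
    if len(spots) != S or len(genes) != G:
        raise ContractError("spot/gene id lists inconsistent with model dimensions")
    # (T, S, G) rates
    rates = m.profiles.T[:, None, :] * m.activities[:, :, None] * m.scaling[None, :, None]
    latent = rng.poisson(rates)
    counts = latent.sum(axis=0)
    si, gi = np.nonzero(counts)
    alloc = LatentAllocation(si, gi, latent[:, si, gi].T.astype(np.int64), (S, G))
    return CountMatrix(genes, spots, counts), alloc
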