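"""Gibbs sampling for the gamma-Poisson factorization model.

The sampler exploits two classical conjugacies:

* Poisson superposition: conditional on the observed total x_gs and the
  current rates, the latent factor contributions x_gts follow a multinomial
  with probabilities proportional to phi_gt * theta_ts (the spot scaling
  sigma_s cancels in the normalization).
* Gamma-Poisson: conditional on the allocation, every phi_gt, theta_ts and
  sigma_s has a gamma full conditional, e.g.
  phi_gt | . ~ Gamma(a + sum_s x_gts, b + sum_s sigma_s theta_ts).

A sweep therefore cycles allocate -> profiles -> activities -> scaling and
records the log posterior.  Optional spatial smoothing adds a pairwise
squared-difference penalty on log-activities over the rook-adjacency graph
of the array (neighbors at L1 distance 1 within a section); the activity
update then becomes Metropolis-within-Gibbs with the conjugate draw as the
proposal, so the penalty alone decides acceptance.

Factor labels are not identifiable (columns of Phi can be permuted, and
Phi/Theta share a scale); :func:`summarize_posterior` fixes the scale by
normalizing profile columns to sum one, and :func:`match_factors` aligns
labels against a reference for evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateAllocationError,
    DegenerateDataError,
    NumericalError,
)
from .io import CountMatrix, SpotId
from .model import FactorModel, LatentAllocation, PriorSpec


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler settings.

    ``n_factors`` is the number of latent factors T (user-set; the sampler
    does not select it).  ``iterations`` counts total sweeps, of which the
    first ``burn_in`` are discarded and every ``thin``-th of the rest is
    retained.  ``smoothing`` is the spatial penalty strength lambda.  With
    ``shared_profiles`` a multi-section matrix is fitted jointly: one Phi
    for all sections, per-spot Theta and sigma.
    """

    n_factors: int = 10
    iterations: int = 2000
    burn_in: int = 500
    thin: int = 10
    seed: int = 0
    smoothing: float = 0.0
    shared_profiles: bool = False
    sample_activities: bool = True
    sample_scaling: bool = True

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ConfigurationError("n_factors must be >= 1")
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigurationError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.smoothing < 0:
            raise ConfigurationError("smoothing must be >= 0")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned posterior draws plus the per-sweep log-posterior trace."""

    draws: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (phi, theta, sigma)
    log_posterior_trace: np.ndarray
    config: GibbsConfig
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if len(self.draws) != self.config.n_draws:
            raise ContractError(
                f"{len(self.draws)} draws inconsistent with config ({self.config.n_draws} expected)"
            )
        if len(self.log_posterior_trace) != self.config.iterations:
            raise ContractError("trace length must equal the number of sweeps")


def allocate_counts(x: int, rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split one observed count over factors by multinomial thinning.

    Conditional on the total of a Poisson superposition, the components are
    multinomial with probabilities proportional to their rates.
    """
    rates = np.asarray(rates, dtype=float)
    if x < 0:
        raise ContractError("count must be non-negative")
    if np.any(rates < 0):
        raise ContractError("rates must be non-negative")
    total = rates.sum()
    if x == 0:
        return np.zeros(rates.shape[0], dtype=np.int64)
    if total <= 0:
        raise DegenerateAllocationError("positive count with all-zero factor rates")
    return rng.multinomial(x, rates / total).astype(np.int64)


def _allocate_all(
    x_nz: np.ndarray,
    gene_idx: np.ndarray,
    spot_idx: np.ndarray,
    phi: np.ndarray,
    theta: np.ndarray,
    rng: np.random.Generator,
    shape: tuple[int, int],
) -> LatentAllocation:
    """Vectorized multinomial thinning over all nonzero matrix entries."""
    rates = phi[gene_idx, :] * theta[:, spot_idx].T  # (nnz, T)
    totals = rates.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateAllocationError("positive count with all-zero factor rates")
    pvals = rates / totals[:, None]
    # guard against floating-point rows summing to slightly more than one
    pvals[:, -1] = np.clip(1.0 - pvals[:, :-1].sum(axis=1), 0.0, 1.0)
    drawn = rng.multinomial(x_nz, pvals).astype(np.int64)
    return LatentAllocation(spot_idx, gene_idx, drawn, shape)


def update_profiles(
    alloc: LatentAllocation,
    theta: np.ndarray,
    sigma: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
    n_genes: int | None = None,
) -> np.ndarray:
    """Conjugate draw phi_gt ~ Gamma(a + sum_s x_gts, b + sum_s sigma_s theta_ts)."""
    shape = priors.a + alloc.totals_by_gene(n_genes)
    rate = priors.b + theta @ sigma  # (T,)
    return rng.gamma(shape, 1.0 / rate[None, :])


def update_activities(
    alloc: LatentAllocation,
    phi: np.ndarray,
    sigma: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
    smoothing: float = 0.0,
    neighbors: list[np.ndarray] | None = None,
    current: np.ndarray | None = None,
    n_spots: int | None = None,
) -> np.ndarray:
    """Draw activities; conjugate when smoothing = 0, else Metropolis-within-Gibbs.

    The smooth target multiplies the conjugate conditional by
    exp(-lambda * sum_{s' in N(s)} sum_t (log theta_ts - log theta_ts')^2);
    the conjugate draw serves as the proposal, so the acceptance ratio is the
    penalty difference alone.
    """
    shape = priors.c + alloc.totals_by_spot(n_spots)  # (T, S)
    rate = priors.d + np.outer(phi.sum(axis=0), sigma)  # (T, S)
    if smoothing == 0.0:
        return rng.gamma(shape, 1.0 / rate)
    if neighbors is None:
        raise ConfigurationError("spatial smoothing requires a neighbor graph")
    if current is None:
        raise ContractError("Metropolis update needs the current activities")
    theta = current.copy()
    log_theta = np.log(theta)
    S = theta.shape[1]
    for s in range(S):
        prop = rng.gamma(shape[:, s], 1.0 / rate[:, s])
        nbr = neighbors[s]
        if nbr.size == 0:
            theta[:, s] = prop
            log_theta[:, s] = np.log(prop)
            continue
        log_prop = np.log(prop)
        d_new = ((log_prop[:, None] - log_theta[:, nbr]) ** 2).sum()
        d_old = ((log_theta[:, s, None] - log_theta[:, nbr]) ** 2).sum()
        if np.log(rng.uniform()) < -smoothing * (d_new - d_old):
            theta[:, s] = prop
            log_theta[:, s] = log_prop
    return theta


def update_scaling(
    alloc: LatentAllocation,
    phi: np.ndarray,
    theta: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
    n_spots: int | None = None,
) -> np.ndarray:
    """Conjugate draw sigma_s ~ Gamma(e + sum_g x_gs, f + sum_gt phi_gt theta_ts)."""
    S = n_spots if n_spots is not None else alloc.shape[0]
    spot_totals = np.bincount(alloc.spot_idx, weights=alloc.observed(), minlength=S)
    shape = priors.e + spot_totals
    rate = priors.f + phi.sum(axis=0) @ theta  # (S,)
    return rng.gamma(shape, 1.0 / rate)


def build_neighbor_graph(spots: list[SpotId]) -> list[np.ndarray]:
    """Rook adjacency on array coordinates: neighbors at L1 distance 1,
    within the same section only."""
    index = {(s.section, s.x, s.y): i for i, s in enumerate(spots)}
    out: list[np.ndarray] = []
    for s in spots:
        nbr = [
            index[key]
            for key in (
                (s.section, s.x - 1, s.y),
                (s.section, s.x + 1, s.y),
                (s.section, s.x, s.y - 1),
                (s.section, s.x, s.y + 1),
            )
            if key in index
        ]
        out.append(np.asarray(nbr, dtype=int))
    return out


class GibbsSampler:
    """Stateful sweep-by-sweep sampler; :func:`run_gibbs` is the high-level
    driver.  Exposed so invariants (e.g. allocation conservation) can be
    inspected mid-chain."""

    def __init__(
        self,
        cm: CountMatrix,
        cfg: GibbsConfig,
        priors: PriorSpec | None = None,
        init: FactorModel | None = None,
    ):
        if cm.n_spots == 0 or cm.n_genes == 0:
            raise DegenerateDataError("empty count matrix")
        if cm.counts.sum() == 0:
            raise DegenerateDataError("all-zero count matrix carries no signal")
        if cfg.shared_profiles and len(cm.sections) < 1:
            raise ConfigurationError("shared_profiles requires section labels")
        self.cm = cm
        self.cfg = cfg
        base = priors if priors is not None else (init.priors if init is not None else PriorSpec())
        if base.smoothing != cfg.smoothing:
            base = PriorSpec(base.a, base.b, base.c, base.d, base.e, base.f, cfg.smoothing)
        self.priors = base
        self.rng = np.random.default_rng(cfg.seed)
        S, G, T = cm.n_spots, cm.n_genes, cfg.n_factors
        self.shape = (S, G)
        si, gi = np.nonzero(cm.counts)
        self._spot_idx = si
        self._gene_idx = gi
        self._x_nz = cm.counts[si, gi].astype(np.int64)
        self._lgamma_const = float(gammaln(self._x_nz + 1.0).sum())
        self._spot_totals = cm.library_sizes.astype(float)
        self.neighbors = build_neighbor_graph(cm.spots) if cfg.smoothing > 0 else None
        if init is not None:
            if init.n_genes != G or init.n_spots != S or init.n_factors != T:
                raise ContractError("initial model dimensions do not match data/config")
            self.model = init.copy()
        else:
            p = self.priors
            self.model = FactorModel(
                self.rng.gamma(p.a, 1.0 / p.b, size=(G, T)),
                self.rng.gamma(p.c, 1.0 / p.d, size=(T, S)),
                self.rng.gamma(p.e, 1.0 / p.f, size=S),
                p,
            )
        self.alloc = self._allocate()
        self.sweep_index = 0

    def _allocate(self) -> LatentAllocation:
        return _allocate_all(
            self._x_nz,
            self._gene_idx,
            self._spot_idx,
            self.model.profiles,
            self.model.activities,
            self.rng,
            self.shape,
        )

    def sweep(self) -> float:
        """One full Gibbs sweep; returns the log posterior afterwards."""
        m, p, cfg = self.model, self.priors, self.cfg
        self.alloc = self._allocate()
        m.profiles = update_profiles(self.alloc, m.activities, m.scaling, p, self.rng, m.n_genes)
        if cfg.sample_activities:
            m.activities = update_activities(
                self.alloc,
                m.profiles,
                m.scaling,
                p,
                self.rng,
                smoothing=cfg.smoothing,
                neighbors=self.neighbors,
                current=m.activities,
                n_spots=m.n_spots,
            )
        if cfg.sample_scaling:
            m.scaling = update_scaling(self.alloc, m.profiles, m.activities, p, self.rng, m.n_spots)
        self.sweep_index += 1
        return self.log_posterior()

    def log_posterior(self) -> float:
        m, p = self.model, self.priors
        phi_sum = m.profiles.sum(axis=0)  # (T,)
        mu_total = float(m.scaling @ (phi_sum @ m.activities))
        rate_nz = np.einsum(
            "kt,kt->k", m.profiles[self._gene_idx], m.activities[:, self._spot_idx].T
        )
        mu_nz = rate_nz * m.scaling[self._spot_idx]
        if np.any(mu_nz <= 0):
            return float("-inf")
        ll = float(self._x_nz @ np.log(mu_nz)) - mu_total - self._lgamma_const
        lp = ll
        lp += _gamma_logpdf_sum(m.profiles, p.a, p.b)
        lp += _gamma_logpdf_sum(m.activities, p.c, p.d)
        lp += _gamma_logpdf_sum(m.scaling, p.e, p.f)
        if self.cfg.smoothing > 0 and self.neighbors is not None:
            log_theta = np.log(m.activities)
            pen = 0.0
            for s, nbr in enumerate(self.neighbors):
                sel = nbr[nbr > s]  # count each edge once
                if sel.size:
                    pen += float(((log_theta[:, s, None] - log_theta[:, sel]) ** 2).sum())
            lp -= self.cfg.smoothing * pen
        return lp


def _gamma_logpdf_sum(x: np.ndarray, shape: float, rate: float) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(
        n * (shape * np.log(rate) - gammaln(shape))
        + (shape - 1.0) * np.log(x).sum()
        - rate * x.sum()
    )


def run_gibbs(
    cm: CountMatrix,
    cfg: GibbsConfig,
    priors: PriorSpec | None = None,
    init: FactorModel | None = None,
) -> PosteriorSamples:
    """Run the full chain and return thinned post-burn-in draws.

    Fully reproducible given ``cfg.seed``; the log posterior is recorded at
    every sweep and a NaN in the trace aborts with the offending sweep index.
    """
    sampler = GibbsSampler(cm, cfg, priors=priors, init=init)
    trace = np.empty(cfg.iterations)
    draws: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i in range(cfg.iterations):
        lp = sampler.sweep()
        if np.isnan(lp):
            raise NumericalError(f"log posterior is NaN at sweep {i}", sweep=i)
        trace[i] = lp
        k = i + 1 - cfg.burn_in
        if k > 0 and k % cfg.thin == 0:
            m = sampler.model
            draws.append((m.profiles.copy(), m.activities.copy(), m.scaling.copy()))
    return PosteriorSamples(draws, trace, cfg, sampler.priors)


def summarize_posterior(ps: PosteriorSamples) -> FactorModel:
    """Element-wise posterior means, renormalized for identifiability.

    Each profile column is scaled to sum one and the scale moved into the
    activities, leaving expected counts unchanged.  Draws are averaged
    without cross-draw label matching: a single conjugate chain mixes within
    one labelling mode, and evaluation against a reference uses
    :func:`match_factors`.  Averaging draws from chains that switched labels
    would blur factors together.
    """
    if not ps.draws:
        raise ContractError("no retained draws to summarize")
    phi = np.mean([d[0] for d in ps.draws], axis=0)
    theta = np.mean([d[1] for d in ps.draws], axis=0)
    sigma = np.mean([d[2] for d in ps.draws], axis=0)
    colsum = phi.sum(axis=0)
    scale = np.where(colsum > 0, colsum, 1.0)
    if np.any(colsum == 0):
        warnings.warn("factor with all-zero posterior-mean profile left unscaled")
    return FactorModel(phi / scale, theta * scale[:, None], sigma, ps.priors)


def match_factors(
    phi_est: np.ndarray, phi_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Align estimated factor columns to reference columns (label switching).

    Returns ``(perm, sims)`` where ``phi_est[:, perm[i]]`` is the estimated
    factor assigned to reference factor i and ``sims[i]`` their cosine
    similarity; the Hungarian algorithm maximizes total similarity.
    """
    phi_est = np.asarray(phi_est, dtype=float)
    phi_true = np.asarray(phi_true, dtype=float)
    if phi_est.shape != phi_true.shape:
        raise ContractError("profile matrices must have identical shapes")
    sim = cosine_similarity_matrix(phi_true, phi_est)
    rows, cols = linear_sum_assignment(-sim)  # rows come back sorted 0..T-1
    perm = cols
    return perm, sim[rows, cols]


def cosine_similarity_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity between columns of ``a`` and ``b``."""
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    na = np.where(na > 0, na, 1.0)
    nb = np.where(nb > 0, nb, 1.0)
    return (a / na).T @ (b / nb)


def heldout_log_likelihood(ps: PosteriorSamples, cm: CountMatrix) -> float:
    """Log-likelihood of held-out data under the posterior-mean model; a
    utility for comparing factor counts T, not an automatic selector."""
    from .model import log_likelihood

    return log_likelihood(summarize_posterior(ps), cm)
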