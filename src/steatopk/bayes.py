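"""Pooled Bayesian estimation of (A, B, sigma) with parallel tempering.

All replicates of one condition (group x analyte) share a single curve
parameter pair (A, B) and a single additive-noise scale sigma; the
log-likelihood is the sum over replicates j and time points k of Gaussian
log-densities

    sum_j sum_k [ -ln(sigma*sqrt(2*pi)) - (x(t_k; A,B) - m_jk)^2 / (2*sigma^2) ].

Priors are uniform boxes: [0, 100] for A and B, [0, 1000] for sigma.

The sampler is an adaptive parallel-tempering Metropolis scheme: a
geometric inverse-temperature ladder (1 down to 0.1 over the chains), a
per-chain Gaussian random-walk proposal whose scale is adapted toward a
0.234 acceptance rate during burn-in only (preserving detailed balance
afterwards), and state-swap proposals between adjacent rungs every 100
iterations.  Only the cold chain is retained.  Burn-in is cut by the
Geweke stationarity test with a floor of 100 samples, and mixing is
summarized by the initial-positive-sequence effective sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .fitting import ConcentrationSeries, PKCurveModel
from .model import PKParams

__all__ = [
    "PriorSpec",
    "PosteriorEnsemble",
    "CredibilityBand",
    "log_likelihood",
    "log_posterior",
    "sample_posterior",
    "geweke_burnin",
    "effective_sample_size",
    "posterior_predictive_band",
    "bands_overlap_at",
    "BayesianPKModel",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior boxes for (A, B, sigma)."""

    a_bounds: tuple[float, float] = (0.0, 100.0)
    b_bounds: tuple[float, float] = (0.0, 100.0)
    sigma_bounds: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.a_bounds, self.b_bounds, self.sigma_bounds):
            if not (0 <= lo < hi):
                raise ValueError(f"invalid prior interval ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.a_bounds[0], self.b_bounds[0], self.sigma_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.a_bounds[1], self.b_bounds[1], self.sigma_bounds[1]])


@dataclass
class PosteriorEnsemble:
    """Cold-chain posterior draws of (A, B, sigma) after burn-in removal."""

    samples: np.ndarray  # (n_retained, 3) columns A, B, sigma
    n_chains: int
    n_samples_requested: int
    burn_in_index: int
    ess: np.ndarray  # per-parameter
    seed: int
    acceptance_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be (n, 3)")
        if self.burn_in_index < 100:
            raise ValueError("burn_in_index must be >= 100")


@dataclass
class CredibilityBand:
    """Pointwise credibility band of the posterior-predictive curve."""

    time_grid: np.ndarray  # h
    lower: np.ndarray  # ng/ml
    upper: np.ndarray
    center: np.ndarray
    level: float

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if np.any(self.lower > self.center + 1e-12) or np.any(self.center > self.upper + 1e-12):
            raise ValueError("band must satisfy lower <= center <= upper")


def _stack_replicates(replicates: list[ConcentrationSeries]) -> tuple[np.ndarray, np.ndarray]:
    ts, cs = [], []
    for s in replicates:
        t, c = s.fit_arrays()
        ts.append(t)
        cs.append(c)
    return np.concatenate(ts), np.concatenate(cs)


def _log_likelihood_stacked(theta: np.ndarray, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorized pooled log-likelihood; theta is (m, 3) -> (m,)."""
    a = theta[:, 0:1]
    b = theta[:, 1:2]
    sig = theta[:, 2:3]
    with np.errstate(over="ignore", invalid="ignore"):
        x = t[None, :] * np.exp(b - a * t[None, :])
    x = np.where(t[None, :] > 0, x, 0.0)  # x(0) = 0 even when exp overflows
    resid2 = (x - c[None, :]) ** 2
    n = t.size
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll = -n * (np.log(sig[:, 0]) + 0.5 * _LOG_2PI) \
            - resid2.sum(axis=1) / (2.0 * sig[:, 0] ** 2)
    return np.where(np.isnan(ll), -np.inf, ll)


def log_likelihood(params: PKParams, sigma: float,
                   replicates: list[ConcentrationSeries]) -> float:
    """Pooled Gaussian log-likelihood of the replicates under one (A, B, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t, c = _stack_replicates(replicates)
    theta = np.array([[params.A, params.B, sigma]])
    return float(_log_likelihood_stacked(theta, t, c)[0])


def log_posterior(params: PKParams, sigma: float,
                  replicates: list[ConcentrationSeries],
                  prior: PriorSpec = PriorSpec()) -> float:
    """Log-posterior: log-likelihood inside the prior box, -inf outside."""
    theta = np.array([params.A, params.B, sigma])
    if np.any(theta < prior.lower) or np.any(theta > prior.upper) or sigma == 0:
        return -np.inf
    return log_likelihood(params, sigma, replicates)


def geweke_burnin(chain: np.ndarray, min_cut: int = 100) -> int:
    """Burn-in index by the Geweke stationarity test with a 100-sample floor.

    Scans candidate cut points starting at ``min_cut``; for each, the
    z-score comparing the means of the leading 10% and trailing 50% of the
    remaining chain (standard errors autocorrelation-adjusted via the
    effective sample size) must satisfy |z| < 2 for every parameter.
    Returns the first passing cut, so an already-stationary chain returns
    exactly the floor.  If no cut passes, returns half the chain length
    with a warning.
    """
    chain = np.atleast_2d(np.asarray(chain, dtype=float))
    if chain.shape[0] == 1 and chain.shape[1] > chain.shape[0]:
        chain = chain.T
    n = chain.shape[0]
    if n <= 2 * min_cut:
        raise ValueError(f"chain length {n} must exceed 2*min_cut = {2 * min_cut}")
    cuts = np.unique(np.linspace(min_cut, n // 2, 41).astype(int))
    for cut in cuts:
        rest = chain[cut:]
        m = rest.shape[0]
        a = rest[: max(int(0.1 * m), 10)]
        b = rest[-max(int(0.5 * m), 10):]
        if _geweke_pass(a, b):
            return int(cut)
    warnings.warn("Geweke test never passed; cutting half the chain")
    return n // 2


def _geweke_pass(a: np.ndarray, b: np.ndarray, z_max: float = 2.0) -> bool:
    # Autocorrelation time and variance are estimated from the trailing
    # segment only (presumed stationary); estimating them from the leading
    # segment would let a level shift inflate its own standard error and
    # mask itself.
    for j in range(a.shape[1]):
        var_b = float(np.var(b[:, j], ddof=1))
        diff = float(np.mean(a[:, j]) - np.mean(b[:, j]))
        if var_b == 0:
            if diff != 0:
                return False
            continue
        try:
            tau = max(1.0, b.shape[0] / effective_sample_size(b[:, j]))
        except ValueError:
            tau = 1.0
        se2 = var_b * tau * (1.0 / a.shape[0] + 1.0 / b.shape[0])
        if abs(diff) / np.sqrt(se2) >= z_max:
            return False
    return True


def effective_sample_size(chain: np.ndarray):
    """Effective sample size N / (1 + 2*sum rho_t).

    The autocorrelation sum is truncated by Geyer's initial positive
    sequence: successive pair sums rho_{2m} + rho_{2m+1} are accumulated
    while positive.  For a 2-D chain the ESS is computed per column.
    Capped at N; raises on constant chains (autocorrelation undefined)
    and on chains shorter than 100.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim == 2:
        return np.array([effective_sample_size(chain[:, j]) for j in range(chain.shape[1])])
    n = chain.size
    if n < 100:
        raise ValueError("chain must have at least 100 samples")
    x = chain - chain.mean()
    var = float(np.dot(x, x) / n)
    if var == 0:
        raise ValueError("constant chain: autocorrelation undefined")
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = -rho[0]  # pair sums double-count lag 0
    for k in range(0, n - 1, 2):
        pair = rho[k] + (rho[k + 1] if k + 1 < n else 0.0)
        if pair <= 0:
            break
        tau += 2.0 * pair
    tau = max(tau, 1.0 / n)
    return float(min(n / tau, n))


def sample_posterior(replicates: list[ConcentrationSeries],
                     prior: PriorSpec = PriorSpec(),
                     n_samples: int = 20_000,
                     n_chains: int = 4,
                     seed: int = 0,
                     min_cut: int = 100,
                     beta_min: float = 0.1,
                     swap_every: int = 100,
                     target_accept: float = 0.234) -> PosteriorEnsemble:
    """Sample the pooled posterior of (A, B, sigma) by parallel tempering.

    The default budget is a desk-scale 20,000 samples; the study-scale
    200,000 is available through ``n_samples``.  Chains start from the
    per-condition least-squares estimate (jittered per rung), the proposal
    scale adapts toward ``target_accept`` during the first quarter of the
    run only, and adjacent-rung swaps are proposed every ``swap_every``
    iterations.  Fully reproducible given ``seed``.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    t, c = _stack_replicates(replicates)
    return _sample_posterior_arrays(
        t, c, prior=prior, n_samples=n_samples, n_chains=n_chains, seed=seed,
        min_cut=min_cut, beta_min=beta_min, swap_every=swap_every,
        target_accept=target_accept)


def _sample_posterior_arrays(t: np.ndarray, c: np.ndarray,
                             prior: PriorSpec, n_samples: int, n_chains: int,
                             seed: int, min_cut: int = 100,
                             beta_min: float = 0.1, swap_every: int = 100,
                             target_accept: float = 0.234) -> PosteriorEnsemble:
    if n_samples <= 2 * min_cut:
        raise ValueError(f"n_samples must exceed 2*min_cut = {2 * min_cut}")
    if np.allclose(c, c[0]):
        raise ValueError("degenerate data: all concentrations identical")

    rng = np.random.default_rng(seed)
    lower, upper = prior.lower, prior.upper

    # start at the pooled least-squares solution with a residual-based sigma
    est = PKCurveModel(random_state=seed % (2**31)).fit(t, c)
    sigma0 = float(np.sqrt(max(est.sse_ / max(t.size - 2, 1), 1e-12)))
    center = np.array([est.A_, est.B_, sigma0])
    center = np.clip(center, lower + 1e-9, upper - 1e-9)

    betas = np.geomspace(1.0, beta_min, n_chains)
    theta = np.clip(center[None, :] * np.exp(rng.normal(0, 0.05, (n_chains, 3))),
                    lower + 1e-9, upper - 1e-9)
    scales = np.maximum(0.05 * np.abs(center), 1e-3)[None, :] * np.ones((n_chains, 1))

    ll = _log_likelihood_stacked(theta, t, c)
    n_adapt = n_samples // 4
    samples = np.empty((n_samples, 3))
    cold_accepts = 0

    for i in range(n_samples):
        prop = theta + scales * rng.standard_normal((n_chains, 3))
        inside = np.all((prop >= lower) & (prop <= upper), axis=1) & (prop[:, 2] > 0)
        ll_prop = np.full(n_chains, -np.inf)
        if inside.any():
            ll_prop[inside] = _log_likelihood_stacked(prop[inside], t, c)
        log_alpha = betas * (ll_prop - ll)
        accept = np.log(rng.random(n_chains)) < log_alpha
        theta[accept] = prop[accept]
        ll[accept] = ll_prop[accept]
        cold_accepts += int(accept[0])

        if i < n_adapt:
            gamma = 2.0 / (i + 10) ** 0.6
            scales *= np.exp(gamma * (accept.astype(float) - target_accept))[:, None]

        if swap_every and (i + 1) % swap_every == 0:
            for k in range(n_chains - 1, 0, -1):  # hottest down to cold
                dlog = (betas[k - 1] - betas[k]) * (ll[k] - ll[k - 1])
                if np.log(rng.random()) < dlog:
                    theta[[k - 1, k]] = theta[[k, k - 1]]
                    ll[[k - 1, k]] = ll[[k, k - 1]]

        samples[i] = theta[0]

    burn = geweke_burnin(samples, min_cut=min_cut)
    retained = samples[burn:]
    ess = effective_sample_size(retained)
    return PosteriorEnsemble(
        samples=retained,
        n_chains=n_chains,
        n_samples_requested=n_samples,
        burn_in_index=int(burn),
        ess=np.asarray(ess),
        seed=seed,
        acceptance_rate=cold_accepts / n_samples,
    )


def posterior_predictive_band(ensemble: PosteriorEnsemble,
                              time_grid,
                              level: float = 0.95,
                              include_noise: bool = False,
                              seed: int = 0) -> CredibilityBand:
    """Pointwise equal-tailed credibility band of the model output.

    Every retained draw (A_i, B_i) is simulated forward over the grid;
    the band is the pointwise (alpha/2, 1-alpha/2) percentile envelope and
    the center the pointwise mean.  By default the band covers the
    noise-free model output; ``include_noise=True`` adds a Gaussian
    measurement-noise draw per sample (sigma_i) for a full posterior
    predictive of new observations.
    """
    if ensemble.samples.size == 0:
        raise ValueError("empty ensemble")
    tg = np.asarray(time_grid, dtype=float)
    a = ensemble.samples[:, 0:1]
    b = ensemble.samples[:, 1:2]
    curves = tg[None, :] * np.exp(b - a * tg[None, :])
    if include_noise:
        rng = np.random.default_rng(seed)
        curves = curves + ensemble.samples[:, 2:3] * rng.standard_normal(curves.shape)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(curves, [100 * alpha, 100 * (1 - alpha)], axis=0)
    center = curves.mean(axis=0)
    return CredibilityBand(time_grid=tg, lower=lo, upper=hi,
                           center=center, level=level)


def bands_overlap_at(b1: CredibilityBand, b2: CredibilityBand, t: float) -> bool:
    """Whether two credibility bands intersect at time ``t`` (closed intervals).

    Non-overlap at a time point is read as a significant difference in the
    dynamics between the two conditions there.
    """
    def _idx(band: CredibilityBand) -> int:
        hits = np.nonzero(np.isclose(band.time_grid, t))[0]
        if hits.size == 0:
            raise ValueError(f"t={t} not on the band's time grid")
        return int(hits[0])

    i1, i2 = _idx(b1), _idx(b2)
    return bool(b1.lower[i1] <= b2.upper[i2] and b2.lower[i2] <= b1.upper[i1])


class BayesianPKModel(BaseEstimator):
    """scikit-learn wrapper around :func:`sample_posterior`.

    ``fit`` takes stacked (time, concentration) pairs from all replicates
    of one condition (the pooled likelihood is a plain sum over points, so
    replicate boundaries are immaterial); ``predict`` returns the
    posterior-mean curve.
    """

    def __init__(self, prior: PriorSpec = PriorSpec(), n_samples: int = 20_000,
                 n_chains: int = 4, random_state: int = 0):
        self.prior = prior
        self.n_samples = n_samples
        self.n_chains = n_chains
        self.random_state = random_state

    def fit(self, X, y):
        # the pooled likelihood depends only on the multiset of (t, c)
        # pairs, so stacked arrays from any number of replicates are fine
        t = np.asarray(X, dtype=float).reshape(-1)
        c = np.asarray(y, dtype=float).reshape(-1)
        self.ensemble_ = _sample_posterior_arrays(
            t, c, prior=self.prior, n_samples=self.n_samples,
            n_chains=self.n_chains, seed=self.random_state)
        self.A_, self.B_, self.sigma_ = self.ensemble_.samples.mean(axis=0)
        return self

    def predict(self, X):
        check = getattr(self, "ensemble_", None)
        if check is None:
            raise ValueError("model is not fitted")
        t = np.asarray(X, dtype=float).reshape(-1)
        return t * np.exp(self.B_ - self.A_ * t)
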