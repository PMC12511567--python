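"""Poisson-mixture analysis of protein–membrane contact distributions.

Coarse-grained simulations of the membrane-anchored E2 produce, per
trajectory frame, the number of contacts between the catalytic UBC
domain (residues 1–168) and the membrane.  The marginal contact
distribution is multimodal — a peak at zero (unbound), a shoulder around
~8 contacts (loosely bound) and peaks near 30 and 50 contacts (tightly
bound conformations) — and is modeled as a K-component Poisson mixture

    P(n) = Σ_k π_k · Poisson(n; λ_k),

fitted by expectation–maximization.  The number of components is chosen
by BIC, and bound-state populations are read off as sums of component
weights under an explicit classification policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "ContactSeries",
    "PoissonMixtureFit",
    "MixtureError",
    "fit_poisson_mixture_em",
    "select_component_count",
    "bound_fraction",
    "residue_contact_frequency",
]

#: Floor on fitted component means; keeps the zero-contact ("unbound")
#: component a proper Poisson distribution.
LAMBDA_FLOOR = 1e-6

_DEGENERATE_WEIGHT = 1e-6


class MixtureError(ValueError):
    """Invalid contact data or mixture configuration."""


@dataclass
class ContactSeries:
    """Per-frame contact counts between a protein region and the membrane."""

    counts: np.ndarray
    condition: str = ""
    frame_stride: int = 1
    region: str = "UBC domain, residues 1-168"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise MixtureError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts, dtype=np.int64)
            if not np.array_equal(as_int, self.counts):
                raise MixtureError("counts must be integers")
            self.counts = as_int
        if np.any(self.counts < 0):
            raise MixtureError("counts must be ≥ 0")

    def __len__(self) -> int:
        return int(self.counts.size)


@dataclass
class PoissonMixtureFit:
    """A fitted K-component Poisson mixture (components sorted by mean)."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    log_likelihood: float
    bic: float
    converged: bool
    n_iterations: int
    n_obs: int
    degenerate: bool = False
    log_likelihood_path: np.ndarray | None = None

    def responsibilities(self, counts: Sequence[int] | np.ndarray) -> np.ndarray:
        """Posterior component probabilities per observation (rows sum to 1)."""
        n = np.asarray(counts, dtype=float)
        logp = _log_component_pmf(n, self.weights, self.means)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def _as_counts(series) -> np.ndarray:
    if isinstance(series, ContactSeries):
        return series.counts
    return ContactSeries(np.asarray(series)).counts


def _log_component_pmf(n: np.ndarray, weights: np.ndarray, means: np.ndarray) -> np.ndarray:
    """log(π_k · Poisson(n; λ_k)) for each observation × component."""
    n = n[:, None]
    lam = np.maximum(means[None, :], LAMBDA_FLOOR)
    return (np.log(weights[None, :]) + n * np.log(lam) - lam - gammaln(n + 1.0))


def _em_once(
    values: np.ndarray,
    freq: np.ndarray,
    lam0: np.ndarray,
    w0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    """EM on a compressed (unique value, frequency) representation.

    Contact counts are small integers, so the n-frame series collapses to
    a few dozen unique values; each EM sweep is then O(unique × K).
    """
    lam = np.maximum(lam0.astype(float), LAMBDA_FLOOR)
    w = w0.astype(float) / w0.sum()
    n_total = freq.sum()
    ll_prev = -np.inf
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = _log_component_pmf(values.astype(float), w, lam)
        log_norm = logsumexp(logp, axis=1)
        ll = float(np.dot(freq, log_norm))
        path.append(ll)
        gamma = np.exp(logp - log_norm[:, None])  # responsibilities
        resp_mass = (freq[:, None] * gamma).sum(axis=0)
        lam = np.maximum(
            (freq[:, None] * gamma * values[:, None]).sum(axis=0)
            / np.maximum(resp_mass, 1e-300),
            LAMBDA_FLOOR,
        )
        w = resp_mass / n_total
        if ll - ll_prev < tol * max(abs(ll), 1.0) and it > 1:
            converged = True
            break
        ll_prev = ll
    # final log-likelihood with the last parameter update
    logp = _log_component_pmf(values.astype(float), w, lam)
    ll = float(np.dot(freq, logsumexp(logp, axis=1)))
    path.append(ll)
    return lam, w, ll, it, converged, np.asarray(path)


def fit_poisson_mixture_em(
    series,
    K: int,
    restarts: int = 20,
    seed: int | None = 0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PoissonMixtureFit:
    """Fit a K-component Poisson mixture by EM with multiple restarts.

    The M-step is closed form (λ_k = responsibility-weighted mean,
    π_k = mean responsibility) and the per-iteration log-likelihood is
    non-decreasing.  Means are initialized at K quantiles of the data
    (jittered across restarts, uniform weights) and the best of
    ``restarts`` runs by final log-likelihood is returned, components
    sorted by ascending mean.  BIC = −2·logL + (2K−1)·ln n.
    """
    counts = _as_counts(series)
    if K < 1:
        raise MixtureError("K must be ≥ 1")
    if counts.size < 10 * K:
        raise MixtureError(
            f"need at least 10·K = {10 * K} observations for K = {K}, "
            f"got {counts.size}"
        )
    values, freq = np.unique(counts, return_counts=True)
    values = values.astype(float)
    freq = freq.astype(float)
    n = counts.size

    if K == 1:
        # Closed form: single Poisson MLE is the sample mean.
        lam = np.array([max(counts.mean(), LAMBDA_FLOOR)])
        w = np.array([1.0])
        logp = _log_component_pmf(values, w, lam)
        ll = float(np.dot(freq, logsumexp(logp, axis=1)))
        return PoissonMixtureFit(
            K=1, weights=w, means=lam, log_likelihood=ll,
            bic=-2.0 * ll + 1.0 * np.log(n), converged=True, n_iterations=0,
            n_obs=n, log_likelihood_path=np.array([ll]),
        )

    rng = np.random.default_rng(seed)
    quantiles = np.quantile(counts, (np.arange(K) + 0.5) / K)
    best = None
    for r in range(max(restarts, 1)):
        lam0 = np.maximum(quantiles, LAMBDA_FLOOR)
        if r > 0:
            lam0 = lam0 * np.exp(rng.normal(0.0, 0.4, size=K))
        w0 = np.full(K, 1.0 / K)
        lam, w, ll, it, conv, path = _em_once(values, freq, lam0, w0, tol, max_iter)
        if best is None or ll > best[2]:
            best = (lam, w, ll, it, conv, path)
    lam, w, ll, it, conv, path = best
    order = np.argsort(lam)
    lam, w = lam[order], w[order]
    degenerate = bool(np.any(w < _DEGENERATE_WEIGHT))
    n_free = 2 * K - 1
    return PoissonMixtureFit(
        K=K, weights=w, means=lam, log_likelihood=ll,
        bic=-2.0 * ll + n_free * np.log(n), converged=conv, n_iterations=it,
        n_obs=n, degenerate=degenerate, log_likelihood_path=path,
    )


def select_component_count(
    series,
    K_max: int = 6,
    criterion: str = "bic",
    restarts: int = 20,
    seed: int | None = 0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[int, dict[int, PoissonMixtureFit]]:
    """Scan K = 1..K_max and pick the component count minimizing BIC.

    Returns ``(K*, fits)`` with one fit per scanned K.  Ks whose data
    requirement (10·K observations) is not met are dropped from the scan
    with a warning.
    """
    counts = _as_counts(series)
    if K_max < 2:
        raise MixtureError("K_max must be ≥ 2")
    if criterion != "bic":
        raise MixtureError(f"unknown criterion {criterion!r}")
    feasible = min(K_max, counts.size // 10)
    if feasible < K_max:
        warnings.warn(
            f"series too short for K up to {K_max}; scanning K ≤ {feasible}",
            stacklevel=2,
        )
    if feasible < 1:
        raise MixtureError("series too short to fit any mixture")
    fits = {
        k: fit_poisson_mixture_em(counts, k, restarts=restarts,
                                  seed=None if seed is None else seed + k,
                                  tol=tol, max_iter=max_iter)
        for k in range(1, feasible + 1)
    }
    k_star = min(fits, key=lambda k: fits[k].bic)
    return k_star, fits


def bound_fraction(
    fit: PoissonMixtureFit,
    policy: str = "threshold",
    bound_threshold: float = 15.0,
) -> float:
    """Membrane-bound population of a fitted contact mixture.

    Two classification policies (the choice must be reported alongside
    the number):

    * ``"threshold"`` — components with mean > ``bound_threshold``
      contacts (default 15) are bound; counts the tightly bound states
      only.
    * ``"all_but_unbound"`` — every component except the smallest-mean
      one is bound; includes the loosely bound state.
    """
    if policy == "threshold":
        return float(fit.weights[fit.means > bound_threshold].sum())
    if policy == "all_but_unbound":
        return float(fit.weights[1:].sum()) if fit.K > 1 else 0.0
    raise MixtureError(f"unknown bound-state policy {policy!r}")


def residue_contact_frequency(matrix) -> pd.Series:
    """Per-residue contact frequency over trajectory frames.

    ``matrix`` is frames × residues, boolean or counts (any nonzero entry
    is a contact); a DataFrame keeps its column labels, a bare array gets
    1-based residue indices.  Returns the mean contact indicator per
    residue, in [0, 1].
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy()
        index = matrix.columns
    else:
        values = np.asarray(matrix)
        if values.ndim != 2:
            raise MixtureError("contact matrix must be 2-D (frames × residues)")
        index = pd.RangeIndex(1, values.shape[1] + 1, name="residue")
    if values.size == 0:
        raise MixtureError("empty contact matrix")
    freq = (values != 0).mean(axis=0)
    return pd.Series(freq, index=index, name="contact_frequency")
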