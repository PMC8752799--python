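"""Target identification from event lifetimes.

Two classifiers are provided, mirroring how multiplexed lifetime imaging is
analysed in practice:

* **Threshold classification** — the per-event fitted lifetimes of a mixed
  sample are modelled as a K-component 1-D Gaussian mixture; the decision
  boundaries between adjacent components are the minimum-error points where
  the weighted component densities are equal, and each event is assigned by
  interval membership.  The expected crosstalk between targets follows
  analytically from Gaussian tail integrals of the fitted mixture.
* **Bayesian pattern matching** — reference TCSPC decay patterns measured
  (or simulated) for each target alone are compared with the event's photon
  delay histogram under a multinomial likelihood, yielding a posterior
  probability per target.  This uses every photon in the decay, not just a
  scalar lifetime, and can separate targets whose fitted-lifetime
  distributions overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import FLPaintError, InvalidConfigurationError

#: Smallest allowed mixture component width (ns); EM re-initializes on collapse.
SIGMA_FLOOR = 0.02


@dataclass
class LifetimeMixture:
    """K-component Gaussian mixture of fitted event lifetimes (components
    sorted by mean)."""

    weights: np.ndarray
    means: np.ndarray  # ns
    sigmas: np.ndarray  # ns
    fit_range: tuple[float, float]
    converged: bool = True

    @property
    def K(self) -> int:
        return len(self.means)

    def pdf(self, tau: np.ndarray) -> np.ndarray:
        tau = np.atleast_1d(np.asarray(tau, float))
        return np.sum(
            self.weights[:, None] * norm.pdf(tau[None, :], self.means[:, None], self.sigmas[:, None]),
            axis=0,
        )

    def responsibilities(self, tau: np.ndarray) -> np.ndarray:
        """Posterior component membership, shape (n, K)."""
        tau = np.atleast_1d(np.asarray(tau, float))
        dens = self.weights[None, :] * norm.pdf(
            tau[:, None], self.means[None, :], self.sigmas[None, :]
        )
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


@dataclass
class ReferencePattern:
    """Peak-registered, normalized decay histogram of a single target."""

    name: str
    probabilities: np.ndarray  # per TCSPC bin over the fit range, sums to 1
    bin_width: float  # ns
    source_photons: int


@dataclass
class ClassificationResult:
    """Per-event target assignment with posteriors."""

    target_id: np.ndarray  # int, -1 = unassigned
    posteriors: np.ndarray  # (n_events, K)
    method: str  # 'threshold' | 'pattern'
    thresholds: np.ndarray | None = None


# ---------------------------------------------------------------------------
# mixture fitting


def fit_lifetime_mixture(
    taus: np.ndarray,
    K: int,
    fit_range: tuple[float, float] = (0.5, 5.0),
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LifetimeMixture:
    """Maximum-likelihood K-component Gaussian mixture of event lifetimes.

    EM with deterministic quantile initialization: component k starts at
    the (k + 1/2)/K quantile with width sample_sd / K and uniform weights.
    Components are returned sorted by mean.
    """
    taus = np.asarray(taus, dtype=float)
    taus = taus[(taus >= fit_range[0]) & (taus <= fit_range[1]) & np.isfinite(taus)]
    if len(taus) < 50 * K:
        raise InvalidConfigurationError(
            f"need at least {50 * K} lifetimes in fit_range to fit K={K} components"
        )
    if K == 1:
        # closed form MLE
        return LifetimeMixture(
            weights=np.array([1.0]),
            means=np.array([taus.mean()]),
            sigmas=np.array([max(taus.std(), SIGMA_FLOOR)]),
            fit_range=fit_range,
        )

    from sklearn.mixture import GaussianMixture

    q = (np.arange(K) + 0.5) / K
    means_init = np.quantile(taus, q)[:, None]
    sd0 = max(taus.std() / K, SIGMA_FLOOR)
    X = taus[:, None]
    for attempt, reg in enumerate([SIGMA_FLOOR**2, (2 * SIGMA_FLOOR) ** 2]):
        gm = GaussianMixture(
            n_components=K,
            covariance_type="diag",
            weights_init=np.full(K, 1.0 / K),
            means_init=means_init,
            precisions_init=np.full((K, 1), 1.0 / sd0**2),
            max_iter=max_iter,
            tol=tol,
            reg_covar=reg,
            n_init=1,
        )
        gm.fit(X)
        sigmas = np.sqrt(gm.covariances_[:, 0])
        if np.all(sigmas >= SIGMA_FLOOR * 0.5):
            order = np.argsort(gm.means_[:, 0])
            return LifetimeMixture(
                weights=gm.weights_[order],
                means=gm.means_[order, 0],
                sigmas=np.maximum(sigmas[order], SIGMA_FLOOR),
                fit_range=fit_range,
                converged=bool(gm.converged_),
            )
    raise FLPaintError("mixture fit degenerate: a component collapsed below the width floor")


def derive_thresholds(mixture: LifetimeMixture) -> np.ndarray:
    """Minimum-error decision boundaries between adjacent components.

    Between means i and i+1 the threshold is where the weighted Gaussian
    densities are equal (falls back to the density-weighted midpoint when
    the densities do not cross inside the interval).
    """
    thr = []
    for i in range(mixture.K - 1):
        w1, m1, s1 = mixture.weights[i], mixture.means[i], mixture.sigmas[i]
        w2, m2, s2 = mixture.weights[i + 1], mixture.means[i + 1], mixture.sigmas[i + 1]

        def diff(x):
            return w1 * norm.pdf(x, m1, s1) - w2 * norm.pdf(x, m2, s2)

        lo, hi = m1, m2
        try:
            if diff(lo) * diff(hi) < 0:
                thr.append(brentq(diff, lo, hi, xtol=1e-9))
            else:
                thr.append(0.5 * (m1 + m2))
        except ValueError:
            thr.append(0.5 * (m1 + m2))
    return np.asarray(thr)


def classify_by_threshold(
    taus: np.ndarray, thresholds: np.ndarray, mixture: LifetimeMixture | None = None
) -> ClassificationResult:
    """Assign each event lifetime to the component interval it falls in.

    Posteriors are the mixture responsibilities when a mixture is given,
    else an indicator on the assigned interval.
    """
    taus = np.asarray(taus, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    labels = np.digitize(taus, thresholds)
    labels = np.where(np.isfinite(taus), labels, -1)
    K = len(thresholds) + 1
    if mixture is not None and mixture.K == K:
        post = mixture.responsibilities(taus)
    else:
        post = np.zeros((len(taus), K))
        ok = labels >= 0
        post[np.flatnonzero(ok), labels[ok]] = 1.0
    return ClassificationResult(
        target_id=labels.astype(int), posteriors=post, method="threshold", thresholds=thresholds
    )


def estimate_crosstalk(mixture: LifetimeMixture, thresholds: np.ndarray) -> np.ndarray:
    """K x K matrix: entry (i, j) is the probability that an event of
    component i is assigned to interval j (Gaussian interval masses)."""
    edges = np.concatenate([[-np.inf], np.asarray(thresholds, float), [np.inf]])
    K = mixture.K
    M = np.empty((K, K))
    for i in range(K):
        cdf = norm.cdf(edges, mixture.means[i], mixture.sigmas[i])
        M[i] = np.diff(cdf)
    # rows are exact interval masses and already sum to 1
    return M


# ---------------------------------------------------------------------------
# Bayesian pattern matching


def build_reference_pattern(
    event_micro_times: list[np.ndarray],
    bin_width: float,
    tcspc_window: float,
    name: str = "",
) -> ReferencePattern:
    """Pool single-target events into a normalized decay pattern.

    Delays are pooled on the raw TCSPC axis: the instrument response fixes
    the position of the decay within the window, so reference and event
    histograms are naturally aligned and no per-event registration is
    needed (per-event peak estimates are far too noisy to shift by).  The
    pooled-histogram peak is recorded in case instruments with a channel
    offset need a one-off global shift.
    """
    arrays = [np.asarray(t, dtype=float) for t in event_micro_times if len(t)]
    if not arrays:
        raise InvalidConfigurationError("no photons to build a reference pattern from")
    pooled = np.concatenate(arrays)
    n_bins = max(1, int(np.ceil(tcspc_window / bin_width - 1e-9)))
    counts, _ = np.histogram(pooled, bins=n_bins, range=(0.0, n_bins * bin_width))
    return ReferencePattern(
        name=name,
        probabilities=counts / counts.sum(),
        bin_width=bin_width,
        source_photons=int(counts.sum()),
    )


def pattern_match(
    event_histogram: np.ndarray,
    patterns: list[ReferencePattern],
    priors: np.ndarray | None = None,
    floor: float = 1e-9,
) -> np.ndarray:
    """Posterior target probabilities for one event.

    ``posterior_k propto prior_k * prod_bins pattern_k(bin)^counts(bin)``
    (multinomial likelihood), computed in log space.  Pattern bins with
    zero probability but nonzero counts are floored at ``floor``.
    """
    counts = np.asarray(event_histogram, dtype=float)
    K = len(patterns)
    priors = np.full(K, 1.0 / K) if priors is None else np.asarray(priors, float) / np.sum(priors)
    logpost = np.empty(K)
    for k, pat in enumerate(patterns):
        p = pat.probabilities
        if len(p) != len(counts):
            raise InvalidConfigurationError(
                f"pattern {pat.name!r} has {len(p)} bins, event histogram has {len(counts)}"
            )
        logpost[k] = np.log(priors[k]) + np.sum(counts * np.log(np.maximum(p, floor)))
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def classify_by_pattern(
    event_micro_times: list[np.ndarray],
    patterns: list[ReferencePattern],
    priors: np.ndarray | None = None,
    min_posterior: float = 0.5,
    tcspc_window: float | None = None,
) -> ClassificationResult:
    """Pattern-match every event; events whose best posterior falls below
    ``min_posterior`` are left unassigned (-1)."""
    bw = patterns[0].bin_width
    n_bins = len(patterns[0].probabilities)
    window = tcspc_window if tcspc_window is not None else n_bins * bw
    K = len(patterns)
    post = np.empty((len(event_micro_times), K))
    labels = np.empty(len(event_micro_times), dtype=int)
    for i, t in enumerate(event_micro_times):
        t = np.asarray(t, dtype=float)
        counts, _ = np.histogram(t, bins=n_bins, range=(0.0, n_bins * bw))
        post[i] = pattern_match(counts, patterns, priors)
        labels[i] = int(np.argmax(post[i])) if post[i].max() >= min_posterior else -1
    return ClassificationResult(target_id=labels, posteriors=post, method="pattern")
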