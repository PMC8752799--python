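"""TCSPC histograms and mono-exponential tail lifetime fitting.

The lifetime of a binding event is estimated from the photon delays in the
*tail* of its TCSPC histogram: everything from a fixed offset (default
0.1 ns) after the histogram peak up to the end of the TCSPC window.
Starting past the peak makes the estimate insensitive to the instrument
response, and because the exponential is memoryless, photons whose true
delay exceeds the laser period and which therefore fold back into the
window still follow the same truncated-exponential law — the tail model

    p(t | tau) = exp(-(t - a)/tau) / (tau * (1 - exp(-(b - a)/tau))),
    t in [a, b],

is exact for the folded decay.  The maximum-likelihood estimate is found by
1-D likelihood maximization; its standard error comes from the observed
information at the optimum.

Fits run on unbinned photon delays when available (exact likelihood); a
binned path over histogram bin centres is provided for parity and agrees
with the unbinned fit to well below a percent at 16 ps bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InvalidConfigurationError

#: Default offset past the TCSPC peak at which the tail fit starts (ns).
DEFAULT_TAIL_OFFSET = 0.1
#: Fits with fewer tail photons than this are flagged as not fitted; below
#: ~50 photons the statistical error exceeds the ~1 ns dye spacing.
MIN_TAIL_PHOTONS = 50

_TAU_LO, _TAU_HI = 0.02, 50.0  # ns, search bracket for the 1-D MLE


@dataclass
class TCSPCHistogram:
    """Photon-delay histogram of one event (or a pooled set of events)."""

    bin_width: float  # ns
    counts: np.ndarray
    bin_centers: np.ndarray  # ns
    t_peak: float  # ns, centre of the maximum bin
    fit_start: float  # ns
    fit_end: float  # ns

    @property
    def n_photons(self) -> int:
        return int(self.counts.sum())


@dataclass
class LifetimeFitResult:
    """Tail-MLE estimate of a mono-exponential lifetime."""

    tau: float  # ns
    tau_stderr: float  # ns
    n_photons_fit: int
    loglik: float
    converged: bool
    fit_start: float = np.nan
    fit_end: float = np.nan


def build_tcspc(
    photon_micro_times: np.ndarray,
    bin_width: float,
    tcspc_window: float,
    tail_offset: float = DEFAULT_TAIL_OFFSET,
    fit_end: float | None = None,
) -> TCSPCHistogram:
    """Histogram photon delays over ``[0, tcspc_window)``.

    ``t_peak`` is the centre of the maximum bin; the default fit range is
    ``[t_peak + tail_offset, tcspc_window]``.
    """
    if bin_width <= 0 or bin_width >= tcspc_window:
        raise InvalidConfigurationError("need 0 < bin_width < tcspc_window")
    t = np.asarray(photon_micro_times, dtype=float)
    n_bins = max(1, int(np.ceil(tcspc_window / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], tcspc_window)  # last bin absorbs rounding
    counts, _ = np.histogram(t, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    t_peak = float(centers[np.argmax(counts)]) if len(t) else 0.0
    end = tcspc_window if fit_end is None else fit_end
    start = min(t_peak + tail_offset, end)
    return TCSPCHistogram(
        bin_width=bin_width,
        counts=counts,
        bin_centers=centers,
        t_peak=t_peak,
        fit_start=start,
        fit_end=end,
    )


def _truncated_exp_loglik(tau: float, shifted: np.ndarray, span: float) -> float:
    """Log-likelihood of delays (already shifted by fit_start) in [0, span]."""
    return float(
        -shifted.sum() / tau
        - len(shifted) * np.log(tau)
        - len(shifted) * np.log1p(-np.exp(-span / tau))
    )


def fit_lifetime_tail(
    hist_or_times: TCSPCHistogram | np.ndarray,
    tail_offset: float = DEFAULT_TAIL_OFFSET,
    window_end: float | None = None,
    min_photons: int = MIN_TAIL_PHOTONS,
    peak_bin_width: float = 0.05,
    background_fraction: float = 0.0,
) -> LifetimeFitResult:
    """Fit a mono-exponential lifetime to the tail of a TCSPC measurement.

    Accepts either a :class:`TCSPCHistogram` (binned likelihood over bin
    centres in the fit range) or a raw array of photon delays (exact
    unbinned likelihood; the peak is located on a ``peak_bin_width``
    histogram first, and ``window_end`` must then be given or defaults to
    the maximum delay).

    ``background_fraction`` optionally mixes a uniform-delay component into
    the tail density, ``p = (1 - f) * trunc_exp(tau) + f / span``, for data
    whose events carry a known fraction of uncorrelated background photons
    (estimated upstream from the fitted per-pixel background).  The default
    is a pure mono-exponential.
    """
    f_bg = float(np.clip(background_fraction, 0.0, 0.95))
    if isinstance(hist_or_times, TCSPCHistogram):
        h = hist_or_times
        sel = (h.bin_centers >= h.fit_start) & (h.bin_centers <= h.fit_end)
        counts = h.counts[sel]
        centers = h.bin_centers[sel]
        n = int(counts.sum())
        a, b = h.fit_start, h.fit_end
        if n < min_photons:
            return LifetimeFitResult(np.nan, np.nan, n, np.nan, False, a, b)
        shifted = centers - a
        weights = counts.astype(float)
        span = b - a
    else:
        t = np.asarray(hist_or_times, dtype=float)
        end = float(window_end) if window_end is not None else (t.max() if len(t) else 0.0)
        peak_hist = build_tcspc(t, peak_bin_width, end, tail_offset, end) if len(t) else None
        a = peak_hist.fit_start if peak_hist is not None else 0.0
        b = end
        tail = t[(t >= a) & (t <= b)]
        n = len(tail)
        if n < min_photons:
            return LifetimeFitResult(np.nan, np.nan, n, np.nan, False, a, b)
        shifted = tail - a
        weights = None
        span = b - a

    if f_bg == 0.0 and weights is None:

        def negll(tau: float) -> float:
            return -_truncated_exp_loglik(tau, shifted, span)

    else:
        w = weights if weights is not None else np.ones_like(shifted)

        def negll(tau: float) -> float:
            dens = (1.0 - f_bg) * np.exp(-shifted / tau) / (
                tau * -np.expm1(-span / tau)
            ) + f_bg / span
            return -float(np.dot(w, np.log(np.maximum(dens, 1e-300))))

    res = minimize_scalar(
        negll, bounds=(_TAU_LO, _TAU_HI), method="bounded", options={"xatol": 1e-7}
    )
    tau_hat = float(res.x)
    converged = bool(res.success) and _TAU_LO * 1.01 < tau_hat < _TAU_HI * 0.99
    # observed information by central difference of the log-likelihood
    hstep = 1e-4 * tau_hat
    d2 = (negll(tau_hat + hstep) - 2.0 * negll(tau_hat) + negll(tau_hat - hstep)) / hstep**2
    stderr = float(1.0 / np.sqrt(d2)) if d2 > 0 else np.nan
    return LifetimeFitResult(
        tau=tau_hat,
        tau_stderr=stderr,
        n_photons_fit=n,
        loglik=-float(res.fun),
        converged=converged,
        fit_start=a,
        fit_end=b,
    )


def filter_lifetimes(events, tau_min: float = 0.5, tau_max: float = 5.0):
    """Keep only events whose fitted lifetime lies in ``[tau_min, tau_max]``.

    Bounds are inclusive.  Failed fits (NaN lifetime) are removed.  Works on
    a pandas DataFrame with a ``tau_ns`` column or on a sequence of objects
    with a ``tau`` attribute; order is preserved.
    """
    import pandas as pd

    if isinstance(events, pd.DataFrame):
        tau = events["tau_ns"].to_numpy(float)
        keep = np.isfinite(tau) & (tau >= tau_min) & (tau <= tau_max)
        n_removed = int((~keep).sum())
        if n_removed:
            import logging

            logging.getLogger(__name__).info(
                "filter_lifetimes removed %d of %d events", n_removed, len(events)
            )
        return events.loc[keep].reset_index(drop=True)
    kept = [
        ev
        for ev in events
        if np.isfinite(getattr(ev, "tau", np.nan)) and tau_min <= ev.tau <= tau_max
    ]
    return kept
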