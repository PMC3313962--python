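"""Rhythm extraction: grid cosinor fits, synchronization degree, actograms.

Period, phase and amplitude are estimated by least-squares fitting of

    y(t) = M0 + A * cos(2 pi (t - phi) / tau)

with the period ``tau`` searched exhaustively on a discrete grid (16-32 h in
15-min steps by default).  For each fixed ``tau`` the fit is linear in
(M0, A cos, A sin), so the search is exact on the grid and free of local
minima.  The phase ``phi`` is the signed time from day onset (lights-on) to
the nearest fitted peak, in (-tau/2, tau/2].

The degree of synchrony of an ensemble over a time window is

    R = Var_t( <y_i(t)>_i ) / < Var_t( y_i(t) ) >_i ,

the ratio of the variance of the ensemble-mean trace to the mean individual
variance: 1 for identical traces, ~1/N for independent ones, 0 when phases
cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CosineFit",
    "RhythmSummary",
    "default_tau_grid",
    "cosine_fit",
    "sync_degree",
    "condition_window",
    "population_summary",
    "actogram",
    "phase_period_histograms",
    "circular_mean_phase",
]

#: Number of trailing days of a condition that summaries average over.
SUMMARY_DAYS = 5


def default_tau_grid(lo: float = 16.0, hi: float = 32.0, step: float = 0.25) -> np.ndarray:
    """Candidate periods in hours: [lo, hi] inclusive at ``step`` resolution."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass(frozen=True)
class CosineFit:
    """One cosinor fit.  ``tau`` is NaN (with A = 0) for a flat series."""

    M0: float
    A: float
    tau: float
    phi: float
    rss: float

    @property
    def ok(self) -> bool:
        return np.isfinite(self.tau)


@dataclass(frozen=True)
class RhythmSummary:
    """Population rhythm metrics over one analysis window."""

    per_neuron: tuple          # CosineFit per neuron (procedure (i) fits)
    mean_tau: float            # h, arithmetic mean over valid fits
    sd_tau: float              # h
    mean_phi: float            # h, circular mean (resultant-vector angle)
    mean_phi_arith: float      # h, plain arithmetic mean
    sd_phi: float              # h
    R: float                   # synchronization degree over the window
    window: tuple              # (t_start, t_end), h
    procedure: str             # "per-neuron-then-average" | "average-then-fit"
    ensemble_fit: CosineFit | None = None  # procedure (ii) fit when computed

    @property
    def tau(self) -> float:
        """Headline period of the chosen procedure."""
        if self.procedure == "average-then-fit" and self.ensemble_fit is not None:
            return self.ensemble_fit.tau
        return self.mean_tau

    @property
    def phi(self) -> float:
        if self.procedure == "average-then-fit" and self.ensemble_fit is not None:
            return self.ensemble_fit.phi
        return self.mean_phi


def _wrap(x: float, period: float) -> float:
    """Wrap into the half-open interval (-period/2, period/2]."""
    w = x % period
    if w > period / 2.0 + 1e-12:
        w -= period
    return w


def cosine_fit(times: np.ndarray, series: np.ndarray,
               tau_grid: np.ndarray | None = None) -> CosineFit:
    """Best grid-cosinor fit of one trace.

    For every candidate period the baseline, cosine and sine amplitudes are
    obtained by linear least squares; the grid period with the smallest
    residual sum of squares wins.  The phase is referenced to the first day
    onset (t = 0 mod 24 h) inside the fitting window.

    A series with (numerically) zero variance is flagged: returns A = 0 and
    ``tau = phi = NaN`` rather than raising.
    """
    t = np.asarray(times, dtype=np.float64)
    y = np.asarray(series, dtype=np.float64)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and series must be equal-length 1-D arrays")
    if tau_grid is None:
        tau_grid = default_tau_grid()
    span = t[-1] - t[0]
    if span < 2.0 * float(np.max(tau_grid)):
        raise ValueError("window must cover at least two full candidate periods")

    ybar = float(y.mean())
    sst = float(((y - ybar) ** 2).sum())
    if sst <= 1e-12 * max(1.0, ybar * ybar) * y.size:
        return CosineFit(M0=ybar, A=0.0, tau=np.nan, phi=np.nan, rss=sst)

    best = None
    yc = y - ybar
    for tau in tau_grid:
        w = 2.0 * np.pi / tau
        c = np.cos(w * t)
        s = np.sin(w * t)
        # 3x3 normal equations on the centred data (intercept kept explicitly)
        X = np.column_stack((np.ones_like(t), c, s))
        coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
        rss = float(((y - pred) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, float(tau), coef)
    rss, tau, (m0, a, b) = best
    A = float(np.hypot(a, b))
    # y = M0 + A cos(w t - psi), peaks at t = psi/w + k tau
    psi = float(np.arctan2(b, a))
    t_peak = psi * tau / (2.0 * np.pi)
    day0 = 24.0 * np.ceil(t[0] / 24.0 - 1e-9)
    phi = _wrap(t_peak - day0, tau)
    return CosineFit(M0=float(m0), A=A, tau=tau, phi=phi, rss=rss)


def sync_degree(series_matrix: np.ndarray, window: slice | None = None) -> float:
    """Synchronization degree R of an (N, T) trace matrix over a window.

    Returns NaN when every individual trace is flat (undefined ratio).
    """
    x = np.asarray(series_matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (N, T) matrix with N >= 2")
    if window is not None:
        x = x[:, window]
    if x.shape[1] < 2:
        raise ValueError("window too short")
    denom = float(np.mean(np.var(x, axis=1)))
    if denom <= 0.0:
        return np.nan
    return float(np.var(x.mean(axis=0)) / denom)


def circular_mean_phase(phis: np.ndarray, period: float) -> float:
    """Resultant-vector mean of phases living on a circle of given period."""
    ang = 2.0 * np.pi * np.asarray(phis, dtype=np.float64) / period
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return _wrap(float(mean_ang) * period / (2.0 * np.pi), period)


def condition_window(schedule, condition: str) -> tuple[float, float]:
    """Half-open [t0, t1) covering the last SUMMARY_DAYS days of a condition."""
    day = schedule.day_length
    cond = condition.upper()
    if cond == "LD":
        if schedule.ld_days < SUMMARY_DAYS:
            raise ValueError(f"protocol has fewer than {SUMMARY_DAYS} LD days")
        t1 = schedule.ld_days * day
    elif cond == "DD":
        if schedule.dd_days < SUMMARY_DAYS:
            raise ValueError(f"protocol has fewer than {SUMMARY_DAYS} DD days")
        t1 = (schedule.ld_days + schedule.dd_days) * day
    else:
        raise ValueError("condition must be 'LD' or 'DD'")
    return t1 - SUMMARY_DAYS * day, t1


def population_summary(result, condition: str = "DD",
                       procedure: str = "per-neuron-then-average",
                       species: str = "PN",
                       tau_grid: np.ndarray | None = None) -> RhythmSummary:
    """Rhythm metrics of an ensemble over the last 5 days of LD or DD.

    Procedure (i), ``per-neuron-then-average``: cosinor fit per neuron, then
    average period and phase over the population (the robust default — under
    desynchronization the ensemble-mean trace flattens and procedure (ii)
    loses the rhythm).  Procedure (ii), ``average-then-fit``: average the
    nuclear-PER trace over neurons first, then fit once.  Both attach the
    synchronization degree R over the same window.
    """
    if procedure not in ("per-neuron-then-average", "average-then-fit"):
        raise ValueError(f"unknown procedure {procedure!r}")
    t0, t1 = condition_window(result.config.schedule, condition)
    if t1 > result.times[-1] + 1e-9:
        raise ValueError(f"result does not cover the requested {condition} window")
    sl = result.window_slice(t0, t1)
    t = result.times[sl]
    traces = result.species(species)[:, sl]

    fits = tuple(cosine_fit(t, traces[i], tau_grid) for i in range(traces.shape[0]))
    taus = np.array([f.tau for f in fits])
    phis = np.array([f.phi for f in fits])
    valid = np.isfinite(taus)
    if valid.any():
        mean_tau = float(taus[valid].mean())
        sd_tau = float(taus[valid].std())
        mean_phi = circular_mean_phase(phis[valid], period=mean_tau)
        mean_phi_arith = float(phis[valid].mean())
        sd_phi = float(phis[valid].std())
    else:
        mean_tau = sd_tau = mean_phi = mean_phi_arith = sd_phi = np.nan

    R = sync_degree(traces) if traces.shape[0] >= 2 else np.nan
    ens = cosine_fit(t, traces.mean(axis=0), tau_grid) \
        if procedure == "average-then-fit" else None
    return RhythmSummary(per_neuron=fits, mean_tau=mean_tau, sd_tau=sd_tau,
                         mean_phi=mean_phi, mean_phi_arith=mean_phi_arith,
                         sd_phi=sd_phi, R=R, window=(t0, t1),
                         procedure=procedure, ensemble_fit=ens)


def actogram(times: np.ndarray, series: np.ndarray,
             day_length: float = 24.0) -> np.ndarray:
    """Double-plot actogram matrix: row d shows days d and d+1 side by side.

    The series is resampled onto a uniform within-day grid (the native
    sampling interval), so a 16-day record yields 15 rows of width
    2 x samples-per-day.
    """
    t = np.asarray(times, dtype=np.float64)
    y = np.asarray(series, dtype=np.float64)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and series must be equal-length 1-D arrays")
    dt = float(np.median(np.diff(t)))
    per_day = int(round(day_length / dt))
    n_days = t.size // per_day  # full days covered by the samples
    if n_days < 2:
        raise ValueError("need at least two full days of data")
    grid = t[0] + dt * np.arange(per_day * n_days)
    yg = np.interp(grid, t, y).reshape(n_days, per_day)
    return np.hstack([yg[:-1], yg[1:]])


def phase_period_histograms(summary: RhythmSummary, bin_width: float = 0.25):
    """Binned per-neuron phase and period counts (two (edges, counts) pairs)."""
    fits = [f for f in summary.per_neuron if f.ok]
    if not fits:
        raise ValueError("summary contains no valid per-neuron fits")
    phis = np.array([f.phi for f in fits])
    taus = np.array([f.tau for f in fits])

    def _hist(x):
        lo = np.floor(x.min() / bin_width) * bin_width
        hi = np.ceil(x.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(x, bins=edges)
        return edges, counts

    return _hist(phis), _hist(taus)
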