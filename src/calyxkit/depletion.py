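"""Resource-depletion model of short-term depression, and the empirical
exponential fits used alongside it.

The model: transmission strength in the absence of plasticity is ``A``.
One or two independent depression states ``D_k`` (each starting at 1)
multiply it.  At each event the observed amplitude is ``A * prod_k D_k``
evaluated just before the event; immediately after, each state is depleted
by its fraction ``f_k`` (``D_k <- D_k * (1 - f_k)``); between events each
state relaxes back toward 1 with its own time constant
(``D_k(t) = 1 - (1 - D_k) * exp(-dt / tau_k)``).

With two states the composition is multiplicative, so single-event
recovery is a mixture of a fast and a slow exponential — the form seen in
spike-derivative recovery curves at this synapse.

Units: times in ms; ``A`` in whatever unit the measured amplitude carries
(mV/ms for EPSP rate-of-rise, V/s for spike derivative, mV for prespike).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "DepletionState",
    "DepletionModelParams",
    "StpFitResult",
    "ExpFitResult",
    "predict_depletion",
    "fit_depletion",
    "fit_onset_decay",
    "fit_recovery_after_tone",
    "steady_state_depression",
    "steady_state_regular_train",
]


@dataclass(frozen=True)
class DepletionState:
    """One depression state: depletion fraction and recovery time constant."""

    f: float  # fraction of the state consumed per event, in [0, 1)
    tau: float  # recovery time constant, ms

    def __post_init__(self) -> None:
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"depletion fraction must be in [0, 1), got {self.f}")
        if self.tau <= 0:
            raise ValueError(f"recovery tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class DepletionModelParams:
    """Transmission strength plus one or two depression states.

    States are kept sorted fast-first (ascending tau).
    """

    A: float
    states: tuple[DepletionState, ...]

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"transmission strength A must be > 0, got {self.A}")
        states = tuple(
            s if isinstance(s, DepletionState) else DepletionState(*s) for s in self.states
        )
        if not 1 <= len(states) <= 2:
            raise ValueError("model supports 1 or 2 depression states")
        states = tuple(sorted(states, key=lambda s: s.tau))
        object.__setattr__(self, "states", states)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def tau_fast(self) -> float:
        return self.states[0].tau

    @property
    def tau_slow(self) -> float:
        return self.states[-1].tau


@dataclass
class StpFitResult:
    """Outcome of a resource-depletion model fit."""

    params: DepletionModelParams | None
    variance_explained: float | None
    predicted: np.ndarray
    residuals: np.ndarray
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class ExpFitResult:
    """Single-exponential fit ``y = y_inf + (y0 - y_inf) * exp(-x / tau)``."""

    y0: float
    y_inf: float
    tau: float
    fit_domain: str  # "time" (tau in ms) or "event_number" (tau in events)
    flags: list[str] = field(default_factory=list)


def _as_sweeps(event_times) -> list[np.ndarray]:
    if isinstance(event_times, (list, tuple)) and (
        len(event_times) == 0 or np.ndim(event_times[0]) == 1
    ):
        sweeps = [np.asarray(t, dtype=float) for t in event_times]
    else:
        sweeps = [np.asarray(event_times, dtype=float)]
    for t in sweeps:
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("event times must be strictly increasing within a sweep")
    return sweeps


def predict_depletion(event_times, params: DepletionModelParams) -> np.ndarray:
    """Per-event amplitudes predicted by the depletion model.

    ``event_times`` may be a single increasing array (ms) or a list of
    such arrays; each sweep starts from the fully recovered state
    (``D_k = 1``).  Returns the concatenated predicted amplitudes.
    """
    f = np.array([s.f for s in params.states])
    tau = np.array([s.tau for s in params.states])
    out: list[np.ndarray] = []
    for times in _as_sweeps(event_times):
        n = times.size
        amps = np.empty(n)
        D = np.ones(len(f))
        t_prev = None
        for i in range(n):
            if t_prev is not None:
                D = 1.0 - (1.0 - D) * np.exp(-(times[i] - t_prev) / tau)
            amps[i] = params.A * np.prod(D)
            D = D * (1.0 - f)
            t_prev = times[i]
        out.append(amps)
    return np.concatenate(out) if out else np.empty(0)


def steady_state_regular_train(rate: float, f: float, tau: float) -> float:
    """Closed-form steady amplitude (as a fraction of A) for a regular
    train at ``rate`` events/s under a single depression state.

    Geometric fixed point of the event-to-event recursion:
    ``D* = (1 - e) / (1 - (1 - f) * e)`` with ``e = exp(-1/(rate*tau))``
    (tau in ms, rate in events/s).
    """
    e = np.exp(-1000.0 / (rate * tau))
    return float((1.0 - e) / (1.0 - (1.0 - f) * e))


def _theta_to_params(theta: np.ndarray, n_states: int) -> DepletionModelParams:
    A = theta[0]
    states = tuple(
        DepletionState(f=theta[1 + 2 * k], tau=theta[2 + 2 * k]) for k in range(n_states)
    )
    return DepletionModelParams(A=A, states=states)


def fit_depletion(
    event_times,
    amplitudes: Sequence[float],
    n_states: int = 1,
    *,
    f_bounds: tuple[float, float] = (0.0, 0.999),
    tau_bounds: tuple[float, float] = (0.1, 1e4),
    tau_grid: Sequence[float] = (1.0, 10.0, 100.0),
    loss: str = "linear",
    f_scale: float = 1.0,
    trim_mult: float | None = None,
) -> StpFitResult:
    """Fit the depletion model to observed per-event amplitudes.

    Bounded nonlinear least squares over ``{A, f_k, tau_k}``, multi-start
    from a log grid on the time constants (all ordered pairs from
    ``tau_grid`` for the two-state model); the start with the smallest
    residual sum of squares wins, ties broken by the smaller fast tau.
    ``variance_explained`` is ``1 - SS_res / SS_tot`` (``None`` when the
    observed series is constant).  ``loss='soft_l1'`` with ``f_scale``
    near the per-event noise scale makes the fit robust to the occasional
    grossly mismeasured amplitude (useful for trace-derived prespikes).
    ``trim_mult`` adds a second pass: events whose first-pass residual
    exceeds that multiple of the robust residual scale are dropped and
    the model refit.
    """
    if n_states not in (1, 2):
        raise ValueError("n_states must be 1 or 2")
    obs = np.asarray(amplitudes, dtype=float)
    sweeps = _as_sweeps(event_times)
    n_events = sum(t.size for t in sweeps)
    if obs.size != n_events:
        raise ValueError("amplitudes length must match total number of events")
    if np.any(obs <= 0):
        raise ValueError("amplitudes must be positive")

    if np.ptp(obs) == 0.0:
        # degenerate: constant amplitudes fit exactly with f = 0 (any tau
        # with full recovery between events would too); report the
        # canonical no-depression solution and flag it
        params = _theta_to_params(
            np.array([obs[0]] + [0.0, 1.0] * n_states), n_states)
        pred = np.full(n_events, obs[0])
        return StpFitResult(
            params=params, variance_explained=None, predicted=pred,
            residuals=np.zeros(n_events), converged=True,
            flags=["variance undefined: constant observed amplitudes",
                   "tau unidentifiable without depression"],
        )

    def resid(theta: np.ndarray) -> np.ndarray:
        return predict_depletion(sweeps, _theta_to_params(theta, n_states)) - obs

    A0 = float(np.max(obs))
    lo = [1e-12] + [f_bounds[0], tau_bounds[0]] * n_states
    hi = [np.inf] + [f_bounds[1], tau_bounds[1]] * n_states
    if n_states == 1:
        starts = [[A0, 0.3, t] for t in tau_grid]
    else:
        starts = [
            [A0, 0.3, t1, 0.3, t2]
            for t1 in tau_grid
            for t2 in tau_grid
            if t1 < t2
        ]
        # degenerate equal-tau starts replaced by a slightly split pair
        starts += [[A0, 0.3, t / 3.0, 0.3, t * 3.0] for t in tau_grid]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                loss=loss, f_scale=f_scale)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-12 or (
            abs(sol.cost - best.cost) <= 1e-12
            and _theta_to_params(sol.x, n_states).tau_fast
            < _theta_to_params(best.x, n_states).tau_fast
        ):
            best = sol

    if best is None or not best.success:
        return StpFitResult(
            params=None,
            variance_explained=None,
            predicted=np.full(n_events, np.nan),
            residuals=np.full(n_events, np.nan),
            converged=False,
            flags=["non-convergence: no start converged"],
        )

    params = _theta_to_params(best.x, n_states)
    pred = predict_depletion(sweeps, params)
    residuals = obs - pred

    if trim_mult is not None:
        sd = 1.4826 * np.median(np.abs(residuals - np.median(residuals)))
        keep = np.abs(residuals) <= trim_mult * max(sd, 1e-12)
        if keep.sum() >= max(10, 0.5 * n_events) and not keep.all():
            ts2, as2, pos = [], [], 0
            for t in sweeps:
                k2 = keep[pos:pos + t.size]
                pos += t.size
                ts2.append(t[k2])
                as2.append(obs[pos - t.size:pos][k2])
            inner = fit_depletion(
                ts2, np.concatenate(as2), n_states,
                f_bounds=f_bounds, tau_bounds=tau_bounds, tau_grid=tau_grid,
                loss=loss, f_scale=f_scale, trim_mult=None)
            if inner.converged:
                inner.flags.append(
                    f"trimmed {int((~keep).sum())} outlier events")
                return inner

    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    flags: list[str] = []
    if ss_tot == 0.0:
        ve = None
        flags.append("variance undefined: constant observed amplitudes")
    else:
        ve = 1.0 - ss_res / ss_tot
    return StpFitResult(
        params=params,
        variance_explained=ve,
        predicted=pred,
        residuals=residuals,
        converged=True,
        flags=flags,
    )


def _fit_single_exp(x: np.ndarray, y: np.ndarray, domain: str) -> ExpFitResult:
    flags: list[str] = []
    if np.allclose(y, y[0]):
        return ExpFitResult(
            y0=float(y[0]), y_inf=float(y[0]), tau=np.nan, fit_domain=domain,
            flags=["tau unidentifiable: constant series"],
        )
    span = float(x[-1] - x[0]) if x[-1] > x[0] else 1.0
    # crude tau start: x scale / 3
    p0 = [float(y[0]), float(y[-1]), max(span / 3.0, 1e-6)]
    try:
        popt, _ = curve_fit(
            lambda t, y0, yinf, tau: yinf + (y0 - yinf) * np.exp(-t / tau),
            x, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return ExpFitResult(
            y0=np.nan, y_inf=np.nan, tau=np.nan, fit_domain=domain,
            flags=["fit did not converge"],
        )
    y0, y_inf, tau = (float(v) for v in popt)
    if y_inf > y0 and domain == "event_number":
        flags.append("series increases with event number")
    if tau > 5 * span:
        flags.append("tau poorly constrained: exceeds 5x the fitted span")
    return ExpFitResult(y0=y0, y_inf=y_inf, tau=tau, fit_domain=domain, flags=flags)


def fit_onset_decay(mean_amplitudes: Sequence[float]) -> ExpFitResult:
    """Fit the depression onset: amplitude vs. sound-evoked event number.

    ``mean_amplitudes[n]`` is the across-sweep mean amplitude of the
    n-th evoked event (n = 0, 1, ...).  Returns a single-exponential fit
    with tau in *events*.
    """
    y = np.asarray(mean_amplitudes, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 event numbers to fit the onset decay")
    n = np.arange(y.size, dtype=float)
    return _fit_single_exp(n, y, "event_number")


def fit_recovery_after_tone(
    times_since_offset: Sequence[float], amplitudes: Sequence[float]
) -> ExpFitResult:
    """Fit the recovery of amplitude after the end of a sound burst.

    ``times_since_offset`` in ms (post-offset events only); fits
    ``y(t) = y_inf - (y_inf - y0) * exp(-t / tau)`` and returns tau in ms.
    """
    t = np.asarray(times_since_offset, dtype=float)
    y = np.asarray(amplitudes, dtype=float)
    if t.size != y.size:
        raise ValueError("times and amplitudes must have equal length")
    if t.size < 5:
        raise ValueError("need at least 5 post-offset points to fit recovery")
    if np.any(t < 0):
        raise ValueError("times since offset must be >= 0")
    order = np.argsort(t)
    return _fit_single_exp(t[order], y[order], "time")


def steady_state_depression(
    event_times: Sequence[float],
    eepsp_slopes: Sequence[float],
    protocol,
    interval: float | None = None,
    steady_window: float = 50.0,
) -> float:
    """Steady-state depression as percent of control.

    ``100 * mean(amplitude in the last `steady_window` ms of the first
    burst) / mean(amplitude in the pre-stimulus silence)``.
    """
    t = np.asarray(event_times, dtype=float)
    y = np.asarray(eepsp_slopes, dtype=float)
    if t.size != y.size:
        raise ValueError("event_times and eepsp_slopes must have equal length")
    if interval is None:
        interval = protocol.inter_burst_intervals[0]
    (on1, off1), _ = protocol.burst_windows(interval)
    pre = (t >= 0) & (t < protocol.pre_silence)
    steady = (t >= off1 - steady_window) & (t < off1)
    if not pre.any():
        raise ValueError("no events in the pre-stimulus window")
    if not steady.any():
        raise ValueError("no events in the steady-state window")
    return float(100.0 * y[steady].mean() / y[pre].mean())
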