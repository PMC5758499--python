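"""Whole-cell intrinsic properties and Na+-current recovery.

Covers the passive-membrane estimates from a hyperpolarizing voltage
step (series / input / membrane resistance), action-potential features,
the two AP-threshold estimators (EPSP inflection point, and the most
positive subthreshold peak at long intervals), Na+-current amplitudes
from paired-pulse sweeps, and the mono-exponential fit of recovery from
inactivation per holding potential.

Voltages can carry a junction-potential correction; the correction is
applied exactly once and recorded, so double-correction cannot happen
through this interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .events import smoothed_derivative
from .synth import SweepRecording

__all__ = [
    "StepFitResult",
    "APFeatures",
    "ThresholdEstimates",
    "NaRecoveryCurve",
    "estimate_resistances",
    "ap_features",
    "threshold_inflection",
    "threshold_from_failures",
    "na_amplitude",
    "fit_na_recovery",
]


@dataclass
class StepFitResult:
    """Resistances from a voltage-clamp step (MΩ)."""

    R_series: float
    R_input: float
    R_membrane: float  # R_input - R_series, by construction

    def __post_init__(self) -> None:
        if self.R_input < self.R_series:
            raise ValueError("R_input must be >= R_series")


@dataclass
class APFeatures:
    v_rest: float  # mV
    ap_amplitude: float  # mV, peak minus rest
    dvdt_max: float  # V/s
    halfwidth: float  # ms
    junction_corrected: bool = False
    junction_mv: float = 0.0


@dataclass
class ThresholdEstimates:
    inflection_mV: float
    failure_based_mV: float


@dataclass
class NaRecoveryCurve:
    holding_potential: float  # mV
    intervals: np.ndarray  # ms
    relative_amplitude: np.ndarray
    tau_rec: float  # ms
    asymptote: float = 1.0
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def _blank_events(current: np.ndarray, dt: float, blank_ms: float = 2.0,
                  thresh_mult: float = 6.0,
                  protect_ms: list[float] | None = None) -> np.ndarray:
    """Replace spontaneous-event epochs by linear interpolation.

    Events are found on the derivative of the trace (robust MAD
    threshold); ±``blank_ms`` around each detection is interpolated.
    ``protect_ms`` lists times (step transitions) whose neighbourhood is
    never treated as an event.
    """
    d = smoothed_derivative(current, dt, 3)
    sd = 1.4826 * np.median(np.abs(d - np.median(d))) + 1e-12
    idx, _ = find_peaks(np.abs(d), height=thresh_mult * sd, distance=int(1.0 / dt))
    if protect_ms:
        guard = int(1.5 / dt)
        keep = np.ones(idx.size, dtype=bool)
        for t in protect_ms:
            keep &= np.abs(idx - int(t / dt)) > guard
        idx = idx[keep]
    out = current.copy()
    half = int(blank_ms / dt)
    mask = np.zeros(current.size, dtype=bool)
    for i in idx:
        mask[max(i - half, 0): min(i + half, current.size)] = True
    if mask.any():
        good = ~mask
        out[mask] = np.interp(np.nonzero(mask)[0], np.nonzero(good)[0], out[good])
    return out


def estimate_resistances(
    step_sweeps: SweepRecording | list[SweepRecording],
    step: float | None = None,
    blank: bool = True,
) -> StepFitResult:
    """Series / input / membrane resistance from a voltage-clamp step.

    Spontaneous synaptic currents are blanked, repeats averaged;
    ``R_series = step / peak``, ``R_input = step / steady state``,
    ``R_membrane`` their difference.  The peak is the extreme sample
    within 0.5 ms of step onset; the steady state is the mean over the
    last 20% of the step.
    """
    sweeps = step_sweeps if isinstance(step_sweeps, list) else [step_sweeps]
    proto = sweeps[0].protocol
    if step is None:
        step = float(proto["step_mV"])
    if step == 0:
        raise ValueError("step must be non-zero")
    dt = sweeps[0].dt_ms
    onset = float(proto["onset_ms"])
    dur = float(proto["duration_ms"])
    edges = [onset, onset + dur]
    traces = [(_blank_events(s.samples, dt, protect_ms=edges) if blank
               else s.samples) for s in sweeps]
    avg = np.mean(traces, axis=0)

    base = np.mean(avg[: int(onset / dt)]) if onset > 0 else 0.0
    i_on = int(onset / dt)
    seg = avg[i_on: i_on + int(0.5 / dt)] - base
    peak = seg[np.argmax(np.abs(seg))]
    ss_lo = int((onset + 0.8 * dur) / dt)
    ss_hi = int((onset + dur) / dt)
    steady = np.mean(avg[ss_lo:ss_hi]) - base
    noise = np.std(avg[: i_on]) if i_on > 10 else 0.0
    if abs(peak) <= 3.0 * noise:
        raise ValueError("step peak not resolvable above the noise floor")
    R_series = step / peak
    R_input = step / steady
    return StepFitResult(R_series=float(R_series), R_input=float(R_input),
                         R_membrane=float(R_input - R_series))


# ---------------------------------------------------------------------------


def _mode_voltage(v: np.ndarray, bin_mv: float = 0.25) -> float:
    lo, hi = np.percentile(v, [0.5, 99.5])
    edges = np.arange(lo, hi + bin_mv, bin_mv)
    if edges.size < 3:
        return float(np.median(v))
    counts, _ = np.histogram(v, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def _ap_peak_indices(v: np.ndarray, dt: float, v_rest: float,
                     min_amp: float = 20.0) -> np.ndarray:
    idx, _ = find_peaks(v, height=v_rest + min_amp, distance=int(1.0 / dt))
    return idx


def ap_features(
    trace: SweepRecording,
    junction_mv: float = 0.0,
    smooth_samples: int = 3,
) -> APFeatures:
    """Resting potential and AP amplitude / max dV/dt / halfwidth.

    The resting potential is the mode of the voltage distribution
    (inter-event baseline dominates the histogram); amplitude is the mean
    AP peak minus rest; the derivative is the smoothed central
    difference.  ``junction_mv`` (e.g. -11 mV in vivo, -13 mV in slices)
    is added to all reported voltages exactly once.
    """
    v = trace.samples
    dt = trace.dt_ms
    v_rest = _mode_voltage(v)
    peaks = _ap_peak_indices(v, dt, v_rest)
    if peaks.size == 0:
        raise ValueError("no action potentials found in the trace")
    d = smoothed_derivative(v, dt, smooth_samples)
    amps, dvdts, hws = [], [], []
    for p in peaks:
        lo = max(p - int(3.0 / dt), 0)
        hi = min(p + int(3.0 / dt), v.size)
        amps.append(v[p] - v_rest)
        dvdts.append(d[lo:p + 1].max())
        half = v_rest + 0.5 * (v[p] - v_rest)
        seg = v[lo:hi]
        above = seg >= half
        k = p - lo
        l = k
        while l > 0 and above[l - 1]:
            l -= 1
        r = k
        while r < seg.size - 1 and above[r + 1]:
            r += 1
        # sub-sample interpolation at both crossings
        tl = l - (half - seg[l]) / (seg[l - 1] - seg[l]) if l > 0 and seg[l - 1] != seg[l] else l
        tr_ = r + (seg[r] - half) / (seg[r] - seg[r + 1]) if r < seg.size - 1 and seg[r] != seg[r + 1] else r
        hws.append((tr_ - tl) * dt)
    return APFeatures(
        v_rest=float(v_rest + junction_mv),
        ap_amplitude=float(np.mean(amps)),
        dvdt_max=float(np.mean(dvdts)),
        halfwidth=float(np.mean(hws)),
        junction_corrected=junction_mv != 0.0,
        junction_mv=junction_mv,
    )


def threshold_inflection(
    trace: SweepRecording,
    junction_mv: float = 0.0,
    smooth_samples: int = 3,
) -> float:
    """AP threshold as the voltage at the maximum of the EPSP derivative.

    For each suprathreshold event, the last local maximum of dV/dt before
    the AP upstroke's own maximum marks the EPSP inflection; the cell
    value is the mean voltage at those points.
    """
    v = trace.samples
    dt = trace.dt_ms
    v_rest = _mode_voltage(v)
    peaks = _ap_peak_indices(v, dt, v_rest)
    if peaks.size == 0:
        raise ValueError("no suprathreshold events in the trace")
    d = smoothed_derivative(v, dt, smooth_samples)
    vals = []
    for p in peaks:
        lo = max(p - int(3.0 / dt), 0)
        dseg = d[lo:p + 1]
        i_up = int(np.argmax(dseg))  # AP upstroke max
        # EPSP inflection: largest derivative local max before the upstroke
        pre = dseg[: max(i_up - int(0.15 / dt), 1)]
        cands, _ = find_peaks(pre)
        if cands.size == 0:
            continue
        i_inf = int(cands[np.argmax(pre[cands])])
        vals.append(v[lo + i_inf])
    if not vals:
        raise ValueError("no EPSP inflection resolvable before any AP")
    return float(np.mean(vals) + junction_mv)


def threshold_from_failures(
    sub_peaks_mv: np.ndarray,
    preceding_intervals_ms: np.ndarray,
    min_interval: float = 10.0,
    statistic: str = "max",
    junction_mv: float = 0.0,
) -> float:
    """AP threshold from subthreshold events at long intervals.

    Uses the most positive peak membrane potential among subthreshold
    EPSPs whose preceding interval exceeds ``min_interval`` (refractory
    effects raise the peaks at shorter ones).  ``statistic='p99'`` uses
    the 99th percentile, which is less sensitive to noise.
    """
    peaks = np.asarray(sub_peaks_mv, dtype=float)
    ivs = np.asarray(preceding_intervals_ms, dtype=float)
    sel = peaks[ivs > min_interval]
    if sel.size < 10:
        raise ValueError(
            f"need >= 10 subthreshold events with intervals > {min_interval} ms, "
            f"got {sel.size}"
        )
    if statistic == "max":
        est = float(sel.max())
    elif statistic == "p99":
        est = float(np.percentile(sel, 99))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return est + junction_mv


# ---------------------------------------------------------------------------


def na_amplitude(
    sweep: SweepRecording,
    baseline_ms: float = 2.0,
    smooth_samples: int = 3,
) -> np.ndarray:
    """Na+-current amplitude per pulse: |peak - local baseline| (nA).

    The local baseline is the median over ``baseline_ms`` immediately
    before each pulse onset (configurable, mirroring a user-set window).
    A light boxcar (3 samples by default) keeps the peak statistic
    from riding single noise samples.
    """
    from .events import _boxcar

    proto = sweep.protocol
    onsets = [float(t) for t in proto["pulse_onsets_ms"]]
    dur = float(proto["pulse_duration_ms"])
    dt = sweep.dt_ms
    x = _boxcar(sweep.samples, smooth_samples)
    out = []
    prev_end = -np.inf
    for on in onsets:
        # keep the baseline window clear of the previous pulse's tail
        b_start = max(on - baseline_ms, prev_end + 0.15)
        b_lo = max(int(b_start / dt), 0)
        b_hi = int(on / dt)
        base = float(np.median(x[b_lo:b_hi])) if b_hi > b_lo else 0.0
        p_lo, p_hi = int(on / dt), min(int((on + dur) / dt), x.size)
        peak = float(x[p_lo:p_hi].min())  # inward (negative) current
        out.append(abs(peak - base))
        prev_end = on + dur
    return np.asarray(out)


def fit_na_recovery(
    intervals: np.ndarray,
    relative_amplitudes: np.ndarray,
    holding_potential: float,
    free_asymptote: bool = False,
) -> NaRecoveryCurve:
    """Mono-exponential recovery from inactivation for one holding potential.

    Fits ``r(dt) = a * (1 - exp(-dt / tau))`` with the asymptote ``a``
    fixed at 1 by default (amplitudes are relative), optionally free for
    noisy data.
    """
    x = np.asarray(intervals, dtype=float)
    y = np.asarray(relative_amplitudes, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 (interval, amplitude) pairs")
    flags: list[str] = []
    tau_lo = 1e-3
    if free_asymptote:
        popt, _ = curve_fit(lambda t, a, tau: a * (1.0 - np.exp(-t / tau)),
                            x, y, p0=[1.0, np.median(x)],
                            bounds=([0.0, tau_lo], [1.5, np.inf]), maxfev=20000)
        a, tau = (float(v) for v in popt)
    else:
        popt, _ = curve_fit(lambda t, tau: 1.0 - np.exp(-t / tau),
                            x, y, p0=[np.median(x)],
                            bounds=([tau_lo], [np.inf]), maxfev=20000)
        a, tau = 1.0, float(popt[0])
    if tau < 0.5 * float(x.min()):
        flags.append("tau below the shortest probed interval: "
                     "no measurable inactivation")
    return NaRecoveryCurve(
        holding_potential=float(holding_potential),
        intervals=x, relative_amplitude=y, tau_rec=tau, asymptote=a,
        flags=flags,
    )
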