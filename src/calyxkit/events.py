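"""Detection and feature extraction of juxtacellular complex waveforms.

A complex event is a prespike (the presynaptic spike), an eEPSP rise, and
— when transmission succeeds — a large eAP deflection with a downward
after-wave.  Detection keys on the eEPSP rise, which both suprathreshold
and subthreshold events share, so failures are detected too.  Per-event
features follow the field's operational definitions: the maximum rate of
rise of the eEPSP (eEPSP') as the strength of transmission, the maximum
first derivative of the eAP (eAP') as postsynaptic excitability, the
prespike peak-to-baseline amplitude for the presynaptic spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .protocol import StimulusProtocol
from .synth import SweepRecording

__all__ = [
    "ComplexEvent",
    "EventConfig",
    "detect_events",
    "measure_event",
    "measure_events",
    "failure_rate",
    "psth",
    "PSTHResult",
    "smoothed_derivative",
]


@dataclass
class ComplexEvent:
    """Features of one detected complex waveform.

    Spike-dependent fields (``eap_*``, ``delay_epsp_ap``) are NaN on
    failures.
    """

    t_event: float  # ms
    prespike_amp: float  # mV
    eepsp_slope_max: float  # mV/ms
    eap_peak: float  # mV
    eap_dvdt_max: float  # V/s
    eap_halfwidth: float  # ms
    delay_pre_epsp: float  # ms
    delay_epsp_ap: float  # ms
    is_failure: bool
    preceding_interval: float  # ms (inf for the first event)
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class EventConfig:
    """Windows and smoothing knobs for detection and measurement (ms)."""

    smooth_samples: int = 3  # boxcar width for measurement derivatives
    detect_smooth_ms: float = 0.1  # boxcar for the detection derivative
    cluster_gap: float = 0.5  # derivative peaks closer than this belong
    # to one complex waveform (prespike / EPSP rise / spike upstroke)
    rise_window: tuple[float, float] = (-0.10, 0.07)  # eEPSP'-search, rel. event
    # (tight: the spike upstroke's leading edge must stay outside)
    prespike_window: tuple[float, float] = (-0.8, -0.1)
    baseline_window_ms: float = 2.0  # before the prespike window
    eap_window: tuple[float, float] = (0.12, 1.5)
    claimed_ms: float = 1.5  # samples this long after a previous event are
    # "claimed" by it and excluded from baseline estimation
    fail_noise_mult: float = 4.0
    fail_slope_mult: float = 1.5
    spike_min_dvdt: float = 15.0  # mV/ms; a lone peak this steep is a spike
    # upstroke, not an EPSP rise
    fallback_pre_gap: float = 0.25  # ms, assumed EPSP-rise -> upstroke-peak
    # gap when the EPSP rise is sub-threshold


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kern = np.ones(width) / width
    return np.convolve(x, kern, mode="same")


def smoothed_derivative(samples: np.ndarray, dt_ms: float, smooth_samples: int = 3) -> np.ndarray:
    """Central-difference first derivative (mV/ms) after boxcar smoothing."""
    d = np.gradient(_boxcar(np.asarray(samples, dtype=float), smooth_samples), dt_ms)
    return d


def _deriv_noise_sd(deriv: np.ndarray) -> float:
    # robust noise scale of the derivative trace (MAD -> SD)
    med = np.median(deriv)
    return float(1.4826 * np.median(np.abs(deriv - med)))


def detect_events(
    trace: SweepRecording,
    detect_threshold: float = 3.0,
    refractory: float = 1.0,
    config: EventConfig = EventConfig(),
) -> np.ndarray:
    """Event times (ms) at the eEPSP rise of each complex waveform.

    Local maxima of the smoothed derivative above ``detect_threshold``
    (mV/ms) are clustered (one cluster per complex waveform).  Within a
    cluster the EPSP-rise peak is identified by shape: when one peak
    dominates the cluster it is the spike upstroke, and the event time is
    the latest peak preceding it by at least the EPSP-to-spike gap;
    otherwise the waveform is subthreshold and the EPSP rise is the last
    peak of the cluster (the prespike's derivative lobes always come
    first).  Detection therefore keys on the eEPSP, which suprathreshold
    and subthreshold events share.  Events closer than ``refractory`` to
    the previous accepted event are suppressed.
    """
    if detect_threshold <= 0:
        raise ValueError("detect_threshold must be > 0")
    samples = trace.samples
    if samples.size == 0:
        return np.empty(0)
    dt = trace.dt_ms
    width = max(int(round(config.detect_smooth_ms / dt)), 1)
    deriv = np.gradient(_boxcar(samples, width), dt)
    idx, props = find_peaks(deriv, height=detect_threshold)
    if idx.size == 0:
        return np.empty(0)
    heights = props["peak_heights"]
    times = idx * dt

    # cluster peaks belonging to one waveform
    clusters: list[list[int]] = [[0]]
    for j in range(1, idx.size):
        if times[j] - times[clusters[-1][-1]] <= config.cluster_gap:
            clusters[-1].append(j)
        else:
            clusters.append([j])

    spike_dominance = 2.0  # spike upstroke towers over EPSP/prespike peaks
    min_pre_gap = 0.12  # ms, EPSP-rise peak precedes the upstroke by this
    max_pre_gap = 0.45  # ms; an earlier peak is the prespike, not the EPSP

    out: list[float] = []
    out_h: list[float] = []
    for members in clusters:
        h = heights[members]
        tm = times[members]
        k_max = int(np.argmax(h))
        others = np.delete(h, k_max)
        is_spike_top = h[k_max] >= config.spike_min_dvdt and (
            not others.size or h[k_max] >= spike_dominance * others.max()
        )
        if is_spike_top:
            gap = tm[k_max] - tm
            before = np.nonzero((gap >= min_pre_gap) & (gap <= max_pre_gap))[0]
            # when the EPSP rise itself stays below threshold (deep
            # depression), fall back to a nominal EPSP-to-upstroke gap
            t_ev = tm[before[-1]] if before.size else tm[k_max] - config.fallback_pre_gap
        else:
            t_ev = tm[-1]
            # distinguish a lone prespike from a subthreshold EPSP rise:
            # the trace keeps rising after an EPSP onset but falls into
            # the prespike's negative lobe after its peak
            i0 = min(int(t_ev / dt), samples.size - 1)
            f0 = min(i0 + int(0.15 / dt), samples.size)
            f1 = min(i0 + int(0.40 / dt), samples.size)
            if f1 > f0 and samples[f0:f1].mean() < samples[i0]:
                lo = min(i0 + int(0.15 / dt), samples.size - 2)
                hi = min(i0 + int(0.55 / dt), samples.size)
                if hi > lo + 2:
                    t_ev = (lo + int(np.argmax(deriv[lo:hi]))) * dt
        if not out or t_ev - out[-1] >= refractory:
            out.append(float(t_ev))
            out_h.append(float(h[k_max]))
        elif h[k_max] >= 2.0 * out_h[-1]:
            # an isolated prespike can form its own small cluster just
            # ahead of the spike's; the far stronger cluster wins
            out[-1] = float(t_ev)
            out_h[-1] = float(h[k_max])
    return np.asarray(out)


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float:
    """First (rising) or last (falling) crossing time of ``level`` by interpolation."""
    above = y >= level
    if rising:
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            return np.nan
        i = idx[0]
    else:
        idx = np.nonzero(above[:-1] & ~above[1:])[0]
        if idx.size == 0:
            return np.nan
        i = idx[-1]
    y0, y1 = y[i], y[i + 1]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[i] + frac * (t[i + 1] - t[i]))


def measure_event(
    trace: SweepRecording,
    t_event: float,
    prev_event: float | None = None,
    config: EventConfig = EventConfig(),
    noise_sd_deriv: float | None = None,
    next_event: float | None = None,
) -> ComplexEvent:
    """Extract the per-event features around one detected event time."""
    samples = trace.samples
    dt = trace.dt_ms
    n = samples.size
    if not 0.0 <= t_event <= n * dt:
        raise ValueError(f"t_event {t_event} ms outside the trace")

    def window(lo_ms: float, hi_ms: float) -> tuple[np.ndarray, np.ndarray]:
        lo = max(int(np.floor((t_event + lo_ms) / dt)), 0)
        hi = min(int(np.ceil((t_event + hi_ms) / dt)) + 1, n)
        idx = np.arange(lo, hi)
        return idx, idx * dt

    deriv = None  # computed lazily over a local span
    span_lo = max(int((t_event - 5.0) / dt), 0)
    span_hi = min(int((t_event + 4.0) / dt) + 1, n)
    local = samples[span_lo:span_hi]
    local_t = np.arange(span_lo, span_hi) * dt
    local_d = smoothed_derivative(local, dt, config.smooth_samples)

    flags: list[str] = []

    def dwin(lo_ms: float, hi_ms: float) -> tuple[np.ndarray, np.ndarray]:
        m = (local_t >= t_event + lo_ms) & (local_t <= t_event + hi_ms)
        return local_t[m], local_d[m]

    # eEPSP maximum rate of rise; an argmax on the window's trailing edge is
    # the spike upstroke's flank, not the EPSP — use the interior local
    # maximum instead when one exists
    tr, dr = dwin(*config.rise_window)
    if tr.size == 0:
        raise ValueError("rise window outside the trace")
    i_rise = int(np.argmax(dr))
    if i_rise == dr.size - 1 and dr.size >= 3:
        pk, _ = find_peaks(dr)
        if pk.size:
            i_rise = int(pk[np.argmax(dr[pk])])
            flags.append("rise window clipped at spike upstroke")
    eepsp_slope_max = float(dr[i_rise])
    t_rise = float(tr[i_rise])

    # baseline: median of the stretch before the prespike window, excluding
    # samples claimed by the previous event's core
    b_hi = t_event + config.prespike_window[0]
    b_lo = b_hi - config.baseline_window_ms
    m = (local_t >= b_lo) & (local_t < b_hi)
    if prev_event is not None and np.isfinite(prev_event):
        claimed = (local_t >= prev_event - 1.0) & (local_t <= prev_event + config.claimed_ms)
        m_excl = m & ~claimed
        if m_excl.sum() >= 5:
            m = m_excl
        else:
            flags.append("baseline overlaps previous event")
    if m.sum() == 0:
        baseline = float(samples[max(int(t_event / dt) - 1, 0)])
        flags.append("no baseline window")
    else:
        baseline = float(np.median(local[m]))

    # prespike: positive peak relative to baseline
    pm = (local_t >= t_event + config.prespike_window[0]) & (
        local_t <= t_event + config.prespike_window[1])
    if pm.sum() == 0:
        prespike_amp = np.nan
        t_pre = np.nan
        flags.append("no prespike window")
    else:
        seg = local[pm]
        i_pre = int(np.argmax(seg))
        prespike_amp = float(seg[i_pre] - baseline)
        t_pre = float(local_t[pm][i_pre])

    # eAP window: peak, derivative, halfwidth; failure classification.
    # The window is trimmed at the next event so a successor's waveform is
    # never mistaken for this event's spike.
    eap_hi = config.eap_window[1]
    if next_event is not None and np.isfinite(next_event):
        eap_hi = min(eap_hi, next_event - t_event - 0.1)
    am = (local_t >= t_event + config.eap_window[0]) & (
        local_t <= t_event + eap_hi)
    ta, ya = local_t[am], local[am]
    da = local_d[am]
    if noise_sd_deriv is None:
        noise_sd_deriv = _deriv_noise_sd(local_d)
    criterion = (config.fail_noise_mult * noise_sd_deriv
                 + config.fail_slope_mult * eepsp_slope_max)
    post_dvdt = float(da.max()) if da.size else -np.inf
    is_failure = post_dvdt < criterion

    if is_failure or ya.size == 0:
        eap_peak = eap_dvdt = eap_hw = delay_epsp_ap = np.nan
    else:
        i_pk = int(np.argmax(ya))
        eap_peak = float(ya[i_pk] - baseline)
        eap_dvdt = post_dvdt
        t_pk = float(ta[i_pk])
        half = baseline + 0.5 * eap_peak
        # crossings around the peak
        left = _interp_crossing(ta[: i_pk + 1], ya[: i_pk + 1], half, rising=True)
        right_seg_t, right_seg_y = ta[i_pk:], ya[i_pk:]
        below = np.nonzero(right_seg_y < half)[0]
        if np.isnan(left) or below.size == 0:
            eap_hw = np.nan
            flags.append("halfwidth not resolvable")
        else:
            j = below[0]
            y0, y1 = right_seg_y[j - 1], right_seg_y[j]
            frac = (half - y0) / (y1 - y0) if y1 != y0 else 0.0
            right = float(right_seg_t[j - 1] + frac * (right_seg_t[j] - right_seg_t[j - 1]))
            eap_hw = right - left
        delay_epsp_ap = t_pk - t_rise

    prev_iv = (t_event - prev_event) if prev_event is not None else np.inf
    return ComplexEvent(
        t_event=t_event,
        prespike_amp=prespike_amp,
        eepsp_slope_max=eepsp_slope_max,
        eap_peak=eap_peak,
        eap_dvdt_max=eap_dvdt,
        eap_halfwidth=eap_hw,
        delay_pre_epsp=(t_rise - t_pre) if np.isfinite(t_pre) else np.nan,
        delay_epsp_ap=delay_epsp_ap,
        is_failure=bool(is_failure),
        preceding_interval=float(prev_iv),
        flags=flags,
    )


def measure_events(
    trace: SweepRecording,
    event_times: np.ndarray,
    config: EventConfig = EventConfig(),
) -> list[ComplexEvent]:
    """Measure every detected event, threading the preceding-event times."""
    d_full = smoothed_derivative(trace.samples, trace.dt_ms, config.smooth_samples)
    noise_sd = _deriv_noise_sd(d_full)
    times = np.asarray(event_times, dtype=float)
    out: list[ComplexEvent] = []
    for j, t in enumerate(times):
        prev = times[j - 1] if j > 0 else None
        nxt = times[j + 1] if j + 1 < times.size else None
        out.append(measure_event(trace, t, prev, config,
                                 noise_sd_deriv=noise_sd, next_event=nxt))
    return out


def failure_rate(events: list[ComplexEvent], window: tuple[float, float] | None = None) -> float:
    """Percent of events classified as failures, optionally within a time window."""
    sel = [e for e in events if window is None or window[0] <= e.t_event < window[1]]
    if not sel:
        raise ValueError("failure_rate undefined: no events in the selected window")
    return 100.0 * sum(e.is_failure for e in sel) / len(sel)


@dataclass
class PSTHResult:
    bin_edges: np.ndarray  # ms
    rate: np.ndarray  # events/s per bin, normalized by sweep count
    onset_peak_rate: float  # max bin rate within the first 10 ms of burst 1
    steady_rate: float  # mean rate over the last 50 ms of burst 1


def psth(
    event_times_per_sweep: list[np.ndarray],
    protocol: StimulusProtocol,
    bin_ms: float = 1.0,
    interval: float | None = None,
) -> PSTHResult:
    """Peristimulus time histogram across sweeps of one gap condition."""
    if len(event_times_per_sweep) == 0:
        raise ValueError("need at least one sweep")
    edges = np.arange(0.0, protocol.sweep_duration + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for times in event_times_per_sweep:
        c, _ = np.histogram(np.asarray(times, dtype=float), bins=edges)
        counts += c
    rate = counts / len(event_times_per_sweep) / (bin_ms / 1000.0)
    (on1, off1), _ = protocol.burst_windows(
        protocol.inter_burst_intervals[0] if interval is None else interval
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    # a light boxcar keeps the max-of-bins statistic from riding noise peaks
    rate_sm = _boxcar(rate, 3)
    onset = rate_sm[(centers >= on1) & (centers < on1 + 10.0)]
    steady = rate[(centers >= off1 - 50.0) & (centers < off1)]
    return PSTHResult(
        bin_edges=edges,
        rate=rate,
        onset_peak_rate=float(onset.max()) if onset.size else 0.0,
        steady_rate=float(steady.mean()) if steady.size else 0.0,
    )
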