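"""Template subtraction of overlapping complex waveforms.

At short inter-event intervals the prespike of an event rides on the
downward after-wave of the previous event, which corrupts both the local
baseline and the prespike peak.  Because the pre- and postsynaptic
contributions are independent voltage sources, the previous event can be
removed by subtracting a scaled average waveform:

1. isolated events (no successor within 2.5 ms) are sorted into 4–6
   subgroups by their maximum downward rate, outliers are removed, and
   each subgroup is averaged into a template;
2. for each overlapped event, the template best matching the *previous*
   event's downward rate is aligned at the point where that event's
   downward phase intersects the baseline, amplitude-scaled by least
   squares over the downward phase, and subtracted;
3. the prespike amplitude is then re-measured on the corrected trace.

The grouping bounds, the one-pass 3x-median outlier rule and the
least-squares scaling objective are conventions of this implementation
(see the methods note); only events from cells with prespikes above
0.3 mV enter the downstream recovery analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import ComplexEvent, EventConfig, measure_event, smoothed_derivative
from .synth import SweepRecording

__all__ = [
    "Template",
    "TemplateConfig",
    "build_templates",
    "subtract_previous",
    "corrected_prespike_series",
    "PRESPIKE_INCLUSION_MV",
]

#: minimum cell-mean prespike amplitude for the recovery analysis
PRESPIKE_INCLUSION_MV = 0.3


@dataclass
class Template:
    """Average isolated-event waveform for one downward-rate subgroup."""

    waveform: np.ndarray  # mV, baseline-subtracted
    downward_rate_range: tuple[float, float]  # mV/ms (negative numbers)
    mean_downward_rate: float
    n_members: int
    alignment_index: float  # fractional sample of the baseline intersection
    peak_index: int  # sample of the spike peak within the waveform
    pre_samples: int  # samples before the event time
    dt_ms: float


@dataclass(frozen=True)
class TemplateConfig:
    isolation_ms: float = 2.5  # no successor within this -> isolated
    window: tuple[float, float] = (-1.0, 8.0)  # ms around the event time
    n_groups: int | None = None  # default: adaptive in [4, 6]
    outlier_mult: float = 3.0  # times the median RMS distance
    down_search: tuple[float, float] = (0.0, 2.0)  # ms, downward-rate search
    scale_extra_ms: float = 1.0  # scaling window: peak .. crossing + this


def _downward_rate(seg: np.ndarray, dt: float, lo: int, hi: int,
                   smooth: int = 3) -> float:
    d = smoothed_derivative(seg, dt, smooth)
    return float(d[lo:hi].min())


def _baseline_crossing(seg: np.ndarray, peak_idx: int) -> float:
    """Fractional index of the first zero crossing after the peak."""
    after = seg[peak_idx:]
    neg = np.nonzero(after[1:] < 0)[0]
    for j in neg:
        y0, y1 = after[j], after[j + 1]
        if y0 >= 0 > y1:
            frac = y0 / (y0 - y1) if y0 != y1 else 0.0
            return float(peak_idx + j + frac)
    return np.nan


def build_templates(
    trace: SweepRecording,
    events: list[ComplexEvent],
    n_groups: int | None = None,
    config: TemplateConfig = TemplateConfig(),
) -> list[Template]:
    """Group isolated suprathreshold events by downward rate and average.

    Raises ``ValueError`` advising fewer groups when too few isolated
    events are available.
    """
    dt = trace.dt_ms
    samples = trace.samples
    times = np.array([e.t_event for e in events])
    lo_ms, hi_ms = config.window
    n_pre = int(round(-lo_ms / dt))
    n_win = int(round((hi_ms - lo_ms) / dt))

    iso: list[tuple[np.ndarray, float]] = []
    for j, e in enumerate(events):
        if e.is_failure:
            continue
        if j + 1 < len(events) and times[j + 1] - times[j] < config.isolation_ms:
            continue
        # the tail of the averaging window must be clean too, otherwise
        # successors at intermediate intervals contaminate the template
        if j + 1 < len(events) and times[j + 1] - times[j] < hi_ms:
            continue
        i0 = int(round((e.t_event + lo_ms) / dt))
        if i0 < 0 or i0 + n_win > samples.size:
            continue
        seg = samples[i0: i0 + n_win].astype(float)
        base = np.median(seg[: max(n_pre // 2, 1)])
        seg = seg - base
        d_lo = int(round((config.down_search[0] - lo_ms) / dt))
        d_hi = int(round((config.down_search[1] - lo_ms) / dt))
        iso.append((seg, _downward_rate(seg, dt, d_lo, d_hi)))

    if n_groups is None:
        n_groups = config.n_groups
    if n_groups is None:
        n_groups = int(np.clip(min(5, len(iso) // 10), 4, 6))
    if not 4 <= n_groups <= 6:
        raise ValueError("n_groups must be between 4 and 6")
    if len(iso) < n_groups:
        raise ValueError(
            f"only {len(iso)} isolated events for {n_groups} groups; "
            "use fewer groups or a longer recording"
        )

    rates = np.array([r for _, r in iso])
    edges = np.quantile(rates, np.linspace(0, 1, n_groups + 1))
    edges[0] -= 1e-9
    groups = np.clip(np.searchsorted(edges, rates, side="right") - 1, 0, n_groups - 1)

    templates: list[Template] = []
    for g in range(n_groups):
        members = [iso[j][0] for j in np.nonzero(groups == g)[0]]
        if not members:
            continue
        stackm = np.stack(members)
        mean0 = stackm.mean(axis=0)
        rms = np.sqrt(np.mean((stackm - mean0) ** 2, axis=1))
        keep = rms <= config.outlier_mult * max(np.median(rms), 1e-12)
        wf = stackm[keep].mean(axis=0)
        peak_idx = n_pre + int(np.argmax(wf[n_pre: n_pre + int(1.5 / dt)]))
        align = _baseline_crossing(wf, peak_idx)
        if np.isnan(align):
            continue
        g_rates = rates[groups == g]
        templates.append(Template(
            waveform=wf,
            downward_rate_range=(float(g_rates.min()), float(g_rates.max())),
            mean_downward_rate=float(g_rates[keep].mean() if keep.any() else g_rates.mean()),
            n_members=int(keep.sum()),
            alignment_index=align,
            peak_index=peak_idx,
            pre_samples=n_pre,
            dt_ms=dt,
        ))
    if not templates:
        raise ValueError("no usable templates; recording may lack spikes")
    return templates


def _best_template(templates: list[Template], rate: float) -> Template:
    return min(templates, key=lambda t: abs(t.mean_downward_rate - rate))


def subtract_previous(
    working: np.ndarray,
    prev_t: float,
    templates: list[Template],
    dt: float,
    config: TemplateConfig = TemplateConfig(),
    t_next: float | None = None,
) -> str:
    """Subtract the previous event's downward phase and tail in place.

    ``working`` is the (copied) trace being corrected; returns a status
    string: ``"subtracted"``, ``"no-downward-phase"`` (previous event was
    a failure or its crossing was not found — a near-zero correction, so
    nothing is done) or ``"unmeasurable"`` (no template bank).
    """
    if not templates:
        return "unmeasurable"
    n = working.size
    # locate the previous event's spike peak and baseline intersection
    i_prev = int(round(prev_t / dt))
    i_hi = min(i_prev + int(1.5 / dt), n)
    if i_hi <= i_prev:
        return "no-downward-phase"
    seg = working[i_prev:i_hi]
    base_lo = max(i_prev - int(3.0 / dt), 0)
    base = np.median(working[base_lo:i_prev]) if i_prev > base_lo else 0.0
    peak_rel = int(np.argmax(seg))
    search = working[i_prev:min(i_prev + int(8.0 / dt), n)] - base
    cross = _baseline_crossing(search, peak_rel)

    d = smoothed_derivative(search, dt, 3)
    down_hi = 2.0
    if t_next is not None:
        # keep the search clear of the next event's own components
        down_hi = min(down_hi, t_next - prev_t - 0.5)
    down_hi = max(down_hi, 0.5)
    down_rate = float(d[: max(int(down_hi / dt), 2)].min())
    tmpl = _best_template(templates, down_rate)

    if down_rate > -3.0:
        # no downward phase at all (previous event was a failure)
        return "no-downward-phase"

    # align the template's crossing to the event's crossing (sub-sample);
    # when the next event starts before the crossing — or distorts it —
    # fall back to aligning the spike peaks
    cross_clean = (
        not np.isnan(cross)
        and (t_next is None or (i_prev + cross) * dt < t_next - 0.6)
    )
    if cross_clean:
        shift0 = (i_prev + cross) - tmpl.alignment_index
    else:
        shift0 = float((i_prev + peak_rel) - tmpl.peak_index)

    # refine the alignment by a small least-squares search over sub-sample
    # offsets: on the steep downstroke, half a sample of misalignment
    # leaves a residual comparable to the prespike being recovered
    best = None
    for d_shift in np.arange(-1.5, 1.51, 0.25):
        shift = shift0 + d_shift
        res = _scaled_residual(working, tmpl, shift, dt, base, config, t_next, n)
        if res is not None and (best is None or res[0] < best[0]):
            best = (res[0], shift, res[1], res[2])
    if best is None:
        return "no-downward-phase"
    _, shift, scale, wf_shifted = best
    i_shift = int(np.floor(shift))

    # subtract the whole aligned template: at very short intervals even the
    # upstroke flank leaks into the next event's prespike window
    wf = tmpl.waveform
    k0 = max(i_shift, 0)
    k1 = min(i_shift + wf.size, n)
    working[k0:k1] -= scale * wf_shifted[k0 - i_shift: k1 - i_shift]
    # two regions cannot be nulled by an amplitude-scaled template: the
    # previous event's own prespike/EPSP (their ratio to the spike varies
    # with the depression state, unlike the spike-locked after-wave) and
    # the sharp spike peak (no sub-sample match by linear interpolation).
    # Bridge both so their residuals never masquerade as the next event's
    # prespike.
    pk = i_prev + peak_rel
    for lo_ms, hi_ref, hi_ms in ((-0.45, i_prev, 0.18), (None, pk, 0.10)):
        if lo_ms is None:
            a = max(pk - int(0.08 / dt), k0 + 1)
        else:
            a = max(i_prev + int(lo_ms / dt), k0 + 1)
        b = min(hi_ref + int(hi_ms / dt), n - 1)
        if b > a:
            working[a:b] = np.linspace(working[a - 1], working[b], b - a + 1)[1:]
    return "subtracted"


def _scaled_residual(working, tmpl, shift, dt, base, config, t_next, n):
    """Least-squares scale over the downward phase for one trial shift.

    Returns ``(ss_res, scale, shifted_waveform)`` or ``None`` when the
    scaling window is unusable.
    """
    i_shift = int(np.floor(shift))
    frac = shift - i_shift
    wf = tmpl.waveform
    wf_shifted = (1.0 - frac) * wf + frac * np.concatenate(([wf[0]], wf[:-1]))
    j0 = tmpl.peak_index
    j1 = min(int(np.ceil(tmpl.alignment_index + config.scale_extra_ms / dt)), wf.size)
    t0 = j0 + i_shift
    t1 = j1 + i_shift
    if t_next is not None:
        # keep the scaling window clear of the next event's own waveform
        t1 = min(t1, int((t_next - 0.6) / dt))
        j1 = t1 - i_shift
    if t0 < 0 or t1 > n or j1 - j0 < 4:
        return None
    target = working[t0:t1] - base
    ref = wf_shifted[j0:j1]
    denom = float(ref @ ref)
    if denom <= 0:
        return None
    scale = float(target @ ref) / denom
    ss = float(np.sum((target - scale * ref) ** 2))
    return ss, scale, wf_shifted


def corrected_prespike_series(
    trace: SweepRecording,
    events: list[ComplexEvent],
    templates: list[Template],
    event_config: EventConfig = EventConfig(),
    config: TemplateConfig = TemplateConfig(),
) -> tuple[np.ndarray, list[str]]:
    """Prespike amplitudes re-measured after sequential template subtraction.

    Walks events in time order on a working copy of the trace; before
    measuring each event the previous event's downward phase is removed,
    so corrections accumulate along the sweep.  Returns the per-event
    amplitudes (mV) and a status flag per event.
    """
    working = trace.samples.astype(float).copy()
    dt = trace.dt_ms
    tail_ms = config.window[1]
    amps = np.full(len(events), np.nan)
    status: list[str] = []
    work_trace = SweepRecording(working, trace.sample_rate, trace.mode,
                                protocol=trace.protocol)
    for j, e in enumerate(events):
        st = "isolated"
        if j > 0 and e.preceding_interval < tail_ms:
            st = subtract_previous(working, events[j - 1].t_event, templates,
                                   dt, config, t_next=e.t_event)
        work_trace.samples = working
        prev_t = events[j - 1].t_event if j > 0 else None
        nxt = events[j + 1].t_event if j + 1 < len(events) else None
        if st == "subtracted":
            # previous event's core is gone from the working trace; the
            # baseline no longer needs to exclude it
            m = measure_event(work_trace, e.t_event, None, event_config,
                              next_event=nxt)
        else:
            m = measure_event(work_trace, e.t_event, prev_t, event_config,
                              next_event=nxt)
        amps[j] = m.prespike_amp
        status.append(st)
    return amps, status
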