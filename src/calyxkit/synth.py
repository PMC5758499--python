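"""Ground-truthed synthetic recordings.

Everything downstream (event detection, template subtraction, the
depletion-model fits, intrinsic-property extraction, AIS measurement) is
validated against data from this module, where the injected truth is
known exactly.  All stochastic operations take an explicit seed and are
bit-reproducible.

Conventions: time ms, voltage mV, current nA, length μm, rates events/s;
sample clock 50 kHz unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .depletion import DepletionModelParams, DepletionState, predict_depletion
from .kernels import WaveformKernel, event_window, render_event
from .protocol import StimulusProtocol, make_stimulus_protocol

__all__ = [
    "CellGroundTruth",
    "EventGroundTruth",
    "SweepRecording",
    "ImageStack",
    "simulate_spike_train",
    "simulate_event_series",
    "synthesize_juxtacellular_trace",
    "synthesize_wholecell_step",
    "synthesize_wholecell_cc",
    "synthesize_na_sweeps",
    "synthesize_ais_stack",
    "wt_like_ground_truth",
    "mutant_like_ground_truth",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class EventGroundTruth:
    """Per-event injected truth for one synthesized sweep."""

    event_times: np.ndarray  # ms, strictly increasing
    true_eepsp_slope: np.ndarray  # mV/ms
    true_eap_dvdt: np.ndarray  # V/s
    true_prespike_amp: np.ndarray  # mV
    is_failure: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.true_eepsp_slope = np.asarray(self.true_eepsp_slope, dtype=float)
        self.true_eap_dvdt = np.asarray(self.true_eap_dvdt, dtype=float)
        self.true_prespike_amp = np.asarray(self.true_prespike_amp, dtype=float)
        self.is_failure = np.asarray(self.is_failure, dtype=bool)
        n = self.event_times.size
        for name in ("true_eepsp_slope", "true_eap_dvdt", "true_prespike_amp", "is_failure"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} must have the same length as event_times")
        if n > 1 and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.event_times.size)


@dataclass
class SweepRecording:
    """Uniformly sampled trace with protocol markers.

    ``mode`` is one of ``juxtacellular`` (mV), ``wholecell_cc`` (mV) or
    ``wholecell_vc`` (nA).
    """

    samples: np.ndarray
    sample_rate: float  # Hz
    mode: str
    protocol: object = None  # StimulusProtocol or a step/pulse descriptor dict
    ground_truth: EventGroundTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.mode not in ("juxtacellular", "wholecell_cc", "wholecell_vc"):
            raise ValueError(f"unknown recording mode {self.mode!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    @property
    def duration_ms(self) -> float:
        return self.samples.size * self.dt_ms

    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt_ms


@dataclass
class ImageStack:
    """Anisotropic 3D intensity volume, axis order (z, y, x)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]  # μm per axis (z, y, x)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3D")
        if self.voxels.shape[0] < 3:
            raise ValueError("stack needs at least 3 planes")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive values")
        self.spacing = spacing


@dataclass
class CellGroundTruth:
    """Generative parameters for one simulated cell.

    Rates follow the sound-driven firing of MNTB principal cells: a
    spontaneous rate outside the noise bursts, and during each burst an
    onset peak decaying exponentially (``adapt_tau``) to a steady rate.
    Per-event amplitudes for the three complex-waveform features are
    produced by independent depletion models.
    """

    spont_rate: float = 26.0  # events/s
    peak_rate: float = 311.0  # events/s at burst onset
    steady_rate: float = 155.0  # events/s late in the burst
    adapt_tau: float = 30.0  # ms
    depletion_params_eepsp: DepletionModelParams = field(
        default_factory=lambda: DepletionModelParams(A=8.0, states=(DepletionState(0.161, 235.0),))
    )
    depletion_params_eap: DepletionModelParams = field(
        default_factory=lambda: DepletionModelParams(
            A=150.0, states=(DepletionState(0.6, 1.58), DepletionState(0.05, 109.0))
        )
    )
    depletion_params_prespike: DepletionModelParams = field(
        default_factory=lambda: DepletionModelParams(A=0.6, states=(DepletionState(0.35, 3.88),))
    )
    failure_prob: float = 0.106
    failure_model: str = "bernoulli"  # or "interval"
    failure_interval_tau: float = 3.0  # ms, for the interval-dependent option
    kernel: WaveformKernel = field(default_factory=WaveformKernel)
    noise_sd: float = 0.05  # mV
    sample_rate: float = 50_000.0  # Hz
    refractory: float = 1.0  # ms, absolute

    def __post_init__(self) -> None:
        for name in ("spont_rate", "peak_rate", "steady_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ValueError("failure_prob must be in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


def wt_like_ground_truth(**overrides) -> CellGroundTruth:
    """Cell parameters at the wild-type group means."""
    return replace(CellGroundTruth(), **overrides) if overrides else CellGroundTruth()


def mutant_like_ground_truth(**overrides) -> CellGroundTruth:
    """Cell parameters at the mutant group means: faster recovery of
    spike and prespike depression, fewer failures."""
    base = CellGroundTruth(
        depletion_params_eap=DepletionModelParams(
            A=150.0, states=(DepletionState(0.6, 1.32), DepletionState(0.05, 100.0))
        ),
        depletion_params_prespike=DepletionModelParams(
            A=0.6, states=(DepletionState(0.35, 2.53),)
        ),
        depletion_params_eepsp=DepletionModelParams(
            A=8.0, states=(DepletionState(0.151, 88.0),)
        ),
        failure_prob=0.014,
    )
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# spike trains


def _rate_profile(t: np.ndarray, protocol: StimulusProtocol | None,
                  interval: float | None, truth: CellGroundTruth) -> np.ndarray:
    rate = np.full(t.shape, truth.spont_rate, dtype=float)
    if protocol is None:
        return rate
    for on, off in protocol.burst_windows(
        protocol.inter_burst_intervals[0] if interval is None else interval
    ):
        inside = (t >= on) & (t < off)
        rate[inside] = truth.steady_rate + (truth.peak_rate - truth.steady_rate) * np.exp(
            -(t[inside] - on) / truth.adapt_tau
        )
    return rate


def simulate_spike_train(
    protocol: StimulusProtocol | None,
    truth: CellGroundTruth,
    seed: int,
    interval: float | None = None,
    duration: float | None = None,
) -> np.ndarray:
    """Event times (ms) of one sweep: dead-time-corrected Poisson thinning.

    The stated rates are targets for the *observed* rate; because an
    absolute refractory period removes a fraction ``r * dead`` of
    opportunities, the underlying hazard is compensated as
    ``h = r / (1 - r * dead)``.  Pass ``protocol=None`` (with ``duration``)
    for a purely spontaneous train.
    """
    rng = np.random.default_rng(seed)
    if duration is None:
        if protocol is None:
            raise ValueError("need a protocol or an explicit duration")
        duration = protocol.sweep_duration
    dead_s = truth.refractory / 1000.0

    def hazard(t: np.ndarray) -> np.ndarray:
        r = _rate_profile(t, protocol, interval, truth)
        denom = 1.0 - r * dead_s
        if np.any(denom <= 0.05):
            raise ValueError("target rate too close to the refractory limit")
        return r / denom

    grid = np.arange(0.0, duration, 1.0)
    h_max = float(hazard(grid).max()) if grid.size else 0.0
    if h_max <= 0:
        return np.empty(0)
    # homogeneous candidates at h_max, thinned to the hazard, then dead time
    n_cand = rng.poisson(h_max * duration / 1000.0)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    keep = rng.uniform(0.0, 1.0, n_cand) * h_max < hazard(cand)
    cand = cand[keep]
    out: list[float] = []
    last = -np.inf
    for t in cand:
        if t - last >= truth.refractory:
            out.append(t)
            last = t
    return np.asarray(out)


# ---------------------------------------------------------------------------
# per-event amplitudes


def simulate_event_series(
    event_times: np.ndarray,
    truth: CellGroundTruth,
    seed: int,
    noise_cv: float = 0.0,
) -> EventGroundTruth:
    """Per-event feature amplitudes from the depletion models plus failures.

    ``noise_cv`` adds multiplicative Gaussian scatter (coefficient of
    variation) independently per feature and event.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(event_times, dtype=float)
    n = times.size
    slopes = predict_depletion(times, truth.depletion_params_eepsp)
    dvdts = predict_depletion(times, truth.depletion_params_eap)
    pres = predict_depletion(times, truth.depletion_params_prespike)
    if noise_cv > 0 and n:
        for arr in (slopes, dvdts, pres):
            arr *= np.clip(1.0 + noise_cv * rng.standard_normal(n), 0.05, None)
    if truth.failure_model == "interval":
        prev = np.diff(times, prepend=np.inf)
        p = np.clip(
            truth.failure_prob + (1.0 - truth.failure_prob)
            * np.exp(-prev / truth.failure_interval_tau),
            0.0, 1.0,
        )
    else:
        p = np.full(n, truth.failure_prob)
    fails = rng.uniform(0.0, 1.0, n) < p
    return EventGroundTruth(times, slopes, dvdts, pres, fails)


# ---------------------------------------------------------------------------
# trace synthesis


def synthesize_juxtacellular_trace(
    ground_truth: EventGroundTruth,
    kernel: WaveformKernel,
    noise_sd: float,
    sample_rate: float,
    seed: int,
    duration: float | None = None,
    protocol: StimulusProtocol | None = None,
) -> SweepRecording:
    """Render a juxtacellular sweep: summed event kernels + white noise."""
    gt = ground_truth
    pre, post = event_window(kernel)
    if duration is None:
        duration = (gt.event_times[-1] + post + 5.0) if len(gt) else 100.0
    dt = 1000.0 / sample_rate
    n_samp = int(round(duration / dt))
    samples = np.zeros(n_samp)
    for i in range(len(gt)):
        t0 = gt.event_times[i]
        i_lo = max(int(np.floor((t0 - pre) / dt)), 0)
        i_hi = min(int(np.ceil((t0 + post) / dt)) + 1, n_samp)
        if i_hi <= i_lo:
            continue
        t_rel = np.arange(i_lo, i_hi) * dt - t0
        samples[i_lo:i_hi] += render_event(
            t_rel, kernel,
            gt.true_prespike_amp[i], gt.true_eepsp_slope[i],
            gt.true_eap_dvdt[i], bool(gt.is_failure[i]),
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples += noise_sd * rng.standard_normal(n_samp)
    return SweepRecording(samples, sample_rate, "juxtacellular",
                          protocol=protocol, ground_truth=gt)


def _epsc_shape(t: np.ndarray, tau_r: float = 0.2, tau_d: float = 1.0) -> np.ndarray:
    y = np.where(t > 0, np.exp(-np.maximum(t, 0) / tau_d) - np.exp(-np.maximum(t, 0) / tau_r), 0.0)
    return y / y.max() if y.max() > 0 else y


def synthesize_wholecell_step(
    Rs: float,
    Rm: float,
    Cm: float,
    step: float,
    spont_events: EventGroundTruth | None = None,
    seed: int = 0,
    *,
    step_onset: float = 20.0,
    step_duration: float = 200.0,
    duration: float = 260.0,
    epsc_amp: float = -0.3,
    noise_sd: float = 0.005,
    sample_rate: float = 50_000.0,
) -> SweepRecording:
    """Ideal single-compartment voltage-clamp step response.

    ``Rs``/``Rm`` in MΩ, ``Cm`` in pF, ``step`` in mV; current in nA.
    Instantaneous peak ``step/Rs`` relaxing with
    ``tau = Cm * Rs*Rm/(Rs+Rm)`` to the steady state ``step/(Rs+Rm)``.
    Spontaneous synaptic events are superposed as EPSC-like transients.
    """
    if Rs <= 0 or Rm <= 0 or Cm <= 0:
        raise ValueError("Rs, Rm and Cm must be > 0")
    if step == 0:
        raise ValueError("step must be non-zero")
    dt = 1000.0 / sample_rate
    t = np.arange(int(round(duration / dt))) * dt
    tau_ms = Cm * (Rs * Rm / (Rs + Rm)) * 1e-3  # pF * MΩ = μs
    i_ss = step / (Rs + Rm)
    i_peak = step / Rs
    inside = (t >= step_onset) & (t < step_onset + step_duration)
    current = np.zeros_like(t)
    current[inside] = i_ss + (i_peak - i_ss) * np.exp(-(t[inside] - step_onset) / tau_ms)
    after = t >= step_onset + step_duration
    t_off = step_onset + step_duration
    i_off = i_ss + (i_peak - i_ss) * np.exp(-step_duration / tau_ms)
    current[after] = (i_off - 0.0 - (i_peak - i_ss)) * np.exp(-(t[after] - t_off) / tau_ms)
    if spont_events is not None:
        for te, sl in zip(spont_events.event_times, spont_events.true_eepsp_slope):
            lo = max(int(te / dt) - 10, 0)
            hi = min(lo + int(8.0 / dt), t.size)
            current[lo:hi] += epsc_amp * _epsc_shape(t[lo:hi] - te)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current += noise_sd * rng.standard_normal(t.size)
    return SweepRecording(
        current, sample_rate, "wholecell_vc",
        protocol={"kind": "step", "step_mV": step, "onset_ms": step_onset,
                  "duration_ms": step_duration},
        ground_truth=spont_events,
        meta={"Rs": Rs, "Rm": Rm, "Cm": Cm},
    )


def _logistic_epsp(t: np.ndarray, dv: float, width: float,
                   decay_onset: float, decay_tau: float) -> np.ndarray:
    y = dv / (1.0 + np.exp(-t / width))
    return y * np.where(t > decay_onset, np.exp(-(t - decay_onset) / decay_tau), 1.0)


def synthesize_wholecell_cc(
    event_times: np.ndarray,
    is_failure: np.ndarray,
    seed: int,
    *,
    v_rest: float = -65.0,
    v_thresh: float = -58.0,
    ap_amplitude: float = 55.0,
    ap_halfwidth: float = 0.44,
    sub_peak_dv: np.ndarray | None = None,
    epsp_width: float = 0.06,
    epsp_decay_tau: float = 3.0,
    noise_sd: float = 0.1,
    duration: float | None = None,
    sample_rate: float = 50_000.0,
) -> SweepRecording:
    """Whole-cell current-clamp sweep with EPSPs and APs.

    Suprathreshold events are fast logistic EPSP rises whose midpoint
    (the maximum of the EPSP first derivative) sits exactly at
    ``v_thresh``, followed by a sharp-onset spike (4th-order
    super-Gaussian) whose width is calibrated so the rendered width at
    half of (peak - rest) equals ``ap_halfwidth`` and whose absolute
    peak is ``v_rest + ap_amplitude``.  Subthreshold events are
    alpha-shaped EPSPs whose peak depolarization is given per event by
    ``sub_peak_dv``.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(event_times, dtype=float)
    fails = np.asarray(is_failure, dtype=bool)
    dt = 1000.0 / sample_rate
    if duration is None:
        duration = (times[-1] + 20.0) if times.size else 100.0
    n = int(round(duration / dt))
    v = np.full(n, float(v_rest))
    if sub_peak_dv is None:
        sub_peak_dv = np.full(times.size, 0.7 * (v_thresh - v_rest))
    sub_peak_dv = np.asarray(sub_peak_dv, dtype=float)

    t_ap = 1.0  # EPSP midpoint -> AP peak, ms
    dv_thr = 2.0 * (v_thresh - v_rest)  # logistic plateau: midpoint = threshold

    def supra_shape(tr: np.ndarray, s: float) -> np.ndarray:
        epsp = _logistic_epsp(tr, dv_thr, epsp_width, t_ap - 0.4, epsp_decay_tau)
        spike = np.exp(-((tr - t_ap) / s) ** 4)
        epsp_at_peak = _logistic_epsp(np.array([t_ap]), dv_thr, epsp_width,
                                      t_ap - 0.4, epsp_decay_tau)[0]
        return epsp + (ap_amplitude - epsp_at_peak) * spike

    # calibrate the spike width so the composite's width at half of
    # (peak - rest) equals the requested halfwidth
    t_fine = np.arange(-2.0, 6.0, dt / 4.0)

    def rendered_hw(s: float) -> float:
        y = supra_shape(t_fine, s)
        half = 0.5 * y.max()
        above = np.nonzero(y >= half)[0]
        return (above[-1] - above[0]) * (dt / 4.0)

    s_lo, s_hi = 0.02, 2.0
    for _ in range(50):
        s_mid = 0.5 * (s_lo + s_hi)
        if rendered_hw(s_mid) < ap_halfwidth:
            s_lo = s_mid
        else:
            s_hi = s_mid
    s_cal = 0.5 * (s_lo + s_hi)

    for i, te in enumerate(times):
        lo = max(int((te - 3.0) / dt), 0)
        hi = min(int((te + 15.0) / dt), n)
        tr = np.arange(lo, hi) * dt - te
        if fails[i]:
            u = np.maximum(tr, 0.0) / 1.0  # alpha tau 1 ms; exact peak at t=tau
            v[lo:hi] += sub_peak_dv[i] * u * np.exp(1.0 - u)
        else:
            v[lo:hi] += supra_shape(tr, s_cal)
    if noise_sd > 0:
        v += noise_sd * rng.standard_normal(n)
    gt = EventGroundTruth(times, np.zeros(times.size), np.zeros(times.size),
                          np.zeros(times.size), fails)
    return SweepRecording(
        v, sample_rate, "wholecell_cc", ground_truth=gt,
        meta={"v_rest": v_rest, "v_thresh": v_thresh,
              "ap_amplitude": ap_amplitude, "ap_halfwidth": ap_halfwidth},
    )


# ---------------------------------------------------------------------------
# sodium-current paired pulses


def _na_pulse_shape(t: np.ndarray, duration: float = 3.0,
                    act_tau: float = 0.15, inact_tau: float = 0.5,
                    deact_tau: float = 0.08) -> np.ndarray:
    tt = np.maximum(t, 0)
    y = np.where(t > 0, (1.0 - np.exp(-tt / act_tau)) * np.exp(-tt / inact_tau), 0.0)
    # the current deactivates rapidly once the voltage step ends
    y = np.where(t > duration,
                 y[np.searchsorted(t, duration) - 1] if t.size else 0.0, y)
    y = np.where(t > duration, y * np.exp(-(np.maximum(t - duration, 0)) / deact_tau), y)
    m = y.max()
    return y / m if m > 0 else y


def synthesize_na_sweeps(
    tau_rec: float,
    intervals: np.ndarray,
    peak_current: float,
    noise_sd: float,
    seed: int,
    *,
    pulse_duration: float = 3.0,
    baseline_offset: float = -0.1,
    pre_time: float = 10.0,
    sample_rate: float = 50_000.0,
) -> list[SweepRecording]:
    """Paired-pulse Na+-current sweeps for one holding potential.

    Each sweep holds two 3 ms inward-current transients; the second peak
    is ``first * (1 - exp(-dt / tau_rec))`` where ``dt`` is the recovery
    interval between the end of the first pulse and the start of the
    second.  A constant baseline offset and white noise are added.
    """
    intervals = np.asarray(intervals, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be > 0")
    rng = np.random.default_rng(seed)
    sweeps = []
    dt_samp = 1000.0 / sample_rate
    for iv in intervals:
        dur = pre_time + pulse_duration + iv + pulse_duration + 10.0
        t = np.arange(int(round(dur / dt_samp))) * dt_samp
        trace = np.full(t.size, baseline_offset)
        on1 = pre_time
        on2 = pre_time + pulse_duration + iv
        rel = 1.0 - np.exp(-iv / tau_rec)
        trace += -abs(peak_current) * _na_pulse_shape(t - on1, pulse_duration)
        trace += -abs(peak_current) * rel * _na_pulse_shape(t - on2, pulse_duration)
        if noise_sd > 0:
            trace += noise_sd * rng.standard_normal(t.size)
        sweeps.append(SweepRecording(
            trace, sample_rate, "wholecell_vc",
            protocol={"kind": "paired_pulse", "interval_ms": float(iv),
                      "pulse_onsets_ms": [on1, on2],
                      "pulse_duration_ms": pulse_duration},
            meta={"tau_rec": tau_rec, "true_ratio": float(rel)},
        ))
    return sweeps


# ---------------------------------------------------------------------------
# AIS stacks


def synthesize_ais_stack(
    skeletal_length: float,
    radius: float,
    orientation: tuple[float, float, float],
    voxel_spacing: tuple[float, float, float] = (0.5, 0.1, 0.1),
    psf_sigma: tuple[float, float, float] = (0.3, 0.15, 0.15),
    peak_intensity: float = 400.0,
    background: float = 20.0,
    seed: int = 0,
    shape: tuple[int, int, int] | None = None,
    blur: bool = True,
    noise: bool = True,
    intensity_cv: float = 0.2,
) -> ImageStack:
    """Confocal-like image of a straight fluorescent rod.

    The rod's centerline (length ``skeletal_length`` μm, the stored
    ground truth) runs through the stack center along ``orientation``
    (a vector in physical z, y, x μm coordinates).  The rod of the given
    radius carries a smooth intensity variation along its axis
    (``intensity_cv``, emulating heterogeneous labeling density), is
    blurred with an anisotropic Gaussian PSF and corrupted with Poisson
    shot noise on top of a uniform background.
    """
    spacing = np.asarray(voxel_spacing, dtype=float)
    if skeletal_length <= 2.0 * spacing.max():
        raise ValueError("skeletal_length must exceed twice the largest voxel spacing")
    direction = np.asarray(orientation, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise ValueError("orientation must be a non-zero vector")
    direction = direction / nrm

    if shape is None:
        extent = np.abs(direction) * skeletal_length + 2.0 * radius + 6.0 * spacing
        shape = tuple(max(int(np.ceil(e / s)) | 1, 5) for e, s in zip(extent, spacing))
    shape = tuple(int(s) for s in shape)

    center = (np.asarray(shape) - 1) / 2.0 * spacing
    half = skeletal_length / 2.0
    ends = np.stack([center - half * direction, center + half * direction])
    if np.any(ends < -1e-9) or np.any(ends > (np.asarray(shape) - 1) * spacing + 1e-9):
        raise ValueError("rod exceeds stack bounds; pass a larger shape")

    zz, yy, xx = np.meshgrid(*(np.arange(s) * sp for s, sp in zip(shape, spacing)),
                             indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1) - center
    # distance from each voxel to the centerline segment
    # flat-capped cylinder: the structure's axial extent equals the
    # ground-truth skeletal length
    proj = pts @ direction
    rad2 = np.sum((pts - proj[..., None] * direction) ** 2, axis=-1)
    inside = (np.abs(proj) <= half) & (rad2 <= radius * radius)
    proj = np.clip(proj, -half, half)
    rng = np.random.default_rng(seed)
    profile = np.ones_like(proj)
    if intensity_cv > 0 and peak_intensity > 0:
        # smooth labeling-density variation: few low spatial harmonics
        amp = rng.standard_normal(3)
        phase = rng.uniform(0, 2 * np.pi, 3)
        mod = np.zeros_like(proj)
        for h in range(3):
            mod += amp[h] * np.sin((h + 1) * np.pi * proj / half + phase[h])
        mod *= intensity_cv / max(np.sqrt(np.sum(amp**2) / 2.0), 1e-9)
        profile = np.clip(1.0 + mod, 0.3, None)
    img = np.where(inside, float(peak_intensity) * profile, 0.0)
    if blur and peak_intensity > 0:
        img = ndimage.gaussian_filter(img, sigma=np.asarray(psf_sigma) / spacing)
    img = img + background
    if noise:
        img = rng.poisson(img).astype(float)
    return ImageStack(
        img, tuple(spacing),
        meta={"true_length_um": float(skeletal_length), "radius_um": float(radius),
              "orientation": tuple(float(v) for v in direction), "seed": int(seed)},
    )
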