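"""Parametric waveform kernels for the juxtacellular complex event.

A complex event is rendered as the sum of three components, all defined in
continuous time relative to the event time (the onset of the EPSP rise,
where the EPSP's first derivative is maximal):

* prespike — asymmetric biphasic lobe pair, positive peak
  ``delay_pre_epsp`` ms before the event time, scaled to the per-event
  prespike amplitude;
* eEPSP — saturating exponential rise whose initial slope equals the
  per-event maximum rate of rise, truncated into a decay once the spike
  takes over (or at the same point, for subthreshold events);
* eAP — a sharp-onset spike (exponential upstroke into a cusp peak
  ``delay_epsp_ap`` ms after the event time, exponential decay sized so
  the full width at half maximum equals ``eap_halfwidth``), whose
  maximum first derivative equals the per-event eAP' value, followed by
  a slower downward after-wave.  The sharp onset keeps the EPSP's
  derivative maximum separable from the spike upstroke, as it is in real
  recordings; the after-wave is what makes events overlap at short
  intervals and is the reason template subtraction exists.

These shapes are parametric conventions chosen for controllability; they
are not claimed to be biophysical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WaveformKernel", "render_event", "event_window"]

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class WaveformKernel:
    """Shape parameters of one cell's complex waveform (ms / mV)."""

    prespike_amp: float = 0.5  # nominal prespike amplitude, mV
    prespike_width: float = 0.06  # positive-lobe sigma, ms
    eepsp_rise_tau: float = 0.12  # EPSP rise time constant, ms
    eap_amp: float = 6.0  # nominal eAP amplitude, mV (metadata / failure scale)
    eap_halfwidth: float = 0.24  # eAP full width at half maximum, ms
    delay_pre_epsp: float = 0.33  # prespike peak -> EPSP max slope, ms
    delay_epsp_ap: float = 0.28  # EPSP max slope -> eAP peak, ms
    epsp_decay_tau: float = 0.6  # EPSP decay after truncation, ms
    eap_rise_tau: float = 0.04  # spike upstroke time constant, ms
    aw_delay: float = 0.25  # eAP peak -> after-wave onset, ms
    aw_tau: float = 0.8  # after-wave alpha time constant, ms
    aw_frac: float = 0.35  # after-wave amplitude as a fraction of eAP peak

    def __post_init__(self) -> None:
        for name in (
            "prespike_amp", "prespike_width", "eepsp_rise_tau", "eap_amp",
            "eap_halfwidth", "epsp_decay_tau", "eap_rise_tau", "aw_tau",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"kernel.{name} must be > 0")
        if self.delay_pre_epsp < 0 or self.delay_epsp_ap < 0 or self.aw_delay < 0:
            raise ValueError("kernel delays must be >= 0")
        if self.aw_frac < 0:
            raise ValueError("kernel.aw_frac must be >= 0")
        if self.eap_decay_tau <= 0:
            raise ValueError(
                "eap_halfwidth too small for eap_rise_tau: "
                "halfwidth/ln2 must exceed the rise tau"
            )

    @property
    def eap_decay_tau(self) -> float:
        """Downstroke time constant implied by the halfwidth (cusp peak)."""
        return self.eap_halfwidth / _LN2 - self.eap_rise_tau


def _prespike_shape(v: np.ndarray) -> np.ndarray:
    # asymmetric biphasic lobe pair in units of the positive-lobe sigma: a
    # sharp positive Gaussian followed by a shallow, slow negative lobe.
    # The slow return keeps the prespike's recovery flank out of the
    # EPSP's derivative, as in real recordings where the two separate.
    return np.exp(-0.5 * v * v) - 0.35 * np.exp(-0.5 * ((v - 3.0) / 2.5) ** 2)


_V = np.linspace(-4.0, 4.0, 8001)
_PS_VPEAK = float(_V[np.argmax(_prespike_shape(_V))])
_PS_MAX = float(_prespike_shape(np.array([_PS_VPEAK]))[0])
del _V


def _prespike(t: np.ndarray, amp: float, k: WaveformKernel) -> np.ndarray:
    # normalized so the positive peak equals amp exactly at -delay_pre_epsp
    v = (t + k.delay_pre_epsp) / k.prespike_width + _PS_VPEAK
    return (amp / _PS_MAX) * _prespike_shape(v)


def _epsp(t: np.ndarray, slope: float, k: WaveformKernel) -> np.ndarray:
    # rise with initial (maximal) derivative = slope at t = 0+,
    # decaying once the spike takes over
    t_trunc = max(k.delay_epsp_ap - 3.0 * k.eap_rise_tau, 0.05)
    y = np.where(
        t > 0.0,
        slope * k.eepsp_rise_tau * -np.expm1(-np.maximum(t, 0.0) / k.eepsp_rise_tau),
        0.0,
    )
    decay = np.where(t > t_trunc, np.exp(-(t - t_trunc) / k.epsp_decay_tau), 1.0)
    return y * decay


def _eap(t: np.ndarray, dvdt: float, k: WaveformKernel) -> np.ndarray:
    # sharp-onset spike: max first derivative = dvdt (mV/ms == V/s) at the
    # cusp; peak amplitude = dvdt * rise_tau
    amp = dvdt * k.eap_rise_tau
    t_ap = k.delay_epsp_ap
    dt = t - t_ap
    y = np.where(dt <= 0, amp * np.exp(dt / k.eap_rise_tau),
                 amp * np.exp(-dt / k.eap_decay_tau))
    # downward after-wave, delayed past the half-maximum crossing so the
    # measured halfwidth stays that of the spike itself
    u = np.maximum(dt - k.aw_delay, 0.0) / k.aw_tau
    y -= k.aw_frac * amp * u * np.exp(1.0 - u)
    return y


def event_window(k: WaveformKernel) -> tuple[float, float]:
    """(pre, post) extent in ms over which one event is rendered."""
    pre = k.delay_pre_epsp + 5.0 * k.prespike_width
    post = k.delay_epsp_ap + k.aw_delay + 12.0 * k.aw_tau
    return pre, post


def render_event(
    t: np.ndarray,
    k: WaveformKernel,
    prespike_amp: float,
    eepsp_slope: float,
    eap_dvdt: float,
    is_failure: bool,
) -> np.ndarray:
    """Evaluate one complex event at times ``t`` (ms, relative to event).

    On failures the spike and its after-wave are omitted; the prespike and
    the EPSP remain.
    """
    y = _prespike(t, prespike_amp, k) + _epsp(t, eepsp_slope, k)
    if not is_failure:
        y = y + _eap(t, eap_dvdt, k)
    return y
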