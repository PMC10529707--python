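"""Periodic chamber-volume waveforms.

The left atrium (LA) and left ventricle (LV) volumes over one heartbeat drive
everything else in the pipeline: the transmitral flow rate is the positive part
of dV_LV/dt, and the total pulmonary-vein inflow follows from mass conservation
of the LA chamber.  Waveforms are represented as a constant baseline plus a sum
of raised-cosine *rate lobes* (compactly supported bumps of dV/dt), which keeps
V(t), dV/dt and the phase markers (V_min, V_max, V_preA, phase windows) exact
and analytic.  A periodic-spline form is provided for externally sampled
waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "RateLobe",
    "VolumeWaveform",
    "LobeWaveform",
    "SplineWaveform",
    "FourierWaveform",
    "band_limited",
    "la_volume_waveform",
    "lv_volume_waveform",
    "laa_volume_waveform",
]


@dataclass(frozen=True)
class RateLobe:
    """Raised-cosine bump of dV/dt.

    ``rate(t) = a * 0.5 * (1 + cos(2*pi*(t - center)/width))`` on
    ``|t - center| < width/2`` and zero outside; its integral over the lobe is
    ``a * width / 2 = volume``.
    """

    center: float  # s, lobe midpoint within [0, T)
    width: float   # s, full support width
    volume: float  # ml, signed volume carried by the lobe

    @property
    def amplitude(self) -> float:
        return 2.0 * self.volume / self.width

    def rate(self, tau: np.ndarray) -> np.ndarray:
        """dV/dt contribution at phase times ``tau`` (already folded to [0,T))."""
        s = tau - self.center
        inside = np.abs(s) < 0.5 * self.width
        out = np.zeros_like(s, dtype=float)
        out[inside] = self.amplitude * 0.5 * (1.0 + np.cos(2.0 * np.pi * s[inside] / self.width))
        return out

    def integral(self, tau: np.ndarray) -> np.ndarray:
        """Cumulative volume contributed by the lobe on [0, tau]."""
        t0 = self.center - 0.5 * self.width
        s = np.clip(tau - t0, 0.0, self.width)
        # antiderivative of a*(1 + cos(2 pi (t-c)/w))/2 with s measured from
        # the lobe onset (phase-shifted by half a width)
        return self.amplitude * 0.5 * (s - self.width / (2.0 * np.pi) * np.sin(2.0 * np.pi * s / self.width))


class VolumeWaveform:
    """Base class: periodic V(t) [ml] with period T [s] and phase markers."""

    period: float
    markers: dict

    def volume(self, t):  # pragma: no cover - interface
        raise NotImplementedError

    def rate(self, t):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, t):
        return self.volume(t)

    def sample(self, n: int):
        """n regular samples of (t, V) over one period (endpoint excluded)."""
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return t, self.volume(t)


class LobeWaveform(VolumeWaveform):
    """Baseline volume plus raised-cosine rate lobes; exactly periodic iff the
    signed lobe volumes sum to zero."""

    def __init__(self, baseline: float, lobes: list[RateLobe], period: float, markers: dict | None = None):
        net = sum(l.volume for l in lobes)
        if abs(net) > 1e-9 * max(1.0, abs(baseline)):
            raise ValueError(f"lobe volumes must sum to zero for periodicity (got {net:g} ml)")
        for l in lobes:
            if not (0.0 <= l.center - 0.5 * l.width and l.center + 0.5 * l.width <= period):
                raise ValueError("rate lobes must lie fully inside one period")
        self.baseline = float(baseline)
        self.lobes = list(lobes)
        self.period = float(period)
        self.markers = dict(markers or {})

    def _fold(self, t):
        return np.mod(np.asarray(t, dtype=float), self.period)

    def volume(self, t):
        tau = self._fold(t)
        v = np.full_like(tau, self.baseline, dtype=float)
        for l in self.lobes:
            v += l.integral(tau)
        return v if v.shape else float(v)

    def rate(self, t):
        tau = self._fold(t)
        q = np.zeros_like(tau, dtype=float)
        for l in self.lobes:
            q += l.rate(tau)
        return q if q.shape else float(q)


class SplineWaveform(VolumeWaveform):
    """Periodic cubic spline through sampled (t, V) anchor points."""

    def __init__(self, t: np.ndarray, v: np.ndarray, period: float, markers: dict | None = None):
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if t[0] != 0.0:
            raise ValueError("sample times must start at 0")
        tt = np.append(t, period)
        vv = np.append(v, v[0])
        self._spline = CubicSpline(tt, vv, bc_type="periodic")
        self.period = float(period)
        if markers is None:
            tau = np.linspace(0.0, period, 2048, endpoint=False)
            vals = self._spline(tau)
            markers = {"t_min": float(tau[np.argmin(vals)]), "t_max": float(tau[np.argmax(vals)])}
        self.markers = dict(markers)

    def volume(self, t):
        out = self._spline(np.mod(t, self.period))
        return out if np.ndim(t) else float(out)

    def rate(self, t):
        out = self._spline(np.mod(t, self.period), 1)
        return out if np.ndim(t) else float(out)


class FourierWaveform(VolumeWaveform):
    """Truncated Fourier series V(t) = a0 + sum_k ak cos + bk sin."""

    def __init__(self, a0: float, ak: np.ndarray, bk: np.ndarray, period: float,
                 markers: dict | None = None):
        self.a0 = float(a0)
        self.ak = np.asarray(ak, dtype=float)
        self.bk = np.asarray(bk, dtype=float)
        self.period = float(period)
        self.markers = dict(markers or {})

    def _angles(self, t):
        k = np.arange(1, len(self.ak) + 1)
        return 2.0 * np.pi / self.period * np.multiply.outer(np.asarray(t, dtype=float), k)

    def volume(self, t):
        th = self._angles(t)
        out = self.a0 + np.cos(th) @ self.ak + np.sin(th) @ self.bk
        return out if np.ndim(t) else float(out)

    def rate(self, t):
        th = self._angles(t)
        w = 2.0 * np.pi / self.period * np.arange(1, len(self.ak) + 1)
        out = -np.sin(th) @ (w * self.ak) + np.cos(th) @ (w * self.bk)
        return out if np.ndim(t) else float(out)


def band_limited(wf: VolumeWaveform, harmonics: int, n_samples: int = 512) -> FourierWaveform:
    """Project a waveform onto its first K temporal harmonics.

    Used to make the volume target exactly representable by a K-harmonic
    surface-motion series: driving the wall toward an unrepresentable target
    would leave ringing in dV/dt and hence in the mass-conservation inflow.
    """
    t = np.linspace(0.0, wf.period, n_samples, endpoint=False)
    c = np.fft.rfft(wf.volume(t)) / n_samples
    a0 = c[0].real
    ak = 2.0 * c[1:harmonics + 1].real
    bk = -2.0 * c[1:harmonics + 1].imag
    return FourierWaveform(a0, ak, bk, wf.period, wf.markers)


# ---------------------------------------------------------------------------
# Physiological constructors
#
# Phase layout (fractions of the cycle, t = 0 at mitral valve closure / LA
# volume minimum): LV ejection & LA reservoir filling on (0.02, 0.38);
# early LV filling (E wave, LA conduit emptying) on (0.40, 0.60); diastasis
# (0.60, 0.78); atrial contraction (A wave, LA booster emptying) on
# (0.78, 0.97).
# ---------------------------------------------------------------------------

_RESERVOIR = (0.20, 0.36)  # (center, width) as cycle fractions
_E_WAVE = (0.52, 0.24)
_A_WAVE = (0.875, 0.19)


def la_volume_waveform(v_min: float, v_max: float, v_pre_a: float, period: float = 1.0) -> LobeWaveform:
    """LA volume waveform hitting V_min (t=0), V_max (end reservoir) and
    V_preA (onset of atrial contraction) exactly."""
    if not (0.0 < v_min < v_pre_a < v_max):
        raise ValueError(f"need 0 < V_min < V_preA < V_max, got {v_min}, {v_pre_a}, {v_max}")
    T = period
    lobes = [
        RateLobe(_RESERVOIR[0] * T, _RESERVOIR[1] * T, v_max - v_min),
        RateLobe(_E_WAVE[0] * T, _E_WAVE[1] * T, -(v_max - v_pre_a)),
        RateLobe(_A_WAVE[0] * T, _A_WAVE[1] * T, -(v_pre_a - v_min)),
    ]
    markers = {
        "t_min": 0.0,
        "t_max": (_RESERVOIR[0] + _RESERVOIR[1] / 2) * T,
        "t_pre_a": (_A_WAVE[0] - _A_WAVE[1] / 2) * T,
        "v_min": v_min,
        "v_max": v_max,
        "v_pre_a": v_pre_a,
    }
    return LobeWaveform(v_min, lobes, T, markers)


def lv_volume_waveform(edv: float, stroke_volume: float, e_fraction: float = 0.65,
                       period: float = 1.0) -> LobeWaveform:
    """LV volume waveform: ejection during systole, E-wave and A-wave filling.

    ``e_fraction`` is the share of the stroke volume entering during early
    filling; ``e_fraction = 1`` gives monophasic (A-wave-free, AF-like) filling.
    """
    if stroke_volume <= 0 or edv <= stroke_volume:
        raise ValueError("need EDV > LVSV > 0")
    if not (0.0 < e_fraction <= 1.0):
        raise ValueError("e_fraction must lie in (0, 1]")
    T = period
    lobes = [RateLobe(_RESERVOIR[0] * T, _RESERVOIR[1] * T, -stroke_volume),
             RateLobe(_E_WAVE[0] * T, _E_WAVE[1] * T, e_fraction * stroke_volume)]
    if e_fraction < 1.0:
        lobes.append(RateLobe(_A_WAVE[0] * T, _A_WAVE[1] * T, (1.0 - e_fraction) * stroke_volume))
    markers = {
        "t_max": 0.0,  # end-diastolic volume at mitral closure
        "t_min": (_RESERVOIR[0] + _RESERVOIR[1] / 2) * T,
        "t_e": _E_WAVE[0] * T,
        "t_a": _A_WAVE[0] * T if e_fraction < 1.0 else None,
        "v_max": edv,
        "v_min": edv - stroke_volume,
        "stroke_volume": stroke_volume,
    }
    return LobeWaveform(edv, lobes, T, markers)


def laa_volume_waveform(v_min: float, v_max: float, period: float = 1.0) -> LobeWaveform:
    """LAA volume waveform: fills with the reservoir, empties mostly with the
    atrial kick (the appendage has no conduit function)."""
    if not (0.0 < v_min < v_max):
        raise ValueError("need 0 < V_min < V_max")
    T = period
    dv = v_max - v_min
    lobes = [
        RateLobe(_RESERVOIR[0] * T, _RESERVOIR[1] * T, dv),
        RateLobe(_E_WAVE[0] * T, _E_WAVE[1] * T, -0.35 * dv),
        RateLobe(_A_WAVE[0] * T, _A_WAVE[1] * T, -0.65 * dv),
    ]
    markers = {"t_min": 0.0, "t_max": (_RESERVOIR[0] + _RESERVOIR[1] / 2) * T,
               "v_min": v_min, "v_max": v_max}
    return LobeWaveform(v_min, lobes, T, markers)
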