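"""TFS1 stimulus synthesis.

Harmonic (H) and inharmonic (I) complex tones for the TFS1 discrimination
paradigm: components at k*f0 (H) or k*f0 + delta_f (I), band-pass filtered
with a Butterworth filter whose -3 dB points are separated by 7*f0, optionally
embedded in a calibrated pink-noise masker that masks cochlear distortion
products.

Calibration convention: a digital RMS of 1.0 corresponds to 94 dB SPL (1 Pa).
All levels in this package are dB SPL under that convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "StimulusCondition",
    "MaskerSpec",
    "StimulusWaveform",
    "BandpassFilter",
    "shift_ladder",
    "design_bandpass",
    "synthesize_complex",
    "make_pink_masker",
    "overall_level_db_spl",
    "envelope_periodicity_hz",
    "db_to_amplitude",
    "SPL_REFERENCE_DB",
]

#: digital full-scale calibration: RMS 1.0 == 94 dB SPL (1 Pa RMS)
SPL_REFERENCE_DB = 94.0

#: sentinel returned for an all-zero signal
SILENT = float("-inf")


def db_to_amplitude(level_db_spl: float) -> float:
    """Peak amplitude of a sinusoid at the given dB SPL level."""
    rms = 10.0 ** ((level_db_spl - SPL_REFERENCE_DB) / 20.0)
    return float(np.sqrt(2.0) * rms)


@dataclass(frozen=True)
class StimulusCondition:
    """Full parametric description of one TFS1 stimulus.

    Parameters
    ----------
    f0 : float
        Fundamental frequency in Hz (200 or 400 in the standard conditions).
    fc : float
        Band-pass center frequency in Hz (1600 or 3200); must be an integer
        multiple of ``f0`` so the harmonic rank N = fc/f0 is well defined.
    delta_f_pct : float
        Upward shift of every component, as a percentage of ``f0``.
        0 gives the harmonic (H) complex.
    filter_order : int
        Butterworth band-pass order (3 for the neural rig, 5 behavioral).
    component_level_db_spl : float
        Per-component level before filtering, dB SPL.
    max_component_freq : float
        Highest unshifted harmonic generated, Hz.
    duration_s : float
        Total stimulus duration, seconds.
    ramp_ms : float
        Hann (raised-cosine) on/off ramp duration in ms; 0 disables ramping.
    sample_rate_hz : float
        Synthesis sample rate (48000 behavioral rig; 48828 neural rig).
    phases_rad : tuple of float, optional
        Per-harmonic starting phases.  If absent they are drawn uniformly on
        [0, 2pi) from ``seed``; H and I members of a trial pair must share
        the same phase vector.
    seed : int
        RNG seed for the phase draw when ``phases_rad`` is not given.
    """

    f0: float = 200.0
    fc: float = 1600.0
    delta_f_pct: float = 0.0
    filter_order: int = 5
    component_level_db_spl: float = 60.0
    max_component_freq: float = 9000.0
    duration_s: float = 0.4
    ramp_ms: float = 0.0
    sample_rate_hz: float = 48000.0
    phases_rad: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self):
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        rank = self.fc / self.f0
        if abs(rank - round(rank)) > 1e-9:
            raise ValueError(
                f"fc={self.fc} is not an integer multiple of f0={self.f0}"
            )
        if not (0.0 <= self.delta_f_pct <= 100.0):
            raise ValueError("delta_f_pct must lie in [0, 100]")
        if self.duration_s - 2.0 * self.ramp_ms / 1000.0 <= 0:
            raise ValueError("ramps longer than the stimulus")
        if self.sample_rate_hz < 2.0 * (self.max_component_freq + self.f0):
            raise ValueError("sample rate too low for the requested components")

    @property
    def harmonic_rank(self) -> int:
        """N = fc / f0."""
        return int(round(self.fc / self.f0))

    @property
    def delta_f_hz(self) -> float:
        """Common upward component shift in Hz."""
        return self.delta_f_pct / 100.0 * self.f0

    @property
    def n_components(self) -> int:
        return int(np.floor(self.max_component_freq / self.f0))

    def component_freqs_hz(self) -> np.ndarray:
        """Frequencies of the generated components (k*f0 + delta_f)."""
        k = np.arange(1, self.n_components + 1)
        return k * self.f0 + self.delta_f_hz

    def phases(self) -> np.ndarray:
        if self.phases_rad is not None:
            p = np.asarray(self.phases_rad, dtype=float)
            if p.size != self.n_components:
                raise ValueError(
                    f"expected {self.n_components} phases, got {p.size}"
                )
            return p
        rng = np.random.default_rng(self.seed)
        return rng.uniform(0.0, 2.0 * np.pi, self.n_components)

    def pair(self, delta_f_pct: float) -> "StimulusCondition":
        """The condition for the other member of an H/I trial pair.

        Shares the frozen phase vector so envelopes match.
        """
        return StimulusCondition(
            **{
                **asdict(self),
                "delta_f_pct": delta_f_pct,
                "phases_rad": tuple(self.phases()),
            }
        )

    def to_json(self) -> str:
        d = asdict(self)
        if d["phases_rad"] is not None:
            d["phases_rad"] = list(d["phases_rad"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusCondition":
        d = json.loads(text)
        if d.get("phases_rad") is not None:
            d["phases_rad"] = tuple(d["phases_rad"])
        return cls(**d)


@dataclass(frozen=True)
class MaskerSpec:
    """Band-limited pink-noise masker specification.

    The power spectral density falls as 1/f between the band edges and is
    anchored at ``psd_anchor_db_spl_per_hz`` dB SPL per Hz at exactly 1 kHz.
    """

    low_freq_hz: float = 100.0
    high_freq_hz: float = 11050.0
    psd_anchor_db_spl_per_hz: float = 13.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.low_freq_hz < self.high_freq_hz):
            raise ValueError("band edges must satisfy 0 < low < high")

    def psd_db_per_hz(self, f: np.ndarray) -> np.ndarray:
        """Nominal one-sided PSD (dB SPL/Hz); -inf outside the band."""
        f = np.asarray(f, dtype=float)
        out = np.full(f.shape, -np.inf)
        inside = (f >= self.low_freq_hz) & (f <= self.high_freq_hz)
        out[inside] = self.psd_anchor_db_spl_per_hz + 10.0 * np.log10(
            1000.0 / f[inside]
        )
        return out


@dataclass
class StimulusWaveform:
    """A calibrated pressure waveform plus its provenance."""

    samples: np.ndarray
    sample_rate_hz: float
    condition: Optional[StimulusCondition] = None
    masker: Optional[MaskerSpec] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz

    def write_wav(self, path, sidecar: bool = True) -> None:
        """float32 WAV plus a JSON sidecar with the full condition."""
        from scipy.io import wavfile

        path = Path(path)
        wavfile.write(path, int(self.sample_rate_hz),
                      self.samples.astype(np.float32))
        if sidecar and self.condition is not None:
            meta = json.loads(self.condition.to_json())
            if self.masker is not None:
                meta["masker"] = asdict(self.masker)
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


class BandpassFilter:
    """Butterworth band-pass with -3 dB points at fc +/- 3.5*f0.

    Evaluated in second-order sections for numerical robustness at high
    order / narrow relative bandwidth.
    """

    def __init__(self, f0: float, fc: float, order: int,
                 sample_rate_hz: float):
        low = fc - 3.5 * f0
        high = fc + 3.5 * f0
        if low <= 0:
            raise ValueError("fc - 3.5*f0 must be positive")
        if high >= sample_rate_hz / 2:
            raise ValueError("upper band edge exceeds Nyquist")
        self.f0, self.fc, self.order = f0, fc, order
        self.sample_rate_hz = sample_rate_hz
        self.low_3db_hz, self.high_3db_hz = low, high
        self.sos = signal.butter(order, [low, high], btype="bandpass",
                                 fs=sample_rate_hz, output="sos")
        if not np.all(np.isfinite(self.sos)):
            raise ValueError(
                "unstable band-pass design; raise the sample rate or reduce "
                "the order"
            )

    def response_db(self, freqs_hz) -> np.ndarray:
        """Magnitude response in dB at arbitrary frequencies."""
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        _, h = signal.sosfreqz(self.sos, worN=freqs_hz,
                               fs=self.sample_rate_hz)
        with np.errstate(divide="ignore"):
            return 20.0 * np.log10(np.abs(h))

    @property
    def asymptotic_skirt_slope_db_per_octave(self) -> float:
        """Asymptotic skirt slope of the design: 20*order*log10(2) dB/oct.

        A Butterworth band-pass of order N rolls off at 6.02*N dB per octave
        far from the passband (18 dB/oct at third order, ~30 at fifth).  The
        digital filter's low skirt follows this; the high skirt is steeper
        near Nyquist because of bilinear frequency warping.
        """
        return 20.0 * self.order * np.log10(2.0)

    def skirt_slope_db_per_octave(self, side: str = "low",
                                  octaves: float = 1.0,
                                  start_octaves: float = 2.0) -> float:
        """Attenuation slope measured on one skirt of the realized filter.

        Measured between ``start_octaves`` and ``start_octaves + octaves``
        beyond the corresponding -3 dB point (below it for ``side='low'``).
        """
        if side == "high":
            f1 = self.high_3db_hz * 2.0 ** start_octaves
            f2 = f1 * 2.0 ** octaves
        else:
            f1 = self.low_3db_hz / 2.0 ** start_octaves
            f2 = f1 / 2.0 ** octaves
        l1, l2 = self.response_db([f1, f2])
        return float((l1 - l2) / octaves)

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Forward (causal) filtering, matching a real-time playback chain."""
        return signal.sosfilt(self.sos, np.asarray(x, dtype=float))


def design_bandpass(f0: float, fc: float, order: int,
                    sample_rate_hz: float) -> BandpassFilter:
    """Design the stimulus band-pass (3-dB points separated by 7*f0)."""
    return BandpassFilter(f0, fc, order, sample_rate_hz)


def shift_ladder(max_pct: float, n_halvings: int,
                 extras: Sequence[float] = ()) -> list:
    """Descending ladder of component shifts: max_pct / 2**k, k = 0..n.

    ``extras`` (e.g. the 31.87% and 15.94% values added for old animals) are
    merged into sorted position; duplicates are removed.
    """
    if max_pct <= 0:
        raise ValueError("max_pct must be positive")
    if n_halvings < 0:
        raise ValueError("n_halvings must be non-negative")
    if any(e <= 0 for e in extras):
        raise ValueError("extras must be positive")
    vals = {max_pct / 2.0 ** k for k in range(n_halvings + 1)}
    vals.update(float(e) for e in extras)
    return sorted(vals, reverse=True)


def synthesize_complex(cond: StimulusCondition,
                       filtered: bool = True) -> StimulusWaveform:
    """Synthesize one H or I complex tone.

    Components at k*f0 + delta_f (k*f0 <= max_component_freq), each at
    ``component_level_db_spl`` before filtering, with the condition's frozen
    phases; band-pass filtered causally; Hann-ramped if ``ramp_ms`` > 0.
    """
    n = int(round(cond.duration_s * cond.sample_rate_hz))
    t = np.arange(n) / cond.sample_rate_hz
    amp = db_to_amplitude(cond.component_level_db_spl)
    freqs = cond.component_freqs_hz()
    phases = cond.phases()
    x = np.zeros(n)
    for f, ph in zip(freqs, phases):
        x += amp * np.cos(2.0 * np.pi * f * t + ph)
    if filtered:
        bp = design_bandpass(cond.f0, cond.fc, cond.filter_order,
                             cond.sample_rate_hz)
        x = bp.apply(x)
    if cond.ramp_ms > 0:
        x = _apply_hann_ramp(x, cond.ramp_ms, cond.sample_rate_hz)
    return StimulusWaveform(x, cond.sample_rate_hz, condition=cond)


def _apply_hann_ramp(x: np.ndarray, ramp_ms: float, fs: float) -> np.ndarray:
    nr = int(round(ramp_ms / 1000.0 * fs))
    env = np.ones(len(x))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
    env[:nr] = ramp
    env[-nr:] = ramp[::-1]
    return x * env


def make_pink_masker(spec: MaskerSpec, duration_s: float,
                     sample_rate_hz: float) -> StimulusWaveform:
    """Band-limited pink noise with an exactly anchored PSD.

    Synthesized in the frequency domain: each retained rfft bin gets
    amplitude sqrt(2 * S(f) * df) with S(f) the nominal 1/f PSD, and a
    random phase, so a Welch estimate of the PSD at 1 kHz matches the
    anchor up to estimation noise.
    """
    if spec.high_freq_hz >= sample_rate_hz / 2:
        raise ValueError("band edge above Nyquist")
    n = int(round(duration_s * sample_rate_hz))
    df = sample_rate_hz / n
    if df > 50.0:
        raise ValueError(
            "duration too short to control the PSD (frequency resolution "
            f"{df:.1f} Hz); lengthen the noise"
        )
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate_hz)
    inside = (freqs >= spec.low_freq_hz) & (freqs <= spec.high_freq_hz)
    s_lin = np.zeros_like(freqs)
    anchor_lin = 10.0 ** ((spec.psd_anchor_db_spl_per_hz
                           - SPL_REFERENCE_DB) / 10.0)
    s_lin[inside] = anchor_lin * 1000.0 / freqs[inside]
    # a_k = sqrt(2 S df): sinusoid of amplitude a has power a^2/2 in one bin
    amps = np.sqrt(2.0 * s_lin * df)
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(freqs))
    spectrum = amps * np.exp(1j * phases) * (n / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n)
    return StimulusWaveform(x, sample_rate_hz, masker=spec)


def envelope_periodicity_hz(w: StimulusWaveform,
                            skip_s: float = 0.05,
                            max_period_s: float = 0.02) -> float:
    """Fundamental periodicity of the Hilbert envelope, in Hz.

    The envelope of a filtered complex tone is periodic at the component
    spacing f0 but rich in harmonics of f0, so the largest spectral
    component is not a reliable periodicity estimate.  Instead the
    envelope's autocorrelation is scanned over lags up to ``max_period_s``
    and the smallest lag reaching 95% of the autocorrelation maximum is
    taken as the fundamental period.
    """
    from scipy.signal import hilbert

    i0 = int(round(skip_s * w.sample_rate_hz))
    env = np.abs(hilbert(w.samples[i0:]))
    env = env - env.mean()
    n_lag = int(round(max_period_s * w.sample_rate_hz))
    ac = np.array([np.dot(env[:-k], env[k:]) for k in range(1, n_lag + 1)])
    # skip the zero-lag shoulder: start after the first zero crossing
    below = np.where(ac <= 0)[0]
    start = below[0] if len(below) else 0
    seg = ac[start:]
    peak = seg.max()
    k = start + int(np.argmax(seg >= 0.95 * peak)) + 1
    return w.sample_rate_hz / k


def overall_level_db_spl(w: StimulusWaveform,
                         t_window: Optional[tuple] = None) -> float:
    """Broadband RMS level in dB SPL (RMS 1.0 == 94 dB SPL).

    ``t_window`` restricts the measurement to (start_s, stop_s), e.g. the
    steady-state portion after the filter transient.
    """
    x = w.samples
    if t_window is not None:
        i0 = int(round(t_window[0] * w.sample_rate_hz))
        i1 = int(round(t_window[1] * w.sample_rate_hz))
        x = x[i0:i1]
    if len(x) == 0:
        raise ValueError("empty measurement window")
    rms = float(np.sqrt(np.mean(x ** 2)))
    if rms == 0.0:
        return SILENT
    return SPL_REFERENCE_DB + 20.0 * np.log10(rms)
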