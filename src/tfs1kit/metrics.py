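"""Single-unit phase-locking analyses.

Implements the measures applied to auditory-nerve responses to TFS1 stimuli:

* tuning metrics (best frequency, rate threshold, half-maximum bandwidth),
* peri-stimulus time histograms with f0-locked bin widths,
* driven-rate and spontaneous-rate population histograms,
* vector-strength spectra from all-order inter-spike-interval histograms,
* single-frequency vector strength and the Rayleigh statistic z = N_avg*V_avg^2,
* the TFS log-z-ratio and ENV/TFS log-z-ratio contrasts,
* the search for the component-shift position of the maximum z value.

Vector strength V(f) = |1/N sum_i exp(-i 2 pi f t_i)| is 1 for perfect
locking and ~1/sqrt(N) for a Poisson train; z = N_avg * V_avg^2 weights VS by
spike count and is approximately Exp(1)-distributed under no locking, so
log ratios of z values are approximately normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .spikes import SpikeTrainSet, LOW_SR_BOUNDARY_SP_S

__all__ = [
    "TuningResult",
    "VSSpectrum",
    "ZMetrics",
    "tuning_metrics",
    "psth",
    "rate_histograms",
    "isi_vs_spectrum",
    "vs_at",
    "f_maxpeak",
    "z_metrics",
    "zpeak_shift_search",
    "LOW_BF_BOUNDARY_HZ",
]

#: best-frequency boundary between the low- and high-BF fiber classes
LOW_BF_BOUNDARY_HZ = 1850.0

#: all-order ISI histogram parameters: 50 us bins over +/-375 ms, Gaussian
#: window SD 200 ms -> spectral resolution 1/0.75 s = 1.333 Hz
ISI_BIN_S = 50e-6
ISI_SPAN_S = 0.375
ISI_WINDOW_SD_S = 0.2


@dataclass
class TuningResult:
    bf_hz: float
    threshold_db_spl: Optional[float]
    halfmax_bandwidth_hz: Optional[float]
    sr_sp_s: float
    sr_sd_sp_s: float
    threshold_flag: Optional[str] = None
    bandwidth_flag: Optional[str] = None


@dataclass
class VSSpectrum:
    """Vector strength vs frequency from the all-order ISI histogram."""

    freqs_hz: np.ndarray
    vs: np.ndarray
    n_isi: int
    window_sd_s: float = ISI_WINDOW_SD_S

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def at(self, f_hz: float) -> float:
        """VS at the bin nearest to f_hz."""
        return float(self.vs[int(np.argmin(np.abs(self.freqs_hz - f_hz)))])


@dataclass
class ZMetrics:
    f_maxpeak_hz: float
    z0: float
    z_df: float
    tfs_log_z_ratio: Optional[float]
    env_tfs_log_z_ratio: Optional[float]
    class_sr: Optional[str] = None
    class_bf: Optional[str] = None


def tuning_metrics(rate_by_freq: Dict[float, float],
                   rate_by_level: Dict[float, float],
                   sr_trials: Sequence[float]) -> TuningResult:
    """Best frequency, rate threshold, and half-maximum bandwidth.

    BF is the frequency evoking the highest mean rate.  The threshold is the
    lowest level at which the rate exceeds both SR + 1.2*SD(SR) and
    15 spikes/s.  The bandwidth is measured at 50% of the maximal driven
    rate by linear interpolation of the two crossings.
    """
    if len(rate_by_freq) < 3:
        raise ValueError("need at least 3 frequencies")
    if len(rate_by_level) < 2:
        raise ValueError("need at least 2 levels")
    if len(sr_trials) < 1:
        raise ValueError("need at least 1 spontaneous-rate trial")
    sr = float(np.mean(sr_trials))
    sr_sd = float(np.std(sr_trials, ddof=1)) if len(sr_trials) > 1 else 0.0

    freqs = np.array(sorted(rate_by_freq))
    rates = np.array([rate_by_freq[f] for f in freqs])
    bf = float(freqs[int(np.argmax(rates))])

    criterion = max(sr + 1.2 * sr_sd, 15.0)
    threshold, thr_flag = None, "not reached"
    for lvl in sorted(rate_by_level):
        if rate_by_level[lvl] > criterion:
            threshold, thr_flag = float(lvl), None
            break

    driven = rates - sr
    bw, bw_flag = _halfmax_bandwidth(freqs, driven)
    return TuningResult(bf, threshold, bw, sr, sr_sd,
                        threshold_flag=thr_flag, bandwidth_flag=bw_flag)


def _halfmax_bandwidth(freqs, driven):
    imax = int(np.argmax(driven))
    half = driven[imax] / 2.0
    lo = hi = None
    for i in range(imax, 0, -1):
        if driven[i - 1] <= half <= driven[i]:
            lo = np.interp(half, [driven[i - 1], driven[i]],
                           [freqs[i - 1], freqs[i]])
            break
    for i in range(imax, len(freqs) - 1):
        if driven[i + 1] <= half <= driven[i]:
            hi = np.interp(half, [driven[i + 1], driven[i]],
                           [freqs[i + 1], freqs[i]])
            break
    if lo is None or hi is None:
        return None, "one-sided" if (lo is not None or hi is not None) \
            else "no half-max crossing"
    return float(hi - lo), None


def psth(trains: SpikeTrainSet, f0: float) -> Tuple[np.ndarray, np.ndarray]:
    """Peri-stimulus time histogram in spikes/s.

    Bin width is 1/10 of the f0 period (0.5 ms at 200 Hz, 0.25 ms at
    400 Hz); counts are divided by bin width and repetition count.  Bins are
    left-closed/right-open and cover the steady-state window.
    """
    bin_w = 1.0 / (10.0 * f0)
    a, b = trains.analysis_window_s
    edges = np.arange(a, b + bin_w / 2, bin_w)
    pooled = np.concatenate(trains.windowed()) if trains.n_reps else np.empty(0)
    counts, _ = np.histogram(pooled, bins=edges)
    rate = counts / (bin_w * max(trains.n_reps, 1))
    centers = edges[:-1] + bin_w / 2
    return centers, rate


def rate_histograms(population: Sequence[SpikeTrainSet],
                    sr_estimates: Sequence[float],
                    driven_bin: float = 2.5, sr_bin: float = 5.0):
    """Population driven-rate and spontaneous-rate histograms.

    Driven rate = stimulated rate over the steady-state window minus the
    fiber's spontaneous rate.  The driven histogram (2.5 sp/s bins) is
    normalized to relative frequency and smoothed with a 3-bin moving
    average; the SR histogram uses 5 sp/s bins.
    """
    driven = np.array([ts.mean_rate_sp_s() - sr
                       for ts, sr in zip(population, sr_estimates)])
    sr = np.asarray(sr_estimates, dtype=float)
    out = {}
    for name, vals, width in (("driven", driven, driven_bin),
                              ("sr", sr, sr_bin)):
        if len(vals) == 0:
            out[name] = (np.empty(0), np.empty(0))
            continue
        # pad by two empty bins per side so the moving average loses no mass
        lo = np.floor(vals.min() / width) * width - 2 * width
        hi = np.ceil(vals.max() / width) * width + 3 * width
        edges = np.arange(lo, hi + width / 2, width)
        counts, _ = np.histogram(vals, bins=edges)
        rel = counts / counts.sum()
        if name == "driven":
            rel = np.convolve(rel, np.ones(3) / 3.0, mode="same")
        out[name] = (edges[:-1] + width / 2, rel)
    return out["driven"], out["sr"]


def isi_vs_spectrum(trains: SpikeTrainSet,
                    window_sd_s: float = ISI_WINDOW_SD_S) -> VSSpectrum:
    """Vector-strength spectrum from the all-order ISI histogram.

    All signed pairwise spike-time differences within each repetition
    (including the zero-lag self pairs) are pooled into a 50 us histogram
    over +/-375 ms, tapered with a zero-centered Gaussian (SD 200 ms),
    normalized by the total pair count, and Fourier transformed; the square
    root of the spectral magnitude is the VS at each bin frequency.  The
    spectral resolution is 1/0.75 s = 1.333 Hz.

    Including the self pairs is what makes the identity exact for a single
    train: sum_ij exp(-i2pif(t_i-t_j)) = |sum_i exp(-i2pif t_i)|^2 = N^2 V^2,
    and the pair count is N^2.
    """
    windowed = trains.windowed()
    if all(len(t) < 2 for t in windowed) and sum(len(t) for t in windowed) < 2:
        raise ValueError("no intervals: fewer than 2 spikes everywhere")
    n_bins = int(round(2 * ISI_SPAN_S / ISI_BIN_S))  # 15000
    edges = np.linspace(-ISI_SPAN_S, ISI_SPAN_S, n_bins + 1)
    hist = np.zeros(n_bins)
    n_isi = 0
    for t in windowed:
        if len(t) == 0:
            continue
        rel = t - trains.analysis_window_s[0]
        diffs = (rel[:, None] - rel[None, :]).ravel()
        h, _ = np.histogram(diffs, bins=edges)
        hist += h
        n_isi += len(t) ** 2
    centers = edges[:-1] + ISI_BIN_S / 2
    if window_sd_s is not None and np.isfinite(window_sd_s):
        hist = hist * np.exp(-0.5 * (centers / window_sd_s) ** 2)
    hist = hist / n_isi
    spec = np.fft.rfft(np.fft.ifftshift(hist))
    vs = np.sqrt(np.abs(spec))
    freqs = np.fft.rfftfreq(n_bins, ISI_BIN_S)
    return VSSpectrum(freqs, vs, n_isi,
                      window_sd_s=window_sd_s if window_sd_s else np.inf)


def vs_at(trains: SpikeTrainSet, f: float) -> Tuple[float, float, float]:
    """Single-frequency vector strength and Rayleigh statistic.

    Returns ``(V_avg, N_avg, z)``: V(f) = |1/N sum exp(-i2pif t_i)| per
    repetition, averaged over repetitions with at least one spike; N_avg is
    the mean spike count over all repetitions (zero-spike repetitions count
    as zero); z = N_avg * V_avg**2.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    windowed = trains.windowed()
    counts = np.array([len(t) for t in windowed])
    if counts.sum() == 0:
        raise ValueError("no spikes")
    vs_vals = []
    for t in windowed:
        if len(t) == 0:
            continue  # excluded from the V average
        vs_vals.append(np.abs(np.mean(np.exp(-2j * np.pi * f * t))))
    v_avg = float(np.mean(vs_vals))
    n_avg = float(np.mean(counts))
    return v_avg, n_avg, n_avg * v_avg ** 2


def f_maxpeak(populations: Sequence[SpikeTrainSet],
              condition) -> float:
    """The harmonic with the maximal population-average z in the passband.

    Candidates are the harmonics k*f0 inside the band-pass (-3 dB points at
    fc +/- 3.5*f0) of the harmonic stimulus; the population average of the
    Rayleigh z over the supplied H-response train sets is maximized.
    """
    if len(populations) == 0:
        raise ValueError("empty population")
    f0, fc = condition.f0, condition.fc
    lo, hi = fc - 3.5 * f0, fc + 3.5 * f0
    k = np.arange(1, int(np.floor(hi / f0)) + 1)
    candidates = k * f0
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    mean_z = [np.mean([vs_at(ts, f)[2] for ts in populations])
              for f in candidates]
    return float(candidates[int(np.argmax(mean_z))])


def _log_ratio(num: float, den: float) -> Optional[float]:
    if num <= 0 or den <= 0:
        return None  # flagged undefined rather than +/-inf
    return float(np.log10(num / den))


def z_metrics(h_trains: SpikeTrainSet, i_trains: SpikeTrainSet,
              condition, delta_f_pct: float, f_maxpeak_hz: float,
              sr_sp_s: Optional[float] = None,
              bf_hz: Optional[float] = None,
              mode: str = "cross") -> ZMetrics:
    """The two log-z-ratio contrasts for one fiber and one component shift.

    With ``mode='cross'`` (default) the TFS log-z-ratio compares z0 from the
    harmonic response at f_maxpeak against z_df from the inharmonic response
    at the shifted frequency f_maxpeak + delta_f; positive values mean
    stronger locking to the harmonic fine structure.  ``mode='within'``
    takes both z values from the inharmonic response (unshifted vs shifted
    frequency within one spectrum).

    The ENV/TFS log-z-ratio compares the inharmonic response's z at f0
    (envelope locking; the envelope stays periodic at f0 under the shift)
    against its z at the shifted fine-structure frequency: positive means
    envelope-dominated, negative fine-structure-dominated.
    """
    if mode not in ("cross", "within"):
        raise ValueError("mode must be 'cross' or 'within'")
    delta_f_hz = delta_f_pct / 100.0 * condition.f0
    f_shifted = f_maxpeak_hz + delta_f_hz
    z_df = vs_at(i_trains, f_shifted)[2]
    if mode == "cross":
        z0 = vs_at(h_trains, f_maxpeak_hz)[2]
    else:
        z0 = vs_at(i_trains, f_maxpeak_hz)[2]
    z_env = vs_at(i_trains, condition.f0)[2]
    return ZMetrics(
        f_maxpeak_hz=f_maxpeak_hz,
        z0=z0,
        z_df=z_df,
        tfs_log_z_ratio=_log_ratio(z0, z_df),
        env_tfs_log_z_ratio=_log_ratio(z_env, z_df),
        class_sr=(None if sr_sp_s is None else
                  ("low" if sr_sp_s <= LOW_SR_BOUNDARY_SP_S else "high")),
        class_bf=(None if bf_hz is None else
                  ("low" if bf_hz <= LOW_BF_BOUNDARY_HZ else "high")),
    )


def zpeak_shift_search(trains: SpikeTrainSet, base_freq_hz: float,
                       ladder_pct: Sequence[float],
                       f0: float) -> Tuple[float, float]:
    """Which component shift maximizes z at base_freq + shift.

    Evaluates the Rayleigh z at base_freq + delta_f for every ladder entry
    (the ladder must include 0) and returns the maximizing shift in percent
    and its z.  Ties are broken toward the smaller shift.
    """
    ladder = sorted(set(float(p) for p in ladder_pct))
    if 0.0 not in ladder:
        raise ValueError("ladder must include the unshifted entry 0")
    best_pct, best_z = None, -np.inf
    for pct in ladder:  # ascending: strict > keeps the smaller shift on ties
        z = vs_at(trains, base_freq_hz + pct / 100.0 * f0)[2]
        if z > best_z:
            best_pct, best_z = pct, z
    return best_pct, best_z
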