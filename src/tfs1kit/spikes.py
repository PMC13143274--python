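"""Synthetic auditory-nerve fiber spike trains.

An inhomogeneous Poisson process with absolute dead time stands in for real
auditory-nerve recordings.  The firing intensity follows the stimulus after
narrow-band filtering around the fiber's best frequency, with independently
controllable locking to the envelope (periodic at f0 for TFS1 stimuli) and to
the temporal fine structure (components near the best frequency).  The model
deliberately omits adaptation and refractory recovery: it provides
ground-truth locking for validating the analysis metrics, not biophysics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal

from .stimuli import StimulusCondition, StimulusWaveform

__all__ = [
    "FiberModel",
    "SpikeTrainSet",
    "intensity_function",
    "simulate",
    "population_preset",
    "write_spike_csv",
    "read_spike_csv",
    "LOW_SR_BOUNDARY_SP_S",
]

#: spontaneous-rate boundary between the low- and high-SR fiber classes
LOW_SR_BOUNDARY_SP_S = 18.0

#: default steady-state analysis window for a 0.4 s unramped stimulus:
#: 375 ms excluding 12.5 ms on/offset fringes
DEFAULT_ANALYSIS_WINDOW_S = (0.0125, 0.3875)


@dataclass(frozen=True)
class FiberModel:
    """Parameters of one simulated auditory-nerve fiber.

    ``env_gain`` and ``tfs_gain`` weight the modulation of the driven rate by
    the narrow-band envelope and fine structure; their sum must not exceed 1
    so the intensity stays non-negative before rectification matters.
    ``dead_time_s`` defaults to 0.7 ms, above the 0.6 ms inter-spike-interval
    criterion used to reject inadequately isolated units.
    """

    sr_sp_s: float = 60.0
    driven_sp_s: float = 70.0
    bf_hz: float = 1600.0
    env_gain: float = 0.0
    tfs_gain: float = 0.0
    dead_time_s: float = 0.0007
    seed: int = 0

    def __post_init__(self):
        if self.sr_sp_s < 0 or self.driven_sp_s < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.env_gain <= 1 and 0 <= self.tfs_gain <= 1):
            raise ValueError("gains must lie in [0, 1]")
        if self.env_gain + self.tfs_gain > 1 + 1e-12:
            raise ValueError("env_gain + tfs_gain must not exceed 1")
        if self.dead_time_s < 0.0006:
            raise ValueError(
                "dead time below the 0.6 ms isolation criterion"
            )

    @property
    def sr_class(self) -> str:
        return "low" if self.sr_sp_s <= LOW_SR_BOUNDARY_SP_S else "high"


@dataclass
class SpikeTrainSet:
    """Spike times for repeated presentations of one stimulus to one fiber."""

    spike_times_s: List[np.ndarray]
    analysis_window_s: Tuple[float, float] = DEFAULT_ANALYSIS_WINDOW_S
    stimulus: Optional[StimulusCondition] = None
    fiber: Optional[FiberModel] = None

    def __post_init__(self):
        self.spike_times_s = [np.sort(np.asarray(t, dtype=float))
                              for t in self.spike_times_s]

    @property
    def n_reps(self) -> int:
        return len(self.spike_times_s)

    def windowed(self) -> List[np.ndarray]:
        """Spike times inside the steady-state window [start, stop)."""
        a, b = self.analysis_window_s
        return [t[(t >= a) & (t < b)] for t in self.spike_times_s]

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.windowed()])

    def mean_rate_sp_s(self) -> float:
        a, b = self.analysis_window_s
        return float(np.mean(self.counts()) / (b - a))

    def min_isi_s(self) -> float:
        isis = [np.diff(t) for t in self.spike_times_s if len(t) > 1]
        if not isis:
            return np.inf
        return float(min(np.min(d) for d in isis))

    def validate_isolation(self, criterion_s: float = 0.0006) -> bool:
        """The inter-spike-interval screen applied to recorded units."""
        return self.min_isi_s() >= criterion_s


def _narrowband(w: StimulusWaveform, bf_hz: float):
    """Half-octave fourth-order band-pass around bf: a crude cochlear filter."""
    fs = w.sample_rate_hz
    if bf_hz >= fs / 2:
        raise ValueError("best frequency above Nyquist")
    lo = bf_hz / 2.0 ** 0.25
    hi = min(bf_hz * 2.0 ** 0.25, 0.99 * fs / 2)
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _signal.sosfilt(sos, w.samples)


def intensity_function(fiber: FiberModel,
                       w: StimulusWaveform) -> np.ndarray:
    """Instantaneous firing rate r(t) in spikes/s, sampled at the stimulus rate.

    r(t) = max(0, sr + driven * (1 + env_gain*E(t) + tfs_gain*F(t))) with E
    the zero-mean unit-peak Hilbert envelope of the narrow-band signal at the
    best frequency, and F the unit-peak narrow-band fine structure.  A silent
    input yields the spontaneous rate alone.
    """
    if not np.any(w.samples):
        return np.full(len(w.samples), fiber.sr_sp_s)
    nb = _narrowband(w, fiber.bf_hz)
    analytic = _signal.hilbert(nb)
    env = np.abs(analytic)
    # center and normalize over the post-transient portion so the causal
    # filter's onset does not dominate the peak and crush the modulation
    i0 = min(int(0.025 * w.sample_rate_hz), len(env) // 4)
    env = env - env[i0:].mean()
    peak = np.max(np.abs(env[i0:]))
    e_hat = env / peak if peak > 0 else env
    fpk = np.max(np.abs(nb[i0:]))
    f_hat = nb / fpk if fpk > 0 else nb
    e_hat = np.clip(e_hat, -1.0, 1.0)
    f_hat = np.clip(f_hat, -1.0, 1.0)
    r = fiber.sr_sp_s + fiber.driven_sp_s * (
        1.0 + fiber.env_gain * e_hat + fiber.tfs_gain * f_hat
    )
    return np.maximum(r, 0.0)


def simulate(fiber: FiberModel, w: StimulusWaveform, n_reps: int = 40,
             seed: Optional[int] = None) -> SpikeTrainSet:
    """Inhomogeneous Poisson spike trains by thinning, with dead time.

    Candidate events are drawn from a homogeneous process at max r(t) and
    accepted with probability r(t)/max r; accepted events closer than the
    dead time to the previous spike are discarded.  Reproducible for a fixed
    seed (defaults to the fiber's seed).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rate = intensity_function(fiber, w)
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite intensity")
    fs = w.sample_rate_hz
    duration = len(rate) / fs
    lam_max = float(np.max(rate))
    rng = np.random.default_rng(fiber.seed if seed is None else seed)
    trains = []
    for _ in range(n_reps):
        if lam_max <= 0:
            trains.append(np.empty(0))
            continue
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        r_at = rate[np.minimum((cand * fs).astype(int), len(rate) - 1)]
        keep = cand[rng.uniform(0, lam_max, n_cand) < r_at]
        trains.append(_enforce_dead_time(keep, fiber.dead_time_s))
    return SpikeTrainSet(trains, stimulus=w.condition, fiber=fiber)


def _enforce_dead_time(times: np.ndarray, dead: float) -> np.ndarray:
    out = []
    last = -np.inf
    for t in times:
        if t - last >= dead:
            out.append(t)
            last = t
    return np.asarray(out)


def population_preset(bf_hz: float, n_low_sr: int = 4, n_high_sr: int = 4,
                      env_gain: float = 0.2, tfs_gain: float = 0.6,
                      seed: int = 0) -> List[FiberModel]:
    """A small fiber population spanning both spontaneous-rate classes.

    Spontaneous rates straddle the 18 spikes/s class boundary (low class
    drawn from 0-18, high from 18-144, mirroring the reported 0-144 sp/s
    range); driven rates around the reported median of ~68 sp/s.
    """
    rng = np.random.default_rng(seed)
    fibers = []
    for i in range(n_low_sr):
        fibers.append(FiberModel(
            sr_sp_s=float(rng.uniform(0, LOW_SR_BOUNDARY_SP_S)),
            driven_sp_s=float(rng.uniform(40, 100)), bf_hz=bf_hz,
            env_gain=env_gain, tfs_gain=tfs_gain,
            seed=int(rng.integers(2 ** 31))))
    for i in range(n_high_sr):
        fibers.append(FiberModel(
            sr_sp_s=float(rng.uniform(LOW_SR_BOUNDARY_SP_S, 144)),
            driven_sp_s=float(rng.uniform(40, 100)), bf_hz=bf_hz,
            env_gain=env_gain, tfs_gain=tfs_gain,
            seed=int(rng.integers(2 ** 31))))
    return fibers


def write_spike_csv(trains: SpikeTrainSet, path, sidecar: bool = True) -> None:
    """CSV with columns rep_index, spike_time_s; JSON sidecar for provenance."""
    import pandas as pd

    path = Path(path)
    rows = [(i, t) for i, times in enumerate(trains.spike_times_s)
            for t in times]
    pd.DataFrame(rows, columns=["rep_index", "spike_time_s"]).to_csv(
        path, index=False)
    if sidecar:
        meta = {
            "n_reps": trains.n_reps,
            "analysis_window_s": list(trains.analysis_window_s),
            "fiber": asdict(trains.fiber) if trains.fiber else None,
            "stimulus": (json.loads(trains.stimulus.to_json())
                         if trains.stimulus else None),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_spike_csv(path, n_reps: Optional[int] = None) -> SpikeTrainSet:
    """Read trains written by :func:`write_spike_csv` (or user data in the
    same format).  Empty repetitions are preserved when the sidecar records
    ``n_reps``."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    total = n_reps or meta.get("n_reps") or (
        int(df["rep_index"].max()) + 1 if len(df) else 0)
    trains = [df.loc[df["rep_index"] == i, "spike_time_s"].to_numpy()
              for i in range(total)]
    kwargs = {}
    if "analysis_window_s" in meta:
        kwargs["analysis_window_s"] = tuple(meta["analysis_window_s"])
    if meta.get("fiber"):
        kwargs["fiber"] = FiberModel(**meta["fiber"])
    if meta.get("stimulus"):
        kwargs["stimulus"] = StimulusCondition.from_json(
            json.dumps(meta["stimulus"]))
    return SpikeTrainSet(trains, **kwargs)
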