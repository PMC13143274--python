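"""Go/No-Go session bookkeeping, d-prime, and threshold estimation.

In the behavioral TFS1 task a harmonic reference plays continuously; on a
trial the target is either an inharmonic complex (test trial) or the
harmonic itself (sham trial).  Leaving the pedestal within the response
window is a "go".  Sensitivity is d' = z(hit rate) - z(false-alarm rate),
and a discrimination threshold is the component shift (percent of f0) at
which d' crosses 1, obtained by the interpolation / extrapolation / capping
cascade described in :func:`threshold`.

A simulated observer with a known true threshold provides end-to-end
validation of the bookkeeping and the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Trial",
    "PsychoSession",
    "PsychoResult",
    "session_valid",
    "d_prime",
    "threshold",
    "simulate_observer",
    "analyze_sessions",
    "check_session_constraints",
    "LEAST_SALIENT_CONDITION",
]

#: the condition that must not occur in two consecutive blocks
LEAST_SALIENT_CONDITION = "200/1600"

WARMUP_SHIFT_PCT = 42.5
N_BLOCKS = 10
TEST_PER_BLOCK = 6
SHAM_PER_BLOCK = 3


@dataclass(frozen=True)
class Trial:
    block_index: int
    condition: str
    trial_type: str  # test | sham | warmup | motivator
    delta_f_pct: float
    response: str  # go | stay


@dataclass
class PsychoSession:
    """One session: 10 blocks of 9 scored trials (6 test + 3 sham).

    Block 0 is the warm-up block (shift 42.5%, excluded from analysis);
    motivator trials follow correct rejections and are also excluded.
    """

    trials: List[Trial]

    def scored_trials(self) -> List[Trial]:
        """All non-motivator trials, warm-up block included."""
        return [t for t in self.trials if t.trial_type != "motivator"]

    def analysis_trials(self) -> List[Trial]:
        """Trials entering the analysis: no warm-up block, no motivators."""
        return [t for t in self.trials
                if t.block_index > 0 and t.trial_type in ("test", "sham")]

    def false_alarm_rate(self) -> float:
        shams = [t for t in self.scored_trials() if t.trial_type == "sham"]
        if not shams:
            return 0.0
        return sum(t.response == "go" for t in shams) / len(shams)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.trials])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PsychoSession":
        return cls([Trial(int(r.block_index), str(r.condition),
                          str(r.trial_type), float(r.delta_f_pct),
                          str(r.response))
                    for r in df.itertuples(index=False)])


@dataclass
class PsychoResult:
    """Per-(condition, shift) rates and d', and per-condition thresholds."""

    cells: pd.DataFrame  # condition, delta_f_pct, n_trials, hit_rate, fa_rate, d_prime
    thresholds: Dict[str, float]
    flags: Dict[str, str] = field(default_factory=dict)


def session_valid(s: PsychoSession) -> Tuple[bool, List[str]]:
    """A session counts if all 90 trials were completed and the session
    false-alarm rate does not exceed 20%."""
    reasons = []
    n = len(s.scored_trials())
    if n != N_BLOCKS * (TEST_PER_BLOCK + SHAM_PER_BLOCK):
        reasons.append("incomplete")
    if s.false_alarm_rate() > 0.20:
        reasons.append("false-alarm rate")
    return (not reasons), reasons


def d_prime(hit_rate: float, fa_rate: float,
            n_hit_trials: int, n_fa_trials: int) -> float:
    """d' = z(hit rate) - z(false-alarm rate).

    Rates of exactly 0 or 1 are corrected by the 1/(2n) rule before the
    normal-quantile transform so d' stays finite.
    """
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_hit_trials == 0 or n_fa_trials == 0:
        raise ValueError("undefined d': zero trials")
    h = _clip_rate(hit_rate, n_hit_trials)
    f = _clip_rate(fa_rate, n_fa_trials)
    return float(norm.ppf(h) - norm.ppf(f))


def _clip_rate(r: float, n: int) -> float:
    if r == 0.0:
        return 1.0 / (2 * n)
    if r == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def threshold(d_by_shift: Dict[float, float],
              min_shift_measured: Optional[float] = None
              ) -> Tuple[float, Optional[str]]:
    """Component-shift threshold at d' = 1, in percent of f0.

    Rule cascade, shifts taken in ascending order:

    1. Linear interpolation between the first shift with d' > 1 and the
       preceding shift (with d' <= 1).
    2. If no shift reaches d' > 1: a least-squares line through all (shift,
       d') points, extrapolated to d' = 1.
    3. If every shift has d' > 1: half the smallest shift measured.
    4. If the fit has non-positive slope or extrapolates beyond 100%, the
       threshold is set to 100.

    Thresholds are always in (0, 100].  Returns ``(threshold, flag)`` with a
    flag naming the fallback rule when one fired.
    """
    if len(d_by_shift) < 2:
        return 100.0, "fewer than 2 shifts"
    shifts = np.array(sorted(d_by_shift))
    d = np.array([d_by_shift[s] for s in shifts])
    if min_shift_measured is None:
        min_shift_measured = float(shifts[0])

    above = d > 1.0
    if above.all():
        return min(min_shift_measured / 2.0, 100.0), "all d' above 1"
    if above.any():
        j = int(np.argmax(above))  # first shift with d' > 1
        if j == 0:
            return min(min_shift_measured / 2.0, 100.0), "all d' above 1"
        thr = shifts[j - 1] + (1.0 - d[j - 1]) / (d[j] - d[j - 1]) * (
            shifts[j] - shifts[j - 1])
        return float(min(thr, 100.0)), None
    slope, intercept = np.polyfit(shifts, d, 1)
    if slope <= 0:
        return 100.0, "non-positive slope"
    thr = (1.0 - intercept) / slope
    if thr > 100.0 or thr <= 0:
        return 100.0, "extrapolation out of range"
    return float(thr), "extrapolated"


def check_session_constraints(s: PsychoSession) -> List[str]:
    """Violations of the session-ordering rules.

    Checks: block 0 is the warm-up block at 42.5%; no two consecutive sham
    trials (within and across blocks, motivators removed); the least salient
    condition never occupies two consecutive blocks; motivators follow
    correct rejections only.
    """
    issues = []
    scored = s.scored_trials()
    warm = [t for t in scored if t.block_index == 0]
    if any(t.trial_type == "test" and t.delta_f_pct != WARMUP_SHIFT_PCT
           for t in warm):
        issues.append("warm-up block shift is not 42.5%")
    prev_sham = False
    for t in scored:
        is_sham = t.trial_type == "sham"
        if is_sham and prev_sham:
            issues.append(f"consecutive sham trials (block {t.block_index})")
        prev_sham = is_sham
    block_cond = {}
    for t in s.trials:
        block_cond[t.block_index] = t.condition
    blocks = [block_cond[i] for i in sorted(block_cond)]
    for a, b in zip(blocks, blocks[1:]):
        if a == b == LEAST_SALIENT_CONDITION:
            issues.append("least salient condition in consecutive blocks")
    for prev, t in zip(s.trials, s.trials[1:]):
        if t.trial_type == "motivator" and not (
                prev.trial_type == "sham" and prev.response == "stay"):
            issues.append("motivator not following a correct rejection")
    return issues


def _assign_block_conditions(rng, conditions: Sequence[str],
                             n_blocks: int) -> List[str]:
    """Pseudo-random block conditions; least salient never twice in a row."""
    while True:
        seq = [conditions[rng.integers(len(conditions))]
               for _ in range(n_blocks)]
        ok = all(not (a == b == LEAST_SALIENT_CONDITION)
                 for a, b in zip(seq, seq[1:]))
        if ok or len(conditions) == 1:
            if len(conditions) == 1:
                return list(conditions) * n_blocks
            return seq


def _block_trial_types(rng, prev_ended_sham: bool = False) -> List[str]:
    """6 test + 3 sham in random order with no two shams adjacent, within
    the block and across the block boundary."""
    while True:
        types = ["test"] * TEST_PER_BLOCK + ["sham"] * SHAM_PER_BLOCK
        rng.shuffle(types)
        if prev_ended_sham and types[0] == "sham":
            continue
        if all(not (a == b == "sham") for a, b in zip(types, types[1:])):
            return types


def simulate_observer(true_threshold_pct, psychometric_slope: float,
                      fa_rate: float, trials_per_cell: int,
                      ladder: Sequence[float], seed: int = 0,
                      conditions: Optional[Sequence[str]] = None,
                      max_sessions: int = 200) -> List[PsychoSession]:
    """Sessions from a stochastic observer with a known true threshold.

    The observer's sensitivity is d(shift) = slope * log2(shift / true
    threshold) + 1, so d' = 1 exactly at the true threshold; it responds
    "go" on a test trial with probability Phi(Phi^-1(fa_rate) + d(shift))
    and with probability ``fa_rate`` on a sham trial.  Sessions obeying all
    block/ordering constraints are generated until every (condition, shift)
    cell holds at least ``trials_per_cell`` analysis test trials.

    ``true_threshold_pct`` may be a scalar (single condition "400/1600") or
    a mapping condition -> threshold.
    """
    if psychometric_slope <= 0:
        raise ValueError("slope must be positive")
    if not (0 <= fa_rate < 0.2):
        raise ValueError("fa_rate must be < 0.2 for acceptable sessions")
    ladder = sorted(set(float(x) for x in ladder))
    if not ladder:
        raise ValueError("empty ladder")
    if np.isscalar(true_threshold_pct):
        thr_map = {"400/1600": float(true_threshold_pct)}
    else:
        thr_map = dict(true_threshold_pct)
    if conditions is None:
        conditions = list(thr_map)
    rng = np.random.default_rng(seed)

    def d_true(cond, shift):
        return psychometric_slope * np.log2(shift / thr_map[cond]) + 1.0

    def p_go(cond, shift):
        return float(norm.cdf(norm.ppf(max(fa_rate, 1e-6)) +
                              d_true(cond, shift)))

    sessions: List[PsychoSession] = []
    counts = {(c, s): 0 for c in conditions for s in ladder}
    # per-condition queues cycle the ladder so cells fill evenly
    queues = {c: [] for c in conditions}
    for _ in range(max_sessions):
        trials: List[Trial] = []
        block_conds = _assign_block_conditions(rng, conditions, N_BLOCKS)
        prev_ended_sham = False
        for b, cond in enumerate(block_conds):
            types = _block_trial_types(rng, prev_ended_sham)
            prev_ended_sham = types[-1] == "sham"
            for ttype in types:
                if ttype == "sham":
                    resp = "go" if rng.random() < fa_rate else "stay"
                    trials.append(Trial(b, cond, "sham", 0.0, resp))
                    if resp == "stay":  # motivator after correct rejection
                        trials.append(Trial(b, cond, "motivator",
                                            max(ladder), "go"))
                    continue
                if b == 0:
                    shift = WARMUP_SHIFT_PCT
                    ttype_out = "test"
                else:
                    if not queues[cond]:
                        order = sorted(ladder,
                                       key=lambda s: counts[(cond, s)])
                        queues[cond] = order
                    shift = queues[cond].pop(0)
                    ttype_out = "test"
                resp = "go" if rng.random() < p_go(cond, shift) else "stay"
                trials.append(Trial(b, cond, ttype_out, shift, resp))
                if b > 0:
                    counts[(cond, shift)] += 1
        sessions.append(PsychoSession(trials))
        if all(v >= trials_per_cell for v in counts.values()):
            break
    return sessions


def analyze_sessions(sessions: Iterable[PsychoSession],
                     fa_scope: str = "condition") -> PsychoResult:
    """Pool accepted sessions into per-cell d' values and thresholds.

    Invalid sessions (incomplete or false-alarm rate > 20%) are dropped.
    The false-alarm rate entering d' is pooled per condition over the
    accepted sessions (``fa_scope='condition'``) or over the whole data set
    (``fa_scope='pooled'``).
    """
    kept = [s for s in sessions if session_valid(s)[0]]
    rows = []
    for s in kept:
        rows.extend(t.__dict__ for t in s.analysis_trials())
    if not rows:
        return PsychoResult(pd.DataFrame(), {}, {"all": "no valid sessions"})
    df = pd.DataFrame(rows)

    shams = df[df.trial_type == "sham"]
    if fa_scope == "pooled":
        fa_all = (shams.response == "go").mean()
        fa_by_cond = {c: fa_all for c in df.condition.unique()}
        nfa_by_cond = {c: len(shams) for c in df.condition.unique()}
    else:
        fa_by_cond = shams.groupby("condition").response.apply(
            lambda r: (r == "go").mean()).to_dict()
        nfa_by_cond = shams.groupby("condition").size().to_dict()

    cells = []
    for (cond, shift), g in df[df.trial_type == "test"].groupby(
            ["condition", "delta_f_pct"]):
        hit = (g.response == "go").mean()
        fa = fa_by_cond.get(cond, 0.0)
        cells.append({
            "condition": cond, "delta_f_pct": shift, "n_trials": len(g),
            "hit_rate": hit, "fa_rate": fa,
            "d_prime": d_prime(hit, fa, len(g), nfa_by_cond.get(cond, 1)),
        })
    cells = pd.DataFrame(cells).sort_values(
        ["condition", "delta_f_pct"]).reset_index(drop=True)

    thresholds, flags = {}, {}
    for cond, g in cells.groupby("condition"):
        d_map = dict(zip(g.delta_f_pct, g.d_prime))
        thr, flag = threshold(d_map)
        thresholds[cond] = thr
        if flag:
            flags[cond] = flag
    return PsychoResult(cells, thresholds, flags)
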