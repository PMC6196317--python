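"""Behavioral test computations: computerized perimetry, blindsight Bayes
factor, adaptive staircases, and robust illusion-strength estimation.

Implements the scoring arithmetic of four lab tests:

* a 32-position visual field screen (4 eccentricity rings x 8 polar sectors,
  two repetitions per position, one stimulus-present and one absent);
* a forced-choice blindsight screen analyzed with a binomial Bayes factor
  BF01 for guessing (p = p0) against a Beta(1, 1) alternative;
* adaptive n-down / 1-up staircases with reversal bookkeeping and a step
  size that shrinks after the fifth reversal (size-ratio version) or fixed
  coherence steps (motion version), plus simulated logistic observers;
* the illusion-strength estimator: mean of reversal levels surviving a
  median +/- 2 MAD filter (unscaled MAD; boundary values kept).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "VF_RING_STEP_DEG",
    "make_vf_session",
    "score_vf",
    "bf01_binomial",
    "StaircaseState",
    "staircase_step",
    "ebbinghaus_staircase",
    "motion_coherence_staircase",
    "LogisticObserver",
    "run_staircase",
    "illusion_strength",
    "fixed_pair_test",
]

# outer radius 37.5 deg divided into four equally spaced rings
VF_RING_STEP_DEG = 37.5 / 4


# ---------------------------------------------------------------------------
# computerized visual field test


def make_vf_session(
    n_rings: int = 4,
    n_sectors: int = 8,
    reps_per_position: int = 2,
    seed: int = 0,
    durations_s=(9.0, 0.5),
) -> pd.DataFrame:
    """Pseudo-random trial list for the computerized visual field test.

    Every (ring, sector) position appears ``reps_per_position`` times with
    half of the repetitions stimulus-present (the default two repetitions
    give one present and one absent trial per position; 4 x 8 x 2 = 64
    trials).  ``durations_s`` tags which stimulus duration each repetition
    pair belongs to, cycling through the provided values.
    """
    if n_rings < 1 or n_sectors < 1 or reps_per_position < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for ring in range(1, n_rings + 1):
        for sector in range(1, n_sectors + 1):
            for rep in range(reps_per_position):
                rows.append(dict(
                    ring=ring,
                    sector=sector,
                    stimulus_present=bool(rep % 2 == 0),
                    duration_s=float(durations_s[rep % len(durations_s)])
                    if durations_s else np.nan,
                ))
    trials = pd.DataFrame(rows)
    trials = trials.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    trials.insert(0, "trial", np.arange(1, len(trials) + 1))
    return trials


def score_vf(trials: pd.DataFrame) -> pd.DataFrame:
    """Score a visual field session into a per-position table.

    ``trials`` needs columns ring, sector, stimulus_present and response
    ('seen' | 'not-seen').  Output rows (one per position) count hits,
    misses, false alarms and correct rejections, and classify the position
    ``intact`` only when every present trial was detected and every absent
    trial correctly rejected; a single error marks it impaired.  Incomplete
    sessions are scored partially with a warning.
    """
    import warnings

    if "response" not in trials.columns:
        raise ValueError("trials need a 'response' column to be scored")
    seen = trials["response"].astype(str).str.lower().isin(("seen", "present", "yes"))
    t = trials.assign(_seen=seen)
    rows = []
    for (ring, sector), grp in t.groupby(["ring", "sector"], sort=True):
        present = grp[grp["stimulus_present"]]
        absent = grp[~grp["stimulus_present"]]
        hits = int(present["_seen"].sum())
        misses = len(present) - hits
        fas = int(absent["_seen"].sum())
        crs = len(absent) - fas
        complete = len(present) >= 1 and len(absent) >= 1
        if not complete:
            warnings.warn(
                f"position (ring {ring}, sector {sector}) incomplete; "
                "partial scoring", stacklevel=2,
            )
        intact = complete and misses == 0 and fas == 0
        rows.append(dict(ring=ring, sector=sector, hits=hits, misses=misses,
                         false_alarms=fas, correct_rejections=crs,
                         complete=complete, intact=intact))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# blindsight Bayes factor


def bf01_binomial(k: int, n: int, p0: float = 0.5, sidedness: str = "two") -> float:
    """Binomial Bayes factor for the null (p = p0) over the alternative.

    The alternative places a uniform Beta(1, 1) prior on the success
    probability (restricted to p > p0 for ``sidedness='greater'`` or p < p0
    for ``'less'``, renormalized).  Two-sided closed form:
    BF01 = (n + 1) * C(n, k) * p0^k * (1 - p0)^(n - k).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie in (0, 1)")
    null_lik = float(stats.binom.pmf(k, n, p0))
    # integral of C(n,k) p^k (1-p)^(n-k) over [0,1] is 1/(n+1);
    # betainc gives the regularized partial integral for one-sided priors
    if sidedness == "two":
        marginal = 1.0 / (n + 1)
    elif sidedness == "greater":
        frac = 1.0 - float(special.betainc(k + 1, n - k + 1, p0))
        marginal = frac / ((n + 1) * (1.0 - p0))
    elif sidedness == "less":
        frac = float(special.betainc(k + 1, n - k + 1, p0))
        marginal = frac / ((n + 1) * p0)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return null_lik / marginal


# ---------------------------------------------------------------------------
# adaptive staircases


@dataclass
class StaircaseState:
    """State of an n-down / 1-up adaptive track.

    Levels are natural-log size-ratios for the Ebbinghaus configuration or
    coherence proportions for the motion configuration.  A reversal is
    recorded at the pre-change level whenever the movement direction flips;
    once ``switch_after_reversals`` reversals are on record the post-switch
    step size applies.
    """

    level: float
    n_down: int = 1
    step_down_pre: float = 0.04
    step_up_pre: float = 0.04
    step_down_post: float = 0.02
    step_up_post: float = 0.02
    switch_after_reversals: int = 5
    bounds: tuple[float, float] = (-math.inf, math.inf)
    reversal_levels: list = field(default_factory=list)
    history: list = field(default_factory=list)  # (level, correct) per trial
    _correct_run: int = 0
    _last_direction: int = 0  # +1 up, -1 down, 0 none yet

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_levels)


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial; returns the (mutated) state.

    Moves down after ``n_down`` consecutive correct responses, up after any
    incorrect one.  The step that records the fifth reversal (and all later
    ones) already uses the post-switch size.
    """
    state.history.append((state.level, bool(correct)))
    if correct:
        state._correct_run += 1
        if state._correct_run < state.n_down:
            return state
        state._correct_run = 0
        direction = -1
    else:
        state._correct_run = 0
        direction = +1

    if state._last_direction != 0 and direction != state._last_direction:
        state.reversal_levels.append(state.level)
    state._last_direction = direction

    post = state.n_reversals >= state.switch_after_reversals
    if direction < 0:
        step = state.step_down_post if post else state.step_down_pre
    else:
        step = state.step_up_post if post else state.step_up_pre
    lo, hi = state.bounds
    state.level = float(min(max(state.level + direction * step, lo), hi))
    return state


def ebbinghaus_staircase(start_level: float) -> StaircaseState:
    """1-down/1-up track in natural-log size-ratio units: 0.04 steps until
    the fifth reversal, 0.02 afterwards."""
    return StaircaseState(level=start_level, n_down=1,
                          step_down_pre=0.04, step_up_pre=0.04,
                          step_down_post=0.02, step_up_post=0.02)


def motion_coherence_staircase(start_level: float = 1.0,
                               step: float = 0.05) -> StaircaseState:
    """2-down/1-up track on coherence proportion with a fixed step
    (0.05 for 100 dots, 0.20 for the five-dot variant), bounded to [0, 1]."""
    return StaircaseState(level=start_level, n_down=2,
                          step_down_pre=step, step_up_pre=step,
                          step_down_post=step, step_up_post=step,
                          switch_after_reversals=0, bounds=(0.0, 1.0))


@dataclass
class LogisticObserver:
    """Simulated observer with a logistic psychometric function.

    p(correct at level L) = lapse/2 + (1 - lapse) / (1 + exp(-(L - pse)/slope)).
    Higher levels are easier; the 50% point of the lapse-free core is ``pse``.
    """

    pse: float
    slope: float
    lapse: float = 0.0

    def p_correct(self, level: float) -> float:
        core = 1.0 / (1.0 + math.exp(-(level - self.pse) / self.slope))
        return self.lapse / 2.0 + (1.0 - self.lapse) * core

    def level_at(self, p: float) -> float:
        """Stimulus level where the psychometric function crosses p."""
        core = (p - self.lapse / 2.0) / (1.0 - self.lapse)
        return self.pse + self.slope * math.log(core / (1.0 - core))

    def respond(self, level: float, rng: np.random.Generator) -> bool:
        return bool(rng.uniform() < self.p_correct(level))


def run_staircase(
    state: StaircaseState,
    observer: LogisticObserver,
    n_trials: int,
    seed: int,
) -> StaircaseState:
    """Drive a staircase against a simulated observer (seed mandatory)."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trials):
        staircase_step(state, observer.respond(state.level, rng))
    return state


# ---------------------------------------------------------------------------
# illusion strength


def illusion_strength(reversal_levels) -> float:
    """Robust threshold: mean of reversals within median +/- 2 MAD.

    MAD is the unscaled median absolute deviation (no normal-consistency
    factor); reversals exactly on a boundary are retained, so identical
    reversals (MAD 0) survive.  Positive values follow the classical
    illusion direction (test with small inducers judged larger at physical
    equality).  Needs at least three reversals.
    """
    levels = np.asarray(list(reversal_levels), dtype=float)
    if levels.size < 3:
        raise ValueError("need at least three reversals")
    med = float(np.median(levels))
    mad = float(np.median(np.abs(levels - med)))
    keep = np.abs(levels - med) <= 2.0 * mad + 1e-12
    if not keep.any():
        raise ValueError("all reversals filtered out; inspect the track")
    return float(levels[keep].mean())


def fixed_pair_test(n_trials: int, responses) -> dict:
    """Physically-equal-pair control: choice proportion and exact binomial p.

    ``responses`` flags, per trial, whether the target with the small
    inducers was judged larger (the classical illusion direction); accepts
    booleans or the strings 'small'/'large'.  Returns the proportion and the
    two-sided exact binomial p-value against chance (0.5): a full illusion
    gives proportion 1.0, chance performance gives p = 1.0.
    """
    flags = []
    for r in responses:
        if isinstance(r, str):
            flags.append(r.lower().startswith("small"))
        else:
            flags.append(bool(r))
    if len(flags) != n_trials:
        raise ValueError("response count does not match n_trials")
    k = sum(flags)
    test = stats.binomtest(k, n_trials, 0.5, alternative="two-sided")
    return dict(k_small=k, n=n_trials, proportion=k / n_trials,
                p_value=float(test.pvalue))
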