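"""Synthetic torchlight-search cohorts.

Generates a full study's worth of participants, per-trial AOI fixation
sequences, and the four derived dependent variables (successful search,
time-to-target, scanning movements, anticipatory looks), with the
statistical structure the downstream analyses assume:

* more scanning in the Uniform than the Skewed condition, with the gap
  ramping up with toddler age and becoming detectable around 24 months;
* more anticipatory looks in the Skewed condition;
* adults scanning more, succeeding more, and transitioning into target
  locations more, while toddlers transition into cue locations more.

The gaze model is a first-order biased walk over the 8 AOIs with log-normal
fixation durations; it is a stand-in for real eye-tracking data, not a model
of oculomotor control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .environment import SKEWED, UNIFORM, SpatialLayout
from .markov import AOISequence

__all__ = [
    "EffectParams",
    "CohortConfig",
    "ParticipantProfile",
    "TrialRecord",
    "DwellCriteria",
    "simulate_trial",
    "generate_cohort",
    "derive_trial_dvs",
    "make_profile",
    "trials_to_frame",
]


@dataclass(frozen=True)
class DwellCriteria:
    """Gaze-contingent success rules of the test trials.

    Dwell credit starts accruing only after ``onset_latency_s`` (stimulus
    onset and orienting at the start of the search phase), so no trial can
    resolve in the first moments of the search window.
    """

    target_dwell_s: float = 0.200
    cue_dwell_s: float = 0.150
    timeout_s: float = 10.0
    onset_latency_s: float = 0.8


class _DwellScorer:
    """Incremental application of the dwell/timeout rules to a fixation
    stream; shared by the trial simulator and the DV derivation so the two
    can never disagree."""

    def __init__(self, condition: str, cue_state: int, target_state: int,
                 dwell: DwellCriteria) -> None:
        self.condition = condition
        self.cue_state = cue_state
        self.target_state = target_state
        self.dwell = dwell
        self.elapsed = 0.0
        self.cue_found = False
        self.success = False
        self.time_to_target: float | None = None
        self._run_aoi: int | None = None
        self._run_credit = 0.0
        self._run_gate_open = False

    @property
    def done(self) -> bool:
        return self.success or self.elapsed >= self.dwell.timeout_s

    def observe(self, aoi: int, duration: float) -> float:
        """Consume one fixation; returns its duration truncated to the
        search window."""
        dw = self.dwell
        d = min(duration, dw.timeout_s - self.elapsed)
        if d <= 0:
            return 0.0
        start = max(self.elapsed, dw.onset_latency_s)
        credit = max(0.0, self.elapsed + d - start)
        if aoi != self._run_aoi:
            self._run_aoi = aoi
            self._run_credit = 0.0
            self._run_gate_open = self.condition == SKEWED or self.cue_found
        before = self._run_credit
        self._run_credit += credit
        if (
            self.condition == UNIFORM
            and aoi == self.cue_state
            and self._run_credit >= dw.cue_dwell_s
        ):
            self.cue_found = True
        if (
            aoi == self.target_state
            and self._run_gate_open
            and self._run_credit >= dw.target_dwell_s
        ):
            self.success = True
            self.time_to_target = start + (dw.target_dwell_s - before)
        self.elapsed += d
        return d


@dataclass(frozen=True)
class EffectParams:
    """Generator effect sizes (the study conditions being emulated).

    The condition-linked parameters are scaled by a participant's
    *adaptivity* ``a``: adults have ``a = 1`` and toddlers follow a logistic
    ramp in age centered at ``ramp_center_months`` so that adaptive behavior
    becomes detectable around 2 years.
    """

    # fixation dynamics
    toddler_median_fixation_s: float = 0.50
    adult_median_fixation_s: float = 0.26
    fixation_sigma_log: float = 0.5
    toddler_stay_prob: float = 0.55
    adult_stay_prob: float = 0.25
    #: preference for saccades to grid-adjacent AOIs (short eye movements)
    proximity_weight: float = 3.0
    #: probability that a trial is attended at all; disengaged trials are
    #: mostly staring (high stay probability, no strategic biases)
    toddler_engagement: float = 0.40
    adult_engagement: float = 0.75
    disengaged_stay_prob: float = 0.945
    #: active-search attention span: an engaged trial falls back to the
    #: disengaged staring dynamics after this much unrewarded search time
    toddler_giveup_s: float = 5.0
    adult_giveup_s: float = 10.0
    # condition-linked exploration biases (scaled by adaptivity)
    cue_attraction_uniform: float = 2.0
    knowledge_skewed: float = 4.5
    guided_target_boost: float = 5.0
    # group-linked biases (age-independent)
    toddler_cue_bias: float = 1.35
    adult_target_bias: float = 1.30
    #: extra engagement in the familiar, predictable context; strongest for
    #: non-adaptive (young) participants, fading as adaptivity ramps up
    skewed_familiarity_engagement: float = 0.24
    # anticipatory looks
    p_anticipate_skewed_base: float = 0.22
    p_anticipate_skewed_gain: float = 0.30
    p_anticipate_uniform: float = 0.25
    # age ramp
    ramp_center_months: float = 24.0
    ramp_width_months: float = 3.0
    # between-participant heterogeneity (condition-independent)
    engagement_kappa: float = 8.0  # Beta concentration around the group mean
    stay_jitter_sd: float = 0.06
    fixation_jitter_sd_log: float = 0.15

    def null_version(self) -> "EffectParams":
        """Zero every condition-linked effect (for type-I-error studies)."""
        return replace(
            self,
            cue_attraction_uniform=0.0,
            knowledge_skewed=0.0,
            guided_target_boost=0.0,
            skewed_familiarity_engagement=0.0,
            p_anticipate_skewed_base=self.p_anticipate_uniform,
            p_anticipate_skewed_gain=0.0,
        )


@dataclass(frozen=True)
class CohortConfig:
    """Sample sizes, trial structure and effect parameters."""

    n_toddlers: int = 60
    n_adults: int = 42
    n_blocks_per_condition: int = 2
    n_test_trials: int = 4
    effects: EffectParams = field(default_factory=EffectParams)
    dwell: DwellCriteria = field(default_factory=DwellCriteria)
    null_mode: bool = False

    def __post_init__(self) -> None:
        if min(self.n_toddlers, self.n_adults) < 1:
            raise ValueError("cohort needs at least one participant per group")
        if min(self.n_blocks_per_condition, self.n_test_trials) < 1:
            raise ValueError("blocks and trials per block must be positive")

    @property
    def effective_effects(self) -> EffectParams:
        return self.effects.null_version() if self.null_mode else self.effects


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant generative parameters."""

    participant_id: str
    group: str  # younger-toddler | older-toddler | adult
    age_months: float | None
    scan_rate: float  # expected fixations per second
    median_fixation_s: float
    stay_prob: float
    engagement: float  # probability a trial is attended
    giveup_s: float  # active-search attention span within a trial
    cue_attraction: float
    target_attraction: float
    adaptivity: float  # 0..1 ramp value; scales condition-linked biases
    p_anticipate: dict[str, float]

    @property
    def is_toddler(self) -> bool:
        return self.group != "adult"


@dataclass(frozen=True)
class TrialRecord:
    """One test trial's derived DVs plus participant metadata."""

    participant_id: str
    group: str
    age_months: float | None
    condition: str
    condition_order: int  # 1 if this condition came first, else 2
    block: int  # 1-4 within the session
    trial: int  # 1-4 within the block
    success: bool
    time_to_target: float | None
    scanning_count: int
    anticipatory_look: bool

    def __post_init__(self) -> None:
        if self.success != (self.time_to_target is not None):
            raise ValueError("time_to_target must be present iff success")
        if self.time_to_target is not None and not 0 < self.time_to_target <= 10:
            raise ValueError("time_to_target must lie in (0, 10]")
        if self.scanning_count < 0:
            raise ValueError("scanning_count must be nonnegative")


def _ramp(age_months: float, center: float, width: float) -> float:
    # Logistic in age; ~0.12 at center-width, ~0.88 at center+width.
    return 1.0 / (1.0 + math.exp(-(age_months - center) / (width / 2.0)))


def make_profile(
    participant_id: str,
    group_kind: str,
    effects: EffectParams,
    age_months: float | None = None,
    rng: np.random.Generator | None = None,
) -> ParticipantProfile:
    """Build a participant's generative profile from the effect parameters.

    ``group_kind`` is ``"toddler"`` (requires ``age_months``) or ``"adult"``.
    Passing an ``rng`` draws person-level variability (engagement, staying
    tendency, fixation tempo) around the group means; without it the profile
    sits exactly at those means.
    """
    if group_kind == "adult":
        adaptivity = 1.0
        median_fix = effects.adult_median_fixation_s
        stay = effects.adult_stay_prob
        engagement = effects.adult_engagement
        giveup = effects.adult_giveup_s
        cue_attr = 1.0
        target_attr = effects.adult_target_bias
        group = "adult"
    elif group_kind == "toddler":
        if age_months is None:
            raise ValueError("toddler profiles require age_months")
        adaptivity = _ramp(
            age_months, effects.ramp_center_months, effects.ramp_width_months
        )
        median_fix = effects.toddler_median_fixation_s
        stay = effects.toddler_stay_prob
        engagement = effects.toddler_engagement
        giveup = effects.toddler_giveup_s
        cue_attr = effects.toddler_cue_bias
        target_attr = 1.0
        group = "younger-toddler" if age_months < 24 else "older-toddler"
    else:
        raise ValueError(f"unknown group kind: {group_kind!r}")
    if rng is not None:
        kappa = effects.engagement_kappa
        if kappa > 0 and 0 < engagement < 1:
            engagement = float(
                rng.beta(engagement * kappa, (1 - engagement) * kappa)
            )
        stay = float(np.clip(stay + rng.normal(0, effects.stay_jitter_sd), 0.05, 0.97))
        median_fix *= float(rng.lognormal(0, effects.fixation_jitter_sd_log))
    mean_fix = median_fix * math.exp(effects.fixation_sigma_log**2 / 2)
    p_ant_skewed = (
        effects.p_anticipate_skewed_base
        + effects.p_anticipate_skewed_gain * adaptivity
    )
    return ParticipantProfile(
        participant_id=participant_id,
        group=group,
        age_months=age_months,
        scan_rate=1.0 / mean_fix,
        median_fixation_s=median_fix,
        stay_prob=stay,
        engagement=engagement,
        giveup_s=giveup,
        cue_attraction=cue_attr,
        target_attraction=target_attr,
        adaptivity=adaptivity,
        p_anticipate={SKEWED: min(p_ant_skewed, 1.0), UNIFORM: effects.p_anticipate_uniform},
    )


def _walk_weights(
    current: int | None,
    condition: str,
    cue_state: int,
    target_state: int,
    cue_found: bool,
    engaged: bool,
    profile: ParticipantProfile,
    effects: EffectParams,
    layout: SpatialLayout,
) -> list[float]:
    """Unnormalized move weights over the 8 AOIs (current AOI excluded)."""
    a = profile.adaptivity if engaged else 0.0
    weights = []
    for aoi in layout.states:
        if aoi == current:
            weights.append(0.0)
            continue
        w = 1.0
        if current is not None and aoi in layout.adjacency[current]:
            w *= effects.proximity_weight  # short saccades preferred
        if aoi in layout.cue_states:
            # once the cue is found, attention shifts to the target row
            if not (condition == UNIFORM and cue_found):
                w *= profile.cue_attraction if engaged else 1.0
            if condition == UNIFORM and not cue_found:
                w *= 1.0 + effects.cue_attraction_uniform * a
        else:
            w *= profile.target_attraction if engaged else 1.0
            if condition == SKEWED and aoi == target_state:
                w *= 1.0 + effects.knowledge_skewed * a
            if condition == UNIFORM and cue_found and aoi == target_state:
                w *= 1.0 + effects.guided_target_boost * a
        weights.append(w)
    return weights


def _weighted_pick(weights: list[float], rng: np.random.Generator) -> int:
    total = sum(weights)
    u = rng.random() * total
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1


def simulate_trial(
    profile: ParticipantProfile,
    condition: str,
    cue_state: int,
    target_state: int,
    layout: SpatialLayout,
    rng: np.random.Generator,
    effects: EffectParams | None = None,
    dwell: DwellCriteria | None = None,
) -> tuple[AOISequence, dict]:
    """Simulate one test trial's fixation path and score it.

    The first fixation lands in the correct column with the profile's
    anticipation probability.  Subsequent fixations follow a biased walk
    (with self-repeats at the profile's stay probability) and log-normal
    durations; the path stops as soon as the condition's dwell criterion is
    met or the 10 s search window closes.  Returns the sequence (with
    durations) and the DV fields computed by :func:`derive_trial_dvs`.
    """
    effects = effects or EffectParams()
    dwell = dwell or DwellCriteria()
    mu = math.log(profile.median_fixation_s)
    sigma = effects.fixation_sigma_log
    correct_col = layout.column_of(target_state)
    engagement = profile.engagement
    if condition == SKEWED:
        engagement = min(
            1.0,
            engagement
            + effects.skewed_familiarity_engagement * (1.0 - profile.adaptivity),
        )
    engaged = rng.random() < engagement

    # first fixation
    p_ant = profile.p_anticipate[condition]
    if rng.random() < p_ant:
        first = target_state if rng.random() < 0.5 else cue_state
    else:
        others = [s for s in layout.states if layout.column_of(s) != correct_col]
        first = int(others[rng.integers(len(others))])

    visits: list[int] = [first]
    durations: list[float] = []
    scorer = _DwellScorer(condition, cue_state, target_state, dwell)
    while True:
        current = visits[-1]
        d = scorer.observe(current, float(rng.lognormal(mu, sigma)))
        durations.append(d)
        if scorer.done:
            break
        # attention span: active search lapses into staring after giveup_s
        engaged_now = engaged and scorer.elapsed < profile.giveup_s
        stay_prob = profile.stay_prob if engaged_now else effects.disengaged_stay_prob
        if rng.random() < stay_prob:
            visits.append(current)
            continue
        weights = _walk_weights(
            current, condition, cue_state, target_state, scorer.cue_found,
            engaged_now, profile, effects, layout,
        )
        visits.append(_weighted_pick(weights, rng))

    seq = AOISequence(
        visits=tuple(visits),
        durations=tuple(durations),
        participant_id=profile.participant_id,
        group=profile.group,
        condition=condition,
    )
    dvs = derive_trial_dvs(seq, condition, cue_state, target_state, layout, dwell)
    return seq, dvs


def derive_trial_dvs(
    seq: AOISequence,
    condition: str,
    cue_state: int,
    target_state: int,
    layout: SpatialLayout,
    dwell: DwellCriteria | None = None,
) -> dict:
    """Apply the dwell/timeout rules to a fixation path, deterministically.

    Success in the Skewed condition requires a >=200 ms fixation on the
    target; in the Uniform condition the correct cue must first be fixated
    for >=150 ms, then the target for >=200 ms - fixating the target without
    the cue never succeeds.  Dwell credit starts at the onset latency and
    the criterion must complete inside the 10 s window.  ``time_to_target``
    is the elapsed time at which the target dwell criterion is reached;
    ``scanning_count`` is the number of between-column eye movements;
    ``anticipatory_look`` marks a first fixation already in the correct
    column.
    """
    dwell = dwell or DwellCriteria()
    if seq.durations is None:
        raise ValueError("sequence has no fixation durations")
    correct_col = layout.column_of(target_state)

    # Dwell accumulates over *consecutive* fixations on the same AOI: the
    # criterion asks for continuous gaze, not a single long fixation.
    scorer = _DwellScorer(condition, cue_state, target_state, dwell)
    for aoi, d in zip(seq.visits, seq.durations):
        scorer.observe(aoi, d)
        if scorer.done:
            break

    columns = [layout.column_of(a) for a in seq.visits]
    scanning = sum(1 for c1, c2 in zip(columns[:-1], columns[1:]) if c1 != c2)
    return {
        "success": scorer.success,
        "time_to_target": scorer.time_to_target,
        "scanning_count": scanning,
        "anticipatory_look": columns[0] == correct_col,
    }


def generate_cohort(
    config: CohortConfig,
    layout: SpatialLayout,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], list[AOISequence]]:
    """Generate the full synthetic study.

    Every participant completes both conditions (order counterbalanced),
    each with ``n_blocks_per_condition`` blocks of ``n_test_trials`` test
    trials.  Skewed blocks keep one target column throughout; Uniform blocks
    shuffle the four columns every four trials.  Toddler ages are uniform on
    [18, 36] months.
    """
    effects = config.effective_effects
    trials: list[TrialRecord] = []
    sequences: list[AOISequence] = []

    roster: list[tuple[str, float | None]] = []
    for i in range(config.n_toddlers):
        roster.append((f"t{i + 1:03d}", float(rng.uniform(18.0, 36.0))))
    for i in range(config.n_adults):
        roster.append((f"a{i + 1:03d}", None))

    cue_of_target = {t: c for c, t in layout.column_pairing.items()}
    for idx, (pid, age) in enumerate(roster):
        kind = "adult" if age is None else "toddler"
        profile = make_profile(pid, kind, effects, age_months=age, rng=rng)
        order = (SKEWED, UNIFORM) if idx % 2 == 0 else (UNIFORM, SKEWED)
        session_block = 0
        for cond_pos, condition in enumerate(order, start=1):
            for _ in range(config.n_blocks_per_condition):
                session_block += 1
                if condition == SKEWED:
                    col = int(rng.integers(4))
                    target_cols = [col] * config.n_test_trials
                else:
                    cols = list(rng.permutation(4))
                    target_cols = [
                        int(cols[t % 4]) for t in range(config.n_test_trials)
                    ]
                for t, col in enumerate(target_cols, start=1):
                    target_state = layout.target_states[col]
                    cue_state = cue_of_target[target_state]
                    seq, dvs = simulate_trial(
                        profile, condition, cue_state, target_state, layout, rng,
                        effects=effects, dwell=config.dwell,
                    )
                    seq = AOISequence(
                        visits=seq.visits,
                        durations=seq.durations,
                        participant_id=pid,
                        group=profile.group,
                        condition=condition,
                        block=session_block,
                        trial=t,
                    )
                    sequences.append(seq)
                    trials.append(
                        TrialRecord(
                            participant_id=pid,
                            group=profile.group,
                            age_months=age,
                            condition=condition,
                            condition_order=cond_pos,
                            block=session_block,
                            trial=t,
                            success=dvs["success"],
                            time_to_target=dvs["time_to_target"],
                            scanning_count=dvs["scanning_count"],
                            anticipatory_look=dvs["anticipatory_look"],
                        )
                    )
    return trials, sequences


def trials_to_frame(trials: list[TrialRecord], collapse_toddlers: bool = False):
    """Trial records as a DataFrame ready for the regression models.

    ``collapse_toddlers`` recodes the two toddler groups into a single
    ``"toddler"`` level for toddler-versus-adult comparisons.
    """
    import pandas as pd
    from dataclasses import asdict

    frame = pd.DataFrame([asdict(t) for t in trials])
    frame["success"] = frame["success"].astype(int)
    frame["anticipatory_look"] = frame["anticipatory_look"].astype(int)
    if collapse_toddlers:
        frame["group"] = np.where(frame["group"] == "adult", "adult", "toddler")
    return frame
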