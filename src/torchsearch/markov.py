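"""Scan-path complexity via Markov transition matrices and their entropy.

A sequence of AOI visits (gaze locations 0-7, or the states visited by the
Q-learning agent) is summarized by a row-stochastic 8 x 8 transition matrix
``P``.  Complexity is the matrix entropy

    H(P) = - sum_{i,j} P_ij * ln(P_ij)

reported on a log scale (``ln H``), so the all-uniform matrix - the random
search baseline where every transition has probability 12.5% - attains the
maximum, ``ln(8 ln 8) ~= 2.81``.  Systematic search concentrates rows on few
destinations and scores lower.

Transition matrices are estimated with a fixed-emission discrete Markov
model: each of the 8 locations is its own state, so the EM fit has a
closed-form optimum at the (smoothed) transition counts.  The estimator is
run with multiple random initializations, each carrying its own randomized
Dirichlet pseudocount, which yields the small between-initialization spread
used for confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .environment import SpatialLayout
from .stats import GLMResult

__all__ = [
    "AOISequence",
    "TransitionMatrix",
    "EntropyEstimate",
    "count_transition_matrix",
    "fit_transition_matrix",
    "matrix_entropy",
    "log_entropy",
    "random_baseline",
    "efficient_search_entropy",
    "entropy_group_model",
    "transition_difference_test",
    "N_STATES",
]

N_STATES = 8

#: Differences smaller than this are treated as exact ties when comparing
#: two transition matrices cell by cell.
TIE_TOLERANCE = 1e-12


@dataclass(frozen=True)
class AOISequence:
    """An ordered list of AOI visits with optional trial metadata.

    ``durations`` (seconds per fixation) are carried when the sequence comes
    from gaze data; agent trajectories leave them as None.
    """

    visits: tuple[int, ...]
    durations: tuple[float, ...] | None = None
    participant_id: str | None = None
    group: str | None = None
    condition: str | None = None
    block: int | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        if len(self.visits) < 1:
            raise ValueError("a sequence must contain at least one visit")
        if any(not 0 <= v < N_STATES for v in self.visits):
            raise ValueError("AOI ids must lie in 0..7")
        if self.durations is not None and len(self.durations) != len(self.visits):
            raise ValueError("durations must match visits in length")

    def __len__(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 8 x 8 transition probabilities."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected an {N_STATES}x{N_STATES} matrix")
        if (probs < -1e-12).any() or (probs > 1 + 1e-12).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1 within 1e-9")
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class EntropyEstimate:
    """One log-scale complexity value tagged by its provenance."""

    log_entropy: float
    group: str
    condition: str = "n/a"
    init_index: int = 0


def _as_visit_lists(seqs: Sequence[AOISequence | Sequence[int]]) -> list[list[int]]:
    out = []
    for seq in seqs:
        visits = list(seq.visits) if isinstance(seq, AOISequence) else list(seq)
        out.append(visits)
    return out


def _transition_counts(
    seqs: Sequence[AOISequence | Sequence[int]],
    concatenate: bool,
    collapse_repeats: bool = False,
) -> np.ndarray:
    counts = np.zeros((N_STATES, N_STATES))
    visit_lists = _as_visit_lists(seqs)
    if collapse_repeats:
        from itertools import groupby

        visit_lists = [[k for k, _ in groupby(v)] for v in visit_lists]
    if concatenate:
        visit_lists = [[v for visits in visit_lists for v in visits]]
    for visits in visit_lists:
        for i, j in zip(visits[:-1], visits[1:]):
            counts[i, j] += 1
    return counts


def count_transition_matrix(
    seqs: Sequence[AOISequence | Sequence[int]],
    pseudocount: float = 0.0,
    concatenate: bool = False,
    collapse_repeats: bool = False,
) -> TransitionMatrix:
    """Maximum-likelihood transition estimate from visit sequences.

    ``P_ij = (count(i->j) + pseudocount) / row total``.  By default no
    transition is counted across sequence boundaries; ``concatenate`` joins
    the sequences end to end first (the pooling used when many episodes are
    treated as one long scan path).  ``collapse_repeats`` merges consecutive
    identical fixations before counting, so the matrix describes eye
    *movements* rather than dwells.  Rows with no observations fall back to
    the uniform distribution, the maximum-entropy choice.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    counts = _transition_counts(seqs, concatenate, collapse_repeats)
    if counts.sum() == 0 and pseudocount == 0:
        raise ValueError("no transitions observed and pseudocount is zero")
    counts = counts + pseudocount
    row_totals = counts.sum(axis=1, keepdims=True)
    probs = np.full((N_STATES, N_STATES), 1.0 / N_STATES)
    observed = row_totals[:, 0] > 0
    probs[observed] = counts[observed] / row_totals[observed]
    return TransitionMatrix(probs)


def fit_transition_matrix(
    seqs: Sequence[AOISequence | Sequence[int]],
    rng: np.random.Generator,
    n_init: int = 30,
    pseudocount: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 100,
    concatenate: bool = False,
    collapse_repeats: bool = False,
) -> list[TransitionMatrix]:
    """Fit the fixed-emission Markov model with ``n_init`` initializations.

    Because the emission matrix is the identity (location = state), the
    states are fully observed and each EM iteration's expected transition
    counts equal the empirical counts; the fit therefore converges to the
    pseudocount-smoothed count estimate.  Each initialization draws its own
    row-stochastic starting matrix and uses it as a randomized Dirichlet
    prior with total weight ``8 * pseudocount`` per row (cell mean
    ``pseudocount``), so the ``n_init`` estimates scatter tightly around the
    count-based maximum-likelihood solution.  With ``pseudocount=0`` every
    initialization returns the pure count estimate.
    """
    if len(seqs) == 0:
        raise ValueError("at least one sequence is required")
    if n_init < 1:
        raise ValueError("n_init must be at least 1")
    counts = _transition_counts(seqs, concatenate, collapse_repeats)
    if counts.sum() == 0 and pseudocount == 0:
        raise ValueError("no transitions observed and pseudocount is zero")

    estimates: list[TransitionMatrix] = []
    for _ in range(n_init):
        init = rng.dirichlet(np.ones(N_STATES), size=N_STATES)
        prior = pseudocount * N_STATES * init  # E[prior_ij] = pseudocount
        transmat = init.copy()
        for _ in range(max_iter):
            # E-step with identity emissions: expected counts == counts.
            posterior_counts = counts + prior
            row_totals = posterior_counts.sum(axis=1, keepdims=True)
            new = np.full((N_STATES, N_STATES), 1.0 / N_STATES)
            observed = row_totals[:, 0] > 0
            new[observed] = posterior_counts[observed] / row_totals[observed]
            delta = np.abs(new - transmat).max()
            transmat = new
            if delta < tol:
                break
        estimates.append(TransitionMatrix(transmat))
    return estimates


def matrix_entropy(P: TransitionMatrix | np.ndarray) -> float:
    """Matrix entropy in nats, with the convention 0 * ln 0 = 0."""
    probs = P.probs if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    if not isinstance(P, TransitionMatrix):
        P = TransitionMatrix(probs)  # validates shape/stochasticity
        probs = P.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(probs), 0.0)
    return float(-terms.sum())


def log_entropy(P: TransitionMatrix | np.ndarray) -> float:
    """Natural log of the matrix entropy (the reported complexity scale)."""
    h = matrix_entropy(P)
    if h <= 0:
        raise ValueError("entropy is zero (deterministic chain); log undefined")
    return float(np.log(h))


def random_baseline() -> EntropyEstimate:
    """Complexity of unstructured search: every transition at 12.5%."""
    uniform = TransitionMatrix(np.full((N_STATES, N_STATES), 1.0 / N_STATES))
    return EntropyEstimate(log_entropy=log_entropy(uniform), group="random")


def efficient_search_entropy(
    spec,
    best_params,
    layout: SpatialLayout,
    rng: np.random.Generator,
    n_train: int = 300,
    n_init: int = 30,
    pseudocount: float = 0.5,
    concatenate: bool = True,
) -> tuple[EntropyEstimate, list[EntropyEstimate]]:
    """Complexity of the most efficient learned search in one condition.

    Trains the best agent, pools the visited-state sequences of all training
    episodes into one scan path (``concatenate``, the default, mirrors how a
    session of trials is analyzed as a single sequence), fits the Markov
    model and returns the mean log-entropy over initializations together
    with the per-initialization estimates.
    """
    from .qlearning import extract_sequences, train_agent

    _, episodes = train_agent(best_params, spec, layout, rng, n_train=n_train)
    seqs = extract_sequences(episodes)
    fits = fit_transition_matrix(
        seqs, rng, n_init=n_init, pseudocount=pseudocount, concatenate=concatenate
    )
    per_init = [
        EntropyEstimate(
            log_entropy=log_entropy(P),
            group="model",
            condition=spec.condition_name,
            init_index=i,
        )
        for i, P in enumerate(fits)
    ]
    mean_est = EntropyEstimate(
        log_entropy=float(np.mean([e.log_entropy for e in per_init])),
        group="model",
        condition=spec.condition_name,
    )
    return mean_est, per_init


def entropy_group_model(estimates: Sequence[EntropyEstimate]) -> GLMResult:
    """OLS of log-entropy on group, condition and their interaction.

    Compares against the intercept-only null via AIC, mirroring how the
    complexity estimates are analyzed across age groups and conditions.
    """
    import pandas as pd
    import statsmodels.formula.api as smf

    frame = pd.DataFrame(
        {
            "log_entropy": [e.log_entropy for e in estimates],
            "group": [e.group for e in estimates],
            "condition": [e.condition for e in estimates],
        }
    )
    if frame["group"].nunique() < 2 or frame["condition"].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 conditions")
    cell_sizes = frame.groupby(["group", "condition"]).size()
    if (cell_sizes < 2).any():
        raise ValueError("need at least 2 estimates per group x condition cell")

    full = smf.ols("log_entropy ~ group * condition", data=frame).fit()
    null = smf.ols("log_entropy ~ 1", data=frame).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    return GLMResult.from_statsmodels(full, family="gaussian", null_aic=float(null.aic))


def transition_difference_test(
    P_toddler: TransitionMatrix,
    P_adult: TransitionMatrix,
    layout: SpatialLayout,
) -> GLMResult:
    """Logistic test of where toddlers transition more than adults.

    Each ordered cell (i, j) contributes a binary outcome: 1 where the
    toddler probability exceeds the adult probability (exact ties dropped).
    The outcome is regressed, without an intercept, on indicators for the
    destination being a cue versus a target location - the two indicators
    partition the destinations, so the no-intercept parameterization gives
    one log-odds per destination type.  A positive cue coefficient means
    toddler-dominant transitions pile up on cue destinations.
    """
    import pandas as pd
    import statsmodels.api as sm

    diff = P_toddler.probs - P_adult.probs
    rows = []
    for i in range(N_STATES):
        for j in range(N_STATES):
            if abs(diff[i, j]) <= TIE_TOLERANCE:
                continue
            rows.append(
                {
                    "toddler_higher": int(diff[i, j] > 0),
                    "dest_is_cue": int(j in layout.cue_states),
                    "dest_is_target": int(j in layout.target_states),
                }
            )
    if not rows:
        raise ValueError("all cells tie: no data for the comparison")
    frame = pd.DataFrame(rows)
    model = sm.GLM(
        frame["toddler_higher"],
        frame[["dest_is_cue", "dest_is_target"]],
        family=sm.families.Binomial(),
    )
    return GLMResult.from_statsmodels(model.fit(), family="binomial")
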