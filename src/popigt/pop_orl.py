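"""Play-or-Pass Outcome-Representation Learning (PoP-ORL) model.

Four free parameters govern play/pass decisions on the task:

* ``A_rew`` — reward learning rate (step size of value updates after gains),
* ``A_pun`` — punishment learning rate (after losses),
* ``beta_f`` — sensitivity to win/loss *frequency* ignoring magnitude,
* ``beta_b`` — go bias, a constant tendency to play rather than pass.

Each deck j carries an expected value EV_j (magnitude-sensitive, delta-rule
on the scaled outcome) and an expected frequency EF_j (sign-sensitive,
delta-rule on sign(outcome)).  These integrate linearly into the value of
playing,

    V_j = EV_j + EF_j * beta_f + beta_b,

while the value of passing is fixed at 0, so the play probability is the
logistic of V_j and choices are Bernoulli.  Updates use A_rew when the
outcome is >= 0 and A_pun when it is negative; a $0 card counts as a gain
for learning-rate selection.  Optionally, the three non-presented decks
receive attenuated *fictive* frequency updates of opposite sign (with the
opposite-valence learning rate), mirroring the frequency mechanism of the
parent ORL model.  Passing produces no outcome and no update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .igt_task import (
    CANONICAL_DECKS,
    SessionLog,
    TaskConfig,
    TrialRecord,
    DataError,
    build_deck_schedules,
    generate_presentation_sequence,
)

DECK_INDEX = {d: i for i, d in enumerate(CANONICAL_DECKS)}


@dataclass(frozen=True)
class ORLParams:
    A_rew: float
    A_pun: float
    beta_f: float
    beta_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.A_rew <= 1.0 and 0.0 <= self.A_pun <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if not (math.isfinite(self.beta_f) and math.isfinite(self.beta_b)):
            raise ValueError("beta_f and beta_b must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.A_rew, self.A_pun, self.beta_f, self.beta_b])


@dataclass(frozen=True)
class ModelConfig:
    """Structural knobs of the update rule.

    outcome_scale divides raw currency before EV updates (so a +100 win is a
    +1 target); fictive_attenuation divides the pseudo-outcome sign used for
    the fictive frequency updates of non-presented decks.
    """

    outcome_scale: float = 100.0
    fictive_updating: bool = True
    fictive_attenuation: float = 3.0

    def __post_init__(self) -> None:
        if self.outcome_scale <= 0:
            raise ValueError("outcome_scale must be positive")


@dataclass
class LatentState:
    EV: np.ndarray
    EF: np.ndarray
    params: ORLParams

    @property
    def V(self) -> np.ndarray:
        return self.EV + self.EF * self.params.beta_f + self.params.beta_b


def init_state(params: ORLParams) -> LatentState:
    """Fresh state: EV = EF = 0, so V_j = beta_b for every deck."""
    return LatentState(np.zeros(4), np.zeros(4), params)


def play_probability(state: LatentState, deck: str) -> float:
    """Logistic probability of playing the presented deck."""
    v = float(state.V[DECK_INDEX[deck]])
    if v >= 0:
        return 1.0 / (1.0 + math.exp(-v))
    ev = math.exp(v)
    return ev / (1.0 + ev)


def update_state(
    state: LatentState,
    deck: str,
    choice: str,
    outcome: float,
    params: ORLParams,
    model_config: ModelConfig = ModelConfig(),
) -> LatentState:
    """One trial's state transition (returns a new state; inputs untouched).

    Pass leaves the state unchanged.  Play applies delta-rule updates to the
    presented deck's EV (target outcome/scale) and EF (target sign(outcome))
    with the valence-gated learning rate, plus fictive EF updates to the
    other decks when enabled.
    """
    if choice == "pass":
        if outcome != 0:
            raise DataError("pass trial with nonzero outcome")
        return LatentState(state.EV.copy(), state.EF.copy(), params)
    if choice != "play":
        raise DataError(f"invalid choice {choice!r}")
    ev = state.EV.copy()
    ef = state.EF.copy()
    j = DECK_INDEX[deck]
    lr = params.A_rew if outcome >= 0 else params.A_pun
    x = outcome / model_config.outcome_scale
    s = float(np.sign(outcome))
    ev[j] += lr * (x - ev[j])
    ef[j] += lr * (s - ef[j])
    if model_config.fictive_updating:
        lr_o = params.A_pun if outcome >= 0 else params.A_rew
        target = -s / model_config.fictive_attenuation
        for k in range(4):
            if k != j:
                ef[k] += lr_o * (target - ef[k])
    return LatentState(ev, ef, params)


# ---------------------------------------------------------------------------
# fast likelihood / simulation cores (numba)


@njit(cache=False)
def _loglik_core(deck_idx, played, outcomes, a_rew, a_pun, beta_f, beta_b,
                 scale, fictive, atten):  # pragma: no cover - exercised via wrapper
    ev = np.zeros(4)
    ef = np.zeros(4)
    ll = 0.0
    for t in range(deck_idx.shape[0]):
        j = deck_idx[t]
        v = ev[j] + ef[j] * beta_f + beta_b
        # numerically stable Bernoulli log-probability
        if v >= 0.0:
            lp_play = -math.log1p(math.exp(-v))
            lp_pass = -v + lp_play
        else:
            lp_pass = -math.log1p(math.exp(v))
            lp_play = v + lp_pass
        if played[t]:
            ll += lp_play
            x = outcomes[t] / scale
            if outcomes[t] >= 0.0:
                lr = a_rew
                lr_o = a_pun
                s = 1.0 if outcomes[t] > 0.0 else 0.0
            else:
                lr = a_pun
                lr_o = a_rew
                s = -1.0
            ev[j] += lr * (x - ev[j])
            ef[j] += lr * (s - ef[j])
            if fictive:
                tgt = -s / atten
                for k in range(4):
                    if k != j:
                        ef[k] += lr_o * (tgt - ef[k])
        else:
            ll += lp_pass
    return ll


@njit(cache=False)
def _simulate_core(deck_idx, uniforms, a_rew, a_pun, beta_f, beta_b,
                   scale, fictive, atten, win_amounts, loss_add):
    """Simulate choices on a fixed schedule.

    ``loss_add[d, k]`` is the loss added to the k-th play on deck d (cyclic
    outcome sequence already unrolled to presentations_per_deck plays).
    """
    n = deck_idx.shape[0]
    ev = np.zeros(4)
    ef = np.zeros(4)
    plays = np.zeros(4, dtype=np.int64)
    choices = np.zeros(n, dtype=np.int64)
    outs = np.zeros(n)
    for t in range(n):
        j = deck_idx[t]
        v = ev[j] + ef[j] * beta_f + beta_b
        if v >= 0.0:
            p = 1.0 / (1.0 + math.exp(-v))
        else:
            e = math.exp(v)
            p = e / (1.0 + e)
        if uniforms[t] < p:
            choices[t] = 1
            o = win_amounts[j] + loss_add[j, plays[j]]
            plays[j] += 1
            outs[t] = o
            x = o / scale
            if o >= 0.0:
                lr = a_rew
                lr_o = a_pun
                s = 1.0 if o > 0.0 else 0.0
            else:
                lr = a_pun
                lr_o = a_rew
                s = -1.0
            ev[j] += lr * (x - ev[j])
            ef[j] += lr * (s - ef[j])
            if fictive:
                tgt = -s / atten
                for k in range(4):
                    if k != j:
                        ef[k] += lr_o * (tgt - ef[k])
    return choices, outs


def session_arrays(session: SessionLog) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(deck index, played 0/1, outcome) arrays for the likelihood core."""
    n = len(session.trials)
    deck_idx = np.empty(n, dtype=np.int64)
    played = np.empty(n, dtype=np.bool_)
    outcomes = np.empty(n)
    for i, t in enumerate(session.trials):
        deck_idx[i] = DECK_INDEX[t.deck]
        played[i] = t.choice == "play" and not t.timeout
        outcomes[i] = t.outcome
    return deck_idx, played, outcomes


def log_likelihood(
    params: ORLParams,
    session: SessionLog,
    model_config: ModelConfig = ModelConfig(),
) -> float:
    """Bernoulli log-likelihood of a session's play/pass choices.

    The play probability for each trial is computed from the state *before*
    that trial's update; timeouts contribute as passes.  An empty session
    has log-likelihood 0.
    """
    if not session.trials:
        return 0.0
    deck_idx, played, outcomes = session_arrays(session)
    return float(
        _loglik_core(
            deck_idx, played, outcomes,
            params.A_rew, params.A_pun, params.beta_f, params.beta_b,
            model_config.outcome_scale, model_config.fictive_updating,
            model_config.fictive_attenuation,
        )
    )


def log_likelihood_reference(
    params: ORLParams,
    session: SessionLog,
    model_config: ModelConfig = ModelConfig(),
) -> float:
    """Literal trial-by-trial likelihood loop over the state objects.

    Slow but transparent; the fast core is required to agree with this to
    high precision.
    """
    state = init_state(params)
    ll = 0.0
    for t in session.trials:
        p = play_probability(state, t.deck)
        effective_choice = "pass" if t.timeout else t.choice
        if effective_choice == "play":
            ll += math.log(p)
        else:
            ll += math.log1p(-p)
        state = update_state(
            state, t.deck, effective_choice,
            0.0 if effective_choice == "pass" else t.outcome,
            params, model_config,
        )
    return ll


def _schedule_tables(config: TaskConfig) -> tuple[np.ndarray, np.ndarray]:
    schedules = config.schedules or build_deck_schedules(config.version)
    wins = np.zeros(4)
    loss_add = np.zeros((4, config.presentations_per_deck))
    for d, s in schedules.items():
        j = DECK_INDEX[d]
        wins[j] = s.win_amount
        for k in range(config.presentations_per_deck):
            loss_add[j, k] = s.outcome(k) - s.win_amount
    return wins, loss_add


def simulate_agent(
    params: ORLParams,
    task_config: TaskConfig,
    model_config: ModelConfig = ModelConfig(),
    seed: int | None = None,
    subject_id: str = "agent",
    wave: int = 1,
) -> SessionLog:
    """Generate a session from the model: Bernoulli choices on logistic V."""
    order = task_config.presentation_order or generate_presentation_sequence(
        task_config.n_trials, task_config.presentations_per_deck
    )
    deck_idx = np.array([DECK_INDEX[d] for d in order[: task_config.n_trials]],
                        dtype=np.int64)
    rng = np.random.default_rng(seed)
    uniforms = rng.random(task_config.n_trials)
    wins, loss_add = _schedule_tables(task_config)
    choices, outs = _simulate_core(
        deck_idx, uniforms,
        params.A_rew, params.A_pun, params.beta_f, params.beta_b,
        model_config.outcome_scale, model_config.fictive_updating,
        model_config.fictive_attenuation, wins, loss_add,
    )
    bank = task_config.starting_bank
    trials = []
    for t in range(task_config.n_trials):
        bank += outs[t]
        trials.append(TrialRecord(
            t, order[t], "play" if choices[t] else "pass", float(outs[t]), bank,
        ))
    return SessionLog(subject_id, wave, trials, task_config.version)
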