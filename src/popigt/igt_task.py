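"""Play-or-Pass Iowa Gambling Task environment.

The task presents one of four card decks on each trial and the participant
chooses to *play* (draw a card, receiving a net monetary outcome) or *pass*
(move on, bank unchanged).  Two decks (canonical labels A, B) lose money on
net across the task; two (C, D) gain on net.  Deck presentation order and the
sequence of outcomes within each deck are fixed across participants, so the
environment is fully deterministic given the task configuration; all
stochasticity lives in the policy making the play/pass decisions.

Two task versions exist which permute the mapping of physical deck positions
to payout schedules; analyses always operate on canonically recoded logs
(A, B bad; C, D good).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import yaml

CANONICAL_DECKS = ("A", "B", "C", "D")

#: physical position label -> canonical deck, per task version.  Version 1 is
#: the identity; version 2 swaps the bad pair with the good pair.
VERSION_MAPS = {
    1: {"P1": "A", "P2": "B", "P3": "C", "P4": "D"},
    2: {"P1": "C", "P2": "D", "P3": "A", "P4": "B"},
}


class ConfigurationError(ValueError):
    """Invalid task configuration (unknown version, inconsistent counts...)."""


class DataError(ValueError):
    """Malformed session data (unknown deck label, bad bank arithmetic...)."""


@dataclass(frozen=True)
class DeckSchedule:
    """Payout schedule of one canonical deck.

    Within each repeating block of ``block_length`` plays the deck pays
    ``win_amount`` on every card, and the cards at ``loss_pattern`` positions
    additionally carry the corresponding loss; the net outcome of a card is
    the sum of the two (so a +50 win with a −50 loss is a $0 card).
    """

    deck_label: str
    win_amount: float
    loss_pattern: tuple[float, ...]
    block_length: int = 10
    # which 0-based positions within a block carry the losses (fixed outcome
    # sequence; same for every participant)
    loss_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.deck_label not in CANONICAL_DECKS:
            raise ConfigurationError(f"unknown deck label {self.deck_label!r}")
        if self.win_amount <= 0:
            raise ConfigurationError("win_amount must be positive")
        if any(x > 0 for x in self.loss_pattern):
            raise ConfigurationError("loss_pattern entries must be <= 0")
        if len(self.loss_pattern) > self.block_length:
            raise ConfigurationError("loss_pattern longer than block")
        if len(self.loss_positions) != len(self.loss_pattern):
            raise ConfigurationError("loss_positions must align with loss_pattern")

    @property
    def net_per_block(self) -> float:
        return self.win_amount * self.block_length + float(sum(self.loss_pattern))

    def outcome(self, play_index: int) -> float:
        """Net outcome of the ``play_index``-th play on this deck (0-based)."""
        pos = play_index % self.block_length
        loss = 0.0
        for p, amount in zip(self.loss_positions, self.loss_pattern):
            if p == pos:
                loss += amount
        return self.win_amount + loss


@dataclass(frozen=True)
class TaskConfig:
    n_trials: int = 120
    presentations_per_deck: int = 30
    starting_bank: float = 2000.0
    timeout_seconds: float = 4.0  # metadata only; no RT model
    version: int = 1
    presentation_order: tuple[str, ...] = ()
    schedules: dict[str, DeckSchedule] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.version not in VERSION_MAPS:
            raise ConfigurationError(f"unknown task version {self.version!r}")
        if self.n_trials != 4 * self.presentations_per_deck:
            raise ConfigurationError("n_trials must equal 4 x presentations_per_deck")
        if self.presentation_order:
            counts = {d: self.presentation_order.count(d) for d in CANONICAL_DECKS}
            if any(c != self.presentations_per_deck for c in counts.values()):
                raise ConfigurationError(
                    "presentation_order must contain each deck exactly "
                    f"{self.presentations_per_deck} times, got {counts}"
                )


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 0-based
    deck: str
    choice: str  # "play" | "pass"
    outcome: float  # 0 when pass
    bank_after: float
    timeout: bool = False

    def __post_init__(self) -> None:
        if self.choice not in ("play", "pass"):
            raise DataError(f"invalid choice {self.choice!r}")
        if self.choice == "pass" and self.outcome != 0:
            raise DataError("pass trial with nonzero outcome")


@dataclass
class SessionLog:
    subject_id: str
    wave: int
    trials: list[TrialRecord]
    task_version: int = 1
    administration_modality: str = "onsite"

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials):
            if t.trial_index != i:
                raise DataError("trial indices must be consecutive from 0")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def final_bank(self) -> float:
        return self.trials[-1].bank_after if self.trials else np.nan


# ---------------------------------------------------------------------------
# schedules and presentation sequence


def build_deck_schedules(version: int = 1) -> dict[str, DeckSchedule]:
    """Canonical A–D payout schedules.

    Classic four-deck structure: bad decks win +100 per play (A spreads five
    moderate losses over a 10-play block, B concentrates one large −1250
    loss), good decks win +50 (C: five −50 losses, i.e. $0 cards; D: one
    −250), for −250 / +250 net per block.  ``version`` selects only the
    physical-position mapping (see :data:`VERSION_MAPS`); canonical payout
    structure is version-invariant.
    """
    if version not in VERSION_MAPS:
        raise ConfigurationError(f"unknown task version {version!r}")
    return {
        "A": DeckSchedule("A", 100.0, (-150.0, -200.0, -250.0, -300.0, -350.0),
                          10, (2, 4, 5, 7, 9)),
        "B": DeckSchedule("B", 100.0, (-1250.0,), 10, (8,)),
        "C": DeckSchedule("C", 50.0, (-50.0, -50.0, -50.0, -50.0, -50.0),
                          10, (1, 3, 6, 7, 9)),
        "D": DeckSchedule("D", 50.0, (-250.0,), 10, (9,)),
    }


def generate_presentation_sequence(
    n_trials: int = 120,
    presentations_per_deck: int = 30,
    build_seed: int = 20240,
) -> tuple[str, ...]:
    """Deterministic deck presentation order (fixed across participants).

    A balanced sequence is drawn once from ``build_seed``: each consecutive
    group of 4 trials contains every deck once, in seeded random order, so
    decks are evenly interleaved the way the task administers them.  The
    shipped default task file stores the sequence generated with the default
    seed.
    """
    if n_trials != 4 * presentations_per_deck:
        raise ConfigurationError("n_trials must equal 4 x presentations_per_deck")
    rng = np.random.default_rng(build_seed)
    seq: list[str] = []
    for _ in range(presentations_per_deck):
        block = list(CANONICAL_DECKS)
        rng.shuffle(block)
        seq.extend(block)
    return tuple(seq)


def default_task_config(version: int = 1) -> TaskConfig:
    """Load the shipped default task configuration fixture."""
    ref = resources.files("popigt.data").joinpath("default_task.yaml")
    raw = yaml.safe_load(ref.read_text())
    schedules = {
        d: DeckSchedule(
            d,
            float(s["win_amount"]),
            tuple(float(x) for x in s["loss_pattern"]),
            int(s["block_length"]),
            tuple(int(p) for p in s["loss_positions"]),
        )
        for d, s in raw["schedules"].items()
    }
    return TaskConfig(
        n_trials=int(raw["n_trials"]),
        presentations_per_deck=int(raw["presentations_per_deck"]),
        starting_bank=float(raw["starting_bank"]),
        timeout_seconds=float(raw["timeout_seconds"]),
        version=version,
        presentation_order=tuple(raw["presentation_order"]),
        schedules=schedules,
    )


# ---------------------------------------------------------------------------
# environment loop


def run_session(
    policy: Callable[[dict], str],
    config: TaskConfig,
    seed: int | None = None,
    subject_id: str = "sim",
    wave: int = 1,
    timeout_prob: float = 0.0,
) -> SessionLog:
    """Run one session of the task under ``policy``.

    ``policy`` receives a state dict (trial index, presented deck, bank,
    trial history so far) and returns ``"play"`` or ``"pass"``.  Outcomes
    follow the fixed per-deck outcome sequences; pass trials leave the bank
    unchanged.  With ``timeout_prob > 0`` a seeded fraction of trials times
    out and is coded as pass (with the timeout flag set), overriding the
    policy, as the task codes nonresponses.
    """
    order = config.presentation_order or generate_presentation_sequence(
        config.n_trials, config.presentations_per_deck
    )
    schedules = config.schedules or build_deck_schedules(config.version)
    rng = np.random.default_rng(seed)
    bank = config.starting_bank
    play_counts = {d: 0 for d in CANONICAL_DECKS}
    trials: list[TrialRecord] = []
    for t, deck in enumerate(order[: config.n_trials]):
        timed_out = bool(timeout_prob > 0 and rng.random() < timeout_prob)
        if timed_out:
            choice = "pass"
        else:
            choice = policy(
                {"trial_index": t, "deck": deck, "bank": bank, "history": trials}
            )
            if choice not in ("play", "pass"):
                raise DataError(f"policy returned invalid choice {choice!r}")
        if choice == "play":
            outcome = schedules[deck].outcome(play_counts[deck])
            play_counts[deck] += 1
            bank += outcome
        else:
            outcome = 0.0
        trials.append(TrialRecord(t, deck, choice, outcome, bank, timed_out))
    return SessionLog(subject_id, wave, trials, config.version)


def recode_to_canonical(raw_log: SessionLog, version: int | None = None) -> SessionLog:
    """Map physical deck positions (P1..P4) to canonical labels.

    Idempotent on logs already carrying canonical labels.
    """
    version = raw_log.task_version if version is None else version
    if version not in VERSION_MAPS:
        raise ConfigurationError(f"unknown task version {version!r}")
    mapping = VERSION_MAPS[version]
    new_trials = []
    for t in raw_log.trials:
        if t.deck in CANONICAL_DECKS:
            new_trials.append(t)
        elif t.deck in mapping:
            new_trials.append(replace(t, deck=mapping[t.deck]))
        else:
            raise DataError(f"unknown deck position label {t.deck!r}")
    return SessionLog(
        raw_log.subject_id, raw_log.wave, new_trials, version,
        raw_log.administration_modality,
    )


# ---------------------------------------------------------------------------
# CSV I/O (long session format)

SESSION_COLUMNS = [
    "subject_id", "wave", "trial", "deck", "choice", "timeout",
    "outcome", "bank_after", "version", "modality",
]


def sessions_to_csv(sessions: Sequence[SessionLog], path) -> None:
    """Write sessions as a long CSV; trial numbers are 1-based in files."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SESSION_COLUMNS)
        for s in sessions:
            for t in s.trials:
                w.writerow([
                    s.subject_id, s.wave, t.trial_index + 1, t.deck, t.choice,
                    int(t.timeout), f"{t.outcome:g}", f"{t.bank_after:g}",
                    s.task_version, s.administration_modality,
                ])


def sessions_from_csv(path) -> list[SessionLog]:
    out: dict[tuple[str, int], list[TrialRecord]] = {}
    meta: dict[tuple[str, int], tuple[int, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["subject_id"], int(row["wave"]))
            rec = TrialRecord(
                int(row["trial"]) - 1, row["deck"], row["choice"],
                float(row["outcome"]), float(row["bank_after"]),
                bool(int(row["timeout"])),
            )
            out.setdefault(key, []).append(rec)
            meta[key] = (int(row["version"]), row["modality"])
    sessions = []
    for (sid, wave), trials in out.items():
        trials.sort(key=lambda t: t.trial_index)
        version, modality = meta[(sid, wave)]
        sessions.append(SessionLog(sid, wave, trials, version, modality))
    return sessions
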