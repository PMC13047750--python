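"""Traditional summary-score scoring of Play-or-Pass IGT sessions.

Session-wide proportions of plays on the good decks (C, D) and bad decks
(A, B), plus their difference (net proportion play, a gross measure of
overall good performance).  Timeouts count as passes: they stay in the
denominator (a presentation happened) but not the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .igt_task import SessionLog

GOOD_DECKS = ("C", "D")
BAD_DECKS = ("A", "B")


@dataclass(frozen=True)
class SummaryScores:
    subject_id: str
    wave: int
    good_prop: float
    bad_prop: float

    @property
    def net(self) -> float:
        return self.good_prop - self.bad_prop


class UndefinedScoreError(ValueError):
    """A deck pair had zero presentations, leaving its proportion undefined."""


def compute_summary(session: SessionLog) -> SummaryScores:
    """Good/bad/net proportion play for one canonical session.

    Denominators are the number of presentations of the respective deck
    pair; numerators count non-timeout plays.
    """
    good_n = bad_n = good_plays = bad_plays = 0
    for t in session.trials:
        played = t.choice == "play" and not t.timeout
        if t.deck in GOOD_DECKS:
            good_n += 1
            good_plays += played
        elif t.deck in BAD_DECKS:
            bad_n += 1
            bad_plays += played
    if good_n == 0 or bad_n == 0:
        raise UndefinedScoreError(
            f"session {session.subject_id} wave {session.wave}: "
            f"{good_n} good and {bad_n} bad presentations"
        )
    return SummaryScores(
        session.subject_id, session.wave, good_plays / good_n, bad_plays / bad_n
    )


def score_sessions(sessions) -> pd.DataFrame:
    """Score many sessions into a tidy frame (one row per subject-wave)."""
    rows = []
    for s in sessions:
        sc = compute_summary(s)
        rows.append({
            "subject_id": sc.subject_id, "wave": sc.wave,
            "good_prop": sc.good_prop, "bad_prop": sc.bad_prop, "net": sc.net,
        })
    return pd.DataFrame(rows)
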