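"""Traditional scoring: good, bad, and net proportion play per session.

Reads results/study/sessions.csv and writes results/study/scores.csv.

Run:  python analysis/03_score_sessions.py
"""

from pathlib import Path

from popigt.igt_task import sessions_from_csv
from popigt.summary_scores import score_sessions

OUT = Path("results/study")


def main() -> None:
    sessions = sessions_from_csv(OUT / "sessions.csv")
    scores = score_sessions(sessions)
    scores.to_csv(OUT / "scores.csv", index=False)
    print(f"scored {len(scores)} sessions")
    print(scores.groupby("wave")[["good_prop", "bad_prop", "net"]]
          .mean().round(3).to_string())


if __name__ == "__main__":
    main()
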