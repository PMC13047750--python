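"""Secondary analyses: parameter-performance correlations and reliability.

Per wave, correlates each PoP-ORL parameter with net proportion play
(BH-FDR within each wave's four tests), and computes adjacent-wave
test-retest reliability for every metric.

Run:  python analysis/05_associations.py
"""

from pathlib import Path

import pandas as pd

from popigt.assoc_stats import metric_wide, param_performance_associations, test_retest
from popigt.growth_models import ALL_METRICS
from popigt.pipeline import assemble_long_table

OUT = Path("results/study")


def main() -> None:
    estimates = pd.read_csv(OUT / "estimates.csv")
    scores = pd.read_csv(OUT / "scores.csv")
    demographics = pd.read_csv(OUT / "demographics.csv")

    assoc = param_performance_associations(estimates, scores)
    assoc.to_csv(OUT / "associations.csv", index=False)
    sig = assoc[assoc["fdr_adjusted_p"] < 0.05]
    print(f"{len(sig)}/{len(assoc)} parameter-performance correlations "
          "significant after BH-FDR; strongest per wave:")
    best = assoc.loc[assoc.groupby("wave")["pearson_r"].idxmax()]
    print(best[["wave", "variable_pair", "pearson_r", "fdr_adjusted_p"]]
          .round(3).to_string(index=False))

    long_df = assemble_long_table(estimates, scores, demographics)
    rows = []
    for metric in ALL_METRICS:
        rel = test_retest(metric_wide(long_df, metric))
        rel.insert(0, "metric", metric)
        rows.append(rel)
    reliability = pd.concat(rows, ignore_index=True)
    reliability.to_csv(OUT / "test_retest.csv", index=False)
    print("\nadjacent-wave test-retest r (rows: metric, cols: wave pair):")
    print(reliability.pivot(index="metric", columns="wave_pair",
                            values="pearson_r").round(2).to_string())


if __name__ == "__main__":
    main()
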