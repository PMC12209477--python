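"""Correlate sentiment series with topic series and document counts.

Reads the stage tables written by 02 and 03 (stage decoupling: nothing is
refit here), computes Pearson correlations between each sentiment category's
quarterly presence proportions and (a) the per-quarter document count,
(b) each topic that passed the two-stage filter, and writes the correlation
table to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from discoursetrends.trendstats import format_p, pearson_corr


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    props = pd.read_csv(args.outdir / "sentiment_proportions.csv")
    tseries = pd.read_csv(args.outdir / "topic_series.csv")
    ttrends = pd.read_csv(args.outdir / "topic_trends.csv")
    selected = ttrends[ttrends["passes_trend_filter"]]["topic_id"].tolist()

    counts = props.groupby("quarter")["n_docs"].first().sort_index()
    rows = []
    for cat, g in props.groupby("category"):
        g = g.sort_values("quarter")
        y = g["proportion_pct"].to_numpy()
        res = pearson_corr(counts.to_numpy(dtype=float), y)
        rows.append({"x": cat, "y": "document_count", "r": round(res.r, 3),
                     "r_squared": round(res.r_squared, 3), "p": format_p(res.p_value), "n": res.n})
        for tid in selected:
            ts = tseries[tseries["topic_id"] == tid].sort_values("quarter")["mean_pct"].to_numpy()
            res = pearson_corr(ts, y)
            rows.append({"x": cat, "y": f"topic_{tid}", "r": round(res.r, 3),
                         "r_squared": round(res.r_squared, 3), "p": format_p(res.p_value), "n": res.n})
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "correlations.csv", index=False)

    strong = table[table["r"].abs() > 0.5]
    print(f"{len(table)} sentiment-series correlations computed "
          f"({len(selected)} filtered topics); {len(strong)} with |r| > 0.5")
    print(strong.to_string(index=False))
    print(f"table in {args.outdir}/correlations.csv")


if __name__ == "__main__":
    main()
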