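"""Pool posts into user-quarter documents and score sentiment presence.

Reads results/data/, writes per-quarter presence proportions and their
linear trends to results/, and prints the trend table (the per-category
percent of documents containing at least one dictionary word, with the
slope per quarter and its significance).
"""

import argparse
import json
from datetime import date
from pathlib import Path

import pandas as pd

from discoursetrends.corpus import build_vocabulary, filter_posts, pool_user_quarter, read_posts_jsonl
from discoursetrends.lexicon import load_liwc_dic, proportion_series, vocabulary_coverage
from discoursetrends.trendstats import format_p, ols_trend

STUDY_START = date(2021, 1, 1)
STUDY_END = date(2022, 12, 31)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    posts = filter_posts(read_posts_jsonl(args.datadir / "posts.jsonl"))
    docs = pool_user_quarter(posts, STUDY_START, STUDY_END)
    dic = load_liwc_dic(args.datadir / "dictionary.dic")
    manifest = json.loads((args.datadir / "manifest.json").read_text())
    scored = list(manifest["sentiment_expected"])

    series = proportion_series(docs, dic, scored)
    rows = [
        {"category": s.category_name, "quarter": q, "n_docs": n, "n_hit": h, "proportion_pct": pct}
        for s in series
        for q, n, h, pct in zip(s.quarters, s.n_docs, s.n_docs_hit, s.proportion_pct)
    ]
    pd.DataFrame(rows).to_csv(args.outdir / "sentiment_proportions.csv", index=False)

    trend_rows = []
    for s in series:
        t = ols_trend(s.proportion_pct)
        trend_rows.append(
            {"category": s.category_name, "overall_pct": round(s.overall_pct, 2),
             "beta0": round(t.beta0, 2), "beta1": round(t.beta1, 3),
             "r_squared": round(t.r_squared, 3), "p": format_p(t.p_value)}
        )
    trends = pd.DataFrame(trend_rows)
    trends.to_csv(args.outdir / "sentiment_trends.csv", index=False)

    vocab = build_vocabulary(docs)
    n_m, n_t, cov = vocabulary_coverage(vocab.terms, dic)
    print(f"{len(docs)} pooled documents; dictionary covers {n_m}/{n_t} corpus terms ({100*cov:.1f}%)")
    print("\nSentiment presence trends (percent of documents, slope per quarter):")
    print(trends.to_string(index=False))
    n_rising = int((trends["beta1"] > 0).sum())
    print(f"\n{n_rising}/{len(trends)} categories trend upward; tables in {args.outdir}/")


if __name__ == "__main__":
    main()
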