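"""End-to-end orchestration: preprocessing -> sentiment -> topics -> statistics.

``run`` executes the stages in order from a :class:`RunConfig`, writing every
intermediate table (CSV/TSV) plus a JSON report with provenance (config
hash, seed).  Stages are decoupled: every reported statistic can be
recomputed from the stage artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import corpus as corpus_mod
from . import dyntopics as dt
from . import lexicon as lex
from . import trendstats as ts
from .wordvec import read_word2vec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run", "count_series"]


@dataclass
class RunConfig:
    posts_path: str
    dictionary_path: str
    embeddings_path: str
    study_start: date
    study_end: date
    output_dir: str
    stopwords_path: str | None = None
    external_rates_path: str | None = None  # CSV: year, group, rate
    min_rate: float = 0.001
    weighting_scheme: str = "tfidf"
    k_w: int = 6
    k_range: tuple[int, int] = (2, 10)
    t_top: int = 20
    min_mean_pct: float = 3.5
    min_r2: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.posts_path, self.dictionary_path, self.embeddings_path,
                  self.stopwords_path, self.external_rates_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.min_rate < 1:
            raise ValueError("min_rate must be in (0,1)")
        if self.weighting_scheme not in ("count", "tfidf"):
            raise ValueError("weighting_scheme must be count or tfidf")
        if isinstance(self.study_start, str):
            self.study_start = date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = date.fromisoformat(self.study_end)
        self.k_range = tuple(self.k_range)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        d = asdict(self)
        d["study_start"] = str(d["study_start"])
        d["study_end"] = str(d["study_end"])
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: pd.DataFrame
    sentiment_table: pd.DataFrame
    coherence_table: pd.DataFrame
    k_best: int
    topic_table: pd.DataFrame
    selected_topics_stage1: list[int]
    selected_topics_stage2: list[int]
    correlation_table: pd.DataFrame
    artifact_dir: str
    artifacts: dict[str, str] = field(default_factory=dict)


def count_series(docs: list[corpus_mod.TokenDoc], T: int | None = None) -> pd.DataFrame:
    """Per-quarter pooled-document and unique-user counts."""
    if T is None:
        T = max((d.quarter_index for d in docs), default=-1) + 1
    n_docs = [0] * T
    users: list[set] = [set() for _ in range(T)]
    for d in docs:
        n_docs[d.quarter_index] += 1
        users[d.quarter_index].add(d.user_id)
    return pd.DataFrame(
        {"quarter": range(T), "n_documents": n_docs, "n_users": [len(u) for u in users]}
    )


def _load_stopwords(path) -> frozenset[str]:
    if path is None:
        return frozenset()
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline; idempotent for fixed config and seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, sep: str = ",") -> None:
        p = out / name
        df.to_csv(p, index=False, sep=sep)
        artifacts[name] = str(p)

    stage = "preprocess"
    try:
        posts = corpus_mod.read_posts_jsonl(config.posts_path)
        posts = corpus_mod.filter_posts(posts)
        stopwords = _load_stopwords(config.stopwords_path)
        docs = corpus_mod.pool_user_quarter(
            posts, config.study_start, config.study_end, stopwords=stopwords
        )
        if not docs:
            raise ValueError("no documents inside the study window")
        T = corpus_mod.quarter_of(config.study_end, config.study_start) + 1
        counts = count_series(docs, T)
        save(counts, "counts.csv")
        vocab = corpus_mod.build_vocabulary(docs, config.min_rate)
        corpus_mod.export_vocabulary_tsv(vocab, docs, out / "vocabulary.tsv")
        artifacts["vocabulary.tsv"] = str(out / "vocabulary.tsv")

        stage = "sentiment"
        dic = lex.load_liwc_dic(config.dictionary_path)
        scored_names = sorted(
            {dic.name_of(c) for cats in list(dic.exact.values()) + list(dic.prefix.values()) for c in cats}
        )
        sent_series = lex.proportion_series(docs, dic, scored_names)
        n_matched, n_terms, cov = lex.vocabulary_coverage(vocab.terms, dic)
        logger.info("dictionary coverage: %d/%d corpus terms (%.1f%%)", n_matched, n_terms, 100 * cov)
        sent_rows = []
        for s in sent_series:
            trend = ts.ols_trend(s.proportion_pct)
            for q, n, h, pct in zip(s.quarters, s.n_docs, s.n_docs_hit, s.proportion_pct):
                sent_rows.append(
                    {"category": s.category_name, "quarter": q, "n_docs": n, "n_hit": h, "proportion_pct": pct}
                )
        save(pd.DataFrame(sent_rows), "sentiment_proportions.csv")
        sentiment_table = pd.DataFrame(
            [
                {
                    "category": s.category_name,
                    "n_docs_hit": s.overall_n_hit,
                    "overall_pct": s.overall_pct,
                    **_trend_cols(ts.ols_trend(s.proportion_pct)),
                }
                for s in sent_series
            ]
        )
        save(sentiment_table, "sentiment_trends.csv")

        stage = "topics"
        emb = read_word2vec(config.embeddings_path)
        by_quarter: dict[int, list[corpus_mod.TokenDoc]] = {}
        for d in docs:
            by_quarter.setdefault(d.quarter_index, []).append(d)
        models = []
        for q in sorted(by_quarter):
            At = corpus_mod.build_dtm(by_quarter[q], vocab, config.weighting_scheme, quarter_index=q)
            models.append(dt.fit_window_nmf(At, config.k_w, seed=config.seed))
        B = dt.stack_window_topics(models)
        k_best, ctable = dt.select_num_topics(
            B, config.k_range, emb, t_top=config.t_top, seed=config.seed
        )
        coherence_table = pd.DataFrame(
            {
                "K": ctable.evaluated_range,
                "tc_w2v": [ctable.entries[k] for k in ctable.evaluated_range],
                "n_oov_top_terms": [ctable.oov_report[k] for k in ctable.evaluated_range],
            }
        )
        save(coherence_table, "coherence.csv")
        dyn = dt.fit_dynamic_nmf(B, k_best, seed=config.seed)
        top_rows = [
            {"topic_id": k, "rank": r + 1, "term": term}
            for k in range(dyn.K)
            for r, term in enumerate(dyn.top_terms[k][: config.t_top])
        ]
        save(pd.DataFrame(top_rows), "topic_top_terms.tsv", sep="\t")
        dists, doc_ids, q_per_doc = dt.doc_topic_distributions(models, dyn)
        doc_df = pd.DataFrame(dists, columns=[f"topic_{k}" for k in range(dyn.K)])
        doc_df.insert(0, "doc_id", doc_ids)
        doc_df.insert(1, "quarter", q_per_doc)
        save(doc_df, "doc_topics.csv")
        series = dt.topic_series(dists, q_per_doc)
        series_rows = [
            {"topic_id": s.dynamic_topic_id, "quarter": q, "mean_pct": pct}
            for s in series
            for q, pct in zip(s.quarters, s.per_quarter_pct)
        ]
        save(pd.DataFrame(series_rows), "topic_series.csv")
        topic_trends = {s.dynamic_topic_id: ts.ols_trend(s.per_quarter_pct) for s in series}
        topic_table = pd.DataFrame(
            [
                {
                    "topic_id": s.dynamic_topic_id,
                    "overall_mean_pct": s.overall_mean_pct,
                    **_trend_cols(topic_trends[s.dynamic_topic_id]),
                }
                for s in series
            ]
        )
        stage1, stage2 = dt.filter_topics(series, topic_trends, config.min_mean_pct, config.min_r2)
        topic_table["passes_mean_filter"] = topic_table["topic_id"].isin(stage1)
        topic_table["passes_trend_filter"] = topic_table["topic_id"].isin(stage2)
        save(topic_table, "topic_trends.csv")

        stage = "statistics"
        corr_rows = []
        sent_by_name = {s.category_name: s for s in sent_series}
        doc_count_series = counts["n_documents"].to_numpy(dtype=float)
        for name, s in sent_by_name.items():
            y = np.asarray(s.proportion_pct, dtype=float)
            res = ts.pearson_corr(doc_count_series[np.asarray(s.quarters)], y)
            corr_rows.append(_corr_row(name, "document_count", "quarterly", res))
            for s2 in series:
                if s2.dynamic_topic_id not in stage2:
                    continue
                res = ts.pearson_corr(s2.per_quarter_pct, y)
                corr_rows.append(_corr_row(name, f"topic_{s2.dynamic_topic_id}", "quarterly", res))
        if config.external_rates_path is not None:
            rates = pd.read_csv(config.external_rates_path)
            for group, gdf in rates.groupby("group"):
                gdf = gdf.sort_values("year")
                for name, s in sent_by_name.items():
                    yearly = ts.aggregate_yearly(np.asarray(s.proportion_pct, dtype=float))
                    m = min(len(yearly), len(gdf))
                    res = ts.pearson_corr(gdf["rate"].to_numpy()[:m], yearly[:m])
                    corr_rows.append(_corr_row(name, f"rate_{group}", "yearly_mean", res))
        correlation_table = pd.DataFrame(corr_rows)
        save(correlation_table, "correlations.csv")

        report = RunReport(
            config_hash=config.config_hash(),
            seed=config.seed,
            counts=counts,
            sentiment_table=sentiment_table,
            coherence_table=coherence_table,
            k_best=k_best,
            topic_table=topic_table,
            selected_topics_stage1=stage1,
            selected_topics_stage2=stage2,
            correlation_table=correlation_table,
            artifact_dir=str(out),
            artifacts=artifacts,
        )
        summary = {
            "config_hash": report.config_hash,
            "seed": report.seed,
            "n_documents": int(counts["n_documents"].sum()),
            "n_terms": len(vocab),
            "dictionary_coverage": cov,
            "k_best": k_best,
            "coherence_at_k_best": ctable.entries[k_best],
            "selected_topics_stage1": stage1,
            "selected_topics_stage2": stage2,
            "artifacts": artifacts,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        artifacts["report.json"] = str(out / "report.json")
        return report
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs in %s", stage, out)
        raise


def _trend_cols(t: ts.TrendResult) -> dict:
    return {
        "beta0": t.beta0,
        "beta1": t.beta1,
        "r_squared": t.r_squared,
        "p_value": t.p_value,
        "p_formatted": ts.format_p(t.p_value),
        "n": t.n,
    }


def _corr_row(x_name: str, y_name: str, agg: str, res: ts.CorrelationResult) -> dict:
    return {
        "x": x_name,
        "y": y_name,
        "aggregation": agg,
        "r": res.r,
        "r_squared": res.r_squared,
        "p_value": res.p_value,
        "p_formatted": ts.format_p(res.p_value),
        "n": res.n,
    }
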