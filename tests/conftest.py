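"""Shared fixtures: one desk-scale synthetic study, generated once per session."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from discoursetrends import dyntopics as dt
from discoursetrends.corpus import build_dtm, build_vocabulary, filter_posts, pool_user_quarter
from discoursetrends.synthcorpus import (
    default_spec,
    generate_corpus,
    generate_dictionary,
    generate_embeddings,
)

STUDY_START = date(2021, 1, 1)
STUDY_END = date(2022, 12, 31)


@pytest.fixture(scope="session")
def spec():
    return default_spec(seed=1)


@pytest.fixture(scope="session")
def corpus(spec):
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def truth(corpus):
    return corpus[1]


@pytest.fixture(scope="session")
def docs(corpus):
    posts, _ = corpus
    return pool_user_quarter(filter_posts(posts), STUDY_START, STUDY_END)


@pytest.fixture(scope="session")
def vocab(docs):
    return build_vocabulary(docs)


@pytest.fixture(scope="session")
def dictionary(spec):
    return generate_dictionary(spec)


@pytest.fixture(scope="session")
def embeddings(spec):
    return generate_embeddings(spec)


@pytest.fixture(scope="session")
def fitted(docs, vocab, spec):
    """Two-layer model at the planted topic count, shared across tests."""
    by_q: dict[int, list] = {}
    for d in docs:
        by_q.setdefault(d.quarter_index, []).append(d)
    models = [
        dt.fit_window_nmf(build_dtm(by_q[q], vocab, "tfidf", quarter_index=q), 6, seed=1)
        for q in sorted(by_q)
    ]
    B = dt.stack_window_topics(models)
    dyn = dt.fit_dynamic_nmf(B, spec.K_true, seed=1)
    dists, doc_ids, q_per_doc = dt.doc_topic_distributions(models, dyn)
    return {
        "models": models,
        "B": B,
        "dyn": dyn,
        "dists": dists,
        "doc_ids": doc_ids,
        "q_per_doc": q_per_doc,
    }


@pytest.fixture(scope="session")
def matched_topics(fitted, truth, vocab):
    """Hungarian matching of recovered dynamic topics to planted topics.

    Returns (cosine per planted topic, recovered->planted map).
    """
    from scipy.optimize import linear_sum_assignment

    widx = {w: i for i, w in enumerate(truth.vocab)}
    K = truth.topic_term_dists.shape[0]
    P = np.array(
        [
            [truth.topic_term_dists[k, widx[t]] if t in widx else 0.0 for t in vocab.terms]
            for k in range(K)
        ]
    )
    H = fitted["dyn"].H2
    Pn = P / np.linalg.norm(P, axis=1, keepdims=True)
    Hn = H / np.linalg.norm(H, axis=1, keepdims=True)
    C = Pn @ Hn.T
    rows, cols = linear_sum_assignment(-C)
    cosines = C[rows, cols]
    rec_to_planted = {int(c): int(r) for r, c in zip(rows, cols)}
    return cosines, rec_to_planted
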