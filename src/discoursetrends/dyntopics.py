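"""Two-layer NMF dynamic topic modeling with embedding-based coherence.

Layer one factorizes each quarter's document-term matrix ``A_t`` into
*window topics* — topics local to one time window.  The unit-normalized
window-topic-term rows from every quarter are stacked into a matrix ``B``,
which a second NMF factorizes into *dynamic topics* that link window topics
across time.  The number of dynamic topics is selected by TC-W2V coherence:
the mean pairwise cosine similarity among each topic's top terms' word
embeddings, averaged over topics.

Solver specifics (Frobenius objective, NNDSVD initialization, coordinate
descent) follow standard NMF topic-modeling practice; both layers are
deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .corpus import DocTermMatrix, Vocabulary
from .trendstats import TrendResult
from .wordvec import EmbeddingModel

logger = logging.getLogger(__name__)

__all__ = [
    "WindowTopicModel",
    "StackedTopicTermMatrix",
    "DynamicTopicModel",
    "CoherenceTable",
    "TopicSeries",
    "fit_window_nmf",
    "stack_window_topics",
    "fit_dynamic_nmf",
    "coherence_tcw2v",
    "model_coherence",
    "select_num_topics",
    "doc_topic_distributions",
    "topic_series",
    "filter_topics",
]

DEFAULT_MAX_ITER = 400
DEFAULT_TOL = 1e-4


@dataclass
class WindowTopicModel:
    quarter_index: int
    k_w: int
    W: np.ndarray  # documents x k_w
    H: np.ndarray  # k_w x |V|, rows unit-L2-normalized
    vocab: Vocabulary
    row_ids: list[str]
    top_terms: list[list[str]]
    converged: bool = True


@dataclass
class StackedTopicTermMatrix:
    """The matrix ``B``: one row per window topic across all quarters."""

    matrix: np.ndarray
    vocab: Vocabulary
    provenance: list[tuple[int, int]]  # (quarter_index, window_topic_index)


@dataclass
class DynamicTopicModel:
    K: int
    W2: np.ndarray  # window topics x K
    H2: np.ndarray  # K x |V|, rows unit-L2-normalized
    vocab: Vocabulary
    provenance: list[tuple[int, int]]
    assignment: np.ndarray  # window topic row -> dynamic topic (argmax, ties -> lowest)
    top_terms: list[list[str]]
    converged: bool = True


@dataclass
class CoherenceTable:
    entries: dict[int, float]
    evaluated_range: list[int]
    oov_report: dict[int, int] = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        best = max(self.entries.values())
        return min(k for k, v in self.entries.items() if v == best)


@dataclass
class TopicSeries:
    dynamic_topic_id: int
    quarters: list[int]
    per_quarter_pct: list[float]
    overall_mean_pct: float


# ---------------------------------------------------------------------------
# factorization layers


def _ranked_terms(h_row: np.ndarray, vocab: Vocabulary, n: int) -> list[str]:
    # descending weight, lexicographic tie-break
    order = np.lexsort((np.array(vocab.terms), -h_row))
    return [vocab.terms[j] for j in order[:n]]


def _fit_nmf(X, k: int, seed: int, max_iter: int, tol: float):
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(matrix shape)={min(X.shape)}")
    model = NMF(
        n_components=k,
        init="nndsvd",
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            W = model.fit_transform(X)
        except ConvergenceWarning:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(X)
            converged = False
            logger.warning("NMF did not converge within %d iterations", max_iter)
    H = model.components_
    # fold H row scales into W so H rows are unit-L2
    norms = np.linalg.norm(H, axis=1)
    norms_safe = np.where(norms > 0, norms, 1.0)
    H = H / norms_safe[:, None]
    W = W * norms_safe[None, :]
    return W, H, converged


def fit_window_nmf(
    At: DocTermMatrix,
    k_w: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_top_terms: int = 50,
) -> WindowTopicModel:
    """First-layer NMF on one quarter's document-term matrix."""
    W, H, converged = _fit_nmf(At.weights, k_w, seed, max_iter, tol)
    top = [_ranked_terms(H[k], At.vocab, n_top_terms) for k in range(k_w)]
    return WindowTopicModel(
        quarter_index=At.quarter_index,
        k_w=k_w,
        W=W,
        H=H,
        vocab=At.vocab,
        row_ids=list(At.row_ids),
        top_terms=top,
        converged=converged,
    )


def stack_window_topics(models: list[WindowTopicModel]) -> StackedTopicTermMatrix:
    """Stack every window topic's unit-normalized term row into ``B``,
    ordered by (quarter, window topic index)."""
    if not models:
        raise ValueError("no window models")
    vocab = models[0].vocab
    for m in models:
        if m.vocab is not vocab and m.vocab.terms != vocab.terms:
            raise ValueError("window models do not share one vocabulary")
    models = sorted(models, key=lambda m: m.quarter_index)
    rows, provenance = [], []
    for m in models:
        for k in range(m.k_w):
            rows.append(m.H[k])
            provenance.append((m.quarter_index, k))
    return StackedTopicTermMatrix(matrix=np.vstack(rows), vocab=vocab, provenance=provenance)


def fit_dynamic_nmf(
    B: StackedTopicTermMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    n_top_terms: int = 50,
) -> DynamicTopicModel:
    """Second-layer NMF over the stacked window-topic-term matrix."""
    W2, H2, converged = _fit_nmf(B.matrix, K, seed, max_iter, tol)
    assignment = np.argmax(W2, axis=1)  # np.argmax takes the lowest index on ties
    top = [_ranked_terms(H2[k], B.vocab, n_top_terms) for k in range(K)]
    return DynamicTopicModel(
        K=K,
        W2=W2,
        H2=H2,
        vocab=B.vocab,
        provenance=list(B.provenance),
        assignment=assignment,
        top_terms=top,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# coherence and model selection


def coherence_tcw2v(top_terms: list[str], emb: EmbeddingModel) -> float | None:
    """Mean pairwise cosine similarity among the terms' embedding vectors.

    Terms missing from the embedding are dropped; with fewer than two
    embedded terms the score is undefined (None).
    """
    vecs = [emb.get(t) for t in top_terms]
    vecs = [v for v in vecs if v is not None]
    if len(vecs) < 2:
        return None
    V = np.vstack(vecs)
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        V = V[norms > 0]
        if V.shape[0] < 2:
            return None
        norms = np.linalg.norm(V, axis=1)
    U = V / norms[:, None]
    G = U @ U.T
    m = G.shape[0]
    iu = np.triu_indices(m, k=1)
    return float(np.mean(G[iu]))


def model_coherence(
    dyn: DynamicTopicModel, emb: EmbeddingModel, t_top: int = 20
) -> tuple[float, int]:
    """Mean TC-W2V over the model's dynamic topics (top ``t_top`` terms each).

    Returns (mean score, count of top terms missing from the embedding).
    Topics with fewer than two embedded top terms are excluded with a warning.
    """
    scores = []
    oov = 0
    for k in range(dyn.K):
        terms = dyn.top_terms[k][:t_top]
        oov += sum(1 for t in terms if t not in emb)
        s = coherence_tcw2v(terms, emb)
        if s is None:
            logger.warning("dynamic topic %d: <2 embedded top terms, excluded from coherence", k)
            continue
        scores.append(s)
    if not scores:
        raise ValueError("no topic had >=2 embedded top terms")
    return float(np.mean(scores)), oov


def select_num_topics(
    B: StackedTopicTermMatrix,
    k_range: tuple[int, int],
    emb: EmbeddingModel,
    t_top: int = 20,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[int, CoherenceTable]:
    """Fit dynamic NMF for each K in ``k_range`` (inclusive) and pick the K
    with the highest mean TC-W2V coherence; ties go to the smallest K."""
    lo, hi = k_range
    lo = max(lo, 2)
    hi = min(hi, B.matrix.shape[0])
    if lo > hi:
        raise ValueError(f"empty usable topic-count range ({k_range})")
    entries: dict[int, float] = {}
    oov_report: dict[int, int] = {}
    for K in range(lo, hi + 1):
        dyn = fit_dynamic_nmf(B, K, seed=seed, max_iter=max_iter, tol=tol)
        entries[K], oov_report[K] = model_coherence(dyn, emb, t_top)
    table = CoherenceTable(entries=entries, evaluated_range=list(range(lo, hi + 1)), oov_report=oov_report)
    return table.best_k, table


# ---------------------------------------------------------------------------
# document-level distributions and series


def doc_topic_distributions(
    models: list[WindowTopicModel], dyn: DynamicTopicModel
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Map each document onto the K-simplex of dynamic topics.

    A document's window-topic weights (its W row, normalized to sum one) are
    pushed through its quarter's window->dynamic mixing (each window topic's
    sum-normalized W2 row) and renormalized.  All-zero W rows get a uniform
    distribution (logged).

    Returns (distributions, doc_ids, quarter_index per doc).
    """
    row_of = {pv: i for i, pv in enumerate(dyn.provenance)}
    # sum-normalized mixing rows; all-zero row -> one-hot at its assignment
    W2n = dyn.W2.copy()
    sums = W2n.sum(axis=1)
    zero = sums == 0
    if np.any(zero):
        for i in np.flatnonzero(zero):
            W2n[i, dyn.assignment[i]] = 1.0
        sums = W2n.sum(axis=1)
    W2n = W2n / sums[:, None]

    dists, doc_ids, quarters = [], [], []
    n_zero_docs = 0
    for m in sorted(models, key=lambda m: m.quarter_index):
        mix = np.vstack([W2n[row_of[(m.quarter_index, k)]] for k in range(m.k_w)])
        w = m.W
        wsum = w.sum(axis=1)
        for i in range(w.shape[0]):
            if wsum[i] == 0:
                d = np.full(dyn.K, 1.0 / dyn.K)
                n_zero_docs += 1
            else:
                d = (w[i] / wsum[i]) @ mix
                d = d / d.sum()
            dists.append(d)
            doc_ids.append(m.row_ids[i])
            quarters.append(m.quarter_index)
    if n_zero_docs:
        logger.warning("%d documents had all-zero topic weights; assigned uniform", n_zero_docs)
    return np.vstack(dists), doc_ids, np.asarray(quarters)


def topic_series(distributions: np.ndarray, quarter_per_doc: np.ndarray) -> list[TopicSeries]:
    """Per-quarter arithmetic mean of document topic distributions, percent."""
    quarters = sorted(set(int(q) for q in quarter_per_doc))
    K = distributions.shape[1]
    out = []
    overall = distributions.mean(axis=0) * 100.0
    per_q = {
        q: distributions[quarter_per_doc == q].mean(axis=0) * 100.0 for q in quarters
    }
    for k in range(K):
        out.append(
            TopicSeries(
                dynamic_topic_id=k,
                quarters=quarters,
                per_quarter_pct=[float(per_q[q][k]) for q in quarters],
                overall_mean_pct=float(overall[k]),
            )
        )
    return out


def filter_topics(
    series: list[TopicSeries],
    trends: dict[int, TrendResult],
    min_mean_pct: float = 3.5,
    min_r2: float = 0.1,
) -> tuple[list[int], list[int]]:
    """Two-stage topic filter.

    Stage 1 keeps topics whose overall mean proportion is at least
    ``min_mean_pct`` percent; stage 2 keeps, of those, topics whose trend
    R-squared strictly exceeds ``min_r2``.  Both stage outputs are returned.
    """
    stage1 = [s.dynamic_topic_id for s in series if s.overall_mean_pct >= min_mean_pct]
    stage2 = [k for k in stage1 if trends[k].r_squared > min_r2]
    return stage1, stage2
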