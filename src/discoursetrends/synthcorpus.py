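"""Synthetic corpus generator with planted, recoverable structure.

Real discourse corpora of this kind (millions of short timestamped posts)
cannot be redistributed, and the licensed sentiment dictionary and the
pretrained embedding model are inputs, not artifacts.  This module generates
all three with known ground truth so the full pipeline can be validated:

* documents are drawn at the pooled user-quarter level from a mixture of
  ``K_true`` planted topics, each owning a disjoint vocabulary block, with
  per-quarter prevalence following linear trends plus quarter-localized
  event spikes;
* sentiment-category words are injected per document with a per-quarter
  probability following its own trend (and optional spikes), so document
  presence proportions have a known trajectory;
* embeddings place each topic's words around a shared anchor direction, so
  TC-W2V coherence peaks when recovered topics align with planted blocks.

All randomness flows from the single ``seed`` in the spec; regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np

from .corpus import PostType, RawPost
from .lexicon import Category, SentimentDictionary, write_liwc_dic
from .wordvec import EmbeddingModel

__all__ = [
    "TopicTrajectory",
    "SentimentCategorySpec",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate_corpus",
    "generate_embeddings",
    "generate_dictionary",
]


@dataclass(frozen=True)
class TopicTrajectory:
    """Per-quarter prevalence weight: baseline + slope*t + event spikes."""

    baseline: float
    slope: float = 0.0
    spikes: tuple[tuple[int, float], ...] = ()


@dataclass(frozen=True)
class SentimentCategorySpec:
    """Injection probability trajectory for one dictionary category."""

    name: str
    parent: str
    n_words: int = 8
    baseline: float = 0.15
    slope: float = 0.0
    spikes: tuple[tuple[int, float], ...] = ()

    def probability(self, t: int) -> float:
        p = self.baseline + self.slope * t
        for q, amp in self.spikes:
            if q == t:
                p += amp
        return float(np.clip(p, 0.0, 1.0))

    @property
    def exact_words(self) -> list[str]:
        # last two words are covered by a prefix (wildcard) entry
        n_prefix = min(2, self.n_words - 1)
        return [f"{self.name}w{i}" for i in range(self.n_words - n_prefix)]

    @property
    def prefix_words(self) -> list[str]:
        n_prefix = min(2, self.n_words - 1)
        return [f"{self.name}x{i}" for i in range(n_prefix)]

    @property
    def words(self) -> list[str]:
        return self.exact_words + self.prefix_words


def _default_sentiments() -> tuple[SentimentCategorySpec, ...]:
    # hierarchy: affective_processes -> {positive_emotions, negative_emotions};
    # negative_emotions -> {anxiety, anger, sadness};
    # drives -> {affiliation, achievement, power, reward, risk}
    return (
        SentimentCategorySpec("positive_emotions", "affective_processes", baseline=0.30, slope=-0.01),
        SentimentCategorySpec("negative_emotions", "affective_processes", baseline=0.35, slope=0.03),
        SentimentCategorySpec("anxiety", "negative_emotions", baseline=0.12, slope=0.02, spikes=((5, 0.30),)),
        SentimentCategorySpec("anger", "negative_emotions", baseline=0.10, slope=0.02),
        SentimentCategorySpec("sadness", "negative_emotions", baseline=0.05, slope=0.005),
        SentimentCategorySpec("affiliation", "drives", baseline=0.15, slope=0.0),
        SentimentCategorySpec("achievement", "drives", baseline=0.20, slope=0.01),
        SentimentCategorySpec("power", "drives", baseline=0.25, slope=0.01),
        SentimentCategorySpec("reward", "drives", baseline=0.12, slope=0.01),
        SentimentCategorySpec("risk", "drives", baseline=0.35, slope=0.025),
    )


def _default_trajectories() -> tuple[TopicTrajectory, ...]:
    # one rising, one falling, one event-spike topic (same quarter as the
    # anxiety spike above), two stable
    return (
        TopicTrajectory(baseline=0.18, slope=0.025),
        TopicTrajectory(baseline=0.26, slope=-0.02),
        TopicTrajectory(baseline=0.12, slope=0.0, spikes=((5, 0.35),)),
        TopicTrajectory(baseline=0.22, slope=0.0),
        TopicTrajectory(baseline=0.22, slope=0.0),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults are the desk-scale study conditions."""

    T: int = 8
    users_per_quarter: float = 200.0
    posts_per_user: float = 2.0
    tokens_per_post: float = 20.0
    K_true: int = 5
    topic_vocab_size: int = 100
    background_vocab_size: int = 100
    background_weight: float = 0.2
    topic_trajectories: tuple[TopicTrajectory, ...] = field(default_factory=_default_trajectories)
    doc_concentration: float = 1.0
    sentiment_categories: tuple[SentimentCategorySpec, ...] = field(default_factory=_default_sentiments)
    embedding_dim: int = 50
    embedding_noise_sd: float = 0.1
    study_start: date = date(2021, 1, 1)
    post_level: bool = False  # emit one post per (user, post) instead of one per document
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.K_true < 1 or self.topic_vocab_size < 1:
            raise ValueError("degenerate spec: T, K_true, topic_vocab_size must be >= 1")
        if len(self.topic_trajectories) != self.K_true:
            raise ValueError("need one trajectory per planted topic")

    # --- vocabulary blocks (deterministic functions of the spec) ---

    def topic_block(self, k: int) -> list[str]:
        return [f"t{k}w{j:03d}" for j in range(self.topic_vocab_size)]

    @property
    def background_block(self) -> list[str]:
        return [f"bgw{j:03d}" for j in range(self.background_vocab_size)]

    @property
    def sentiment_words(self) -> list[str]:
        return [w for c in self.sentiment_categories for w in c.words]

    @property
    def all_words(self) -> list[str]:
        words = [w for k in range(self.K_true) for w in self.topic_block(k)]
        words += self.background_block + self.sentiment_words
        return words

    def prevalence(self) -> np.ndarray:
        """T x K_true simplex rows of planted topic prevalence."""
        P = np.zeros((self.T, self.K_true))
        for k, traj in enumerate(self.topic_trajectories):
            for t in range(self.T):
                w = traj.baseline + traj.slope * t
                for q, amp in traj.spikes:
                    if q == t:
                        w += amp
                P[t, k] = max(w, 0.0)
        row_sums = P.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError("topic trajectories give zero total prevalence in some quarter")
        return P / row_sums[:, None]


@dataclass
class GroundTruth:
    """Planted structure against which pipeline recovery is measured."""

    vocab: list[str]
    topic_term_dists: np.ndarray  # K_true x |vocab|, simplex rows
    prevalence: np.ndarray  # T x K_true, simplex rows
    doc_mixtures: dict[str, np.ndarray]  # doc_id -> K_true simplex
    doc_dominant: dict[str, int]
    sentiment_expected: dict[str, list[float]]  # category -> p_c(t)
    sentiment_realized: dict[str, list[float]]  # category -> realized fraction
    n_docs_per_quarter: list[int]


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


def generate_corpus(spec: SyntheticSpec) -> tuple[list[RawPost], GroundTruth]:
    """Draw a corpus of raw posts plus its ground truth.

    Per quarter: user count ~ Poisson; per user one pooled document whose
    topic mixture ~ Dirichlet(doc_concentration * prevalence[t]); tokens are
    drawn from the planted topic-term distributions (near-uniform over the
    topic's block with a mild Zipf tilt) mixed with a Zipf background; each
    sentiment category independently injects >= 1 of its words with
    probability p_c(t).  With ``post_level=True`` the document's tokens are
    split across the user's posts to exercise pooling.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])

    vocab = spec.all_words
    word_index = {w: i for i, w in enumerate(vocab)}
    V = len(vocab)

    # planted topic-term distributions over the full vocabulary
    topic_dists = np.zeros((spec.K_true, V))
    topic_words: list[np.ndarray] = []
    topic_probs: list[np.ndarray] = []
    for k in range(spec.K_true):
        block = spec.topic_block(k)
        w = _zipf_weights(len(block), exponent=0.25)  # mild tilt
        idx = np.array([word_index[t] for t in block])
        topic_dists[k, idx] = w
        topic_words.append(idx)
        topic_probs.append(w)
    bg_idx = np.array([word_index[t] for t in spec.background_block])
    bg_probs = _zipf_weights(len(bg_idx), exponent=0.5)

    prevalence = spec.prevalence()
    vocab_arr = np.array(vocab)

    posts: list[RawPost] = []
    doc_mixtures: dict[str, np.ndarray] = {}
    doc_dominant: dict[str, int] = {}
    sent_expected = {c.name: [c.probability(t) for t in range(spec.T)] for c in spec.sentiment_categories}
    sent_hits = {c.name: [0] * spec.T for c in spec.sentiment_categories}
    n_docs_per_quarter = [0] * spec.T

    quarter_days = 90  # posts timestamped inside the quarter; exact day irrelevant

    for t in range(spec.T):
        n_users = max(1, int(rng.poisson(spec.users_per_quarter)))
        n_docs_per_quarter[t] = n_users
        alpha = np.maximum(spec.doc_concentration * prevalence[t], 1e-6)
        q_start = _quarter_start(spec.study_start, t)
        for u in range(n_users):
            user_id = f"u{t:02d}_{u:04d}"
            doc_id = f"{user_id}:q{t}"
            mixture = rng.dirichlet(alpha)
            doc_mixtures[doc_id] = mixture
            doc_dominant[doc_id] = int(np.argmax(mixture))

            n_posts = 1 + int(rng.poisson(max(spec.posts_per_user - 1, 0)))
            post_lens = 1 + rng.poisson(max(spec.tokens_per_post - 1, 0), size=n_posts)
            n_tokens = int(post_lens.sum())

            is_bg = rng.random(n_tokens) < spec.background_weight
            topics = rng.choice(spec.K_true, size=n_tokens, p=mixture)
            token_idx = np.empty(n_tokens, dtype=int)
            for k in range(spec.K_true):
                mask = (~is_bg) & (topics == k)
                if mask.any():
                    token_idx[mask] = rng.choice(topic_words[k], size=int(mask.sum()), p=topic_probs[k])
            if is_bg.any():
                token_idx[is_bg] = rng.choice(bg_idx, size=int(is_bg.sum()), p=bg_probs)
            tokens = list(vocab_arr[token_idx])

            for c in spec.sentiment_categories:
                if rng.random() < sent_expected[c.name][t]:
                    sent_hits[c.name][t] += 1
                    n_inj = 1 + int(rng.poisson(0.5))
                    words = rng.choice(c.words, size=n_inj)
                    pos = rng.integers(0, len(tokens) + 1, size=n_inj)
                    for w, p_ in sorted(zip(words, pos), key=lambda x: -x[1]):
                        tokens.insert(int(p_), str(w))

            day = int(rng.integers(0, quarter_days))
            if spec.post_level and n_posts > 1:
                bounds = np.cumsum(post_lens)[:-1]
                # injection may have lengthened the doc; rescale boundaries
                bounds = (bounds * len(tokens) / max(n_tokens, 1)).astype(int)
                chunks = np.split(np.array(tokens, dtype=object), bounds)
            else:
                chunks = [np.array(tokens, dtype=object)]
            for pi, chunk in enumerate(chunks):
                ts = datetime.combine(q_start + timedelta(days=day), datetime.min.time())
                posts.append(
                    RawPost(
                        post_id=f"{doc_id}:p{pi}",
                        user_id=user_id,
                        timestamp=ts + timedelta(minutes=pi),
                        text=" ".join(str(x) for x in chunk),
                        post_type=PostType.ORIGINAL,
                    )
                )

    realized = {
        name: [h / n if n else float("nan") for h, n in zip(hits, n_docs_per_quarter)]
        for name, hits in sent_hits.items()
    }
    truth = GroundTruth(
        vocab=vocab,
        topic_term_dists=topic_dists,
        prevalence=prevalence,
        doc_mixtures=doc_mixtures,
        doc_dominant=doc_dominant,
        sentiment_expected=sent_expected,
        sentiment_realized=realized,
        n_docs_per_quarter=n_docs_per_quarter,
    )
    return posts, truth


def _quarter_start(study_start: date, t: int) -> date:
    month = study_start.month - 1 + 3 * t
    return date(study_start.year + month // 12, month % 12 + 1, 1)


def generate_embeddings(spec: SyntheticSpec) -> EmbeddingModel:
    """Topic-aligned embeddings: each planted topic's words cluster around a
    random unit anchor (Gaussian noise, renormalized); background and
    sentiment words get independent random unit vectors."""
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    dim = spec.embedding_dim

    def unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    vectors: dict[str, np.ndarray] = {}
    for k in range(spec.K_true):
        anchor = unit(rng.normal(size=dim))
        for w in spec.topic_block(k):
            vectors[w] = unit(anchor + rng.normal(scale=spec.embedding_noise_sd, size=dim))
    for w in spec.background_block + spec.sentiment_words:
        vectors[w] = unit(rng.normal(size=dim))
    return EmbeddingModel(vectors=vectors, dimension=dim)


def generate_dictionary(spec: SyntheticSpec, path=None) -> SentimentDictionary:
    """Build the fixture sentiment dictionary (LIWC .dic convention).

    Synthetic stand-in for a licensed hierarchical sentiment dictionary:
    parent categories mirror the affective-processes / negative-emotions /
    drives subtree; each scored category's words are exact entries except the
    last two, covered by one trailing-wildcard prefix entry.  Entries list
    only the category that owns the word (no roll-up), so each category's
    presence trajectory equals its own injection trajectory.
    """
    # declare parent categories that are not themselves scored categories
    scored = {c.name for c in spec.sentiment_categories}
    parents: list[str] = []
    for c in spec.sentiment_categories:
        if c.parent not in scored and c.parent not in parents:
            parents.append(c.parent)

    categories: list[Category] = []
    next_id = 1
    id_of: dict[str, int] = {}
    for p in parents:
        categories.append(Category(next_id, p, None))
        id_of[p] = next_id
        next_id += 1
    for c in spec.sentiment_categories:
        categories.append(Category(next_id, c.name, c.parent))
        id_of[c.name] = next_id
        next_id += 1

    exact: dict[str, frozenset[int]] = {}
    prefix: dict[str, frozenset[int]] = {}
    for c in spec.sentiment_categories:
        cid = frozenset({id_of[c.name]})
        for w in c.exact_words:
            exact[w] = cid
        if c.prefix_words:
            prefix[f"{c.name}x"] = cid

    d = SentimentDictionary(categories=categories, exact=exact, prefix=prefix)
    if path is not None:
        write_liwc_dic(d, path)
    return d


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The desk-scale study conditions with a chosen seed."""
    return replace(SyntheticSpec(seed=seed), **overrides)
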