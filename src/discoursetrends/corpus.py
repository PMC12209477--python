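"""Raw-post filtering, text normalization, user-quarter pooling and
document-term matrices.

The unit of analysis downstream is the *pooled document*: all of one user's
posts within one calendar quarter, merged into a single token list.  This
module takes timestamped raw posts, filters out reshares, normalizes and
tokenizes the text, pools by (user, quarter), builds the corpus-wide
vocabulary with a per-quarter document-frequency threshold, and assembles
one nonnegative document-term matrix per quarter (``A_t``).
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PostType",
    "RawPost",
    "TokenDoc",
    "Vocabulary",
    "DocTermMatrix",
    "filter_posts",
    "normalize_text",
    "tokenize",
    "whitespace_tokenizer",
    "quarter_of",
    "pool_user_quarter",
    "build_vocabulary",
    "build_dtm",
]


class PostType(str, Enum):
    ORIGINAL = "original"
    RETWEET = "retweet"
    QUOTE = "quote"
    REPLY = "reply"


@dataclass
class RawPost:
    """One timestamped short post.

    ``referenced_text`` carries the text of the post a quote or reply points
    at; it is discarded during filtering so only the author's own words are
    analyzed.
    """

    post_id: str
    user_id: str
    timestamp: datetime
    text: str
    post_type: PostType = PostType.ORIGINAL
    referenced_text: str | None = None


@dataclass
class TokenDoc:
    """One user's pooled, tokenized posts for one quarter."""

    doc_id: str
    user_id: str
    quarter_index: int
    tokens: list[str]


@dataclass
class Vocabulary:
    """Ordered (lexicographic) term list with a term -> column index map."""

    terms: list[str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("vocabulary terms must be unique")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class DocTermMatrix:
    """Per-quarter nonnegative documents x terms matrix (the ``A_t``)."""

    quarter_index: int
    row_ids: list[str]
    vocab: Vocabulary
    weights: sp.csr_matrix
    weighting_scheme: str  # "count" | "tfidf"


# ---------------------------------------------------------------------------
# filtering


def filter_posts(posts: Sequence[RawPost]) -> list[RawPost]:
    """Drop retweets; strip referenced text from quotes and replies.

    Originals pass through unchanged.  An unknown ``post_type`` raises a
    ``ValueError`` naming the offending post.
    """
    out: list[RawPost] = []
    for p in posts:
        try:
            ptype = PostType(p.post_type)
        except ValueError:
            raise ValueError(f"post {p.post_id!r}: unknown post_type {p.post_type!r}")
        if ptype is PostType.RETWEET:
            continue
        if ptype in (PostType.QUOTE, PostType.REPLY) and p.referenced_text is not None:
            p = RawPost(p.post_id, p.user_id, p.timestamp, p.text, ptype, None)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# normalization

_URL_RE = re.compile(r"https?://\S+", re.IGNORECASE)
_HASHTAG_RE = re.compile(r"[#＃]\S*")

# Unicode general categories removed wholesale: symbols and control/format
# marks. Punctuation is kept out of this set so tokenizer plug-ins can use it.
_REMOVED_CATEGORIES = {"So", "Sk", "Sc", "Sm", "Cf", "Co", "Cs"}

# Supplementary emoji/pictograph blocks (NFKC does not touch these).
_EMOJI_RANGES = (
    (0x1F000, 0x1FAFF),
    (0x2600, 0x27BF),
    (0xFE00, 0xFE0F),  # variation selectors
    (0x2190, 0x21FF),  # arrows
)


def _is_removed_char(ch: str) -> bool:
    cp = ord(ch)
    for lo, hi in _EMOJI_RANGES:
        if lo <= cp <= hi:
            return True
    return unicodedata.category(ch) in _REMOVED_CATEGORIES


def normalize_text(text: str) -> str:
    """Remove URLs, hashtags, emoji and symbol characters; lowercase and map
    full-width characters to half-width (NFKC)."""
    text = _URL_RE.sub(" ", text)
    text = _HASHTAG_RE.sub(" ", text)
    text = unicodedata.normalize("NFKC", text)
    text = "".join(" " if _is_removed_char(c) else c for c in text)
    text = text.lower()
    return re.sub(r"\s+", " ", text).strip()


# ---------------------------------------------------------------------------
# tokenization

Tokenizer = Callable[[str], list[str]]


def whitespace_tokenizer(text: str) -> list[str]:
    """Default tokenizer: split on whitespace, no lemmatization.

    A morphological analyzer (e.g. a MeCab wrapper emitting lemmas for verbs
    and adjectives) can be plugged in anywhere a tokenizer is accepted; it
    only needs to be a ``str -> list[str]`` callable.
    """
    return text.split()


def tokenize(
    text: str,
    tokenizer: Tokenizer = whitespace_tokenizer,
    stopwords: frozenset[str] | set[str] = frozenset(),
) -> list[str]:
    """Tokenize ``text`` and drop stopwords, preserving order.

    Tokenizer failures are logged and yield an empty token list rather than
    aborting a corpus run.
    """
    try:
        tokens = tokenizer(text)
    except Exception:  # noqa: BLE001 - plug-in tokenizers may fail arbitrarily
        logger.warning("tokenizer failed on document; skipping", exc_info=True)
        return []
    return [t for t in tokens if t and t not in stopwords]


# ---------------------------------------------------------------------------
# pooling


def quarter_of(ts: datetime | date, study_start: date) -> int:
    """0-based calendar-quarter index of ``ts`` relative to the study start.

    Quarters are calendar quarters (Jan-Mar, Apr-Jun, ...); ``study_start``
    must be the first day of a quarter.
    """
    if (study_start.month - 1) % 3 != 0 or study_start.day != 1:
        raise ValueError("study window must start on a quarter boundary")
    return (ts.year - study_start.year) * 4 + (ts.month - 1) // 3 - (study_start.month - 1) // 3


def pool_user_quarter(
    posts: Sequence[RawPost],
    study_start: date,
    study_end: date,
    tokenizer: Tokenizer = whitespace_tokenizer,
    stopwords: frozenset[str] | set[str] = frozenset(),
    pre_normalized: bool = False,
) -> list[TokenDoc]:
    """Merge each user's posts within one calendar quarter into one document.

    Tokens are concatenated in timestamp order.  Posts outside
    [study_start, study_end] are excluded (count logged).  Returns documents
    sorted by (quarter_index, user_id).
    """
    n_quarters = quarter_of(study_end, study_start) + 1
    buckets: dict[tuple[str, int], list[tuple[datetime, list[str]]]] = {}
    dropped = 0
    for p in posts:
        ts_date = p.timestamp.date() if isinstance(p.timestamp, datetime) else p.timestamp
        if ts_date < study_start or ts_date > study_end:
            dropped += 1
            continue
        q = quarter_of(p.timestamp, study_start)
        text = p.text if pre_normalized else normalize_text(p.text)
        toks = tokenize(text, tokenizer, stopwords)
        buckets.setdefault((p.user_id, q), []).append((p.timestamp, toks))
    if dropped:
        logger.info("pool_user_quarter: %d posts outside study window dropped", dropped)

    docs: list[TokenDoc] = []
    for (user_id, q), items in sorted(buckets.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        items.sort(key=lambda it: it[0])
        tokens = [t for _, toks in items for t in toks]
        docs.append(TokenDoc(doc_id=f"{user_id}:q{q}", user_id=user_id, quarter_index=q, tokens=tokens))
    assert all(d.quarter_index < n_quarters for d in docs)
    return docs


# ---------------------------------------------------------------------------
# vocabulary


def build_vocabulary(docs: Sequence[TokenDoc], min_rate: float = 0.001) -> Vocabulary:
    """Build the global vocabulary with a per-quarter document-frequency cut.

    A term is retained iff, in at least one quarter, the fraction of that
    quarter's documents containing it is >= ``min_rate``.  The resulting term
    order is lexicographic, so the vocabulary is deterministic for a given
    corpus and threshold.
    """
    if not 0 < min_rate < 1:
        raise ValueError("min_rate must be in (0, 1)")
    if not docs:
        raise ValueError("empty corpus")

    quarters: dict[int, list[TokenDoc]] = {}
    for d in docs:
        quarters.setdefault(d.quarter_index, []).append(d)

    retained: set[str] = set()
    for q, qdocs in quarters.items():
        n_docs = len(qdocs)
        if n_docs == 0:
            logger.warning("quarter %d has no documents; skipped", q)
            continue
        df: dict[str, int] = {}
        for d in qdocs:
            for t in set(d.tokens):
                df[t] = df.get(t, 0) + 1
        threshold = min_rate * n_docs
        retained.update(t for t, c in df.items() if c >= threshold)
    return Vocabulary(sorted(retained))


def build_dtm(
    docs: Sequence[TokenDoc],
    vocab: Vocabulary,
    scheme: str = "tfidf",
    quarter_index: int | None = None,
) -> DocTermMatrix:
    """Assemble one quarter's document-term matrix.

    ``count`` rows are raw in-vocabulary term counts.  ``tfidf`` rows are
    tf * log(N/df) computed within the quarter, then scaled to unit Euclidean
    norm (zero rows left as zero).  Out-of-vocabulary tokens are silently
    dropped; all-zero rows are permitted but logged.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    if scheme not in ("count", "tfidf"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if quarter_index is None:
        qset = {d.quarter_index for d in docs}
        if len(qset) != 1:
            raise ValueError("docs span multiple quarters; pass quarter_index explicitly")
        quarter_index = qset.pop()

    n, v = len(docs), len(vocab)
    rows, cols, vals = [], [], []
    for i, d in enumerate(docs):
        counts: dict[int, int] = {}
        for t in d.tokens:
            j = vocab.index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    mat = sp.csr_matrix((np.asarray(vals, dtype=float), (rows, cols)), shape=(n, v))

    zero_rows = int(n - np.count_nonzero(mat.getnnz(axis=1)))
    if zero_rows:
        logger.info("build_dtm: quarter %d has %d all-zero rows", quarter_index, zero_rows)

    if scheme == "tfidf":
        df = (mat > 0).sum(axis=0).A1  # docs containing each term, this quarter
        idf = np.zeros(v)
        nz = df > 0
        idf[nz] = np.log(n / df[nz])
        mat = mat.multiply(idf).tocsr()
        norms = sp.linalg.norm(mat, axis=1)
        inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
        mat = sp.diags(inv) @ mat

    return DocTermMatrix(
        quarter_index=quarter_index,
        row_ids=[d.doc_id for d in docs],
        vocab=vocab,
        weights=mat.tocsr(),
        weighting_scheme=scheme,
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_posts_jsonl(path) -> list[RawPost]:
    """Read posts from JSONL (one object per line, UTF-8)."""
    import json

    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            posts.append(
                RawPost(
                    post_id=obj["post_id"],
                    user_id=obj["user_id"],
                    timestamp=datetime.fromisoformat(obj["timestamp"]),
                    text=obj["text"],
                    post_type=PostType(obj.get("post_type", "original")),
                    referenced_text=obj.get("referenced_text"),
                )
            )
    return posts


def write_posts_jsonl(posts: Iterable[RawPost], path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            obj = {
                "post_id": p.post_id,
                "user_id": p.user_id,
                "timestamp": p.timestamp.isoformat(),
                "text": p.text,
                "post_type": PostType(p.post_type).value,
            }
            if p.referenced_text is not None:
                obj["referenced_text"] = p.referenced_text
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def export_vocabulary_tsv(vocab: Vocabulary, docs: Sequence[TokenDoc], path) -> None:
    """Write term / index / max per-quarter document frequency as TSV."""
    quarters: dict[int, list[TokenDoc]] = {}
    for d in docs:
        quarters.setdefault(d.quarter_index, []).append(d)
    max_df = {t: 0.0 for t in vocab.terms}
    for qdocs in quarters.values():
        n = len(qdocs)
        df: dict[str, int] = {}
        for d in qdocs:
            for t in set(d.tokens):
                if t in vocab:
                    df[t] = df.get(t, 0) + 1
        for t, c in df.items():
            max_df[t] = max(max_df[t], c / n)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tindex\tmax_quarter_doc_freq\n")
        for t in vocab.terms:
            fh.write(f"{t}\t{vocab.index[t]}\t{max_df[t]:.6f}\n")
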