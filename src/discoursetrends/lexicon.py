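"""LIWC-format dictionary parsing and document-presence sentiment scoring.

The scoring statistic is the *document presence proportion*: for each
dictionary category and each quarter, the percentage of pooled documents
containing at least one word of that category.  Scoring is binary at the
document level — repeated hits do not count extra — which matches word-based
sentiment analysis with hierarchical category dictionaries of the LIWC
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import TokenDoc

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "SentimentDictionary",
    "SentimentSeries",
    "load_liwc_dic",
    "match_token",
    "score_document",
    "proportion_series",
    "vocabulary_coverage",
]


@dataclass(frozen=True)
class Category:
    category_id: int
    name: str
    parent_name: str | None = None


@dataclass
class SentimentDictionary:
    """Hierarchical category -> word-pattern dictionary.

    Entries are either exact words or prefix stems (written ``stem*`` in the
    .dic source; stored without the wildcard).  One pattern may belong to
    several categories.
    """

    categories: list[Category]
    exact: dict[str, frozenset[int]]
    prefix: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        self._by_id = {c.category_id: c for c in self.categories}
        declared = set(self._by_id)
        used = set().union(*self.exact.values(), *self.prefix.values(), frozenset())
        undeclared = used - declared
        if undeclared:
            raise ValueError(f"entries reference undeclared categories: {sorted(undeclared)}")

    def name_of(self, category_id: int) -> str:
        return self._by_id[category_id].name

    def id_of(self, name: str) -> int:
        for c in self.categories:
            if c.name == name:
                return c.category_id
        raise KeyError(name)

    @property
    def n_entries(self) -> int:
        return len(self.exact) + len(self.prefix)


@dataclass
class SentimentSeries:
    """Per-quarter presence counts and percentages for one category."""

    category_name: str
    quarters: list[int]
    n_docs: list[int]
    n_docs_hit: list[int]
    proportion_pct: list[float]  # NaN where a quarter has no documents
    overall_n_hit: int
    overall_pct: float


# ---------------------------------------------------------------------------
# parsing


def load_liwc_dic(path) -> SentimentDictionary:
    """Parse a LIWC-convention .dic file.

    Layout: a category header block delimited by ``%`` lines, each line
    ``id<TAB>name[<TAB>parent_name]``; then entry lines
    ``pattern<TAB>cat_id[<TAB>cat_id...]``.  A trailing ``*`` on a pattern
    marks prefix matching.  Duplicate (pattern, kind) pairs merge their
    category sets.
    """
    categories: list[Category] = []
    exact: dict[str, set[int]] = {}
    prefix: dict[str, set[int]] = {}
    declared: set[int] = set()

    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    in_header = False
    header_done = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line == "%":
            if not header_done and not in_header:
                in_header = True
            elif in_header:
                in_header = False
                header_done = True
            continue
        parts = line.split("\t")
        if in_header:
            cid = int(parts[0])
            name = parts[1]
            parent = parts[2] if len(parts) > 2 and parts[2] else None
            categories.append(Category(cid, name, parent))
            declared.add(cid)
        else:
            pattern = parts[0]
            if not pattern:
                raise ValueError(f"{path}:{lineno}: empty pattern")
            try:
                cids = {int(x) for x in parts[1:]}
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed category id") from exc
            bad = cids - declared
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: entry {pattern!r} references undeclared categories {sorted(bad)}"
                )
            if pattern.endswith("*"):
                stem = pattern[:-1]
                if not stem:
                    raise ValueError(f"{path}:{lineno}: bare wildcard pattern")
                prefix.setdefault(stem, set()).update(cids)
            else:
                exact.setdefault(pattern, set()).update(cids)

    if not categories or (not exact and not prefix):
        raise ValueError(f"{path}: empty dictionary")
    return SentimentDictionary(
        categories=categories,
        exact={p: frozenset(c) for p, c in exact.items()},
        prefix={p: frozenset(c) for p, c in prefix.items()},
    )


def write_liwc_dic(d: SentimentDictionary, path) -> None:
    """Serialize back to the .dic convention (used by fixture generation)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%\n")
        for c in d.categories:
            if c.parent_name:
                fh.write(f"{c.category_id}\t{c.name}\t{c.parent_name}\n")
            else:
                fh.write(f"{c.category_id}\t{c.name}\n")
        fh.write("%\n")
        for pattern in sorted(d.exact):
            ids = "\t".join(str(i) for i in sorted(d.exact[pattern]))
            fh.write(f"{pattern}\t{ids}\n")
        for stem in sorted(d.prefix):
            ids = "\t".join(str(i) for i in sorted(d.prefix[stem]))
            fh.write(f"{stem}*\t{ids}\n")


# ---------------------------------------------------------------------------
# matching & scoring


def match_token(token: str, d: SentimentDictionary) -> frozenset[int]:
    """Category ids matched by ``token``: the exact entry equal to it plus
    every prefix entry whose stem is a prefix of it."""
    cats: set[int] = set(d.exact.get(token, frozenset()))
    # check all prefixes of the token against the stem map: O(len(token))
    for i in range(1, len(token) + 1):
        hit = d.prefix.get(token[:i])
        if hit:
            cats.update(hit)
    return frozenset(cats)


def score_document(doc: TokenDoc, d: SentimentDictionary) -> frozenset[str]:
    """Names of categories with at least one matching token in ``doc``."""
    cats: set[int] = set()
    for t in set(doc.tokens):
        cats.update(match_token(t, d))
    return frozenset(d.name_of(c) for c in cats)


def proportion_series(
    docs: Sequence[TokenDoc],
    d: SentimentDictionary,
    categories: Iterable[str] | None = None,
) -> list[SentimentSeries]:
    """Per-quarter and overall document presence proportions (percent).

    Quarters with zero documents yield NaN proportions (excluded from any
    downstream regression).  Deterministic and order-independent.
    """
    names = list(categories) if categories is not None else [c.name for c in d.categories]
    if not docs:
        raise ValueError("no documents")
    quarters = sorted({doc.quarter_index for doc in docs})
    q_pos = {q: i for i, q in enumerate(quarters)}
    n_docs = [0] * len(quarters)
    hits = {name: [0] * len(quarters) for name in names}

    for doc in docs:
        i = q_pos[doc.quarter_index]
        n_docs[i] += 1
        present = score_document(doc, d)
        for name in names:
            if name in present:
                hits[name][i] += 1

    out = []
    total_docs = sum(n_docs)
    for name in names:
        n_hit = hits[name]
        pct = [100.0 * h / n if n > 0 else float("nan") for h, n in zip(n_hit, n_docs)]
        overall = sum(n_hit)
        out.append(
            SentimentSeries(
                category_name=name,
                quarters=quarters,
                n_docs=list(n_docs),
                n_docs_hit=n_hit,
                proportion_pct=pct,
                overall_n_hit=overall,
                overall_pct=100.0 * overall / total_docs,
            )
        )
    return out


def vocabulary_coverage(terms: Iterable[str], d: SentimentDictionary) -> tuple[int, int, float]:
    """Fraction of corpus vocabulary matched by >= 1 dictionary entry.

    Returns (n_matched, n_terms, fraction) — a coverage audit statistic,
    reported but never asserted against.
    """
    terms = list(terms)
    matched = sum(1 for t in terms if match_token(t, d))
    return matched, len(terms), matched / len(terms) if terms else float("nan")
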