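"""Name normalization, string similarity and annotation suggestions.

The "re-use first" step: when an item needs an annotation, entries with
similar names are retrieved from the term index and proposed before any
vocabulary lookup, so curated codes win over raw terminology hits and the
same meaning converges on the same signature across models.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

import edlib

from .odm_model import AnnotationSignature

if TYPE_CHECKING:  # pragma: no cover
    from .repository import TermIndex, TermIndexEntry
    from .vocabulary import Vocabulary

DEFAULT_THRESHOLD = 0.6
DEFAULT_LIMIT = 20

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_name(text: str) -> str:
    """Canonical form of an element name for indexing and comparison.

    Casefold (which also expands sharp-s to "ss"), decompose accented letters
    and drop their combining marks, replace every remaining non-alphanumeric
    character by a space, collapse whitespace and trim.  Idempotent.

    >>> normalize_name("Größe (cm)")
    'grosse cm'
    """
    text = unicodedata.normalize("NFKD", text.casefold())
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = _NON_ALNUM.sub(" ", text)
    return " ".join(text.split())


def levenshtein(a: str, b: str) -> int:
    """Exact edit distance (unit costs), via edlib's banded alignment."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def similarity(a: str, b: str) -> float:
    """Similarity in [0, 1] between two *normalized* names.

    The larger of two cheap, explainable measures: Jaccard similarity of the
    token sets (order-insensitive, catches reordered multi-word names) and
    1 - Levenshtein(a, b) / max(|a|, |b|) (catches typos and inflections).
    Symmetric; 1.0 for equal strings; two empty strings are defined equal.
    """
    if a == b:
        return 1.0
    ta, tb = set(a.split()), set(b.split())
    jaccard = len(ta & tb) / len(ta | tb) if (ta or tb) else 1.0
    lev = 1.0 - levenshtein(a, b) / max(len(a), len(b))
    return max(jaccard, lev)


def search_similar(index: "TermIndex", name: str,
                   threshold: float = DEFAULT_THRESHOLD,
                   limit: int = DEFAULT_LIMIT) -> list["TermIndexEntry"]:
    """Term-index entries whose name is similar to *name*.

    Ranked by similarity descending, then usage count descending, then
    canonical signature ascending; truncated to *limit*.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    query = normalize_name(name)
    scored = []
    for entry in index.entries.values():
        sim = similarity(query, entry.normalized_name)
        if sim >= threshold:
            scored.append((sim, entry))
    scored.sort(key=lambda t: (-t[0], -t[1].count, t[1].signature.canonical))
    return [entry for _, entry in scored[:limit]]


# ---------------------------------------------------------------------------
# Suggestions
# ---------------------------------------------------------------------------

Origin = Literal["repository", "vocabulary"]


@dataclass(frozen=True)
class Suggestion:
    """One candidate signature for a human reviewer to accept or reject.

    ``origin`` records whether the codes are curated re-use from the term
    index (``repository``) or a raw terminology hit (``vocabulary``); the
    distinction is what lets reviewers prefer curated codes.
    """

    signature: AnnotationSignature
    origin: Origin
    similarity: float
    count: int = 0
    example_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must be in [0, 1]")
        if self.origin == "repository" and self.count < 1:
            raise ValueError("repository suggestions must carry a usage count >= 1")


@dataclass
class SuggestionList:
    query_name: str
    suggestions: list[Suggestion] = field(default_factory=list)

    def __iter__(self):
        return iter(self.suggestions)

    def __len__(self) -> int:
        return len(self.suggestions)


def suggest(index: "TermIndex", vocab: "Vocabulary", item_name: str,
            threshold: float = DEFAULT_THRESHOLD,
            limit: int = DEFAULT_LIMIT) -> SuggestionList:
    """Ranked annotation candidates for one element name.

    Repository-origin suggestions (from :func:`search_similar`, merged per
    signature) always come first; vocabulary-origin suggestions from
    :func:`~odmannotate.vocabulary.find_concepts` are appended only while the
    repository yields fewer than *limit* candidates.  Vocabulary hits never
    outrank curated re-use, whatever their string similarity.
    """
    from .vocabulary import find_concepts  # deferred to avoid an import cycle

    query = normalize_name(item_name)

    merged: dict[str, dict] = {}
    for entry in search_similar(index, item_name, threshold, limit):
        sim = similarity(query, entry.normalized_name)
        slot = merged.setdefault(entry.signature.canonical, {
            "signature": entry.signature, "similarity": 0.0, "count": 0, "names": set(),
        })
        slot["similarity"] = max(slot["similarity"], sim)
        slot["count"] += entry.count
        slot["names"].add(entry.normalized_name)
    repo = [
        Suggestion(signature=s["signature"], origin="repository",
                   similarity=s["similarity"], count=s["count"],
                   example_names=tuple(sorted(s["names"])))
        for s in merged.values()
    ]
    repo.sort(key=lambda s: (-s.similarity, -s.count, s.signature.canonical))
    repo = repo[:limit]

    suggestions = list(repo)
    if len(suggestions) < limit:
        for record in find_concepts(vocab, item_name):
            if len(suggestions) >= limit:
                break
            suggestions.append(Suggestion(
                signature=AnnotationSignature.from_codes([record.code]),
                origin="vocabulary",
                similarity=similarity(query, normalize_name(record.preferred_term)),
                count=0,
                example_names=(record.preferred_term,),
            ))
    return SuggestionList(query_name=item_name, suggestions=suggestions)


def suggestions_to_tsv(sl: SuggestionList) -> str:
    lines = ["rank\torigin\tsignature\tsimilarity\tcount\texample_names"]
    for rank, s in enumerate(sl.suggestions, 1):
        lines.append(f"{rank}\t{s.origin}\t{s.signature.canonical}"
                     f"\t{s.similarity:.4f}\t{s.count}\t{'; '.join(s.example_names)}")
    return "\n".join(lines) + "\n"
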