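"""A pluggable, UMLS-like concept table.

A flat vocabulary (no hierarchy — semantic-network relations between
concepts are deliberately not modelled) used as the fallback when no curated
annotation exists in the term index.  The on-disk contract is a small TSV;
a real terminology export can be dropped in through the same contract.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .matching import normalize_name, similarity
from .odm_model import (AnnotationSignature, ConceptCode, EmptySignatureError,
                        OdmError)


class VocabularyFormatError(OdmError):
    """The vocabulary TSV violates its contract."""


class UnknownCodeError(OdmError):
    """A concept code is absent from the vocabulary."""


@dataclass
class ConceptRecord:
    code: ConceptCode
    preferred_term: str
    synonyms: list[str] = field(default_factory=list)
    semantic_type: str = ""

    def terms(self) -> list[str]:
        return [self.preferred_term, *self.synonyms]


class Vocabulary:
    """Concept records keyed by code, with a normalized-term lookup table."""

    def __init__(self, records: list[ConceptRecord] | None = None) -> None:
        self.records: dict[str, ConceptRecord] = {}
        for r in records or []:
            self.records[r.code.value] = r

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, code) -> bool:
        value = code.value if isinstance(code, ConceptCode) else str(code)
        return value in self.records


_COLUMNS = ["code", "term", "term_type", "semantic_type"]


def load_vocabulary(table_text: str) -> Vocabulary:
    """Parse a vocabulary TSV (columns: code, term, term_type, semantic_type).

    Every code must have exactly one row with term_type ``preferred``; any
    number of ``synonym`` rows may follow.  An empty input yields an empty,
    valid vocabulary.
    """
    stripped = table_text.strip()
    if not stripped:
        return Vocabulary()
    reader = csv.reader(io.StringIO(table_text), delimiter="\t")
    header = next(reader)
    if [h.strip() for h in header] != _COLUMNS:
        raise VocabularyFormatError(
            f"header must be {_COLUMNS}, got {header}")
    preferred: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    semantic_types: dict[str, str] = {}
    seen_terms: set[tuple[str, str]] = set()
    order: list[str] = []
    for lineno, row in enumerate(reader, 2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != 4:
            raise VocabularyFormatError(f"line {lineno}: expected 4 columns, got {len(row)}")
        code, term, term_type, semantic_type = (c.strip() for c in row)
        if (code, term) in seen_terms:
            raise VocabularyFormatError(f"line {lineno}: duplicate term {term!r} for code {code}")
        seen_terms.add((code, term))
        if code not in synonyms:
            synonyms[code] = []
            order.append(code)
        if term_type == "preferred":
            if code in preferred:
                raise VocabularyFormatError(
                    f"line {lineno}: code {code} has more than one preferred term")
            preferred[code] = term
            semantic_types[code] = semantic_type
        elif term_type == "synonym":
            synonyms[code].append(term)
        else:
            raise VocabularyFormatError(
                f"line {lineno}: term_type must be 'preferred' or 'synonym', got {term_type!r}")
    missing = [c for c in order if c not in preferred]
    if missing:
        raise VocabularyFormatError(f"codes without a preferred term: {missing}")
    return Vocabulary([
        ConceptRecord(ConceptCode(c), preferred[c], synonyms[c], semantic_types[c])
        for c in order
    ])


def save_vocabulary(vocab: Vocabulary) -> str:
    """Serialize back to the TSV contract (codes sorted, preferred row first)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(_COLUMNS)
    for code in sorted(vocab.records):
        r = vocab.records[code]
        writer.writerow([code, r.preferred_term, "preferred", r.semantic_type])
        for syn in sorted(r.synonyms):
            writer.writerow([code, syn, "synonym", r.semantic_type])
    return out.getvalue()


def find_concepts(vocab: Vocabulary, query: str) -> list[ConceptRecord]:
    """Records whose preferred term or any synonym contains all query tokens.

    Token containment is computed on normalized text; results are ranked by
    similarity of the preferred term to the query (descending), ties broken
    by code ascending — deterministic and independent of insertion order.
    """
    query_norm = normalize_name(query)
    query_tokens = set(query_norm.split())
    hits: list[tuple[float, str, ConceptRecord]] = []
    for record in vocab.records.values():
        for term in record.terms():
            if query_tokens <= set(normalize_name(term).split()):
                sim = similarity(query_norm, normalize_name(record.preferred_term))
                hits.append((sim, record.code.value, record))
                break
    hits.sort(key=lambda t: (-t[0], t[1]))
    return [record for _, _, record in hits]


def get_concept(vocab: Vocabulary, code: ConceptCode | str) -> ConceptRecord:
    value = code.value if isinstance(code, ConceptCode) else str(code)
    try:
        return vocab.records[value]
    except KeyError:
        raise UnknownCodeError(f"concept code {value!r} not in vocabulary") from None


def make_signature(vocab: Vocabulary, codes, strict: bool = False) -> AnnotationSignature:
    """Canonicalize a list of codes into a (possibly postcoordinated) signature.

    Duplicates collapse; when *strict*, every code must exist in the
    vocabulary.  An empty list raises :class:`EmptySignatureError`.
    """
    codes = [c if isinstance(c, ConceptCode) else ConceptCode(str(c)) for c in codes]
    if not codes:
        raise EmptySignatureError("cannot build a signature from zero codes")
    if strict:
        for c in codes:
            if c.value not in vocab.records:
                raise UnknownCodeError(f"concept code {c.value!r} not in vocabulary")
    return AnnotationSignature.from_codes(codes)
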