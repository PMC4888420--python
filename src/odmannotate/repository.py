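"""The term index: a local surrogate of a curated metadata repository.

Maps normalized element names to annotation signatures with usage counts and
form references.  The key is the (name, signature) combination — exactly the
unit a reviewer sees when deciding whether to re-use a curated code — and a
per-model contributions ledger makes updates retractable, so repeatedly
edited models never inflate counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .matching import normalize_name
from .odm_model import AnnotationSignature, DataModel, OdmError, annotation_targets


class DuplicateModelError(OdmError):
    """Two corpus models share a model_id."""


class MissingModelError(OdmError):
    """A referenced model_id cannot be resolved in the corpus store."""


class IndexFormatError(OdmError):
    """A persisted index file is malformed."""


Key = tuple[str, str]  # (normalized_name, signature canonical string)


@dataclass
class TermIndexEntry:
    """One (name, signature) combination with its usage statistics."""

    normalized_name: str
    signature: AnnotationSignature
    count: int
    refs: set[tuple[str, str]] = field(default_factory=set)  # (model_id, form_oid)

    @property
    def key(self) -> Key:
        return (self.normalized_name, self.signature.canonical)

    def __eq__(self, other) -> bool:
        return (isinstance(other, TermIndexEntry)
                and self.key == other.key
                and self.count == other.count
                and self.refs == other.refs)


# One ledger record per annotated element occurrence: the entry key it fed
# plus the form OIDs the element appeared on.
Contribution = tuple[Key, tuple[str, ...]]


class TermIndex:
    """Incrementally maintained map of (normalized name, signature) -> usage."""

    def __init__(self) -> None:
        self.entries: dict[Key, TermIndexEntry] = {}
        self.ledger: dict[str, list[Contribution]] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TermIndex):
            return NotImplemented
        return (self.entries == other.entries
                and {m: sorted(c) for m, c in self.ledger.items()}
                == {m: sorted(c) for m, c in other.ledger.items()})

    def total_count(self) -> int:
        return sum(e.count for e in self.entries.values())


def _model_contributions(model: DataModel,
                         include_codelist_entries: bool) -> list[tuple[Key, tuple[str, ...]]]:
    contribs: list[tuple[Key, tuple[str, ...]]] = []
    item_forms = {it.oid: tuple(model.forms_of_item(it.oid)) for it in model.items}
    # a code-list entry inherits the forms of every item using its code list
    codelist_forms: dict[str, tuple[str, ...]] = {}
    for it in model.items:
        if it.codelist_ref:
            prev = codelist_forms.get(it.codelist_ref, ())
            codelist_forms[it.codelist_ref] = tuple(dict.fromkeys(prev + item_forms[it.oid]))

    for oid, kind, name, annotation in annotation_targets(model, include_codelist_entries):
        if annotation is None:
            continue
        if kind == "item":
            forms = item_forms[oid]
        else:
            forms = codelist_forms.get(oid.partition(":")[0], ())
        contribs.append(((normalize_name(name), annotation.canonical), forms))
    return contribs


def update_index(index: TermIndex, model: DataModel,
                 include_codelist_entries: bool = True) -> TermIndex:
    """Fold one model into the index, replacing any earlier contribution.

    If the model_id is already present its previous contributions are fully
    retracted first (counts decremented, emptied entries removed, its refs
    dropped), then the model's current annotations are added.  Idempotent for
    an unchanged model.  The index is modified in place and returned.
    """
    previous = index.ledger.pop(model.model_id, [])
    touched: set[Key] = set()
    for key, _forms in previous:
        entry = index.entries[key]
        entry.count -= 1
        touched.add(key)
    for key in touched:
        entry = index.entries[key]
        if entry.count <= 0:
            del index.entries[key]
        else:
            entry.refs = {r for r in entry.refs if r[0] != model.model_id}

    contribs = _model_contributions(model, include_codelist_entries)
    for (name, canonical), forms in contribs:
        key = (name, canonical)
        entry = index.entries.get(key)
        if entry is None:
            entry = TermIndexEntry(name, AnnotationSignature.parse(canonical), 0)
            index.entries[key] = entry
        entry.count += 1
        for form_oid in forms or ("",):
            entry.refs.add((model.model_id, form_oid))
    if contribs:
        index.ledger[model.model_id] = contribs
    return index


def build_index(corpus: Iterable[DataModel],
                include_codelist_entries: bool = True) -> TermIndex:
    """Build a fresh index over a corpus of models.

    Equivalent to folding :func:`update_index` over the corpus in any order.
    Raises :class:`DuplicateModelError` when two models share a model_id.
    """
    index = TermIndex()
    seen: set[str] = set()
    for model in corpus:
        if model.model_id in seen:
            raise DuplicateModelError(f"duplicate model_id {model.model_id!r} in corpus")
        seen.add(model.model_id)
        update_index(index, model, include_codelist_entries)
    return index


def lookup_exact(index: TermIndex, name: str) -> list[TermIndexEntry]:
    """All entries for exactly this (normalized) name.

    Sorted by usage count descending; ties broken by canonical signature
    ascending, so the most re-used signature is proposed first.
    """
    query = normalize_name(name)
    matches = [e for e in index.entries.values() if e.normalized_name == query]
    matches.sort(key=lambda e: (-e.count, e.signature.canonical))
    return matches


def form_context(index: TermIndex, entry: TermIndexEntry,
                 corpus_store: dict[str, DataModel]) -> list[tuple[str, str, str]]:
    """Resolve an entry's references to (model_id, form_oid, form_name) rows.

    This is the review context: the forms on which a name/signature
    combination was used, so a human can judge whether the meaning matches.
    Raises :class:`MissingModelError` for an unresolvable model_id.
    """
    if index.entries.get(entry.key) is not entry and entry.key not in index.entries:
        raise KeyError(f"entry {entry.key!r} does not belong to this index")
    rows: list[tuple[str, str, str]] = []
    for model_id, form_oid in sorted(entry.refs):
        model = corpus_store.get(model_id)
        if model is None:
            raise MissingModelError(f"model {model_id!r} not found in corpus store")
        form_name = next((f.name for f in model.forms if f.oid == form_oid), "")
        rows.append((model_id, form_oid, form_name))
    return rows


# ---------------------------------------------------------------------------
# Persistence: JSON lines, one entry per line, refs sorted (diff-friendly).
# Ledger lines (top-level key "ledger_model") follow the entry lines so that
# replace-on-update still works after a round trip.
# ---------------------------------------------------------------------------


def save_index(index: TermIndex) -> str:
    lines = []
    for key in sorted(index.entries):
        e = index.entries[key]
        lines.append(json.dumps({
            "name": e.normalized_name,
            "signature": e.signature.canonical,
            "count": e.count,
            "refs": [{"model": m, "form": f} for m, f in sorted(e.refs)],
        }, ensure_ascii=False, sort_keys=True))
    for model_id in sorted(index.ledger):
        lines.append(json.dumps({
            "ledger_model": model_id,
            "contributions": [
                {"name": k[0], "signature": k[1], "forms": list(forms)}
                for k, forms in index.ledger[model_id]
            ],
        }, ensure_ascii=False, sort_keys=True))
    return "".join(line + "\n" for line in lines)


def load_index(text: str) -> TermIndex:
    """Inverse of :func:`save_index`; raises :class:`IndexFormatError` with
    the offending line number on malformed input."""
    index = TermIndex()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise IndexFormatError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
        if not isinstance(obj, dict):
            raise IndexFormatError(f"line {lineno}: expected a JSON object")
        if "ledger_model" in obj:
            try:
                index.ledger[obj["ledger_model"]] = [
                    ((c["name"], c["signature"]), tuple(c["forms"]))
                    for c in obj["contributions"]
                ]
            except (KeyError, TypeError) as exc:
                raise IndexFormatError(f"line {lineno}: malformed ledger record") from exc
            continue
        try:
            name, sig, count, refs = obj["name"], obj["signature"], obj["count"], obj["refs"]
        except KeyError as exc:
            raise IndexFormatError(f"line {lineno}: missing field {exc.args[0]!r}") from exc
        if not isinstance(count, int) or count < 1:
            raise IndexFormatError(f"line {lineno}: count must be a positive integer")
        try:
            signature = AnnotationSignature.parse(sig)
            ref_set = {(r["model"], r["form"]) for r in refs}
        except (OdmError, KeyError, TypeError) as exc:
            raise IndexFormatError(f"line {lineno}: malformed entry") from exc
        if not ref_set:
            raise IndexFormatError(f"line {lineno}: refs must be non-empty")
        entry = TermIndexEntry(name, signature, count, ref_set)
        if entry.key in index.entries:
            raise IndexFormatError(f"line {lineno}: duplicate entry key {entry.key!r}")
        index.entries[entry.key] = entry
    return index
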