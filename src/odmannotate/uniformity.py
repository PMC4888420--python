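"""Uniformity analysis: how many coding variants exist per data element.

Given a corpus of annotated models and a human-supplied map from data-element
labels to name patterns, annotation occurrences are grouped per element and
tallied per signature.  Uniform coding means exactly one variant: every
occurrence of the element carries the same signature.  The label map is an
explicit input because deciding which names denote the same element is the
very problem expert annotation exists to solve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .matching import normalize_name
from .odm_model import (AnnotationSignature, DataModel, OdmError,
                        annotation_targets)
from .vocabulary import Vocabulary


class AmbiguousMappingError(OdmError):
    """A name pattern is claimed by more than one element label."""


@dataclass
class UniformityRow:
    """All observed coding variants of one data element."""

    element_label: str
    variants: list[tuple[AnnotationSignature, int]] = field(default_factory=list)
    unannotated_occurrences: int = 0

    @property
    def total_occurrences(self) -> int:
        return sum(count for _, count in self.variants)

    @property
    def variant_count(self) -> int:
        return len(self.variants)

    def __eq__(self, other) -> bool:
        return (isinstance(other, UniformityRow)
                and self.element_label == other.element_label
                and self.variants == other.variants
                and self.unannotated_occurrences == other.unannotated_occurrences)


@dataclass
class UniformitySummary:
    by_variant_count: dict[int, int]
    uniform_elements: int
    max_variant_count: int


def group_elements(corpus: Iterable[DataModel],
                   element_map: Mapping[str, Sequence[str]],
                   include_codelist_entries: bool = True) -> list[UniformityRow]:
    """Group annotation occurrences per data element and tally variants.

    *element_map* maps an element label to the normalized names that denote
    it; an element name matches a label when its normalized form equals one
    of the label's patterns.  A pattern claimed by two labels raises
    :class:`AmbiguousMappingError`.  Rows keep the label-map order; variants
    are sorted by occurrence count descending, then canonical signature
    ascending.  Unannotated matching occurrences are counted separately.
    """
    pattern_to_label: dict[str, str] = {}
    for label, patterns in element_map.items():
        for pattern in patterns:
            norm = normalize_name(pattern)
            other = pattern_to_label.get(norm)
            if other is not None and other != label:
                raise AmbiguousMappingError(
                    f"pattern {pattern!r} maps to both {other!r} and {label!r}")
            pattern_to_label[norm] = label

    tallies: dict[str, dict[str, int]] = {label: {} for label in element_map}
    unannotated: dict[str, int] = {label: 0 for label in element_map}
    signatures: dict[str, AnnotationSignature] = {}

    for model in corpus:
        for _oid, _kind, name, annotation in annotation_targets(
                model, include_codelist_entries):
            label = pattern_to_label.get(normalize_name(name))
            if label is None:
                continue
            if annotation is None:
                unannotated[label] += 1
                continue
            canonical = annotation.canonical
            signatures[canonical] = annotation
            tallies[label][canonical] = tallies[label].get(canonical, 0) + 1

    rows = []
    for label in element_map:
        variants = [(signatures[c], n) for c, n in tallies[label].items()]
        variants.sort(key=lambda v: (-v[1], v[0].canonical))
        rows.append(UniformityRow(label, variants, unannotated[label]))
    return rows


def summarize(rows: Sequence[UniformityRow]) -> UniformitySummary:
    """Distribution of variant counts over elements."""
    by_count: dict[int, int] = {}
    for row in rows:
        by_count[row.variant_count] = by_count.get(row.variant_count, 0) + 1
    return UniformitySummary(
        by_variant_count=dict(sorted(by_count.items())),
        uniform_elements=by_count.get(1, 0),
        max_variant_count=max((r.variant_count for r in rows), default=0),
    )


# ---------------------------------------------------------------------------
# Renderings
# ---------------------------------------------------------------------------


def report_table(rows: Sequence[UniformityRow],
                 vocab: Optional[Vocabulary] = None) -> str:
    """Human-readable table: one block per element, one ``Nx SIGNATURE`` line
    per variant, decorated with preferred terms when a vocabulary is given."""
    lines = ["Data element | #Occurrences | Semantic annotations"]
    for row in rows:
        lines.append(f"{row.element_label} | {row.total_occurrences} | "
                     f"{row.variant_count} variant(s)")
        for signature, count in row.variants:
            terms = ""
            if vocab is not None:
                names = [vocab.records[c.value].preferred_term
                         for c in signature.codes if c.value in vocab.records]
                terms = " " + "; ".join(names) if names else ""
            lines.append(f"  {count}x {signature.canonical}{terms}")
    return "\n".join(lines) + "\n"


_TSV_HEADER = "element_label\ttotal\tvariant_count\tunannotated\tvariants"


def rows_to_tsv(rows: Sequence[UniformityRow]) -> str:
    """Machine-readable rendering; :func:`rows_from_tsv` is its exact inverse."""
    lines = [_TSV_HEADER]
    for row in rows:
        variants = ";".join(f"{n}x{s.canonical}" for s, n in row.variants)
        lines.append(f"{row.element_label}\t{row.total_occurrences}\t"
                     f"{row.variant_count}\t{row.unannotated_occurrences}\t{variants}")
    return "\n".join(lines) + "\n"


def rows_from_tsv(text: str) -> list[UniformityRow]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or lines[0] != _TSV_HEADER:
        raise OdmError("uniformity TSV must start with its header row")
    rows = []
    for ln in lines[1:]:
        label, _total, _vc, unannotated, variants_text = ln.split("\t")
        variants = []
        for frag in filter(None, variants_text.split(";")):
            count_text, _, canonical = frag.partition("x")
            variants.append((AnnotationSignature.parse(canonical), int(count_text)))
        rows.append(UniformityRow(label, variants, int(unannotated)))
    return rows


def rows_to_json(rows: Sequence[UniformityRow]) -> str:
    payload = [
        {
            "element_label": r.element_label,
            "total_occurrences": r.total_occurrences,
            "variant_count": r.variant_count,
            "unannotated_occurrences": r.unannotated_occurrences,
            "variants": [{"signature": s.canonical, "count": n} for s, n in r.variants],
        }
        for r in rows
    ]
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
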