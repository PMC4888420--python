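"""The annotation workflow engine: propose, decide, apply, feed back.

For every unannotated element a ranked suggestion list is produced
(curated re-use first, vocabulary fallback second).  A human's choices are
expressed as :class:`DecisionRecord` rows — in batch mode a TSV file, in
interactive mode a prompt — and applying them both annotates the model and
updates the term index, so each accepted code is immediately available the
next time an element with the same meaning is annotated.  The library never
auto-commits a vocabulary suggestion without a decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import Config
from .matching import SuggestionList, normalize_name, suggest
from .odm_model import (AnnotationSignature, ConceptCode, DataModel, OdmError,
                        UnknownTargetError, annotation_targets, set_annotation)
from .repository import TermIndex, update_index
from .vocabulary import Vocabulary, make_signature

ACTIONS = ("reuse", "vocabulary", "postcoordinate", "skip")


@dataclass(frozen=True)
class DecisionRecord:
    """One expert decision for one target element.

    ``reuse`` takes codes from a repository suggestion, ``vocabulary`` takes a
    code straight from the concept table, ``postcoordinate`` combines several
    codes by hand, and ``skip`` records that no appropriate code exists yet.
    """

    target_oid: str
    action: str
    codes: tuple[ConceptCode, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"action must be one of {ACTIONS}, got {self.action!r}")
        if self.action != "skip" and not self.codes:
            raise ValueError(f"action {self.action!r} requires at least one code")


@dataclass
class AnnotationReport:
    """Outcome of one batch of decisions."""

    counts: dict[str, int] = field(default_factory=lambda: {a: 0 for a in ACTIONS})
    coverage_before: float = 0.0
    coverage_after: float = 0.0
    new_index_entries: int = 0
    warnings: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "coverage_before": self.coverage_before,
            "coverage_after": self.coverage_after,
            "new_index_entries": self.new_index_entries,
            "warnings": list(self.warnings),
            "skipped": list(self.skipped),
        }


def coverage(model: DataModel, include_codelist_entries: bool = True) -> float:
    """Fraction of annotatable elements that carry a signature (1.0 if none)."""
    targets = annotation_targets(model, include_codelist_entries)
    if not targets:
        return 1.0
    annotated = sum(1 for _, _, _, ann in targets if ann is not None)
    return annotated / len(targets)


def propose_all(model: DataModel, index: TermIndex, vocab: Vocabulary,
                config: Optional[Config] = None) -> dict[str, SuggestionList]:
    """One suggestion list per unannotated element; annotated ones are left alone."""
    config = config or Config()
    proposals: dict[str, SuggestionList] = {}
    for oid, _kind, name, annotation in annotation_targets(
            model, config.count_codelist_entries):
        if annotation is not None:
            continue
        proposals[oid] = suggest(index, vocab, name,
                                 config.similarity_threshold, config.suggestion_limit)
    return proposals


def apply_decisions(model: DataModel, decisions: Sequence[DecisionRecord],
                    index: TermIndex, vocab: Vocabulary,
                    config: Optional[Config] = None,
                    ) -> tuple[DataModel, TermIndex, AnnotationReport]:
    """Apply expert decisions to a model and fold the result into the index.

    Each non-skip decision sets the canonicalized signature on its target
    (``vocabulary`` decisions are checked against the concept table); a
    ``reuse`` decision whose signature is absent from the index is applied
    but flagged with a warning in the report.  The index is updated through
    :func:`~odmannotate.repository.update_index`, so re-running the same
    batch is idempotent.
    """
    config = config or Config()
    report = AnnotationReport(
        coverage_before=coverage(model, config.count_codelist_entries))
    targets = {oid: name for oid, _, name, _ in
               annotation_targets(model, include_codelist_entries=True)}
    entries_before = set(index.entries)

    for decision in decisions:
        if decision.target_oid not in targets:
            raise UnknownTargetError(
                f"decision targets unknown OID {decision.target_oid!r}")
        if decision.action == "skip":
            report.counts["skip"] += 1
            report.skipped.append(decision.target_oid)
            continue
        signature = make_signature(vocab, decision.codes,
                                   strict=(decision.action == "vocabulary"))
        if decision.action == "reuse":
            key = (normalize_name(targets[decision.target_oid]), signature.canonical)
            if key not in index.entries:
                report.warnings.append(
                    f"reuse decision for {decision.target_oid!r}: signature "
                    f"{signature.canonical!r} was not found in the index for "
                    f"name {targets[decision.target_oid]!r}")
        set_annotation(model, decision.target_oid, signature)
        report.counts[decision.action] += 1

    update_index(index, model, config.count_codelist_entries)
    report.new_index_entries = len(set(index.entries) - entries_before)
    report.coverage_after = coverage(model, config.count_codelist_entries)
    return model, index, report


# ---------------------------------------------------------------------------
# Decisions TSV (batch mode)
# ---------------------------------------------------------------------------


def decisions_from_tsv(text: str) -> list[DecisionRecord]:
    """Parse a decisions file: target_oid \\t action \\t codes(+-joined) \\t note."""
    decisions: list[DecisionRecord] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if lineno == 1 and parts[0] == "target_oid":
            continue
        if len(parts) < 2:
            raise OdmError(f"decisions line {lineno}: expected at least 2 columns")
        target_oid, action = parts[0], parts[1]
        codes = tuple(ConceptCode(c) for c in parts[2].split("+")) \
            if len(parts) > 2 and parts[2] else ()
        note = parts[3] if len(parts) > 3 else ""
        decisions.append(DecisionRecord(target_oid, action, codes, note))
    return decisions


def decisions_to_tsv(decisions: Iterable[DecisionRecord]) -> str:
    lines = ["target_oid\taction\tcodes\tnote"]
    for d in decisions:
        lines.append(f"{d.target_oid}\t{d.action}\t"
                     f"{'+'.join(c.value for c in d.codes)}\t{d.note}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Re-use-first policy (the uniformity mechanism, runnable without a human)
# ---------------------------------------------------------------------------


def reuse_first_decisions(model: DataModel, index: TermIndex, vocab: Vocabulary,
                          config: Optional[Config] = None) -> list[DecisionRecord]:
    """Mechanical stand-in for the expert: always accept the top repository
    suggestion when one exists, otherwise the top vocabulary suggestion,
    otherwise skip.  This is the policy under which name clusters converge to
    a single signature."""
    config = config or Config()
    decisions = []
    for oid, sl in propose_all(model, index, vocab, config).items():
        if not sl.suggestions:
            decisions.append(DecisionRecord(oid, "skip"))
            continue
        top = sl.suggestions[0]
        action = "reuse" if top.origin == "repository" else "vocabulary"
        decisions.append(DecisionRecord(oid, action, top.signature.codes))
    return decisions


def annotate_corpus_reuse_first(corpus: Sequence[DataModel], vocab: Vocabulary,
                                config: Optional[Config] = None,
                                index: Optional[TermIndex] = None,
                                ) -> tuple[list[DataModel], TermIndex, list[AnnotationReport]]:
    """Annotate a corpus sequentially under the re-use-first policy.

    Models are processed in order; every accepted code immediately enters the
    index and is re-used for later models, which is the mechanism that drives
    coding uniformity.  Models are copied; the originals are not modified.
    """
    config = config or Config()
    index = index if index is not None else TermIndex()
    annotated: list[DataModel] = []
    reports: list[AnnotationReport] = []
    for model in corpus:
        working = model.copy()
        decisions = reuse_first_decisions(working, index, vocab, config)
        working, index, report = apply_decisions(working, decisions, index, vocab, config)
        annotated.append(working)
        reports.append(report)
    return annotated, index, reports
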