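"""Runtime configuration shared by the matching and annotation steps."""

from __future__ import annotations

from dataclasses import dataclass

from .matching import DEFAULT_LIMIT, DEFAULT_THRESHOLD
from .odm_model import DEFAULT_ALIAS_CONTEXT


@dataclass
class Config:
    """Knobs of the annotation workflow.

    similarity_threshold: minimum name similarity for a term-index entry to
        be proposed (0..1).
    suggestion_limit: maximum number of suggestions per element.
    alias_context: the ODM Alias ``Context`` label that marks semantic
        annotations (the terminology label; configurable because different
        repositories use different context strings).
    count_codelist_entries: whether annotated code-list entries count as
        elements in the index and in coverage.
    """

    similarity_threshold: float = DEFAULT_THRESHOLD
    suggestion_limit: int = DEFAULT_LIMIT
    alias_context: str = DEFAULT_ALIAS_CONTEXT
    count_codelist_entries: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in [0, 1]")
        if self.suggestion_limit < 1:
            raise ValueError("suggestion_limit must be >= 1")
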