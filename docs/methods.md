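# Methods

## The annotation model

A *data element* follows the ISO/IEC 11179 split into a concept domain (what
the element means: name, question, annotation) and a value domain (data type,
range, unit, permissible values). Both are carried by the CDISC ODM 1.3
metadata subset this package reads and writes: `Study` →
`MetaDataVersion` → `FormDef` → `ItemGroupDef` → `ItemDef`, plus `CodeList`s
for enumerated value domains. Clinical-data sections, Define-XML specifics,
digital signatures and vendor extensions are out of scope.

A *semantic annotation* is an `AnnotationSignature`: a non-empty set of
concept codes (UMLS-style CUIs by default) in canonical form — deduplicated,
sorted ascending by code string, rendered joined with `+`. Canonicalization
matters because uniformity is defined on rendered signatures: any permutation
of the same code set must compare equal. Postcoordination (one meaning, several
codes) is simply a multi-code signature. On the wire, a signature is one ODM
`Alias` element per code with a configurable `Context` label (default
`"UMLS"`); `Alias` is ODM's standard extension point for terminology bindings,
and the context string is a setting because repositories differ in the label
they use. Code lists are annotated the same way, on `CodeListItem` elements;
since entries have no OID of their own they are addressed as
`"<codelist_oid>:<coded_value>"`.

Multilingual `Question` text: the first `TranslatedText` is kept together
with its language tag; no language-dependent logic is applied.

## The term index

The index is the curated-repository surrogate. Its key is the pair
(normalized element name, canonical signature) — precisely the
"name/code combination" a reviewer weighs when deciding whether an existing
annotation fits a new element — and each entry stores the occurrence count
and the (model, form) references where the combination was used, so the
reviewer can inspect context (`form_context`).

Counting unit: one annotated item or one annotated code-list entry counts 1.
Code-list entries are included by default because value domains are annotated
too; `count_codelist_entries=False` excludes them everywhere consistently.

Updates are *replace-on-update*: a per-model contributions ledger records
which keys a model fed, so re-processing an edited model first retracts its
previous contributions (counts decremented, emptied entries removed, its refs
dropped) and then adds the current ones. This makes `update_index` idempotent
for unchanged models and guarantees that the incrementally maintained index
equals a from-scratch rebuild — a property the tests check directly.
Persistence is JSON lines (one entry per line, refs sorted, diff-friendly);
ledger lines follow the entries so that retraction still works after a
round trip.

## Name matching

Normalization: casefold (which also expands ß→ss), Unicode NFKD
decomposition with combining marks stripped (ö→o, è→e), every remaining
non-alphanumeric character replaced by a space, whitespace collapsed. The
transliteration is therefore fixed by the Unicode decomposition tables —
reproducible across platforms, no external library. It is idempotent, which
the property tests exercise on arbitrary text.

Similarity of two normalized names is

```
sim(a, b) = max( |T(a) ∩ T(b)| / |T(a) ∪ T(b)| ,  1 − Lev(a, b) / max(|a|, |b|) )
```

with `T(x)` the token set and `Lev` the unit-cost edit distance (computed by
edlib; an independent dynamic-programming oracle backs it in the tests). The
token route catches reordered multi-word names ("pressure, systolic"), the
edit route catches typos and inflections; the max is symmetric, bounded in
[0, 1], equals 1 for identical strings, and two empty strings are defined
similar. Defaults: threshold 0.6, suggestion limit 20 — the threshold sits
above typical cross-concept similarities of short clinical names while
accepting case/punctuation/order variants, and both are exposed in `Config`.

Suggestion ranking: repository entries at or above the threshold, merged per
signature, ordered by (similarity desc, count desc, signature asc);
vocabulary hits are appended only while fewer than `limit` curated
suggestions exist and never outrank them, whatever their string similarity —
the uniformity argument rests on curated re-use, so the machinery must not
let a raw terminology hit displace it. The library never commits a
vocabulary suggestion without an explicit decision; a `skip` action exists
because some concepts have no adequate code yet.

## Vocabulary

A flat concept table (code, preferred term, synonyms, semantic type) behind a
TSV contract; concept-hierarchy relations are deliberately not modelled, so
no subsumption reasoning is attempted. `find_concepts` uses normalized
token containment (all query tokens present in a term), ranked by similarity
of the preferred term to the query, ties broken by code — deterministic and
independent of insertion order. The shipped toy vocabulary holds 20 real
CUIs for common clinical concepts; semantic types not well established are
marked `(unspecified)` rather than invented. A real UMLS export can be
plugged in through the same TSV contract.

## Uniformity analysis

Deciding which surface names denote the same data element is exactly the
unsolved problem expert annotation addresses, so the analyzer takes an
explicit label → name-patterns map as input rather than guessing concept
identity. A pattern matches by normalized-name equality; a pattern claimed by
two labels is an error. Per label, annotated occurrences are tallied per
canonical signature (variants sorted by count desc, signature asc);
unannotated matching occurrences are counted separately. An element is
uniformly coded iff it has exactly one variant. The optional
"number of matching terminology codes" columns seen in published tallies
depend on a full terminology release and are accepted as externally supplied
metadata, never computed.

## Synthetic data

Two generators make every claim testable without licensed content:

* **Reference corpus** (`make_table1_fixture`): five common data elements
  (Body weight, Date of Birth, Creatinine in Serum, Platelets, ALT) with
  their observed coding variants and occurrence tallies
  (86; 55+30; 44+13+9; 13+12+4; 30+7 = 303 annotated occurrences).
  Occurrences are dealt round-robin over 10 small one-form models rather
  than one big model so per-model update/retraction paths are exercised.
* **Synonym-cluster corpus** (`make_synonym_corpus`): n concept clusters,
  each appearing once per model under a seeded random surface variant
  (case, punctuation, token-order perturbations that all normalize to the
  same token set), plus a vocabulary offering k synonymous codes per
  cluster and a ground-truth map. Defaults used in the acceptance run —
  5 clusters × 10 models × 3 codes — are small enough to run in seconds yet
  large enough that independent coding demonstrably diverges.

What the synthetic corpora do *not* emulate: portal scale (hundreds of
thousands of terms), genuinely ambiguous homonyms, multilingual item names,
and human disagreement between annotators. Passing tests therefore show the
*mechanism* — re-use first yields one signature per cluster by construction,
while any per-model independent choice that varies (here: with model parity)
yields several — not that real corpora converge as cleanly.

## Numerical and procedural choices

* Canonical signature order is lexicographic on code strings; ties in every
  ranking break on the canonical signature string, so all outputs are
  deterministic for identical inputs.
* `similarity("body weight", "weight")` = 6/11 ≈ 0.545: the edit-distance
  route exceeds the token-Jaccard 0.5 and the measure takes the max.
* XML serialization is byte-stable (fixed element ordering, one alias per
  code in canonical order), so write→read→write is the identity on bytes.
* Coverage of a model with no annotatable elements is defined as 1.0.
* `set_annotation` replaces rather than merges: the human decision is
  authoritative.
* Empty inputs: an ODM file with zero items is rejected as an empty model; an
  empty vocabulary and an empty index are valid and yield empty suggestion
  lists (the signal to postcoordinate manually).

## Limitations

* Similar-name retrieval scans all index entries per query — fine for
  desk-scale corpora, not for portal scale; no inverted index is built.
* The interactive reviewer loop is deliberately thin; the batch decisions
  TSV is the tested path.
* No inter-rater tooling, no audit trail beyond the per-batch report, no
  concurrency control on the index file.
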