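# odmannotate

Uniform semantic annotation of clinical study metadata in CDISC ODM format.

## The problem

Integrating patient data across studies and EHR systems requires knowing when
two data elements mean the same thing. Attaching terminology codes (semantic
annotation / terminology binding) makes that decidable — but large
terminologies such as UMLS offer *several* plausible codes for most concepts:
"height" can be coded `C0489786` or `C0005890`, "patient sex" and "gender of
patient" carry different CUIs, and postcoordination (combining codes like
`C0005615+C0011008+C0027361` for a date of birth) multiplies the options.
Picking codes independently per study therefore produces *coding variants*:
elements with identical meaning but different annotations, which defeats
data integration.

`odmannotate` implements the curation workflow that drives coding toward
uniformity: annotations are **re-used from a term index** built over a corpus
of already-annotated data models, and only when no curated code exists is a
vocabulary (UMLS-like concept table) consulted. Every accepted code feeds
back into the index immediately, so the next element with the same meaning
gets the same signature. A uniformity analyzer measures the outcome: for each
data element *e* with annotation occurrences grouped by canonical signature
*s*, it reports the variant set {(s, n_s)} and the element counts as
*uniformly coded* iff |{s}| = 1.

Intended users: clinical research informaticians curating metadata
repositories, and anyone studying terminology-binding quality in study
metadata.

## What is in the box

| module | role |
|---|---|
| `odm_model` | read/write/validate the ODM 1.3 metadata subset; annotations as `Alias` elements (one per code, `Context="UMLS"` by default) |
| `repository` | the term index: (normalized name, signature) → usage count + form refs, with retractable per-model contributions |
| `matching` | name normalization, `max(Jaccard, 1 − Lev/max len)` similarity, ranked suggestions (curated re-use always outranks vocabulary hits) |
| `vocabulary` | pluggable flat concept table (TSV contract), fallback lookup, postcoordinated signature construction |
| `annotate` | propose → decide → apply → feed back; batch decisions TSV; a mechanical re-use-first policy for experiments |
| `uniformity` | per-element variant grouping, summary, report renderings |
| `synthdata` | toy 20-CUI vocabulary, a reference corpus with published per-variant tallies, seeded synonym-cluster corpora |
| `cli` | `odmannotate fixture / build-index / suggest / annotate / uniformity` |

## Worked example

Generate the built-in reference corpus (10 small ODM models realizing the
annotation tallies of five common data elements), index it, and analyze
uniformity:

```sh
odmannotate fixture table1 fx
odmannotate build-index fx index.jsonl
odmannotate uniformity fx fx/label_map.json --vocab fx/vocabulary.tsv
```

prints:

```
Data element | #Occurrences | Semantic annotations
Body weight | 86 | 1 variant(s)
  86x C0005910 Body weight
Date of Birth | 85 | 2 variant(s)
  55x C0421451 Patient date of birth
  30x C0005615+C0011008+C0027361 Birth; Date in time; Persons
Creatinine in Serum | 66 | 3 variant(s)
  44x C0201976 Creatinine measurement, serum
  13x C0010294 Creatinine
  9x C0201975 Creatinine measurement
Platelets | 29 | 3 variant(s)
  13x C0005821 Blood Platelets
  12x C0942474 Platelets:NCnc:Pt:Bld:Qn
  4x C1287267 Finding of platelet count
ALT | 37 | 2 variant(s)
  30x C0201836 Alanine aminotransferase measurement
  7x C0001899 Alanine Transaminase
```

Reading: of 303 annotated occurrences, only *Body weight* is uniformly coded
(one signature, 86 occurrences); *Date of Birth* was coded two ways — a
single CUI 55 times and a three-code postcoordination 30 times — and the lab
elements carry up to three variants each. `Nx SIGNATURE` lines show how often
each name/signature combination occurs; the trailing words are the
vocabulary's preferred terms for the codes.

To annotate a new model, ask for suggestions (curated re-use first):

```sh
odmannotate suggest new_model.xml index.jsonl fx/vocabulary.tsv
```

then record expert choices in a decisions TSV
(`target_oid  action  codes  note`, actions: `reuse`, `vocabulary`,
`postcoordinate`, `skip`) and apply them — this annotates the model *and*
updates the index:

```sh
odmannotate annotate new_model.xml decisions.tsv index.jsonl fx/vocabulary.tsv out.xml
```

The same workflow is available as a library
(`propose_all`, `apply_decisions`, `annotate_corpus_reuse_first`, ...); see
`docs/methods.md` for the method itself.

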