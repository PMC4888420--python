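"""Self-contained fixtures and synthetic corpora.

Everything other modules need for testing and demonstration is generated
here from code: a toy concept table of well-known UMLS CUIs, a small
reference corpus reproducing published per-variant annotation tallies for
five common data elements, and seeded synonym-cluster corpora for probing
how re-use drives coding uniformity.  No downloads, no licensed content.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .odm_model import (AnnotationSignature, ConceptCode, DataItem, DataModel,
                        FormDef, ItemGroup, write_odm)
from .matching import normalize_name
from .vocabulary import Vocabulary, load_vocabulary

# ---------------------------------------------------------------------------
# Toy vocabulary: 20 real UMLS CUIs for common clinical concepts.  Semantic
# types are given where well established; "(unspecified)" otherwise.
# ---------------------------------------------------------------------------

TOY_VOCABULARY_TSV = """\
code	term	term_type	semantic_type
C0001899	Alanine Transaminase	preferred	(unspecified)
C0005615	Birth	preferred	(unspecified)
C0005821	Blood Platelets	preferred	(unspecified)
C0005821	Platelets	synonym	(unspecified)
C0005890	Body Height	preferred	(unspecified)
C0005890	Height	synonym	(unspecified)
C0005910	Body weight	preferred	(unspecified)
C0005910	Weight	synonym	(unspecified)
C0010294	Creatinine	preferred	(unspecified)
C0011008	Date in time	preferred	(unspecified)
C0027361	Persons	preferred	(unspecified)
C0150831	Patient sex	preferred	Organism Attribute T032
C0201836	Alanine aminotransferase measurement	preferred	(unspecified)
C0201836	ALT measurement	synonym	(unspecified)
C0201975	Creatinine measurement	preferred	(unspecified)
C0201976	Creatinine measurement, serum	preferred	(unspecified)
C0421451	Patient date of birth	preferred	(unspecified)
C0421451	Date of Birth	synonym	(unspecified)
C0475440	Tumor size	preferred	(unspecified)
C0489786	Height	preferred	(unspecified)
C0942474	Platelets:NCnc:Pt:Bld:Qn	preferred	(unspecified)
C1276997	Antidementia drug	preferred	Pharmacologic Substance T121
C1287267	Finding of platelet count	preferred	(unspecified)
C1531592	Antidementia agents	preferred	Pharmacologic Substance T121
C1548569	Gender of patient	preferred	Intellectual Product T170
"""


def make_toy_vocabulary() -> Vocabulary:
    """The 20-concept toy vocabulary (see :data:`TOY_VOCABULARY_TSV`)."""
    return load_vocabulary(TOY_VOCABULARY_TSV)


# ---------------------------------------------------------------------------
# Reference corpus: five common data elements with their observed coding
# variants and occurrence tallies in a large public metadata portal.
# ---------------------------------------------------------------------------

#: (element label, data type, [(canonical signature, occurrences), ...])
TABLE1_ELEMENTS: list[tuple[str, str, list[tuple[str, int]]]] = [
    ("Body weight", "float", [("C0005910", 86)]),
    ("Date of Birth", "date", [("C0421451", 55),
                               ("C0005615+C0011008+C0027361", 30)]),
    ("Creatinine in Serum", "float", [("C0201976", 44), ("C0010294", 13),
                                      ("C0201975", 9)]),
    ("Platelets", "float", [("C0005821", 13), ("C0942474", 12),
                            ("C1287267", 4)]),
    ("ALT", "float", [("C0201836", 30), ("C0001899", 7)]),
]

#: Label map for the uniformity analyzer over the reference corpus.
TABLE1_LABEL_MAP: dict[str, list[str]] = {
    label: [label] for label, _, _ in TABLE1_ELEMENTS
}


def make_table1_fixture(n_models: int = 10) -> list[DataModel]:
    """A corpus of small one-form models realizing the reference tallies.

    Each annotated occurrence becomes one item; occurrences are dealt out
    round-robin over *n_models* models so that per-model update and
    retraction paths get exercised on realistic, multi-model data.
    """
    slots: list[tuple[str, str, str]] = []
    for label, dtype, variants in TABLE1_ELEMENTS:
        for canonical, occurrences in variants:
            slots.extend((label, dtype, canonical) for _ in range(occurrences))

    models = []
    for k in range(n_models):
        models.append(DataModel(
            model_id=f"T1M{k + 1:02d}",
            study_name=f"Reference corpus model {k + 1}",
            forms=[FormDef(oid="F.1", name=f"Reference form {k + 1}",
                           group_refs=["IG.1"])],
            groups=[ItemGroup(oid="IG.1", name="Data elements", item_refs=[])],
        ))
    for i, (label, dtype, canonical) in enumerate(slots):
        model = models[i % n_models]
        oid = f"IT.{len(model.items) + 1}"
        model.items.append(DataItem(oid=oid, name=label, data_type=dtype,
                                    annotation=AnnotationSignature.parse(canonical)))
        model.groups[0].item_refs.append(oid)
    return models


# ---------------------------------------------------------------------------
# Synonym-cluster corpus: the testbed for the uniformity mechanism.
# ---------------------------------------------------------------------------

_ADJECTIVES = ["systolic", "diastolic", "fasting", "resting", "peak", "basal",
               "serum", "urinary", "hepatic", "renal", "cardiac", "plasma"]
_NOUNS = ["pressure", "glucose", "pulse", "volume", "sodium", "ferritin",
          "albumin", "lactate", "cortisol", "bilirubin", "amylase", "oxygen"]


@dataclass
class SynonymClusterSpec:
    """Ground truth for one concept cluster: the synonymous coding variants a
    vocabulary offers for it and the surface-name variants it appears under."""

    concept_label: str
    candidate_codes: list[ConceptCode]
    name_variants: list[str]
    occurrences: int

    def __post_init__(self) -> None:
        if not self.candidate_codes or not self.name_variants or self.occurrences < 1:
            raise ValueError("cluster needs >=1 code, >=1 name variant, >=1 occurrence")


def _cluster_base_name(i: int) -> str:
    adj = _ADJECTIVES[i % len(_ADJECTIVES)]
    noun = _NOUNS[(i + i // len(_ADJECTIVES)) % len(_NOUNS)]
    suffix = f" {i // (len(_ADJECTIVES) * len(_NOUNS))}" \
        if i >= len(_ADJECTIVES) * len(_NOUNS) else ""
    return f"{adj} {noun}{suffix}"


def _name_variants(base: str) -> list[str]:
    """Case, punctuation and token-order perturbations that all denote the
    same concept (and normalize to the same token set)."""
    tokens = base.split()
    swapped = " ".join(reversed(tokens))
    return [
        base,
        base.title(),
        base.upper(),
        "-".join(tokens),
        f"{tokens[-1]}, {' '.join(tokens[:-1])}",
        swapped,
    ]


def make_synonym_corpus(n_clusters: int, models_per_cluster: int,
                        codes_per_cluster: int, seed: int,
                        ) -> tuple[list[DataModel], Vocabulary, dict[str, SynonymClusterSpec]]:
    """A seeded corpus of unannotated models plus a deliberately redundant
    vocabulary.

    Every model carries one item per concept cluster, under a randomly chosen
    surface-name variant; the vocabulary offers *codes_per_cluster*
    synonymous codes for each cluster.  Whether annotation converges to one
    signature per cluster then depends purely on the annotation policy, which
    is exactly what the truth map lets tests check.
    """
    if min(n_clusters, models_per_cluster, codes_per_cluster) < 1:
        raise ValueError("all corpus parameters must be >= 1")
    rng = random.Random(seed)

    truth: dict[str, SynonymClusterSpec] = {}
    vocab_rows = ["code\tterm\tterm_type\tsemantic_type"]
    for i in range(n_clusters):
        base = _cluster_base_name(i)
        codes = [ConceptCode(f"C{9000000 + i * 100 + j}")
                 for j in range(codes_per_cluster)]
        for j, code in enumerate(codes):
            term = base if j == 0 else f"{base} variant {j}"
            vocab_rows.append(f"{code.value}\t{term}\tpreferred\tsynthetic cluster {i}")
        truth[base] = SynonymClusterSpec(
            concept_label=base, candidate_codes=codes,
            name_variants=_name_variants(base), occurrences=models_per_cluster)
    vocab = load_vocabulary("\n".join(vocab_rows) + "\n")

    models = []
    for m in range(models_per_cluster):
        model = DataModel(
            model_id=f"SYN{m + 1:03d}",
            study_name=f"Synthetic study {m + 1}",
            forms=[FormDef(oid="F.1", name=f"Synthetic form {m + 1}",
                           group_refs=["IG.1"])],
            groups=[ItemGroup(oid="IG.1", name="Observations", item_refs=[])],
        )
        for i, spec in enumerate(truth.values()):
            oid = f"IT.{i + 1}"
            model.items.append(DataItem(oid=oid,
                                        name=rng.choice(spec.name_variants),
                                        data_type="float"))
            model.groups[0].item_refs.append(oid)
        models.append(model)
    return models, vocab, truth


def label_map_from_truth(truth: dict[str, SynonymClusterSpec]) -> dict[str, list[str]]:
    """Uniformity label map covering every normalized surface form of each cluster."""
    return {
        label: sorted({normalize_name(v) for v in spec.name_variants})
        for label, spec in truth.items()
    }


# ---------------------------------------------------------------------------
# Fixture directories (for the command-line workflow)
# ---------------------------------------------------------------------------


def write_fixture_dir(kind: str, out_dir: str | Path, seed: int = 0) -> Path:
    """Write a fixture corpus (ODM XML files + vocabulary TSV + label map
    JSON) to *out_dir*.  ``kind`` is ``"table1"`` or ``"synonyms"``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "table1":
        models = make_table1_fixture()
        vocab_tsv = TOY_VOCABULARY_TSV
        label_map = TABLE1_LABEL_MAP
    elif kind == "synonyms":
        models, vocab, truth = make_synonym_corpus(
            n_clusters=5, models_per_cluster=10, codes_per_cluster=3, seed=seed)
        from .vocabulary import save_vocabulary
        vocab_tsv = save_vocabulary(vocab)
        label_map = label_map_from_truth(truth)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; use 'table1' or 'synonyms'")
    for model in models:
        (out / f"{model.model_id}.xml").write_text(write_odm(model), encoding="utf-8")
    (out / "vocabulary.tsv").write_text(vocab_tsv, encoding="utf-8")
    (out / "label_map.json").write_text(
        json.dumps(label_map, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
    return out
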