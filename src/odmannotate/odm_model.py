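"""In-memory model of the CDISC ODM 1.3 study-metadata subset.

Only the structural metadata that carries data elements and their semantic
annotations is modelled: forms, item groups, items, code lists, units, range
checks and terminology-binding aliases.  Clinical-data sections (subject
records), Define-XML specifics and vendor extensions are out of scope.

Semantic annotations ride on ODM ``Alias`` elements: one ``Alias`` per concept
code with a configurable ``Context`` label (default ``"UMLS"``).  Several
aliases on one element form a single postcoordinated
:class:`AnnotationSignature`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

from lxml import etree

ODM_NS = "http://www.cdisc.org/ns/odm/v1.3"
DEFAULT_ALIAS_CONTEXT = "UMLS"

#: Permitted ODM data types for items.
DATA_TYPES = ("integer", "float", "string", "date", "datetime", "boolean", "text")


class OdmError(Exception):
    """Base class for all errors raised by this package."""


class OdmParseError(OdmError):
    """The input is not well-formed XML or not an ODM document."""


class IntegrityError(OdmError):
    """A referential-integrity or invariant violation, naming the offender."""


class EmptyModelError(OdmError):
    """The metadata section defines no items."""


class UnknownTargetError(OdmError):
    """A target OID does not name an item or code-list entry."""


class EmptySignatureError(OdmError):
    """An annotation signature must contain at least one concept code."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ConceptCode:
    """A terminology concept code, e.g. a UMLS CUI like ``C0005890``.

    ``value`` is any non-empty whitespace-free token; UMLS-style codes follow
    the pattern ``C`` + 7 digits.  ``source`` labels the terminology.
    """

    value: str
    source: str = "UMLS"

    def __post_init__(self) -> None:
        if not self.value:
            raise ValueError("concept code must be non-empty")
        if any(c.isspace() for c in self.value):
            raise ValueError(f"concept code may not contain whitespace: {self.value!r}")


@dataclass(frozen=True)
class AnnotationSignature:
    """A canonicalized, non-empty set of concept codes.

    The signature is the unit of "uniform coding": two data elements mean the
    same thing exactly when they carry the same signature.  Postcoordination
    (one meaning expressed by several codes) is a multi-code signature.

    Canonical form: codes deduplicated, sorted ascending by code string and
    joined with ``"+"``, so any permutation of the same code set renders
    identically.
    """

    codes: tuple[ConceptCode, ...]

    @classmethod
    def from_codes(cls, codes) -> "AnnotationSignature":
        seen: dict[str, ConceptCode] = {}
        for c in codes:
            if not isinstance(c, ConceptCode):
                c = ConceptCode(str(c))
            seen.setdefault(c.value, c)
        if not seen:
            raise EmptySignatureError("annotation signature requires at least one code")
        ordered = tuple(seen[v] for v in sorted(seen))
        return cls(ordered)

    @classmethod
    def parse(cls, text: str, source: str = "UMLS") -> "AnnotationSignature":
        """Parse a ``"+"``-joined canonical rendering back into a signature."""
        parts = [p for p in text.split("+") if p]
        return cls.from_codes(ConceptCode(p, source) for p in parts)

    def __post_init__(self) -> None:
        values = [c.value for c in self.codes]
        if not values:
            raise EmptySignatureError("annotation signature requires at least one code")
        if values != sorted(set(values)):
            raise ValueError("signature codes must be unique and sorted; use from_codes()")

    @property
    def canonical(self) -> str:
        return "+".join(c.value for c in self.codes)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


@dataclass
class CodeListEntry:
    coded_value: str
    decode_text: str
    annotation: Optional[AnnotationSignature] = None


@dataclass
class CodeList:
    oid: str
    name: str
    entries: list[CodeListEntry] = field(default_factory=list)


@dataclass
class DataItem:
    """One data element: concept domain (name/question/annotation) plus value
    domain (data type, range, unit, code list)."""

    oid: str
    name: str
    data_type: str = "text"
    description: Optional[str] = None
    question: Optional[str] = None
    question_lang: Optional[str] = None
    range_min: Optional[float] = None
    range_max: Optional[float] = None
    unit: Optional[str] = None
    codelist_ref: Optional[str] = None
    annotation: Optional[AnnotationSignature] = None


@dataclass
class ItemGroup:
    oid: str
    name: str
    item_refs: list[str] = field(default_factory=list)


@dataclass
class FormDef:
    oid: str
    name: str
    group_refs: list[str] = field(default_factory=list)


@dataclass
class DataModel:
    """One ODM metadata file: forms -> item groups -> items, plus code lists."""

    model_id: str
    study_name: str = ""
    forms: list[FormDef] = field(default_factory=list)
    groups: list[ItemGroup] = field(default_factory=list)
    items: list[DataItem] = field(default_factory=list)
    codelists: list[CodeList] = field(default_factory=list)

    # -- lookup helpers -----------------------------------------------------

    def item(self, oid: str) -> DataItem:
        for it in self.items:
            if it.oid == oid:
                return it
        raise UnknownTargetError(f"no item with OID {oid!r} in model {self.model_id!r}")

    def codelist(self, oid: str) -> CodeList:
        for cl in self.codelists:
            if cl.oid == oid:
                return cl
        raise UnknownTargetError(f"no code list with OID {oid!r} in model {self.model_id!r}")

    def forms_of_item(self, item_oid: str) -> list[str]:
        """OIDs of the forms that (transitively) reference an item."""
        groups = {g.oid for g in self.groups if item_oid in g.item_refs}
        return [f.oid for f in self.forms if groups.intersection(f.group_refs)]

    def copy(self) -> "DataModel":
        return copy.deepcopy(self)


def entry_oid(codelist_oid: str, coded_value: str) -> str:
    """Composite OID addressing one code-list entry (entries have no ODM OID)."""
    return f"{codelist_oid}:{coded_value}"


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    """One validation finding; issues are data, not exceptions."""

    oid: str
    kind: str
    message: str


def validate(model: DataModel) -> list[Issue]:
    """Check every structural invariant; empty list means the model is valid.

    Kinds: ``duplicate-oid``, ``dangling-ref``, ``range-order``,
    ``duplicate-coded-value``, ``bad-data-type``.
    """
    issues: list[Issue] = []

    for label, elems in (
        ("form", model.forms),
        ("item group", model.groups),
        ("item", model.items),
        ("code list", model.codelists),
    ):
        seen: set[str] = set()
        for e in elems:
            if e.oid in seen:
                issues.append(Issue(e.oid, "duplicate-oid", f"duplicate {label} OID {e.oid!r}"))
            seen.add(e.oid)

    group_oids = {g.oid for g in model.groups}
    item_oids = {i.oid for i in model.items}
    codelist_oids = {c.oid for c in model.codelists}

    for f in model.forms:
        for ref in f.group_refs:
            if ref not in group_oids:
                issues.append(Issue(f.oid, "dangling-ref",
                                    f"form {f.oid!r} references missing item group {ref!r}"))
    for g in model.groups:
        for ref in g.item_refs:
            if ref not in item_oids:
                issues.append(Issue(g.oid, "dangling-ref",
                                    f"item group {g.oid!r} references missing item {ref!r}"))
    for it in model.items:
        if it.codelist_ref is not None and it.codelist_ref not in codelist_oids:
            issues.append(Issue(it.oid, "dangling-ref",
                                f"item {it.oid!r} references missing code list {it.codelist_ref!r}"))
        if it.range_min is not None and it.range_max is not None and it.range_min > it.range_max:
            issues.append(Issue(it.oid, "range-order",
                                f"item {it.oid!r} has range_min {it.range_min} > range_max {it.range_max}"))
        if it.data_type not in DATA_TYPES:
            issues.append(Issue(it.oid, "bad-data-type",
                                f"item {it.oid!r} has unknown data type {it.data_type!r}"))
    for cl in model.codelists:
        seen_cv: set[str] = set()
        for entry in cl.entries:
            if entry.coded_value in seen_cv:
                issues.append(Issue(cl.oid, "duplicate-coded-value",
                                    f"code list {cl.oid!r} repeats coded value {entry.coded_value!r}"))
            seen_cv.add(entry.coded_value)
    return issues


# ---------------------------------------------------------------------------
# Reading ODM XML
# ---------------------------------------------------------------------------


def _q(tag: str) -> str:
    return f"{{{ODM_NS}}}{tag}"


def _first_translated_text(parent) -> tuple[Optional[str], Optional[str]]:
    """First TranslatedText value and its xml:lang tag (no language logic)."""
    for tt in parent.iter(_q("TranslatedText")):
        lang = tt.get("{http://www.w3.org/XML/1998/namespace}lang")
        return (tt.text or "").strip() or None, lang
    return None, None


def _parse_aliases(elem, alias_context: str) -> Optional[AnnotationSignature]:
    codes = [
        ConceptCode(a.get("Name"), alias_context)
        for a in elem.findall(_q("Alias"))
        if a.get("Context") == alias_context and a.get("Name")
    ]
    return AnnotationSignature.from_codes(codes) if codes else None


def read_odm(xml_text: str | bytes, alias_context: str = DEFAULT_ALIAS_CONTEXT) -> DataModel:
    """Parse an ODM 1.3 metadata document into a :class:`DataModel`.

    All FormDef/ItemGroupDef/ItemDef/CodeList metadata is read; Alias elements
    whose ``Context`` equals *alias_context* become annotation signatures
    (several aliases on one element fold into one postcoordinated signature).

    Raises :class:`OdmParseError` for malformed XML, :class:`EmptyModelError`
    when no ItemDefs are present, and :class:`IntegrityError` for dangling OID
    references.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise OdmParseError(f"malformed XML: {exc}") from exc
    if etree.QName(root).localname != "ODM":
        raise OdmParseError(f"root element is {root.tag!r}, expected ODM")

    study = root.find(_q("Study"))
    if study is None:
        raise EmptyModelError("document contains no Study element")
    model_id = study.get("OID") or ""
    study_name = ""
    gv = study.find(_q("GlobalVariables"))
    if gv is not None:
        sn = gv.find(_q("StudyName"))
        if sn is not None and sn.text:
            study_name = sn.text.strip()

    units: dict[str, str] = {}
    bd = study.find(_q("BasicDefinitions"))
    if bd is not None:
        for mu in bd.findall(_q("MeasurementUnit")):
            sym, _ = _first_translated_text(mu)
            units[mu.get("OID")] = sym or mu.get("Name") or ""

    mdv = study.find(_q("MetaDataVersion"))
    if mdv is None:
        raise EmptyModelError("document contains no MetaDataVersion element")

    model = DataModel(model_id=model_id, study_name=study_name)

    for fd in mdv.findall(_q("FormDef")):
        refs = [r.get("ItemGroupOID") for r in fd.findall(_q("ItemGroupRef"))]
        model.forms.append(FormDef(fd.get("OID"), fd.get("Name") or "", refs))

    for gd in mdv.findall(_q("ItemGroupDef")):
        refs = [r.get("ItemOID") for r in gd.findall(_q("ItemRef"))]
        model.groups.append(ItemGroup(gd.get("OID"), gd.get("Name") or "", refs))

    for idf in mdv.findall(_q("ItemDef")):
        item = DataItem(oid=idf.get("OID"), name=idf.get("Name") or "",
                        data_type=idf.get("DataType") or "text")
        desc = idf.find(_q("Description"))
        if desc is not None:
            item.description, _ = _first_translated_text(desc)
        q = idf.find(_q("Question"))
        if q is not None:
            item.question, item.question_lang = _first_translated_text(q)
        mur = idf.find(_q("MeasurementUnitRef"))
        if mur is not None:
            item.unit = units.get(mur.get("MeasurementUnitOID"))
        for rc in idf.findall(_q("RangeCheck")):
            cv = rc.find(_q("CheckValue"))
            if cv is None or cv.text is None:
                continue
            value = float(cv.text)
            if rc.get("Comparator") == "GE":
                item.range_min = value
            elif rc.get("Comparator") == "LE":
                item.range_max = value
        clr = idf.find(_q("CodeListRef"))
        if clr is not None:
            item.codelist_ref = clr.get("CodeListOID")
        item.annotation = _parse_aliases(idf, alias_context)
        model.items.append(item)

    for cld in mdv.findall(_q("CodeList")):
        cl = CodeList(cld.get("OID"), cld.get("Name") or "")
        for cli in cld.findall(_q("CodeListItem")):
            decode = cli.find(_q("Decode"))
            text = ""
            if decode is not None:
                t, _ = _first_translated_text(decode)
                text = t or ""
            cl.entries.append(CodeListEntry(
                coded_value=cli.get("CodedValue") or "",
                decode_text=text,
                annotation=_parse_aliases(cli, alias_context),
            ))
        model.codelists.append(cl)

    if not model.items:
        raise EmptyModelError(f"model {model_id!r} defines no items")

    dangling = [i for i in validate(model) if i.kind == "dangling-ref"]
    if dangling:
        raise IntegrityError("; ".join(i.message for i in dangling))
    return model


# ---------------------------------------------------------------------------
# Writing ODM XML
# ---------------------------------------------------------------------------


def _append_translated(parent, tag: str, text: str, lang: Optional[str] = None) -> None:
    wrapper = etree.SubElement(parent, _q(tag))
    tt = etree.SubElement(wrapper, _q("TranslatedText"))
    if lang:
        tt.set("{http://www.w3.org/XML/1998/namespace}lang", lang)
    tt.text = text


def _append_aliases(parent, signature: Optional[AnnotationSignature], context: str) -> None:
    if signature is None:
        return
    for code in signature.codes:
        etree.SubElement(parent, _q("Alias"), Context=context, Name=code.value)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_odm(model: DataModel, alias_context: str = DEFAULT_ALIAS_CONTEXT) -> str:
    """Serialize a model to ODM 1.3 XML (UTF-8, deterministic element order).

    Every annotation signature is written as one ``Alias`` element per code,
    in canonical code order.  Raises :class:`IntegrityError` when the model
    fails :func:`validate`.
    """
    issues = validate(model)
    if issues:
        raise IntegrityError("; ".join(i.message for i in issues))

    root = etree.Element(_q("ODM"), nsmap={None: ODM_NS})
    root.set("FileType", "Snapshot")
    root.set("FileOID", model.model_id)
    root.set("ODMVersion", "1.3")
    study = etree.SubElement(root, _q("Study"), OID=model.model_id)
    gv = etree.SubElement(study, _q("GlobalVariables"))
    sn = etree.SubElement(gv, _q("StudyName"))
    sn.text = model.study_name or model.model_id

    units = sorted({it.unit for it in model.items if it.unit})
    unit_oid = {u: f"MU.{i + 1}" for i, u in enumerate(units)}
    if units:
        bd = etree.SubElement(study, _q("BasicDefinitions"))
        for u in units:
            mu = etree.SubElement(bd, _q("MeasurementUnit"), OID=unit_oid[u], Name=u)
            _append_translated(mu, "Symbol", u)

    mdv = etree.SubElement(study, _q("MetaDataVersion"), OID="MDV.1", Name="Metadata")
    for f in model.forms:
        fd = etree.SubElement(mdv, _q("FormDef"), OID=f.oid, Name=f.name, Repeating="No")
        for order, ref in enumerate(f.group_refs, 1):
            etree.SubElement(fd, _q("ItemGroupRef"), ItemGroupOID=ref,
                             OrderNumber=str(order), Mandatory="No")
    for g in model.groups:
        gd = etree.SubElement(mdv, _q("ItemGroupDef"), OID=g.oid, Name=g.name, Repeating="No")
        for order, ref in enumerate(g.item_refs, 1):
            etree.SubElement(gd, _q("ItemRef"), ItemOID=ref,
                             OrderNumber=str(order), Mandatory="No")
    for it in model.items:
        idf = etree.SubElement(mdv, _q("ItemDef"), OID=it.oid, Name=it.name,
                               DataType=it.data_type)
        if it.description:
            _append_translated(idf, "Description", it.description)
        if it.question:
            _append_translated(idf, "Question", it.question, it.question_lang)
        if it.unit:
            etree.SubElement(idf, _q("MeasurementUnitRef"),
                             MeasurementUnitOID=unit_oid[it.unit])
        if it.range_min is not None:
            rc = etree.SubElement(idf, _q("RangeCheck"), Comparator="GE", SoftHard="Soft")
            etree.SubElement(rc, _q("CheckValue")).text = _fmt_num(it.range_min)
        if it.range_max is not None:
            rc = etree.SubElement(idf, _q("RangeCheck"), Comparator="LE", SoftHard="Soft")
            etree.SubElement(rc, _q("CheckValue")).text = _fmt_num(it.range_max)
        if it.codelist_ref:
            etree.SubElement(idf, _q("CodeListRef"), CodeListOID=it.codelist_ref)
        _append_aliases(idf, it.annotation, alias_context)
    for cl in model.codelists:
        cld = etree.SubElement(mdv, _q("CodeList"), OID=cl.oid, Name=cl.name, DataType="text")
        for entry in cl.entries:
            cli = etree.SubElement(cld, _q("CodeListItem"), CodedValue=entry.coded_value)
            _append_translated(cli, "Decode", entry.decode_text)
            _append_aliases(cli, entry.annotation, alias_context)

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode("utf-8")


# ---------------------------------------------------------------------------
# Annotation access
# ---------------------------------------------------------------------------

OwnerKind = Literal["item", "codelist_entry"]


def set_annotation(model: DataModel, target_oid: str,
                   signature: AnnotationSignature) -> DataModel:
    """Attach a signature to an item or code-list entry, replacing any
    previous one.  Code-list entries are addressed as
    ``"<codelist_oid>:<coded_value>"``.  Raises :class:`UnknownTargetError`
    for an unknown OID.  The model is modified in place and returned.
    """
    signature = AnnotationSignature.from_codes(signature.codes)
    for it in model.items:
        if it.oid == target_oid:
            it.annotation = signature
            return model
    if ":" in target_oid:
        cl_oid, _, coded_value = target_oid.partition(":")
        for cl in model.codelists:
            if cl.oid != cl_oid:
                continue
            for entry in cl.entries:
                if entry.coded_value == coded_value:
                    entry.annotation = signature
                    return model
    raise UnknownTargetError(
        f"no item or code-list entry with OID {target_oid!r} in model {model.model_id!r}")


@dataclass(frozen=True)
class AnnotationRow:
    owner_oid: str
    owner_kind: OwnerKind
    name: str
    signature: AnnotationSignature


def extract_annotations(model: DataModel) -> list[AnnotationRow]:
    """One row per annotated item and annotated code-list entry."""
    rows: list[AnnotationRow] = []
    for it in model.items:
        if it.annotation is not None:
            rows.append(AnnotationRow(it.oid, "item", it.name, it.annotation))
    for cl in model.codelists:
        for entry in cl.entries:
            if entry.annotation is not None:
                rows.append(AnnotationRow(entry_oid(cl.oid, entry.coded_value),
                                          "codelist_entry", entry.decode_text,
                                          entry.annotation))
    return rows


def annotation_targets(model: DataModel,
                       include_codelist_entries: bool = True) -> list[tuple[str, OwnerKind, str, Optional[AnnotationSignature]]]:
    """Every annotatable element: (owner_oid, kind, display name, annotation)."""
    targets: list[tuple[str, OwnerKind, str, Optional[AnnotationSignature]]] = [
        (it.oid, "item", it.name, it.annotation) for it in model.items
    ]
    if include_codelist_entries:
        for cl in model.codelists:
            for entry in cl.entries:
                targets.append((entry_oid(cl.oid, entry.coded_value), "codelist_entry",
                                entry.decode_text, entry.annotation))
    return targets


def annotations_to_tsv(model: DataModel) -> str:
    """Export extracted annotations as TSV: owner_oid, owner_kind, name, signature."""
    lines = ["owner_oid\towner_kind\tname\tsignature"]
    for row in extract_annotations(model):
        lines.append(f"{row.owner_oid}\t{row.owner_kind}\t{row.name}\t{row.signature.canonical}")
    return "\n".join(lines) + "\n"
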