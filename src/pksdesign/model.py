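"""Hierarchical PKS object model and its JSON interchange format.

A type I modular PKS is described as a :class:`Cluster` of ordered
:class:`Subunit` polypeptides, each carrying ordered :class:`Module` objects,
each an ordered list of :class:`DomainAnnotation`. Module index 0 is the
loading module; extension modules follow in catalytic order. The JSON format
is documented normatively in ``data/cluster.schema.json`` and is validated in
code here, with errors that name the offending JSON path.

Curation edits are expressed as :class:`CorrectionRecord` documents — flat,
ordered, idempotent command lists that are re-applied on top of any
automatically generated annotation, so a manually corrected cluster stays
corrected when its upstream annotation is regenerated.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

from .errors import CorrectionError, SchemaError, ValidationError

SCHEMA_VERSION = "1.0"

DOMAIN_KINDS = ("AT_L", "KS", "AT", "KR", "DH", "ER", "cMT", "oMT", "ACP", "TE")
KR_TYPES = ("A1", "A2", "B1", "B2", "C1", "C2", "U")
TE_MODES = ("hydrolysis", "cyclization")
REDUCTIVE_KINDS = ("KR", "DH", "ER")

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class DomainAnnotation:
    """A single catalytic domain with its curated annotation.

    ``residue_range`` is 1-based inclusive ``(start, stop)`` into the parent
    subunit's sequence, or ``None`` for synthetic domains without coordinates.
    ``annotations`` is a free-form map reserved for externally supplied
    per-residue strings (secondary structure, solvent accessibility); the
    package stores but never computes them.
    """

    kind: str
    active: bool = True
    substrate_specificity: str | None = None
    kr_type: str | None = None
    te_mode: str | None = None
    cyclization_site: int | None = None
    residue_range: tuple[int, int] | None = None
    annotations: dict = field(default_factory=dict)


@dataclass
class Module:
    """One chain-extension unit (or the loading didomain, ``index`` 0)."""

    index: int
    domains: list[DomainAnnotation]
    iterations: int = 1
    is_loading: bool = False

    def domain(self, kind: str) -> DomainAnnotation | None:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None

    def active_kinds(self) -> set[str]:
        return {d.kind for d in self.domains if d.active}


@dataclass
class Subunit:
    """A single polypeptide carrying one or more modules."""

    name: str
    sequence: str = ""
    modules: list[Module] = field(default_factory=list)

    @property
    def standalone(self) -> bool:
        """True iff the subunit carries exactly one non-loading module.

        Loading-only didomain subunits are not standalone under this
        definition.
        """
        return sum(1 for m in self.modules if not m.is_loading) == 1


@dataclass
class Cluster:
    """A complete (possibly truncated) PKS assembly line."""

    id: str
    name: str
    subunits: list[Subunit] = field(default_factory=list)
    known_product: str | None = None
    truncated: bool = False
    provenance: dict = field(default_factory=dict)

    def iter_modules(self):
        """Yield ``(subunit, module)`` in catalytic order."""
        for su in self.subunits:
            for mod in su.modules:
                yield su, mod

    def module(self, index: int) -> tuple[Subunit, Module]:
        for su, mod in self.iter_modules():
            if mod.index == index:
                return su, mod
        raise CorrectionError(f"cluster {self.id!r} has no module {index}")

    @property
    def modules(self) -> list[Module]:
        return [mod for _, mod in self.iter_modules()]


@dataclass
class CorrectionRecord:
    """Ordered, idempotent curation edits addressed to one cluster."""

    cluster_id: str
    edits: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# validation

def _require(cond: bool, message: str, path: str) -> None:
    if not cond:
        raise SchemaError(message, path)


def validate_cluster(cluster: Cluster) -> None:
    """Check every model invariant; raise :class:`ValidationError` on the
    first violation."""
    seen_loading = 0
    expected_index = 0
    for si, su in enumerate(cluster.subunits):
        if su.sequence and not set(su.sequence) <= AMINO_ALPHABET:
            bad = sorted(set(su.sequence) - AMINO_ALPHABET)
            raise ValidationError(
                f"subunit {su.name!r}: sequence contains non-amino-acid "
                f"letters {bad}")
        prev_stop = 0
        for mod in su.modules:
            if mod.index != expected_index:
                raise ValidationError(
                    f"module indices must be consecutive from 0 in subunit "
                    f"order; found {mod.index}, expected {expected_index} "
                    f"(subunit {su.name!r})")
            expected_index += 1
            if mod.iterations < 1:
                raise ValidationError(
                    f"module {mod.index}: iterations must be >= 1")
            kinds = [d.kind for d in mod.domains]
            if mod.is_loading:
                seen_loading += 1
                if mod.index != 0:
                    raise ValidationError(
                        f"loading module must be module 0, found at "
                        f"{mod.index}")
                if "KS" in kinds:
                    raise ValidationError("loading module must not contain KS")
                if kinds.count("AT_L") != 1 or "ACP" not in kinds:
                    raise ValidationError(
                        "loading module must contain exactly one AT_L and an "
                        "ACP")
            else:
                for needed in ("KS", "AT", "ACP"):
                    if kinds.count(needed) != 1:
                        raise ValidationError(
                            f"module {mod.index}: a non-loading module "
                            f"contains exactly one KS, one AT and one ACP "
                            f"(found {kinds.count(needed)} {needed})")
            prev_stop = 0
            for d in mod.domains:
                _validate_domain_fields(d, mod.index)
                if d.residue_range is not None:
                    start, stop = d.residue_range
                    if start > stop:
                        raise ValidationError(
                            f"module {mod.index} {d.kind}: residue_range "
                            f"start {start} > stop {stop}")
                    if start <= prev_stop:
                        raise ValidationError(
                            f"module {mod.index} {d.kind}: residue ranges "
                            f"within a module must be non-overlapping and "
                            f"ordered by start")
                    if su.sequence and stop > len(su.sequence):
                        raise ValidationError(
                            f"module {mod.index} {d.kind}: residue_range "
                            f"stop {stop} exceeds sequence length "
                            f"{len(su.sequence)} of subunit {su.name!r}")
                    prev_stop = stop
    if seen_loading != 1:
        raise ValidationError(
            f"cluster must contain exactly one loading module and it must be "
            f"first (found {seen_loading})")


def _validate_domain_fields(d: DomainAnnotation, module_index: int) -> None:
    where = f"module {module_index} {d.kind}"
    if d.kind not in DOMAIN_KINDS:
        raise ValidationError(f"{where}: unknown domain kind")
    if d.kind in ("AT", "AT_L"):
        if not d.substrate_specificity:
            raise ValidationError(
                f"{where}: AT/AT_L domains require substrate_specificity")
    elif d.substrate_specificity is not None:
        raise ValidationError(
            f"{where}: substrate_specificity is only valid on AT/AT_L")
    if d.kind == "KR":
        if d.kr_type not in KR_TYPES:
            raise ValidationError(
                f"{where}: KR requires kr_type in {KR_TYPES}")
    elif d.kr_type is not None:
        raise ValidationError(f"{where}: kr_type is only valid on KR")
    if d.kind == "TE":
        if d.te_mode not in TE_MODES:
            raise ValidationError(
                f"{where}: TE requires te_mode in {TE_MODES}")
        if d.te_mode == "cyclization" and d.cyclization_site is None:
            raise ValidationError(
                f"{where}: TE cyclization requires cyclization_site")
    elif d.te_mode is not None or d.cyclization_site is not None:
        raise ValidationError(f"{where}: te_mode is only valid on TE")


# ---------------------------------------------------------------------------
# JSON parsing / writing

def parse_cluster_json(text: str, strict: bool = False) -> Cluster:
    """Parse and validate a cluster interchange document.

    A subunit containing an unrecognized domain kind truncates the cluster:
    that subunit and all later subunits are dropped and ``truncated`` is set,
    mirroring the behaviour of an annotation pipeline that stops at domains
    it cannot simulate. With ``strict=True`` the same situation raises
    :class:`SchemaError` instead.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not well-formed JSON: {exc}") from exc
    return cluster_from_dict(doc, strict=strict)


def cluster_from_dict(doc: dict, strict: bool = False) -> Cluster:
    _require(isinstance(doc, dict), "document must be a JSON object", "$")
    version = doc.get("$schema_version")
    _require(version == SCHEMA_VERSION,
             f"unsupported $schema_version {version!r}", "$.$schema_version")
    for key in ("id", "name", "subunits"):
        _require(key in doc, f"missing required key {key!r}", "$")
    _require(isinstance(doc["id"], str) and doc["id"],
             "id must be a non-empty string", "$.id")
    _require(isinstance(doc["subunits"], list) and doc["subunits"],
             "subunits must be a non-empty array", "$.subunits")

    subunits: list[Subunit] = []
    truncated = bool(doc.get("truncated", False))
    for si, sdoc in enumerate(doc["subunits"]):
        spath = f"$.subunits[{si}]"
        _require(isinstance(sdoc, dict), "subunit must be an object", spath)
        _require("name" in sdoc and sdoc["name"],
                 "subunit requires a non-empty name", spath)
        _require("modules" in sdoc and isinstance(sdoc["modules"], list),
                 "subunit requires a modules array", spath)
        try:
            su = _subunit_from_dict(sdoc, spath)
        except _UnrecognizedDomain as exc:
            if strict:
                raise SchemaError(
                    f"unrecognized domain kind {exc.kind!r}", exc.path)
            truncated = True
            break
        subunits.append(su)

    cluster = Cluster(
        id=doc["id"],
        name=doc.get("name", doc["id"]),
        subunits=subunits,
        known_product=doc.get("known_product"),
        truncated=truncated,
        provenance=dict(doc.get("provenance", {})),
    )
    validate_cluster(cluster)
    return cluster


class _UnrecognizedDomain(Exception):
    def __init__(self, kind: str, path: str):
        self.kind = kind
        self.path = path


def _subunit_from_dict(sdoc: dict, spath: str) -> Subunit:
    modules = []
    for mi, mdoc in enumerate(sdoc["modules"]):
        mpath = f"{spath}.modules[{mi}]"
        _require(isinstance(mdoc, dict), "module must be an object", mpath)
        _require("index" in mdoc and isinstance(mdoc["index"], int),
                 "module requires an integer index", mpath)
        _require("domains" in mdoc and isinstance(mdoc["domains"], list)
                 and mdoc["domains"],
                 "module requires a non-empty domains array", mpath)
        domains = []
        for di, ddoc in enumerate(mdoc["domains"]):
            dpath = f"{mpath}.domains[{di}]"
            _require(isinstance(ddoc, dict), "domain must be an object", dpath)
            kind = ddoc.get("kind")
            _require(isinstance(kind, str), "domain requires a kind", dpath)
            if kind not in DOMAIN_KINDS:
                raise _UnrecognizedDomain(kind, f"{dpath}.kind")
            rr = ddoc.get("residue_range")
            if rr is not None:
                _require(isinstance(rr, list) and len(rr) == 2
                         and all(isinstance(x, int) and x >= 1 for x in rr),
                         "residue_range must be [start, stop] of 1-based "
                         "integers", f"{dpath}.residue_range")
                rr = (rr[0], rr[1])
            domains.append(DomainAnnotation(
                kind=kind,
                active=bool(ddoc.get("active", True)),
                substrate_specificity=ddoc.get("substrate_specificity"),
                kr_type=ddoc.get("kr_type"),
                te_mode=ddoc.get("te_mode"),
                cyclization_site=ddoc.get("cyclization_site"),
                residue_range=rr,
                annotations=dict(ddoc.get("annotations", {})),
            ))
        modules.append(Module(
            index=mdoc["index"],
            domains=domains,
            iterations=int(mdoc.get("iterations", 1)),
            is_loading=bool(mdoc.get("is_loading", False)),
        ))
    return Subunit(name=sdoc["name"], sequence=sdoc.get("sequence", ""),
                   modules=modules)


def cluster_to_dict(cluster: Cluster) -> dict:
    doc = {
        "$schema_version": SCHEMA_VERSION,
        "id": cluster.id,
        "name": cluster.name,
        "known_product": cluster.known_product,
        "truncated": cluster.truncated,
        "provenance": cluster.provenance,
        "subunits": [],
    }
    for su in cluster.subunits:
        sdoc = {"name": su.name, "sequence": su.sequence, "modules": []}
        for mod in su.modules:
            mdoc = {
                "index": mod.index,
                "is_loading": mod.is_loading,
                "iterations": mod.iterations,
                "domains": [],
            }
            for d in mod.domains:
                ddoc: dict = {"kind": d.kind, "active": d.active}
                if d.substrate_specificity is not None:
                    ddoc["substrate_specificity"] = d.substrate_specificity
                if d.kr_type is not None:
                    ddoc["kr_type"] = d.kr_type
                if d.te_mode is not None:
                    ddoc["te_mode"] = d.te_mode
                if d.cyclization_site is not None:
                    ddoc["cyclization_site"] = d.cyclization_site
                if d.residue_range is not None:
                    ddoc["residue_range"] = list(d.residue_range)
                if d.annotations:
                    ddoc["annotations"] = d.annotations
                mdoc["domains"].append(ddoc)
            sdoc["modules"].append(mdoc)
        doc["subunits"].append(sdoc)
    return doc


def write_cluster_json(cluster: Cluster) -> str:
    """Emit the canonical JSON form: sorted keys, 2-space indent, ``\\n``
    line ends. ``parse(write(c))`` reproduces ``c`` and
    ``write(parse(write(c)))`` is byte-identical to ``write(c)``."""
    validate_cluster(cluster)
    return json.dumps(cluster_to_dict(cluster), sort_keys=True, indent=2,
                      ensure_ascii=False) + "\n"


# ---------------------------------------------------------------------------
# corrections

def parse_corrections_json(text: str) -> CorrectionRecord:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not well-formed JSON: {exc}") from exc
    _require(isinstance(doc, dict), "document must be a JSON object", "$")
    _require(isinstance(doc.get("cluster_id"), str) and doc["cluster_id"],
             "cluster_id required", "$.cluster_id")
    edits = doc.get("edits", [])
    _require(isinstance(edits, list), "edits must be an array", "$.edits")
    return CorrectionRecord(cluster_id=doc["cluster_id"],
                            edits=[dict(e) for e in edits])


def _renumber(cluster: Cluster) -> None:
    idx = 0
    for su in cluster.subunits:
        for mod in su.modules:
            mod.index = idx
            idx += 1


def apply_corrections(cluster: Cluster, record: CorrectionRecord) -> Cluster:
    """Apply curation edits in listed order to a deep copy of ``cluster``.

    Edits address modules by their index *at the time the edit is applied*
    (reordering edits renumber). The operation is idempotent: applying the
    same record twice equals applying it once; in particular
    ``remove_subunit`` of an already absent subunit is a no-op.
    """
    if record.cluster_id != cluster.id:
        raise CorrectionError(
            f"record addresses cluster {record.cluster_id!r}, got "
            f"{cluster.id!r}")
    out = copy.deepcopy(cluster)
    for i, edit in enumerate(record.edits):
        try:
            _apply_edit(out, edit)
        except CorrectionError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with edit context
            raise CorrectionError(f"edit {i} {edit!r} failed: {exc}") from exc
    validate_cluster(out)
    return out


def _apply_edit(cluster: Cluster, edit: dict) -> None:
    op = edit.get("op")
    if op == "reorder_subunits":
        order = edit["order"]
        by_name = {su.name: su for su in cluster.subunits}
        if sorted(order) != sorted(by_name):
            raise CorrectionError(
                f"reorder_subunits order {order} does not name exactly the "
                f"subunits {sorted(by_name)}")
        cluster.subunits = [by_name[n] for n in order]
        _renumber(cluster)
    elif op == "remove_subunit":
        before = len(cluster.subunits)
        cluster.subunits = [su for su in cluster.subunits
                            if su.name != edit["name"]]
        if len(cluster.subunits) != before:
            _renumber(cluster)
    elif op == "set_iterations":
        _, mod = cluster.module(edit["module"])
        n = int(edit["n"])
        if n < 1:
            raise CorrectionError("iterations must be >= 1")
        mod.iterations = n
    elif op == "set_domain_activity":
        _, mod = cluster.module(edit["module"])
        d = mod.domain(edit["domain"])
        if d is None:
            raise CorrectionError(
                f"module {edit['module']} has no {edit['domain']} domain")
        d.active = bool(edit["active"])
    elif op == "set_substrate":
        _, mod = cluster.module(edit["module"])
        d = mod.domain("AT") or mod.domain("AT_L")
        if d is None:
            raise CorrectionError(
                f"module {edit['module']} has no AT/AT_L domain")
        d.substrate_specificity = edit["name"]
    elif op == "set_kr_type":
        _, mod = cluster.module(edit["module"])
        d = mod.domain("KR")
        if d is None:
            raise CorrectionError(f"module {edit['module']} has no KR domain")
        if edit["type"] not in KR_TYPES:
            raise CorrectionError(f"unknown KR type {edit['type']!r}")
        d.kr_type = edit["type"]
    elif op == "set_te_mode":
        _, mod = cluster.module(edit["module"])
        d = mod.domain("TE")
        if d is None:
            raise CorrectionError(f"module {edit['module']} has no TE domain")
        if edit["mode"] not in TE_MODES:
            raise CorrectionError(f"unknown TE mode {edit['mode']!r}")
        d.te_mode = edit["mode"]
        d.cyclization_site = edit.get("site")
    else:
        raise CorrectionError(f"unknown edit op {op!r}")


# ---------------------------------------------------------------------------
# architecture predicates

@dataclass(frozen=True)
class ArchitectureSignature:
    """Search-filter facts about one module: whether its subunit is
    standalone, the AT substrate, the set of *active* reductive domains and
    whether a methyltransferase is present."""

    standalone: bool
    at_substrate: str | None
    cassette: frozenset[str]
    has_mt: bool


def architecture_signature(module: Module,
                           subunit: Subunit | None = None
                           ) -> ArchitectureSignature:
    """Read off the architecture signature of ``module``.

    ``subunit`` supplies the context for the standalone predicate; without
    it, standalone is reported as False.
    """
    at = module.domain("AT") or module.domain("AT_L")
    cassette = frozenset(
        d.kind for d in module.domains
        if d.kind in REDUCTIVE_KINDS and d.active)
    has_mt = any(d.kind in ("cMT", "oMT") for d in module.domains)
    return ArchitectureSignature(
        standalone=bool(subunit is not None and subunit.standalone),
        at_substrate=at.substrate_specificity if at else None,
        cassette=cassette,
        has_mt=has_mt,
    )


# ---------------------------------------------------------------------------
# FASTA export

def write_subunit_fasta(clusters: list[Cluster]) -> str:
    """One record per subunit, id ``cluster_id|subunit_name``."""
    lines = []
    for cluster in clusters:
        for su in cluster.subunits:
            lines.append(f">{cluster.id}|{su.name}")
            seq = su.sequence
            for i in range(0, len(seq), 60):
                lines.append(seq[i:i + 60])
    return "\n".join(lines) + "\n"
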