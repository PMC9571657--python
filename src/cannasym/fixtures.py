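"""Packaged collection records and the Florescence Description Format (FDF).

The builtin registry transcribes the 16 aberrant partial-florescence
collections (Ci-1..Ci-8 from *Canna indica*, Cg-1..Cg-8 from *C. glauca*)
plus two normal-type cincinni, one per species, flagged ``normal``.  Each
record couples a branching topology with the observed per-flower floral
diagrams, provenance annotations and figure cross-references.

FDF is a canonical JSON document::

    {"version": "1.0", "id": ..., "species": ..., "pf_class": ...,
     "normal": bool, "figures": [...], "topology": <node>,
     "observed": {<flower_id>: <phenotype>}, "annotations": {...},
     "rule_exceptions": {<flower_id>: true}}

with node = {"kind", "order", "bract": {"order_index", "angle_deg",
"fused_with"} | null, "status", "handedness" | null, "children": [...]}.
Child order is significant.  Serialization is canonical (sorted keys,
integral angles written as integers), so write-then-read and
read-then-write are identities on valid records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional

from .morphology import FloralPhenotype, OrganState
from .topology import (
    BractPlacement,
    FlorescenceNode,
    MATURE,
    assign_ids,
    classify_partial_florescence,
    validate_tree,
)

FDF_VERSION = "1.0"

COLLECTION_IDS = (
    "Ci-1", "Ci-2", "Ci-3", "Ci-4", "Ci-5", "Ci-6", "Ci-7", "Ci-8",
    "Cg-1", "Cg-2", "Cg-3", "Cg-4", "Cg-5", "Cg-6", "Cg-7", "Cg-8",
    "Ci-normal", "Cg-normal",
)


class FDFError(ValueError):
    """Malformed or invariant-violating FDF document; carries a JSON path."""

    def __init__(self, path: str, message: str) -> None:
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass
class CollectionRecord:
    """One partial florescence: topology, observations, provenance."""

    id: str
    species: str
    pf_class: str
    topology: FlorescenceNode
    observed: dict[str, FloralPhenotype] = field(default_factory=dict)
    annotations: dict[str, Any] = field(default_factory=dict)
    rule_exceptions: dict[str, bool] = field(default_factory=dict)
    normal: bool = False
    figures: list[str] = field(default_factory=list)

    def validate(self) -> list[str]:
        problems = [f"topology: {v}" for v in validate_tree(self.topology)]
        pf = classify_partial_florescence(self.topology)
        if pf.label != self.pf_class:
            problems.append(
                f"pf_class: recorded {self.pf_class!r} but topology classifies as {pf.label!r}"
            )
        mature_ids = {f.id for f in self.topology.flowers(status=MATURE)}
        for fid, phenotype in self.observed.items():
            if fid not in mature_ids:
                problems.append(f"observed[{fid!r}]: not a mature flower of the topology")
            problems.extend(f"observed[{fid!r}]: {p}" for p in phenotype.validate())
        for fid in self.rule_exceptions:
            if fid not in mature_ids:
                problems.append(f"rule_exceptions[{fid!r}]: not a mature flower")
        return problems


# ---------------------------------------------------------------------------
# (de)serialization


def _num(x: float) -> Any:
    """Write integral floats as ints for byte-stable canonical output."""
    if isinstance(x, float) and x.is_integer():
        return int(x)
    return x


def _node_to_obj(node: FlorescenceNode) -> dict:
    bract = None
    if node.subtending_bract is not None:
        bract = {
            "order_index": node.subtending_bract.order_index,
            "angle_deg": _num(node.subtending_bract.angle_deg),
            "fused_with": node.subtending_bract.fused_with,
        }
    return {
        "kind": node.kind,
        "order": node.order,
        "bract": bract,
        "status": node.status,
        "handedness": node.handedness,
        "children": [_node_to_obj(c) for c in node.children],
    }


def _phenotype_to_obj(p: FloralPhenotype) -> dict:
    return {
        "sepal_count": p.sepal_count,
        "petal_count": p.petal_count,
        "organ_states": [
            {
                "whorl": o.whorl,
                "identity": o.identity,
                "state": o.state,
                "position_deg": _num(o.position_deg),
            }
            for o in p.organ_states
        ],
        "theca_count": p.theca_count,
        "appendage_side": p.appendage_side,
        "locule_count": p.locule_count,
        "style_form": p.style_form,
        "symmetry": p.symmetry,
        "zygomorphy_axis": p.zygomorphy_axis,
    }


def record_to_document(record: CollectionRecord) -> dict:
    return {
        "version": FDF_VERSION,
        "id": record.id,
        "species": record.species,
        "pf_class": record.pf_class,
        "normal": record.normal,
        "figures": list(record.figures),
        "topology": _node_to_obj(record.topology),
        "observed": {fid: _phenotype_to_obj(p) for fid, p in sorted(record.observed.items())},
        "annotations": record.annotations,
        "rule_exceptions": {fid: v for fid, v in sorted(record.rule_exceptions.items())},
    }


def write_collection(record: CollectionRecord) -> str:
    """Canonical FDF text for a record (sorted keys, 2-space indent)."""
    problems = record.validate()
    if problems:
        raise FDFError("$", "cannot serialize invalid record: " + "; ".join(problems))
    return json.dumps(record_to_document(record), sort_keys=True, indent=2) + "\n"


def _expect(obj: Any, typ, path: str, allow_none: bool = False) -> Any:
    if obj is None and allow_none:
        return None
    if typ is float and isinstance(obj, int) and not isinstance(obj, bool):
        return float(obj)
    if typ is int and isinstance(obj, bool):
        raise FDFError(path, "expected an integer, got a boolean")
    if not isinstance(obj, typ):
        raise FDFError(path, f"expected {typ.__name__}, got {type(obj).__name__}")
    return obj


def _obj_to_node(obj: Any, path: str) -> FlorescenceNode:
    _expect(obj, dict, path)
    bract_obj = obj.get("bract")
    bract = None
    if bract_obj is not None:
        _expect(bract_obj, dict, f"{path}.bract")
        bract = BractPlacement(
            order_index=_expect(bract_obj.get("order_index"), int, f"{path}.bract.order_index"),
            angle_deg=_expect(bract_obj.get("angle_deg"), float, f"{path}.bract.angle_deg"),
            fused_with=_expect(
                bract_obj.get("fused_with"), str, f"{path}.bract.fused_with", allow_none=True
            ),
        )
    children_obj = _expect(obj.get("children", []), list, f"{path}.children")
    return FlorescenceNode(
        kind=_expect(obj.get("kind"), str, f"{path}.kind"),
        order=_expect(obj.get("order"), int, f"{path}.order"),
        subtending_bract=bract,
        status=_expect(obj.get("status", MATURE), str, f"{path}.status"),
        handedness=_expect(obj.get("handedness"), str, f"{path}.handedness", allow_none=True),
        children=[
            _obj_to_node(c, f"{path}.children[{i}]") for i, c in enumerate(children_obj)
        ],
    )


def _obj_to_phenotype(obj: Any, path: str) -> FloralPhenotype:
    _expect(obj, dict, path)
    organs = []
    for i, o in enumerate(_expect(obj.get("organ_states", []), list, f"{path}.organ_states")):
        opath = f"{path}.organ_states[{i}]"
        _expect(o, dict, opath)
        try:
            organs.append(
                OrganState(
                    whorl=_expect(o.get("whorl"), str, f"{opath}.whorl"),
                    identity=_expect(o.get("identity"), str, f"{opath}.identity"),
                    state=_expect(o.get("state"), str, f"{opath}.state"),
                    position_deg=_expect(o.get("position_deg"), float, f"{opath}.position_deg"),
                )
            )
        except ValueError as exc:
            raise FDFError(opath, str(exc)) from exc
    return FloralPhenotype(
        sepal_count=_expect(obj.get("sepal_count"), int, f"{path}.sepal_count", allow_none=True),
        petal_count=_expect(obj.get("petal_count"), int, f"{path}.petal_count", allow_none=True),
        organ_states=organs,
        theca_count=_expect(obj.get("theca_count"), int, f"{path}.theca_count", allow_none=True),
        appendage_side=_expect(obj.get("appendage_side", "none"), str, f"{path}.appendage_side"),
        locule_count=_expect(obj.get("locule_count"), int, f"{path}.locule_count", allow_none=True),
        style_form=_expect(obj.get("style_form"), str, f"{path}.style_form", allow_none=True),
        symmetry=_expect(obj.get("symmetry"), str, f"{path}.symmetry", allow_none=True),
        zygomorphy_axis=_expect(
            obj.get("zygomorphy_axis"), str, f"{path}.zygomorphy_axis", allow_none=True
        ),
    )


def read_collection(document: str | dict) -> CollectionRecord:
    """Parse and validate one FDF document (text or parsed object)."""
    if isinstance(document, str):
        if not document.strip():
            raise FDFError("$", "empty document")
        try:
            obj = json.loads(document)
        except json.JSONDecodeError as exc:
            raise FDFError("$", f"not valid JSON: {exc}") from exc
    else:
        obj = document
    _expect(obj, dict, "$")
    version = _expect(obj.get("version"), str, "$.version")
    if version != FDF_VERSION:
        raise FDFError("$.version", f"unsupported FDF version {version!r}")
    topology = assign_ids(_obj_to_node(obj.get("topology"), "$.topology"))
    observed_obj = _expect(obj.get("observed", {}), dict, "$.observed")
    record = CollectionRecord(
        id=_expect(obj.get("id"), str, "$.id"),
        species=_expect(obj.get("species"), str, "$.species"),
        pf_class=_expect(obj.get("pf_class"), str, "$.pf_class"),
        topology=topology,
        observed={
            fid: _obj_to_phenotype(p, f"$.observed[{fid!r}]") for fid, p in observed_obj.items()
        },
        annotations=_expect(obj.get("annotations", {}), dict, "$.annotations"),
        rule_exceptions={
            fid: bool(v)
            for fid, v in _expect(obj.get("rule_exceptions", {}), dict, "$.rule_exceptions").items()
        },
        normal=bool(obj.get("normal", False)),
        figures=list(_expect(obj.get("figures", []), list, "$.figures")),
    )
    problems = record.validate()
    if problems:
        raise FDFError("$", "; ".join(problems))
    return record


# ---------------------------------------------------------------------------
# builtin registry


def _data_dir():
    return resources.files("cannasym").joinpath("data", "collections")


def load_collections(
    source: str | Path = "builtin",
    *,
    species: Optional[str] = None,
    include_normal: bool = True,
) -> list[CollectionRecord]:
    """Load collection records from the builtin registry or an FDF file/directory.

    The builtin registry returns 16 aberrant records (8 per species) plus 2
    normal-type records unless ``include_normal=False``.  ``species`` filters
    by binomial (e.g. ``"Canna glauca"``).
    """
    records: list[CollectionRecord] = []
    if source == "builtin":
        base = _data_dir()
        for cid in COLLECTION_IDS:
            text = base.joinpath(f"{cid}.fdf.json").read_text(encoding="utf-8")
            records.append(read_collection(text))
    else:
        path = Path(source)
        if path.is_dir():
            for p in sorted(path.glob("*.fdf.json")):
                records.append(read_collection(p.read_text(encoding="utf-8")))
        elif path.is_file():
            records.append(read_collection(path.read_text(encoding="utf-8")))
        else:
            raise FileNotFoundError(f"no FDF source at {source}")
    if species is not None:
        records = [r for r in records if r.species == species]
    if not include_normal:
        records = [r for r in records if not r.normal]
    return records


def get_collection(collection_id: str) -> CollectionRecord:
    """One builtin record by its registry label (e.g. ``"Ci-5"``)."""
    for record in load_collections("builtin"):
        if record.id == collection_id:
            return record
    raise KeyError(f"no builtin collection {collection_id!r}")
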