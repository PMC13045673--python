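"""Biologic-indication rule sets evaluated with three-valued logic.

Two expert recommendation sets define when a CRSwNP patient is indicated
for biologic therapy:

* **EUFOREA 2021** — uncontrolled severe disease: disease history (prior
  endoscopic sinus surgery and/or >= 1 systemic corticosteroid course in
  the past year), severity (nasal polyp score >= 4), and at least one
  persistent-symptom criterion (SNOT-22 >= 35, VAS total sinus symptoms
  >= 50 mm, VAS nasal blockage >= 50 mm, VAS loss of smell >= 52 mm).
* **EPOS/EUFOREA 2023** — prior endoscopic sinus surgery plus at least
  3 of 5 uncontrolled-severe criteria: type-2 inflammation (blood
  eosinophils >= 150 cells/uL and/or total IgE >= 100 IU/mL), >= 2
  corticosteroid courses in the past year, SNOT-22 >= 40, VAS loss of
  smell >= 52 mm, and comorbid asthma.

Rule sets are declarative criterion trees (serializable to JSON, schema in
``data/ruleset_schema.json``) rather than hard-coded branching, so users can
express national variants (e.g. NPS >= 5 or SNOT-22 >= 50); only the two
international sets ship.

Records with missing fields are evaluated under strong Kleene logic
(:mod:`crseligible.tristate`): a composite can be determinate even when
some leaves are not — e.g. a failed surgery gate settles the 2023 verdict
regardless of missing laboratory values.  A patient is *evaluable* for a
rule set iff the composite verdict is determinate, which is what makes the
reported denominators of a composite differ from its components'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .cohort_model import FIELDS, PatientRecord
from .tristate import (FALSE, TRUE, UNKNOWN, TriState, kleene_and, kleene_or,
                       lift_bool)

__all__ = [
    "TriState", "kleene_and", "kleene_or", "threshold_test", "at_least_k",
    "Threshold", "Flag", "AllOf", "AnyOf", "AtLeast", "RuleSet", "Verdict",
    "euforea_2021", "epos_2023", "bundled_rulesets", "evaluate",
    "eval_type2", "eval_euforea2021", "eval_epos2023",
    "ruleset_to_json", "ruleset_from_json", "RuleSetSchemaError",
]


def threshold_test(value: Optional[float], cutoff: float) -> TriState:
    """Three-valued >= comparison: UNKNOWN when the value is missing."""
    if cutoff is None or not (float(cutoff) == float(cutoff)):
        raise ValueError("cutoff must be a finite number")
    if value is None:
        return UNKNOWN
    return TRUE if value >= cutoff else FALSE


def at_least_k(states: Sequence[TriState], k: int) -> TriState:
    """Three-valued "at least k of n".

    TRUE when the TRUE count already reaches ``k``; FALSE when even turning
    every UNKNOWN into TRUE cannot reach ``k``; UNKNOWN otherwise.  This is
    exactly the completion semantics: TRUE iff every completion of the
    UNKNOWNs meets the quota, FALSE iff none does.
    """
    if not (1 <= k <= len(states)):
        raise ValueError(f"k={k} out of range for {len(states)} states")
    n_true = sum(1 for s in states if s is TRUE)
    n_unknown = sum(1 for s in states if s is UNKNOWN)
    if n_true >= k:
        return TRUE
    if n_true + n_unknown < k:
        return FALSE
    return UNKNOWN


# ---------------------------------------------------------------------------
# criterion trees


@dataclass(frozen=True)
class Threshold:
    """Leaf: numeric record field compared as ``field >= cutoff``."""

    id: str
    field: str
    cutoff: float

    def evaluate(self, record: PatientRecord) -> TriState:
        return threshold_test(getattr(record, self.field), self.cutoff)


@dataclass(frozen=True)
class Flag:
    """Leaf: boolean record field lifted to TriState (missing -> UNKNOWN)."""

    id: str
    field: str

    def evaluate(self, record: PatientRecord) -> TriState:
        return lift_bool(getattr(record, self.field))


@dataclass(frozen=True)
class AllOf:
    """Kleene conjunction of child criteria."""

    id: str
    children: Tuple["Criterion", ...]

    def evaluate(self, record: PatientRecord) -> TriState:
        out = TRUE
        for child in self.children:
            out = kleene_and(out, child.evaluate(record))
        return out


@dataclass(frozen=True)
class AnyOf:
    """Kleene disjunction of child criteria."""

    id: str
    children: Tuple["Criterion", ...]

    def evaluate(self, record: PatientRecord) -> TriState:
        out = FALSE
        for child in self.children:
            out = kleene_or(out, child.evaluate(record))
        return out


@dataclass(frozen=True)
class AtLeast:
    """At-least-k-of-n over child criteria (completion semantics)."""

    id: str
    k: int
    children: Tuple["Criterion", ...]

    def evaluate(self, record: PatientRecord) -> TriState:
        return at_least_k([c.evaluate(record) for c in self.children], self.k)


Criterion = Union[Threshold, Flag, AllOf, AnyOf, AtLeast]


def walk_postorder(node: Criterion) -> List[Criterion]:
    """All nodes, children before parents — the documented component order
    (matches the row order of the published indication tables)."""
    out: List[Criterion] = []
    for child in getattr(node, "children", ()):
        out.extend(walk_postorder(child))
    out.append(node)
    return out


def leaves(node: Criterion) -> List[Criterion]:
    return [n for n in walk_postorder(node) if isinstance(n, (Threshold, Flag))]


# ---------------------------------------------------------------------------
# rule sets

#: Threshold constants shared by the bundled rule sets.
THRESHOLDS: Mapping[str, float] = MappingProxyType({
    "nps_min": 4,
    "snot22_min_2021": 35,
    "snot22_min_2023": 40,
    "vas_tss_min": 50.0,   # mm
    "vas_nb_min": 50.0,    # mm
    "vas_los_min": 52.0,   # mm, smell-loss VAS surrogate for anosmia
    "bec_min": 150.0,      # cells/uL
    "ige_min": 100.0,      # IU/mL
    "scs_min_2021": 1,     # courses/year
    "scs_min_2023": 2,     # courses/year
    "k_of_n": (3, 5),
})


@dataclass(frozen=True)
class RuleSet:
    """A named criterion tree plus its threshold table (read-only)."""

    name: str
    tree: Criterion
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "thresholds",
                           MappingProxyType(dict(self.thresholds)))

    @property
    def component_ids(self) -> Tuple[str, ...]:
        return tuple(n.id for n in walk_postorder(self.tree))


@dataclass(frozen=True)
class Verdict:
    """Composite TriState plus the per-criterion breakdown.

    ``components`` holds every node of the rule tree (leaves and named
    sub-composites) in documented order; ``evaluable`` is True iff the
    overall verdict is determinate.
    """

    ruleset_name: str
    overall: TriState
    components: Mapping[str, TriState]
    evaluable: bool


def euforea_2021() -> RuleSet:
    """EUFOREA 2021 indication rule: history AND severe AND uncontrolled."""
    t = THRESHOLDS
    tree = AllOf("overall", (
        AnyOf("history", (
            Threshold("ess", "n_ess", 1),
            Threshold("scs", "n_scs_past_year", t["scs_min_2021"]),
        )),
        AllOf("uncontrolled_severe", (
            Threshold("nps", "nps", t["nps_min"]),
            AnyOf("uncontrolled", (
                Threshold("snot22", "snot22", t["snot22_min_2021"]),
                Threshold("vas_tss", "vas_tss", t["vas_tss_min"]),
                Threshold("vas_nb", "vas_nb", t["vas_nb_min"]),
                Threshold("vas_los", "vas_los", t["vas_los_min"]),
            )),
        )),
    ))
    return RuleSet("EUFOREA2021", tree, t)


def epos_2023() -> RuleSet:
    """EPOS/EUFOREA 2023 rule: prior surgery AND >=3 of 5 uncontrolled-severe."""
    t = THRESHOLDS
    tree = AllOf("overall", (
        Threshold("ess", "n_ess", 1),
        AtLeast("uncontrolled_severe", t["k_of_n"][0], (
            AnyOf("type2", (
                Threshold("bec", "bec", t["bec_min"]),
                Threshold("ige", "ige", t["ige_min"]),
            )),
            Threshold("scs", "n_scs_past_year", t["scs_min_2023"]),
            Threshold("snot22", "snot22", t["snot22_min_2023"]),
            Threshold("vas_los", "vas_los", t["vas_los_min"]),
            Flag("asthma", "asthma"),
        )),
    ))
    return RuleSet("EPOS2023", tree, t)


def bundled_rulesets() -> Dict[str, RuleSet]:
    """The two shipped rule sets keyed by canonical name."""
    return {"EUFOREA2021": euforea_2021(), "EPOS2023": epos_2023()}


def evaluate(ruleset: RuleSet, record: PatientRecord) -> Verdict:
    """Evaluate a rule set on one record, recording every component."""
    components = {
        node.id: node.evaluate(record) for node in walk_postorder(ruleset.tree)
    }
    overall = components[ruleset.tree.id]
    return Verdict(
        ruleset_name=ruleset.name,
        overall=overall,
        components=MappingProxyType(components),
        evaluable=overall.is_determinate(),
    )


def eval_type2(bec: Optional[float], ige: Optional[float],
               ruleset: Optional[RuleSet] = None) -> TriState:
    """Type-2 inflammation: BEC >= 150 cells/uL and/or total IgE >= 100 IU/mL."""
    t = ruleset.thresholds if ruleset is not None else THRESHOLDS
    return kleene_or(threshold_test(bec, t["bec_min"]),
                     threshold_test(ige, t["ige_min"]))


def eval_euforea2021(record: PatientRecord,
                     ruleset: Optional[RuleSet] = None) -> Verdict:
    return evaluate(ruleset if ruleset is not None else euforea_2021(), record)


def eval_epos2023(record: PatientRecord,
                  ruleset: Optional[RuleSet] = None) -> Verdict:
    return evaluate(ruleset if ruleset is not None else epos_2023(), record)


# ---------------------------------------------------------------------------
# JSON serialization


class RuleSetSchemaError(ValueError):
    """A rule-set JSON document does not match the published schema."""


def _node_to_dict(node: Criterion) -> dict:
    if isinstance(node, Threshold):
        return {"type": "threshold", "id": node.id,
                "field": node.field, "cutoff": node.cutoff}
    if isinstance(node, Flag):
        return {"type": "flag", "id": node.id, "field": node.field}
    if isinstance(node, AllOf):
        return {"type": "all_of", "id": node.id,
                "children": [_node_to_dict(c) for c in node.children]}
    if isinstance(node, AnyOf):
        return {"type": "any_of", "id": node.id,
                "children": [_node_to_dict(c) for c in node.children]}
    if isinstance(node, AtLeast):
        return {"type": "at_least", "id": node.id, "k": node.k,
                "children": [_node_to_dict(c) for c in node.children]}
    raise TypeError(f"unknown node {node!r}")


def _node_from_dict(doc: dict, where: str = "tree") -> Criterion:
    if not isinstance(doc, dict) or "type" not in doc:
        raise RuleSetSchemaError(f"{where}: node must be an object with 'type'")
    ntype = doc["type"]
    nid = doc.get("id")
    if not isinstance(nid, str) or not nid:
        raise RuleSetSchemaError(f"{where}: missing or empty 'id'")
    if ntype == "threshold":
        fname, cutoff = doc.get("field"), doc.get("cutoff")
        if fname not in FIELDS or FIELDS[fname].kind not in ("int", "float"):
            raise RuleSetSchemaError(
                f"{where}/{nid}: 'field' must name a numeric record field")
        if not isinstance(cutoff, (int, float)) or isinstance(cutoff, bool):
            raise RuleSetSchemaError(f"{where}/{nid}: 'cutoff' must be a number")
        return Threshold(nid, fname, cutoff)
    if ntype == "flag":
        fname = doc.get("field")
        if fname not in FIELDS or FIELDS[fname].kind != "bool":
            raise RuleSetSchemaError(
                f"{where}/{nid}: 'field' must name a boolean record field")
        return Flag(nid, fname)
    if ntype in ("all_of", "any_of", "at_least"):
        raw = doc.get("children")
        if not isinstance(raw, list) or not raw:
            raise RuleSetSchemaError(
                f"{where}/{nid}: 'children' must be a non-empty array")
        children = tuple(
            _node_from_dict(c, f"{where}/{nid}") for c in raw)
        if ntype == "all_of":
            return AllOf(nid, children)
        if ntype == "any_of":
            return AnyOf(nid, children)
        k = doc.get("k")
        if not isinstance(k, int) or isinstance(k, bool) \
                or not 1 <= k <= len(children):
            raise RuleSetSchemaError(
                f"{where}/{nid}: 'k' must be an integer in [1, n_children]")
        return AtLeast(nid, k, children)
    raise RuleSetSchemaError(f"{where}: unknown node type {ntype!r}")


def ruleset_to_json(ruleset: RuleSet) -> str:
    """Serialize a rule set to a JSON document."""
    doc = {
        "name": ruleset.name,
        "thresholds": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in ruleset.thresholds.items()},
        "tree": _node_to_dict(ruleset.tree),
    }
    return json.dumps(doc, indent=2)


def ruleset_from_json(text_or_path: Union[str, Path]) -> RuleSet:
    """Parse and validate a rule-set JSON document (string or file path)."""
    if isinstance(text_or_path, Path):
        text = text_or_path.read_text(encoding="utf-8")
    else:
        text = text_or_path
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RuleSetSchemaError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise RuleSetSchemaError("document must be a JSON object")
    name = doc.get("name")
    if not isinstance(name, str) or not name:
        raise RuleSetSchemaError("missing or empty 'name'")
    tree = _node_from_dict(doc.get("tree"), "tree")
    ids = [n.id for n in walk_postorder(tree)]
    if len(ids) != len(set(ids)):
        raise RuleSetSchemaError("criterion ids must be unique within a tree")
    thresholds = doc.get("thresholds", {})
    if not isinstance(thresholds, dict):
        raise RuleSetSchemaError("'thresholds' must be an object")
    thresholds = {k: tuple(v) if isinstance(v, list) else v
                  for k, v in thresholds.items()}
    return RuleSet(name, tree, thresholds)
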