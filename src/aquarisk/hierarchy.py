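"""Weighted index hierarchy for introduction-risk assessment.

The model is a three-layer criterion tree below a single total node: primary
indices (hazard / entry / exposure / consequence), secondary indices beneath
them, and tertiary indices that receive the 0-5 expert scores.  Each non-root
node carries the weight of its contribution to its parent; the weights of any
sibling group sum to one, so every aggregate is a convex combination of the
scores beneath it.

The default model (four primary, twelve secondary, sixty tertiary indices,
with weights derived by the analytic hierarchy process) ships with the
package; :func:`load_hierarchy` accepts any other depth-3 tree with the same
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError

LEVELS = ("total", "primary", "secondary", "tertiary")

#: printed weight coefficients carry four decimal places, so a sibling group
#: may miss 1 by up to one unit in the fourth decimal per child
WEIGHT_SUM_TOL = 1e-4

_DATA = resources.files("aquarisk") / "data"
DEFAULT_MODEL_RESOURCE = _DATA / "default_model.yaml"


@dataclass(frozen=True)
class IndexNode:
    """One criterion in the hierarchy.

    ``weight`` is the node's unitless fraction of its parent, in (0, 1];
    it is ``None`` only for the total (root) node.
    """

    id: str
    label: str
    level: str
    parent_id: str | None = None
    weight: float | None = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ConfigError(
                f"node {self.id!r}: unknown level {self.level!r} "
                f"(expected one of {LEVELS})"
            )
        if self.level == "total":
            if self.parent_id is not None or self.weight is not None:
                raise ConfigError(f"total node {self.id!r} must not have a parent or weight")
        else:
            if self.parent_id is None:
                raise ConfigError(f"node {self.id!r}: missing parent")
            if self.weight is None:
                raise ConfigError(f"node {self.id!r}: missing weight")
            if not 0.0 < self.weight <= 1.0:
                raise ConfigError(
                    f"node {self.id!r}: weight {self.weight} outside (0, 1]"
                )


class RiskHierarchy:
    """A validated weighted index tree.

    Nodes are kept in configuration order, which for the default model is the
    published table order; ``tertiary_ids`` therefore matches the row order of
    the published score sheet.
    """

    def __init__(self, nodes: Iterable[IndexNode], model_name: str = "unnamed",
                 model_version: str = "0"):
        self.model_name = model_name
        self.model_version = model_version
        self.nodes: dict[str, IndexNode] = {}
        self._children: dict[str, list[str]] = {}
        root = None
        for node in nodes:
            if node.id in self.nodes:
                raise ConfigError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
            if node.level == "total":
                if root is not None:
                    raise ConfigError(
                        f"multiple total nodes: {root!r} and {node.id!r}"
                    )
                root = node.id
            else:
                self._children.setdefault(node.parent_id, []).append(node.id)
        if root is None:
            raise ConfigError("no total (root) node in configuration")
        self.root_id = root
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        parent_level = {"primary": "total", "secondary": "primary",
                        "tertiary": "secondary"}
        reached = set()
        for node in self.nodes.values():
            if node.level == "total":
                reached.add(node.id)
                continue
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise ConfigError(
                    f"node {node.id!r}: parent {node.parent_id!r} does not exist"
                )
            if parent.level != parent_level[node.level]:
                raise ConfigError(
                    f"node {node.id!r} ({node.level}) has parent "
                    f"{parent.id!r} of level {parent.level!r}; expected "
                    f"{parent_level[node.level]!r}"
                )
            reached.add(node.id)
        if reached != set(self.nodes):
            raise ConfigError("hierarchy is not a single connected tree")
        for node in self.nodes.values():
            if node.level in ("total", "primary", "secondary") and not self._children.get(node.id):
                raise ConfigError(f"internal node {node.id!r} has no children")
        bad = []
        for parent_id, child_ids, total in self.sibling_weight_groups():
            if abs(total - 1.0) > WEIGHT_SUM_TOL:
                bad.append(f"{parent_id} -> {child_ids} sums to {total:.4f}")
        if bad:
            raise ConfigError(
                "sibling weights must sum to 1 within "
                f"{WEIGHT_SUM_TOL}: " + "; ".join(bad)
            )

    def children(self, parent_id: str) -> list[str]:
        return list(self._children.get(parent_id, []))

    def ids_at_level(self, level: str) -> list[str]:
        return [n.id for n in self.nodes.values() if n.level == level]

    @property
    def tertiary_ids(self) -> list[str]:
        return self.ids_at_level("tertiary")

    def level_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(LEVELS, 0)
        for node in self.nodes.values():
            counts[node.level] += 1
        return counts

    def sibling_weight_groups(self) -> list[tuple[str, tuple[str, ...], float]]:
        """Every (parent id, child ids, weight sum) group, in node order.

        The default model has 17 groups: one at the total level, four
        primary->secondary, and twelve secondary->tertiary.
        """
        groups = []
        for parent_id, child_ids in self._children.items():
            total = sum(self.nodes[c].weight for c in child_ids)
            groups.append((parent_id, tuple(child_ids), total))
        return groups

    # -- (de)serialisation -------------------------------------------------

    def to_config(self) -> dict:
        records = []
        for node in self.nodes.values():
            rec = {"id": node.id, "label": node.label, "level": node.level}
            if node.level != "total":
                rec["parent"] = node.parent_id
                rec["weight"] = node.weight
            records.append(rec)
        return {
            "model_name": self.model_name,
            "model_version": self.model_version,
            "schema_version": 1,
            "nodes": records,
        }


def _node_from_record(rec: Mapping, position: int) -> IndexNode:
    if not isinstance(rec, Mapping):
        raise ConfigError(f"node record #{position} is not a mapping: {rec!r}")
    missing = {"id", "level"} - set(rec)
    if missing:
        raise ConfigError(
            f"node record #{position} ({rec.get('id', '?')!r}) is missing "
            f"fields: {sorted(missing)}"
        )
    weight = rec.get("weight")
    return IndexNode(
        id=str(rec["id"]),
        label=str(rec.get("label", rec["id"])),
        level=str(rec["level"]),
        parent_id=rec.get("parent"),
        weight=float(weight) if weight is not None else None,
    )


def load_model_config(source: str | Path | Mapping | None = None) -> dict:
    """Read a full model-configuration document (hierarchy, rubric, grades).

    ``source`` may be a path to a YAML document, an already-parsed mapping, or
    ``None`` / ``"default"`` for the bundled default model.
    """
    if source is None or source == "default":
        raw = DEFAULT_MODEL_RESOURCE.read_text()
        doc = yaml.safe_load(raw)
    elif isinstance(source, Mapping):
        doc = source
    else:
        try:
            doc = yaml.safe_load(Path(source).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse model config {source}: {exc}") from exc
    if not isinstance(doc, Mapping) or "nodes" not in doc:
        raise ConfigError("model config must be a mapping with a 'nodes' list")
    return dict(doc)


def load_hierarchy(source: str | Path | Mapping | None = None) -> RiskHierarchy:
    """Build a validated :class:`RiskHierarchy` from a configuration document."""
    doc = load_model_config(source)
    nodes = [_node_from_record(rec, i) for i, rec in enumerate(doc["nodes"])]
    return RiskHierarchy(
        nodes,
        model_name=str(doc.get("model_name", "unnamed")),
        model_version=str(doc.get("model_version", "0")),
    )


def default_hierarchy() -> RiskHierarchy:
    """The bundled published model: 1 total, 4 primary, 12 secondary, 60 tertiary."""
    return load_hierarchy(None)


def save_hierarchy(h: RiskHierarchy, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(h.to_config(), fh, sort_keys=False, allow_unicode=True)
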