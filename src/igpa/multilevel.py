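"""Multi-level ensemble trees.

Classifier outputs sit at the leaves (level 0); each internal node fuses
its children with information-gain proportioned averaging, optionally after
keeping only its top-k most accurate children.  A node's level is one more
than the highest internal level beneath it, and its ``alpha`` defaults to
that level.  The reference topology mirrors the three-level stack used for
HAM10000 dermoscopy classification: nine backbone groups over four
attention-head variants each, merged into DenseNet / MobileNet /
Inception-Xception families, then into a single root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .combiners import igpa_ensemble, select_top_k
from .core import LabelVector, PredictionMatrix, WeightVector

__all__ = [
    "EnsembleNode",
    "NodeRecord",
    "EnsembleReport",
    "build_tree",
    "run_tree",
    "reference_topology",
    "single_level_igpa",
    "BACKBONES",
    "HEADS",
    "LEVEL2_GROUPS",
]

# The MobileNet(V1) backbone is labelled MNv1 so its node id stays distinct
# from the MobileNet-family group node "MN" one level up.
BACKBONES = ("DN121", "DN169", "DN201", "MNv1", "MNv2", "MNv3L", "Iv3", "IRv2", "X")
HEADS = ("CCNN", "CACNN", "SEACNN", "SACNN")
LEVEL2_GROUPS: dict[str, tuple[str, ...]] = {
    "DN": ("DN121", "DN169", "DN201"),
    "MN": ("MNv1", "MNv2", "MNv3L"),
    "IX": ("Iv3", "IRv2", "X"),
}


@dataclass
class EnsembleNode:
    """One internal node of the ensemble tree.

    ``children`` holds either sub-nodes or string references to leaf
    prediction sources.  ``selection`` is ``"all"`` or ``"top_k"`` (with
    ``k``); ``alpha`` defaults to the node's level.
    """

    node_id: str
    children: list["EnsembleNode | str"]
    selection: str = "all"
    k: int | None = None
    alpha: float | None = None
    level: int = field(init=False, default=1)

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError(f"node {self.node_id!r} has no children")
        if self.selection not in ("all", "top_k"):
            raise ValueError(f"node {self.node_id!r}: unknown selection {self.selection!r}")
        if self.selection == "top_k":
            if self.k is None or self.k < 1:
                raise ValueError(f"node {self.node_id!r}: top_k needs k >= 1")
            if self.k > len(self.children):
                raise ValueError(
                    f"node {self.node_id!r}: k={self.k} exceeds "
                    f"{len(self.children)} children"
                )
        child_levels = [
            c.level if isinstance(c, EnsembleNode) else 0 for c in self.children
        ]
        self.level = 1 + max(child_levels)
        if self.alpha is None:
            self.alpha = float(self.level)
        elif self.alpha <= 0:
            raise ValueError(f"node {self.node_id!r}: alpha must be positive")
        seen: set[str] = set()
        for node in self.walk():
            if node.node_id in seen:
                raise ValueError(f"duplicate node_id {node.node_id!r}")
            seen.add(node.node_id)

    def walk(self):
        """Yield every internal node of the subtree, post-order."""
        for c in self.children:
            if isinstance(c, EnsembleNode):
                yield from c.walk()
        yield self

    def leaf_refs(self) -> list[str]:
        refs: list[str] = []
        for c in self.children:
            if isinstance(c, EnsembleNode):
                refs.extend(c.leaf_refs())
            else:
                refs.append(c)
        return refs

    def n_internal(self) -> int:
        return sum(1 for _ in self.walk())


@dataclass(frozen=True)
class NodeRecord:
    """Audit record of one node's fusion: who was kept, scored how, weighted what."""

    node_id: str
    level: int
    alpha: float
    mode: str
    selection: str
    child_ids: tuple[str, ...]
    selected_ids: tuple[str, ...]
    accuracies: tuple[float, ...]
    ig_values: tuple[float, ...]
    weights: WeightVector


@dataclass(frozen=True)
class EnsembleReport:
    """Per-node records of a tree run, keyed in post-order."""

    records: tuple[NodeRecord, ...]
    final_id: str
    mode: str

    def __getitem__(self, node_id: str) -> NodeRecord:
        for r in self.records:
            if r.node_id == node_id:
                return r
        raise KeyError(node_id)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "final_id": self.final_id,
            "nodes": [
                {
                    "node_id": r.node_id,
                    "level": r.level,
                    "alpha": r.alpha,
                    "mode": r.mode,
                    "selection": r.selection,
                    "child_ids": list(r.child_ids),
                    "selected_ids": list(r.selected_ids),
                    "accuracies": list(r.accuracies),
                    "ig_values": list(r.ig_values),
                    "weights": list(map(float, r.weights.weights)),
                    "weight_source_ids": list(r.weights.source_ids),
                }
                for r in self.records
            ],
        }


def build_tree(config: Mapping, known_sources: set[str] | None = None) -> EnsembleNode:
    """Build and validate an ensemble tree from a nested mapping.

    The mapping has ``id``, ``children`` (nested mappings or leaf-reference
    strings) and optional ``selection``, ``k``, ``alpha``.  A top-level
    ``{"topology": "reference_all" | "reference_best3"}`` shortcut resolves
    to :func:`reference_topology`.
    """
    if "topology" in config:
        name = config["topology"]
        if name == "reference_all":
            return reference_topology("all")
        if name == "reference_best3":
            return reference_topology("best3")
        raise ValueError(f"unknown named topology {name!r}")

    def _build(cfg: Mapping) -> EnsembleNode:
        if "id" not in cfg:
            raise ValueError("tree node missing 'id'")
        children: list[EnsembleNode | str] = []
        for c in cfg.get("children", []):
            if isinstance(c, str):
                if known_sources is not None and c not in known_sources:
                    raise ValueError(
                        f"node {cfg['id']!r} references unknown source {c!r}"
                    )
                children.append(c)
            else:
                children.append(_build(c))
        return EnsembleNode(
            node_id=str(cfg["id"]),
            children=children,
            selection=cfg.get("selection", "all"),
            k=cfg.get("k"),
            alpha=cfg.get("alpha"),
        )

    return _build(config)


def reference_topology(variant: str = "all") -> EnsembleNode:
    """The three-level, 36-leaf stack used for dermoscopy classification.

    Level 1: one node per backbone over its four attention heads (alpha 1).
    Level 2: DN, MN and IX family nodes over three backbones each (alpha 2).
    Level 3: a root over the three families (alpha 3).  Variant ``best3``
    applies top-3 selection at every node with four or more children (at
    the three-child nodes top-3 is the identity and is set uniformly for
    symmetry).
    """
    if variant not in ("all", "best3"):
        raise ValueError(f"unknown variant {variant!r}")
    best3 = variant == "best3"

    def sel(n_children: int) -> dict:
        if best3:
            return {"selection": "top_k", "k": min(3, n_children)}
        return {"selection": "all"}

    level1 = {
        b: EnsembleNode(
            node_id=b,
            children=[f"{b}_{h}" for h in HEADS],
            alpha=1.0,
            **sel(len(HEADS)),
        )
        for b in BACKBONES
    }
    level2 = [
        EnsembleNode(
            node_id=group,
            children=[level1[b] for b in members],
            alpha=2.0,
            **sel(len(members)),
        )
        for group, members in LEVEL2_GROUPS.items()
    ]
    return EnsembleNode(
        node_id="DMIX", children=list(level2), alpha=3.0, **sel(len(level2))
    )


def run_tree(
    root: EnsembleNode,
    store: Mapping[str, PredictionMatrix],
    weighting_truth: LabelVector,
    h_prior: float = 1.0,
    mode: str = "multiplicative",
    weighting_rows: np.ndarray | None = None,
) -> tuple[PredictionMatrix, EnsembleReport]:
    """Evaluate the tree bottom-up, fusing at every internal node.

    Children are resolved (leaves from ``store``, sub-nodes recursively),
    optionally filtered to the node's top-k most accurate, then fused with
    information-gain proportioned averaging at the node's ``alpha``.
    ``weighting_rows`` restricts correctness/ranking to a row subset (a
    leak-free weighting partition) while fusion covers every row.
    """
    missing = [r for r in root.leaf_refs() if r not in store]
    if missing:
        raise ValueError(f"unresolvable leaf references: {missing[:5]}")
    records: list[NodeRecord] = []
    from .combiners import _weighting_view
    from .core import correctness, information_gain

    def _wview(p: PredictionMatrix) -> PredictionMatrix:
        return _weighting_view(p, weighting_rows)

    def _eval(node: EnsembleNode) -> PredictionMatrix:
        child_preds: list[PredictionMatrix] = []
        for c in node.children:
            if isinstance(c, EnsembleNode):
                child_preds.append(_eval(c))
            else:
                child_preds.append(store[c])
        child_ids = tuple(p.source_id for p in child_preds)
        if node.selection == "top_k":
            ranked_views = select_top_k(
                [_wview(p) for p in child_preds], weighting_truth, node.k
            )
            keep = {v.source_id for v in ranked_views}
            child_preds = [p for p in child_preds if p.source_id in keep]
        fused, w = igpa_ensemble(
            child_preds,
            weighting_truth,
            alpha=node.alpha,
            h_prior=h_prior,
            mode=mode,
            source_id=node.node_id,
            weighting_rows=weighting_rows,
        )
        accs = tuple(
            correctness(_wview(p), weighting_truth).accuracy for p in child_preds
        )
        igs = tuple(
            information_gain(
                correctness(_wview(p), weighting_truth), node.alpha, h_prior, mode
            ).value
            for p in child_preds
        )
        records.append(
            NodeRecord(
                node_id=node.node_id,
                level=node.level,
                alpha=node.alpha,
                mode=mode,
                selection=node.selection,
                child_ids=child_ids,
                selected_ids=tuple(p.source_id for p in child_preds),
                accuracies=accs,
                ig_values=igs,
                weights=w,
            )
        )
        return fused

    fused = _eval(root)
    return fused, EnsembleReport(tuple(records), final_id=root.node_id, mode=mode)


def single_level_igpa(
    preds: Sequence[PredictionMatrix],
    weighting_truth: LabelVector,
    h_prior: float = 1.0,
    mode: str = "multiplicative",
) -> tuple[PredictionMatrix, EnsembleReport]:
    """Flat baseline: one IGPA fusion over every classifier at alpha = 1."""
    node = EnsembleNode(
        node_id="SL", children=[p.source_id or str(i) for i, p in enumerate(preds)], alpha=1.0
    )
    store = {
        (p.source_id or str(i)): p for i, p in enumerate(preds)
    }
    if len(store) != len(preds):
        raise ValueError("classifier source_ids must be unique")
    return run_tree(node, store, weighting_truth, h_prior=h_prior, mode=mode)
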