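"""The 60-classifier localization ensemble.

A cell's 16-element localization assignment is produced in three levels:

1. **Quality control** — DEAD then GHOST classifiers; a positive call
   short-circuits all further classification.
2. **Cell-cycle stage** — UNBUDDED / SMALLBUDDED / LARGEMEDIUMBUDDED
   classifiers.  A cell positive in either budded classifier is "budded"
   and is routed through budded-gated nodes (budneck, bud, budsite, the
   budded variants of cortical patches, cell periphery, spindle pole).
3. **Localization** — 20 subgroups of binary classifiers, one or more
   per localization class.  Within a subgroup, membership is the
   conjunction of the primary node (e.g. ER) and its discriminator nodes
   (e.g. ER_CYTOPLASM, ER_VACUOLEVACUOLARMEMBRANE, ER_CELLPERIPHERY): a
   cell joins the class only if every node of the subgroup agrees.
   Classes with cycle-specific variants take the disjunction over the
   variants applicable to the cell's stage.  Refinement nodes
   (CYTOPLASMNOTNUCLEAR, NUCLEINOTCYTOPLASM, VACUOLE_VACUOLARMEMBRANE)
   annotate positive cells and never veto membership.

Memberships are independent booleans: a cell may join several classes
(multi-localization) or none (unclassifiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .features import FeatureRegistry, FeatureVector, default_registry
from .phantom import CLASSES
from .train import BagEnsemble, TrainingSet, train_bagged

UNDETERMINED = "undetermined"
_STAGE_NAMES = ("unbudded", "small-budded", "large/medium-budded")


@dataclass(frozen=True)
class EnsembleNode:
    classifier_id: str
    name: str
    level: int
    group: str
    class_name: str  # one of the 16 classes, or "-" for QC/cycle nodes
    variant: str  # "" for single-variant groups
    role: str  # qc | cycle | primary | discriminator | refinement
    gate: str  # "" | "budded" | "unbudded"
    n_pos: int = 0
    n_neg: int = 0


@dataclass
class EnsembleConfig:
    """The classifier graph layout (default: the packaged 60-node table)."""

    nodes: list[EnsembleNode]
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        ids = [n.classifier_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate classifier ids")
        if len(self.classes) != 16:
            raise ValueError("exactly 16 localization classes expected")
        for n in self.level(3):
            if n.class_name not in self.classes:
                raise ValueError(
                    f"node {n.classifier_id} references unknown class {n.class_name!r}"
                )

    def level(self, lv: int) -> list[EnsembleNode]:
        return [n for n in self.nodes if n.level == lv]

    def node(self, classifier_id: str) -> EnsembleNode:
        for n in self.nodes:
            if n.classifier_id == classifier_id:
                return n
        raise KeyError(classifier_id)

    @property
    def subgroups(self) -> dict[tuple[str, str], list[EnsembleNode]]:
        """Level-3 (group, variant) subgroups, refinement nodes excluded."""
        out: dict[tuple[str, str], list[EnsembleNode]] = {}
        for n in self.level(3):
            if n.role == "refinement":
                continue
            out.setdefault((n.group, n.variant), []).append(n)
        return out


def default_config() -> EnsembleConfig:
    """Load the packaged 60-node configuration table."""
    text = resources.files("ensloc.data").joinpath("ensemble_config.tsv").read_text()
    return parse_config(text)


def parse_config(text: str) -> EnsembleConfig:
    nodes = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        nodes.append(
            EnsembleNode(
                classifier_id=row["classifier_id"],
                name=row["name"],
                level=int(row["level"]),
                group=row["group"],
                class_name=row["class"] if row["class"] != "-" else "-",
                variant=row["variant"] if row["variant"] != "-" else "",
                role=row["role"],
                gate=row["gate"] if row["gate"] != "-" else "",
                n_pos=int(row["n_pos"]),
                n_neg=int(row["n_neg"]),
            )
        )
    return EnsembleConfig(nodes)


@dataclass
class AssignmentVector:
    """Per-cell output of the ensemble."""

    cell_ref: tuple
    qc: str  # pass | dead | ghost
    cycle_stage: str  # unbudded | small-budded | large/medium-budded | undetermined
    memberships: np.ndarray  # 16 booleans aligned to config.classes
    classes: tuple[str, ...] = CLASSES
    sub_annotations: dict[str, bool] = field(default_factory=dict)
    trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=bool)
        if self.memberships.shape != (16,):
            raise ValueError("memberships must have exactly 16 elements")
        if self.qc != "pass" and self.memberships.any():
            raise ValueError("non-passing QC forbids class memberships")

    @property
    def classifiable(self) -> bool:
        return bool(self.memberships.any())

    def assigned_classes(self) -> list[str]:
        return [c for c, m in zip(self.classes, self.memberships) if m]


class EnsembleBuildError(ValueError):
    pass


@dataclass
class EnsembleGraph:
    """Executable ensemble: config plus one trained model per node."""

    config: EnsembleConfig
    models: dict[str, BagEnsemble]
    registry_hash: str = ""


def build_ensemble(
    config: EnsembleConfig, models: dict[str, BagEnsemble]
) -> EnsembleGraph:
    """Validate that every node has a trained model on one registry."""
    missing = [n.classifier_id for n in config.nodes if n.classifier_id not in models]
    if missing:
        raise EnsembleBuildError(f"missing models for nodes: {', '.join(missing)}")
    hashes = {m.registry_hash for m in models.values() if m.registry_hash}
    if len(hashes) > 1:
        raise EnsembleBuildError(f"models trained on different registries: {hashes}")
    return EnsembleGraph(config, models, hashes.pop() if hashes else "")


# ---------------------------------------------------------------------------
# execution


def _node_by_name(config: EnsembleConfig, name: str) -> EnsembleNode:
    for n in config.nodes:
        if n.name == name:
            return n
    raise KeyError(name)


def classify_cells(
    graph: EnsembleGraph,
    X: np.ndarray,
    cell_refs: list[tuple] | None = None,
    registry_hash: str = "",
) -> list[AssignmentVector]:
    """Run the ensemble on a (cells x features) matrix.

    Nodes are evaluated level by level with gating: dead/ghost cells are
    dropped after quality control, budded- and unbudded-gated subgroups
    run only on cells of the matching stage, and cells whose stage is
    undetermined (all three cycle classifiers negative) pass only through
    ungated subgroups.  Each cell's trace lists the nodes actually
    consulted for it.
    """
    if registry_hash and graph.registry_hash and registry_hash != graph.registry_hash:
        raise ValueError("feature matrix registry does not match ensemble registry")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = len(X)
    cfg = graph.config
    preds: dict[str, np.ndarray] = {}
    traces: list[list[str]] = [[] for _ in range(n)]

    def run(node: EnsembleNode, rows: np.ndarray) -> np.ndarray:
        """Evaluate a node on a boolean row mask; False elsewhere."""
        out = np.zeros(n, dtype=bool)
        if rows.any():
            out[rows] = graph.models[node.classifier_id].predict(X[rows])
            for i in np.nonzero(rows)[0]:
                traces[i].append(node.classifier_id)
        preds[node.classifier_id] = out
        return out

    all_rows = np.ones(n, dtype=bool)
    dead = run(_node_by_name(cfg, "DEAD"), all_rows)
    ghost = run(_node_by_name(cfg, "GHOST"), ~dead) & ~dead
    alive = ~dead & ~ghost

    unb = run(_node_by_name(cfg, "UNBUDDED"), alive)
    sb = run(_node_by_name(cfg, "SMALLBUDDED"), alive)
    lmb = run(_node_by_name(cfg, "LARGEMEDIUMBUDDED"), alive)
    budded = sb | lmb
    # precedence when several stage classifiers fire: larger morphology wins
    stage = np.full(n, UNDETERMINED, dtype=object)
    stage[unb] = "unbudded"
    stage[sb] = "small-budded"
    stage[lmb] = "large/medium-budded"
    unbudded = alive & (stage == "unbudded")

    def gate_rows(gate: str) -> np.ndarray:
        if gate == "budded":
            return alive & budded
        if gate == "unbudded":
            return unbudded
        return alive

    memberships = np.zeros((n, 16), dtype=bool)
    class_idx = {c: i for i, c in enumerate(cfg.classes)}
    for (group, variant), nodes in sorted(cfg.subgroups.items()):
        rows = gate_rows(nodes[0].gate)
        agree = rows.copy()
        for node in nodes:
            if not agree.any():
                preds[node.classifier_id] = np.zeros(n, dtype=bool)
                continue
            agree &= run(node, agree)
        memberships[:, class_idx[nodes[0].class_name]] |= agree

    # refinement nodes annotate members of their class without vetoing
    annotations: dict[str, np.ndarray] = {}
    for node in cfg.level(3):
        if node.role != "refinement":
            continue
        rows = gate_rows(node.gate) & memberships[:, class_idx[node.class_name]]
        annotations[node.name] = run(node, rows)

    out: list[AssignmentVector] = []
    for i in range(n):
        if dead[i]:
            qc = "dead"
        elif ghost[i]:
            qc = "ghost"
        else:
            qc = "pass"
        out.append(
            AssignmentVector(
                cell_ref=cell_refs[i] if cell_refs else (i,),
                qc=qc,
                cycle_stage=str(stage[i]) if qc == "pass" else UNDETERMINED,
                memberships=memberships[i] if qc == "pass" else np.zeros(16, bool),
                classes=cfg.classes,
                sub_annotations={
                    name: bool(vals[i]) for name, vals in annotations.items() if vals[i]
                },
                trace=traces[i],
            )
        )
    return out


def classify_cell(graph: EnsembleGraph, fv: FeatureVector) -> AssignmentVector:
    """Classify a single cell (see :func:`classify_cells`)."""
    if fv.registry_hash and graph.registry_hash and fv.registry_hash != graph.registry_hash:
        raise ValueError("feature vector registry does not match ensemble registry")
    if not fv.extractable:
        return AssignmentVector(
            cell_ref=fv.cell_ref,
            qc="pass",
            cycle_stage=UNDETERMINED,
            memberships=np.zeros(16, dtype=bool),
            classes=graph.config.classes,
        )
    return classify_cells(graph, fv.values[None, :], [fv.cell_ref])[0]


def consolidate_group(
    config: EnsembleConfig,
    group: str,
    decisions: dict[str, bool],
) -> bool:
    """Consolidate one subgroup's binary decisions into class membership.

    ``decisions`` maps classifier_id to its vote for the executed nodes
    of the group.  Within a variant, membership is the conjunction of the
    primary and all discriminator nodes; across variants (for groups with
    cycle-specific variants) membership is the disjunction over variants
    whose nodes were executed.  Refinement nodes are ignored.  A variant
    with some but not all of its nodes decided is an error.
    """
    variants: dict[str, list[EnsembleNode]] = {}
    for n in config.level(3):
        if n.group == group and n.role != "refinement":
            variants.setdefault(n.variant, []).append(n)
    if not variants:
        raise KeyError(f"unknown or empty group {group!r}")
    result = False
    any_executed = False
    for nodes in variants.values():
        have = [n.classifier_id in decisions for n in nodes]
        if not any(have):
            continue  # variant gated out for this cell
        if not all(have):
            missing = [n.classifier_id for n, h in zip(nodes, have) if not h]
            raise ValueError(f"missing decisions for {group!r}: {missing}")
        any_executed = True
        result |= all(decisions[n.classifier_id] for n in nodes)
    if not any_executed:
        return False
    return result


# ---------------------------------------------------------------------------
# phantom-trained default ensemble

_SUFFIX_TO_CLASS = {
    "CYTOPLASM": "cytoplasm",
    "NUCLEI": "nucleus",
    "SPINDLEPOLE": "spindle pole",
    "MITOCHONDRIA": "mitochondria",
    "VACUOLEVACUOLARMEMBRANE": "vacuole/vacuolar membrane",
    "CELLPERIPHERY": "cell periphery",
    "GOLGI": "Golgi",
    "ENDOSOME": "endosome",
    "BUD": "bud",
    "BUDNECK": "budneck",
    "NUCLEARPERIPHERY": "nuclear periphery",
    "NUCLEOLUS": "nucleolus",
}

_VARIANT_PARAMS = {
    "onedot": {"n_dots": 1},
    "twodotfar": {"n_dots": 2, "separation": (8.0, 12.0)},
    "twodotclose": {"n_dots": 2, "separation": (3.0, 5.0)},
}


class PhantomPoolFactory:
    """Renders and featurizes pools of single-cell crops, with caching.

    One pool is a list of feature vectors for crops of a given recipe
    (label, forced cycle stage, pattern-parameter override).  Pools are
    the raw material from which per-node training sets are assembled.
    """

    def __init__(
        self,
        n_per_pool: int = 150,
        seed: int = 0,
        registry: FeatureRegistry | None = None,
        noise: tuple[float, float] = (2.0, 1.0),
    ):
        from . import features as F
        from . import phantom as P

        self._F, self._P = F, P
        self.n = n_per_pool
        self.seed = seed
        self.registry = registry or default_registry()
        self.noise = noise
        self._cache: dict[tuple, np.ndarray] = {}

    def _render_pool(self, key: tuple) -> np.ndarray:
        label, stage, params_key = key
        params = dict(params_key) if params_key else None
        import hashlib

        stable = int.from_bytes(
            hashlib.sha256(repr(key).encode()).digest()[:4], "big"
        )
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, stable]))
        rows = []
        mix_labels = None
        if label == "mixcells":
            mix_labels = [
                c
                for c in self._P.CLASSES
                if stage is None or c not in self._P.BUDDED_ONLY_CLASSES
            ]
        while len(rows) < self.n:
            lab = label
            if mix_labels is not None:
                lab = mix_labels[rng.integers(len(mix_labels))]
            crop = self._P.render_crop(lab, rng, stage=stage, params=params, noise=self.noise)
            fv = self._F.extract_from_crop(crop, self.registry)
            if fv.extractable:
                rows.append(fv.values)
        return np.vstack(rows)

    def pool(self, label: str, stage: str | None = None, params: dict | None = None) -> np.ndarray:
        key = (label, stage, tuple(sorted(params.items())) if params else None)
        if key not in self._cache:
            self._cache[key] = self._render_pool(key)
        return self._cache[key]


def node_training_set(
    node: EnsembleNode, factory: PhantomPoolFactory, rng: np.random.Generator
) -> TrainingSet:
    """Assemble a phantom training set for one ensemble node."""
    P = factory._P
    stage = node.gate or None

    def class_pool(cls: str, stg: str | None, params: dict | None = None) -> np.ndarray:
        if cls in P.BUDDED_ONLY_CLASSES:
            stg = "budded"
        return factory.pool(cls, stg, params)

    def negative_class_pools(exclude: str, stg: str | None) -> list[np.ndarray]:
        return [
            class_pool(c, stg)
            for c in P.CLASSES
            if c != exclude and not (stg == "unbudded" and c in P.BUDDED_ONLY_CLASSES)
        ]

    def other_classes_pool(exclude: str, stg: str | None) -> np.ndarray:
        stacked = np.vstack(negative_class_pools(exclude, stg))
        idx = rng.choice(len(stacked), size=factory.n, replace=False)
        return stacked[idx]

    def mined_negatives(pos: np.ndarray, exclude: str, stg: str | None) -> np.ndarray:
        """One round of hard-negative mining for a primary node.

        A provisional classifier trained on a balanced negative mix is
        scored against each negative class's pool; the final negative set
        re-weights classes by how often they leak through, the phantom
        analogue of hand-picking negatives per classifier.
        """
        from .train import train_bagged as _tb

        pools = negative_class_pools(exclude, stg)
        balanced = np.vstack(pools)
        provisional = _tb(
            TrainingSet(pos, balanced, node.name, factory.registry.hash),
            n_bags=7,
            seed=int(rng.integers(2**31 - 1)),
        )
        fp = np.array([provisional.predict(p).mean() for p in pools])
        weights = 1.0 + 10.0 * fp  # confusable classes dominate the draw
        weights /= weights.sum()
        parts = []
        for w, p in zip(weights, pools):
            take = max(2, int(round(w * 2 * factory.n)))
            parts.append(p[rng.integers(0, len(p), size=take)])
        return np.vstack(parts)

    if node.role == "qc":
        # each QC node must reject the other artifact class as well as live cells
        pos = factory.pool("dead" if node.name == "DEAD" else "ghost")
        other = "ghost" if node.name == "DEAD" else "dead"
        neg = np.vstack([factory.pool("mixcells", None), factory.pool(other)])
    elif node.role == "cycle":
        stages = {
            "UNBUDDED": "unbudded",
            "SMALLBUDDED": "small-budded",
            "LARGEMEDIUMBUDDED": "large/medium-budded",
        }
        target = stages[node.name]
        pos = factory.pool("mixcells", target)
        neg = np.vstack(
            [factory.pool("mixcells", s) for s in stages.values() if s != target]
        )
    elif node.name == "CYTOPLASMNOTNUCLEAR":
        pos = class_pool("cytoplasm", None)
        neg = class_pool("nucleus", None)
    elif node.name == "NUCLEINOTCYTOPLASM":
        pos = class_pool("nucleus", None)
        neg = class_pool("cytoplasm", None)
    elif node.name == "VACUOLE_VACUOLARMEMBRANE":
        pos = class_pool("vacuole/vacuolar membrane", None, {"p_membrane": 0.0})
        neg = class_pool("vacuole/vacuolar membrane", None, {"p_membrane": 1.0})
    else:
        params = _VARIANT_PARAMS.get(node.variant)
        pos = class_pool(node.class_name, stage, params)
        if node.role == "discriminator":
            suffix = node.name.split("_", 1)[1]
            neg_class = _SUFFIX_TO_CLASS[suffix]
            neg = class_pool(neg_class, stage)
        else:
            neg = mined_negatives(pos, node.class_name, stage)
    return TrainingSet(pos, neg, node.name, factory.registry.hash)


def train_phantom_ensemble(
    config: EnsembleConfig | None = None,
    n_per_pool: int = 150,
    seed: int = 0,
    *,
    n_bags: int = 25,
    k_features: int = 50,
    noise: tuple[float, float] = (2.0, 1.0),
    verbose: bool = False,
) -> EnsembleGraph:
    """Train the full default ensemble on phantom-rendered training sets.

    This is the desk-scale analogue of training on handpicked real cells:
    every one of the 60 nodes gets positives rendered from its own class
    recipe and negatives per its role (discriminators vs their named
    confuser class, primaries vs a mix of the other classes).
    """
    config = config or default_config()
    factory = PhantomPoolFactory(n_per_pool=n_per_pool, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 60]))
    models: dict[str, BagEnsemble] = {}
    for i, node in enumerate(config.nodes):
        ts = node_training_set(node, factory, rng)
        models[node.classifier_id] = train_bagged(
            ts,
            n_bags=n_bags,
            seed=seed + 7919 * (i + 1),
            k_features=k_features,
        )
        if verbose:
            print(f"trained {node.classifier_id} {node.name}")
    return build_ensemble(config, models)


def write_assignments(path: str | Path, assignments: list[AssignmentVector]) -> None:
    """Per-cell assignment table: qc, cycle stage, one boolean per class."""
    classes = assignments[0].classes if assignments else CLASSES
    with open(path, "w") as fh:
        fh.write("cell_ref\tqc\tcycle_stage\t" + "\t".join(classes) + "\n")
        for a in assignments:
            ref = ":".join(str(x) for x in a.cell_ref)
            fh.write(
                f"{ref}\t{a.qc}\t{a.cycle_stage}\t"
                + "\t".join(str(int(m)) for m in a.memberships)
                + "\n"
            )
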