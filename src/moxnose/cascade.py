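"""Hierarchical three-step cascade of small feed-forward networks.

The classification task is factored along the label hierarchy: a root node
recognizes the seasoning (12 vs 24 months); one node per seasoning separates
the two rind working processes; one node per (seasoning x process) assigns
the three rind classes — seven nodes in total.  Zero-rind replicas carry no
working process, so they participate in the root node only.

Each node is a multilayer perceptron with hyperbolic-tangent hidden layers
and a winner-take-all (argmax) output.  The number of hidden layers follows
the size d of the node's selected-feature subset (1 layer for d <= 8, 2 for
d <= 16, 3 beyond) and every hidden layer has d neurons.  Features are
standardized with training-split statistics; training minimizes
L2-regularized cross-entropy with the full-batch quasi-Newton optimizer
(LBFGS) under a fixed iteration budget — the right regime for nodes with
tens of training replicas, where held-out early-stopping folds are too small
to be reliable.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .design import Process, Seasoning, load_published_selection
from .selection import SelectionConfig, SelectionReport, select_features

__all__ = [
    "architecture_for",
    "stratified_split",
    "NodeModel",
    "CascadeModel",
    "train_node",
    "train_cascade",
    "predict_cascade",
]

#: Canonical node names of the 1 + 2 + 4 topology.
NODE_NAMES = (
    "step1",
    "step2/M12",
    "step2/M24",
    "step3/M12_WR",
    "step3/M12_SR",
    "step3/M24_WR",
    "step3/M24_SR",
)


def architecture_for(d: int) -> list[int]:
    """Hidden-layer sizes for a node with ``d`` selected features: depth 1
    for d <= 8, 2 for d <= 16, 3 beyond; every hidden layer has d neurons."""
    if d < 1:
        raise ValueError("a node needs at least one selected feature")
    depth = 1 if d <= 8 else 2 if d <= 16 else 3
    return [d] * depth


def stratified_split(
    ids: Sequence[str],
    target: Sequence[str],
    seed: int,
    train_fraction: float = 2.0 / 3.0,
) -> tuple[list[str], list[str]]:
    """Deterministic stratified split (default 2:1 train:test).

    Per class the train share is the rounded fraction, clamped so both sides
    are nonempty; classes with fewer than 3 rows are rejected.
    """
    ids = list(ids)
    target = list(target)
    if len(ids) != len(target):
        raise ValueError("ids and target must align")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    classes = sorted(set(target))
    for cls in classes:
        members = [i for i, c in zip(ids, target) if c == cls]
        if len(members) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 rows; cannot split 2:1")
        n_train = int(round(len(members) * train_fraction))
        n_train = min(max(n_train, 1), len(members) - 1)
        order = rng.permutation(len(members))
        train.extend(members[k] for k in order[:n_train])
        test.extend(members[k] for k in order[n_train:])
    return sorted(train), sorted(test)


@dataclass
class NodeModel:
    """One trained cascade node."""

    name: str
    features: list[str]
    classes: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    mlp: MLPClassifier
    seed: int
    converged: bool = True
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    @property
    def hidden_layers(self) -> list[int]:
        return list(self.mlp.hidden_layer_sizes)

    def _standardize(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise KeyError(f"node {self.name}: missing feature columns {missing}")
        x = table[self.features].to_numpy(dtype=float)
        return (x - self.mu) / self.sigma

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Winner-take-all class prediction for each row."""
        return self.mlp.predict(self._standardize(table))


def train_node(
    table: pd.DataFrame,
    target: str | pd.Series,
    features: Sequence[str],
    seed: int,
    name: str = "node",
    epochs: int = 500,
    l2: float = 0.1,
) -> NodeModel:
    """Train one node on the given rows.

    Features are standardized with the training rows' mean/SD (zero-variance
    columns get SD 1).  ``l2`` is the ridge penalty on the network weights;
    a node that exhausts its iteration budget is returned with
    ``converged=False`` and the event logged as a warning.
    """
    features = list(features)
    if not features:
        raise ValueError(f"node {name}: empty feature subset")
    y = (table[target] if isinstance(target, str) else target).astype(str).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"node {name}: training rows contain a single class")
    x = table[features].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    sigma[sigma == 0] = 1.0
    xs = (x - mu) / sigma
    hidden = tuple(architecture_for(len(features)))
    mlp = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="tanh",
        solver="lbfgs",
        alpha=l2,
        max_iter=epochs,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(xs, y)
    converged = mlp.n_iter_ < epochs
    if not converged:
        warnings.warn(
            f"node {name}: epoch budget exhausted (final loss {mlp.loss_:.4g})",
            stacklevel=2,
        )
    return NodeModel(
        name=name,
        features=features,
        classes=[str(c) for c in mlp.classes_],
        mu=mu,
        sigma=sigma,
        mlp=mlp,
        seed=seed,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# cascade assembly

_LABEL_COLS = ("seasoning", "process", "rind_pct", "rind_class")


def _node_rows(table: pd.DataFrame, name: str) -> tuple[pd.DataFrame, str]:
    """Rows and target column for one node of the topology."""
    if name == "step1":
        return table, "seasoning"
    kind, branch = name.split("/")
    if kind == "step2":
        sub = table[(table["seasoning"] == branch) & (table["process"] != Process.NONE.value)]
        return sub, "process"
    seasoning, process = branch.split("_")
    sub = table[(table["seasoning"] == seasoning) & (table["process"] == process)]
    return sub, "rind_class"


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _LABEL_COLS and c != "replica_id"]


@dataclass
class CascadeModel:
    """Seven trained nodes arranged in the 3-level hierarchy."""

    nodes: dict[str, NodeModel]
    selection_reports: dict[str, SelectionReport] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [n for n in NODE_NAMES if n not in self.nodes]
        if missing:
            raise ValueError(f"cascade is missing nodes: {missing}")

    def node(self, name: str) -> NodeModel:
        return self.nodes[name]

    def save(self, directory: str | Path) -> None:
        """Serialize as a directory: topology JSON + per-node weights (npz)
        + standardization JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        topo = {"seed": self.seed, "nodes": {}}
        for name, node in self.nodes.items():
            slug = name.replace("/", "_")
            arrays = {}
            for i, (w, b) in enumerate(zip(node.mlp.coefs_, node.mlp.intercepts_)):
                arrays[f"w{i}"] = w
                arrays[f"b{i}"] = b
            np.savez(directory / f"{slug}.npz", **arrays)
            topo["nodes"][name] = {
                "file": f"{slug}.npz",
                "features": node.features,
                "classes": node.classes,
                "hidden_layers": node.hidden_layers,
                "mu": node.mu.tolist(),
                "sigma": node.sigma.tolist(),
                "seed": node.seed,
                "converged": node.converged,
                "train_ids": node.train_ids,
                "test_ids": node.test_ids,
            }
        (directory / "topology.json").write_text(json.dumps(topo, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "CascadeModel":
        directory = Path(directory)
        topo = json.loads((directory / "topology.json").read_text())
        nodes: dict[str, NodeModel] = {}
        for name, meta in topo["nodes"].items():
            with np.load(directory / meta["file"]) as arrays:
                n_layers = len([k for k in arrays.files if k.startswith("w")])
                coefs = [arrays[f"w{i}"] for i in range(n_layers)]
                intercepts = [arrays[f"b{i}"] for i in range(n_layers)]
            mlp = MLPClassifier(
                hidden_layer_sizes=tuple(meta["hidden_layers"]),
                activation="tanh",
                random_state=meta["seed"],
            )
            # rebuild the fitted state without re-training
            mlp.coefs_ = coefs
            mlp.intercepts_ = intercepts
            mlp.n_layers_ = n_layers + 1
            mlp.n_outputs_ = coefs[-1].shape[1]
            mlp.out_activation_ = "softmax" if mlp.n_outputs_ > 2 else "logistic"
            mlp.classes_ = np.array(meta["classes"])
            mlp._label_binarizer = _binarizer_for(mlp.classes_)
            nodes[name] = NodeModel(
                name=name,
                features=list(meta["features"]),
                classes=list(meta["classes"]),
                mu=np.asarray(meta["mu"], float),
                sigma=np.asarray(meta["sigma"], float),
                mlp=mlp,
                seed=int(meta["seed"]),
                converged=bool(meta["converged"]),
                train_ids=list(meta["train_ids"]),
                test_ids=list(meta["test_ids"]),
            )
        return cls(nodes=nodes, seed=int(topo["seed"]))


def _binarizer_for(classes: np.ndarray):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(classes)
    return lb


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(salt,)).generate_state(1)[0] % (2**31))


def train_cascade(
    table: pd.DataFrame,
    seed: int = 0,
    selection: str = "auto",
    selection_config: SelectionConfig | None = None,
    epochs: int = 500,
) -> CascadeModel:
    """Train the full seven-node cascade from a labelled feature table.

    ``selection='auto'`` screens each node's candidate features by
    ANOVA/Tukey on that node's rows (training rows only under the default
    ``train_only`` scope); ``selection='published'`` uses the packaged published
    per-step subsets; ``selection='all'`` keeps all feature columns.

    Step-2/3 nodes are trained and split on ground-truth-routed rows (their
    true branch subsets); zero-rind replicas never enter steps 2-3.
    """
    if selection not in ("auto", "published", "all"):
        raise ValueError(f"selection must be auto, published or all, got {selection!r}")
    cfg = selection_config or SelectionConfig()
    all_features = _feature_columns(table)
    table = table.set_index("replica_id", drop=False) if "replica_id" in table.columns else table
    nodes: dict[str, NodeModel] = {}
    reports: dict[str, SelectionReport] = {}
    for salt, name in enumerate(NODE_NAMES):
        rows, target = _node_rows(table, name)
        if rows.empty:
            raise ValueError(f"node {name}: no rows in the feature table")
        split_seed = _sub_seed(seed, 2 * salt)
        train_ids, test_ids = stratified_split(
            rows["replica_id"].tolist(), rows[target].tolist(), seed=split_seed
        )
        train_rows = rows.loc[train_ids]
        if selection == "published":
            step = int(name[4])
            feats = load_published_selection(step).columns()
            feats = [f for f in feats if f in all_features]
        elif selection == "all":
            feats = all_features
        else:
            scope_rows = train_rows if cfg.scope == "train_only" else rows
            report = select_features(
                scope_rows, target, all_features, config=cfg, step=name
            )
            reports[name] = report
            feats = report.retained
        if not feats:
            raise ValueError(
                f"node {name}: screening retained no features; cannot build a network"
            )
        node = train_node(
            train_rows,
            target,
            feats,
            seed=_sub_seed(seed, 2 * salt + 1),
            name=name,
            epochs=epochs,
        )
        node.train_ids = list(train_ids)
        node.test_ids = list(test_ids)
        nodes[name] = node
    return CascadeModel(nodes=nodes, selection_reports=reports, seed=seed)


def predict_cascade(model: CascadeModel, table: pd.DataFrame) -> pd.DataFrame:
    """Route each row through the hierarchy.

    The root's seasoning prediction selects the step-2 node, whose process
    prediction selects the step-3 node; the output is the full predicted
    triple per row (indexed like ``table``).
    """
    seasoning = model.node("step1").predict(table)
    process = np.empty(len(table), dtype=object)
    rind = np.empty(len(table), dtype=object)
    for i in range(len(table)):
        row = table.iloc[[i]]
        s = seasoning[i]
        p = model.node(f"step2/{s}").predict(row)[0]
        r = model.node(f"step3/{s}_{p}").predict(row)[0]
        process[i] = p
        rind[i] = r
    return pd.DataFrame(
        {"seasoning": seasoning, "process": process, "rind_class": rind},
        index=table.index,
    )
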