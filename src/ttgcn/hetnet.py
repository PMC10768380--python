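"""Heterogeneous drug-target network and metapath neighbor graphs.

The network has four node types — drugs, targets (proteins), diseases and
side effects — connected by binary relations (drug-drug interaction,
drug-target interaction, drug-disease association, drug-side-effect
association, target-target interaction, target-disease association) plus
optional dense similarity matrices for drugs and targets.

A metapath such as drug-disease-drug induces a homogeneous neighbor graph
over its anchor type: node j is a metapath neighbor of node i iff at least
one path instance connects them. Per-metapath neighbor graphs are the input
to both the attention and the convolution encoder channels; merging them
gives the combined neighbor graph.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "NODE_TYPES", "RELATION_TYPES", "SIMILARITY_TYPES",
    "HeteroNetwork", "Metapath", "MetapathGraph",
    "compose_metapath", "merge_neighbor_graphs", "initial_features",
    "default_metapaths", "write_network", "read_network",
    "export_metapath_graph",
]

NODE_TYPES = ("drug", "target", "disease", "sideeffect")

# relation name -> (row node type, column node type)
RELATION_TYPES = {
    "drug-drug": ("drug", "drug"),
    "drug-target": ("drug", "target"),
    "drug-disease": ("drug", "disease"),
    "drug-sideeffect": ("drug", "sideeffect"),
    "target-target": ("target", "target"),
    "target-disease": ("target", "disease"),
}

SIMILARITY_TYPES = {
    "drug-sim": ("drug", "drug"),
    "target-sim": ("target", "target"),
}


@dataclass
class HeteroNetwork:
    """Typed node counts plus binary relation and similarity matrices."""

    n_drugs: int
    n_targets: int
    n_diseases: int
    n_sideeffects: int
    relations: dict = field(default_factory=dict)
    similarities: dict = field(default_factory=dict)
    node_ids: dict = field(default_factory=dict)  # type -> list of string ids

    def count(self, node_type: str) -> int:
        return {"drug": self.n_drugs, "target": self.n_targets,
                "disease": self.n_diseases, "sideeffect": self.n_sideeffects}[node_type]

    def ids(self, node_type: str) -> list:
        if node_type in self.node_ids:
            return list(self.node_ids[node_type])
        return [f"{node_type}{i}" for i in range(self.count(node_type))]

    def validate(self) -> None:
        """Check binarity, symmetry, dimensions and similarity ranges."""
        for name, mat in self.relations.items():
            if name not in RELATION_TYPES:
                raise ValueError(f"unknown relation {name!r}")
            rt, ct = RELATION_TYPES[name]
            want = (self.count(rt), self.count(ct))
            if mat.shape != want:
                raise ValueError(f"relation {name!r} has shape {mat.shape}, expected {want}")
            vals = np.unique(mat)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"relation {name!r} is not binary")
            if rt == ct:
                if not np.array_equal(mat, mat.T):
                    raise ValueError(f"within-type relation {name!r} is not symmetric")
                if np.diagonal(mat).any():
                    raise ValueError(f"within-type relation {name!r} has nonzero diagonal")
        for name, mat in self.similarities.items():
            if name not in SIMILARITY_TYPES:
                raise ValueError(f"unknown similarity {name!r}")
            rt, ct = SIMILARITY_TYPES[name]
            want = (self.count(rt), self.count(ct))
            if mat.shape != want:
                raise ValueError(f"similarity {name!r} has shape {mat.shape}, expected {want}")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"similarity {name!r} is not symmetric")
            if mat.min() < 0 or mat.max() > 1:
                raise ValueError(f"similarity {name!r} has values outside [0,1]")
            if not np.allclose(np.diagonal(mat), 1.0):
                raise ValueError(f"similarity {name!r} lacks a unit diagonal")

    def relation_or_zero(self, name: str) -> np.ndarray:
        if name in self.relations:
            return np.asarray(self.relations[name], dtype=float)
        rt, ct = RELATION_TYPES[name]
        return np.zeros((self.count(rt), self.count(ct)))


@dataclass(frozen=True)
class Metapath:
    """A composite relation starting and ending at `anchor_type`.

    `relation_chain` entries are relation names; a leading "~" means the
    relation is traversed against its stored orientation (transposed).
    A similarity name ("drug-sim"/"target-sim") may appear as a single-step
    chain and is binarized at `sim_threshold`.
    """

    name: str
    anchor_type: str
    relation_chain: tuple
    sim_threshold: float = 0.5

    def step_types(self, step: str):
        trans = step.startswith("~")
        base = step[1:] if trans else step
        table = RELATION_TYPES if base in RELATION_TYPES else SIMILARITY_TYPES
        if base not in table:
            raise ValueError(f"unknown relation {base!r} in metapath {self.name!r}")
        rt, ct = table[base]
        return (ct, rt) if trans else (rt, ct)

    def validate(self) -> None:
        if self.anchor_type not in ("drug", "target"):
            raise ValueError("anchor_type must be 'drug' or 'target'")
        if not self.relation_chain:
            raise ValueError("relation_chain must be nonempty")
        rt0, _ = self.step_types(self.relation_chain[0])
        _, ctL = self.step_types(self.relation_chain[-1])
        if rt0 != self.anchor_type or ctL != self.anchor_type:
            raise ValueError(f"metapath {self.name!r} does not start and end at {self.anchor_type!r}")
        for a, b in zip(self.relation_chain, self.relation_chain[1:]):
            if self.step_types(a)[1] != self.step_types(b)[0]:
                raise ValueError(
                    f"metapath {self.name!r}: relation {a!r} (ends at "
                    f"{self.step_types(a)[1]!r}) does not compose with {b!r} "
                    f"(starts at {self.step_types(b)[0]!r})")


@dataclass
class MetapathGraph:
    """Boolean adjacency over the anchor node set of one metapath."""

    metapath: Metapath
    adjacency: np.ndarray
    includes_self_loops: bool = True

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def _step_matrix(net: HeteroNetwork, mp: Metapath, step: str) -> np.ndarray:
    trans = step.startswith("~")
    base = step[1:] if trans else step
    if base in SIMILARITY_TYPES:
        sim = net.similarities.get(base)
        if sim is None:
            n = net.count(SIMILARITY_TYPES[base][0])
            sim = np.eye(n)
        mat = (np.asarray(sim, dtype=float) >= mp.sim_threshold).astype(float)
        np.fill_diagonal(mat, 0.0)  # self-similarity carries no path information
    else:
        mat = net.relation_or_zero(base)
    return mat.T if trans else mat


def compose_metapath(net: HeteroNetwork, mp: Metapath, add_self_loops: bool = True) -> MetapathGraph:
    """Boolean product of the chain's relation matrices over the anchor set.

    Path multiplicities are discarded: entry (i,j) is 1 iff at least one
    metapath instance connects i and j. The diagonal is zeroed, then self
    loops are added (default) so isolated nodes still aggregate their own
    features.
    """
    mp.validate()
    prod = _step_matrix(net, mp, mp.relation_chain[0])
    for step in mp.relation_chain[1:]:
        nxt = _step_matrix(net, mp, step)
        if prod.shape[1] != nxt.shape[0]:
            raise ValueError(
                f"dimension mismatch composing {mp.relation_chain} "
                f"at step {step!r}: {prod.shape} @ {nxt.shape}")
        prod = prod @ nxt
    adj = (prod > 0).astype(float)
    np.fill_diagonal(adj, 0.0)
    if add_self_loops:
        adj = adj + np.eye(adj.shape[0])
    return MetapathGraph(metapath=mp, adjacency=adj, includes_self_loops=add_self_loops)


def merge_neighbor_graphs(graphs) -> MetapathGraph:
    """Elementwise boolean union of per-metapath neighbor graphs."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("no graphs to merge")
    anchor = graphs[0].metapath.anchor_type
    n = graphs[0].n
    for g in graphs[1:]:
        if g.metapath.anchor_type != anchor:
            raise ValueError(
                f"cannot merge graphs over mixed anchor types "
                f"({anchor!r} vs {g.metapath.anchor_type!r})")
        if g.n != n:
            raise ValueError("cannot merge graphs of different sizes")
    union = np.zeros((n, n))
    for g in graphs:
        union = np.maximum(union, (g.adjacency > 0).astype(float))
    merged_mp = Metapath(name="merged", anchor_type=anchor,
                         relation_chain=graphs[0].metapath.relation_chain)
    return MetapathGraph(metapath=merged_mp, adjacency=union,
                         includes_self_loops=all(g.includes_self_loops for g in graphs))


def initial_features(net: HeteroNetwork, node_type: str) -> np.ndarray:
    """Initial node features: [similarity | interaction profile].

    Drugs get [drug-drug similarity | drug-target interactions]; targets get
    [target-target similarity | transposed drug-target interactions]. When a
    similarity matrix is absent the identity stands in for it.
    """
    dt = net.relation_or_zero("drug-target")
    if node_type == "drug":
        sim = net.similarities.get("drug-sim")
        sim = np.eye(net.n_drugs) if sim is None else np.asarray(sim, dtype=float)
        return np.concatenate([sim, dt], axis=1)
    if node_type == "target":
        sim = net.similarities.get("target-sim")
        sim = np.eye(net.n_targets) if sim is None else np.asarray(sim, dtype=float)
        return np.concatenate([sim, dt.T], axis=1)
    raise ValueError(f"node_type must be 'drug' or 'target', got {node_type!r}")


def default_metapaths(node_type: str, sim_threshold: float = 0.5):
    """The default four metapaths per anchor type (length <= 2)."""
    if node_type == "drug":
        return [
            Metapath("r-r", "drug", ("drug-drug",)),
            Metapath("r-d-r", "drug", ("drug-disease", "~drug-disease")),
            Metapath("r-se-r", "drug", ("drug-sideeffect", "~drug-sideeffect")),
            Metapath("r-t-r", "drug", ("drug-target", "~drug-target")),
        ]
    if node_type == "target":
        return [
            Metapath("t-t", "target", ("target-target",)),
            Metapath("t-d-t", "target", ("target-disease", "~target-disease")),
            Metapath("t-r-t", "target", ("~drug-target", "drug-target")),
            Metapath("t-sim-t", "target", ("target-sim",), sim_threshold=sim_threshold),
        ]
    raise ValueError(f"node_type must be 'drug' or 'target', got {node_type!r}")


# ---------------------------------------------------------------------------
# File I/O: TSV edge lists per relation, dense TSV per similarity, MTX export
# ---------------------------------------------------------------------------

def write_network(net: HeteroNetwork, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    ids = {t: net.ids(t) for t in NODE_TYPES}
    for t in NODE_TYPES:
        with open(os.path.join(outdir, f"{t}_ids.txt"), "w") as fh:
            fh.write("\n".join(ids[t]) + "\n")
    manifest = {"counts": {t: net.count(t) for t in NODE_TYPES},
                "relations": {}, "similarities": {}}
    for name, mat in net.relations.items():
        rt, ct = RELATION_TYPES[name]
        rows, cols = np.nonzero(mat)
        fname = f"{name}.tsv"
        pd.DataFrame({"source": [ids[rt][i] for i in rows],
                      "target": [ids[ct][j] for j in cols]}
                     ).to_csv(os.path.join(outdir, fname), sep="\t", index=False, header=False)
        manifest["relations"][name] = fname
    for name, mat in net.similarities.items():
        rt, _ = SIMILARITY_TYPES[name]
        fname = f"{name}.tsv"
        pd.DataFrame(np.asarray(mat), index=ids[rt], columns=ids[rt]
                     ).to_csv(os.path.join(outdir, fname), sep="\t")
        manifest["similarities"][name] = fname
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_network(indir: str) -> HeteroNetwork:
    with open(os.path.join(indir, "manifest.json")) as fh:
        manifest = json.load(fh)
    counts = manifest["counts"]
    node_ids, index = {}, {}
    for t in NODE_TYPES:
        path = os.path.join(indir, f"{t}_ids.txt")
        with open(path) as fh:
            node_ids[t] = [line.strip() for line in fh if line.strip()]
        if len(node_ids[t]) != counts[t]:
            raise ValueError(f"id file for {t!r} lists {len(node_ids[t])} ids, "
                             f"manifest says {counts[t]}")
        index[t] = {s: i for i, s in enumerate(node_ids[t])}
    net = HeteroNetwork(counts["drug"], counts["target"], counts["disease"],
                        counts["sideeffect"], node_ids=node_ids)
    for name, fname in manifest["relations"].items():
        rt, ct = RELATION_TYPES[name]
        mat = np.zeros((counts[rt], counts[ct]))
        path = os.path.join(indir, fname)
        if os.path.getsize(path):
            edges = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                                dtype=str)
            for s, t in zip(edges["source"], edges["target"]):
                mat[index[rt][s], index[ct][t]] = 1.0
        net.relations[name] = mat
    for name, fname in manifest["similarities"].items():
        df = pd.read_csv(os.path.join(indir, fname), sep="\t", index_col=0)
        net.similarities[name] = df.to_numpy(dtype=float)
    net.validate()
    return net


def export_metapath_graph(graph: MetapathGraph, net: HeteroNetwork, outdir: str) -> None:
    """Write one metapath graph as MatrixMarket + node id file."""
    os.makedirs(outdir, exist_ok=True)
    stem = graph.metapath.name.replace("/", "_")
    mmwrite(os.path.join(outdir, f"{stem}.mtx"), coo_matrix(graph.adjacency))
    with open(os.path.join(outdir, f"{stem}_ids.txt"), "w") as fh:
        fh.write("\n".join(net.ids(graph.metapath.anchor_type)) + "\n")


def read_metapath_graph(path_mtx: str, metapath: Metapath) -> MetapathGraph:
    adj = np.asarray(mmread(path_mtx).todense(), dtype=float)
    return MetapathGraph(metapath=metapath, adjacency=adj,
                         includes_self_loops=bool(np.diagonal(adj).all()))
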