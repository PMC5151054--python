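"""Reading and writing networks, partitions and symmetry pairings.

Supported network formats:

* dense matrix table (TSV/CSV) with a header row and first column of node
  labels; absent connections stored as 0,
* 3-column edge list ``source<TAB>target<TAB>weight`` (nodes ordered by
  sorted label),
* GraphML (via networkx) with a ``weight`` edge attribute.

Companion files carry distances/bandwidths (same dense matrix layout),
partitions (2-column TSV: label, module; ``UNASSIGNED`` or ``-`` marks
unassigned nodes) and symmetry pairings (2-column TSV of label pairs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .network import Network, Partition, UNASSIGNED, pairs_to_mirror

UNASSIGNED_TOKENS = {"UNASSIGNED", "-", "NA"}


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------- matrices

def load_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=_sep(path), index_col=0,
                     float_precision="round_trip")
    labels = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != labels:
        raise ValueError(f"{path}: row and column labels differ (matrix not square?)")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return m, labels


def save_matrix(path, matrix: np.ndarray, labels: list[str]) -> None:
    sep = _sep(path)
    with open(path, "w") as fh:
        fh.write(sep.join([""] + list(labels)) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + sep + sep.join(repr(float(x)) for x in row) + "\n")


# ---------------------------------------------------------------- networks

def load_edge_list(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=_sep(path), header=None,
                     names=["source", "target", "weight"], comment="#")
    labels = sorted({str(x) for x in df["source"]} | {str(x) for x in df["target"]})
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    for _, row in df.iterrows():
        w[idx[str(row["source"])], idx[str(row["target"])]] = float(row["weight"])
    return w, labels


def save_edge_list(path, net: Network) -> None:
    sep = _sep(path)
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(net.weights)):
            fh.write(sep.join([net.labels[i], net.labels[j],
                               repr(float(net.weights[i, j]))]) + "\n")


def load_graphml(path) -> tuple[np.ndarray, list[str]]:
    g = nx.read_graphml(path)
    labels = sorted(str(v) for v in g.nodes)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    w = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w[idx[str(u)], idx[str(v)]] = float(data.get("weight", 1.0))
    return w, labels


def save_graphml(path, net: Network) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(net.labels)
    for i, j in zip(*np.nonzero(net.weights)):
        g.add_edge(net.labels[i], net.labels[j], weight=float(net.weights[i, j]))
    nx.write_graphml(g, path)


def load_network(path, fmt: str | None = None, *, distances=None, bandwidths=None,
                 pairing=None) -> Network:
    """Load a network, optionally with companion distance/bandwidth/pairing
    files.  ``fmt`` is one of ``dense``, ``edgelist``, ``graphml`` (inferred
    from the extension when omitted: ``.graphml`` → graphml, ``.edges``/
    ``.edgelist`` → edge list, otherwise dense)."""
    if fmt is None:
        s = str(path)
        if s.endswith(".graphml"):
            fmt = "graphml"
        elif s.endswith((".edges", ".edgelist")):
            fmt = "edgelist"
        else:
            fmt = "dense"
    if fmt == "dense":
        w, labels = load_matrix(path)
    elif fmt == "edgelist":
        w, labels = load_edge_list(path)
    elif fmt == "graphml":
        w, labels = load_graphml(path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")

    dist = bw = None
    if distances is not None:
        dist, dl = load_matrix(distances)
        if dl != labels:
            raise ValueError("distance matrix labels do not match network labels")
    if bandwidths is not None:
        bw, bl = load_matrix(bandwidths)
        if bl != labels:
            raise ValueError("bandwidth matrix labels do not match network labels")
    mirror = None
    if pairing is not None:
        mirror = load_pairing(pairing, labels)
    return Network(weights=w, distances=dist, bandwidths=bw, labels=labels,
                   mirror=mirror)


def save_network(path, net: Network, fmt: str = "dense") -> None:
    if fmt == "dense":
        save_matrix(path, net.weights, net.labels)
    elif fmt == "edgelist":
        save_edge_list(path, net)
    elif fmt == "graphml":
        save_graphml(path, net)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


# ------------------------------------------------------------ partitions

def load_partition(path, labels: list[str]) -> Partition:
    df = pd.read_csv(path, sep=_sep(path), header=None,
                     names=["label", "module"], comment="#")
    mapping = {str(r["label"]): str(r["module"]) for _, r in df.iterrows()}
    missing = [lab for lab in labels if lab not in mapping]
    if missing:
        raise ValueError(f"partition file is missing nodes: {missing[:5]}")
    mods = []
    names = {}
    for lab in labels:
        tok = mapping[lab]
        if tok in UNASSIGNED_TOKENS:
            mods.append(UNASSIGNED)
        else:
            mods.append(names.setdefault(tok, len(names)))
    return Partition(np.array(mods))


def save_partition(path, part: Partition, labels: list[str]) -> None:
    sep = _sep(path)
    with open(path, "w") as fh:
        for lab, m in zip(labels, part.modules):
            tok = "UNASSIGNED" if m == UNASSIGNED else str(int(m))
            fh.write(f"{lab}{sep}{tok}\n")


# -------------------------------------------------------------- pairings

def load_pairing(path, labels: list[str]) -> np.ndarray:
    df = pd.read_csv(path, sep=_sep(path), header=None,
                     names=["a", "b"], comment="#")
    idx = {lab: i for i, lab in enumerate(labels)}
    pairs = []
    for _, r in df.iterrows():
        a, b = str(r["a"]), str(r["b"])
        if a not in idx or b not in idx:
            raise ValueError(f"pairing references unknown node {a!r} or {b!r}")
        pairs.append((idx[a], idx[b]))
    return pairs_to_mirror(pairs, len(labels))


def save_pairing(path, net: Network) -> None:
    if net.mirror is None:
        raise ValueError("network has no symmetry pairing")
    sep = _sep(path)
    seen = set()
    with open(path, "w") as fh:
        for i, j in enumerate(net.mirror):
            if i in seen or j in seen:
                continue
            seen.update((i, int(j)))
            fh.write(f"{net.labels[i]}{sep}{net.labels[int(j)]}\n")


def load_club(path, labels: list[str]) -> np.ndarray:
    """Rich-club node set: one label per line → sorted index array."""
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    idx = {lab: i for i, lab in enumerate(labels)}
    unknown = [nm for nm in names if nm not in idx]
    if unknown:
        raise ValueError(f"club file references unknown nodes: {unknown[:5]}")
    return np.array(sorted(idx[nm] for nm in names), dtype=np.int64)
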