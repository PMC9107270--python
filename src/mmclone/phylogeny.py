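"""Binary alteration matrix, Manhattan distances and neighbor-joining trees.

The per-patient phylogeny is inferred the way distance methods are used for
multi-lesion copy-number/mutation data: lesions become rows of a binary
matrix over alteration features (driver-panel SNVs, CNV/LOH events), an
optional all-zero "germline" row provides the outgroup, pairwise Manhattan
distance (= Hamming count on binary data) gives the distance matrix, and the
classical Saitou–Nei neighbor-joining algorithm produces the tree.

NJ is implemented here rather than delegated because the output must be
bit-deterministic: ties in the Q criterion are broken by the lowest
(row, col) pair in label-sorted order, and negative branch lengths are
clamped to zero with the deficit moved to the sister branch.  NJ is exact on
additive (tree-metric) inputs, which the tests exploit as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .case import PatientCase
from .config import AnalysisConfig
from .features import CaseFeatures, extract_case_features


@dataclass
class Clade:
    """Node of a phylogenetic tree; ``branch_length`` is the length of the
    edge to the parent (None at the root)."""

    name: str | None = None
    branch_length: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaf_names())
        return out


def build_feature_matrix(case: PatientCase,
                         config: AnalysisConfig | None = None,
                         features: CaseFeatures | None = None,
                         include_outgroup: bool | None = None,
                         ) -> pd.DataFrame:
    """Lesions x features binary matrix (driver-panel SNVs + CNV events).

    Columns shared by every lesion are retained: together with the all-zero
    germline row they carry the signal separating the root from the tumour
    clade.
    """
    config = config or AnalysisConfig()
    if include_outgroup is None:
        include_outgroup = config.include_outgroup
    features = features or extract_case_features(
        case, config, panel_only_snvs=True)
    keys = features.feature_keys
    if not keys:
        raise ValueError(
            f"patient {case.patient_id!r} has no alteration features; "
            "review filter and event-calling thresholds")
    rows = {lesion: [int(k in features.presence[lesion]) for k in keys]
            for lesion in case.lesion_ids}
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=keys)
    if include_outgroup:
        if config.outgroup_label in matrix.index:
            raise ValueError(
                f"lesion id collides with outgroup label "
                f"{config.outgroup_label!r}")
        matrix.loc[config.outgroup_label] = 0
    return matrix


def manhattan_distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Manhattan (city-block) distances between matrix rows."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows for a distance matrix")
    dist = squareform(pdist(matrix.to_numpy(dtype=float), metric="cityblock"))
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def _validate_distance(dist: pd.DataFrame) -> np.ndarray:
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not (
            list(dist.index) == list(dist.columns)):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    return arr


def neighbor_joining(dist: pd.DataFrame,
                     outgroup: str | None = "germline") -> Clade:
    """Classical Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),
    with branch lengths from the standard closed forms.  The result is the
    unrooted NJ tree, represented with a trifurcating root; when ``outgroup``
    names a leaf, the tree is rooted at that leaf's attachment node so the
    outgroup appears as a child of the root.
    """
    arr = _validate_distance(dist)
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 labels")

    order = sorted(range(len(labels)), key=lambda i: str(labels[i]))
    d = arr[np.ix_(order, order)].astype(float)
    nodes: list[Clade] = [Clade(name=str(labels[i])) for i in order]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair among the minima -> deterministic ties
        i, j = min(zip(*np.nonzero(np.isclose(q, q.min()))))
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, dij)
        new = Clade(children=[_with_length(nodes[i], li),
                              _with_length(nodes[j], lj)])
        d_new = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)],
                       d_new[keep][None, :]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    (a, b, c), dm = nodes, d
    la = 0.5 * (dm[0, 1] + dm[0, 2] - dm[1, 2])
    lb = 0.5 * (dm[0, 1] + dm[1, 2] - dm[0, 2])
    lc = 0.5 * (dm[0, 2] + dm[1, 2] - dm[0, 1])
    root = Clade(children=[_with_length(a, max(la, 0.0)),
                           _with_length(b, max(lb, 0.0)),
                           _with_length(c, max(lc, 0.0))])
    if outgroup is not None and outgroup in map(str, labels):
        root = _root_at_leaf_parent(root, outgroup)
    return root


def _clamp_pair(li: float, lj: float, dij: float) -> tuple[float, float]:
    # negative branch -> clamp to 0, transfer deficit to the sister branch
    if li < 0.0:
        li, lj = 0.0, dij
    if lj < 0.0:
        li, lj = dij, 0.0
    return max(li, 0.0), max(lj, 0.0)


def _with_length(node: Clade, length: float) -> Clade:
    node.branch_length = float(length)
    return node


def _root_at_leaf_parent(root: Clade, leaf_name: str) -> Clade:
    """Re-root an unrooted tree at the node adjacent to the named leaf, so
    the leaf becomes the first child (outgroup) of the new root."""
    adjacency: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str | None] = {}

    def register(node: Clade, parent_id: int | None) -> int:
        node_id = len(names)
        names[node_id] = node.name
        adjacency.setdefault(node_id, [])
        if parent_id is not None:
            length = float(node.branch_length or 0.0)
            adjacency[node_id].append((parent_id, length))
            adjacency[parent_id].append((node_id, length))
        for child in node.children:
            register(child, node_id)
        return node_id

    register(root, None)
    leaf_id = next(i for i, nm in names.items() if nm == leaf_name
                   and len(adjacency[i]) == 1)
    anchor_id, leaf_length = adjacency[leaf_id][0]

    def rebuild(node_id: int, parent_id: int | None,
                length: float | None) -> Clade:
        children = [rebuild(other, node_id, l)
                    for other, l in adjacency[node_id] if other != parent_id]
        return Clade(name=names[node_id], branch_length=length,
                     children=children)

    new_root = rebuild(anchor_id, leaf_id, None)
    new_root.children.insert(0, Clade(name=leaf_name,
                                      branch_length=leaf_length))
    return new_root


def tree_distance_matrix(tree: Clade) -> pd.DataFrame:
    """Leaf-to-leaf path-length distances of a tree (used to verify
    additivity of NJ output)."""
    leaves = sorted(tree.leaf_names())
    n = len(leaves)
    dist = pd.DataFrame(np.zeros((n, n)), index=leaves, columns=leaves)

    def fill(node: Clade) -> dict[str, float]:
        # returns distance from this node down to each descendant leaf
        if node.is_leaf:
            return {node.name: 0.0}
        below = []
        for child in node.children:
            sub = fill(child)
            below.append({k: v + float(child.branch_length or 0.0)
                          for k, v in sub.items()})
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for la, da in below[i].items():
                    for lb, db in below[j].items():
                        dist.loc[la, lb] = dist.loc[lb, la] = da + db
        merged: dict[str, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    fill(tree)
    return dist


_RESERVED = set("();:,'[] \t\n")


def _quote(label: str) -> str:
    if any(ch in _RESERVED for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: Clade) -> tuple[str, str]:
    """Render a node; returns (newick fragment, smallest leaf label) for
    deterministic child ordering."""
    if node.is_leaf:
        fragment = _quote(node.name)
        smallest = node.name
    else:
        rendered = sorted((_newick_node(c) for c in node.children),
                          key=lambda t: t[1])
        fragment = "(" + ",".join(r[0] for r in rendered) + ")"
        if node.name:
            fragment += _quote(node.name)
        smallest = min(r[1] for r in rendered)
    if node.branch_length is not None:
        fragment += f":{node.branch_length:g}"
    return fragment, smallest


def to_newick(tree: Clade) -> str:
    """Newick string with branch lengths; children ordered lexicographically
    by the smallest leaf label of each subtree."""
    return _newick_node(tree)[0] + ";"


def write_newick(tree: Clade, path: str | Path | None = None) -> str:
    newick = to_newick(tree)
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
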