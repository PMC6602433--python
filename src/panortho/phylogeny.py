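"""Species tree from the concatenated core proteome.

The built-in engine computes pairwise p-distances (mismatches over columns
where both rows have residues) and runs neighbor joining (Saitou-Nei
Q-criterion), which is guaranteed to recover the generating tree on
additive distances.  NJ on p-distances is the always-available default; a
maximum-likelihood engine (RAxML, LG+G+I on the protein supermatrix) plugs
in through :func:`external_ml_adapter` and falls back to NJ when absent.

Trees are unrooted, leaves are genome ids, negative NJ branch estimates
are clamped to 0, and Newick serialisation is deterministic (children
ordered by smallest descendant leaf id, 6 significant digits).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import ProteinMSA
from .genome_io import write_fasta

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric distances over genome ids, zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def min_leaf(self) -> str:
        return min(lf.name or "" for lf in self.leaves())

    def sort(self) -> None:
        """Canonical child order: by smallest descendant leaf id."""
        for c in self.children:
            c.sort()
        self.children.sort(key=lambda c: c.min_leaf())


@dataclass
class PhyloTree:
    """Unrooted tree over genome ids (stored with an arbitrary basal node)."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return sorted(lf.name for lf in self.root.leaves())


def p_distances(supermatrix: ProteinMSA) -> DistanceMatrix:
    """Pairwise p-distances: mismatches over columns non-gap in both rows."""
    taxa = sorted(supermatrix.rows)
    if len(taxa) < 2:
        raise ValueError("need at least 2 genomes for distances")
    if supermatrix.n_columns == 0:
        raise ValueError("empty alignment")
    arrays = {
        t: np.frombuffer(supermatrix.rows[t].encode(), dtype="S1") for t in taxa
    }
    gap = np.bytes_("-")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrays[taxa[i]], arrays[taxa[j]]
            comparable = (a != gap) & (b != gap)
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(
                    f"insufficient overlap: {taxa[i]} and {taxa[j]} share no aligned columns"
                )
            mism = int(((a != b) & comparable).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(taxa=taxa, d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou-Nei), deterministic tie-breaking.

    The Q-criterion pair with the smallest value is joined each round; ties
    go to the lexicographically smallest pair of node labels (internal
    nodes are labelled by their smallest descendant leaf).  Negative branch
    estimates are clamped to 0.  With 2 taxa the single edge is split
    evenly; 3 taxa get the closed-form star.
    """
    taxa = list(dm.taxa)
    n = len(taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in taxa}
    labels = {t: t for t in taxa}  # working label -> smallest descendant leaf
    d = {
        (a, b): dm.value(a, b)
        for a in taxa
        for b in taxa
        if a != b
    }
    active = sorted(taxa)

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, min(labels[a], labels[b]), max(labels[a], labels[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new_label = f"__internal_{len(nodes)}"
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length, nodes[b].length = la, lb
        nodes[new_label] = parent
        labels[new_label] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (dist(a, c) + dist(b, c) - dab)
            d[(new_label, c)] = d[(c, new_label)] = max(dn, 0.0)
        active = sorted(
            [c for c in active if c not in (a, b)] + [new_label],
            key=lambda c: labels[c],
        )

    if len(active) == 2:
        a, b = active
        half = dist(a, b) / 2.0
        nodes[a].length = nodes[b].length = max(half, 0.0)
        root = TreeNode(children=[nodes[a], nodes[b]])
    else:
        a, b, c = active
        ba = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
        bb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
        bc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        for node, ln in ((a, ba), (b, bb), (c, bc)):
            nodes[node].length = max(ln, 0.0)
        root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.sort()
    return PhyloTree(root=root)


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def _newick_of(node: TreeNode) -> str:
    if not node.children:
        body = node.name or ""
    else:
        body = "(" + ",".join(_newick_of(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if node.length is not None:
        body += f":{_format_length(node.length)}"
    return body


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    """Serialise to Newick (canonical child order); optionally write to file."""
    tree.root.sort()
    text = _newick_of(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string; malformed input raises with parse position."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as e:  # dendropy error messages carry line/column
        raise ValueError(f"malformed Newick: {e}") from e

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        node = TreeNode(
            name=name,
            length=float(dnode.edge.length) if dnode.edge.length is not None else None,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    root.sort()
    return PhyloTree(root=root)


def write_phylip_distances(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance-matrix format."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for i, t in enumerate(dm.taxa):
            row = " ".join(f"{dm.d[i, j]:.6f}" for j in range(len(dm.taxa)))
            fh.write(f"{t:<10s} {row}\n")


@dataclass
class MLConfig:
    binary: str = "raxmlHPC"
    model: str = "PROTGAMMAILG"  # LG + gamma(4) + invariant sites
    partition_file: str | None = None
    extra_args: tuple[str, ...] = ()


def external_ml_adapter(supermatrix: ProteinMSA, config: MLConfig | None = None) -> PhyloTree:
    """Maximum-likelihood tree via an external engine (LG+G+I).

    Falls back to NJ on p-distances, with a prominent warning, when the
    binary is not installed.
    """
    config = config or MLConfig()
    if shutil.which(config.binary) is None:
        logger.warning(
            "ML engine %r not installed; FALLING BACK to neighbor joining on p-distances",
            config.binary,
        )
        return nj_tree(p_distances(supermatrix))
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        phy = tmp / "core.fasta"
        write_fasta(supermatrix.rows, phy)
        cmd = [
            config.binary, "-s", str(phy), "-m", config.model,
            "-p", "12345", "-n", "panortho", "-w", str(tmp), *config.extra_args,
        ]
        if config.partition_file:
            cmd += ["-q", config.partition_file]
        subprocess.run(cmd, check=True, capture_output=True)
        best = tmp / "RAxML_bestTree.panortho"
        return read_newick(best.read_text())
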