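"""Independent brute-force oracles used by the test suite.

Each oracle is written from the mathematical definition, deliberately
avoiding the code paths of the implementation it checks.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from Bio.Align import substitution_matrices

from panortho.genome_io import revcomp
from panortho.orf import DEFAULT_START_CODONS, STOP_CODONS

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Exhaustive Gotoh DP for local alignment; a length-k gap costs open + k*ext."""
    NEG = -1e9
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + BLOSUM62[a[i - 1]][b[j - 1]], E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def nw_global_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Exhaustive Gotoh DP for global alignment under the same gap model."""
    NEG = -1e9
    m, n = len(a), len(b)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for j in range(1, n + 1):
        E[0][j] = -gap_open - gap_extend * j
        H[0][j] = E[0][j]
    for i in range(1, m + 1):
        F[i][0] = -gap_open - gap_extend * i
        H[i][0] = F[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + BLOSUM62[a[i - 1]][b[j - 1]], E[i][j], F[i][j])
    return H[m][n]


def six_frame_orfs(
    seq: str, min_len: int = 90, starts=DEFAULT_START_CODONS
) -> set[tuple[str, int, int]]:
    """All (strand, start, end) ORFs by direct enumeration of stop/start pairs.

    For each frame the stop codons partition the sequence; within each
    inter-stop segment the most upstream start codon opens the single
    reported ORF for the terminating stop.  Intervals are forward-strand,
    half-open, stop codon included.
    """
    out: set[tuple[str, int, int]] = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for frame in range(3):
            stops = [i for i in range(frame, n - 2, 3) if s[i : i + 3] in STOP_CODONS]
            prev = frame - 3
            for stop in stops:
                cands = [
                    i for i in range(prev + 3, stop, 3) if s[i : i + 3] in starts
                ]
                if cands and stop - cands[0] >= min_len:
                    i = cands[0]
                    if strand == "+":
                        out.add(("+", i, stop + 3))
                    else:
                        out.add(("-", n - (stop + 3), n - i))
                prev = stop
    return out


def naive_mcl(g: nx.Graph, inflation: float = 2.0) -> list[frozenset]:
    """Independent dense MCL with canonical defaults.

    Clusters are read off the limit matrix as attractor systems (rows with
    nonzero diagonal, grouped when they exchange flow); every remaining node
    joins the attractor receiving most of its column flow, smallest
    attractor first on ties — the same partition semantics as the
    implementation, recomputed from scratch.
    """
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b in g.edges():
        M[idx[a], idx[b]] = M[idx[b], idx[a]] = 1.0
    for i in range(n):
        M[i, i] = 1.0
    M = M / M.sum(0)
    for _ in range(200):
        new = (M @ M) ** inflation
        new[new < 1e-5] = 0.0
        s = new.sum(0)
        for i in np.flatnonzero(s == 0):
            new[i, i] = 1.0
        new = new / new.sum(0)
        if np.abs(new - M).max() < 1e-6:
            M = new
            break
        M = new
    attractors = [i for i in range(n) if M[i, i] > 0] or list(range(n))
    h = nx.Graph()
    h.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > 0 or M[j, i] > 0):
                h.add_edge(i, j)
    systems = [set(comp) for comp in nx.connected_components(h)]
    clusters = [set(s) for s in systems]
    for j in range(n):
        if j in set(attractors):
            continue
        flows = sorted(((M[i, j], -i) for i in attractors), reverse=True)
        top_flow, neg_i = flows[0]
        if top_flow == 0:
            clusters.append({j})
            continue
        winner = -neg_i
        for s, c in zip(systems, clusters):
            if winner in s:
                c.add(j)
                break
    return sorted(
        (frozenset(nodes[i] for i in c) for c in clusters if c), key=min
    )


def rbh_edges_bruteforce(scores: dict, genome_of: dict) -> set[frozenset]:
    """Edge set by checking both directed top-hit relations for every pair.

    ``scores`` maps unordered frozenset({a, b}) -> score for cross-genome
    pairs that passed the score floor.
    """
    def top_hit(q: str, target_genome: str):
        cands = [
            (s, t)
            for pair, s in scores.items()
            for t in pair
            if q in pair and t != q and genome_of[t] == target_genome
        ]
        if not cands:
            return None
        best_score = max(s for s, _ in cands)
        return min(t for s, t in cands if s == best_score)

    edges = set()
    for pair in scores:
        a, b = sorted(pair)
        if genome_of[a] == genome_of[b]:
            continue
        if top_hit(a, genome_of[b]) == b and top_hit(b, genome_of[a]) == a:
            edges.add(frozenset((a, b)))
    return edges


def pair_counting_scores(
    truth: dict[str, str], inferred: dict[str, str]
) -> tuple[float, float]:
    """(precision, recall) of co-clustering by explicit pair enumeration."""
    import itertools

    items = sorted(truth)
    tp = fp = fn = 0
    for a, b in itertools.combinations(items, 2):
        t = truth[a] == truth[b]
        i = a in inferred and b in inferred and inferred[a] == inferred[b]
        if t and i:
            tp += 1
        elif i:
            fp += 1
        elif t:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


def tree_path_distances(tree, taxa: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of a PhyloTree (branch-length sums)."""
    adj: dict[int, dict[int, float]] = {}

    def walk(node, parent):
        if parent is not None:
            adj.setdefault(id(node), {})[id(parent)] = node.length
            adj.setdefault(id(parent), {})[id(node)] = node.length
        for c in node.children:
            walk(c, node)

    walk(tree.root, None)
    leafid = {}

    def collect(node):
        if not node.children:
            leafid[node.name] = id(node)
        for c in node.children:
            collect(c)

    collect(tree.root)
    n = len(taxa)
    D = np.zeros((n, n))
    for i, t in enumerate(taxa):
        dist = {leafid[t]: 0.0}
        queue = [leafid[t]]
        while queue:
            u = queue.pop()
            for v, w in adj.get(u, {}).items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for j, t2 in enumerate(taxa):
            D[i, j] = dist[leafid[t2]]
    return D


def random_additive_matrix(rng, n: int) -> np.ndarray:
    """Distance matrix realised by a random binary tree with random branch lengths."""
    adj: dict[int, dict[int, float]] = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    avail = list(range(n))
    nxt = n
    while len(avail) > 1:
        a = avail.pop(rng.randrange(len(avail)))
        b = avail.pop(rng.randrange(len(avail)))
        add_edge(a, nxt, rng.uniform(0.05, 1.0))
        add_edge(b, nxt, rng.uniform(0.05, 1.0))
        avail.append(nxt)
        nxt += 1
    D = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        queue = [i]
        while queue:
            u = queue.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    queue.append(v)
        for j in range(n):
            D[i, j] = dist[j]
    np.fill_diagonal(D, 0.0)
    return D
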