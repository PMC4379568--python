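"""Maximum-parsimony phylogenetics for LTR sequence families.

The reconstruction pipeline mirrors classic distance-guided progressive
alignment followed by a heuristic maximum-parsimony search:

* :func:`build_msa` — progressive multiple alignment with a
  neighbor-joining guide tree computed from pairwise p-distances and
  profile-profile global alignment up the guide tree;
* :func:`fitch_score` — Fitch small parsimony (minimum state changes),
  with gaps and ``N`` treated as missing data;
* :func:`mp_search` — heuristic search: seeded random stepwise addition
  of taxa followed by subtree-pruning-regrafting (SPR) hill climbing
  that accepts the first improving move per iteration; all tied-best
  topologies are retained;
* :func:`bootstrap_support` — site resampling with replacement, an MP
  search per replicate and a majority-rule consensus whose internal
  nodes carry percentage supports (only clades above 50% appear).

The search operates on site *patterns* (unique columns with
multiplicities), restricted to parsimony-informative patterns; the
topology-independent contribution of uninformative sites is added back
to reported scores.  Candidate SPR insertions are scored exactly in
O(1) vector operations per edge using directional (edge-rooted) Fitch
state sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .pairwise_align import (
    DEFAULT_SCORING,
    ScoringScheme,
    _gotoh_tables,
    _trace_moves,
    global_align,
    percent_identity,
)
from .sequence_io import ParseError

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


# ---------------------------------------------------------------------------
# multiple sequence alignment container
# ---------------------------------------------------------------------------


@dataclass
class Msa:
    labels: List[str]
    rows: List[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def degapped(self, label: str) -> str:
        return self.rows[self.labels.index(label)].replace("-", "")


def load_aligned_fasta(path) -> Msa:
    """Load an externally aligned FASTA (rows must have equal length)."""
    from Bio import SeqIO

    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not labels:
        raise ParseError(f"no records in {path}")
    return Msa(labels, rows)


def _encode_msa(msa: Msa) -> np.ndarray:
    """Leaf x site matrix of state bitmasks; gap/N/other -> missing (15)."""
    X = np.full((len(msa.rows), msa.n_sites), _MISSING, dtype=np.uint8)
    for i, row in enumerate(msa.rows):
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for base, bit in _BITS.items():
            X[i, arr == ord(base)] = bit
    return X


def _compress(X: np.ndarray):
    """Unique site patterns, their multiplicities and column->pattern map."""
    patterns, inverse, counts = np.unique(
        X, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(np.int64), inverse


def _informative_mask(patterns: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean mask of parsimony-informative patterns and, for the rest,
    their topology-independent parsimony length (distinct states - 1)."""
    n_pat = patterns.shape[1]
    informative = np.zeros(n_pat, dtype=bool)
    const_len = np.zeros(n_pat, dtype=np.int64)
    for p in range(n_pat):
        col = patterns[:, p]
        counts = [(col == bit).sum() for bit in (1, 2, 4, 8)]
        n_repeated = sum(1 for c in counts if c >= 2)
        n_present = sum(1 for c in counts if c >= 1)
        if n_repeated >= 2:
            informative[p] = True
        else:
            const_len[p] = max(n_present - 1, 0)
    return informative, const_len


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------


class PhyloTree:
    """Unrooted tree over sequence labels, with optional integer parsimony
    score and per-clade bootstrap supports stored as internal node labels."""

    def __init__(self, dtree: dendropy.Tree, parsimony_score: Optional[int] = None,
                 note: Optional[str] = None):
        self.dtree = dtree
        self.parsimony_score = parsimony_score
        self.note = note
        for leaf in dtree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("tree contains an unlabeled leaf")

    @classmethod
    def from_newick(cls, text: str, **kw) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ParseError(f"malformed newick: {exc}") from exc
        return cls(dtree, **kw)

    def as_newick(self) -> str:
        return self.dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(l.taxon.label for l in self.dtree.leaf_node_iter())

    def bipartitions(self) -> FrozenSet[FrozenSet[str]]:
        """Non-trivial splits, each canonicalized as the side not
        containing the lexicographically smallest leaf label."""
        labels = self.leaf_labels
        if not labels:
            return frozenset()
        ref = min(labels)
        n = len(labels)
        splits = set()
        for node in self.dtree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            side = clade if ref not in clade else labels - clade
            if 2 <= len(side) <= n - 2:
                splits.add(frozenset(side))
        return frozenset(splits)

    def support_for(self, labels) -> Optional[int]:
        """Support of the bipartition separating ``labels`` from the rest,
        whichever side of the split the tree's rooting places them on."""
        clade = frozenset(labels)
        sup = self.supports()
        if clade in sup:
            return sup[clade]
        return sup.get(self.leaf_labels - clade)

    def supports(self) -> Dict[FrozenSet[str], int]:
        """Map of clade label-set -> integer support, from internal labels."""
        out = {}
        for node in self.dtree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or node.label is None:
                continue
            try:
                sup = int(round(float(node.label)))
            except ValueError:
                continue
            out[frozenset(l.taxon.label for l in node.leaf_iter())] = sup
        return out


# ---------------------------------------------------------------------------
# Fitch small parsimony on arbitrary (dendropy-backed) trees
# ---------------------------------------------------------------------------


def _fold_children(child_sets, w):
    """Sequential Fitch fold of child state sets; returns (set, changes)."""
    cur = child_sets[0]
    changes = 0
    for nxt in child_sets[1:]:
        inter = cur & nxt
        miss = inter == 0
        changes += int((w * miss).sum())
        cur = np.where(miss, cur | nxt, inter)
    return cur, changes


def fitch_score(tree: PhyloTree, msa: Msa) -> int:
    """Minimum number of state changes the alignment requires on the tree.

    Gaps and N are missing data: a missing leaf is compatible with any
    state and never forces a change on its own.
    """
    if tree.leaf_labels != frozenset(msa.labels):
        raise ValueError("tree leaf set does not match alignment labels")
    X = _encode_msa(msa)
    patterns, w, _ = _compress(X)
    row_of = {lab: i for i, lab in enumerate(msa.labels)}
    total = 0
    sets: Dict[int, np.ndarray] = {}
    for node in tree.dtree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = patterns[row_of[node.taxon.label]]
            continue
        kids = [sets[id(c)] for c in node.child_nodes()]
        cur, changes = _fold_children(kids, w)
        total += changes
        sets[id(node)] = cur
    return int(total)


# ---------------------------------------------------------------------------
# compact unrooted binary trees for the heuristic search
# ---------------------------------------------------------------------------
# Leaves are 0..n-1; internal nodes get ids >= n.  Adjacency is a dict of
# sets.  All scoring below runs on (pattern, weight) arrays.


def _rooted_order(adj, root):
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    return parent, order


def _score_adj(adj, X, w) -> int:
    """Fitch score of an unrooted tree given leaf pattern rows X."""
    if len(adj) == 2:  # two leaves, single edge
        a, b = sorted(adj)
        inter = X[a] & X[b]
        return int((w * (inter == 0)).sum())
    root = next(iter(adj[0]))  # internal neighbor of leaf 0
    parent, order = _rooted_order(adj, root)
    sets = {}
    total = 0
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            sets[u] = X[u]
            continue
        cur, changes = _fold_children([sets[v] for v in kids], w)
        total += changes
        sets[u] = cur
    return int(total)


def _combine(a, b, w):
    """Fitch-join two (set, count) pairs."""
    sa, ca = a
    sb, cb = b
    inter = sa & sb
    miss = inter == 0
    cost = int((w * miss).sum())
    return np.where(miss, sa | sb, inter), ca + cb + cost


def _directional(adj, X, w, root):
    """Down (subtree) and up (rest-of-tree) Fitch sets for every non-root
    node, relative to an internal ``root``."""
    parent, order = _rooted_order(adj, root)
    down = {}
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            down[u] = (X[u], 0)
            continue
        acc = down[kids[0]]
        for v in kids[1:]:
            acc = _combine(acc, down[v], w)
        down[u] = acc
    up = {}
    for u in order:
        for v in adj[u]:
            if parent[v] != u:
                continue
            pieces = [] if u == root else [up[u]]
            pieces += [down[s] for s in adj[u] if s != v and parent.get(s) == u]
            acc = pieces[0]
            for piece in pieces[1:]:
                acc = _combine(acc, piece, w)
            up[v] = acc
    return parent, down, up


def _join3_cost(A, B, R, w) -> int:
    """Fitch changes created by joining three directional sets at a node."""
    inter = A & B
    m1 = inter == 0
    s1 = np.where(m1, A | B, inter)
    m2 = (s1 & R) == 0
    return int((w * m1).sum() + (w * m2).sum())


def _insertion_scores(adj, X, w, root, r_set, r_cnt):
    """Score attaching a subtree (r_set, r_cnt) into every edge.

    Returns list of ((parent, child), total_score), edges in sorted order.
    """
    parent, down, up = _directional(adj, X, w, root)
    out = []
    for v in sorted(parent):
        u = parent[v]
        if u is None:
            continue
        ds, dc = down[v]
        us, uc = up[v]
        sc = dc + uc + r_cnt + _join3_cost(ds, us, r_set, w)
        out.append(((u, v), sc))
    return out


def _subtree_state(adj, v, banned, X, w):
    """(set, count) of the subtree at ``v`` looking away from ``banned``."""
    parent = {v: banned}
    order = [v]
    stack = [v]
    while stack:
        u = stack.pop()
        for nb in adj[u]:
            if nb != parent[u]:
                parent[nb] = u
                order.append(nb)
                stack.append(nb)
    acc = {}
    for u in reversed(order):
        kids = [nb for nb in adj[u] if nb != parent[u]]
        if not kids:
            acc[u] = (X[u], 0)
            continue
        cur = acc[kids[0]]
        for nb in kids[1:]:
            cur = _combine(cur, acc[nb], w)
        acc[u] = cur
    return acc[v]


def _pick_root(adj):
    for node, nbrs in adj.items():
        if len(nbrs) > 1:
            return node
    return None


def _stepwise_addition(X, w, order, start_id):
    """Greedy stepwise addition of taxa in the given order."""
    a, b, c = order[:3]
    nid = start_id
    adj = {a: {nid}, b: {nid}, c: {nid}, nid: {a, b, c}}
    nid += 1
    for t in order[3:]:
        root = _pick_root(adj)
        scores = _insertion_scores(adj, X, w, root, X[t], 0)
        (u, v), _ = min(scores, key=lambda e: (e[1], e[0]))
        adj[u].discard(v)
        adj[v].discard(u)
        adj[nid] = {u, v, t}
        adj[u].add(nid)
        adj[v].add(nid)
        adj[t] = {nid}
        nid += 1
    return adj


def _spr_once(adj, X, w, current_score):
    """First improving SPR move, or None at a local optimum."""
    edges = sorted(
        (u, v) for u in adj for v in adj[u] if len(adj[u]) == 3
    )  # prune the v-side subtree; u must be internal so it can be suppressed
    for u, v in edges:
        host = {k: set(nb) for k, nb in adj.items()}
        # detach v-side subtree and suppress u
        host[u].discard(v)
        host[v].discard(u)
        sub_nodes = set(_rooted_order(host, v)[1])
        for node in sub_nodes:
            del host[node]
        nb = list(host[u])
        a_node, b_node = nb
        del host[u]
        host[a_node].discard(u)
        host[b_node].discard(u)
        host[a_node].add(b_node)
        host[b_node].add(a_node)
        if len(host) < 4:
            continue  # re-insertion can only restore the original tree
        root = _pick_root(host)
        if root is None:
            continue
        r_set, r_cnt = _subtree_state(adj, v, u, X, w)
        for (p, c), sc in _insertion_scores(host, X, w, root, r_set, r_cnt):
            if {p, c} == {a_node, b_node}:
                continue  # original attachment point
            if sc < current_score:
                for node in sub_nodes:
                    host[node] = set(adj[node])
                host[p].discard(c)
                host[c].discard(p)
                host[u] = {p, c, v}
                host[p].add(u)
                host[c].add(u)
                return host, sc
    return None


def _spr_optimize(adj, X, w, score):
    while True:
        res = _spr_once(adj, X, w, score)
        if res is None:
            return adj, score
        adj, score = res


def _canonical_splits(adj, n_leaves) -> FrozenSet[FrozenSet[int]]:
    all_leaves = frozenset(range(n_leaves))
    if len(adj) <= 2:
        return frozenset()
    root = next(iter(adj[0]))
    parent, order = _rooted_order(adj, root)
    below: Dict[int, frozenset] = {}
    splits = set()
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            below[u] = frozenset([u])
            continue
        below[u] = frozenset().union(*(below[v] for v in kids))
    for v, u in parent.items():
        if u is None:
            continue
        side = below[v]
        if 0 in side:
            side = all_leaves - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(side)
    return frozenset(splits)


def _adj_to_newick(adj, labels) -> str:
    if len(adj) == 2:
        return f"({labels[0]},{labels[1]});"
    root = next(iter(adj[0]))
    parent, _ = _rooted_order(adj, root)

    def minleaf(u):
        if u < len(labels):
            return u
        return min(minleaf(v) for v in adj[u] if v != parent[u])

    def render(u):
        if u < len(labels):
            return labels[u]
        kids = sorted((v for v in adj[u] if v != parent[u]), key=minleaf)
        return "(" + ",".join(render(v) for v in kids) + ")"

    return render(root) + ";"


def _adj_to_tree(adj, labels, score=None) -> PhyloTree:
    return PhyloTree.from_newick(_adj_to_newick(adj, labels),
                                 parsimony_score=score)


# ---------------------------------------------------------------------------
# public search interface
# ---------------------------------------------------------------------------


def mp_search(
    msa: Msa,
    n_random_addition_starts: int = 10,
    seed: int = 0,
    spr: bool = True,
) -> List[PhyloTree]:
    """Heuristic maximum-parsimony search.

    Each start adds taxa in a seeded random order (each to its best
    insertion point) and then hill-climbs with SPR, accepting the first
    improving move per iteration, until no move improves the score.
    All distinct topologies tying the best score are returned,
    deterministically ordered.
    """
    n = len(msa.labels)
    if n < 4:
        tree = PhyloTree.from_newick("(" + ",".join(msa.labels) + ");",
                                     note="fewer than 4 taxa: trivial topology")
        tree.parsimony_score = fitch_score(tree, msa)
        return [tree]
    X = _encode_msa(msa)
    patterns, w, _ = _compress(X)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    adjs, score = _search(patterns, w, n, n_random_addition_starts, rng, spr)
    trees = []
    for key in sorted(adjs, key=_split_sort_key):
        trees.append(_adj_to_tree(adjs[key], msa.labels, score))
    return trees


def _split_sort_key(splits):
    return tuple(sorted(tuple(sorted(s)) for s in splits))


def _search(patterns, w, n_leaves, n_starts, rng, spr):
    """Core search on pattern/weight arrays; returns ({splits: adj}, best)."""
    informative, const_len = _informative_mask(patterns)
    const = int((w[~informative] * const_len[~informative]).sum())
    Xi = patterns[:, informative]
    wi = w[informative]
    if Xi.shape[1] == 0:
        # no informative sites: every resolved topology ties, so no
        # grouping is defensible — return the star topology
        hub = n_leaves
        adj = {hub: set(range(n_leaves))}
        adj.update({i: {hub} for i in range(n_leaves)})
        return {_canonical_splits(adj, n_leaves): adj}, const
    best: Dict = {}
    best_score = None
    for _ in range(max(n_starts, 1)):
        order = list(rng.permutation(n_leaves))
        adj = _stepwise_addition(Xi, wi, order, n_leaves)
        sc = _score_adj(adj, Xi, wi)
        if spr:
            adj, sc = _spr_optimize(adj, Xi, wi, sc)
        if best_score is None or sc < best_score:
            best_score = sc
            best = {_canonical_splits(adj, n_leaves): adj}
        elif sc == best_score:
            best.setdefault(_canonical_splits(adj, n_leaves), adj)
    return best, best_score + const


# ---------------------------------------------------------------------------
# consensus and bootstrap
# ---------------------------------------------------------------------------


def majority_rule_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Majority-rule consensus: exactly the bipartitions present in more
    than half of the input trees, supports = occurrence percentages."""
    if not trees:
        raise ValueError("no trees given")
    leafset = trees[0].leaf_labels
    for t in trees[1:]:
        if t.leaf_labels != leafset:
            raise ValueError("trees have mismatching leaf sets")
    counts: Dict[FrozenSet[str], int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    return _consensus_from_counts(counts, len(trees), leafset)


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    """Consensus containing only the bipartitions shared by every tree."""
    if not trees:
        raise ValueError("no trees given")
    leafset = trees[0].leaf_labels
    counts: Dict[FrozenSet[str], int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    kept = {s: n for s, n in counts.items() if n == len(trees)}
    return _consensus_from_counts(kept, len(trees), leafset, min_frac=0.999999)


def _consensus_from_counts(counts, n_total, leafset, min_frac=0.5) -> PhyloTree:
    kept = [(s, c) for s, c in counts.items() if c / n_total > min_frac]
    # nest larger clades first; all kept splits are pairwise compatible
    kept.sort(key=lambda sc: (-len(sc[0]), _split_sort_key([sc[0]])))

    class _Node:
        def __init__(self, labels, support=None):
            self.labels = labels
            self.support = support
            self.children: List[_Node] = []

    root = _Node(frozenset(leafset))
    root.children = [_Node(frozenset([lab])) for lab in sorted(leafset)]
    for split, c in kept:
        cur = root
        while True:
            host = next(
                (ch for ch in cur.children
                 if len(ch.labels) > 1 and split < ch.labels),
                None,
            )
            if host is None:
                break
            cur = host
        grouped = [ch for ch in cur.children if ch.labels <= split]
        rest = [ch for ch in cur.children if not (ch.labels <= split)]
        new = _Node(split, support=int(round(100.0 * c / n_total)))
        new.children = grouped
        cur.children = rest + [new]

    def render(node):
        if not node.children:
            return next(iter(node.labels))
        inner = ",".join(render(ch) for ch in
                         sorted(node.children, key=lambda x: min(x.labels)))
        sup = "" if node.support is None else str(node.support)
        return f"({inner}){sup}"

    return PhyloTree.from_newick(render(root) + ";")


def bootstrap_support(
    msa: Msa,
    n_reps: int = 1000,
    seed: int = 0,
    n_random_addition_starts: int = 1,
    spr: bool = True,
) -> PhyloTree:
    """Bootstrap the MP reconstruction by resampling alignment sites.

    Replicate ``r`` draws its randomness from ``SeedSequence(seed,
    spawn_key=(r,))``, so runs are reproducible and replicates
    independent.  Returns the majority-rule consensus of the replicate
    trees with integer percentage supports; by construction only clades
    with support above 50 appear.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(msa.labels)
    X = _encode_msa(msa)
    patterns, _, inverse = _compress(X)
    n_sites = msa.n_sites
    counts: Dict[FrozenSet[int], int] = {}
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))
        idx = rng.integers(0, n_sites, n_sites)
        w_rep = np.bincount(inverse[idx], minlength=patterns.shape[1]).astype(np.int64)
        if n < 4:
            continue
        adjs, _ = _search(patterns, w_rep, n, n_random_addition_starts, rng, spr)
        first = adjs[sorted(adjs, key=_split_sort_key)[0]]
        for split in _canonical_splits(first, n):
            counts[split] = counts.get(split, 0) + 1
    label_counts = {
        frozenset(msa.labels[i] for i in split): c for split, c in counts.items()
    }
    return _consensus_from_counts(label_counts, n_reps, frozenset(msa.labels))


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def build_msa(seqs, scoring: Optional[ScoringScheme] = None) -> Msa:
    """Progressive multiple alignment.

    Pairwise p-distances (1 - identity) from global alignments feed a
    neighbor-joining guide tree; profiles are then aligned pairwise up
    the guide tree with the same affine-gap scheme.  Deterministic for a
    fixed input order and scoring.
    """
    scoring = scoring or DEFAULT_SCORING
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence ids")
    seq_of = {s.id: s.seq.upper() for s in seqs}
    if len(seqs) == 2:
        aln = global_align(seqs[0], seqs[1], scoring)
        return Msa(labels, [aln.aligned_a, aln.aligned_b])

    n = len(seqs)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(global_align(seqs[i], seqs[j], scoring))
            dmat[i, j] = dmat[j, i] = 1.0 - pid / 100.0
    guide = nj(DistanceMatrix(dmat, ids=labels))

    def profile(node):
        if node.is_tip():
            return [node.name], [seq_of[node.name]]
        kids = node.children
        labs, rows = profile(kids[0])
        for child in kids[1:]:
            labs2, rows2 = profile(child)
            rows, rows2 = _profile_align(rows, rows2, scoring)
            labs, rows = labs + labs2, rows + rows2
        return labs, rows

    labs, rows = profile(guide.root())
    row_of = dict(zip(labs, rows))
    return Msa(labels, [row_of[lab] for lab in labels])


def _profile_align(rows_a: List[str], rows_b: List[str], scoring: ScoringScheme):
    """Align two gapped profiles; returns the two row groups re-gapped."""
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    sub = np.full((4, 4), float(scoring.mismatch))
    np.fill_diagonal(sub, float(scoring.match))
    S = fa @ sub @ fb.T
    go, ge = float(scoring.gap_open), float(scoring.gap_extend)
    M, E, F = _gotoh_tables(S, go, ge)
    moves = _trace_moves(M, E, F, go, ge)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for mv in moves:
        if mv in ("D", "V"):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
        if mv in ("D", "H"):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _profile_freqs(rows: List[str]) -> np.ndarray:
    length = len(rows[0])
    freqs = np.zeros((length, 4))
    for row in rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for k, base in enumerate("ACGT"):
            freqs[arr == ord(base), k] += 1.0
    return freqs / len(rows)
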