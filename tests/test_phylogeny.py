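"""Parsimony phylogenetics: Fitch oracle, search, consensus, bootstrap."""

import itertools

import dendropy
import numpy as np
import pytest

import hervetools as h
from hervetools import phylogeny as ph
from hervetools.phylogeny import (
    Msa,
    PhyloTree,
    _compress,
    _encode_msa,
    _score_adj,
    bootstrap_support,
    build_msa,
    fitch_score,
    majority_rule_consensus,
    mp_search,
)
from hervetools.sequence_io import LtrSequence


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_fitch(tree: PhyloTree, msa: Msa) -> int:
    """Exhaustive small parsimony: minimize edge changes over all internal
    state assignments; a missing leaf costs nothing whatever its parent."""
    dt = tree.dtree
    nodes = list(dt.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    total = 0
    for site in range(msa.n_sites):
        state = {
            lab: msa.rows[k][site] for k, lab in enumerate(msa.labels)
        }
        best = None
        for assign in itertools.product("ACGT", repeat=len(internal)):
            amap = {id(n): s for n, s in zip(internal, assign)}
            cost = 0
            for n in nodes:
                if n.parent_node is None:
                    continue
                up = amap[id(n.parent_node)]
                if n.is_leaf():
                    s = state[n.taxon.label]
                    if s in "ACGT":
                        cost += s != up
                    # gap/N: free to match the parent, zero cost
                else:
                    cost += amap[id(n)] != up
            best = cost if best is None else min(best, cost)
        total += best
    return total


def all_topologies(n):
    """All unrooted binary topologies over leaves 0..n-1 (adjacency dicts)."""
    trees = [({0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}, n + 1)]
    for t in range(3, n):
        new = []
        for adj, nid in trees:
            for u, v in {tuple(sorted(e)) for x in adj for e in
                         ((x, y) for y in adj[x])}:
                a2 = {k: set(s) for k, s in adj.items()}
                a2[u].discard(v)
                a2[v].discard(u)
                a2[nid] = {u, v, t}
                a2[u].add(nid)
                a2[v].add(nid)
                a2[t] = {nid}
                new.append((a2, nid + 1))
        trees = new
    return [a for a, _ in trees]


def exhaustive_best_score(msa: Msa) -> int:
    X = _encode_msa(msa)
    patterns, w, _ = _compress(X)
    return min(
        _score_adj(adj, patterns, w) for adj in all_topologies(len(msa.labels))
    )


def random_binary_newick(rng, labels):
    items = list(labels)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        items[i] = f"({items[i]},{items.pop(j)})"
    return "(" + ",".join(items) + ");"


def random_msa(rng, n, sites, alphabet="ACGT-"):
    return Msa(
        [f"T{i}" for i in range(n)],
        ["".join(rng.choice(list(alphabet), sites)) for _ in range(n)],
    )


def simulated_msa(rng, n=7, sites=60, p=0.08):
    root = "".join(rng.choice(list("ACGT"), sites))
    seqs = [root]
    while len(seqs) < n:
        parent = list(seqs[int(rng.integers(len(seqs)))])
        for i in range(sites):
            if rng.random() < p:
                parent[i] = rng.choice([b for b in "ACGT" if b != parent[i]])
        seqs.append("".join(parent))
    return Msa([f"T{i}" for i in range(n)], seqs)


# ---------------------------------------------------------------------------
# build_msa
# ---------------------------------------------------------------------------


class TestBuildMsa:
    def test_identical_pair_gap_free(self):
        seqs = [LtrSequence("a", "ACGTACGT"), LtrSequence("b", "ACGTACGT")]
        msa = build_msa(seqs)
        assert msa.rows == ["ACGTACGT", "ACGTACGT"]

    def test_degap_recovers_inputs(self):
        seqs = [LtrSequence("a", "ACGT"), LtrSequence("b", "AGT"),
                LtrSequence("c", "ACT")]
        msa = build_msa(seqs)
        for s in seqs:
            assert msa.degapped(s.id) == s.seq

    def test_degap_recovers_inputs_large(self, rng):
        base = "".join(rng.choice(list("ACGT"), 200))
        seqs = []
        for k in range(6):
            mutated = list(base)
            for pos in rng.choice(200, 15, replace=False):
                mutated[pos] = rng.choice([c for c in "ACGT" if c != mutated[pos]])
            cut = int(rng.integers(20, 180))
            seqs.append(LtrSequence(f"s{k}", "".join(mutated[:cut] + mutated[cut + 4:])))
        msa = build_msa(seqs)
        for s in seqs:
            assert msa.degapped(s.id) == s.seq

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_msa([LtrSequence("a", "ACGT")])

    def test_unequal_aligned_fasta_rejected(self, tmp_path):
        p = tmp_path / "aln.fa"
        p.write_text(">a\nAC-GT\n>b\nACGT\n")
        with pytest.raises(ValueError):
            ph.load_aligned_fasta(p)

    def test_deterministic(self, rng):
        seqs = [
            LtrSequence(f"s{k}", "".join(rng.choice(list("ACGT"), 100)))
            for k in range(5)
        ]
        assert build_msa(seqs).rows == build_msa(seqs).rows


# ---------------------------------------------------------------------------
# fitch_score
# ---------------------------------------------------------------------------


class TestFitchScore:
    def test_identical_rows_score_zero(self):
        msa = Msa(["A1", "B1", "C1", "D1"], ["ACGT"] * 4)
        tree = PhyloTree.from_newick("((A1,B1),(C1,D1));")
        assert fitch_score(tree, msa) == 0

    def test_single_informative_site(self):
        msa = Msa(["t1", "t2", "t3", "t4"], ["A", "A", "C", "C"])
        assert fitch_score(PhyloTree.from_newick("((t1,t2),(t3,t4));"), msa) == 1
        assert fitch_score(PhyloTree.from_newick("((t1,t3),(t2,t4));"), msa) == 2

    def test_label_mismatch_rejected(self):
        msa = Msa(["a", "b", "c", "d"], ["A"] * 4)
        with pytest.raises(ValueError):
            fitch_score(PhyloTree.from_newick("((a,b),(c,x));"), msa)

    def test_matches_exhaustive_assignment_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 7))
            msa = random_msa(rng, n, int(rng.integers(3, 8)))
            nwk = random_binary_newick(rng, msa.labels)
            tree = PhyloTree.from_newick(nwk)
            assert fitch_score(tree, msa) == brute_fitch(tree, msa)


# ---------------------------------------------------------------------------
# mp_search
# ---------------------------------------------------------------------------


class TestMpSearch:
    def test_four_taxa_equals_enumeration(self, rng):
        msa = random_msa(rng, 4, 12, alphabet="ACGT")
        best = exhaustive_best_score(msa)
        trees = mp_search(msa, n_random_addition_starts=3, seed=0)
        assert trees[0].parsimony_score == best

    def test_seven_taxa_equals_enumeration(self, rng):
        for trial in range(5):
            msa = simulated_msa(rng)
            best = exhaustive_best_score(msa)
            trees = mp_search(msa, n_random_addition_starts=10, seed=trial)
            assert trees[0].parsimony_score == best

    def test_deterministic_given_seed(self, rng):
        msa = simulated_msa(rng)
        a = [t.as_newick() for t in mp_search(msa, 5, seed=7)]
        b = [t.as_newick() for t in mp_search(msa, 5, seed=7)]
        assert a == b

    def test_fewer_than_four_taxa_trivial(self):
        msa = Msa(["a", "b", "c"], ["ACGT", "ACGT", "AGGT"])
        trees = mp_search(msa)
        assert len(trees) == 1
        assert trees[0].note is not None
        assert trees[0].leaf_labels == {"a", "b", "c"}

    def test_reported_score_matches_full_fitch(self, rng):
        msa = simulated_msa(rng, n=8, sites=40)
        for tree in mp_search(msa, 5, seed=1):
            assert fitch_score(tree, msa) == tree.parsimony_score


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [PhyloTree.from_newick("((A,B),(C,D),E);") for _ in range(4)]
        cons = majority_rule_consensus(trees)
        assert cons.bipartitions() == trees[0].bipartitions()
        assert set(cons.supports().values()) == {100}

    def test_two_of_three_share_a_split(self):
        trees = [
            PhyloTree.from_newick("((A,B),(C,D),E);"),
            PhyloTree.from_newick("((A,B),(C,E),D);"),
            PhyloTree.from_newick("((A,C),(B,D),E);"),
        ]
        cons = majority_rule_consensus(trees)
        sup = cons.support_for({"A", "B"})
        assert sup == 67
        assert len(cons.bipartitions()) == 1

    def test_fully_conflicting_trees_give_star(self):
        trees = [
            PhyloTree.from_newick("((A,B),(C,D),E);"),
            PhyloTree.from_newick("((A,C),(B,E),D);"),
            PhyloTree.from_newick("((A,D),(B,C),E);"),
        ]
        assert majority_rule_consensus(trees).bipartitions() == frozenset()

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            majority_rule_consensus([
                PhyloTree.from_newick("((A,B),(C,D),E);"),
                PhyloTree.from_newick("((A,B),(C,D),F);"),
            ])

    def test_matches_dendropy_consensus(self, rng):
        """Cross-check the consensus topology against dendropy's
        majority-rule implementation on random tree samples."""
        for trial in range(5):
            labels = [f"T{i}" for i in range(6)]
            newicks = [random_binary_newick(rng, labels) for _ in range(7)]
            mine = majority_rule_consensus(
                [PhyloTree.from_newick(nwk) for nwk in newicks]
            )
            tns = dendropy.TaxonNamespace()
            tl = dendropy.TreeList.get(
                data="\n".join(newicks), schema="newick", taxon_namespace=tns
            )
            theirs = PhyloTree(tl.consensus(min_freq=0.5))
            assert mine.bipartitions() == theirs.bipartitions()


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


class TestBootstrap:
    def test_identical_rows_give_star(self):
        msa = Msa(["a", "b", "c", "d"], ["ACGTACGT"] * 4)
        cons = bootstrap_support(msa, n_reps=10, seed=0)
        assert cons.bipartitions() == frozenset()

    def test_single_replicate_full_support(self, rng):
        msa = simulated_msa(rng, n=6, sites=80, p=0.10)
        cons = bootstrap_support(msa, n_reps=1, seed=3)
        assert all(v == 100 for v in cons.supports().values())

    def test_supports_in_range_and_majority(self, rng):
        msa = simulated_msa(rng, n=7, sites=60)
        cons = bootstrap_support(msa, n_reps=30, seed=5)
        for v in cons.supports().values():
            assert 50 < v <= 100

    def test_three_clade_recovery(self, rng):
        """Three well-separated ancestral families are each recovered as
        a supported clade."""
        ancestors = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(3)]
        # make ancestors ~25% diverged from each other
        labels, rows = [], []
        for fam, anc in enumerate(ancestors):
            for k in range(4):
                seq = list(anc)
                for pos in rng.choice(120, 5, replace=False):
                    seq[pos] = rng.choice([c for c in "ACGT" if c != seq[pos]])
                labels.append(f"F{fam}_{k}")
                rows.append("".join(seq))
        msa = Msa(labels, rows)
        cons = bootstrap_support(msa, n_reps=50, seed=9)
        for fam in range(3):
            clade = {lab for lab in labels if lab.startswith(f"F{fam}_")}
            sup = cons.support_for(clade)
            assert sup is not None and sup >= 90, (fam, sup)

    def test_deterministic_given_seed(self, rng):
        msa = simulated_msa(rng, n=6, sites=50)
        a = bootstrap_support(msa, n_reps=10, seed=2).as_newick()
        b = bootstrap_support(msa, n_reps=10, seed=2).as_newick()
        assert a == b
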