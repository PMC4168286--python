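"""Shared fixtures: random tree/alignment generators and brute-force oracles.

The oracles here deliberately avoid the code paths they check: bipartitions
are enumerated by deleting edges from a networkx graph, distances by direct
per-character loops, and counts by naive column/run enumeration.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import networkx as nx
import numpy as np
import pytest

from barcodeval import DistanceMatrix, LocusAlignment, SampleTable


# ---------------------------------------------------------------------------
# Random inputs
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary unrooted tree; returns (taxa, path-distance matrix, tree).

    Built by sequential random attachment with branch lengths in [0.1, 2],
    so the distance matrix is strictly additive with positive internal edges.
    """
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    g = nx.Graph()
    g.add_edge(taxa[0], taxa[1], length=float(rng.uniform(0.1, 2.0)))
    internal = itertools.count()
    for leaf in taxa[2:]:
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        length = g.edges[u, v]["length"]
        mid = f"i{next(internal)}"
        split = float(rng.uniform(0.25, 0.75))
        g.remove_edge(u, v)
        g.add_edge(u, mid, length=length * split)
        g.add_edge(mid, v, length=length * (1 - split))
        g.add_edge(mid, leaf, length=float(rng.uniform(0.1, 2.0)))
    n = len(taxa)
    D = np.zeros((n, n))
    for i, a in enumerate(taxa):
        lengths = nx.single_source_dijkstra_path_length(g, a, weight="length")
        for j, b in enumerate(taxa):
            D[i, j] = lengths[b]
    return taxa, D, g


def dmat_from_square(taxa, D) -> DistanceMatrix:
    n = len(taxa)
    return DistanceMatrix(
        taxa=tuple(taxa),
        d=np.asarray(D, dtype=float),
        defined=np.ones((n, n), dtype=bool),
        P=np.zeros((n, n)),
        Q=np.zeros((n, n)),
        n_sites=np.full((n, n), 1, dtype=int),
    )


def random_labelled_tree(rng: np.random.Generator, n_leaves: int, n_species: int,
                         n_groups: int = 2):
    """Random rooted tree with random (possibly zero) branch lengths plus a
    metadata table mapping leaves to species and species to groups."""
    taxa = [f"x{i:02d}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(taxa)
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in taxa]
    while len(nodes) > 1:
        k = int(rng.integers(2, min(3, len(nodes)) + 1))
        idx = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        parent = dendropy.Node()
        for i in idx:
            child = nodes.pop(i)
            parent.add_child(child)
            child.edge.length = float(rng.choice([0.0, 0.5, 1.0]))
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = False
    species = [f"sp{int(rng.integers(n_species)):02d}" for _ in taxa]
    groups = {f"sp{i:02d}": f"g{i % n_groups}" for i in range(n_species)}
    table = SampleTable.from_records(
        [
            {
                "accession_id": t,
                "species": sp,
                "group": groups[sp],
                "endangered": bool(rng.integers(2)),
                "region": "r",
            }
            for t, sp in zip(taxa, species)
        ]
    )
    return tree, table


def random_alignment(rng: np.random.Generator, n_seqs: int, length: int,
                     gap_prob: float = 0.08) -> LocusAlignment:
    alphabet = np.array(list("ACGT"))
    rows = {}
    for i in range(n_seqs):
        chars = alphabet[rng.integers(0, 4, size=length)]
        gaps = rng.random(length) < gap_prob
        chars = np.where(gaps, "-", chars)
        rows[f"s{i:02d}"] = "".join(chars)
    return LocusAlignment(locus_name="rand", sequences=rows)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_bipartition_leaf_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Both sides of every edge-removal bipartition, via graph surgery."""
    g = nx.Graph()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            g.add_edge(id(nd.parent_node), id(nd))
    label = {
        id(lf): lf.taxon.label for lf in tree.leaf_node_iter()
    }
    sets = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        for comp in nx.connected_components(h):
            leaves = frozenset(label[x] for x in comp if x in label)
            if leaves and len(leaves) < len(label):
                sets.add(leaves)
    return sets


def oracle_k2p(seq_a: str, seq_b: str):
    """Per-character K2P: returns (d, P, Q, n) with d=nan when undefined."""
    purines = {"A", "G"}
    n = ts = tv = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x in "ACGT" and y in "ACGT":
            n += 1
            if x != y:
                if (x in purines) == (y in purines):
                    ts += 1
                else:
                    tv += 1
    if n == 0:
        return math.nan, math.nan, math.nan, 0
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    d = (
        -0.5 * math.log(w1) - 0.25 * math.log(w2)
        if w1 > 0 and w2 > 0
        else math.nan
    )
    return d, P, Q, n


def oracle_parsimony_informative(aln: LocusAlignment) -> int:
    seqs = list(aln.sequences.values())
    count = 0
    for col in range(aln.aligned_length):
        tally = {}
        for s in seqs:
            c = s[col]
            if c in "ACGT":
                tally[c] = tally.get(c, 0) + 1
        if len([1 for v in tally.values() if v >= 2]) >= 2:
            count += 1
    return count


def oracle_indel_events(aln: LocusAlignment) -> int:
    events = set()
    for s in aln.sequences.values():
        i = 0
        while i < len(s):
            if s[i] == "-":
                j = i
                while j < len(s) and s[j] == "-":
                    j += 1
                events.add((i, j))
                i = j
            else:
                i += 1
    return len(events)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140821)
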