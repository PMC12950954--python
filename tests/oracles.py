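"""Independent reference implementations used only to cross-check results.

These deliberately avoid the code paths they verify: the Tanimoto oracle is
a per-bit Python loop, and the common-substructure oracle enumerates all
connected induced subgraphs of one molecule (Wernicke-style ESU enumeration)
and tests each for an induced, label-preserving embedding in the other via
networkx subgraph isomorphism.
"""

from __future__ import annotations

import networkx as nx
from networkx.algorithms import isomorphism


def tanimoto_bit_loop(bits_a, bits_b) -> float:
    a = b = c = 0
    for x, y in zip(bits_a, bits_b):
        if x:
            a += 1
        if y:
            b += 1
        if x and y:
            c += 1
    if a + b == 0:
        return 0.0
    return c / (a + b - c)


def molecule_to_nx(mol) -> nx.Graph:
    g = nx.Graph()
    for idx, (symbol, _charge, aromatic) in enumerate(mol.atoms):
        g.add_node(idx, element=symbol, aromatic=aromatic)
    for i, j, order in mol.bonds:
        g.add_edge(i, j, order=order)
    return g


def connected_subsets(g: nx.Graph):
    """Every connected node subset of ``g``, each exactly once (ESU)."""
    results = []

    def extend(sub: set, ext: set, root: int):
        results.append(frozenset(sub))
        ext = set(ext)
        while ext:
            w = min(ext)
            ext.remove(w)
            exclusive = {
                u
                for u in g[w]
                if u > root and u not in sub and all(u not in g[s] for s in sub)
            }
            extend(sub | {w}, ext | exclusive, root)

    for v in sorted(g.nodes):
        extend({v}, {u for u in g[v] if u > v}, v)
    return results


def _node_match(a, b):
    return a["element"] == b["element"] and a["aromatic"] == b["aromatic"]


def _edge_match(a, b):
    return a["order"] == b["order"]


def mcs_size_oracle(mol_a, mol_b) -> int:
    """Size (atom count) of the maximum connected common induced subgraph."""
    ga, gb = molecule_to_nx(mol_a), molecule_to_nx(mol_b)
    small, big = (ga, gb) if len(ga) <= len(gb) else (gb, ga)
    best = 0
    for subset in sorted(connected_subsets(small), key=len, reverse=True):
        if len(subset) <= best:
            break
        matcher = isomorphism.GraphMatcher(
            big, small.subgraph(subset), node_match=_node_match, edge_match=_edge_match
        )
        if matcher.subgraph_is_isomorphic():
            best = len(subset)
    return best
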