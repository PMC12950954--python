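"""Exact maximum common substructure between two molecules.

The method is the classical reduction of the maximum common *induced*
subgraph problem to maximum clique on the modular (compatibility) product
graph: a product vertex pairs an atom of A with a compatible atom of B, and
two product vertices are adjacent when the underlying atom pairs agree on
their bond relation (both bonded with a matching bond type, or both
non-bonded).  A clique then encodes an injective atom mapping that preserves
bonds and non-bonds, and a maximum clique is a maximum common induced
subgraph.

The default, chemistry-appropriate variant restricts the answer to mappings
whose common subgraph is *connected*; that is enforced during the search by
only growing a clique through product vertices linked to it by a
bonded-bonded ("c") edge, in the manner of Koch's connected-clique
enumeration.  The search is a deterministic branch-and-bound over vertices in
canonical order, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .chemstruct import ChemError, Molecule


class SizeLimitError(ChemError):
    """Product graph too large for exact search; pre-filter the fragments."""


@dataclass(frozen=True)
class MatchRules:
    """Atom/bond compatibility rules.

    Atoms match on element identity, plus aromaticity when
    ``match_aromaticity`` (default), plus formal charge when ``match_charge``
    (off by default so a zwitterionic aromatic N can match a neutral one).
    Bonds match on exact order with aromatic matching aromatic, unless
    ``any_bond_order`` relaxes that to any-bonded-matches-any-bonded.
    """

    match_aromaticity: bool = True
    match_charge: bool = False
    any_bond_order: bool = False


@dataclass
class CompatibilityGraph:
    """Modular product of two molecular graphs.

    ``vertices[v] = (i, j)`` pairs atom ``i`` of A with atom ``j`` of B.
    ``adj`` holds all compatibility edges; ``c_adj`` the subset whose atom
    pairs are bonded in both molecules (the edges along which a connected
    common subgraph can grow).
    """

    vertices: list
    adj: list
    c_adj: list

    @property
    def n(self) -> int:
        return len(self.vertices)


def _bond_orders(mol: Molecule) -> dict:
    orders = {}
    for i, j, order in mol.bonds:
        orders[(i, j)] = order
        orders[(j, i)] = order
    return orders


def _atoms_match(mol_a: Molecule, i: int, mol_b: Molecule, j: int, rules: MatchRules) -> bool:
    ea, ca, ara = mol_a.atoms[i]
    eb, cb, arb = mol_b.atoms[j]
    if ea != eb:
        return False
    if rules.match_aromaticity and ara != arb:
        return False
    if rules.match_charge and ca != cb:
        return False
    return True


def build_modular_product(
    mol_a: Molecule, mol_b: Molecule, rules: MatchRules = MatchRules()
) -> CompatibilityGraph:
    """Construct the compatibility (modular product) graph of two molecules."""
    bonds_a = _bond_orders(mol_a)
    bonds_b = _bond_orders(mol_b)
    vertices = [
        (i, j)
        for i in range(mol_a.n_atoms)
        for j in range(mol_b.n_atoms)
        if _atoms_match(mol_a, i, mol_b, j, rules)
    ]
    n = len(vertices)
    adj = [set() for _ in range(n)]
    c_adj = [set() for _ in range(n)]
    for u in range(n):
        i, j = vertices[u]
        for v in range(u + 1, n):
            k, l = vertices[v]
            if i == k or j == l:
                continue  # keeps any clique injective on both sides
            oa = bonds_a.get((i, k))
            ob = bonds_b.get((j, l))
            if oa is None and ob is None:
                adj[u].add(v)
                adj[v].add(u)
            elif oa is not None and ob is not None:
                if rules.any_bond_order or oa == ob:
                    adj[u].add(v)
                    adj[v].add(u)
                    c_adj[u].add(v)
                    c_adj[v].add(u)
    return CompatibilityGraph(vertices=vertices, adj=adj, c_adj=c_adj)


def find_max_clique(
    g: CompatibilityGraph,
    connected_constraint: bool = True,
    max_cliques: int = 256,
    max_vertices: int = 4000,
) -> list[tuple[int, ...]]:
    """All maximum cliques of the compatibility graph, up to ``max_cliques``.

    With ``connected_constraint`` the clique must stay connected through
    bonded-bonded edges, so the induced common subgraph is a single fragment.
    Returns sorted vertex tuples in lexicographic order; deterministic.
    """
    if g.n > max_vertices:
        raise SizeLimitError(
            f"compatibility graph has {g.n} vertices (limit {max_vertices}); "
            "pre-filter the fragments or raise max_vertices"
        )
    if g.n == 0:
        return []

    best_size = 0
    results: set = set()

    def record(clique: list):
        nonlocal best_size
        size = len(clique)
        if size > best_size:
            best_size = size
            results.clear()
        if size == best_size and len(results) < max_cliques:
            results.add(tuple(sorted(clique)))

    if not connected_constraint:
        def expand(clique: list, cand: set):
            nonlocal best_size
            if not cand:
                record(clique)
                return
            cand = set(cand)
            while cand:
                if len(clique) + len(cand) < best_size:
                    return
                v = min(cand)
                cand.remove(v)
                expand(clique + [v], cand & g.adj[v])

        expand([], set(range(g.n)))
    else:
        def expand(clique: list, conn: set, disc: set):
            # conn: candidates adjacent to the whole clique and reachable by a
            # c-edge; disc: adjacent but not yet c-connected.
            nonlocal best_size
            if not conn:
                record(clique)
                return
            conn = set(conn)
            disc = set(disc)
            while conn:
                if len(clique) + len(conn) + len(disc) < best_size:
                    return
                v = min(conn)
                conn.remove(v)
                new_conn = (conn & g.adj[v]) | (disc & g.c_adj[v])
                new_disc = (disc & g.adj[v]) - g.c_adj[v]
                expand(clique + [v], new_conn, new_disc)

        seen: set = set()
        for seed in range(g.n):
            record([seed])
            expand([seed], (g.c_adj[seed] - seen), (g.adj[seed] - g.c_adj[seed]) - seen)
            seen.add(seed)

    return sorted(results)


@dataclass(frozen=True)
class MCSResult:
    """Maximum common substructure evidence between two molecules."""

    mapping: tuple          # ((atom index in A, atom index in B), ...)
    n_atoms: int
    n_bonds: int
    pattern: str            # SMARTS of the common substructure ("" if empty)
    connected: bool

    def atoms_a(self) -> tuple:
        return tuple(i for i, _ in self.mapping)

    def atoms_b(self) -> tuple:
        return tuple(j for _, j in self.mapping)


_SMARTS_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    "ar": Chem.BondType.AROMATIC,
}


def _pattern_smarts(mol_a: Molecule, atom_idx: list, rules: MatchRules) -> str:
    """SMARTS for the subgraph of A induced on ``atom_idx``.

    Atoms are emitted as bare atomic numbers (charge-free unless charges are
    part of the match rules) so the pattern hits both parents; bond symbols
    carry the order/aromaticity constraint.
    """
    emol = Chem.RWMol()
    pos = {}
    for i in atom_idx:
        symbol, charge, _arom = mol_a.atoms[i]
        atom = Chem.Atom(symbol)
        atom.SetNoImplicit(True)
        if rules.match_charge:
            atom.SetFormalCharge(charge)
        pos[i] = emol.AddAtom(atom)
    in_set = set(atom_idx)
    for i, j, order in mol_a.bonds:
        if i in in_set and j in in_set:
            bt = Chem.BondType.UNSPECIFIED if rules.any_bond_order else _SMARTS_BOND[order]
            emol.AddBond(pos[i], pos[j], bt)
    return Chem.MolToSmarts(emol)


def _subgraph_connected(mol: Molecule, atom_idx: tuple) -> bool:
    if not atom_idx:
        return True
    in_set = set(atom_idx)
    neigh = {i: set() for i in atom_idx}
    for i, j, _ in mol.bonds:
        if i in in_set and j in in_set:
            neigh[i].add(j)
            neigh[j].add(i)
    stack = [atom_idx[0]]
    seen = {atom_idx[0]}
    while stack:
        for nb in neigh[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(in_set)


def compute_mcs(
    mol_a: Molecule,
    mol_b: Molecule,
    rules: MatchRules = MatchRules(),
    connected: bool = True,
    max_vertices: int = 4000,
) -> MCSResult:
    """Exact maximum common (induced) substructure of two molecules.

    Maximises the number of mapped atoms; ties are broken by larger bond
    count, then by the lexicographically smallest mapping.  The returned
    SMARTS pattern is verified to substructure-match both parents.
    """
    g = build_modular_product(mol_a, mol_b, rules)
    cliques = find_max_clique(g, connected_constraint=connected, max_vertices=max_vertices)
    if not cliques:
        return MCSResult(mapping=(), n_atoms=0, n_bonds=0, pattern="", connected=connected)

    bonds_a = _bond_orders(mol_a)
    best = None
    for clique in cliques:
        mapping = tuple(sorted(g.vertices[v] for v in clique))
        atom_idx = [i for i, _ in mapping]
        n_bonds = sum(
            1
            for x in range(len(atom_idx))
            for y in range(x + 1, len(atom_idx))
            if (atom_idx[x], atom_idx[y]) in bonds_a
        )
        key = (-n_bonds, mapping)
        if best is None or key < best[0]:
            best = (key, mapping, n_bonds)

    _key, mapping, n_bonds = best
    atom_idx = [i for i, _ in mapping]
    smarts = _pattern_smarts(mol_a, atom_idx, rules)
    _verify_pattern(smarts, mol_a, mol_b)
    return MCSResult(
        mapping=mapping,
        n_atoms=len(mapping),
        n_bonds=n_bonds,
        pattern=smarts,
        connected=_subgraph_connected(mol_a, tuple(atom_idx)),
    )


def _verify_pattern(smarts: str, mol_a: Molecule, mol_b: Molecule) -> None:
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise RuntimeError(f"internal error: generated invalid SMARTS {smarts!r}")
    for mol in (mol_a, mol_b):
        if not mol.rdmol.HasSubstructMatch(query):
            raise RuntimeError(
                f"internal error: MCS pattern {smarts!r} does not match {mol.id!r}"
            )
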