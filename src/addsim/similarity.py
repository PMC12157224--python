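"""Structural similarity: atom-pair fingerprints, flexible maximum common
substructure, and the overlap / Tanimoto coefficients derived from them.

Two complementary views of similarity are provided:

* **Atom pairs** — every unordered pair of heavy atoms in the same
  component, typed by (element, heavy-neighbor count, π-electron count)
  and annotated with the shortest bond-path length.  The fingerprint is
  the multiset of such pairs; the Tanimoto coefficient is the min-count
  overlap divided by the union size.

* **Maximum common substructure (MCS)** — the largest connected subgraph
  shared by two heavy-atom graphs under element and bond-order-class
  matching, found by branch-and-bound backtracking.  From the MCS size c
  and the heavy-atom counts a, b, the overlap coefficient is
  OC = c / min(a, b) and the Tanimoto coefficient TC = c / (a + b − c).
  "Flexible" matching admits bounded numbers of atom- and bond-label
  mismatches.
"""

from __future__ import annotations

import time
import warnings
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .molgraph import Molecule

__all__ = [
    "AtomPairType",
    "AtomPairSet",
    "MCSResult",
    "SimilarityMatrix",
    "atom_pair_set",
    "tanimoto_ap",
    "ap_matrix",
    "mcs",
    "oc",
    "tc_mcs",
    "mcs_matrix",
]


# ---------------------------------------------------------------------------
# Atom pairs (Eq-1 similarity)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomPairType:
    element: str
    heavy_degree: int
    pi_electrons: int


@dataclass
class AtomPairSet:
    """Multiset of typed atom pairs with shortest-path distances.

    Every unordered heavy-atom pair within a connected component
    contributes one entry (endpoints canonically ordered); multiplicities
    are retained — two fingerprints overlap by the minimum of their
    per-pair counts.
    """
    pairs: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return sum(self.pairs.values())


def _atom_pair_types(mol: Molecule) -> dict[int, AtomPairType]:
    types: dict[int, AtomPairType] = {}
    adj = mol.adjacency()
    for a in mol.heavy_atoms:
        heavy_deg = sum(1 for b in adj[a.index]
                        if mol.atoms[b.other(a.index)].element != "H")
        if a.aromatic:
            pi = 1
        else:
            pi = 0
            for b in adj[a.index]:
                if b.order == "double":
                    pi += 1
                elif b.order == "triple":
                    pi += 2
        types[a.index] = AtomPairType(a.element, heavy_deg, min(pi, 2))
    return types


def atom_pair_set(mol: Molecule) -> AtomPairSet:
    """Atom-pair fingerprint of the heavy-atom graph.

    Pairs spanning disconnected components are omitted (no finite bond
    path).  A single-heavy-atom molecule has an empty fingerprint.
    """
    types = _atom_pair_types(mol)
    g = mol.to_networkx(heavy_only=True)
    key = {i: (t.element, t.heavy_degree, t.pi_electrons)
           for i, t in types.items()}
    pairs: Counter = Counter()
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        for src in nodes:
            dist = _bfs_dist(g, src)
            for dst in nodes:
                if dst <= src:
                    continue
                ta, tb = sorted((key[src], key[dst]))
                pairs[(ta, tb, dist[dst])] += 1
    return AtomPairSet(pairs)


def _bfs_dist(g: nx.Graph, src: int) -> dict[int, int]:
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def tanimoto_ap(a: AtomPairSet, b: AtomPairSet) -> float:
    """Tanimoto similarity |A∩B| / (|A| + |B| − |A∩B|) on pair multisets."""
    na, nb = len(a), len(b)
    if na == 0 and nb == 0:
        warnings.warn("both fingerprints empty; similarity defined as 0",
                      stacklevel=2)
        return 0.0
    inter = sum(min(cnt, b.pairs[key]) for key, cnt in a.pairs.items())
    return inter / (na + nb - inter)


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    ids: list
    values: np.ndarray          # symmetric, unit diagonal
    cutoff: float | None = None

    def masked(self) -> np.ndarray:
        """Values with sub-cutoff cells replaced by NaN (no-op without cutoff)."""
        if self.cutoff is None:
            return self.values.copy()
        out = self.values.copy()
        out[out < self.cutoff] = np.nan
        return out

    def validate(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or len(self.ids) != v.shape[0]:
            raise ValueError("shape mismatch between ids and matrix")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")


def ap_matrix(mols: list[Molecule], cutoff: float | None = 0.30) -> SimilarityMatrix:
    """Pairwise atom-pair Tanimoto matrix; unit diagonal, symmetric.

    ``cutoff`` only affects masked reporting, not the stored values.
    """
    if not mols:
        raise ValueError("need at least one molecule")
    fps = [atom_pair_set(m) for m in mols]
    n = len(mols)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = tanimoto_ap(fps[i], fps[j])
    ids = [m.cid if m.cid is not None else i for i, m in enumerate(mols)]
    return SimilarityMatrix(ids=ids, values=v, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Maximum common substructure
# ---------------------------------------------------------------------------

@dataclass
class MCSResult:
    c: int
    mapping: list[tuple[int, int]]
    a: int
    b: int
    oc: float
    tc: float
    exhausted: bool


def oc(r: MCSResult) -> float:
    """Overlap coefficient c / min(a, b)."""
    if min(r.a, r.b) == 0:
        raise ValueError("overlap coefficient undefined for empty molecule")
    return r.c / min(r.a, r.b)


def tc_mcs(r: MCSResult) -> float:
    """MCS-based Tanimoto coefficient c / (a + b − c)."""
    if r.a + r.b - r.c == 0:
        raise ValueError("Tanimoto undefined: both molecules empty")
    return r.c / (r.a + r.b - r.c)


class _HeavyGraph:
    """Flat adjacency view of a molecule's heavy atoms for the search."""

    __slots__ = ("n", "elem", "adj", "bond", "orig")

    def __init__(self, mol: Molecule):
        heavy = [a.index for a in mol.heavy_atoms]
        remap = {idx: i for i, idx in enumerate(heavy)}
        self.n = len(heavy)
        self.elem = [mol.atoms[idx].element for idx in heavy]
        self.adj: list[list[int]] = [[] for _ in range(self.n)]
        self.bond: dict[tuple[int, int], str] = {}
        for b in mol.bonds:
            if b.a in remap and b.b in remap:
                i, j = remap[b.a], remap[b.b]
                self.adj[i].append(j)
                self.adj[j].append(i)
                self.bond[(i, j)] = self.bond[(j, i)] = b.order
        self.orig = heavy  # search index -> original atom index


def mcs(mol_a: Molecule, mol_b: Molecule, atom_mismatches: int = 0,
        bond_mismatches: int = 0, timeout: float = 60.0) -> MCSResult:
    """Largest connected common substructure of two heavy-atom graphs.

    Branch-and-bound backtracking over compatible atom-pair extensions.
    Matching is induced: two matched atoms are bonded in one molecule iff
    their images are bonded in the other (rings never open into chains).
    Atoms match by element (up to ``atom_mismatches`` exceptions) and
    bonds by order class with aromatic as its own class (up to
    ``bond_mismatches`` class exceptions).  The search is order-symmetric
    and deterministic; on timeout the best result found so far is
    returned with ``exhausted=False``.
    """
    ga, gb = _HeavyGraph(mol_a), _HeavyGraph(mol_b)
    swapped = ga.n > gb.n
    if swapped:
        ga, gb = gb, ga
    a_n, b_n = ga.n, gb.n
    if a_n == 0 or b_n == 0:
        return MCSResult(0, [], mol_a.num_heavy, mol_b.num_heavy,
                         0.0, 0.0, True)

    deadline = time.monotonic() + timeout
    best: dict = {"size": 0, "map": {}}
    au_total, bu_total = atom_mismatches, bond_mismatches

    # rarity-first seed order: rare elements anchor the search cheaply
    b_elem_count = Counter(gb.elem)
    seed_order = sorted(range(a_n),
                        key=lambda i: (b_elem_count[ga.elem[i]],
                                       -len(ga.adj[i]), i))
    seed_rank = {v: r for r, v in enumerate(seed_order)}

    def element_bound(mapping: dict[int, int], used_b: set[int],
                      excluded: set[int], au_left: int) -> int:
        rem_a: Counter = Counter()
        for i in range(a_n):
            if i not in mapping and i not in excluded:
                rem_a[ga.elem[i]] += 1
        rem_b: Counter = Counter()
        for j in range(b_n):
            if j not in used_b:
                rem_b[gb.elem[j]] += 1
        exact = sum(min(rem_a[e], rem_b[e]) for e in rem_a)
        loose = min(sum(rem_a.values()), sum(rem_b.values()))
        return min(loose, exact + au_left)

    def extend(mapping: dict[int, int], used_b: set[int],
               excluded: set[int], au_left: int, bu_left: int) -> bool:
        """Depth-first extension; returns False when out of time."""
        if len(mapping) > best["size"]:
            best["size"] = len(mapping)
            best["map"] = dict(mapping)
        if best["size"] >= min(a_n, b_n):
            return True
        if time.monotonic() > deadline:
            return False
        if len(mapping) + element_bound(mapping, used_b,
                                        excluded, au_left) <= best["size"]:
            return True
        # frontier: unmapped, non-excluded atoms adjacent to the mapping
        frontier = sorted({
            nb for i in mapping for nb in ga.adj[i]
            if nb not in mapping and nb not in excluded})
        if not frontier:
            return True
        pivot = frontier[0]
        # candidate images: bond pattern to the mapped set must agree
        # (induced matching), with ≥1 bond linking into the mapping
        candidates: list[tuple[int, int, int]] = []
        for j in range(b_n):
            if j in used_b:
                continue
            elem_cost = 0 if gb.elem[j] == ga.elem[pivot] else 1
            if elem_cost > au_left:
                continue
            bond_cost = 0
            connected = compatible = False
            for i, jj in mapping.items():
                ea = ga.bond.get((i, pivot))
                eb = gb.bond.get((jj, j))
                if (ea is None) != (eb is None):
                    break
                if ea is not None:
                    connected = True
                    if ea != eb:
                        bond_cost += 1
            else:
                compatible = True
            if not compatible or not connected or bond_cost > bu_left:
                continue
            candidates.append((j, elem_cost, bond_cost))
        candidates.sort(key=lambda t: (t[1] + t[2], -len(gb.adj[t[0]]), t[0]))
        for j, e_cost, b_cost in candidates:
            mapping[pivot] = j
            used_b.add(j)
            ok = extend(mapping, used_b, excluded,
                        au_left - e_cost, bu_left - b_cost)
            del mapping[pivot]
            used_b.remove(j)
            if not ok:
                return False
        # branch: pivot not in the common subgraph
        excluded.add(pivot)
        ok = extend(mapping, used_b, excluded, au_left, bu_left)
        excluded.remove(pivot)
        return ok

    exhausted = True
    for a0 in seed_order:
        if best["size"] >= min(a_n, b_n) or not exhausted:
            break
        excluded = {v for v in range(a_n) if seed_rank[v] < seed_rank[a0]}
        b_seeds = sorted(
            (j for j in range(b_n)
             if gb.elem[j] == ga.elem[a0] or au_total >= 1),
            key=lambda j: (0 if gb.elem[j] == ga.elem[a0] else 1,
                           -len(gb.adj[j]), j))
        for j in b_seeds:
            e_cost = 0 if gb.elem[j] == ga.elem[a0] else 1
            if not extend({a0: j}, {j}, excluded, au_total - e_cost, bu_total):
                exhausted = False
                break

    mapping = best["map"]
    # translate back to original atom indices (respecting the swap)
    pairs = [(ga.orig[i], gb.orig[j]) for i, j in sorted(mapping.items())]
    if swapped:
        pairs = [(p, q) for q, p in pairs]
    a_count, b_count = mol_a.num_heavy, mol_b.num_heavy
    c = best["size"]
    denom_oc = min(a_count, b_count)
    denom_tc = a_count + b_count - c
    return MCSResult(
        c=c, mapping=pairs, a=a_count, b=b_count,
        oc=c / denom_oc if denom_oc else 0.0,
        tc=c / denom_tc if denom_tc else 0.0,
        exhausted=exhausted,
    )


def mcs_matrix(mols: list[Molecule], atom_mismatches: int = 0,
               bond_mismatches: int = 0, timeout: float = 60.0,
               cutoff: float | None = None,
               ) -> tuple[SimilarityMatrix, SimilarityMatrix, np.ndarray]:
    """All-pairs MCS overlap and Tanimoto matrices.

    Each unordered pair is computed once; per-pair timeouts are collected
    in the returned boolean ``exhausted`` matrix and never abort the batch.
    """
    if len(mols) < 2:
        raise ValueError("need at least two molecules")
    n = len(mols)
    oc_v = np.eye(n)
    tc_v = np.eye(n)
    done = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            r = mcs(mols[i], mols[j], atom_mismatches, bond_mismatches,
                    timeout)
            oc_v[i, j] = oc_v[j, i] = r.oc
            tc_v[i, j] = tc_v[j, i] = r.tc
            done[i, j] = done[j, i] = r.exhausted
    ids = [m.cid if m.cid is not None else i for i, m in enumerate(mols)]
    return (SimilarityMatrix(ids, oc_v, cutoff),
            SimilarityMatrix(ids, tc_v, cutoff), done)
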