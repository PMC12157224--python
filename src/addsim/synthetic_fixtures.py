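"""Study-compound fixtures, random generators with known ground truth, and
brute-force oracles.

The 24 study additives are shipped as a SMILES table with provenance
flags: ``from_printed_name`` structures were encoded once from the
chemical names in the source listing and verified against the printed
molecular formulas; two records (CIDs 24667 and 4992761) carry printed
names inconsistent with their printed formulas and are marked
``requires_lookup`` — their shipped structures are synthetic
reconstructions chosen to satisfy every printed structural datum.

The random generators (molecules, planted-core pairs, Gaussian feature
matrices) are pure functions of their integer seed, driven by NumPy's
PCG64 generator, so "seeded determinism" is a portable, testable
contract.  The exhaustive MCS oracle enumerates connected subgraphs of
the smaller molecule (Wernicke's ESU scheme) and tests induced
subgraph isomorphism against the larger — exponential, but exact, and
entirely independent of the branch-and-bound search it validates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import isomorphism as iso

from .molgraph import Atom, Bond, Molecule, parse_smiles

__all__ = [
    "FixtureCompound",
    "PlantedPair",
    "study_fixtures",
    "study_molecules",
    "random_molecule",
    "planted_mcs_pair",
    "gaussian_feature_matrix",
    "oracle_mcs",
]

ORACLE_SIZE_LIMIT = 12


@dataclass
class FixtureCompound:
    cid: int
    name: str
    smiles: str
    provenance: str  # from_printed_name | requires_lookup

    def molecule(self) -> Molecule:
        return parse_smiles(self.smiles, cid=self.cid, name=self.name)


@dataclass
class PlantedPair:
    mol_a: Molecule
    mol_b: Molecule
    core_size: int


def study_fixtures() -> list[FixtureCompound]:
    """The 24 packaged study compounds, in reference-table order."""
    with resources.files("addsim.data").joinpath("study_compounds.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [FixtureCompound(int(r.cid), r.name, r.smiles, r.provenance)
            for r in df.itertuples()]


def study_molecules() -> dict[int, Molecule]:
    """Parsed study compounds keyed by CID."""
    return {f.cid: f.molecule() for f in study_fixtures()}


# ---------------------------------------------------------------------------
# Random molecule generator
# ---------------------------------------------------------------------------

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}

DEFAULT_HETERO_PROBS = {"C": 0.70, "O": 0.14, "N": 0.10, "S": 0.04,
                        "Cl": 0.02}


def random_molecule(seed: int, n_heavy: int, ring_prob: float = 0.2,
                    hetero_probs: dict[str, float] | None = None,
                    double_prob: float = 0.15) -> Molecule:
    """Random valence-correct connected molecule.

    A random tree is grown atom by atom (each new atom bonds to a
    uniformly chosen existing atom with free valence), then ring-closing
    single bonds are added with probability ``ring_prob`` per candidate
    pass.  Elements are drawn from ``hetero_probs``; a bond becomes a
    double bond with probability ``double_prob`` when both endpoints can
    support it.  Deterministic in ``seed``.
    """
    if n_heavy < 1:
        raise ValueError("n_heavy must be at least 1")
    probs = dict(hetero_probs or DEFAULT_HETERO_PROBS)
    for el in probs:
        if el not in _VALENCE:
            raise ValueError(f"unsupported element {el!r}")
    rng = np.random.default_rng(seed)
    elements = sorted(probs)
    weights = np.array([probs[e] for e in elements], dtype=float)
    weights /= weights.sum()

    mol = Molecule()
    free: list[int] = []

    def draw_element(require_capacity: int = 1) -> str:
        while True:
            el = str(rng.choice(elements, p=weights))
            if _VALENCE[el] >= require_capacity:
                return el

    first = draw_element(2 if n_heavy > 1 else 1)
    mol.atoms.append(Atom(index=0, element=first))
    free.append(_VALENCE[first])
    for i in range(1, n_heavy):
        hosts = [j for j in range(i) if free[j] >= 1]
        if not hosts:
            raise ValueError("infeasible valence request: no open attachment")
        host = int(rng.choice(hosts))
        remaining = n_heavy - 1 - i
        for _ in range(50):  # redraw until open valence survives
            el = draw_element()
            order = "single"
            if (rng.random() < double_prob and free[host] >= 2
                    and _VALENCE[el] >= 2):
                order = "double"
            cost = 2 if order == "double" else 1
            total_after = (sum(free) - cost) + (_VALENCE[el] - cost)
            if remaining == 0 or total_after >= 1:
                break
        else:
            el, order, cost = "C", "single", 1
        mol.atoms.append(Atom(index=i, element=el))
        mol.bonds.append(Bond(host, i, order))
        free[host] -= cost
        free.append(_VALENCE[el] - cost)
    # ring closures between non-adjacent open atoms
    existing = {(min(b.a, b.b), max(b.a, b.b)) for b in mol.bonds}
    open_atoms = [i for i in range(n_heavy) if free[i] >= 1]
    rng.shuffle(open_atoms)
    for u in open_atoms:
        if free[u] < 1 or rng.random() >= ring_prob:
            continue
        partners = [v for v in open_atoms
                    if v != u and free[v] >= 1
                    and (min(u, v), max(u, v)) not in existing]
        if not partners:
            continue
        v = int(rng.choice(partners))
        mol.bonds.append(Bond(u, v, "single"))
        existing.add((min(u, v), max(u, v)))
        free[u] -= 1
        free[v] -= 1
    for i, a in enumerate(mol.atoms):
        a.implicit_h = free[i]
    return mol


# ---------------------------------------------------------------------------
# Planted-core MCS pairs
# ---------------------------------------------------------------------------

def planted_mcs_pair(seed: int, core_size: int, decorations_a: int = 3,
                     decorations_b: int = 3,
                     decoration_elements: tuple[str, str] = ("F", "Br"),
                     ) -> PlantedPair:
    """Two molecules sharing a planted carbon core of known size.

    The core is a random all-carbon single-bonded graph; copy A is
    decorated with ``decorations_a`` atoms of the first decoration
    element, copy B with the second.  Because the decoration elements do
    not occur in the core, the planted core is the unique maximal common
    substructure: mcs(A, B).c == core_size.
    """
    if core_size < 2:
        raise ValueError("core_size must be at least 2")
    el_a, el_b = decoration_elements
    if "C" in decoration_elements or el_a == el_b:
        raise ValueError("decoration elements must be distinct non-core "
                         "elements")
    core = random_molecule(seed, core_size, ring_prob=0.3,
                           hetero_probs={"C": 1.0}, double_prob=0.0)
    rng = np.random.default_rng(seed + 1)

    def decorate(n_dec: int, element: str, offset: int) -> Molecule:
        mol = Molecule(
            atoms=[Atom(a.index, a.element, a.formal_charge, a.implicit_h,
                        a.aromatic) for a in core.atoms],
            bonds=[Bond(b.a, b.b, b.order) for b in core.bonds])
        local = np.random.default_rng(seed + offset)
        placed = 0
        for _ in range(10 * n_dec):
            if placed == n_dec:
                break
            host = int(local.integers(0, core_size))
            if mol.atoms[host].implicit_h < 1:
                continue
            idx = len(mol.atoms)
            mol.atoms.append(Atom(index=idx, element=element, implicit_h=0))
            mol.bonds.append(Bond(host, idx, "single"))
            mol.atoms[host].implicit_h -= 1
            placed += 1
        return mol

    del rng
    return PlantedPair(decorate(decorations_a, el_a, 101),
                       decorate(decorations_b, el_b, 202), core_size)


# ---------------------------------------------------------------------------
# Gaussian cluster generator
# ---------------------------------------------------------------------------

def gaussian_feature_matrix(seed: int, k: int, n_per_cluster: int, dim: int,
                            separation: float, sd: float,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian clusters with centers at mutual distance
    ``separation``.

    Centers sit on a scaled coordinate simplex (requires dim ≥ k), noise
    is N(0, sd²) per coordinate.  Returns (X, true_labels), deterministic
    in ``seed``.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if dim < k:
        raise ValueError("need dim >= k to place equidistant centers")
    rng = np.random.default_rng(seed)
    centers = np.zeros((k, dim))
    for i in range(k):
        centers[i, i] = separation / np.sqrt(2)
    n = k * n_per_cluster
    labels = np.repeat(np.arange(k), n_per_cluster)
    X = centers[labels] + rng.normal(0.0, sd, size=(n, dim))
    return X, labels


# ---------------------------------------------------------------------------
# Exhaustive MCS oracle
# ---------------------------------------------------------------------------

def _connected_subsets(g: nx.Graph) -> list[frozenset]:
    """All connected node subsets, each exactly once (ESU enumeration)."""
    out: list[frozenset] = []
    nodes = sorted(g)

    def extend(sub: set, ext: list, root) -> None:
        out.append(frozenset(sub))
        ext = list(ext)
        while ext:
            w = ext.pop()
            neigh_sub = {u for v in sub for u in g.neighbors(v)}
            new_ext = [u for u in ext] + [
                u for u in g.neighbors(w)
                if u > root and u not in sub and u not in neigh_sub]
            extend(sub | {w}, new_ext, root)

    for v in nodes:
        extend({v}, [u for u in g.neighbors(v) if u > v], v)
    return out


def oracle_mcs(mol_a: Molecule, mol_b: Molecule) -> int:
    """Exact maximum connected common (induced) substructure size.

    Enumerates every connected heavy-atom subset of the smaller molecule
    in decreasing size and tests induced subgraph isomorphism into the
    larger (element and bond-order-class matching).  Exponential; inputs
    are limited to 12 heavy atoms each.
    """
    ga = mol_a.to_networkx(heavy_only=True)
    gb = mol_b.to_networkx(heavy_only=True)
    if ga.number_of_nodes() > ORACLE_SIZE_LIMIT or \
            gb.number_of_nodes() > ORACLE_SIZE_LIMIT:
        raise ValueError(f"size bound exceeded ({ORACLE_SIZE_LIMIT} heavy atoms)")
    if ga.number_of_nodes() > gb.number_of_nodes():
        ga, gb = gb, ga
    if ga.number_of_nodes() == 0:
        return 0
    big_elements = Counter(d["element"] for _, d in gb.nodes(data=True))
    node_match = iso.categorical_node_match("element", None)
    edge_match = iso.categorical_edge_match("order", None)
    subsets = sorted(_connected_subsets(ga), key=len, reverse=True)
    for sub in subsets:
        small_elements = Counter(ga.nodes[v]["element"] for v in sub)
        if any(small_elements[e] > big_elements.get(e, 0)
               for e in small_elements):
            continue
        h = ga.subgraph(sub)
        gm = iso.GraphMatcher(gb, h, node_match=node_match,
                              edge_match=edge_match)
        if gm.subgraph_is_isomorphic():
            return len(sub)
    return 0
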