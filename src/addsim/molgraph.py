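"""Molecular graphs: data model, SMILES/SDF I/O and the structural census.

A :class:`Molecule` is an attributed graph — atoms carry element, formal
charge, implicit-hydrogen count and an aromatic flag; bonds carry one of
four order classes (single, double, triple, aromatic).  Molecules may be
disconnected (salts and co-crystals are one record with several
components).  The census operations compute the quantities a screening
table lists per compound: Hill formula, molecular weight, per-element atom
counts, functional-group counts over twelve classes, and ring counts
(total and aromatic).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import networkx as nx

from .elements import (
    AROMATIC_CAPABLE,
    ATOMIC_WEIGHTS,
    METALS,
    ORGANIC_SUBSET,
    charge_adjusted_valences,
)

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "StructuralCensus",
    "ParseError",
    "parse_smiles",
    "parse_sdf",
    "write_sdf",
    "perceive_aromaticity",
    "perceive_rings",
    "molecular_formula",
    "molecular_weight",
    "atom_counts",
    "detect_functional_groups",
    "structural_census",
    "GROUP_CLASSES",
]

BOND_ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

GROUP_CLASSES = (
    "R3N", "RNH2", "R2NH", "ROH", "RCOR", "RCHO",
    "RCOOH", "RCOOR", "ROR", "ROPO3", "RCCH", "RCN",
)


class ParseError(ValueError):
    """Raised for malformed SMILES or SDF input."""


@dataclass
class Atom:
    index: int
    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    aromatic: bool = False


@dataclass
class Bond:
    a: int
    b: int
    order: str  # single | double | triple | aromatic

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    cid: int | None = None
    name: str | None = None
    coords: list[tuple[float, float, float]] | None = None

    # -- graph access -------------------------------------------------

    def adjacency(self) -> dict[int, list[Bond]]:
        adj: dict[int, list[Bond]] = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            adj[b.a].append(b)
            adj[b.b].append(b)
        return adj

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self.adjacency()[idx]]

    def to_networkx(self, heavy_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            if heavy_only and a.element == "H":
                continue
            g.add_node(a.index, element=a.element, charge=a.formal_charge,
                       aromatic=a.aromatic, implicit_h=a.implicit_h)
        for b in self.bonds:
            if b.a in g and b.b in g:
                g.add_edge(b.a, b.b, order=b.order)
        return g

    def components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.to_networkx())]

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    @property
    def num_heavy(self) -> int:
        return len(self.heavy_atoms)

    def total_h(self, idx: int) -> int:
        """Implicit plus explicit hydrogens on atom ``idx``."""
        a = self.atoms[idx]
        return a.implicit_h + sum(
            1 for n in self.neighbors(idx) if self.atoms[n].element == "H")

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.a == b.b:
                raise ValueError(f"self-bond on atom {b.a}")
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise ValueError(f"bond endpoint out of range: {b}")
            key = (min(b.a, b.b), max(b.a, b.b))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        adj = self.adjacency()
        for a in self.atoms:
            if a.element not in ATOMIC_WEIGHTS:
                raise ValueError(f"unsupported element {a.element!r}")
            if a.implicit_h < 0:
                raise ValueError(f"negative implicit H on atom {a.index}")
            if a.element in METALS:
                continue
            order_sum = _order_sum(a, adj[a.index])
            allowed = charge_adjusted_valences(a.element, a.formal_charge)
            total = order_sum + a.implicit_h
            if not a.aromatic and total not in allowed and total > max(allowed):
                raise ValueError(
                    f"valence violation on atom {a.index} ({a.element}): "
                    f"{total} not in {allowed}")


def _order_sum(atom: Atom, bonds: list[Bond]) -> float:
    """Explicit bond-order sum; aromatic systems count ring bonds as one
    each plus a single shared π contribution."""
    n_arom = sum(1 for b in bonds if b.order == "aromatic")
    other = sum(BOND_ORDER_VALUE[b.order] for b in bonds if b.order != "aromatic")
    if atom.aromatic or n_arom:
        return n_arom + 1 + other
    return other


def _assign_implicit_h(mol: Molecule, strict: bool = True) -> None:
    adj = mol.adjacency()
    for a in mol.atoms:
        if a.implicit_h:          # set explicitly (bracket atom / SDF H)
            continue
        if a.element in METALS or a.element == "H":
            a.implicit_h = 0
            continue
        order_sum = _order_sum(a, adj[a.index])
        need = math.ceil(order_sum - 1e-9)
        allowed = charge_adjusted_valences(a.element, a.formal_charge)
        for v in allowed:
            if v >= need:
                a.implicit_h = v - need
                break
        else:
            if a.aromatic:
                a.implicit_h = 0  # pyrrole-type: lone pair in the ring
            elif strict:
                raise ParseError(
                    f"valence violation: atom {a.index} ({a.element}"
                    f"{'+' if a.formal_charge > 0 else ''}"
                    f"{a.formal_charge or ''}) has bond order sum {order_sum}")
            else:
                a.implicit_h = 0


# ---------------------------------------------------------------------------
# SMILES
# ---------------------------------------------------------------------------

_BRACKET_RE = re.compile(
    r"^(?P<isotope>\d+)?(?P<symbol>[A-Z][a-z]?|[cnosp]|se|as)"
    r"(?P<stereo>@{1,2})?(?P<hcount>H\d*)?(?P<charge>\+{1,}|-{1,}|\+\d+|-\d+)?$"
)

_TWO_LETTER = ("Cl", "Br")


def parse_smiles(text: str, cid: int | None = None, name: str | None = None,
                 aromatize: bool = True) -> Molecule:
    """Parse a SMILES string into a valence-complete :class:`Molecule`.

    Supports the organic subset, bracket atoms with charge and explicit H
    count, branches, ring closures (including ``%nn``), aromatic lowercase
    forms, dot-separated components and the four bond symbols; stereo
    markers (``@``, ``/``, ``\\``) are accepted and discarded — the
    downstream census and similarity measures are stereo-blind.
    """
    text = text.strip()
    if not text:
        raise ParseError("empty SMILES")
    mol = Molecule(cid=cid, name=name)
    prev: list[int | None] = [None]   # branch stack of attachment atoms
    pending_bond: str | None = None
    ring_open: dict[str, tuple[int, str | None]] = {}
    i, n = 0, len(text)

    def add_atom(element: str, aromatic: bool, charge: int = 0,
                 hcount: int = 0) -> int:
        idx = len(mol.atoms)
        mol.atoms.append(Atom(index=idx, element=element, formal_charge=charge,
                              implicit_h=hcount, aromatic=aromatic))
        return idx

    def add_bond(a: int, b: int, order: str | None) -> None:
        if order is None:
            order = ("aromatic" if mol.atoms[a].aromatic and mol.atoms[b].aromatic
                     else "single")
        mol.bonds.append(Bond(a, b, order))

    def attach(idx: int) -> None:
        nonlocal pending_bond
        if prev[-1] is not None:
            add_bond(prev[-1], idx, pending_bond)
        pending_bond = None
        prev[-1] = idx

    while i < n:
        ch = text[i]
        if ch in "-=#:":
            pending_bond = {"-": "single", "=": "double",
                            "#": "triple", ":": "aromatic"}[ch]
            i += 1
        elif ch in "/\\":
            pending_bond = "single"  # cis/trans marker: bond is single
            i += 1
        elif ch == "(":
            prev.append(prev[-1])
            i += 1
        elif ch == ")":
            if len(prev) < 2:
                raise ParseError(f"unbalanced ')' at position {i}")
            prev.pop()
            i += 1
        elif ch == ".":
            if len(prev) != 1:
                raise ParseError("component separator inside a branch")
            prev[-1] = None
            pending_bond = None
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                if i + 2 >= n or not text[i + 1:i + 3].isdigit():
                    raise ParseError(f"malformed %nn ring closure at {i}")
                label, i = text[i + 1:i + 3], i + 3
            else:
                label, i = ch, i + 1
            cur = prev[-1]
            if cur is None:
                raise ParseError(f"ring closure {label} before any atom")
            if label in ring_open:
                other, open_bond = ring_open.pop(label)
                order = pending_bond or open_bond
                add_bond(other, cur, order)
                pending_bond = None
            else:
                ring_open[label] = (cur, pending_bond)
                pending_bond = None
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ParseError(f"unclosed bracket atom at {i}")
            m = _BRACKET_RE.match(text[i + 1:j])
            if not m:
                raise ParseError(f"malformed bracket atom {text[i:j + 1]!r}")
            sym = m.group("symbol")
            aromatic = sym[0].islower()
            element = sym.capitalize() if aromatic else sym
            if element not in ATOMIC_WEIGHTS:
                raise ParseError(f"unknown element symbol {sym!r}")
            h = m.group("hcount")
            hcount = 0 if h is None else (1 if h == "H" else int(h[1:]))
            c = m.group("charge") or ""
            if c in ("", "+", "-"):
                charge = 1 if c == "+" else (-1 if c == "-" else 0)
            elif set(c) <= {"+"}:
                charge = len(c)
            elif set(c) <= {"-"}:
                charge = -len(c)
            else:
                charge = int(c)
            idx = add_atom(element, aromatic, charge, hcount)
            attach(idx)
            i = j + 1
        else:
            sym = None
            if text[i:i + 2] in _TWO_LETTER:
                sym = text[i:i + 2]
                i += 2
            elif ch.isupper():
                sym, i = ch, i + 1
            elif ch in "bcnops":
                sym, i = ch, i + 1
            else:
                raise ParseError(f"unexpected character {ch!r} at position {i}")
            aromatic = sym.islower()
            element = sym.upper() if aromatic else sym
            if element not in ORGANIC_SUBSET:
                raise ParseError(f"unknown element symbol {sym!r}")
            if aromatic and element not in AROMATIC_CAPABLE:
                raise ParseError(f"{sym!r} cannot be aromatic")
            idx = add_atom(element, aromatic)
            attach(idx)

    if ring_open:
        labels = ", ".join(sorted(ring_open))
        raise ParseError(f"unclosed ring bond(s): {labels}")
    if len(prev) != 1:
        raise ParseError("unbalanced '(' in SMILES")
    _assign_implicit_h(mol)
    if aromatize:
        perceive_aromaticity(mol)
    return mol


# ---------------------------------------------------------------------------
# SDF V2000
# ---------------------------------------------------------------------------

def parse_sdf(source: str | TextIO) -> list[Molecule]:
    """Parse a (multi-record) SDF V2000 text into Molecules.

    The record name is used as the CID when it is numeric.  ``M  CHG``
    properties are honored; aromatic bonds may be written as type 4 (our
    writer's convention) or Kekulé (types 1/2), in which case aromaticity
    is perceived.
    """
    text = source if isinstance(source, str) else source.read()
    mols: list[Molecule] = []
    records = [r for r in re.split(r"\$\$\$\$\r?\n?", text) if r.strip()]
    for ri, rec in enumerate(records):
        try:
            mols.append(_parse_sdf_record(rec))
        except ParseError as exc:
            raise ParseError(f"record {ri}: {exc}") from exc
    return mols


def _parse_sdf_record(rec: str) -> Molecule:
    lines = rec.splitlines()
    if len(lines) < 4:
        raise ParseError("truncated record header")
    name = lines[0].strip()
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed counts line {counts!r}") from exc
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError("atom/bond block shorter than counts line claims")
    mol = Molecule(name=name or None)
    if name.isdigit():
        mol.cid = int(name)
    coords = []
    for i in range(n_atoms):
        ln = lines[4 + i]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            sym = ln[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed atom line {i + 1}") from exc
        if sym not in ATOMIC_WEIGHTS:
            raise ParseError(f"unknown element symbol {sym!r} (atom {i + 1})")
        mol.atoms.append(Atom(index=i, element=sym))
        coords.append((x, y, z))
    mol.coords = coords
    order_map = {1: "single", 2: "double", 3: "triple", 4: "aromatic"}
    for i in range(n_bonds):
        ln = lines[4 + n_atoms + i]
        try:
            a, b, t = int(ln[0:3]), int(ln[3:6]), int(ln[6:9])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed bond line {i + 1}") from exc
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise ParseError(f"bond {i + 1} references atom out of range")
        mol.bonds.append(Bond(a - 1, b - 1, order_map.get(t, "single")))
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            parts = ln.split()
            cnt = int(parts[2])
            for j in range(cnt):
                idx, chg = int(parts[3 + 2 * j]) - 1, int(parts[4 + 2 * j])
                mol.atoms[idx].formal_charge = chg
        elif ln.startswith("M  END"):
            break
    for b in mol.bonds:  # type-4 input: flag endpoints before H assignment
        if b.order == "aromatic":
            mol.atoms[b.a].aromatic = True
            mol.atoms[b.b].aromatic = True
    _assign_implicit_h(mol)
    perceive_aromaticity(mol)
    return mol


def write_sdf(mols: Iterable[Molecule], stream: TextIO) -> None:
    """Write V2000 records readable back by :func:`parse_sdf`.

    Aromatic bonds are emitted as type 4.  Coordinates are written when the
    molecule carries them (parsed from SDF), otherwise zero — the census and
    similarity stages never consume geometry.
    """
    order_map = {"single": 1, "double": 2, "triple": 3, "aromatic": 4}
    for mol in mols:
        for a in mol.atoms:
            if a.element not in ATOMIC_WEIGHTS:
                raise ValueError(f"element without mass entry: {a.element!r}")
        name = str(mol.cid) if mol.cid is not None else (mol.name or "")
        stream.write(f"{name}\n  addsim\n\n")
        stream.write(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0"
                     f"  0  0  0  0999 V2000\n")
        for i, a in enumerate(mol.atoms):
            x, y, z = (mol.coords[i] if mol.coords else (0.0, 0.0, 0.0))
            stream.write(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3} 0"
                         "  0  0  0  0  0  0  0  0  0  0  0\n")
        for b in mol.bonds:
            stream.write(f"{b.a + 1:3d}{b.b + 1:3d}{order_map[b.order]:3d}"
                         "  0  0  0  0\n")
        charged = [(a.index + 1, a.formal_charge)
                   for a in mol.atoms if a.formal_charge]
        for i in range(0, len(charged), 8):
            chunk = charged[i:i + 8]
            stream.write(f"M  CHG{len(chunk):3d}" + "".join(
                f"{idx:4d}{chg:4d}" for idx, chg in chunk) + "\n")
        stream.write("M  END\n$$$$\n")


# ---------------------------------------------------------------------------
# Rings and aromaticity
# ---------------------------------------------------------------------------

def _sssr(mol: Molecule) -> list[list[int]]:
    """Smallest set of smallest rings, each returned in traversal order."""
    g = mol.to_networkx()
    rings = []
    for nodes in nx.minimum_cycle_basis(g):
        sub = g.subgraph(nodes)
        try:
            cyc = [e[0] for e in nx.find_cycle(sub)]
        except nx.NetworkXNoCycle:  # pragma: no cover - basis is cyclic
            continue
        rings.append(cyc)
    return rings


def perceive_rings(mol: Molecule) -> tuple[int, int, list[list[int]]]:
    """Ring census: (ring_count, aromatic_ring_count, SSSR atom lists).

    ``ring_count`` is the cycle-space dimension (bonds − atoms +
    components), realized as an SSSR basis; a ring counts as aromatic when
    all of its bonds carry the aromatic order class (assigned at parse time
    from lowercase SMILES or perceived from Kekulé input by
    :func:`perceive_aromaticity`).
    """
    g = mol.to_networkx()
    dim = g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)
    rings = _sssr(mol)
    bond_order = {frozenset((b.a, b.b)): b.order for b in mol.bonds}
    n_arom = 0
    for ring in rings:
        edges = [frozenset((ring[i], ring[(i + 1) % len(ring)]))
                 for i in range(len(ring))]
        if all(bond_order.get(e) == "aromatic" for e in edges):
            n_arom += 1
    return dim, n_arom, rings


def perceive_aromaticity(mol: Molecule) -> None:
    """Mark Hückel-aromatic SSSR rings (atoms and ring bonds) aromatic.

    A ring qualifies when every member is sp2-capable and the per-ring π
    count satisfies 4n+2: an atom with an in-ring double bond contributes
    1, a heteroatom contributing a lone pair 2, an atom with only an
    exocyclic double bond 0 (and disqualifies the ring unless it is a
    carbonyl-free system), an already-aromatic atom 1.  Fused systems are
    handled by iterating to a fixpoint.
    """
    adj = mol.adjacency()
    rings = _sssr(mol)
    for _ in range(3):
        changed = False
        for ring in rings:
            ring_set = set(ring)
            edges = [frozenset((ring[i], ring[(i + 1) % len(ring)]))
                     for i in range(len(ring))]
            bond_by_edge = {frozenset((b.a, b.b)): b for b in mol.bonds}
            if all(bond_by_edge[e].order == "aromatic" for e in edges):
                continue
            pi = 0
            ok = True
            for idx in ring:
                a = mol.atoms[idx]
                if a.element not in AROMATIC_CAPABLE:
                    ok = False
                    break
                doubles = [b for b in adj[idx] if b.order in ("double", "triple")]
                in_ring_double = any(b.other(idx) in ring_set and b.order == "double"
                                     for b in doubles)
                arom_bond = any(b.order == "aromatic" for b in adj[idx])
                if in_ring_double:
                    pi += 1
                elif a.aromatic or arom_bond:
                    pi += 1
                elif doubles:      # exocyclic double bond: sp2, 0 π
                    pi += 0
                elif a.element in ("N", "O", "S") or a.formal_charge < 0:
                    pi += 2        # lone pair enters the ring
                else:
                    ok = False     # sp3 carbon
                    break
            if ok and pi % 4 == 2:
                for idx in ring:
                    mol.atoms[idx].aromatic = True
                for e in edges:
                    bond_by_edge[e].order = "aromatic"
                changed = True
        if not changed:
            break


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

def atom_counts(mol: Molecule) -> dict[str, int]:
    """Per-element atom counts, hydrogens included."""
    counts: Counter[str] = Counter()
    for a in mol.atoms:
        counts[a.element] += 1
        counts["H"] += a.implicit_h
    if counts.get("H") == 0:
        del counts["H"]
    return dict(counts)


def molecular_formula(mol: Molecule) -> str:
    """Hill-order formula (C, H, then alphabetically); components merged."""
    counts = atom_counts(mol)
    parts = []
    for el in ("C", "H"):
        if el in counts:
            n = counts.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(counts):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def molecular_weight(mol: Molecule) -> float:
    """Sum of conventional atomic weights (g/mol), full precision."""
    w = 0.0
    for el, n in atom_counts(mol).items():
        try:
            w += ATOMIC_WEIGHTS[el] * n
        except KeyError as exc:
            raise ValueError(f"element lacking weight entry: {el!r}") from exc
    return w


def detect_functional_groups(mol: Molecule) -> dict[str, int]:
    """Count the twelve functional-group classes on a molecule.

    Each oxygen/nitrogen is assigned to at most one class, with precedence
    ester > acid > ketone/aldehyde > ether > alcohol, so e.g. ester oxygens
    are never double-counted as ethers.  Metal carboxylates (zinc stearate)
    count as RCOOH.
    """
    counts = {g: 0 for g in GROUP_CLASSES}
    adj = mol.adjacency()
    consumed: set[int] = set()

    def heavy_nbrs(idx: int) -> list[tuple[int, Bond]]:
        return [(b.other(idx), b) for b in adj[idx]
                if mol.atoms[b.other(idx)].element != "H"]

    def has_h(idx: int) -> bool:
        return mol.total_h(idx) > 0

    carbons = [a for a in mol.atoms if a.element == "C"]
    # esters and acids (incl. carboxylates / metal salts)
    for c in carbons:
        if c.aromatic:
            continue
        dbl_o = [i for i, b in heavy_nbrs(c.index)
                 if mol.atoms[i].element == "O" and b.order == "double"]
        sgl_o = [i for i, b in heavy_nbrs(c.index)
                 if mol.atoms[i].element == "O" and b.order == "single"]
        if len(dbl_o) == 1 and len(sgl_o) == 1:
            o_s = sgl_o[0]
            others = [i for i, _ in heavy_nbrs(o_s) if i != c.index]
            if others and mol.atoms[others[0]].element == "C":
                counts["RCOOR"] += 1
            elif (has_h(o_s) or mol.atoms[o_s].formal_charge < 0
                  or not others
                  or mol.atoms[others[0]].element in METALS):
                counts["RCOOH"] += 1
            else:
                continue
            consumed.update(dbl_o + sgl_o)
    # ketones / aldehydes
    for c in carbons:
        dbl_o = [i for i, b in heavy_nbrs(c.index)
                 if mol.atoms[i].element == "O" and b.order == "double"
                 and i not in consumed]
        if dbl_o:
            counts["RCHO" if has_h(c.index) else "RCOR"] += 1
            consumed.update(dbl_o)
    # phosphate esters (a phosphite P(OR)3 has no P=O and does not count)
    for a in mol.atoms:
        if a.element != "P":
            continue
        dbl_o = [i for i, b in heavy_nbrs(a.index)
                 if mol.atoms[i].element == "O" and b.order == "double"]
        sgl_o = [i for i, b in heavy_nbrs(a.index)
                 if mol.atoms[i].element == "O" and b.order == "single"]
        if dbl_o and len(sgl_o) >= 3:
            counts["ROPO3"] += 1
            consumed.update(dbl_o + sgl_o)
    # ethers then alcohols over the remaining oxygens
    for a in mol.atoms:
        if a.element != "O" or a.index in consumed or a.aromatic:
            continue
        nbrs = heavy_nbrs(a.index)
        c_nbrs = [i for i, _ in nbrs if mol.atoms[i].element == "C"]
        if len(nbrs) == 2 and len(c_nbrs) == 2 and not has_h(a.index):
            counts["ROR"] += 1
            consumed.add(a.index)
        elif len(c_nbrs) >= 1 and has_h(a.index):
            counts["ROH"] += 1
            consumed.add(a.index)
    # amines (aromatic and amide nitrogens excluded)
    for a in mol.atoms:
        if a.element != "N" or a.aromatic:
            continue
        bonds = adj[a.index]
        if any(b.order in ("double", "triple", "aromatic") for b in bonds):
            continue
        nbrs = heavy_nbrs(a.index)
        amide = any(
            mol.atoms[i].element == "C" and any(
                mol.atoms[bb.other(i)].element == "O" and bb.order == "double"
                for bb in adj[i])
            for i, _ in nbrs)
        if amide:
            continue
        n_c = sum(1 for i, _ in nbrs if mol.atoms[i].element == "C")
        n_h = mol.total_h(a.index)
        if n_c == 3 and n_h == 0:
            counts["R3N"] += 1
        elif n_c == 2 and n_h == 1:
            counts["R2NH"] += 1
        elif n_c == 1 and n_h == 2:
            counts["RNH2"] += 1
    # alkyne / nitrile terminal groups
    for b in mol.bonds:
        if b.order != "triple":
            continue
        ea, eb = mol.atoms[b.a].element, mol.atoms[b.b].element
        if {ea, eb} == {"C", "N"}:
            counts["RCN"] += 1
        elif ea == eb == "C" and (has_h(b.a) or has_h(b.b)):
            counts["RCCH"] += 1
    return counts


@dataclass
class StructuralCensus:
    mf: str
    mw: float
    atom_counts: dict[str, int]
    group_counts: dict[str, int]
    ring_count: int
    aromatic_ring_count: int


def structural_census(mol: Molecule) -> StructuralCensus:
    """The per-compound structural summary a screening table prints."""
    rings, arom, _ = perceive_rings(mol)
    return StructuralCensus(
        mf=molecular_formula(mol),
        mw=molecular_weight(mol),
        atom_counts=atom_counts(mol),
        group_counts=detect_functional_groups(mol),
        ring_count=rings,
        aromatic_ring_count=arom,
    )
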