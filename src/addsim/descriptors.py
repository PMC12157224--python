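"""Molecular descriptors: Ertl TPSA, H-bond donor/acceptor counts, and
Crippen-style LogP / molar refractivity.

TPSA is the sum of tabulated polar-fragment surface contributions over
atom environments (element, charge, attached hydrogens, bond-order
multiset, aromaticity, 3-ring membership).  The shipped table carries the
published N/O contributions plus the S and P extensions; S/P inclusion is
the default because a screening profile of sulfur- and phosphorus-bearing
additives (thioethers, phosphites) would otherwise report zero polar
surface for their heteroatom cores.

LogP and MR are atomic-contribution sums over a curated Crippen-style
atom-type table shipped as plain-text data.  They are this package's own
convention — additive LogP engines differ in their type systems, so these
values are suited to rank ordering and risk classification, not to
cross-engine numeric comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache

import pandas as pd

from .molgraph import Molecule

__all__ = [
    "DescriptorSet",
    "tpsa",
    "count_hbd",
    "count_hba",
    "crippen_logp_mr",
    "descriptor_table",
    "load_reference_descriptors",
]

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass
class DescriptorSet:
    cid: int | None
    hba: int
    hbd: int
    logp: float
    mr: float
    tpsa: float


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("addsim.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=1)
def _tpsa_table() -> dict[tuple, float]:
    df = _read_data("tpsa_fragments.tsv")
    return {
        (r.element, bool(r.aromatic), int(r.charge), int(r.n_h),
         int(r.n_single), int(r.n_double), int(r.n_triple),
         int(r.n_aromatic), bool(r.in_3ring)): float(r.psa)
        for r in df.itertuples()
    }


@lru_cache(maxsize=1)
def _crippen_table() -> dict[str, tuple[float, float]]:
    df = _read_data("crippen_contributions.tsv")
    return {r.type: (float(r.logp), float(r.mr)) for r in df.itertuples()}


def load_reference_descriptors() -> pd.DataFrame:
    """Printed reference descriptor values for the 24 study compounds.

    Carried as metadata for side-by-side reporting; the HBA/LogP/MR columns
    follow the undocumented convention of the engine that produced them and
    are not reproduced by this package.
    """
    return _read_data("reference_descriptors.tsv").set_index("cid")


# ---------------------------------------------------------------------------
# TPSA
# ---------------------------------------------------------------------------

def _atom_environment(mol: Molecule, idx: int,
                      three_ring_atoms: set[int]) -> tuple:
    a = mol.atoms[idx]
    n_single = n_double = n_triple = n_arom = 0
    for b in mol.adjacency()[idx]:
        if mol.atoms[b.other(idx)].element == "H":
            continue
        if b.order == "single":
            n_single += 1
        elif b.order == "double":
            n_double += 1
        elif b.order == "triple":
            n_triple += 1
        else:
            n_arom += 1
    return (a.element, a.aromatic, a.formal_charge, mol.total_h(idx),
            n_single, n_double, n_triple, n_arom, idx in three_ring_atoms)


def tpsa(mol: Molecule, include_s_p: bool = True) -> float:
    """Topological polar surface area (Å², full precision).

    Sums fragment contributions over N and O environments, plus S and P
    when ``include_s_p`` (the default; pass False for the N/O-only
    variant).  Unknown polar environments contribute 0 with a warning.
    """
    from .molgraph import perceive_rings

    elements = {"N", "O"} | ({"S", "P"} if include_s_p else set())
    _, _, rings = perceive_rings(mol)
    three_ring = {i for r in rings if len(r) == 3 for i in r}
    table = _tpsa_table()
    total = 0.0
    for a in mol.atoms:
        if a.element not in elements:
            continue
        env = _atom_environment(mol, a.index, three_ring)
        contrib = table.get(env)
        if contrib is None:
            # 3-ring flag only distinguishes a few entries; retry without it
            contrib = table.get(env[:-1] + (False,))
        if contrib is None:
            warnings.warn(
                f"no TPSA fragment for environment {env}; contributing 0",
                stacklevel=2)
            contrib = 0.0
        total += contrib
    return total


# ---------------------------------------------------------------------------
# Hydrogen bonding
# ---------------------------------------------------------------------------

def count_hbd(mol: Molecule) -> int:
    """Hydrogen-bond donors: total hydrogens borne by O and N atoms."""
    return sum(mol.total_h(a.index) for a in mol.atoms
               if a.element in ("N", "O"))


def count_hba(mol: Molecule) -> int:
    """Hydrogen-bond acceptors, Lipinski-style N+O count.

    Excludes pyrrole-type aromatic nitrogens (lone pair delocalized into
    the ring) and amide/acid N–H nitrogens.
    """
    adj = mol.adjacency()
    n = 0
    for a in mol.atoms:
        if a.element == "O":
            n += 1
        elif a.element == "N":
            conn = sum(1 for b in adj[a.index]
                       if mol.atoms[b.other(a.index)].element != "H")
            if a.aromatic and conn + mol.total_h(a.index) >= 3:
                continue  # pyrrole-type
            if mol.total_h(a.index) > 0 and any(
                mol.atoms[b.other(a.index)].element == "C" and any(
                    bb.order == "double"
                    and mol.atoms[bb.other(b.other(a.index))].element == "O"
                    for bb in adj[b.other(a.index)])
                for b in adj[a.index]
            ):
                continue  # amide N-H
            n += 1
    return n


# ---------------------------------------------------------------------------
# Crippen-style LogP / MR
# ---------------------------------------------------------------------------

def _classify_atom(mol: Molecule, idx: int) -> str | None:
    """Map an atom to a contribution type key (None for untyped)."""
    a = mol.atoms[idx]
    el = a.element
    adj = mol.adjacency()[idx]
    heavy = [(b.other(idx), b) for b in adj
             if mol.atoms[b.other(idx)].element != "H"]
    if el == "C":
        if a.aromatic:
            n_arom = sum(1 for _, b in heavy if b.order == "aromatic")
            subst = [(i, b) for i, b in heavy if b.order != "aromatic"]
            if n_arom >= 3:
                return "C.ar.fused"
            if not subst:
                return "C.ar.h"
            s_el = mol.atoms[subst[0][0]].element
            if s_el == "C":
                return "C.ar.fused" if mol.atoms[subst[0][0]].aromatic else "C.ar.c"
            if s_el == "N":
                return "C.ar.n"
            if s_el == "O":
                return "C.ar.o"
            if s_el == "S":
                return "C.ar.s"
            if s_el in _HALOGENS:
                return "C.ar.x"
            return "C.ar.c"
        if any(b.order == "double" and mol.atoms[i].element != "C"
               for i, b in heavy):
            return "C.carbonyl"
        if any(b.order == "double" for _, b in heavy):
            return "C.sp2"
        if any(b.order == "triple" for _, b in heavy):
            return "C.sp"
        hetero = any(mol.atoms[i].element != "C" for i, _ in heavy)
        branched = len(heavy) >= 3
        if hetero:
            return "C.sp3.het.branched" if branched else "C.sp3.het"
        return "C.sp3.cc.branched" if branched else "C.sp3.cc"
    if el == "N":
        if a.aromatic:
            return "N.ar"
        if any(b.order == "triple" for _, b in heavy):
            return "N.nitrile"
        if any(b.order == "double" for _, b in heavy):
            return "N.sp2"
        n_h = mol.total_h(idx)
        if n_h >= 2:
            return "N.prim"
        if n_h == 1:
            return "N.sec"
        if len(heavy) >= 3:
            return "N.tert"
        return "N.other"
    if el == "O":
        if a.aromatic:
            return "O.ar"
        if a.formal_charge < 0:
            return "O.anion"
        if any(b.order == "double" for _, b in heavy):
            return "O.carbonyl"
        if mol.total_h(idx) > 0:
            return "O.hydroxyl"
        if len(heavy) == 2:
            return "O.ether"
        return "O.other"
    if el == "S":
        return "S.any"
    if el == "P":
        return "P.any"
    if el in _HALOGENS:
        return el
    return None


def crippen_logp_mr(mol: Molecule) -> tuple[float, float]:
    """Additive LogP and molar refractivity (cm³/mol) over atom types.

    Hydrogens contribute by host element.  Atoms outside the type system
    (e.g. metals) contribute 0 with a warning.
    """
    table = _crippen_table()
    logp = mr = 0.0
    h_key = {"C": "H.c", "O": "H.o", "N": "H.n", "S": "H.s"}
    for a in mol.atoms:
        if a.element == "H":
            continue
        key = _classify_atom(mol, a.index)
        if key is None:
            warnings.warn(f"unparameterized atom type for {a.element} "
                          f"(atom {a.index}); contributing 0", stacklevel=2)
        else:
            lp, m = table[key]
            logp += lp
            mr += m
        hk = h_key.get(a.element, "H.c")
        lp, m = table[hk]
        n_h = mol.total_h(a.index)
        logp += n_h * lp
        mr += n_h * m
    return logp, mr


# ---------------------------------------------------------------------------
# Batch table
# ---------------------------------------------------------------------------

def descriptor_table(mols: list[Molecule]) -> pd.DataFrame:
    """One descriptor row per molecule, in input order.

    Columns: cid, hba, hbd, logp, mr, tpsa.  Values carry full precision;
    round only at serialization.
    """
    rows = []
    for m in mols:
        logp, mr = crippen_logp_mr(m)
        rows.append({
            "cid": m.cid,
            "hba": count_hba(m),
            "hbd": count_hbd(m),
            "logp": logp,
            "mr": mr,
            "tpsa": tpsa(m),
        })
    return pd.DataFrame(rows, columns=["cid", "hba", "hbd", "logp", "mr", "tpsa"])
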