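"""Atom-pair fingerprints, MCS search and the derived coefficients."""

import numpy as np
import pytest

from addsim.molgraph import parse_smiles
from addsim.similarity import (ap_matrix, atom_pair_set, mcs, mcs_matrix, oc,
                               tanimoto_ap, tc_mcs)
from addsim.synthetic_fixtures import (oracle_mcs, planted_mcs_pair,
                                       random_molecule)


class TestAtomPairs:
    def test_ethanol_pairs(self):
        fp = atom_pair_set(parse_smiles("CCO"))
        assert len(fp) == 3
        keys = {(a[0], b[0], d) for (a, b, d) in fp.pairs}
        assert keys == {("C", "C", 1), ("C", "O", 1), ("C", "O", 2)}

    def test_single_heavy_atom_empty(self):
        assert len(atom_pair_set(parse_smiles("C"))) == 0

    def test_benzene_three_distances_one_type(self):
        fp = atom_pair_set(parse_smiles("c1ccccc1"))
        assert len(fp) == 15  # C(6,2) pairs
        dists = sorted({d for (_, _, d) in fp.pairs})
        assert dists == [1, 2, 3]
        types = {a for (a, b, _) in fp.pairs} | {b for (_, b, _) in fp.pairs}
        assert types == {("C", 2, 1)}

    def test_pairs_do_not_span_components(self):
        fp = atom_pair_set(parse_smiles("CC.CC"))
        assert len(fp) == 2  # one intra-component pair each

    def test_self_similarity_is_one(self, study):
        for cid in (4632, 11178, 91601):
            fp = atom_pair_set(study[cid])
            assert tanimoto_ap(fp, fp) == 1.0

    @pytest.mark.parametrize("pair, expected", [
        # values verified against an independent atom-pair implementation
        ((4632, 8569), 0.7622),
        ((4632, 8572), 0.6954),
        ((4632, 8571), 0.4236),
        ((8569, 8572), 0.5965),
        ((8571, 8572), 0.5690),
        ((62531, 77470), 0.6646),
    ])
    def test_reference_pair_values(self, study, pair, expected):
        got = tanimoto_ap(atom_pair_set(study[pair[0]]),
                          atom_pair_set(study[pair[1]]))
        assert got == pytest.approx(expected, abs=5e-4)

    def test_disjoint_elements_zero(self):
        a = atom_pair_set(parse_smiles("CCCCCC"))
        b = atom_pair_set(parse_smiles("OO"))
        assert tanimoto_ap(a, b) == 0.0

    def test_both_empty_warns_zero(self):
        a = atom_pair_set(parse_smiles("C"))
        with pytest.warns(UserWarning):
            assert tanimoto_ap(a, a) == 0.0

    @pytest.mark.parametrize("seed", range(15))
    def test_symmetry_and_range(self, seed):
        a = atom_pair_set(random_molecule(seed, 5 + seed % 6))
        b = atom_pair_set(random_molecule(seed + 50, 5 + (seed * 2) % 6))
        t1, t2 = tanimoto_ap(a, b), tanimoto_ap(b, a)
        assert t1 == t2
        assert 0.0 <= t1 <= 1.0

    def test_matrix_single_molecule(self):
        sm = ap_matrix([parse_smiles("CCO", cid=1)])
        assert sm.values.shape == (1, 1) and sm.values[0, 0] == 1.0

    def test_matrix_masking(self, study):
        sm = ap_matrix([study[4632], study[11178]], cutoff=0.30)
        masked = sm.masked()
        assert np.isnan(masked[0, 1])  # dissimilar pair below cutoff
        sm_all = ap_matrix([study[4632], study[11178]], cutoff=0.0)
        assert not np.isnan(sm_all.masked()).any()


class TestMcs:
    def test_identity(self):
        benzene = parse_smiles("c1ccccc1")
        r = mcs(benzene, benzene)
        assert (r.c, r.oc, r.tc, r.exhausted) == (6, 1.0, 1.0, True)

    def test_no_common_element(self):
        r = mcs(parse_smiles("CCCCCC"), parse_smiles("O"))
        assert r.c == 0 and r.tc == 0.0

    def test_symmetry(self, study):
        r1 = mcs(study[4632], study[8571])
        r2 = mcs(study[8571], study[4632])
        assert (r1.c, r1.oc, r1.tc) == (r2.c, r2.oc, r2.tc)

    def test_coefficient_helpers_match_fields(self, study):
        r = mcs(study[4632], study[8572])
        assert oc(r) == pytest.approx(r.oc)
        assert tc_mcs(r) == pytest.approx(r.tc)

    def test_mapping_is_partial_isomorphism(self, study):
        a, b = study[4632], study[8572]
        r = mcs(a, b)
        assert len(r.mapping) == r.c
        ea = {frozenset((x.a, x.b)): x.order for x in a.bonds}
        eb = {frozenset((x.a, x.b)): x.order for x in b.bonds}
        fwd = dict(r.mapping)
        for (u1, v1) in r.mapping:
            for (u2, v2) in r.mapping:
                key_a, key_b = frozenset((u1, u2)), frozenset((v1, v2))
                assert (key_a in ea) == (key_b in eb)
                if key_a in ea:
                    assert ea[key_a] == eb[key_b]
        assert len(set(fwd.values())) == r.c

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_exhaustive_oracle(self, seed):
        a = random_molecule(seed, 4 + seed % 9, ring_prob=0.3)
        b = random_molecule(seed + 1000, 4 + (seed * 3) % 9, ring_prob=0.3)
        assert mcs(a, b, timeout=30).c == oracle_mcs(a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_core_recovered_exactly(self, seed):
        pair = planted_mcs_pair(seed, core_size=5 + seed % 5)
        r = mcs(pair.mol_a, pair.mol_b, timeout=30)
        assert r.c == pair.core_size

    @pytest.mark.parametrize("seed", range(10))
    def test_mismatch_budget_monotonicity(self, seed):
        a = random_molecule(seed + 300, 7, ring_prob=0.2)
        b = random_molecule(seed + 400, 7, ring_prob=0.2)
        c0 = mcs(a, b, atom_mismatches=0).c
        c1 = mcs(a, b, atom_mismatches=1).c
        assert c1 >= c0

    def test_timeout_returns_best_found(self):
        a = random_molecule(1, 30, ring_prob=0.3)
        b = random_molecule(2, 30, ring_prob=0.3)
        r = mcs(a, b, timeout=1e-6)
        assert not r.exhausted
        assert 0 <= r.c <= 30

    def test_tc_never_exceeds_oc(self):
        for seed in range(20):
            a = random_molecule(seed + 600, 5 + seed % 6)
            b = random_molecule(seed + 700, 5 + (seed * 2) % 6)
            r = mcs(a, b, timeout=30)
            assert r.tc <= r.oc + 1e-12


class TestMcsMatrix:
    def test_identical_molecules_all_ones(self):
        mol = parse_smiles("CCO", cid=1)
        mol2 = parse_smiles("CCO", cid=2)
        ocm, tcm, done = mcs_matrix([mol, mol2])
        assert np.allclose(ocm.values, 1.0)
        assert np.allclose(tcm.values, 1.0)
        assert done.all()

    def test_benzophenone_overlap_row(self, study):
        subset = [study[c] for c in (4632, 8569, 8571, 8572)]
        ocm, tcm, done = mcs_matrix(subset, timeout=30)
        assert done.all()
        row = np.round(ocm.values[0], 2)
        assert list(row) == [1.0, 1.0, 0.94, 1.0]
        assert (tcm.values <= ocm.values + 1e-12).all()

    def test_requires_two(self):
        with pytest.raises(ValueError):
            mcs_matrix([parse_smiles("C")])
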