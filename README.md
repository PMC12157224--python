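# addsim

Structural census, similarity and clustering toolkit for polymer
additives — antioxidants, UV stabilizers, quenchers, photoinitiators.

Polymer formulations rely on small-molecule additives whose environmental
fate matters as much as their function: lipophilic, membrane-permeable
molecules bioaccumulate when they leach from discarded plastic.  `addsim`
profiles a set of additives from structure alone: it parses SMILES/SDF
into attributed molecular graphs, computes a structural census (formula,
atom counts, functional groups, rings) and physicochemical descriptors,
quantifies pairwise structural similarity two ways, groups the compounds
by hierarchical clustering with full validity and stability assessment,
and flags environmental risk from LogP/TPSA decision rules.

## Methods at a glance

* **Atom-pair fingerprints** — every heavy-atom pair typed by (element,
  heavy-neighbor count, π-electron count) with its shortest bond-path
  length; similarity is the Tanimoto coefficient on the pair multisets,
  TC = |A∩B| / (|A| + |B| − |A∩B|).
* **Maximum common substructure (MCS)** — the largest connected common
  subgraph (induced matching; element and bond-order-class compatible;
  optional atom/bond mismatch budgets) found by deterministic
  branch-and-bound.  With c the MCS heavy-atom count and a, b the
  molecule sizes: overlap coefficient OC = c / min(a, b) and Tanimoto
  TC = c / (a + b − c).  OC = 1 means the smaller molecule embeds
  entirely in the larger one.
* **Ertl TPSA** — topological polar surface area as a sum of tabulated
  polar-fragment contributions over N/O (plus S/P) environments;
  Crippen-style additive LogP and molar refractivity from a shipped
  atom-type table.
* **Clustering** — binning (threshold single linkage), hierarchical
  clustering (single/average/complete/Ward.D2) selected by cophenetic
  correlation, internal indices (connectivity, Dunn, silhouette),
  column-deletion stability (APN, AD, ADM, FOM), majority-rule choice of
  k, and bootstrap cluster stability via best-match Jaccard coefficients
  (unstable < 0.65 ≤ stable ≤ 0.85 < highly stable).
* **Risk flags** — LogP > 5 with TPSA < 75 Å² ⇒ hazard; LogP > 5 with
  TPSA 75–83 Å², or LogP 3–5 with TPSA < 60 Å² ⇒ investigate; TPSA >
  140 Å² (too polar to cross membranes) ⇒ low risk regardless of LogP.

The 24 study compounds ship with the package as a SMILES table
(`addsim/data/study_compounds.tsv`), encoded from their chemical names
and verified against the reference structural table.

## Worked example

Descriptors for three benzophenone UV stabilizers (CIDs 4632, 8572,
8571):

```sh
$ addsim descriptors benzo.smi
cid     hba     hbd     logp    mr      tpsa
4632    3       1       2.7174  67.8218 46.53
8572    3       2       2.0633  63.0316 57.53
8571    5       4       1.4745  68.2132 97.99
```

TPSA 46.53 Å² for 2-hydroxy-4-methoxybenzophenone is the sum of one
phenolic OH (20.23), one aryl ether oxygen (9.23) and one carbonyl
oxygen (17.07); with LogP ≈ 2.7 it classifies as mild lipophilicity /
polar-surface concern — low joint risk.  The MCS between CIDs 4632 and
8572:

```python
>>> from addsim.synthetic_fixtures import study_molecules
>>> from addsim.similarity import mcs
>>> m = study_molecules()
>>> r = mcs(m[4632], m[8572])
>>> r.c, r.a, r.b, round(r.oc, 2), round(r.tc, 2)
(16, 17, 16, 1.0, 0.94)
```

All 16 heavy atoms of 2,4-dihydroxybenzophenone map into the methoxy
analogue (OC = 1): the smaller additive's substructure — and hence its
UV-absorbing chromophore — is fully preserved in the larger one, so the
pair are candidates for substitution screening.  The full pipeline
(`addsim report --input compounds.smi --outdir out`) writes descriptor,
similarity, clustering, validation, bootstrap and risk tables plus a
Newick dendrogram and a leaf-ordered heatmap matrix.

## Layout

```
src/addsim/
  molgraph.py            graph model, SMILES/SDF I/O, census
  descriptors.py         TPSA, HBD/HBA, Crippen-style LogP/MR
  similarity.py          atom pairs, MCS, OC/TC matrices
  clustering.py          binning, HC, k-means, validity, bootstrap
  riskflags.py           LogP/TPSA decision rules
  synthetic_fixtures.py  study compounds, generators, exhaustive oracle
  report.py, cli.py      pipeline orchestration and the addsim CLI
  data/                  parameter tables and the study-compound table
docs/methods.md          model assumptions, conventions, limitations
```
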