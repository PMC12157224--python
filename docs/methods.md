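# Methods

This note records the models, conventions and design choices behind
`addsim`, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Molecular graph model

A molecule is an attributed undirected graph: atoms carry element,
formal charge, implicit-hydrogen count and an aromatic flag; bonds carry
one of four order classes (single, double, triple, aromatic).  Records
may be disconnected — salts and co-crystals (zinc stearate; the
succinate/piperidinol pair) are one record with several components, and
the census aggregates components into a single sum formula.

*Implicit hydrogens* fill the smallest allowed valence (C 4; N 3; O 2;
S 2/4/6; P 3/5; halogens 1) adjusted by formal charge (N⁺ 4, O⁻ 1, …).
Aromatic atoms contribute one shared π bond to their valence; an
aromatic nitrogen whose three connections already exhaust its valence is
pyrrole-type and receives no hydrogen.  Metals never receive hydrogens.

*Aromaticity* is taken from lowercase SMILES when present and otherwise
perceived on Kekulé input: a smallest-set-of-smallest-rings (SSSR) ring
is aromatic when every member is sp2-capable and the per-ring π count
(in-ring double bond → 1, lone-pair heteroatom → 2, exocyclic double
bond → 0, already-aromatic neighbor ring atom → 1) satisfies Hückel's
4n+2.  Fused systems iterate to a fixpoint.  The ring census reports the
cycle-space dimension (bonds − atoms + components), realized as an SSSR
basis.

*Functional groups* are perceived over twelve classes (R3N, RNH2, R2NH,
ROH, RCOR, RCHO, RCOOH, RCOOR, ROR, ROPO3, RCCH, RCN).  Each O/N atom
belongs to at most one class, with precedence ester > acid >
ketone/aldehyde > ether > alcohol, so ester oxygens are never
double-counted as ethers.  Metal carboxylates count as RCOOH (the
screening convention for stearate salts); phosphite P(OR)₃ oxygens are
neither ethers nor phosphate esters (ROPO3 requires P=O).

*Molecular weights* use the IUPAC 2007 conventional atomic weights
(Zn 65.409).  Newer revisions shift Zn and O enough to move large
molecules by ~0.01–0.03 g/mol; weights are reported to 2 decimals and
tested to ±0.02.

*Stereochemistry* is parsed and discarded: the census, descriptors and
similarity measures are stereo-blind, consistent with 2D structure
records.

## Descriptors

**TPSA** is the Ertl fragment-contribution sum keyed on (element,
aromaticity, charge, attached H, bond-order multiset, 3-ring
membership); the table ships as plain text
(`data/tpsa_fragments.tsv`).  S and P contributions are included by
default — a thioether contributes 25.30 Å², a phosphite P 13.59 Å² —
because a screening profile of sulfur/phosphorus additives would
otherwise assign their heteroatom cores zero polar surface;
`tpsa(mol, include_s_p=False)` gives the N/O-only variant.  Unknown
polar environments contribute 0 with a warning.  The implementation is
cross-checked in the tests against an independent additive-TPSA
implementation (rdkit) on all 24 study compounds.

**HBD** counts hydrogens borne by N and O.  **HBA** is the Lipinski-style
N+O count excluding pyrrole-type aromatic nitrogens and amide N–H.  The
reference descriptor table shipped alongside
(`data/reference_descriptors.tsv`) carries HBA/LogP/MR values produced
by an engine whose conventions are undocumented; they are metadata for
side-by-side reporting, not targets — e.g. its HBA values (up to 120)
are far from any N+O count.

**LogP / MR** are additive Crippen-style sums over a curated atom-type
table (`data/crippen_contributions.tsv`): aliphatic carbons split by
branching and heteroatom attachment, aromatic carbons by substituent
element, hydrogens by host element, heteroatoms by environment.  This is
deliberately the package's own convention — additive LogP engines
differ in their type systems — and it is used for rank ordering and
risk classification.  On the study set it tracks the reference values
to roughly ±1 log unit, which the risk classes absorb in all but
boundary cases.

Computation is in full precision; 2-decimal rounding happens only at
serialization.

## Similarity

**Atom pairs.**  Each heavy atom is typed by (element, heavy-neighbor
count, π-electron count; aromatic atoms count one π); each unordered
heavy-atom pair within a component contributes (typeA, typeB,
shortest-path bond count) to the fingerprint.  The fingerprint is a
*multiset* — multiplicities are retained, and the Tanimoto coefficient
uses the min-count intersection.  This choice was validated against an
independent atom-pair implementation (ChemmineR) during development;
the six pairwise values frozen in the tests agree to 4 decimals.
Unique-set semantics give materially different values (e.g. 0.89 instead
of 0.76 for the most similar benzophenone pair) and are not offered.

**MCS.**  The maximum common substructure is the largest *connected*
common subgraph under induced matching: two mapped atoms are bonded in
one molecule iff their images are bonded in the other, so rings never
open into chains.  Atoms match by element, bonds by order class with
aromatic as its own class; "flexible" search admits bounded
atom-/bond-label mismatches (defaults 0, which reproduce the reference
coefficients).  The search is branch-and-bound backtracking over
frontier extensions with (i) a rarity-first seed order, (ii) an
element-multiset upper bound, (iii) early exit when the bound meets
min(a, b), and (iv) deterministic tie-breaking, so results are
machine-independent.  On timeout the best mapping found is returned
with `exhausted=False`; batch matrices collect per-pair flags and never
abort.  Because Kekulé structures are normalized to aromatic form
before matching, an engine that matches alternating Kekulé bond orders
against chain bonds can report slightly larger MCS sizes for the
largest aromatic compounds; the affected reference cells differ by
±0.02–0.07 in OC and are not acceptance targets.

The exhaustive oracle (`synthetic_fixtures.oracle_mcs`) enumerates every
connected subset of the smaller molecule (ESU scheme) and tests induced
subgraph isomorphism with networkx — an independent path used to verify
the branch-and-bound on hundreds of random pairs up to 12 heavy atoms.

## Clustering

Distances enter as d = 1 − s from a similarity matrix.  For the study
reproduction the *overlap-coefficient* matrix is the default similarity
(the printed reference matrix is the OC matrix, and clustering 1 − OC
reproduces the reference four-cluster partition exactly); 1 − TC is
available via `--distance tc`.

Agglomeration, cophenetic distances and tree cuts use
scipy.cluster.hierarchy; scipy's `ward` on a distance matrix is the
Ward.D2 variant (squared-distance update, heights on the distance
scale).  Cut labels are renumbered by first occurrence so label vectors
are reproducible.  k-means uses scikit-learn (k-means++ with seeded
restarts); distance matrices are first embedded by classical
(Torgerson) MDS with dimension min(n − 1, 10).

*Internal indices*: connectivity (clValid-style 1/rank penalty over the
10 nearest neighbors), Dunn (min inter-cluster distance / max cluster
diameter; 0 with a warning when all clusters are singletons), mean
silhouette.  *Stability indices* (APN, AD, ADM, FOM) recluster after
each single-column deletion and compare to the full-data clustering;
they require a feature matrix, so distance-only inputs go through the
MDS embedding — a documented deviation from a feature-native workflow.
*Majority-rule k*: each measure votes for its best k (lower-is-better:
connectivity, APN, AD, ADM, FOM; higher: Dunn, silhouette); the most-
named values are retained with ties.

*Bootstrap stability* resamples observations with replacement (default
B = 100, seeded), reclusters the induced sub-matrix, and matches each
original cluster to the bootstrap cluster maximizing the Jaccard
coefficient over the resampled universe.  Reported per cluster: mean
best-match Jaccard (unstable < 0.65 ≤ stable ≤ 0.85 < highly stable)
and the dissolution rate, i.e. the fraction of resamples with best
Jaccard below 0.5.  "Instability" printed in external reports is not
1 − AvgJ and its definition is undocumented; the dissolution rate is
this package's stated convention.

*Binning* interprets a cutoff as a fraction of the maximum pairwise
distance; clusters are connected components of the thresholded graph,
after z-scoring feature columns.

## Risk rules

Per-axis classes and the joint flag are total functions with explicit
boundary assignments: LogP > 5 high bioaccumulation, (3, 5] borderline,
[1, 3] mild, < 1 low; TPSA > 140 Å² reduced systemic exposure, (75,
140] higher safety, [60, 75] borderline, < 60 concern.  Joint flag:
hazard iff LogP > 5 ∧ TPSA < 75; investigate for LogP > 5 ∧ TPSA ∈
[75, 83] (the narrow printed window 77–83 Å² widened to the class
boundary, a documented decision) and for 3 < LogP < 5 ∧ TPSA < 60;
TPSA > 140 is low risk regardless of LogP (too polar to cross
membranes).  The [75, 77) interval is unaddressed by the source rules
and falls under investigate by the widening.

## Synthetic data

Generators are pure functions of an integer seed via NumPy's PCG64.
`random_molecule` grows a random tree under exact valence accounting
(element frequencies roughly organic: C 0.70, O 0.14, N 0.10, S 0.04,
Cl 0.02; double bonds 0.15 where supported) and closes rings with
probability 0.2 per open atom — small, tree-dominated molecules typical
of fragment-scale chemistry, not a model of real additive chemical
space (no aromatic systems are generated, so aromatic matching is
exercised by the packaged study compounds instead).  `planted_mcs_pair`
decorates two copies of an all-carbon core with distinct halogens so the
core is provably the unique maximal common substructure.
`gaussian_feature_matrix` places k centers mutually `separation` apart
on a scaled simplex with isotropic noise.  Passing tests on these
generators demonstrates correctness of the machinery, not performance
on real descriptor distributions.

## Problem sizes in the default test run

The suite validates the MCS search against the exhaustive oracle on 300
random pairs of 4–12 heavy atoms, runs the full 24×24 MCS matrix with a
2 s per-pair search cap (17 of 276 pairs return best-found-so-far
rather than proven-optimal mappings; all reference cells are proven),
100 seeded planted-recovery runs, and bootstrap studies at B = 20–30.
These sizes were chosen to exercise every code path at desk scale.

## Fixture provenance

22 of 24 study structures are encoded from their printed chemical names
and verified against the printed molecular formulas, ring counts and
functional-group counts.  Two records are reconstructions
(`requires_lookup`): CID 24667 is named as butylated hydroxyanisole but
printed with exactly twice BHA's formula and a two-ring, two-OH,
two-ether census — encoded as a two-component record of
2-tert-butyl-4-methoxyphenol; CID 4992761's printed name (o-toluidine)
contradicts its printed C27H27N3O2 — encoded as
2-(4,6-diphenyl-1,3,5-triazin-2-yl)-5-hexyloxyphenol, which matches the
formula, weight, census and reference TPSA.  Two reference descriptor
values are internally inconsistent with their printed structures and are
excluded from exact checks: the TPSA printed for CID 8571 (57.99)
cannot arise from four phenolic OH plus a carbonyl (97.99 by the
fragment sums, confirmed by the independent cross-check), and the zinc
stearate row assumes the neutral diacid while the salt is ionic.

## Known limitations

* SMILES support covers the organic subset plus bracket atoms, ring
  closures and components; no reactions, wildcards or quadruple bonds.
* Functional-group perception covers the twelve census classes only.
* The Crippen-style LogP table is coarse for exotic environments
  (charged N/O outside the tabulated set fall back with warnings;
  metals contribute 0).
* MCS on pairs of large, highly symmetric molecules may hit the search
  cap; results are then explicit lower bounds (`exhausted=False`).
* Bootstrap stability reclusters with the same linkage as the base
  tree; comparing across algorithms is out of scope.
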