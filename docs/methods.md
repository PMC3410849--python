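# Methods

`ppivar` quantifies how reproducible the molecular details of a
protein-protein interface are when the "same" interaction is solved more
than once.  This note documents the model, the parameters that matter, the
synthetic test bed, and the numerical and design choices behind them.

## Interface definition

For a hetero-dimer (two interacting chains mapped to different protein
accessions) a residue pair (Rx, Ry) is part of the interface if either

1. **distance rule** - at least one atom pair of the two residues is
   closer than the contact cutoff (default 6 Å), or
2. **dASA rule** - all of: both residues lose accessible surface area on
   binding (dASA above the quadrature noise floor of 0.1 Å²); Rx has no
   partner on the other chain within the cutoff; and, among the other
   chain's dASA-positive residues, Ry is the one closest to Rx.

Rule 2 recovers genuine contacts that fall slightly above the distance
cutoff (heavy-atom geometry caps the effect at roughly 6.0-6.2 Å for the
closest pair) while still burying surface.  The rule as written is
asymmetric in Rx/Ry; because an interface is a symmetric object we
evaluate it in both directions and take the union (a one-directional mode
is available for sensitivity analysis).  dASA is the classical contrast
"chain alone minus chain in the complex", i.e. the partner replaced by
solvent.  ASA is the Shrake-Rupley rolling-probe quadrature (probe 1.4 Å,
960 sphere points by default, element van der Waals radii; unknown
elements fall back to 1.8 Å with a warning), computed via biotite.  The
two *faces* of an interface are the per-chain projections of the admitted
pairs; dimers with fewer than five residues on either face are dropped.
Each retained dimer gets an *interface copy number*: the number of dimers
in the same assembly with exactly the same unordered SEQRES pair.

Entry-level selection mirrors standard practice for high-resolution
interaction sets: X-ray entries with resolution strictly below 2.5 Å
whose chains map to at least two distinct accessions.  The chain-protein
mapping is an explicit TSV input (assembly_id, chain_id, accession,
family); a deterministic global-alignment identity fallback (≥30
residues, ≥90% aligned coverage, ties to the smallest accession) stands
in where the table is silent.  Residues are indexed on SEQRES so entries
with different author numbering are comparable; hetero-atoms and
non-standard residues are excluded.

## Similarity measures

Before any comparison the two dimers are reduced to common residues: the
identity map for identical sequences, otherwise a global alignment
(BLOSUM62, gap open -10, extend -0.5) restricted to aligned, non-gap
positions resolved in both structures.  Comparisons with less than 30%
coverage of the shorter sequence are skipped.

* **Face Position Similarity (fps)** - per side, |shared face positions| /
  sqrt(|faceA| · |faceB|) after reduction; the two sides are combined by
  their arithmetic mean (the combiner is a package choice; both per-side
  values are retained so any other combiner can be applied downstream).
  A side whose face vanishes after reduction makes the comparison
  undefined.
* **L_rms** - the CAPRI ligand RMSD: superpose the larger chains
  ("receptors", ties broken by the smaller accession) on backbone atoms
  (N, CA, C, O; per-residue fallback to whatever backbone subset both
  residues share), apply that transform to the smaller chains, report the
  ligand backbone RMSD.
* **I_rms** - the CAPRI interface RMSD: superpose jointly on the backbone
  of the interface region common to both dimers (per side, every mapped
  position in either dimer's face) and report that minimized RMSD.

Superposition is least-squares rigid (Kabsch; proper rotation enforced),
validated in the tests against an independent quaternion (Horn) oracle.
Degenerate point sets (fewer than 3 points, collinear) raise an error and
the comparison is skipped.  When the two dimers join two proteins of one
family, chain roles cannot be fixed by accession or family; both
orientations are evaluated and the more similar one (by fps) is kept.

## Redundancy hierarchy and distributions

Dimers are grouped by unordered key at three levels: identical SEQRES
pair (SameSeq), identical accession pair (SameProt), identical family
pair (Interolog).  The SameSeq key also carries the accession and family
pair so the hierarchy is always a tree.  Distributions are built
bottom-up with *unweighted* averaging at every step so heavily deposited
complexes, proteins and families do not dominate:

* **D-SameSeq** - per SameSeq group with ≥2 members, the histogram of all
  pairwise member similarities (intra-assembly copies included and
  flagged; a switch excludes them); averaged over SameSeq groups per
  SameProt, over SameProt per Interolog, and over Interolog groups.
* **D-SameProt** - per SameProt group, each unordered pair of distinct
  SameSeq children contributes the histogram of its cross-child
  comparisons (never within-child ones); averaged up identically.
* **D-Interolog** - per Interolog group, for each unordered pair of
  distinct SameProt children every (SameSeq, SameSeq) cross combination
  contributes a histogram; averaged to the protein-pair, family, and
  overall level.  Families with more than 50 protein pairs, or proteins
  with more than 50 sequence pairs, are subsampled with the run's seeded
  RNG (recorded in the output metadata).

fps histograms use ten equal bins on [0, 1] (half-open, the last bin
closed); Å-valued measures use 1-Å bins from 0 to 9 with an open top bin,
chosen so the conventional thresholds (<1 Å, >2 Å, >9 Å) are bin edges.
Groups whose comparisons were all skipped contribute nothing and are
excluded from the averages (logged).  Per-bin standard errors come from a
bootstrap over the top-level (family) groups — the only level at which
groups are exchangeable — with a seeded RNG; cumulative masses are sums
of whole bins (no interpolation).

## Homomer best-match filtering

A protein may bind several copies of a partner that itself forms a
homo-oligomer, producing genuinely different interfaces for one protein
pair.  To measure how much diversity this explains, a comparison X/Y vs
X′/Y′ is retained only if it is the best match among all alternative
interfaces that X′ or Y′ forms with chains of the same homomer (the
alternative set always contains X′/Y′ itself), and the same test passes
with the roles of the two dimers swapped.  Homomer membership is the
transitive closure of the contact graph over sequence-identical chains
(mode *sequence*) or same-family chains (mode *structural*), so all
subunits of an n-ring count as one oligomer even when not pairwise in
contact.  "Best" means maximal fps or minimal Å-distance, per measure
independently; exact ties are retained (discarding ties would delete the
case where the only alternative is as good as the focal interface).
Structural mode is only applied to D-Interolog and only to interactions
between two different families; same-family interactions pass through it
unfiltered.

## Synthetic worlds

The generator emulates the data regimes the analysis must distinguish,
with no physical realism beyond what the pipeline's rules read:

* Chains are idealized rods: straight CA trace at 3.8 Å per residue with
  N, C, O, CB placed on a 100°-per-residue twist (phase set by the fold
  seed).  Glycine is excluded from the synthetic alphabet so every
  residue carries a CB.  Rods are trivially self-avoiding; backbone atom
  clouds are fully three-dimensional, so superpositions are
  well-conditioned.
* A family pair has `modes_per_pair` binding modes: disjoint sequence
  windows (center ± 4 residues) evenly spaced along both chains.  Docking
  crosses the two rods at their window centers (axes 5.4 Å apart at 25°),
  which makes the annotated faces land inside the windows and gives
  cross-mode comparisons fps ≈ 0 and same-mode comparisons fps = 1.
* Observations: each single-copy assembly draws its mode independently
  from the planted mixture, so two observations are cross-mode with
  probability 1 − Σqᵢ² (= 2p(1−p) for two modes).  An assembly with k
  copies places them on successive modes (m, m+1, ...) — the packing
  motif by which one partner occupies several sites of a multimer — so
  the cross-mode fraction rises with the copy-number mean and the
  closed-form expectation is computable exactly (`expected_cross_fraction`).
  With two modes the fraction saturates at copy number 2; the monotone
  statements tested are therefore monotonicity in the *mean* copy number
  along {1, 2}-mixtures and in the expected cross-mode pair *count*.
* With probability `homomer_rate` an observation is the homomer-bridge
  topology: two X copies in mutual contact binding one Y at different
  windows (the second copy is swung around Y's axis by a deterministic
  grid search until it touches the first without clashing).
* Optionally a world includes two alpha3-beta3 rings around a central
  core chain: same-family alpha/beta rods alternate on a circle with
  staggered heights, so each subunit touches a different region of the
  core; the second ring permutes the heights, giving a "rotational"
  correspondence.  This is the structural-homomer scenario.

Default world parameters (4 families × 2 protein pairs × 2 sequence
variants × 3 observations; mode mixture 0.8/0.2; copy numbers 1-3 biased
to 1; homomer rate 0.2; point-mutation rate 0.03; family divergence 0.4)
are one fixed realization of "a few observations of modestly diverse
interactions": enough structure for every level of the hierarchy to be
populated while keeping a world to a few seconds of compute.  Sequence
variants keep the backbone, so variability measured across variants
isolates the planted mode structure from conformational noise — which
also means the synthetic tests say nothing about flexibility, disorder,
side-chain packing or crystal contacts in real data; they validate the
statistical machinery, not structural biology.

## Validation experiments

`ppivar.experiments` drives the full stack on generated worlds:

* *Mixture recovery* — 40 replicate worlds (12 families × 4 single-copy
  observations, modes 0.8/0.2); per world the D-SameSeq mass below fps
  0.5 is compared with 2p(1−p) via a 99% percentile bootstrap CI over the
  per-family values (2,000 resamples).  The CI level and world size were
  fixed in advance to make the bootstrap over 12 exchangeable groups
  reliable.
* *Homomer filter direction* — worlds rich in homomer topologies and
  multi-copy assemblies; after sequence-mode filtering the top-bin mass
  must not fall and the below-0.5 mass must not rise at any level.
* *Copy-number effect* — the realized D-SameSeq below-0.5 mass rises as
  the copy-number distribution moves from all-1 to all-2.

`scripts/acceptance.py` reruns these plus the worked example, the
best-match toy, the oracle-equivalence checks and a byte-level
determinism check, and writes the numbers as JSON.  Problem sizes (40
worlds, 12 families, 100 point sets) keep the full script to about a
minute on one CPU.

## Numerical choices and degenerate inputs

* dASA positivity threshold 0.1 Å²: quadrature is deterministic but
  discretized; sub-0.1 Å² differences are noise at 960 points.
* The rule-2 candidate search radius is 12 Å; mutual occlusion of heavy
  atoms is geometrically impossible beyond ~9 Å, so this bound changes
  nothing while keeping the neighbor search sparse.
* Chains without resolved atoms raise an annotation error and the dimer
  is skipped with a logged reason; unresolved residues stay in SEQRES but
  never enter geometry.
* Ties: best-match filtering retains ties; receptor choice ties break by
  accession; rule-2 distance ties break by the smaller residue index;
  subsampling under caps keeps the original group order after a seeded
  unordered draw.
* All randomness in a run flows from one seed (world generation, caps
  subsampling, bootstrap), which is why reruns are byte-identical.

## Known limitations

* The identity-fallback mapping is a stand-in for a real sequence-database
  search; it assumes reference sequences are provided and uses plain
  identity, not an E-value model.
* Further similarity measures found in the literature (sphere radius
  ratio, convex hull overlap, interface position similarity, CAPRI f_nat)
  and cross-correlation analyses between measures are out of scope; so
  are GO-term enrichment and automated assembly prediction.
* Absolute percentages from PDB-wide surveys are not reproducible from
  synthetic worlds and are not targets here; the package validates
  definitions, estimators and directions of effect.
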