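# Methods

This note records the models, parameter choices and numerical decisions
behind `rotasuite`, and what the synthetic study does and does not show.

## The rotamer catalog and family schemes

The packaged catalog (`rotasuite/data/rotamer_table.tsv`) lists the 46
consensus RNA backbone suite rotamers with mean torsions, circular spreads
and frequency weights, transcribed (rounded to whole degrees) from the
published consensus rotamer table; the four most-frequent representatives
of the δδ pucker families (`1a`, `1b`, `2a`, `2[`) are verbatim, and the
remaining rows are best-effort values consistent with the family structure
and the modal torsion peaks (δ ≈ 81–86° for C3′-endo vs ≈ 144–148° for
C2′-endo; γ and α in their gauche+/trans/gauche− wells).  The family map
(`family_map.tsv`) is the published grouping verbatim: 22 (δδαγ), 10
(δδα), 10 (δδγ), 7 (αγ) and 4 (δδ) families, plus the two binary A-form
splits.  Where the published table's caption and body disagree on one
A-form-related member (`6b` is not among the 46 ids), the body (`6d`) is
followed.

Nearest-rotamer assignment uses unweighted circular Euclidean distance
over the seven torsions; ties break toward higher catalog frequency, then
lexicographic id.  An option scales per-angle differences by catalog
spreads; there is no outlier rejection by default (an optional
max-distance threshold flags suites as unassigned).  Sampling wrapped
normals at catalog spreads and re-assigning returns the generating rotamer
for ≈97 % of draws; the remainder is tail overlap between genuinely
adjacent clusters and is logged, not suppressed.

## Suite extraction

Structures are read with gemmi (PDB and mmCIF).  Torsions follow the
standard nucleic-acid atom quadruples (α = O3′(i−1)–P–O5′–C5′ and so on),
reported on [0, 360) and signed per the IUPAC convention (cross-checked
against gemmi's dihedral).  One suite is built per consecutive residue
pair whose O3′(i−1)–P(i) distance is within 2.0 Å; chain breaks,
unobserved residues and missing backbone atoms drop the affected suite
with a logged warning.  By default only the first model of an NMR ensemble
is used (the conventional lowest-energy representative); a flag extracts
all models.  Modified/HETATM nucleotides are skipped; residue numbers are
the file's author numbering.

## Rigid-geometry conformer sampling

Each of the 16 dinucleotide templates is generated programmatically from
standard bond lengths and angles as a NeRF construction tree (heavy atoms
only; idealized planar bases).  A rigid rotation about a torsion's middle
bond moves the downstream subtree, conserving every tree bond length and
bond angle to machine precision.

One geometric compromise is intrinsic to this representation: a rigid
rotation about C4′–C3′ (the δ torsion) is incompatible with a closed
five-membered ribose ring.  The ring is therefore built with a *soft*
O4′–C1′ closure — not a tree edge — whose length flexes between ≈1.4 and
≈1.7 Å across the C3′-endo…C2′-endo δ range (branch torsion offsets were
solved numerically at the pucker midpoint δ = 115°).  The closure still
counts as a bond in the clash-exclusion topology.  Because intra-residue
geometry is either invariant under suite-torsion rotation or distorted by
this soft closure, clash detection scores only inter-residue atom pairs;
within that set, pairs ≤3 bonds apart are excluded and a clash is any
distance below 0.7 × the sum of van der Waals radii (C 1.70, N 1.55,
O 1.52, P 1.80 Å).  Glycosidic geometry (the torsion placing the base
nitrogen and the base-plane spin) uses anti-region defaults chosen so the
common rotamers' mean conformations are clash-free on all templates.

Sampling draws each torsion independently from a wrapped normal with the
catalog mean and spread — the simplest distribution consistent with a
mean/spread table; no joint model is attempted — rejects clashing
conformers, and stops at the target count or after 100× attempts (then
returns a flagged partial set).  Runs are reproducible for a fixed seed.

## Entropy-based subsample size

Conformer-set entropy is the **sum of the seven marginal per-torsion
histogram entropies**, S = −Σ pᵢ ln pᵢ over fixed 5° bins.  A joint 7-D
histogram at this bin width is essentially unpopulated at sample sizes
below ~100, so the marginal sum is the only operable reading; the choice
is isolated behind `shannon_entropy`/`entropy_curve`.  The subsample size
is the smallest n whose mean entropy over replicate subsamples reaches
80 % of the full pool's entropy — around a few tens of conformers per
rotamer at catalog spreads, hence the default of 40 retained conformers
per rotamer and sequence.

## Shift referencing

δ<sub>comp</sub> = σ<sub>ref</sub> − σ<sub>comp</sub> with the scalar
σ<sub>ref</sub> = 185.00 ppm (near the theoretical TMS shielding) as the
simple convention.  Four effective-reference refinements are fittable from
paired theoretical/experimental records: per base sequence, per δδ pucker
family, per carbon nucleus (each via the moment-matching estimate
σ<sub>ref</sub>(cell) = mean(σ<sub>comp</sub> + δ<sub>exp</sub>)), and a
least-squares regression of δ<sub>exp</sub> on σ<sub>comp</sub>.  Cells
with fewer than two pairs fall back to the scalar.

## The synthetic shielding generator

The generator replaces quantum-chemical shielding computation, which is
out of scope at desk scale.  Its defaults encode the effect hierarchy the
classification stage is meant to expose, as the generator's ground truth:

* baseline shieldings per nucleus (93, 110, 112, 103, 122 ppm for
  C1′–C5′ — roughly 185 minus typical ribose shifts);
* **dominant** δδ pucker-family offsets of a few ppm (pairwise family
  separation ≥ ≈3.8 ppm in the 5-D nucleus space);
* **weak** smooth α/γ dependence (cosine series, ≲0.5 ppm) — so rotamers
  within a pucker family are barely separable;
* additive sequence offsets (±0.5 ppm scale, with a 0.3-weighted echo of
  the preceding base) — so sequence-aware features help;
* Gaussian theoretical noise (sd 0.3 ppm).

The experimental-like transform adds i.i.d. Gaussian noise of sd 1.47 ppm
per nucleus — the magnitude of the expected theory-vs-experiment
discrepancy — and can subsample records per rotamer to mimic the sparsity
of experimental archives (e.g. zeroing 8 rotamers leaves the 38
experimentally represented ones).  Noise independence across nuclei is an
assumption; only the magnitude is constrained by prior knowledge.

What passing tests show — and do not.  The generator makes the pucker
hierarchy true *by construction*, so the reproduced orderings
(F1(δδ families) > F1(46 rotamers) for every classifier; monotone
degradation with noise; sparsity lowering weighted accuracy; A-form vs
rest no better than chance beyond pucker) validate the *pipeline*, not the
physics: real shielding surfaces, conformational averaging, ring-current
and solvent effects are not modelled, and absolute scores on real data
will differ.

## ROSUM and scoring

W[a,b] = exp(−d(a,b)²/2λ²) with d the circular torsion-space distance
between rotamer means; λ defaults to the median off-diagonal distance
(auto bandwidth).  Family matrices use frequency-weighted mean pairwise
member distances.  The diagonal is exactly 1; the kernel's limits are the
identity (λ→0) and the all-ones matrix (λ→∞).  Rotamer frequencies enter
through the random baseline — the expected weighted accuracy of a
classifier drawing labels from the catalog frequency distribution —
reported alongside every score rather than baked into W, keeping the
matrix interpretable.  Precision/recall/F1 are support-weighted
(scikit-learn), with zero precision for predicted-only labels.

## Classification

Features are the five shifts standardized with training-set statistics
only, plus a 16-column one-hot dinucleotide encoding (dimension 21; 5
without sequence).  Classifiers: k-NN, decision tree, random forest, a
small MLP and an RBF SVM, plus the frequency-weighted random baseline.
Default sweep grids are deliberately small and documented: k ∈ {1,3,5,7},
tree depth ∈ {3,10,∞}, 100 trees, one hidden layer ∈ {10,50}, C ∈ {1,10}.
Regimes: train-theoretical/test-experimental (single fit), and
leave-one-out within one dataset (one suite held out per iteration; the
scaler refits inside every fold).  All randomized components take derived
seeds, making LOO runs bit-reproducible.

## Problem sizes

The packaged demo and the test suite run the study at reduced scale — 10
rotamers × 2 sequences × 40 conformers (800 records) for the ordering
checks, smaller sets for LOO determinism — which keeps the full suite in
the minutes range on a single core while leaving every qualitative
conclusion intact; full-scale runs (46 rotamers × 16 sequences) are a
configuration change, not a code change.

## Known limitations

* The 42 non-representative catalog rows are consensus-consistent
  reconstructions, not verbatim transcriptions; analyses that depend on
  fine inter-rotamer geometry should load a user-supplied table
  (`load_catalog(rotamer_table=...)`).
* The soft ribose ring closure distorts intra-residue geometry at
  C2′-endo δ values; intra-residue contacts are therefore not scored in
  clash elimination.
* The ROSUM kernel form and bandwidth are package choices (the original
  matrix construction is not fully specified in public sources); both are
  configurable.
* Base geometry is idealized (regular rings); sufficient for steric bulk,
  not for stacking energetics, which the sampler does not attempt.
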