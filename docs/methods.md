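# Methods

## Atom representation and typing

Atoms are represented qualitatively by semicolon-joined attributes: element
symbol, explicit valence (total bond order including hydrogens),
heavy-neighbour count, attached-hydrogen count, (optionally aromaticity,) and
ring membership. The six-element variant keeps the aromaticity flag; the
five-element variant — used by both distance-aware feature families — drops
it, on the grounds that aromaticity is nearly redundant with ring membership.

**Protein side.** Protein atoms are typed by a dictionary keyed on (residue
name, PDB atom name), so a protein structure needs neither hydrogens nor
chemical perception. The shipped dictionary
(`assets/protein_types.tsv`, 167 entries) is derived with RDKit from capped
ACE-X-NME models of the 20 standard amino acids
(`scripts/build_assets.py`) under fixed, single-state conventions:

* aspartate/glutamate carboxylates deprotonated (physiological pH);
* lysine and arginine protonated (arginine drawn with the formal charge on
  NH1);
* histidine neutral in the ε-tautomer — hydrogen on NE2, none on ND1 — so
  HIS-NE2 types as `N;3;2;1;1`;
* cysteine as the free thiol; one conformer-independent state per residue.

These conventions yield 20 distinct six-element protein types. Atoms with no
dictionary entry (non-standard residues, metals, terminal OXT) produce no
features; waters, HETATM records and altlocs other than ''/'A' are excluded
at load time.

**Ligand side.** Ligand atoms are typed from RDKit's perception of the SDF
bond block; the protonation/tautomer state is taken exactly as written in the
file (no pKa adjustment). Explicit and implicit hydrogens are equivalent: the
loader uses total valence and total hydrogen counts. The shipped ligand type
list (`assets/ligand_types.tsv`) enumerates 77 chemically realizable
heavy-atom environments over C/N/O/S/P/B/halogens; every entry carries a
*witness* molecule (SMILES plus atom index) that realizes it, validated at
asset-build time. Ligand atoms whose environment falls outside the list are
skipped with a warning rather than an error.

## The pair vocabulary

The feature space is the full cross product of the protein and ligand type
lists, ordered lexicographically (protein-major); the order is part of the
output contract. The six-element vocabulary has 20 × 77 = **1540** pairs, the
published dimensionality. Dropping the aromaticity flag merges environment
pairs that differ only in that flag (for example pyridine-type
`N;3;2;0;1;1` with cyclic-imine `N;3;2;0;0;1`); nine ligand environments
merge this way, so the five-element vocabulary deduplicates to 20 × 68 =
**1360** pairs. We treat the merge as the semantic point of removing
aromaticity (a piperidine NH and a pyrrole NH become the same feature) and
document the reduced dimensionality rather than padding the list to preserve
a nominal 1540.

Because the original reference type lists are not redistributable here, the
shipped lists are reconstructions: the protein dictionary from first
principles as above, the ligand list as a curated enumeration. Exact type
membership may therefore differ from other implementations; the dictionary
semantics, the pair-space construction and the printed worked-example types
are preserved.

## Feature families

Let d_ij be the Euclidean distance between protein atom i (type X) and ligand
atom j (type Y), and keep pairs with d_ij ≤ t (threshold inclusive).

* **Counts (classic ECIF):** f[X–Y] = #{(i,j) : d_ij ≤ t}; default t = 6 Å,
  six-element variant.
* **Multi-shelled counts:** a shell scheme is the ordered bound list from a
  minimum shell (default 2.5 Å, below which contacts are vanishingly rare), a
  constant step, and the threshold; the terminal shell is capped at the
  threshold and may be narrower. Shells are half-open (lower, upper]; the
  first shell is (0, min_shell]. Feature `X–Y-b_k` counts contacts in shell
  k. Defaults: t = 10 Å, step 2 Å → bounds 2.5/4.5/6.5/8.5/10.0, five-element
  variant (1360 × 5 = 6800 interaction features).
* **Weighted sums:** f[X–Y] = Σ 1/d_ij (or 1/d_ij² with `squared=True`, the
  default); t = 10 Å, five-element variant. Zero distances are an error
  (training corpora exclude sub-2 Å contacts as artifacts).

Boundary conventions (threshold inclusive; shell upper bound inclusive) are
not discriminated by the printed worked examples, so they are fixed here and
tested. Pair enumeration is an exact vectorized all-pairs distance
computation (`scipy.spatial.distance.cdist`) — no neighbour-grid pruning is
needed at binding-site sizes — and unit tests compare it against an explicit
double loop.

Ligand descriptors: the RDKit `Descriptors` catalog is computed per ligand
(non-finite results recorded as null); a retention filter drops descriptors
with zero variance, any null, or any magnitude above an `extreme_bound`
(default 1e8 — large enough to touch only numeric-overflow artifacts such as
the information-content indices on big molecules). Because the catalog drifts
across provider versions, the default retained list is a versioned asset
(181 names) regenerated from a packaged 62-molecule drug-like corpus, not
recomputed at run time; the filter is exposed to regenerate it from any
training corpus. Assembled vectors are interaction features first, then
retained descriptors.

## Models and validation protocol

Gradient-boosted regression trees (scikit-learn) with least-squares loss
predict pK. Published best hyperparameters are exposed as defaults:

| family | stages | depth | learning rate | subsample | min split | max features |
|---|---|---|---|---|---|---|
| multishell | 20 000 | 10 | 0.005 | 0.6 | 3 | sqrt |
| weighted | 30 000 | 10 | 0.005 | 0.6 | 2 | sqrt |
| ecif_baseline | 20 000 | 8 | 0.005 | 0.7 | 2 | sqrt |

These stage counts assume ~9000-complex corpora; tests and examples use
reduced configurations (30–500 stages on 60–500 synthetic complexes) chosen
to finish in seconds-to-minutes while leaving the learning signal
recoverable, and the config object keeps the scaling explicit.

Cross-validation: k-fold (default 10) repeated over trials (default 10) with
per-trial seeds; fold assignment is shuffled indices split into contiguous
blocks, unstratified. The per-trial mean of Pearson's R / RMSE is the unit
for comparing conditions. A two-stage grid-search utility scans
{stages, learning rate, depth} first, then
{min split, max features, subsample} at the stage-one optimum. Models are
persisted with joblib together with their config and exact feature-name
order; prediction aligns columns by name and rejects missing names.

## Evaluation machinery

* **Scoring power:** Pearson's R and RMSE; undefined-R (zero-variance) inputs
  are an error, not a silent NaN.
* **Enrichment factor:** top set of size ceil(fraction·n) on the descending
  score ranking (higher predicted pK = better), ties broken by stable input
  order; EF = top-set active rate ÷ overall active rate. Per-template EFs are
  aggregated as mean and sample SD (single template → SD 0). A random ranking
  has expected EF 1, verified by Monte-Carlo calibration.
* **Bootstrap comparison** of two prediction vectors on one test set:
  complexes (rows) are resampled with replacement (default 10 000
  replicates); per replicate both metrics are computed for both models, and
  the replicate distributions are compared per metric by two-sided
  Mann–Whitney U with Cliff's delta (derived from the U statistic) as effect
  size.
* **Seed-ensemble comparison** of two per-seed metric samples: independent
  two-sample t-test, Bonferroni correction (p × number of comparisons, capped
  at 1), pooled-SD Cohen's d.
* **Permutation importance:** scikit-learn's permutation_importance (mean
  score drop over 30 shuffles by default), with an exact-zero guarantee for
  features the model never uses.
* **Per-shell ablation:** models trained on single distance bands of a
  multi-shelled table (no ligand descriptors), compared by repeated-seed CV,
  to rank shells by contribution.

All stochastic procedures take explicit seeds and are bit-reproducible.

## Synthetic data: what it emulates and what it does not

`make_toy_complex` realizes requested typed contacts exactly: protein atoms
are emitted as isolated residues whose names select the dictionary type
(typing is by dictionary, so geometry is free), and ligand types are realized
by witness fragments whose non-witness atoms are parked hundreds of Å away —
bond lengths in the file are deliberately unphysical, which is sound because
chemical perception reads the bond block, not coordinates. Clusters are
spaced 40 Å apart, so enumeration recovers exactly the requested pairs
(verified to 1e-3 Å, the PDB coordinate precision). This validates the
featurization arithmetic, not pose realism: toy complexes have no packing,
no chains, no competing contacts.

`make_regression_dataset` produces sparse non-negative count columns plus
dense descriptor-like columns, with pK a linear-plus-mild-interaction
function of a few informative columns and Gaussian noise (defaults: informative
counts ~ Poisson(2), background ~ Poisson(0.25), noise SD 0.5 pK at n = 500
for recovery checks). Passing tests show the learning and importance
machinery recovers planted signal at this signal-to-noise; they do not show
that real binding data carries such signal.

Consequently, corpus-scale results — scoring power near R ≈ 0.88 on a
285-complex crystal benchmark, screening enrichment on real targets, and the
empirical ranking of distance shells — depend on external datasets
(PDBbind-derived training sets, LIT-PCBA) and corpus-scale training, and are
explicitly not asserted by this repository's tests.

## Numerical and degenerate-input choices

* Shell bounds are accumulated with rounding to 9 decimals so thresholds like
  10.0 with step 2.0 terminate exactly; bound rendering always keeps a
  decimal point (`6.0`, not `6`).
* A distance above the scheme threshold inside the shelled featurizer is an
  internal-consistency error, not a silent drop.
* Empty pair lists yield all-zero vectors of full vocabulary length.
* Degenerate shell schemes (terminal shell narrower than the step, or
  threshold barely above the minimum shell) are supported and tested.
* An all-constant pK trains to a constant predictor; zero-variance inputs to
  correlation metrics raise.
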