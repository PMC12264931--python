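# Methods

This note documents the models, defaults and numerical choices behind
`molaudit`, and what the synthetic study conditions do and do not show.

## Bond perception and filtering

Atoms i, j are bonded iff d(i,j) ≤ f·(rᵢ + rⱼ) with covalent radii from the
Cordero-style single-bond compilation (shipped in `periodic.py`) and factor
f = 1.3, the value appropriate for chemically diverse sets (it cleanly
separates H–H at 0.74 Å, threshold 0.806 Å, from non-bonded contacts).
Bond orders and aromaticity are assigned by RDKit's connectivity-based
bond-order determination; a molecule whose perception leaves unpaired
electrons or fails valence rules is flagged invalid and excluded from all
denominators, mirroring how unparseable canonical SMILES are excluded in
practice. The set filter removes, in order: bond graphs with more than one
connected component, invalid molecules, and canonical-SMILES duplicates
(first occurrence kept). Duplicate identity is canonical SMILES by design:
molecules that cannot be canonicalized cannot be deduplicated and are
dropped beforehand. The filter is idempotent.

One perception contract (RDKit's aromaticity model) is fixed throughout;
counts involving "aromatic" differ by a few percent across toolkits and no
attempt is made to reconcile them.

## Two-sample tests

Welch's unequal-variance t (Welch–Satterthwaite df, two-sided) and the
two-sample Kolmogorov–Smirnov test are applied to headline scalar
distributions (molecular weight by default). Both are delegated to SciPy;
tests in the suite verify them against the closed-form statistic, a 10⁵
permutation oracle, and a brute-force ECDF supremum. No multiple-testing
correction is applied: the audit runs the two tests on single headline
comparisons. Binning defaults: atom counts at width 1, molecular weight at
10 g/mol, bonded distances at 0.02 Å over [0.8, 2.2] Å — fine enough to
resolve the single/double/triple C–C peaks near 1.54/1.33/1.20 Å.

## Structural (SOAP-style) descriptor

Each atomic environment is a species-resolved Gaussian neighbor density
(width σ, the central atom included) truncated at a radial cutoff, expanded
in an orthonormal polynomial radial basis gₙ(r) ∝ (r_c − r)^{n+2}
(orthonormalized through the analytic overlap with weight r²) and spherical
harmonics. The rotation-invariant power spectrum

  p^{Z₁Z₂}_{n₁n₂l} = π √(8/(2l+1)) Σₘ c^{Z₁}_{n₁lm} c^{Z₂*}_{n₂lm}

is averaged over atoms to give one vector per molecule. Expansion
coefficients are analytic up to a 64-node Gauss–Legendre radial quadrature,
using the modified-spherical-Bessel expansion of an off-center Gaussian;
the on-center term reduces to the l = 0 channel (i_l(0) = δ_{l0}), which is
what the single-atom closed-form test checks. The construction is exactly
invariant to rigid motion and atom reindexing and additive over fragments
separated beyond the cutoff (per-atom averaging).

Defaults: cutoff 5.0 Å, n_radial 8, l_max 6, σ 0.3 Å. The audit pipeline
defaults to a lighter setting (cutoff 4.0 Å, n_radial 4, l_max 3) — for
latent-map purposes only the leading principal component is consumed, and
the PC1 structure is stable under the heavier setting; users studying
descriptor detail should raise the resolution in `AuditConfig`.

## Bonding descriptor

An explicit, versioned feature schema (the feature list is the source of
truth): per-element counts; bond counts per (element pair × bond type in
{single, double, triple, aromatic}); SSSR ring counts per (size 3–8 ×
class in {aromatic, unsaturated-aliphatic, saturated}); functional-group
match counts from the SMARTS catalog; and four global scalars (molecular
weight, heavy-atom count, hydrogen fraction, rotatable bonds). With the
default 16-element alphabet (that of diverse organic crystal databases) and
the 42-group catalog the schema has ~620 features; the audit narrows the
alphabet to the elements actually present in the data. A ring is aromatic iff all its bonds are aromatic, saturated iff
it has no multiple or aromatic bond, otherwise unsaturated-aliphatic; the
three classes partition the SSSR count by construction.

## Latent map, KDE, clustering

Independent PCAs are fit per descriptor on the concatenation of all sets
under comparison, and every molecule is mapped to (structural PC1 score,
bonding PC1 score); later sets are projected through the *stored* means and
loadings, never refit, so maps remain comparable. Further components are
stored but unused. The 2D KDE uses a diagonal Gaussian kernel with Scott's
rule per axis (σ_k·n^{-1/6}), evaluated on a regular grid padded by three
bandwidths so the surface integrates to 1 within 2 %. Clustering is BIRCH
followed by agglomerative merging of the subclusters to the requested count
(default 25); the BIRCH threshold starts at half the mean per-axis spread
and is halved until the subcluster stage yields at least 4× the final
cluster count, so the merge stage can produce clusters of different sizes.

## Corrective samplers

*Histogram matching*: with reference bin probabilities p_b over an integer
key (atoms per molecule) and source availabilities a_b, the scale
s = min_{p_b>0, a_b>0} a_b/p_b is the largest sample size preserving the
reference shape; each bin contributes ⌊s·p_b⌋ molecules drawn uniformly
without replacement. Reference bins with no source molecules get quota 0
with a coverage warning. Per-bin deviation from the scaled reference is
bounded by 1 (flooring only). Note the scale is a minimum over bins, so on
small sets with long-tailed keys the yield can be a small fraction of the
source — the same behavior seen when matching tens of thousands of
generated molecules to a training size distribution.

*Grid flattening*: the bounding box of the latent plane is split into an
n_grid × n_grid regular grid (square in index space, each axis scaled to
its own bounds; points on the max edge fall in the last cell) and exactly
one uniformly chosen molecule is kept per occupied cell. The resolution is
chosen by flattening at each candidate, fitting the KDE to the survivors
and minimizing a localization score; the score is the coefficient of
variation of the survivors' self-density — 0 for perfectly even coverage —
a simple, testable operationalization of "lack of spatial localization".
Ties go to the smallest candidate; candidates keeping fewer than 10
molecules are excluded with a warning. Both samplers serialize their
selection as a JSON plan (indices, parameters, seed) and replay bit-exactly.

## Discriminator

One decision tree per depth in 3–17, balanced class weights, trained on the
train split; the depth maximizing validation balanced accuracy is chosen
(shallowest on ties, for interpretability) and reported on the held-out
test split. "Accuracy" is balanced accuracy (mean per-class recall)
throughout — the safer reading given balanced class weights and possibly
unequal set sizes. Splits are stratified: 20 % test, then 90:10
train:validation. Top-5 impurity importances are reported with feature
names. Fingerprint defaults: Morgan radius 2, 2048 bits, count augmentation
(heavy-atom total plus per-element counts) on — augmentation helps when the
size distribution itself is informative and is harmless otherwise.

## Synthetic study conditions

The generator grows a random carbon tree (uniform attachment to open
valences), closes rings between non-adjacent open atoms, substitutes
heteroatoms, promotes C–C bond orders, inserts functional groups
(hydroxyl/amine/thiol; their heavy atoms count toward the drawn size), and
fills remaining valence with explicit hydrogens. Substitution runs on the
single-bonded skeleton *before* unsaturation and draws from the
valence-compatible subset of the element alphabet, so the heteroatom knob
is not silently suppressed at branched or unsaturated sites and the
molecular-weight bias axis responds monotonically to the knob.

Defaults emulate small functional organic molecules: 4–14 heavy atoms with
mode 9 (≈19 atoms with hydrogens); substitution alphabet
N 0.45 / O 0.40 / F 0.07 / S 0.05 / Cl 0.03; heteroatom probability 0.12
per skeleton atom; unsaturation probability 0.15 per C–C bond (applied
again for promotion to a triple); ring-closure probability 0.25 per
attempt; group rates hydroxyl 0.25, amine 0.10, thiol 0.05 per molecule.

`bias_config(cfg, shift)` moves heteroatom and unsaturation probabilities
linearly toward ceilings of 0.85 and ring propensity toward a floor of
0.05; shift 0 is the identity and shift 1 is defined as near-total bias
(almost every substitutable atom heteroatomic, almost every C–C bond
unsaturated) — the scale endpoint at which the two populations are nearly
disjoint in composition. 3D coordinates come from RDKit's ETKDG distance
geometry with an MMFF clean-up; geometry is idealized, not DFT-quality,
but bonded distances land close enough to covalent-radius sums that
perception recovers the intended graph on ≥ 95 % of molecules.

What passing tests show: the pipeline's statistics are exactly what their
definitions say (oracle equivalence), the tests are calibrated under a true
null, and detection power grows monotonically along the injected bias axes.
What they do not show: behavior on real generator output — conformer
quality, tautomers and charge states, elements outside the default
alphabet, and molecules far larger than ~20 heavy atoms are outside the
synthetic conditions.

## Problem sizes and determinism

The statistical suite uses 1000 molecules per side with 1000 repeats for
null calibration, 20 seeds for the discriminator null, and 5 seeds per
level for the power curve; oracle fixtures are ≤ 500 molecules. All
randomness flows from explicit seeds; the audit fans a single global seed
out to per-stage seeds through a fixed `SeedSequence` derivation, so stages
can be re-run in isolation and reports are reproducible modulo one
timestamp field.

## Known limitations

* Aromaticity in the generator only arises when perception re-interprets
  promoted ring bonds; explicitly aromatic growth is not modeled, so
  aromatic-ring prevalence in synthetic sets is low.
* The histogram-matching sampler trades yield for shape fidelity; on small
  or strongly shifted sets the matched subset can be very small, and
  downstream stages then run on few molecules (they warn, not fail).
* The latent map uses only PC1 per descriptor; structure not captured by
  the leading component is invisible to the flattening and clustering
  stages.
* Gold–thiolate chemistry is supported in the catalog and perception
  tables, but the generator does not emit Au-containing molecules.
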