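# Methods

This note documents the models implemented in `nmrens`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that affect results.

## Ensemble statistics

### Unbiased mean structure

For a selection resolving to *n* atoms in each of *M* conformers, the mean
distance matrix `D̄ᵢⱼ = (1/M) Σₘ |xᵢ⁽ᵐ⁾ − xⱼ⁽ᵐ⁾|` is embedded by classical
scaling: `B = −½ J D̄∘² J` with `J = I − 11ᵀ/n`, eigendecomposition of B,
coordinates from the top three eigenpairs. Because a distance matrix
averaged over distinct conformations is generally non-Euclidean, the
spectrum has a negative tail; it is reported in full so embedding quality
can be inspected (for well-ordered selections the top three eigenvalues
dominate by orders of magnitude). Exactly planar inputs embed with a
vanishing third eigenvalue; inputs that are degenerate below two dimensions
(collinear) are rejected, as no meaningful 3-D mean exists.

Classical scaling cannot distinguish enantiomers. The reflection is
resolved deterministically: of the two mirror images, the one with the
lower Kabsch RMSD to the *first* conformer is returned. For any real
protein ensemble the margin is enormous; the choice only matters for
pathological synthetic inputs.

### Superposition and RMSD conventions

Kabsch superposition uses the SVD of the weighted covariance with the usual
determinant correction, so the rotation is always proper; collinear point
sets (rotation not unique) are rejected. No mass or B-factor weighting is
applied anywhere, since none of the quantities reported here conventionally
use it.

"Backbone" means N, CA, C, O by default (the PROCHECK-style convention);
`backbone_no_O` (N, CA, C) is available because published "backbone heavy
atom" figures do not always say whether carbonyl O is included, and the two
conventions differ by a few hundredths of an Å on typical ensembles.
Ensemble RMSD is summarised both as the arithmetic mean and as the rms of
the per-model values, again because published numbers rarely state which
summary was used.

The representative conformer of an ensemble is the one with the lowest
RMSD to the unbiased mean over the analysis selection. Fragment RMSD
between motif copies (e.g. the two CXXCXXC spans, residues 176–182 vs
188–194) is quoted on that conformer, with per-model values available.

## Model-free analysis

### Forward model

Interaction constants: d² from μ₀ħγHγN/(4π r³) with r(N–H) = 1.02 Å, CSA
c² = (ωN Δσ)²/3 with Δσ = −160 ppm. These community-standard values are
`FieldConfig` fields and can be overridden; at the default field
(600.13 MHz ¹H) they give the familiar rigid-limit R2/R1 ≈ 4.2 at
τm = 5.67 ns. Frequencies are kept signed (γN < 0), which places the
J(ωH−ωN) term at |ωH|+|ωN| — the correct assignment for ¹⁵N, and a classic
source of sign bugs when magnitudes are used.

Models 1–5 fix parameters as: 1 = S²; 2 = S², τe; 3 = S², R_ex (τe = 0);
4 = S², τe, R_ex; 5 = S², τe, S_f² (R_ex = 0), with S² ≤ S_f² enforced.
Units at the interface are ns for τm, ps for τe, s⁻¹ for R_ex; SI
internally.

### Fitting and model selection

χ² = Σ[(obs − pred)/σ]² over (R1, R2, NOE) is minimised by a small
projected Levenberg–Marquardt solver within bounds S², S_f² ∈ [0, 1],
τe ∈ [0, τm], R_ex ∈ [0, 50 s⁻¹], started from a deterministic 4-point grid
per free parameter (ties broken by lower χ², then lower model number).
The dedicated solver exists because the selection protocol refits hundreds
of Monte-Carlo draws per residue; it reproduces scipy's bounded
least-squares optima to tight tolerance at a fraction of the overhead.

Selection proceeds 1 → 2 → 3 → 4 → 5. A model with positive dof is
accepted if its χ² is below the α = 0.05 critical value of a seeded
Monte-Carlo null (default 500 draws: data simulated from the fitted
parameters with the record's uncertainties, refitted, χ² quantile taken) —
Mandel-style testing; an analytic χ² null is available as a cheaper
option. Before acceptance, one-parameter nested extensions that retain
dof > 0 are checked by an F-test at α = 0.20; a significant improvement
defers to the larger model. The exactly-determined models 4 and 5 (dof = 0)
fit three observables with three parameters, so an F-test in their favour
is vacuous; they are reached only when all simpler models fail the
goodness-of-fit stage, and are accepted only when they reproduce the data
essentially exactly. If nothing passes, the residue is reported as fitted
to no model — on real data this is the fate of residues whose rates are
inconsistent with any isotropic-tumbling model at the given τm.

Parameter uncertainties come from Monte-Carlo refits around the
back-calculated rates (SD of the refitted parameters; deterministic per
seed; fewer than 50 draws triggers a warning).

### Rate extraction

R1/R2 come from weighted monoexponential fits I(t) = I₀e^(−Rt) at the
conventional delay series (0.1/1/2/4 s and 17–237 ms); a fitted R ≤ 0 is
returned flagged rather than hidden. The heteronuclear NOE is the plain
saturated/reference intensity ratio, negative values passed through (mobile
termini genuinely go negative).

## τm from R2/R1

The per-residue apparent τc solves the rigid-rotor (S² = 1, τe = 0,
R_ex = 0) ratio equation by Brent root-finding on [0.5, 50] ns — the ratio
is monotone on that bracket, and the bracket covers peptides through large
domains (configurable). Filtering is a single pass: first drop NOE < 0.6,
then compute mean and SD of R2/R1 over the survivors and drop
|ratio − mean| > 1 SD (strict, so a zero-SD set keeps everything). The
published description of this filter is one sentence; the
NOE-first/one-pass reading is implemented because it is deterministic and
order-independent, and an `iterate` flag repeats the SD trim to convergence
for sensitivity analysis. τm is the arithmetic mean of the surviving τc;
the spread is reported as both SD and SEM because "±" conventions vary.

## Validation

The Ramachandran grid is a packaged 36×36 text table (10° cells) with four
regions (most favoured / additional / generous / disallowed) built from
Morris-style polygon definitions of the α, β and left-handed-α regions,
with the generous band obtained by dilating the allowed regions 20° on the
torus. It approximates the PROCHECK map rather than copying it; percentages
for residues near region borders can differ from PROCHECK's by a few
points, which is why region definitions are confined to one data file.
Gly, Pro and chain-terminal residues are excluded from statistics, and
ensemble summaries pool classifications over all models.

Zinc-site geometry reports 4 S–Zn bonds, 6 S–Zn–S angles and per-cysteine
Cα–Cβ–S / Cβ–S–Zn (and Hβ–Cβ–S where hydrogens exist) against targets
2.3 Å / 109.5° / 114.3558° / 109.5° / 107.9185°, with default tolerances
0.1 Å for bonds and 5° for angles — the targets are restraint values, and
water-refined structures relax around them, so the tolerance is a
reporting threshold, not a claim about the force field.

Cysteine-to-cluster assignment clusters the ensemble-mean SG–SG distance
matrix (average linkage, cut at two); with eight cysteines any split other
than 4+4 is an error that reports the offending partition. A mean
silhouette score quantifies separation.

## Synthetic generators

Templates are built from ideal backbone internal coordinates (NeRF chain
construction; helix φ/ψ = −57°/−47°, coil drawn from the
favoured+additional Ramachandran regions, seeded). The default construct
mirrors the analysis target: 56 residues numbered 167–222, ordered
segments 175–196 and 208–217, coil loop 197–207 and termini, cysteines at
the two-cluster motif positions. Ensembles add iid Gaussian atomic
displacements with a per-residue σ profile smoothed over a 3-residue
window (defaults 0.3 Å core / 2.0 Å flexible), zinc sites are exact
tetrahedra with optional Gaussian distortion, and relaxation data are
generated from per-residue model-free truth (ordered residues S² ≈ 0.84,
τe 20–50 ps, a few exchange residues with R_ex 2–5 s⁻¹; loop/termini
model 5 with S² 0.3–0.5, S_f² 0.7–0.85, τe 0.8–1.5 ns — parameters chosen
so flexible residues fall below the NOE cutoff at 600.13 MHz, as they do
experimentally) with relative Gaussian noise on R1/R2 (default 2 %) and
absolute noise of the same magnitude on the NOE.

What this does *not* emulate: Cartesian Gaussian perturbation is not
torsion-space sampling, so perturbed ensembles have worse Ramachandran
statistics than real refined ensembles of the same coordinate spread
(restricting to ordered segments still improves the percentages, but the
absolute values are pessimistic); the synthetic template's cysteines trace
the backbone rather than coordinating zincs, so cluster-assignment tests
use the dedicated two-site generator; there is no anisotropic diffusion,
no multi-field data, and no spectral (peak-shape) noise. Passing tests
therefore demonstrate correct recovery under the stated statistical model,
not robustness to every pathology of real data.

## Problem sizes and determinism

All generators and studies are pure functions of their seed. The replicate
study of model selection runs 40 replicates per model class (200 staged
selections, each with 500-draw Monte-Carlo nulls per candidate model) —
sized so the whole verification suite completes in minutes on one CPU while
keeping the binomial uncertainty on a 90 % accuracy threshold at ~5
percentage points. Back-projection exactness uses 30 random clouds of 4–50
points; the Kabsch/quaternion comparison uses 25 random 10-point sets with
a 20 000-orientation search plus simplex polish.

## Known limitations

* Isotropic tumbling throughout; axially symmetric/anisotropic diffusion
  tensors are out of scope, as is fitting τm jointly with internal
  parameters.
* The Ramachandran map is a reconstruction, not PROCHECK's file; absolute
  region percentages carry a few points of map-dependence.
* The τm filter implements the deterministic one-pass reading; iterated
  trimming is available but changes results only for pathological ratio
  distributions.
* Insertion codes, alternate locations beyond 'A', and mmCIF input are not
  supported.
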