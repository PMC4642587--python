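# nmrens

Analysis toolkit for solution-NMR studies of small proteins — written around
the complete computational workflow for a two-zinc CXXC domain: ensemble
statistics about an *unbiased* mean structure, Lipari–Szabo model-free
backbone dynamics from ¹⁵N relaxation, rotational-correlation-time
estimation from R2/R1, and structure validation (Ramachandran regions,
Cys₄–Zn coordination geometry, data-driven assignment of cysteines to zinc
clusters). A synthetic-data module generates ground-truth-known ensembles,
zinc sites and relaxation datasets so every stage of the pipeline can be
exercised and quantified without downloading anything.

It is aimed at structural biologists who have a multi-model PDB ensemble
and/or per-residue ¹⁵N R1/R2/NOE tables and want the standard quantities a
structure paper reports, from a tested, scriptable library rather than a
chain of one-off programs.

## The models and statistics at the core

**Unbiased mean structure.** Conventional mean structures superpose all
conformers on an arbitrary reference first, biasing the mean toward it.
Here the pairwise distance matrix is averaged over the ensemble,
`D̄ᵢⱼ = ⟨|xᵢ − xⱼ|⟩`, and back-projected into Cartesian space by classical
scaling: the Gram matrix `B = −½ J D̄∘² J` (J the centring operator) is
eigendecomposed and the top three eigenpairs give coordinates
`X = V₃ Λ₃^½`. Ensemble RMSDs are per-model Kabsch superpositions onto that
mean, summarised as both the mean and the rms over models.

**Model-free dynamics.** ¹⁵N relaxation is predicted from the spectral
density

    J(ω) = (2/5) [ S²τm / (1 + (ωτm)²) + (1 − S²)τ / (1 + (ωτ)²) ],
    1/τ = 1/τm + 1/τe,

with the extended two-timescale form replacing (1 − S²) by (S_f² − S²), and
the standard dipolar + CSA expressions for R1, R2 (plus an exchange term
R_ex on R2 only) and the heteronuclear NOE. Per residue, models 1–5
(S²; S²,τe; S²,R_ex; S²,τe,R_ex; S²,τe,S_f²) are fitted by bounded
least squares at fixed τm, and the simplest model passing a seeded
Monte-Carlo goodness-of-fit test (with F-tests guarding nested extensions)
is selected.

**Rotational correlation time.** Each residue's apparent τc solves
`R2/R1 (τc) = observed ratio` for a rigid isotropic rotor; residues with
NOE < 0.6, or with R2/R1 more than one standard deviation from the mean of
the remainder, are excluded, and τm is the mean τc of the survivors.

**Validation.** φ/ψ torsions are classified on a packaged four-region
10°×10° Ramachandran grid (Gly/Pro/termini excluded); Cys₄–Zn sites are
measured against tetrahedral restraint targets (S–Zn 2.3 Å, S–Zn–S 109.5°,
Cα–Cβ–S 114.36°, Cβ–S–Zn 109.5°); cysteines are partitioned into two zinc
clusters by average-linkage clustering of ensemble-mean SG–SG distances.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data with known truth. Step 04/05 output, for the default 56-residue
construct (τm truth 5.67 ns, 2 % rate noise):

```
$ python analysis/04_relaxation_and_tauc.py
wrote 56 residues -> results/rates.csv
R1 from decay refits: median |rel err| = 3.96 % over 56 residues
tau_m = 5.576 ns (SD 0.103, SEM 0.019) from 28 residues; truth 5.67 ns -> 1.66 % error
excluded 28 residues: {'low_NOE': 24, 'ratio_outlier': 4}

$ python analysis/05_modelfree_fit.py
fitting 56 residues at tau_m = 5.576 ns
models assigned to 56/56 residues; class counts: {1: 5, 2: 21, 4: 6, 5: 24}
correct model family for 54/56 fitted residues
mean S2 over 175-196: fitted 0.836 vs truth 0.839
mean S2 over 208-217: fitted 0.827 vs truth 0.830
```

Reading: all 24 flexible loop/terminus residues fall below the NOE cutoff
and drop out of the τm average, which lands within 2 % of the generating
tumbling time; model selection assigns the exchange and two-timescale
models to the residues actually generated with them, and the mean order
parameter over each ordered segment is recovered to ±0.003.

The same commands are available ad hoc via the `nmrens` CLI
(`nmrens rmsd`, `nmrens fragrmsd`, `nmrens rama`, `nmrens zinc`,
`nmrens cyscluster`, `nmrens taum`, `nmrens fit`, `nmrens sim-ensemble`,
`nmrens sim-relax`).

## Analysing a real deposit

Every structural routine runs unchanged on a real multi-model PDB file,
e.g. `nmrens rmsd --pdb 4D4W.pdb --residues 175-196,208-217 --atoms
all_heavy`. The test suite contains checks against the published statistics
of the 4D4W ensemble; they require a local copy at `data/4D4W.pdb`
(not redistributed) and fail with a clear message without it.

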