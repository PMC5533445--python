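# bboxnmr

Solution-NMR analysis toolkit for small zinc-binding protein domains such as
the TRIM-family B-box2 (a ~45-residue RING-like ββαβ fold stabilized by
tetrahedral Zn²⁺ coordination).  It reimplements, as a tested and reusable
library, the analysis chain used to characterize such a domain:

* **Backbone ¹⁵N relaxation** — monoexponential fits of R₁ and R₁ρ decay
  series, reconstruction of R₂ from off-resonance spin-lock data via the
  tilted-frame relation
  `R₁ρ = R₁·cos²θ + R₂·sin²θ`, `θ = arctan(B₁/Ω)`,
  heteronuclear NOE ratios, and estimation of the rotational correlation
  time τ_c from R₂/R₁ ratios with a rigid isotropic rotor spectral density
  `J(ω) = (2/5)·S²·τ_c / (1 + (ωτ_c)²)`.
* **Chemical-shift perturbation (CSP) mapping** — the composite amide shift
  change `Δδ_comp = √(Δδ_H² + (Δδ_N/6.5)²)` per backbone or side-chain
  site, significance selection (default cutoff 0.10 ppm), and titration
  trajectories under fast exchange.
* **Shift-based structure inference** — chemical-shift-index (CSI)
  helix/strand/coil classification against a bundled random-coil reference,
  and a configurable logistic score for cysteine Zn²⁺ coordination from
  Cα/Cβ shifts.
* **Zinc-site restraints** — heavy-atom distance-restraint schemes that keep
  a Cys₃His- or CysAspHis₂-type site tetrahedral, NOE restraint
  classification by sequence separation, and violation counting against a
  multi-model ensemble.
* **Ensemble statistics** — Kabsch superposition, average pairwise RMSD,
  ordered-residue detection from Cα RMSF, a reduced (H/E/C) Kabsch–Sander
  secondary-structure assignment, Shrake–Rupley solvent accessibility with
  extended Gly-X-Gly normalization, and single-linkage clustering of
  perturbed sites into surface patches.
* **Synthetic data** — seeded generators for every input class (decays,
  titrations, coordinate ensembles, restraint lists) with known ground
  truth, so the entire chain runs and is testable without any download.

Supported file formats: Sparky-style peak lists, TSV shift tables, a
minimal NMR-STAR subset, multi-model PDB, and CYANA-style `.upl`
upper-limit restraint lists.

## Worked example

Forward-model ¹⁵N rates for a 3.4 ns rigid rotor at 600 MHz, then invert
the R₂/R₁ ratio:

```python
from bboxnmr.relaxation import MotionModel, RateResult, predict_rates, estimate_tauc

m = MotionModel(tau_c=3.4, field_1h=600.0)
r1, r2, noe = predict_rates(m)
print(f"R1 = {r1:.3f} s-1, R2 = {r2:.3f} s-1, hetNOE = {noe:.3f}")

est = estimate_tauc([RateResult(i, r1, 0, 1, 1) for i in range(20)],
                    [RateResult(i, r2, 0, 1, 1) for i in range(20)], 600.0)
print(f"tau_c = {est.tau_c:.3f} ns from {est.n_residues_used} residues")
```

prints

```
R1 = 2.691 s-1, R2 = 6.045 s-1, hetNOE = 0.742
tau_c = 3.400 ns from 16 residues
```

R₁ ≈ 2.7 s⁻¹ and R₂ ≈ 6.0 s⁻¹ are typical of a well-folded ~5 kDa monomer
at 25 °C, the hetNOE of ≈ 0.74 marks rigid backbone amides, and the
estimator recovers the input correlation time exactly (16 of the 20
identical residues survive the default 10% ratio trimming).  Likewise,
`composite_csp(0.06, 0.52)` — a 0.06 ppm proton and 0.52 ppm nitrogen
change — evaluates to exactly the 0.10 ppm significance cutoff.

The same operations are available from the shell, e.g.:

```sh
bboxnmr simulate ensemble --seed 2 --out ens.pdb --length 8 --n-models 3
bboxnmr ensemble-stats ens.pdb
bboxnmr zinc-restraints --site "siteI:92,CYS,SG;95,HIS,NE2;111,CYS,SG;114,CYS,SG"
bboxnmr pipeline --config config.yaml
```

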