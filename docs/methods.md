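# Methods

## Relaxation analysis

Decay series are modeled as `I(t) = I0·exp(−R·t)` and fit by unweighted
least squares, seeded by a log-linear regression on the positive
intensities.  Rate uncertainties come from Monte-Carlo residual resampling
(200 redraws with replacement, fixed seed) rather than from the fit
covariance: for short, 18–19-point decays the resampling estimate is more
robust and, being seeded, keeps every pipeline run bit-reproducible.  The
reduced χ² uses the supplied noise level when one is given, otherwise the
residual variance (in which case it is ≈ 1 by construction and only flags
gross model misfit).

R₂ is reconstructed from rotating-frame data by inverting
`R₁ρ = R₁·cos²θ + R₂·sin²θ` with tilt angle `θ = arctan(B₁/Ω)`, where Ω is
the offset of the ¹⁵N resonance from the spin-lock carrier in Hz (ppm
offset × nitrogen frequency in MHz).  On resonance θ = 90° and R₂ = R₁ρ
exactly; the inversion refuses resonances with sin²θ ≤ 10⁻⁶, where the
spin-lock no longer interrogates transverse relaxation.  Errors propagate
in quadrature.

The forward model for validation and τ_c estimation is a rigid isotropic
rotor: `J(ω) = (2/5)·S²·τ_c/(1+(ωτ_c)²)` entering the standard ¹⁵N
dipolar + CSA expressions for R₁, R₂ and the steady-state NOE.  Constants:
N–H distance 1.02 Å, axially symmetric ¹⁵N CSA of −160 ppm, S² = 1 by
default.  Both constants largely cancel in the R₂/R₁ ratio, which is why
the τ_c estimate is insensitive to them.

τ_c estimation takes per-residue R₂/R₁ ratios, discards the upper and
lower 10% (chemical exchange inflates R₂; fast internal motion depresses
it — trimming handles both without a hetNOE cutoff), and converts the
trimmed mean ratio to τ_c.  The classical single-field closed form
`τ_c = √(6·R₂/R₁ − 7)/(4π·ν_N)` is used as the initial value and then
refined by numerically inverting the forward-model ratio curve, which is
strictly increasing in τ_c.  The refinement matters: the closed form is
biased low by ≈ 2% at 3.4 ns/600 MHz and by > 30% at 1 ns, while the
numeric inversion is exact for rigid-rotor data by construction.  Passing
`refine=False` recovers the pure closed form, whose root at R₂/R₁ = 7/6
maps to τ_c = 0.

## Chemical-shift analysis

Composite CSPs use `√(Δδ_H² + (Δδ_N/6.5)²)`; the nitrogen scale factor is
configurable and setting it to 1 reduces the measure to the Euclidean
norm.  Side-chain amides (e.g. a Trp indole NεH) are tracked as separate
sites under the same formula.  The significance cutoff defaults to
0.10 ppm and is applied inclusively.  Titration trajectories are computed
against the apo point; under fast exchange they must be non-decreasing in
ligand equivalents, so any decrease beyond a user noise floor is flagged.

CSI classification compares observed N/H/Hα/Cα/Cβ/C′ shifts to a bundled
neighbor-uncorrected random-coil table (swappable for any other reference;
no web service is called).  Per-atom deviations are thresholded at
±0.7 ppm for Cα/Cβ and ±0.1 ppm for Hα; downfield Cα and upfield Hα count
as helix evidence, upfield Cα, downfield Cβ and downfield Hα as strand
evidence.  A helix or strand is called only for runs of ≥ 4 consecutive
residues with the same non-coil consensus sign.  Because only differences
enter, a referencing offset applied to both tables cancels.

The cysteine zinc-coordination score is a deliberately simple surrogate
for published shift-based predictors: a logistic function of the signed
distance of a residue's (Cα, Cβ) point along the axis from a
"free-reduced" centroid (59.0, 28.0 ppm) to a "metal-bound" centroid
(58.5, 31.5 ppm), steepness 1.5 ppm⁻¹, value 0.5 on the perpendicular
bisector.  It captures the diagnostic downfield Cβ shift of
Zn-coordinated cysteines and orders candidates sensibly, but the defaults
are not calibrated probabilities and make no claim to reproduce any
specific published values; both centroids and the steepness are
configuration.

## Zinc-site restraints

A zinc site is 2–4 donor ligands (Cys Sγ, His Nε2/Nδ1, Asp Oδ).  The
default scheme emits, per site: one Zn–donor restraint per ligand
(addressed to a Zn pseudo-atom named `ZN`; no explicit metal placement or
tool-specific linker constructs), a donor–anchor tether per Cys (SG–CB)
and Asp (OD–CG), all Cys SG–SG pairs, and every His NE2/ND1–Cys SG pair.
His coordination defaults to Nε2 with Nδ1 selectable per ligand.  All
bounds live in one table (`DEFAULT_ZINC_SCHEME`) and follow common
zinc-site calibrations; they are calibration constants meant to be
overridden to match the downstream structure-calculation force field
rather than measured quantities.  Emission order is canonical, so the
output is independent of ligand listing order.

NOE restraints are binned by sequence separation s = |i−j| into intra
(s = 0), sequential (s = 1), medium (2 ≤ s ≤ 4) and long (s ≥ 5); the bins
are disjoint and exhaustive.  A restraint counts as violated when, in any
model of the ensemble, the distance exceeds the upper bound (or undercuts
the lower bound) by more than the threshold (default 0.5 Å) — the
strictest max-over-models convention, counted per restraint.  CYANA-style
`Q*` pseudo-atoms resolve to the matching proton group and are evaluated
at the group centroid; unresolvable atoms skip the restraint with a
warning rather than failing the run.

## Ensemble statistics

Superposition uses the SVD (Kabsch) construction with a determinant guard
against reflections.  Pairwise RMSD averages over all unordered model
pairs, each pair fitted on the selection being measured; the backbone atom
set is {N, Cα, C} (no O), `heavy` uses all non-hydrogen atoms.
Ordered-residue detection superposes all models onto model 1 on all Cα,
forms the mean structure and thresholds the per-residue Cα RMSF (default
1.0 Å).  This is a deliberately simple stand-in for dihedral-order-based
definitions used by validation suites, and agreement with such tools is
asserted only as set overlap, not identity.

Secondary structure is a reduced Kabsch–Sander assignment: backbone
hydrogen bonds from the electrostatic energy
`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with the
−0.5 kcal/mol cutoff; helices from two consecutive i→i+4 turns; strands
from parallel/antiparallel bridge patterns.  π- and 3₁₀-helices, isolated
turns and bends all collapse to coil — the three-state {H, E, C} output is
all the downstream reporting uses.  Missing amide protons are rebuilt at
1.01 Å along the bisector of the C(i−1)→N(i) and Cα(i)→N(i) directions;
chains break where consecutive residues are non-sequential or the C–N
distance exceeds 2.5 Å.

Solvent accessibility is numeric Shrake–Rupley quadrature with 960 fixed
Fibonacci-spiral points per atom, probe 1.4 Å, heavy atoms only (vdW
radii: C 1.70, N 1.55, O 1.52, S 1.80 Å; unknown elements fall back to
1.70 Å with a warning).  The quadrature error on an isolated sphere is
below 0.5%.  Relative side-chain exposure normalizes by the side-chain
SASA of the residue type in an extended Gly-X-Gly tripeptide built by the
package's own peptide constructor, computed on demand and cached — the
normalization is therefore exactly self-consistent.  Side chains below
15% exposure are flagged buried; glycine has no side chain and reports
NaN, never buried.

Surface patches are single-linkage clusters of significant sites: two
sites link when the minimum heavy-atom distance between their residues,
averaged over models (averaging before clustering keeps the result stable
under ensemble jitter), is at most the cutoff (default 8 Å).  Patches
partition the resolvable sites and the patch count is non-increasing in
the cutoff.

## Synthetic data

All generators are pure functions of (parameters, seed); one ``numpy``
Generator is created per call and no global state is touched.

*Relaxation*: exponential decays with additive Gaussian noise on the
default grids of 19 delays spanning 10–646 ms (R₁-type) and 18 delays
spanning 6–100 ms (R₁ρ-type), matching common 2D-detected experiments.

*Titrations*: the bound fraction comes from the exact 1:1 quadratic
`f = ((P+L+K_d) − √((P+L+K_d)² − 4PL))/(2P)` and observed shifts are
population-weighted (`δ_obs = δ_free + f·Δδ_max`), i.e. strictly fast
exchange.  Defaults follow a typical experiment: 200 µM protein titrated
at 0, 0.25, 0.5, 1.0 and 2.0 equivalents.  Intermediate-exchange line
broadening and slow-exchange peak doubling are not simulated, so passing
titration tests says nothing about regimes where the fast-exchange
population average breaks down.

*Ensembles*: idealized backbones are grown from canonical dihedrals
(helix −57°/−47°, extended −139°/135°) with standard bond geometry; side
chains, when requested, are grafted from ideal residue templates.  The
antiparallel hairpin is built as two extended strands, the second placed
by a deterministic 6-DOF rigid optimization against the intended
inter-strand hydrogen-bond network (H···O 1.90 Å, N···O 2.90 Å at every
other residue pair) — template dihedrals alone do not close the
hydrogen-bond registry of a twisted strand, and the two strands carry a
2-residue numbering gap in place of an explicit turn.  Per-model Gaussian
jitter is parameterized by the per-atom RMS displacement σ (each
coordinate gets σ/√3), so the expected pairwise RMSD of two jittered
copies is √2·σ and a tail σ is directly comparable to an RMSF threshold.
These ensembles have rigid-body disorder only; they do not emulate
correlated loop motions, side-chain rotamer exchange or the
restraint-driven anisotropy of real NMR ensembles, so ensemble-statistics
tests validate the estimators, not the realism of any particular
structure.

*Restraints*: every inter-residue heavy-atom pair within 5.0 Å in model 1
becomes an upper limit at the observed distance + 0.2 Å slack, which makes
the generating model violation-free by construction and lets tests plant
violations with exact arithmetic.

## Pipeline

Stages run in dependency order (I/O → relaxation and shift analysis →
restraints and ensemble statistics); all referenced input files are
checked before any stage runs.  A stage failure is recorded and aborts the
run immediately only in `strict` mode, but any failure makes the run exit
nonzero.  The report carries a provenance block (SHA-256 of the
materialized config with defaults filled in, the seed, the package
version) and serializes to JSON plus per-section TSVs; re-running an
unchanged config reproduces the report byte for byte.

## Problem sizes

The test suite and acceptance script run on deliberately small synthetic
problems: peptides of 8–60 residues, ensembles of 1–10 models, 20 residues
for the τ_c round trip, and 1000 Monte-Carlo seeds for the fit-bias check.
These sizes were chosen as the smallest that make the statistical
assertions sharp; every estimator scales to deposited-ensemble sizes
(20 models × ~700 atoms) in seconds.

## Known limitations

* The τ_c estimator assumes isotropic tumbling and S² = 1 for the retained
  residues; anisotropic diffusion tensors and per-residue model-free
  fitting are out of scope.
* CSI thresholds and the consensus rule are classical conventions, not a
  trained predictor; populations of partial structure are not estimated.
* The zinc score is an uncalibrated surrogate (see above).
* The reduced DSSP omits π/3₁₀ helices, bends and chirality annotations.
* Restraint violation checking treats pseudo-atoms by group centroid, not
  r⁻⁶ averaging.
* NMR-STAR support covers only the atom-shift and distance-restraint
  loops; full NMR-STAR, mmCIF and shift-referencing correction are out of
  scope.
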