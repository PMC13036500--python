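# Methods

This note documents the models implemented in flexens, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## NMR observables

The composite amide chemical-shift difference is
δCS = √(δHN² + (δN/6.51)²) (ppm). The rotational correlation time is
derived from the ¹⁵N T1/T2 ratio, τc = √(6·T1/T2 − 7)/(4π·νN), defined only
above the rigid-limit bound 6·T1/T2 ≥ 7; its uncertainty is propagated to
first order from the T1 and T2 errors (verified against central finite
differences in the tests).

The PRE distance conversion is

    r = [ K/Γ₂ · (4τc + 3τc/(1 + ωH²τc²)) ]^(1/6)

with K = 1.23·10⁻³² cm⁶ s⁻² by default. K is a configurable scalar; its
own uncertainty is excluded from error propagation. At the detection cap of
170 s⁻¹, τc = 11 ns and a 700 MHz ¹H frequency this evaluates to 12.1 Å,
which is why vanished amide peaks are interpreted as "within about 12 Å of
the label". Distance restraints are derived as upl = r + σr and
lol = r − σr with σr from the analytic gradient with respect to Γ₂ and τc;
vanished peaks give upper-limit-only restraints at the cap-equivalent
distance; records whose σr exceeds 50% of r are dropped as unreliable
(logged, never raised).

## Label model and forward predictions

Real spin labels sample a rotamer distribution. flexens abstracts this as a
weighted point cloud per (site, conformer); the registry is pluggable. The
default `gauss_cloud` model draws 64 points from an isotropic Gaussian
(σ = 2.5 Å) centred 7 Å from the attachment Cα along the outward direction
(Cα minus the host domain's Cα centroid). These values mimic the spatial
extent of a nitroxide label's accessible volume; they are not fitted to any
rotamer library. Clouds are seeded per conformer *identity* (provenance
tag), so a sub-ensemble keeps exactly the clouds its conformers had in the
parent pool — this makes noiseless recovery problems exactly representable
by reweighting.

Pair distance distributions accumulate all cross-cloud point distances with
product weights, smoothed by a Gaussian kernel (default σ = 1.0 Å) onto a
uniform grid (module default 10–100 Å, step 0.5 Å). An error is raised if
more than 1% of the predicted mass falls outside the grid. PRE rates use
the r⁻⁶-effective distance over the cloud, r_eff = (Σ p_k r_k⁻⁶)^(-1/6),
converted by the equation above and clipped to the cap *per conformer*; the
ensemble prediction is then an exact linear combination of conformer
predictions. The model treats clouds as static (no internal-motion
correction time); interconversion between conformers during the relaxation
delay is likewise not modelled.

## Reweighting

Both objectives are convex functionals of the linear ensemble prediction.
Weights are parameterized as w = softmax(z); minimization uses L-BFGS-B
from the uniform start (gradient tolerance 1e-8), analytically
differentiated through the EMD's CDF formulation and the χ² residuals.
Because L-BFGS-B's relative-reduction criterion can trigger early on these
stiff objectives, the optimizer is re-invoked from its stall point (which
resets the curvature memory) until the objective stops improving; the
returned objective is never worse than at the start.

Balanced mode first computes EMD_min and χ²_min (each refined from the
other objective's solution as a deterministic multi-start), then minimizes
L = ½(EMD/EMD_min + χ²/χ²_min) − 1 from three deterministic starts. The
normalizing minima are floored at 1e-6 so L stays defined on noiseless
fixtures where both optima are numerically zero; if the balanced solution
itself improves on a recorded minimum, the minimum is updated so the ratio
terms never drop below one. Multi-restraint aggregation is the unweighted
mean EMD across distributions and the pooled mean χ² across PRE residues.
A vanished PRE residue contributes zero when the prediction saturates the
cap and ((cap − pred)/σ)² otherwise.

Pruning removes conformers below 1% of the largest weight and refits once
in the same mode, warm-started from the retained weights, so the reported
figures of merit belong to the reported conformer set. The convergence
curve refits on pool prefixes of one block (default 100 conformers) at a
time; the convergence flag requires the last two rows to agree within 2%
relative (plus a 1e-6 Å absolute slack for near-zero objectives).

## Jackknife and superensemble

Only distance distributions are jackknifed; the PRE set is always retained.
Validation ensembles here are reweighted subsets of one pool, so the
superensemble pool is the exact union of retained conformer sets. Because
the loss of merit is normalized by set-specific minima, L values computed
on different conformer sets are not directly comparable; the superensemble
refit therefore evaluates both the cold refit and the embedded original
solution under the union's normalizers and returns the better one, which
guarantees the refit never degrades the balanced objective under a common
normalization. Uncertainty estimates report mean ± 2·SD (population SD)
of a descriptor across validation ensembles.

## Descriptors

R_g uses Cα atoms only and combines conformers as √(Σ w_c R_g,c²). D_kl is
the RMS difference of all internal Cα–Cα distances (superposition-free; a
stride option subsamples for large systems). The abstract-conformer-space
embedding is classical MDS: double-centre the squared D_kl matrix,
eigendecompose, truncate negative eigenvalues to zero. R_g,ACS is the
*weighted* radius of gyration of the embedded points — weighting keeps the
descriptor consistent with the weighted real-space R_g. Contacts use a 3 Å
minimum atom-pair cutoff and report population fractions as summed
conformer weights (formatted to one decimal percent). Binding poses pass
when the shortest motif-to-domain atom distance is below 7.5 Å.
Merged-pool clustering uses average linkage on D_kl, cut to about 12
conformers per cluster; cluster-class populations are normalized within
each source ensemble.

## Multi-state modelling

The engine fixes domain 1 in the laboratory frame and gives domain 2 one
rigid-body transform per state; the linker enters only as a closure
constraint (anchor gap ≤ (n_linker + 1)·3.8 Å). Label positions are cloud
centroids fixed in the host domain's frame. Each restraint is scored
through the r⁻⁶ state average D* = (Σ dᵢ⁻⁶)^(-1/6) with quadratic penalty
v² on bound violations; all states have equal population.

The search is simulated annealing over all state transforms: proposals
rotate one state by up to 15° about its linker anchor (closure-preserving),
translate it by up to 2 Å, or — with 3% probability — re-place it entirely
(a basin-hopping move; the landscape has near-degenerate alternative poses
when the far state contributes almost nothing through r⁻⁶ averaging).
Geometric cooling runs from 1.0 to 0.01 score units over 10⁴ steps; three
independently seeded cycles are run and the best is polished by a bounded
derivative-free (Powell) minimization with a quadratic closure penalty.
States whose anchor gap exceeds 0.8 of the closure bound are flagged
elongated. The state-count scan selects the smallest N whose best score is
within 5% of the overall minimum and has no elongated states — elongated
states are how the engine "parks" superfluous copies, so their appearance
marks an over-specified N. With bounded optimization effort the *found*
scores are not guaranteed monotone in N even though the true optima are
nested; the scan therefore judges adequacy by the plateau rule rather than
strict monotonicity.

## Synthetic generator

The generator defines the study conditions: two rigid domains of 70
residues each, modelled as Cα beads drawn once per system from a 10 Å-radius
ball (attachment residues swapped to the most exposed points); a 30-residue
linker resampled per conformer as a 3.8 Å fixed-bond random chain grown
bead-by-bead with a 3.0 Å soft self-avoidance check against non-bonded
beads and domain 1; domain 2 placed at the linker end with a random
orientation and a 3.0 Å clash check against domain 1. Three label sites
per domain plus one linker site; acquisition scalars τc = 11 ns and a
700 MHz ¹H frequency; a 170 s⁻¹ cap. Default noise: distribution density
noise of 5% of the peak (clipped at zero, renormalized; confidence bands at
±2σ) and PRE noise of max(2 s⁻¹, 5% of Γ₂), with the same σ reported as the
error column (floored at 1 s⁻¹ when a fully noise-free specification is
used, so χ² stays defined). The generator's manifest grid is 0–120 Å: the
linker can stretch past 100 Å and label clouds of adjacent domains can
approach a few Å, so the generator must cover its own support.

What the synthetic benchmarks show: that the estimators are correct and
that the full pipeline recovers a known truth when the truth is inside the
pool and the forward model is exact. What they do not show: robustness to
rotamer-library mismatch, label-induced conformational perturbation,
internal label dynamics, or force-field realism — none of which the bead
model contains. Side chains are absent by design (R_g, D_kl and the label
clouds never need them) and amide positions are approximated by Cα beads
for PRE targets; for all-atom models with backbone N/CA/C, amide protons
can be reconstructed geometrically (1.01 Å along the negative N→CA/N→C(prev)
bisector).

## Problem sizes and numerical choices

The recovery benchmark uses a 200-conformer pool containing a 20-conformer
Dirichlet-weighted truth, 8 distance distributions and 2 PRE sites; the
jackknife demonstration uses an 80-conformer pool with a 10-conformer
truth. These sizes are large enough that the fits are non-trivially
underdetermined yet complete in about a minute on one CPU. Distribution
tables carry a mandatory header; all coordinates and distances are in Å,
times in s, rates in s⁻¹; manifest frequencies are given in MHz and
converted once at load. Degenerate inputs (all-zero densities, non-uniform
grids, topology mismatches between PDB models, labels placed on top of
their target) raise structured errors rather than propagating NaNs.

## Known limitations

- The label cloud is a geometric stand-in, not a rotamer library; absolute
  EMD values against real DEER data would include a 2–3 Å modelling error
  that the synthetic benchmarks do not exhibit.
- PRE back-calculation ignores internal label motion and
  conformer-interconversion during the relaxation delay.
- The multi-state annealer is a desk-scale rigid-body engine, not a
  torsion-angle dynamics program; linker coordinates are not rebuilt after
  annealing and same-frame restraints are constant by construction.
- Ensemble-similarity scoring between independently generated ensembles is
  out of scope; conformer identity is tracked by provenance tag, and
  coordinate-level deduplication is not attempted.
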