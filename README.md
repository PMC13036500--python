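# flexens

Integrative ensemble modelling of flexibly linked tandem protein domains
from EPR distance-distribution restraints (DEER) and NMR paramagnetic
relaxation enhancements (PRE).

## The scientific problem

Many multi-domain RNA-binding proteins carry two folded domains joined by an
intrinsically disordered linker. Such proteins do not adopt a single
conformation in solution: the domains sample a broad distribution of
relative arrangements, and binding may only partially order them. A single
"structure" is the wrong model — the object to infer is a *conformational
ensemble*: a set of conformers with population weights.

Two complementary restraint classes inform such ensembles:

- **DEER distance distributions** between pairs of spin labels report
  directly on the *width* of the ensemble in the ≈15–100 Å range. Each
  restraint is a full probability density P(r), not a mean value.
- **PRE rates** Γ₂ = R₂,para − R₂,dia scale as r⁻⁶ with the electron–proton
  distance and probe the short-range regime (≈12–25 Å). A peak broadened
  beyond detection marks a distance of about 12 Å or less; such rates are
  capped at 170 s⁻¹. The distance conversion is

      r = [ K/Γ₂ · (4τc + 3τc/(1 + ωH²τc²)) ]^(1/6),

  with K = 1.23·10⁻³² cm⁶ s⁻², τc the rotational correlation time obtained
  from ¹⁵N T1/T2 as τc = √(6·T1/T2 − 7)/(4π·νN), and ωH the ¹H Larmor
  frequency.

## What the package does

1. **Forward models** (`flexens.labels`): spin labels are pluggable point
   clouds; pair distributions come from all cross-cloud distances smoothed
   by a Gaussian kernel; PREs from r⁻⁶-effective distances, converted by
   the equation above and clipped to the 170 s⁻¹ cap per conformer.
2. **Ensemble reweighting** (`flexens.reweigh`): conformer weights w on the
   probability simplex are fitted so the linear ensemble prediction
   Σ w_c pred_c matches experiment. The DEER objective is the mean earth
   mover's distance (EMD, 1-D Wasserstein); the PRE objective a mean χ².
   The two are balanced through the loss of merit

       L = ½ (EMD/EMD_min + χ²/χ²_min) − 1,

   where EMD_min and χ²_min are single-objective optima; L ≫ 0 signals
   inconsistent restraint sets. Conformers below 1% of the largest weight
   are pruned; pool-size sufficiency is checked by a block-wise convergence
   curve.
3. **Jackknife validation** (`flexens.jackknife`): each distance
   distribution is left out in turn, the ensemble refitted, and the omitted
   distribution back-calculated. Pooling all validation ensembles with the
   original one gives a *superensemble* that is refit against all
   restraints; descriptor spread across validation ensembles gives 2·SD
   uncertainty estimates.
4. **Descriptors** (`flexens.descriptors`): weighted radius of gyration
   R_g = √(Σ w_c R_g,c²) over Cα atoms; the distance-RMSD matrix D_kl; the
   disorder parameter δ = R_g,ACS/R_g, where R_g,ACS is the radius of
   gyration of the conformer set embedded into abstract conformer space by
   classical multidimensional scaling of D_kl (δ ≈ 0.1 for rigid folded
   ensembles, 0.6–0.8 for random-coil-like ones); 3 Å contact maps; 7.5 Å
   binding-pose checks; and merged-pool cluster analysis of binding
   transitions.
5. **Multi-state PRE modelling** (`flexens.multistate`): N rigid copies of
   the system are optimized jointly so that each PRE distance restraint is
   satisfied by the r⁻⁶ state average D* = (Σ dᵢ⁻⁶)^(-1/6) rather than by
   every copy. A scan over 1–10 states selects the smallest adequate N;
   runs are split into equal-weight conformer ensembles.
6. **Synthetic ground truth** (`flexens.synthetic`): a seeded generator for
   two ~70-residue rigid domains joined by a 30-residue flexible linker,
   with label sites, Dirichlet-weighted truth ensembles, and noisy forward
   restraints — every stage of the pipeline is testable against known truth.

## Worked example

```python
import numpy as np
from flexens import synthetic as syn, reweigh, descriptors

spec = syn.ToySystemSpec(seed=3)                       # 70+30+70 residues
pool = syn.build_pool(spec, 40, seed=5)                # candidate conformers
truth, idx = syn.make_truth_ensemble(pool, 8, 1.0, seed=11)
gt = syn.simulate_restraints(truth, spec, syn.NoiseSpec.zero(), seed=1)

sites = syn.default_sites(spec, pool, seed=0)
pred = reweigh.build_predictions(
    pool, sites, gt.noiseless,
    tau_c=syn.DEFAULT_TAU_C, omega_h=2 * np.pi * syn.DEFAULT_NU_H_HZ,
)
fit = reweigh.fit_weights(pred, gt.noiseless, "balanced")
fitted = pool.subset(fit.indices, fit.weights)
print(f"mean EMD  {fit.mean_emd:.2e} Å   chi2 {fit.chi2:.2e}   L {fit.loss:.3f}")
print(f"Rg truth  {descriptors.radius_of_gyration(truth):.3f} Å"
      f"   fitted {descriptors.radius_of_gyration(fitted):.3f} Å")
```

prints

```
mean EMD  3.77e-05 Å   chi2 9.41e-09   L 0.000
Rg truth  17.347 Å   fitted 17.347 Å
```

i.e. with noiseless restraints whose source conformers are contained in the
pool, balanced reweighting recovers the truth ensemble essentially exactly:
the mean EMD is far below the 1 Å smoothing kernel, the PRE χ² is zero, the
loss of merit is zero (the two restraint sets are perfectly consistent),
and the weighted radius of gyration of the fitted ensemble matches the
truth to the printed precision.

A command-line interface wraps the same functionality:

```bash
flexens simulate out/fixture --pool-size 200 --truth-size 20 --seed 1
flexens fit out/fixture/manifest.yaml out/fixture/pool.pdb out/fit
flexens jackknife out/fixture/manifest.yaml out/fixture/pool.pdb out/jk
flexens describe out/fixture/pool.pdb
flexens multistate out/ms --n-states 2 --runs 20 --keep 20
```

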