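"""Shared fixtures: small synthetic systems and the recovery benchmark."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from flexens import descriptors, reweigh
from flexens import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_spec() -> syn.ToySystemSpec:
    return syn.ToySystemSpec(seed=3)


@pytest.fixture(scope="session")
def small_pool(toy_spec):
    return syn.build_pool(toy_spec, 30, seed=5)


@pytest.fixture(scope="session")
def small_recovery(toy_spec, small_pool):
    """Noiseless recovery problem on a 30-conformer pool (8-conformer truth)."""
    truth, idx = syn.make_truth_ensemble(small_pool, 8, 1.0, seed=11)
    gt = syn.simulate_restraints(truth, toy_spec, syn.NoiseSpec.zero(), seed=1)
    sites = syn.default_sites(toy_spec, small_pool, seed=0)
    predictions = reweigh.build_predictions(
        small_pool, sites, gt.noiseless,
        tau_c=syn.DEFAULT_TAU_C,
        omega_h=2 * np.pi * syn.DEFAULT_NU_H_HZ,
        cap=170.0, kernel_sigma=1.0,
    )
    return {
        "spec": toy_spec,
        "pool": small_pool,
        "truth": truth,
        "truth_indices": idx,
        "ground_truth": gt,
        "sites": sites,
        "predictions": predictions,
        "observations": gt.noiseless,
    }


@pytest.fixture(scope="session")
def acceptance_recovery():
    """The benchmark recovery problem: 200-conformer pool holding a
    20-conformer truth ensemble, 8 noiseless distance distributions and 2
    PRE sites."""
    spec = syn.ToySystemSpec(seed=1)
    pool = syn.build_pool(spec, 200, seed=2)
    truth, idx = syn.make_truth_ensemble(pool, 20, 1.0, seed=3)
    gt = syn.simulate_restraints(truth, spec, syn.NoiseSpec.zero(), seed=4)
    sites = syn.default_sites(spec, pool, seed=0)
    predictions = reweigh.build_predictions(
        pool, sites, gt.noiseless,
        tau_c=syn.DEFAULT_TAU_C,
        omega_h=2 * np.pi * syn.DEFAULT_NU_H_HZ,
        cap=170.0, kernel_sigma=1.0,
    )
    fit = reweigh.fit_weights(predictions, gt.noiseless, "balanced")
    return {
        "spec": spec,
        "pool": pool,
        "truth": truth,
        "truth_indices": idx,
        "ground_truth": gt,
        "predictions": predictions,
        "observations": gt.noiseless,
        "fit": fit,
    }


@pytest.fixture(scope="session")
def jackknife_problem(toy_spec):
    """Mid-size noiseless problem for jackknife/superensemble tests."""
    pool = syn.build_pool(toy_spec, 80, seed=2)
    truth, idx = syn.make_truth_ensemble(pool, 10, 1.0, seed=3)
    gt = syn.simulate_restraints(truth, toy_spec, syn.NoiseSpec.zero(), seed=4)
    sites = syn.default_sites(toy_spec, pool, seed=0)
    predictions = reweigh.build_predictions(
        pool, sites, gt.noiseless,
        tau_c=syn.DEFAULT_TAU_C,
        omega_h=2 * np.pi * syn.DEFAULT_NU_H_HZ,
        cap=170.0, kernel_sigma=1.0,
    )
    return {
        "spec": toy_spec,
        "pool": pool,
        "truth": truth,
        "predictions": predictions,
        "observations": gt.noiseless,
    }


def fitted_ensemble(pool, fit):
    return pool.subset(fit.indices, fit.weights)


@pytest.fixture(scope="session")
def disorder_pools(toy_spec):
    """A rigid-jitter pool and a broad-linker pool for disorder calibration."""
    rigid = syn.build_rigid_jitter_pool(toy_spec, 30, seed=9, jitter_sigma=0.3)
    broad = syn.build_pool(toy_spec, 60, seed=9)
    return rigid, broad
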