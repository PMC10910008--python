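"""Shared fixtures: small synthetic cohorts and a reusable short chain."""

import numpy as np
import pandas as pd
import pytest

import caninerx as cx
from caninerx.design import DESIGN_COLUMNS
from caninerx.vocab import FLAG_COLUMNS


def make_two_drug_truth(
    focal: str = "amoxicillin",
    weight_or: float = 1.13,
    sigma_u: float = 0.5,
    focal_logit_at_mean: float = -0.85,
):
    """Ground truth for a two-drug study with a known weight effect.

    The focal intercept is set so that a dog of average weight (18.2 kg)
    has the given log-odds of receiving the focal drug.
    """
    drugs = ("co-amoxiclav", focal)
    beta = {d: np.zeros(len(DESIGN_COLUMNS)) for d in drugs}
    beta[focal][0] = focal_logit_at_mean - np.log(weight_or) * 18.2
    beta[focal][DESIGN_COLUMNS.index("weight_kg")] = np.log(weight_or)
    return cx.TrueModel(
        drugs=drugs, beta=beta, sigma_u={"co-amoxiclav": 0.0, focal: sigma_u}
    )


def make_pair_design(seed: int, n_patients: int = 2800, **truth_kw):
    """Simulate a two-drug cohort and build the focal-vs-reference design."""
    cfg = cx.PopulationConfig(n_patients=n_patients, seed=seed, p_sex_unknown=0.0)
    pats = cx.sample_patients(cfg)
    txn = cx.sample_transactions(pats, cfg)
    truth = make_two_drug_truth(**truth_kw)
    lab = cx.assign_drugs(txn, truth, seed + 10_000)
    design = cx.build_pair_dataset(lab, truth.drugs[1], drop_organ="unspecified")
    return design, truth


def tiny_design(seed: int = 0, n: int = 20, p: int = 4, n_patients: int = 6):
    """A random tiny design for brute-force oracle checks."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.integers(0, 2, size=n).astype(np.int8)
    idx = rng.integers(0, n_patients, size=n)
    return cx.PairedDesign(
        X=X,
        y=y,
        patient_index=idx.astype(np.intp),
        patients=np.arange(n_patients),
        labels=tuple(f"x{i}" for i in range(p)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A filtered synthetic cohort of ~1,000 transactions (rare drugs drop
    out at this size via the unique-patient rule)."""
    table, truth = cx.generate_study(cx.PopulationConfig(n_patients=600, seed=7))
    cohort, report = cx.apply_exclusions(table)
    return cohort, truth, report


@pytest.fixture(scope="session")
def short_chain():
    """One short-but-real MCMC fit on simulated pair data, reused widely."""
    design, truth = make_pair_design(seed=11, n_patients=700)
    spec = cx.ModelSpec(focal=truth.drugs[1], parameterization="orthogonal")
    config = cx.MCMCConfig(burn_in=500, n_iter=6000, thin=2, seed=11)
    chain = cx.fit(design, spec, config)
    return chain, design, truth


def manual_transactions(rows):
    """Build a minimal valid transaction table from a list of dicts."""
    base = {
        "txn_id": "T0",
        "patient_id": "P0",
        "date": pd.Timestamp("2021-06-01"),
        "sex": "F",
        "neutered": False,
        "weight_kg": 12.0,
        "age_y": 5.0,
        "drug": "co-amoxiclav",
        "quantity": 7,
        "cost": 20.0,
        **{c: False for c in FLAG_COLUMNS},
    }
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec["txn_id"] = f"T{i}"
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)
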