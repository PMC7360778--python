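"""Shared fixtures: simulated cohorts and a hand-built cohort factory."""

import numpy as np
import pandas as pd
import pytest

from sibmr import FamilyCohort, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Genetics-only cohort: v_gx = 0.1, every other path zero."""
    return simulate_cohort(SimulationConfig(n_families=2000, seed=7))


@pytest.fixture(scope="session")
def dynastic_cohort():
    """Null causal effect with dynastic confounding (b_ux = 0.1, c = 0.1)."""
    return simulate_cohort(SimulationConfig(
        n_families=4000, b_ux=0.1, c_x=0.1, c_y=0.1, seed=11))


def build_cohort(dosages, roles, family_ids, x=None, y=None):
    """Hand-built cohort from a dosage matrix for degenerate-case tests.

    ``roles`` uses 'mother'/'father'/'sib1'/'sib2'...; parent links are
    wired within each family.  Alleles are any pair consistent with the
    dosage; transmission is marked unavailable.
    """
    d = np.asarray(dosages, dtype=np.int8)
    n, L = d.shape
    roles = list(roles)
    family_ids = [str(f) for f in family_ids]
    ids = [f"{f}_{r}" for f, r in zip(family_ids, roles)]
    mothers = {f: i for f, r, i in zip(family_ids, roles, ids)
               if r == "mother"}
    fathers = {f: i for f, r, i in zip(family_ids, roles, ids)
               if r == "father"}
    samples = pd.DataFrame({
        "individual_id": ids,
        "family_id": family_ids,
        "father_id": [fathers.get(f, "0") if r not in ("mother", "father")
                      else "0" for f, r in zip(family_ids, roles)],
        "mother_id": [mothers.get(f, "0") if r not in ("mother", "father")
                      else "0" for f, r in zip(family_ids, roles)],
        "sex": 0,
        "role": roles,
        "deme": 0,
    })
    pheno = pd.DataFrame({
        "individual_id": ids,
        "x": np.zeros(n) if x is None else np.asarray(x, dtype=float),
        "y": np.zeros(n) if y is None else np.asarray(y, dtype=float),
        "confounder": np.zeros(n),
    })
    alleles = np.stack([np.minimum(d, 1), np.maximum(d - 1, 0)],
                       axis=2).astype(np.uint8)
    transmission = np.full((n, L, 2), -1, dtype=np.int8)
    return FamilyCohort(samples=samples, phenotypes=pheno, alleles=alleles,
                        transmission=transmission)
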