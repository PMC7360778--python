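"""Simulator unit and property tests: meiosis, phenotype model, IBD, I/O."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sibmr import (SimulationConfig, StratSpec, assign_phenotypes,
                   load_config, read_cohort, sibling_ibd, simulate_cohort,
                   transmit, write_cohort)
from sibmr.famsim import config_to_dict


def _ols_r2(y, x):
    x = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(x, y, rcond=None)
    return 1.0 - res[0] / np.sum((y - y.mean()) ** 2)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

class TestTransmit:
    def test_homozygous_parents_transmit_deterministically(self):
        rng = np.random.default_rng(0)
        mo = np.ones((50, 3, 2), dtype=np.uint8)    # dosage 2 everywhere
        fa = np.zeros((50, 3, 2), dtype=np.uint8)   # dosage 0 everywhere
        child, ind = transmit(mo, fa, rng)
        assert (child[:, :, 0] == 1).all()  # maternal allele always 1
        assert (child[:, :, 1] == 0).all()  # paternal allele always 0
        assert set(np.unique(ind)) <= {0, 1}

    def test_heterozygous_transmission_is_fair(self):
        # binomial oracle: frequency 0.5 +/- 3*sqrt(0.25/n)
        rng = np.random.default_rng(1)
        n = 10_000
        het = np.tile([1, 0], (n, 1, 1)).astype(np.uint8)
        child, _ = transmit(het, het, rng)
        for k in range(2):
            freq = child[:, 0, k].mean()
            assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_rejects_malformed_parents(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            transmit(np.ones((5, 3, 2)), np.ones((4, 3, 2)), rng)
        with pytest.raises(ValueError):
            transmit(np.full((5, 3, 2), 2), np.ones((5, 3, 2)), rng)


# ---------------------------------------------------------------------------
# cohort structure
# ---------------------------------------------------------------------------

class TestCohortStructure:
    def test_counts_and_roles(self):
        coh = simulate_cohort(SimulationConfig(n_families=500, seed=0))
        assert coh.n_individuals == 2000
        assert (coh.samples["role"].value_counts() == 500).all()
        grp = coh.samples.groupby("family_id")["role"]
        assert (grp.apply(lambda r: sorted(r) ==
                          ["father", "mother", "sib1", "sib2"])).all()

    def test_offspring_alleles_reproduce_from_parents(self):
        coh = simulate_cohort(SimulationConfig(n_families=300, seed=3))
        coh.validate()  # raises on any inconsistency

    def test_reproducible_given_seed(self):
        cfg = SimulationConfig(n_families=200, b_xy=0.01, b_ux=0.1,
                               c_x=0.1, c_y=0.1, assort_rho=0.3, seed=42)
        a = simulate_cohort(cfg)
        b = simulate_cohort(dataclasses.replace(cfg))
        assert np.array_equal(a.alleles, b.alleles)
        assert a.phenotypes.equals(b.phenotypes)

    def test_allele_frequency_conserved_across_generations(self):
        coh = simulate_cohort(SimulationConfig(n_families=10_000, seed=5))
        d = coh.dosages
        par = np.concatenate([coh.role_rows("mother"),
                              coh.role_rows("father")])
        off = coh.offspring_rows
        se = 3 * np.sqrt(0.5 * 0.5 * 2 / (2 * len(off)))
        diff = d[off].mean(axis=0) - d[par].mean(axis=0)
        assert (np.abs(diff) < 3 * se).all()

    def test_variance_share_validation(self):
        with pytest.raises(ValueError, match="exposure"):
            SimulationConfig(n_families=10, v_gx=0.6, c_x=0.5).validate()
        with pytest.raises(ValueError, match="outcome"):
            SimulationConfig(n_families=10, b_xy=0.5, b_ux=0.3,
                             c_y=0.3).validate()
        with pytest.raises(ValueError):
            SimulationConfig(n_families=10, allele_freq=1.0).validate()


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

class TestPhenotypeModel:
    def test_genetic_variance_share_matches_v_gx(self):
        # R^2 of exposure on the true weighted allele score ~ 0.10
        coh = simulate_cohort(SimulationConfig(n_families=20_000, seed=9))
        rows = coh.offspring_rows
        score = coh.dosages[rows].astype(float) @ coh.true_gamma
        r2 = _ols_r2(coh.phenotypes["x"].to_numpy()[rows], score)
        assert abs(r2 - 0.10) < 0.01

    def test_null_model_has_no_xy_correlation(self):
        coh = simulate_cohort(SimulationConfig(n_families=10_000, seed=13))
        rows = coh.offspring_rows
        ph = coh.phenotypes
        r = np.corrcoef(ph["x"].to_numpy()[rows], ph["y"].to_numpy()[rows])
        assert abs(r[0, 1]) < 3 / np.sqrt(len(rows))

    def test_causal_slope_is_sqrt_share(self):
        # b_xy = 0.01 on standardized phenotypes implies slope 0.1;
        # checked by OLS on ~100k parents (no dynastic term for parents)
        coh = simulate_cohort(SimulationConfig(
            n_families=50_000, b_xy=0.01, seed=17))
        par = np.concatenate([coh.role_rows("mother"),
                              coh.role_rows("father")])
        ph = coh.phenotypes
        x = ph["x"].to_numpy()[par]
        y = ph["y"].to_numpy()[par]
        slope = np.cov(x, y)[0, 1] / np.var(x)
        assert abs(slope - 0.1) < 3 / np.sqrt(len(par))

    def test_dynastic_share_matches_b_ux(self):
        # regression R^2 of offspring outcome on the parental exposure sum
        coh = simulate_cohort(SimulationConfig(
            n_families=20_000, b_ux=0.1, seed=19))
        rows = coh.role_rows("sib1")
        mo = coh.role_rows("mother")
        fa = coh.role_rows("father")
        ph = coh.phenotypes
        psum = ph["x"].to_numpy()[mo] + ph["x"].to_numpy()[fa]
        r2 = _ols_r2(ph["y"].to_numpy()[rows], psum)
        assert abs(r2 - 0.10) < 0.012

    def test_no_dynastic_path_when_b_ux_zero(self):
        # partial correlation of offspring y with parental exposure sum,
        # given offspring x, vanishes
        coh = simulate_cohort(SimulationConfig(
            n_families=10_000, b_xy=0.05, seed=23))
        ph = coh.phenotypes
        s1 = coh.role_rows("sib1")
        mo, fa = coh.role_rows("mother"), coh.role_rows("father")
        x = ph["x"].to_numpy()[s1]
        y = ph["y"].to_numpy()[s1]
        psum = ph["x"].to_numpy()[mo] + ph["x"].to_numpy()[fa]
        # residualize both on x
        ry = y - np.polyval(np.polyfit(x, y, 1), x)
        rp = psum - np.polyval(np.polyfit(x, psum, 1), x)
        r = np.corrcoef(ry, rp)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(s1))

    @pytest.mark.parametrize("role", ["mother", "father", "sib1", "sib2"])
    def test_phenotype_variance_near_one(self, role):
        coh = simulate_cohort(SimulationConfig(
            n_families=10_000, b_xy=0.05, b_ux=0.2, c_x=0.2, c_y=0.2,
            seed=29))
        rows = coh.role_rows(role)
        for col in ("x", "y"):
            v = coh.phenotypes[col].to_numpy()[rows].var()
            assert 0.95 < v < 1.05, (role, col, v)

    def test_assign_phenotypes_redraws_on_fixed_genotypes(self):
        cfg = SimulationConfig(n_families=500, b_ux=0.1, seed=31)
        coh = simulate_cohort(cfg)
        redrawn = assign_phenotypes(coh, cfg, seed=99)
        assert np.array_equal(coh.alleles, redrawn.alleles)
        assert not np.allclose(coh.phenotypes["x"], redrawn.phenotypes["x"])
        assert 0.9 < redrawn.phenotypes["x"].var() < 1.1


# ---------------------------------------------------------------------------
# mating structure and stratification
# ---------------------------------------------------------------------------

class TestMatingAndStrat:
    def test_assortative_mating_hits_target_correlation(self):
        coh = simulate_cohort(SimulationConfig(
            n_families=20_000, assort_rho=0.4, seed=37))
        ph = coh.phenotypes
        xm = ph["x"].to_numpy()[coh.role_rows("mother")]
        xf = ph["x"].to_numpy()[coh.role_rows("father")]
        assert abs(np.corrcoef(xm, xf)[0, 1] - 0.4) < 0.03

    def test_random_mating_spouses_uncorrelated(self):
        coh = simulate_cohort(SimulationConfig(n_families=10_000, seed=41))
        ph = coh.phenotypes
        xm = ph["x"].to_numpy()[coh.role_rows("mother")]
        xf = ph["x"].to_numpy()[coh.role_rows("father")]
        assert abs(np.corrcoef(xm, xf)[0, 1]) < 3 / np.sqrt(len(xm))

    def test_two_deme_stratification(self):
        coh = simulate_cohort(SimulationConfig(
            n_families=10_000, seed=43,
            strat=StratSpec(freq_offset=0.1, outcome_offset=0.5, prop=0.5)))
        s = coh.samples
        deme = s["deme"].to_numpy()
        d = coh.dosages.mean(axis=1)
        assert d[deme == 1].mean() > d[deme == 0].mean()
        y = coh.phenotypes["y"].to_numpy()
        assert y[deme == 1].mean() > y[deme == 0].mean()
        # spouses share a deme
        fam_demes = s.groupby("family_id")["deme"].nunique()
        assert (fam_demes == 1).all()


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------

class TestIBD:
    def test_ibd_distribution_matches_theory(self):
        # closed form: mean 1/2, SD sqrt(0.125/L)
        coh = simulate_cohort(SimulationConfig(n_families=5000, seed=47))
        ibd = sibling_ibd(coh)
        assert (ibd.per_pair >= 0).all() and (ibd.per_pair <= 1).all()
        assert abs(ibd.mean - 0.5) < 0.01
        theory = np.sqrt(0.125 / 90)
        assert abs(ibd.sd - theory) < 0.1 * theory

    def test_ibd_extremes_from_constructed_indicators(self):
        coh = simulate_cohort(SimulationConfig(n_families=50, seed=53))
        s1 = coh.role_rows("sib1")
        s2 = coh.role_rows("sib2")
        # identical transmission -> IBD proportion exactly 1
        coh.transmission[s2] = coh.transmission[s1]
        assert (sibling_ibd(coh).per_pair == 1.0).all()
        # fully opposite indicators -> 0
        coh.transmission[s2] = 1 - coh.transmission[s1]
        assert (sibling_ibd(coh).per_pair == 0.0).all()

    def test_ibd_requires_transmission_provenance(self, tmp_path):
        coh = simulate_cohort(SimulationConfig(n_families=20, seed=59))
        write_cohort(coh, str(tmp_path / "c"))
        loaded = read_cohort(str(tmp_path / "c"))
        with pytest.raises(ValueError, match="transmission"):
            sibling_ibd(loaded)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestIO:
    def test_roundtrip_preserves_dosages_and_phenotypes(self, tmp_path):
        coh = simulate_cohort(SimulationConfig(
            n_families=100, b_xy=0.05, seed=61))
        write_cohort(coh, str(tmp_path / "c"))
        loaded = read_cohort(str(tmp_path / "c"))
        assert np.array_equal(coh.dosages, loaded.dosages)
        assert np.allclose(coh.phenotypes["x"], loaded.phenotypes["x"])
        assert list(loaded.snp_ids) == list(coh.snp_ids)
        assert loaded.samples["role"].tolist() == \
            coh.samples["role"].tolist()

    def test_config_yaml_roundtrip(self, tmp_path):
        import yaml
        cfg = SimulationConfig(n_families=50, b_ux=0.1, seed=3,
                               strat=StratSpec(freq_offset=0.02))
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(config_to_dict(cfg)))
        loaded = load_config(str(path))
        assert loaded == cfg


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(max_examples=20, deadline=None, derandomize=True)
@given(n_families=st.integers(2, 40), n_snps=st.integers(1, 12),
       freq=st.floats(0.05, 0.95), seed=st.integers(0, 2**31 - 1),
       v_gx=st.floats(0, 0.5), b_ux=st.floats(0, 0.5))
def test_simulated_cohorts_satisfy_invariants(n_families, n_snps, freq,
                                              seed, v_gx, b_ux):
    cfg = SimulationConfig(n_families=n_families, n_snps=n_snps,
                           allele_freq=freq, v_gx=v_gx, b_ux=b_ux,
                           seed=seed)
    coh = simulate_cohort(cfg)
    d = coh.dosages
    assert d.min() >= 0 and d.max() <= 2
    coh.validate()
    ibd = sibling_ibd(coh)
    assert (ibd.per_pair >= 0).all() and (ibd.per_pair <= 1).all()
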