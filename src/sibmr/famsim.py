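"""Forward-in-time simulation of nuclear families for within-family MR.

Simulates cohorts of mother-father-offspring families in which each parent
transmits one allele per locus to each child, and the parents' exposure
phenotype can exert a *dynastic* effect on the offspring outcome.  Optional
assortative mating (spousal correlation on the exposure) and two-deme
population stratification reproduce the classic confounding structures that
bias Mendelian randomization in samples of unrelated individuals.

All phenotypes are built on the standardized scale: every structural path is
parameterized by the fraction of variance it explains, and the coefficient
applied to the (variance-1) source is the square root of that fraction, so
each phenotype has theoretical mean 0 and variance 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = ("mother", "father", "sib1", "sib2")
PARENT_ROLES = ("mother", "father")

__all__ = [
    "StratSpec",
    "SimulationConfig",
    "FamilyCohort",
    "IBDSummary",
    "simulate_cohort",
    "transmit",
    "assign_phenotypes",
    "sibling_ibd",
    "write_cohort",
    "read_cohort",
    "load_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratSpec:
    """Two-deme population stratification.

    Families are assigned to deme 1 with probability ``prop``; deme 0
    otherwise.  Allele frequencies are shifted by ``freq_offset`` (+ in deme
    1, - in deme 0, clipped away from the boundary) and the outcome mean by
    ``outcome_offset`` (centred so the population mean stays 0).  Mating is
    within deme.
    """

    freq_offset: float = 0.05
    outcome_offset: float = 0.0
    prop: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.prop < 1.0:
            raise ValueError("strat.prop must lie strictly inside (0, 1)")
        if self.freq_offset < 0:
            raise ValueError("strat.freq_offset must be >= 0")


@dataclass
class SimulationConfig:
    """Generative parameters for one simulated cohort.

    Parameters
    ----------
    n_families : int
        Number of mother-father-sibling-pair families.
    n_snps : int
        Number of independently segregating biallelic loci (default 90).
    allele_freq : float or array of float
        Effect-allele frequency, scalar or one per locus, strictly in (0, 1).
    v_gx : float
        Fraction of exposure variance jointly explained by the loci (the
        per-locus contribution is ``v_gx / n_snps``).
    b_xy : float
        Fraction of outcome variance explained by the individual's exposure
        (the true causal path; the standardized slope is ``sqrt(b_xy)``).
    b_ux : float
        Fraction of offspring-outcome variance explained by the combined
        parental exposure — the dynastic path.
    c_x, c_y : float
        Fractions of exposure/outcome variance explained by an individual
        normal confounder.
    assort_rho : float
        Target spousal correlation on the exposure; 0 means random mating.
    dynastic_route : {"outcome", "both"}
        "outcome" sends the parental-exposure signal straight to the
        offspring outcome; "both" also routes it into the offspring
        exposure with the same variance share (a child-confounder reading).
    pleiotropy : float
        Optional variance share of direct SNP -> outcome effects (random
        balanced weights); 0 by default (no horizontal pleiotropy).
    strat : StratSpec, optional
        Two-deme stratification; None disables it.
    seed : int or numpy SeedSequence, optional
        Source of all randomness; identical configs give identical cohorts.
    """

    n_families: int
    n_snps: int = 90
    allele_freq: float | Sequence[float] = 0.5
    v_gx: float = 0.1
    b_xy: float = 0.0
    b_ux: float = 0.0
    c_x: float = 0.0
    c_y: float = 0.0
    assort_rho: float = 0.0
    dynastic_route: str = "outcome"
    pleiotropy: float = 0.0
    strat: StratSpec | None = None
    seed: int | np.random.SeedSequence | None = None

    # -- derived -----------------------------------------------------------
    def freqs(self) -> np.ndarray:
        p = np.broadcast_to(np.asarray(self.allele_freq, dtype=float),
                            (self.n_snps,)).copy()
        return p

    def validate(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        p = self.freqs()
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("allele_freq must lie strictly inside (0, 1)")
        for name, val in (("v_gx", self.v_gx), ("b_xy", self.b_xy),
                          ("b_ux", self.b_ux), ("c_x", self.c_x),
                          ("c_y", self.c_y), ("pleiotropy", self.pleiotropy)):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.assort_rho < 1.0:
            raise ValueError("assort_rho must lie in [0, 1)")
        if self.dynastic_route not in ("outcome", "both"):
            raise ValueError("dynastic_route must be 'outcome' or 'both'")
        x_share = self.v_gx + self.c_x
        if self.dynastic_route == "both":
            x_share += self.b_ux
        if x_share >= 1.0:
            raise ValueError(
                f"exposure variance shares sum to {x_share:.3f} >= 1")
        y_share = self.b_xy + self.c_y + self.b_ux + self.pleiotropy
        if y_share >= 1.0:
            raise ValueError(
                f"outcome variance shares sum to {y_share:.3f} >= 1")
        if self.strat is not None:
            self.strat.validate()
            if np.any(p - self.strat.freq_offset <= 0) or \
                    np.any(p + self.strat.freq_offset >= 1):
                raise ValueError("strat.freq_offset pushes allele_freq "
                                 "outside (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class FamilyCohort:
    """A simulated (or loaded) family cohort.

    Rows of ``samples``, ``phenotypes``, ``alleles`` and ``transmission``
    are aligned.  ``alleles`` has shape (n, L, 2); for offspring the pair is
    ordered (maternal allele, paternal allele).  ``transmission`` records,
    for offspring, which parental allele copy (0 = first, 1 = second) each
    parent transmitted; parents carry -1.
    """

    samples: pd.DataFrame        # individual_id, family_id, father_id, mother_id, sex, role, deme
    phenotypes: pd.DataFrame     # individual_id, x, y, confounder
    alleles: np.ndarray          # (n, L, 2) uint8
    transmission: np.ndarray     # (n, L, 2) int8, -1 where not applicable
    config: SimulationConfig | None = None
    true_gamma: np.ndarray | None = None  # per-SNP true dosage slope on x
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.alleles.shape[1])]
        self._dosage_cache: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def dosages(self) -> np.ndarray:
        """(n, L) additive dosage matrix (allele-pair sums, 0/1/2)."""
        if self._dosage_cache is None:
            self._dosage_cache = (self.alleles[:, :, 0]
                                  + self.alleles[:, :, 1]).astype(np.int8)
        return self._dosage_cache

    def role_rows(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.samples["role"].to_numpy() == role)

    @property
    def offspring_rows(self) -> np.ndarray:
        return np.flatnonzero(
            ~self.samples["role"].isin(PARENT_ROLES).to_numpy())

    def family_codes(self, rows: np.ndarray) -> np.ndarray:
        """Integer family labels for the given rows (stable order)."""
        fam = self.samples["family_id"].to_numpy()[rows]
        return pd.factorize(fam)[0]

    def sib_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All within-family offspring pairs as two aligned row arrays."""
        off = self.offspring_rows
        fam = self.samples["family_id"].to_numpy()[off]
        first, second = [], []
        for _, grp in pd.Series(off, index=fam).groupby(level=0, sort=False):
            rows = grp.to_numpy()
            for i in range(len(rows)):
                for k in range(i + 1, len(rows)):
                    first.append(rows[i])
                    second.append(rows[k])
        return np.asarray(first, dtype=int), np.asarray(second, dtype=int)

    def trio_rows(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(offspring, mother, father) row indices — one offspring/family."""
        s = self.samples
        row_of = pd.Series(np.arange(len(s)), index=s["individual_id"])
        off = s[~s["role"].isin(PARENT_ROLES)]
        off = off.sort_values("individual_id").groupby("family_id",
                                                       sort=False).head(1)
        ok = off["mother_id"].isin(row_of.index) & \
            off["father_id"].isin(row_of.index)
        off = off[ok]
        return (row_of[off["individual_id"]].to_numpy(),
                row_of[off["mother_id"]].to_numpy(),
                row_of[off["father_id"]].to_numpy())

    def validate(self) -> None:
        """Check pedigree/transmission consistency invariants."""
        d = self.dosages
        if d.min() < 0 or d.max() > 2:
            raise AssertionError("dosages outside {0,1,2}")
        off, mo, fa = _offspring_parent_rows(self.samples)
        tr = self.transmission[off]
        if (tr < 0).any():
            return  # transmission provenance unavailable (loaded cohort)
        mat = np.take_along_axis(self.alleles[mo], tr[:, :, :1], axis=2)[:, :, 0]
        pat = np.take_along_axis(self.alleles[fa], tr[:, :, 1:], axis=2)[:, :, 0]
        if not np.array_equal(mat, self.alleles[off][:, :, 0]) or \
                not np.array_equal(pat, self.alleles[off][:, :, 1]):
            raise AssertionError("offspring alleles do not reproduce from "
                                 "parents and transmission indicators")


def _offspring_parent_rows(samples: pd.DataFrame):
    """Row indices of every offspring and its mother/father."""
    row_of = pd.Series(np.arange(len(samples)),
                       index=samples["individual_id"])
    off = samples[~samples["role"].isin(PARENT_ROLES)]
    return (row_of[off["individual_id"]].to_numpy(),
            row_of[off["mother_id"]].to_numpy(),
            row_of[off["father_id"]].to_numpy())


@dataclass
class IBDSummary:
    """Identity-by-descent sharing between sibling pairs."""

    per_pair: np.ndarray       # mean IBD proportion per sibling pair
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def transmit(mother_alleles: np.ndarray, father_alleles: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One offspring per couple by independent Mendelian transmission.

    At every locus each parent transmits one of its two allele copies with
    probability 1/2, independently across loci and parents.  Returns the
    offspring allele pairs, ordered (maternal, paternal), together with the
    transmission indicators (which copy each parent gave) needed for IBD
    computation.

    Parameters
    ----------
    mother_alleles, father_alleles : (F, L, 2) arrays of 0/1
    rng : numpy Generator

    Returns
    -------
    offspring : (F, L, 2) uint8
    indicators : (F, L, 2) uint8
        ``indicators[..., 0]`` is the maternal copy index, ``[..., 1]``
        the paternal copy index.
    """
    mother_alleles = np.asarray(mother_alleles)
    father_alleles = np.asarray(father_alleles)
    if mother_alleles.shape != father_alleles.shape or \
            mother_alleles.ndim != 3 or mother_alleles.shape[2] != 2:
        raise ValueError("parent allele arrays must both be (F, L, 2)")
    if mother_alleles.min() < 0 or mother_alleles.max() > 1 or \
            father_alleles.min() < 0 or father_alleles.max() > 1:
        raise ValueError("alleles must be 0/1")
    F, L, _ = mother_alleles.shape
    ind = rng.integers(0, 2, size=(F, L, 2), dtype=np.uint8)
    mat = np.take_along_axis(mother_alleles, ind[:, :, :1], axis=2)[:, :, 0]
    pat = np.take_along_axis(father_alleles, ind[:, :, 1:], axis=2)[:, :, 0]
    child = np.stack([mat, pat], axis=2).astype(np.uint8)
    return child, ind


# ---------------------------------------------------------------------------
# phenotype assignment
# ---------------------------------------------------------------------------

def _genetic_score(dosage: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Equal-weight standardized polygenic component, theoretical var 1."""
    z = (dosage - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return z.sum(axis=1) / np.sqrt(dosage.shape[1])


def _residual_scale(total_used: float, label: str) -> float:
    resid = 1.0 - total_used
    if resid < 0:
        raise ValueError(
            f"{label} variance shares (incl. covariance terms) sum to "
            f"{total_used:.3f} >= 1")
    return np.sqrt(resid)


def _parent_phenotypes(G: np.ndarray, cfg: SimulationConfig,
                       rng: np.random.Generator,
                       y_offset: np.ndarray | float = 0.0):
    n = G.shape[0]
    C = rng.standard_normal(n)
    sx = _residual_scale(cfg.v_gx + cfg.c_x, "exposure")
    x = (np.sqrt(cfg.v_gx) * G + np.sqrt(cfg.c_x) * C
         + sx * rng.standard_normal(n))
    # cov(x, C) = sqrt(c_x): subtract the b_xy/c_y cross-term so var(y) = 1
    used = (cfg.b_xy + cfg.c_y
            + 2.0 * np.sqrt(cfg.b_xy * cfg.c_y * cfg.c_x))
    sy = _residual_scale(used, "outcome")
    y = (np.sqrt(cfg.b_xy) * x + np.sqrt(cfg.c_y) * C
         + sy * rng.standard_normal(n) + y_offset)
    return x, y, C


def _offspring_phenotypes(G: np.ndarray, x_m: np.ndarray, x_f: np.ndarray,
                          cfg: SimulationConfig, rng: np.random.Generator,
                          pleio: np.ndarray | float = 0.0,
                          y_offset: np.ndarray | float = 0.0):
    """Offspring exposure/outcome including the dynastic path.

    ``P`` is the standardized combined parental exposure.  Residual scales
    subtract the analytic covariance cross-terms (random-mating values) so
    that the theoretical phenotype variance is 1.
    """
    n = G.shape[0]
    C = rng.standard_normal(n)
    rho = cfg.assort_rho
    P = (x_m + x_f) / np.sqrt(2.0 * (1.0 + rho))
    cov_GP = np.sqrt(cfg.v_gx) / np.sqrt(2.0 * (1.0 + rho))

    bux_x = cfg.b_ux if cfg.dynastic_route == "both" else 0.0
    used_x = (cfg.v_gx + cfg.c_x + bux_x
              + 2.0 * np.sqrt(cfg.v_gx * bux_x) * cov_GP)
    sx = _residual_scale(used_x, "exposure")
    x = (np.sqrt(cfg.v_gx) * G + np.sqrt(cfg.c_x) * C
         + np.sqrt(bux_x) * P + sx * rng.standard_normal(n))

    cov_xP = np.sqrt(cfg.v_gx) * cov_GP + np.sqrt(bux_x)
    used_y = (cfg.b_xy + cfg.c_y + cfg.b_ux + cfg.pleiotropy
              + 2.0 * np.sqrt(cfg.b_xy * cfg.c_y * cfg.c_x)
              + 2.0 * np.sqrt(cfg.b_xy * cfg.b_ux) * cov_xP)
    sy = _residual_scale(used_y, "outcome")
    y = (np.sqrt(cfg.b_xy) * x + np.sqrt(cfg.c_y) * C
         + np.sqrt(cfg.b_ux) * P + np.sqrt(cfg.pleiotropy) * pleio
         + sy * rng.standard_normal(n) + y_offset)
    return x, y, C


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _assort_permutation(x_m: np.ndarray, x_f: np.ndarray, rho: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Permutation of fathers realizing spousal exposure correlation ~ rho.

    Rank-matches mothers on x against fathers on x plus calibrated noise:
    matching on ``x_f + e`` with var(e) = 1/rho^2 - 1 yields a spousal
    correlation of about rho for Gaussian phenotypes.
    """
    n = len(x_m)
    if rho <= 0 or n < 2:
        return np.arange(n)
    s = np.sqrt(1.0 / rho**2 - 1.0)
    key_f = x_f + s * rng.standard_normal(n)
    perm = np.empty(n, dtype=int)
    perm[np.argsort(x_m, kind="stable")] = np.argsort(key_f, kind="stable")
    return perm


def simulate_cohort(config: SimulationConfig) -> FamilyCohort:
    """Simulate a cohort of two-parent, two-offspring families.

    Parents' genotypes are drawn under Hardy-Weinberg equilibrium at the
    configured allele frequencies; couples are formed at random (or by
    exposure rank-matching under ``assort_rho``, within deme under
    stratification); each offspring receives one allele per locus from each
    parent; phenotypes follow the variance-share structural model, with the
    parents' exposures acting on the offspring outcome through the dynastic
    path.  Deterministic given the seed.
    """
    config.validate()
    rng = config.rng()
    F, L = config.n_families, config.n_snps
    p = config.freqs()

    if config.strat is not None:
        deme = (rng.random(F) < config.strat.prop).astype(np.int8)
        freq = p[None, :] + config.strat.freq_offset * np.where(
            deme[:, None] == 1, 1.0, -1.0)
        y_off_fam = config.strat.outcome_offset * (
            deme - config.strat.prop)
    else:
        deme = np.zeros(F, dtype=np.int8)
        freq = np.broadcast_to(p, (F, L))
        y_off_fam = np.zeros(F)

    mother = (rng.random((F, L, 2)) < freq[:, :, None]).astype(np.uint8)
    father = (rng.random((F, L, 2)) < freq[:, :, None]).astype(np.uint8)

    G_m = _genetic_score(mother.sum(axis=2), p)
    G_f = _genetic_score(father.sum(axis=2), p)
    x_m, y_m, C_m = _parent_phenotypes(G_m, config, rng, y_off_fam)
    x_f, y_f, C_f = _parent_phenotypes(G_f, config, rng, y_off_fam)

    # couple formation: permute fathers (within deme under stratification)
    if config.assort_rho > 0:
        perm = np.arange(F)
        for d in np.unique(deme):
            idx = np.flatnonzero(deme == d)
            perm[idx] = idx[_assort_permutation(
                x_m[idx], x_f[idx], config.assort_rho, rng)]
        father, G_f = father[perm], G_f[perm]
        x_f, y_f, C_f = x_f[perm], y_f[perm], C_f[perm]

    sib1, tr1 = transmit(mother, father, rng)
    sib2, tr2 = transmit(mother, father, rng)

    if config.pleiotropy > 0:
        a = rng.standard_normal(L)
        a /= np.linalg.norm(a)
    else:
        a = np.zeros(L)

    def pleio_score(alle):
        z = (alle.sum(axis=2) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        return z @ a

    G_s1 = _genetic_score(sib1.sum(axis=2), p)
    G_s2 = _genetic_score(sib2.sum(axis=2), p)
    x_s1, y_s1, C_s1 = _offspring_phenotypes(
        G_s1, x_m, x_f, config, rng, pleio_score(sib1), y_off_fam)
    x_s2, y_s2, C_s2 = _offspring_phenotypes(
        G_s2, x_m, x_f, config, rng, pleio_score(sib2), y_off_fam)

    # assemble row-aligned tables, family-major order
    fam_ids = np.array([f"F{k:06d}" for k in range(F)])
    ids = {r: np.char.add(fam_ids, f"_{r}") for r in ROLES}
    n = 4 * F

    samples = pd.DataFrame({
        "individual_id": np.stack([ids[r] for r in ROLES], axis=1).ravel(),
        "family_id": np.repeat(fam_ids, 4),
        "father_id": np.stack([np.full(F, "0"), np.full(F, "0"),
                               ids["father"], ids["father"]], axis=1).ravel(),
        "mother_id": np.stack([np.full(F, "0"), np.full(F, "0"),
                               ids["mother"], ids["mother"]], axis=1).ravel(),
        "sex": np.stack([np.full(F, 2), np.full(F, 1),
                         rng.integers(1, 3, F), rng.integers(1, 3, F)],
                        axis=1).ravel(),
        "role": np.tile(np.array(ROLES), F),
        "deme": np.repeat(deme, 4),
    })

    def interleave(*arrs):
        return np.stack(arrs, axis=1).reshape((n,) + arrs[0].shape[1:])

    alleles = interleave(mother, father, sib1, sib2)
    transmission = np.full((n, L, 2), -1, dtype=np.int8)
    transmission[2::4] = tr1
    transmission[3::4] = tr2

    phenotypes = pd.DataFrame({
        "individual_id": samples["individual_id"],
        "x": interleave(x_m, x_f, x_s1, x_s2),
        "y": interleave(y_m, y_f, y_s1, y_s2),
        "confounder": interleave(C_m, C_f, C_s1, C_s2),
    })

    true_gamma = np.sqrt(config.v_gx / L) / np.sqrt(2.0 * p * (1.0 - p))
    return FamilyCohort(samples=samples, phenotypes=phenotypes,
                        alleles=alleles, transmission=transmission,
                        config=config, true_gamma=true_gamma)


def assign_phenotypes(cohort: FamilyCohort, config: SimulationConfig,
                      seed: int | np.random.SeedSequence | None = None
                      ) -> FamilyCohort:
    """Redraw all phenotypes on an existing pedigree/genotype scaffold.

    Parents' phenotypes are drawn first, then each offspring's, with the
    dynastic path fed by the freshly drawn parental exposures.  The couple
    pairing is taken as given, so under assortative mating the realized
    spousal correlation of the *new* exposures is not re-matched.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.freqs()
    d = cohort.dosages
    s = cohort.samples
    if config.strat is not None and "deme" in s:
        y_off = config.strat.outcome_offset * (
            s["deme"].to_numpy() - config.strat.prop)
    else:
        y_off = np.zeros(len(s))

    G = _genetic_score(d, p)
    x = np.empty(len(s))
    y = np.empty(len(s))
    C = np.empty(len(s))

    par_rows = np.flatnonzero(s["role"].isin(PARENT_ROLES).to_numpy())
    x[par_rows], y[par_rows], C[par_rows] = _parent_phenotypes(
        G[par_rows], config, rng, y_off[par_rows])

    off, mo, fa = _offspring_parent_rows(s)
    if config.pleiotropy > 0:
        a = rng.standard_normal(cohort.n_snps)
        a /= np.linalg.norm(a)
        z = (d[off] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        pleio = z @ a
    else:
        pleio = 0.0
    x[off], y[off], C[off] = _offspring_phenotypes(
        G[off], x[mo], x[fa], config, rng, pleio, y_off[off])

    pheno = cohort.phenotypes.copy()
    pheno["x"], pheno["y"], pheno["confounder"] = x, y, C
    return FamilyCohort(samples=s, phenotypes=pheno, alleles=cohort.alleles,
                        transmission=cohort.transmission, config=config,
                        true_gamma=np.sqrt(config.v_gx / cohort.n_snps)
                        / np.sqrt(2.0 * p * (1.0 - p)),
                        snp_ids=cohort.snp_ids)


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------

def sibling_ibd(cohort: FamilyCohort) -> IBDSummary:
    """Mean identity-by-descent proportion for every sibling pair.

    At each locus a pair shares 0, 1 or 2 parental allele copies according
    to whether each parent transmitted the same copy to both siblings; the
    per-pair value is the locus average of (shared copies)/2.  With L
    independent loci the theoretical distribution across pairs is mean 1/2,
    SD sqrt(0.125/L) (0.0373 at L = 90).
    """
    r1, r2 = cohort.sib_pairs()
    if len(r1) == 0:
        raise ValueError("cohort contains no family with >= 2 offspring")
    t1, t2 = cohort.transmission[r1], cohort.transmission[r2]
    if (t1 < 0).any() or (t2 < 0).any():
        raise ValueError("transmission indicators unavailable "
                         "(cohort loaded from dosage files?)")
    shared = (t1 == t2).sum(axis=2)          # 0, 1 or 2 per locus
    per_pair = shared.mean(axis=1) / 2.0
    return IBDSummary(per_pair=per_pair, mean=float(per_pair.mean()),
                      sd=float(per_pair.std(ddof=1)))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: FamilyCohort, prefix: str) -> dict[str, str]:
    """Write sample/dosage/phenotype TSVs; returns the paths written."""
    paths = {
        "samples": f"{prefix}.samples.tsv",
        "dosages": f"{prefix}.dosages.tsv",
        "phenotypes": f"{prefix}.phenotypes.tsv",
    }
    cols = ["family_id", "individual_id", "father_id", "mother_id",
            "sex", "role", "deme"]
    cohort.samples[cols].to_csv(paths["samples"], sep="\t", index=False)
    dos = pd.DataFrame(cohort.dosages, columns=cohort.snp_ids)
    dos.insert(0, "individual_id", cohort.samples["individual_id"].to_numpy())
    dos.to_csv(paths["dosages"], sep="\t", index=False)
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths


def read_cohort(prefix: str) -> FamilyCohort:
    """Load a cohort from the TSV trio written by :func:`write_cohort`.

    Allele-level phase and transmission provenance are not serialized:
    alleles are reconstructed from dosages (so dosage-level analyses are
    exact) and transmission is marked unavailable.
    """
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t",
                          dtype={"family_id": str, "individual_id": str,
                                 "father_id": str, "mother_id": str})
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t")
    pheno = pd.read_csv(f"{prefix}.phenotypes.tsv", sep="\t",
                        dtype={"individual_id": str})
    dos = dos.set_index("individual_id").loc[samples["individual_id"]]
    d = dos.to_numpy(dtype=np.int8)
    alleles = np.stack([np.minimum(d, 1), np.maximum(d - 1, 0)],
                       axis=2).astype(np.uint8)
    transmission = np.full(alleles.shape, -1, dtype=np.int8)
    pheno = pheno.set_index("individual_id").loc[
        samples["individual_id"]].reset_index()
    return FamilyCohort(samples=samples, phenotypes=pheno, alleles=alleles,
                        transmission=transmission,
                        snp_ids=list(dos.columns))


def load_config(path: str) -> SimulationConfig:
    """Read a SimulationConfig from a YAML or JSON mapping."""
    with open(path) as fh:
        raw = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    if "strat" in raw and raw["strat"] is not None:
        raw["strat"] = StratSpec(**raw["strat"])
    return SimulationConfig(**raw)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if isinstance(d.get("seed"), np.random.SeedSequence):
        d["seed"] = None
    return d
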