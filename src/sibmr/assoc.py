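"""Per-SNP association estimators for family data.

Four estimators of the SNP-phenotype association: ordinary least squares on
unrelated individuals, the sibling-difference regression, the family
fixed-effects (within) regression, and the trio regression adjusting for
both parents' genotypes.  All standard errors are sandwich estimators;
family-clustered (CR1) wherever observations share a family.

The sibling-difference and family fixed-effects estimators give identical
point estimates when every family contributes exactly two siblings: with
two members the within transformation reduces to +/- half the sibling
difference, and the through-origin difference regression follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .famsim import FamilyCohort

__all__ = [
    "AssocResult",
    "InestimableError",
    "assoc_unrelated",
    "sib_diff_assoc",
    "family_fe_assoc",
    "trio_assoc",
    "cluster_robust_cov",
    "bulk_unrelated",
    "bulk_family_fe",
    "bulk_trio",
    "cohort_assoc_table",
    "cohort_assoc_tables",
]


class InestimableError(ValueError):
    """The requested association is not identified from the data given."""


@dataclass
class AssocResult:
    """One SNP-phenotype association estimate."""

    snp_id: str
    beta: float
    se: float
    p: float
    n: int
    method: str
    beta_mother: float | None = None
    se_mother: float | None = None
    beta_father: float | None = None
    se_father: float | None = None

    def to_dict(self) -> dict:
        d = {"snp_id": self.snp_id, "method": self.method, "beta": self.beta,
             "se": self.se, "p": self.p, "n": self.n}
        if self.beta_mother is not None:
            d.update(beta_mother=self.beta_mother, se_mother=self.se_mother,
                     beta_father=self.beta_father, se_father=self.se_father)
        return d


# ---------------------------------------------------------------------------
# sandwich covariances
# ---------------------------------------------------------------------------

def cluster_robust_cov(X: np.ndarray, resid: np.ndarray,
                       clusters: np.ndarray) -> np.ndarray:
    """CR1 cluster-robust covariance of OLS coefficients.

    ``cov = c * (X'X)^-1 [ sum_g (X_g' e_g)(X_g' e_g)' ] (X'X)^-1`` with the
    finite-sample factor ``c = G/(G-1) * (N-1)/(N-K)`` used by the standard
    econometric fixed-effects packages.

    Parameters
    ----------
    X : (N, K) design matrix
    resid : (N,) residual vector
    clusters : (N,) cluster labels (families)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(resid) == X.shape[1]:
        X = X.T
    resid = np.asarray(resid, dtype=float)
    codes, uniq = pd.factorize(np.asarray(clusters))
    G = len(uniq)
    if G < 2:
        raise InestimableError("cluster-robust covariance needs >= 2 clusters")
    N, K = X.shape
    bread = np.linalg.inv(X.T @ X)
    Xe = X * resid[:, None]
    # cluster score sums
    S = np.zeros((G, K))
    np.add.at(S, codes, Xe)
    meat = S.T @ S
    c = G / (G - 1) * (N - 1) / max(N - K, 1)
    return c * bread @ meat @ bread


def _hc1_cov(X: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Heteroskedasticity-robust (HC1) covariance."""
    N, K = X.shape
    bread = np.linalg.inv(X.T @ X)
    Xe = X * resid[:, None]
    meat = Xe.T @ Xe
    return N / max(N - K, 1) * bread @ meat @ bread


def _p_from_t(beta: float, se: float, df: int) -> float:
    if se <= 0 or df < 1:
        return np.nan
    return float(2.0 * stats.t.sf(abs(beta) / se, df))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise InestimableError("design matrix is rank deficient")
    return coef, y - X @ coef


# ---------------------------------------------------------------------------
# single-SNP estimators
# ---------------------------------------------------------------------------

def assoc_unrelated(dosage: np.ndarray, phenotype: np.ndarray,
                    covariates: np.ndarray | None = None,
                    clusters: np.ndarray | None = None,
                    snp_id: str = "snp") -> AssocResult:
    """OLS association of a phenotype with an additive dosage.

    Robust (HC1) standard errors by default; family-clustered CR1 when
    ``clusters`` is supplied, with t reference on G - 1 degrees of freedom.
    """
    g = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if len(g) < 3:
        raise InestimableError("need at least 3 observations")
    if np.ptp(g) == 0:
        raise InestimableError(f"{snp_id}: genotype is constant")
    cols = [g, np.ones_like(g)]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(g):
            C = C.T
        cols = [g] + [C[:, k] for k in range(C.shape[1])] + [np.ones_like(g)]
    X = np.column_stack(cols)
    coef, resid = _ols(X, y)
    if clusters is not None:
        cov = cluster_robust_cov(X, resid, clusters)
        df = len(pd.unique(np.asarray(clusters))) - 1
    else:
        cov = _hc1_cov(X, resid)
        df = len(g) - X.shape[1]
    se = float(np.sqrt(cov[0, 0]))
    return AssocResult(snp_id=snp_id, beta=float(coef[0]), se=se,
                       p=_p_from_t(coef[0], se, df), n=len(g),
                       method="unrelated")


def sib_diff_assoc(cohort: FamilyCohort, snp: int | str, phenotype: str = "x",
                   intercept: bool = False) -> AssocResult:
    """Sibling-difference association for one SNP.

    Regresses the within-pair phenotype difference on the dosage difference
    through the origin.  Every within-family sibling pair enters as a
    pseudo-independent pair; standard errors are clustered on family.  An
    intercept can be added for diagnostics but is off by default.
    """
    j = _snp_index(cohort, snp)
    r1, r2 = cohort.sib_pairs()
    if len(r1) < 2:
        raise InestimableError("need >= 2 sibling pairs")
    d = cohort.dosages[:, j].astype(float)
    ph = cohort.phenotypes[phenotype].to_numpy()
    dg = d[r1] - d[r2]
    dy = ph[r1] - ph[r2]
    if np.all(dg == 0):
        raise InestimableError(f"{_snp_id(cohort, snp)}: no within-pair "
                               "genotype variation")
    X = np.column_stack([dg, np.ones_like(dg)]) if intercept else dg[:, None]
    coef, resid = _ols(X, dy)
    fam = cohort.samples["family_id"].to_numpy()[r1]
    cov = cluster_robust_cov(X, resid, fam)
    se = float(np.sqrt(cov[0, 0]))
    df = len(pd.unique(fam)) - 1
    return AssocResult(snp_id=_snp_id(cohort, snp), beta=float(coef[0]),
                       se=se, p=_p_from_t(coef[0], se, df), n=len(dg),
                       method="sib_diff")


def family_fe_assoc(cohort: FamilyCohort, snp: int | str,
                    phenotype: str = "x",
                    covariates: np.ndarray | None = None) -> AssocResult:
    """Family fixed-effects (within) association for one SNP.

    Demeans dosage and phenotype by family across the cohort's siblings and
    regresses the demeaned phenotype on the demeaned dosage; equivalent to
    including a dummy variable per family.  CR1 family-clustered standard
    errors, t reference with G - 1 degrees of freedom.
    """
    j = _snp_index(cohort, snp)
    rows = cohort.offspring_rows
    fam = cohort.family_codes(rows)
    g = cohort.dosages[rows, j].astype(float)
    ph = cohort.phenotypes[phenotype].to_numpy()[rows]
    gw = g - _group_mean(g, fam)
    yw = ph - _group_mean(ph, fam)
    if np.allclose(gw, 0):
        raise InestimableError(f"{_snp_id(cohort, snp)}: no within-family "
                               "genotype variation")
    cols = [gw]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(rows):
            C = C.T
        cols += [C[:, k] - _group_mean(C[:, k], fam)
                 for k in range(C.shape[1])]
    X = np.column_stack(cols)
    coef, resid = _ols(X, yw)
    cov = cluster_robust_cov(X, resid, fam)
    se = float(np.sqrt(cov[0, 0]))
    G = fam.max() + 1
    return AssocResult(snp_id=_snp_id(cohort, snp), beta=float(coef[0]),
                       se=se, p=_p_from_t(coef[0], se, G - 1), n=len(rows),
                       method="family_fe")


def trio_assoc(cohort: FamilyCohort, snp: int | str,
               phenotype: str = "x") -> AssocResult:
    """Offspring association conditional on both parents' genotypes.

    OLS of the offspring phenotype on offspring, mother and father dosages
    (one offspring per family), returning the conditional coefficient for
    each.  Robust (HC1) standard errors.
    """
    j = _snp_index(cohort, snp)
    off, mo, fa = cohort.trio_rows()
    if len(off) < 5:
        raise InestimableError("need >= 5 complete trios")
    d = cohort.dosages[:, j].astype(float)
    X = np.column_stack([d[off], d[mo], d[fa], np.ones(len(off))])
    if np.linalg.matrix_rank(X) < 4:
        raise InestimableError(
            f"{_snp_id(cohort, snp)}: offspring/mother/father dosages are "
            "collinear (rank deficient)")
    y = cohort.phenotypes[phenotype].to_numpy()[off]
    coef, resid = _ols(X, y)
    cov = _hc1_cov(X, resid)
    se = np.sqrt(np.diag(cov))
    df = len(off) - 4
    return AssocResult(snp_id=_snp_id(cohort, snp), beta=float(coef[0]),
                       se=float(se[0]), p=_p_from_t(coef[0], se[0], df),
                       n=len(off), method="trio_adjusted",
                       beta_mother=float(coef[1]), se_mother=float(se[1]),
                       beta_father=float(coef[2]), se_father=float(se[2]))


def _snp_index(cohort: FamilyCohort, snp: int | str) -> int:
    if isinstance(snp, str):
        return cohort.snp_ids.index(snp)
    return int(snp)


def _snp_id(cohort: FamilyCohort, snp: int | str) -> str:
    return snp if isinstance(snp, str) else cohort.snp_ids[int(snp)]


def _group_mean(v: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-group mean broadcast back to observations (codes 0..G-1)."""
    sums = np.bincount(codes, weights=v)
    cnts = np.bincount(codes)
    return (sums / cnts)[codes]


# ---------------------------------------------------------------------------
# vectorized all-SNP estimators (used by the simulation study)
# ---------------------------------------------------------------------------

def _as_pheno_matrix(y) -> tuple[np.ndarray, bool]:
    Y = np.asarray(y, dtype=float)
    single = Y.ndim == 1
    return (Y[:, None] if single else Y), single


def bulk_unrelated(G: np.ndarray, y: np.ndarray):
    """Simple-regression slope of each phenotype on each dosage column.

    Vectorized across SNPs with HC1 standard errors and normal-reference
    p-values (the summary-export convention).  ``y`` may be (n,) or (n, K)
    — multiple phenotypes share the centred genotype matrix.  Columns with
    zero genotype variance get NaN estimates.  Returns a DataFrame per
    phenotype (a single DataFrame for 1-D input).
    """
    G = np.asarray(G, dtype=float)
    Y, single = _as_pheno_matrix(y)
    n, L = G.shape
    gc = G - G.mean(axis=0)
    sgg = (gc * gc).sum(axis=0)
    ok = sgg > 0
    Yc = Y - Y.mean(axis=0)
    B = gc.T @ Yc  # (L, K)
    out = []
    for k in range(Y.shape[1]):
        beta = np.full(L, np.nan)
        se = np.full(L, np.nan)
        beta[ok] = B[ok, k] / sgg[ok]
        e = Yc[:, k][:, None] - gc[:, ok] * beta[ok]
        meat = ((gc[:, ok] * e) ** 2).sum(axis=0)
        se[ok] = np.sqrt(n / (n - 2) * meat) / sgg[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(beta / se))
        out.append(pd.DataFrame({"beta": beta, "se": se, "p": p, "n": n}))
    return out[0] if single else out


def bulk_family_fe(G: np.ndarray, y: np.ndarray, fam_codes: np.ndarray):
    """Family fixed-effects slope for every SNP, CR1 clustered SEs.

    ``fam_codes`` are integer family labels.  ``y`` may be (n,) or (n, K);
    phenotypes share the family-demeaned genotype matrix.  Normal-reference
    p-values.
    """
    G = np.asarray(G, dtype=float)
    Y, single = _as_pheno_matrix(y)
    codes = np.asarray(fam_codes)
    order = np.argsort(codes, kind="stable")
    G, Y, codes = G[order], Y[order], codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    cnts = np.diff(np.r_[starts, len(codes)])
    rep = np.repeat(np.arange(len(starts)), cnts)

    Gw = G - (np.add.reduceat(G, starts, axis=0) / cnts[:, None])[rep]
    Yw = Y - (np.add.reduceat(Y, starts, axis=0) / cnts[:, None])[rep]

    sgg = (Gw * Gw).sum(axis=0)
    ok = sgg > 0
    L = G.shape[1]
    B = Gw.T @ Yw
    nG = len(starts)
    N = len(Y)
    c = nG / (nG - 1)
    out = []
    for k in range(Y.shape[1]):
        beta = np.full(L, np.nan)
        se = np.full(L, np.nan)
        beta[ok] = B[ok, k] / sgg[ok]
        e = Yw[:, k][:, None] - Gw[:, ok] * beta[ok]
        S = np.add.reduceat(Gw[:, ok] * e, starts, axis=0)  # family scores
        se[ok] = np.sqrt(c * (S * S).sum(axis=0)) / sgg[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(beta / se))
        out.append(pd.DataFrame({"beta": beta, "se": se, "p": p, "n": N}))
    return out[0] if single else out


def bulk_trio(Go: np.ndarray, Gm: np.ndarray, Gf: np.ndarray, y: np.ndarray):
    """Parent-adjusted offspring slope for every SNP, HC1 SEs.

    Per SNP: OLS of the phenotype on [offspring, mother, father dosage, 1];
    reports the offspring conditional coefficient plus the parental
    coefficients.  ``y`` may be (n,) or (n, K).
    """
    Go = np.asarray(Go, dtype=float)
    Y, single = _as_pheno_matrix(y)
    n, L = Go.shape
    K = Y.shape[1]
    ones = np.ones(n)
    out = np.full((K, L, 6), np.nan)
    for j in range(L):
        X = np.column_stack([Go[:, j], Gm[:, j], Gf[:, j], ones])
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < 4:
            continue
        bread = np.linalg.inv(XtX)
        coefs = bread @ (X.T @ Y)  # (4, K)
        for k in range(K):
            e = Y[:, k] - X @ coefs[:, k]
            Xe = X * e[:, None]
            cov = n / (n - 4) * bread @ (Xe.T @ Xe) @ bread
            sd = np.sqrt(np.diag(cov))
            out[k, j] = [coefs[0, k], sd[0], coefs[1, k], sd[1],
                         coefs[2, k], sd[2]]
    frames = []
    for k in range(K):
        o = out[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = 2.0 * stats.norm.sf(np.abs(o[:, 0] / o[:, 1]))
        frames.append(pd.DataFrame(
            {"beta": o[:, 0], "se": o[:, 1], "p": p, "n": n,
             "beta_mother": o[:, 2], "se_mother": o[:, 3],
             "beta_father": o[:, 4], "se_father": o[:, 5]}))
    return frames[0] if single else frames


def cohort_assoc_tables(cohort: FamilyCohort, method: str,
                        phenotypes=("x", "y")) -> dict[str, pd.DataFrame]:
    """All-SNP association tables for several phenotypes in one pass.

    ``method`` is one of ``unrelated`` (one sibling per family, the first
    by individual-ID order), ``family_fe`` (all siblings), ``sib_diff``
    (identical point estimates to ``family_fe`` for two-sibling families)
    or ``trio`` (one offspring per family, parent-adjusted).  The
    phenotypes share the (demeaned) genotype matrix, which dominates the
    cost.  Returns {phenotype: tidy table keyed on snp_id}.
    """
    Y = cohort.phenotypes[list(phenotypes)].to_numpy(dtype=float)
    d = cohort.dosages
    if method == "unrelated":
        rows = _first_sibling_rows(cohort)
        tabs = bulk_unrelated(d[rows].astype(float), Y[rows])
    elif method in ("family_fe", "sib_diff"):
        rows = cohort.offspring_rows
        tabs = bulk_family_fe(d[rows].astype(float), Y[rows],
                              cohort.family_codes(rows))
    elif method == "trio":
        off, mo, fa = cohort.trio_rows()
        tabs = bulk_trio(d[off].astype(float), d[mo].astype(float),
                         d[fa].astype(float), Y[off])
    else:
        raise ValueError(f"unknown association method {method!r}")
    out = {}
    for name, tab in zip(phenotypes, tabs):
        tab.insert(0, "snp_id", cohort.snp_ids)
        tab.insert(1, "method", method)
        tab.insert(2, "phenotype", name)
        out[name] = tab
    return out


def cohort_assoc_table(cohort: FamilyCohort, method: str,
                       phenotype: str = "x") -> pd.DataFrame:
    """All-SNP association table for one phenotype and estimator."""
    return cohort_assoc_tables(cohort, method, (phenotype,))[phenotype]


def _first_sibling_rows(cohort: FamilyCohort) -> np.ndarray:
    """One offspring per family: the first by stable individual-ID order."""
    s = cohort.samples
    off = s[~s["role"].isin(("mother", "father"))]
    keep = off.sort_values("individual_id").groupby(
        "family_id", sort=False).head(1)
    return keep.index.to_numpy()
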