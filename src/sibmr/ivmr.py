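"""Individual-level instrumental-variable MR: scores and 2SLS.

Allele harmonization of external weight tables, weighted polygenic score
(PRS) construction, and two-stage least squares of the outcome on the
exposure instrumented by the score (or by raw SNPs), with optional family
fixed effects and family-clustered standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import InestimableError, cluster_robust_cov, _hc1_cov, _p_from_t
from .famsim import FamilyCohort

__all__ = [
    "IVEstimate",
    "harmonize",
    "build_prs",
    "tsls",
    "cohort_tsls",
]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class IVEstimate:
    """A 2SLS causal-effect estimate (outcome units per exposure unit)."""

    beta: float
    se: float
    p: float
    n: int
    first_stage_f: float
    method: str

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)


# ---------------------------------------------------------------------------
# allele harmonization and score construction
# ---------------------------------------------------------------------------

def harmonize(weights: pd.DataFrame,
              target: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Align a SNP weight table to a target allele coding.

    Both tables are keyed on ``snp_id`` with ``effect_allele`` and
    ``other_allele`` columns.  Matching allele pairs pass through; swapped
    pairs flip the sign of ``weight``; irreconcilable pairs (or SNPs absent
    from the target) are dropped.  Palindromic (A/T, C/G) SNPs are kept but
    flagged, since strand cannot be resolved without frequencies.

    Returns the aligned table (target allele coding) and a report dict with
    ``n_flipped``, ``n_dropped``, ``dropped`` ids and ``palindromic`` ids.
    """
    for col in ("snp_id", "effect_allele", "other_allele"):
        if col not in weights or col not in target:
            raise ValueError(f"both tables need a {col!r} column")
    m = weights.merge(target[["snp_id", "effect_allele", "other_allele"]],
                      on="snp_id", suffixes=("", "_target"), how="inner")
    same = (m["effect_allele"] == m["effect_allele_target"]) & \
           (m["other_allele"] == m["other_allele_target"])
    swapped = (m["effect_allele"] == m["other_allele_target"]) & \
              (m["other_allele"] == m["effect_allele_target"])
    keep = m[same | swapped].copy()
    keep.loc[swapped[same | swapped], "weight"] *= -1.0
    keep["effect_allele"] = keep.pop("effect_allele_target")
    keep["other_allele"] = keep.pop("other_allele_target")
    palin = [sid for sid, ea, oa in zip(keep["snp_id"], keep["effect_allele"],
                                        keep["other_allele"])
             if frozenset((ea, oa)) in _PALINDROMIC]
    dropped = sorted(set(weights["snp_id"]) - set(keep["snp_id"]))
    report = {"n_input": len(weights), "n_aligned": len(keep),
              "n_flipped": int(swapped.sum()), "n_dropped": len(dropped),
              "dropped": dropped, "palindromic": palin}
    return keep.reset_index(drop=True), report


def build_prs(dosages: pd.DataFrame | np.ndarray,
              weights: pd.DataFrame,
              snp_ids: list[str] | None = None) -> np.ndarray:
    """Weighted polygenic score: score_i = sum_j w_j * dosage_ij.

    ``dosages`` is a DataFrame with SNP columns (or an array plus
    ``snp_ids``).  SNPs in the weight table but absent from the dosage
    matrix are skipped; zero usable SNPs is an error.
    """
    if isinstance(dosages, pd.DataFrame):
        cols = list(dosages.columns)
        mat = dosages.to_numpy(dtype=float)
    else:
        if snp_ids is None:
            raise ValueError("snp_ids required with an array dosage matrix")
        cols = list(snp_ids)
        mat = np.asarray(dosages, dtype=float)
    pos = {s: k for k, s in enumerate(cols)}
    used = weights[weights["snp_id"].isin(pos)]
    if len(used) == 0:
        raise InestimableError("no weight-table SNP present in the dosages")
    idx = np.array([pos[s] for s in used["snp_id"]])
    w = used["weight"].to_numpy(dtype=float)
    return mat[:, idx] @ w


# ---------------------------------------------------------------------------
# two-stage least squares
# ---------------------------------------------------------------------------

def tsls(outcome: np.ndarray, exposure: np.ndarray,
         instruments: np.ndarray,
         covariates: np.ndarray | None = None,
         clusters: np.ndarray | None = None,
         family_fe: bool = False,
         family: np.ndarray | None = None,
         method: str | None = None) -> IVEstimate:
    """Two-stage least squares of outcome on exposure.

    With ``family_fe`` every variable (outcome, exposure, instruments,
    covariates) is within-transformed by ``family`` before estimation and
    no intercept is fitted; the within-family variation of the instrument
    identifies the effect.  Standard errors are CR1 family-clustered when
    ``clusters`` (or, under FE, ``family``) is given, HC1 otherwise.  The
    first-stage strength is reported as the (cluster-)robust F statistic of
    the excluded instruments.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    Z = np.asarray(instruments, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    C = None
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
    n = len(y)

    if family_fe:
        if family is None:
            raise ValueError("family labels required when family_fe=True")
        codes = pd.factorize(np.asarray(family))[0]
        y = y - _gmean(y, codes)
        x = x - _gmean(x, codes)
        Z = Z - np.column_stack([_gmean(Z[:, k], codes)
                                 for k in range(Z.shape[1])])
        if C is not None:
            C = C - np.column_stack([_gmean(C[:, k], codes)
                                     for k in range(C.shape[1])])
        exog = C if C is not None else np.empty((n, 0))
        if clusters is None:
            clusters = family
    else:
        ones = np.ones((n, 1))
        exog = np.hstack([C, ones]) if C is not None else ones

    if np.allclose(Z.var(axis=0), 0):
        raise InestimableError("instrument has no (within-)variance")
    X = np.hstack([x[:, None], exog])
    Zfull = np.hstack([Z, exog])

    ZtZ = Zfull.T @ Zfull
    try:
        ZtZ_inv = np.linalg.inv(ZtZ)
    except np.linalg.LinAlgError as err:
        raise InestimableError(f"instrument matrix singular: {err}") from err
    ZtX = Zfull.T @ X
    Zty = Zfull.T @ y
    A = ZtX.T @ ZtZ_inv @ ZtX
    try:
        beta = np.linalg.solve(A, ZtX.T @ ZtZ_inv @ Zty)
    except np.linalg.LinAlgError as err:
        raise InestimableError(f"2SLS normal equations singular: {err}") \
            from err
    resid = y - X @ beta
    Xhat = Zfull @ (ZtZ_inv @ ZtX)
    if clusters is not None:
        cov = cluster_robust_cov(Xhat, resid, clusters)
        G = len(pd.unique(np.asarray(clusters)))
        df = G - 1
    else:
        cov = _hc1_cov(Xhat, resid)
        df = n - X.shape[1]
    se = float(np.sqrt(cov[0, 0]))

    fstat = _first_stage_f(x, Z, exog, clusters)
    tag = method or ("tsls_family_fe" if family_fe
                     else ("tsls_siblings" if clusters is not None
                           else "tsls_unrelated"))
    return IVEstimate(beta=float(beta[0]), se=se,
                      p=_p_from_t(beta[0], se, df), n=n,
                      first_stage_f=fstat, method=tag)


def _first_stage_f(x, Z, exog, clusters):
    """Robust Wald F for the excluded instruments in the first stage."""
    W = np.hstack([Z, exog])
    coef, _, rank, _ = np.linalg.lstsq(W, x, rcond=None)
    if rank < W.shape[1]:
        return np.nan
    resid = x - W @ coef
    if clusters is not None:
        try:
            cov = cluster_robust_cov(W, resid, clusters)
        except InestimableError:
            return np.nan
    else:
        cov = _hc1_cov(W, resid)
    k = Z.shape[1]
    b = coef[:k]
    V = cov[:k, :k]
    try:
        return float(b @ np.linalg.solve(V, b) / k)
    except np.linalg.LinAlgError:
        return np.nan


def _gmean(v: np.ndarray, codes: np.ndarray) -> np.ndarray:
    sums = np.bincount(codes, weights=v)
    cnts = np.bincount(codes)
    return (sums / cnts)[codes]


# ---------------------------------------------------------------------------
# cohort-level convenience wrappers (the MR-PRS estimators)
# ---------------------------------------------------------------------------

def cohort_tsls(cohort: FamilyCohort, weights: pd.DataFrame | None = None,
                design: str = "unrelated",
                exposure: str = "x", outcome: str = "y") -> IVEstimate:
    """PRS-instrumented 2SLS on a family cohort.

    ``design``: ``unrelated`` uses one sibling per family (first by
    individual-ID order) without fixed effects; ``siblings`` uses all
    siblings with family-clustered errors but no fixed effects;
    ``siblings_fe`` adds family fixed effects.  Without a weight table the
    score weights every SNP equally (the simulator's generative shape).
    """
    from .assoc import _first_sibling_rows

    d = cohort.dosages.astype(float)
    if weights is not None:
        dos = pd.DataFrame(d, columns=cohort.snp_ids)
        score = build_prs(dos, weights)
    else:
        score = d.sum(axis=1)
    ph = cohort.phenotypes
    x = ph[exposure].to_numpy()
    y = ph[outcome].to_numpy()
    fam = cohort.samples["family_id"].to_numpy()

    if design == "unrelated":
        rows = _first_sibling_rows(cohort)
        est = tsls(y[rows], x[rows], score[rows], method="tsls_unrelated")
    elif design == "siblings":
        rows = cohort.offspring_rows
        est = tsls(y[rows], x[rows], score[rows], clusters=fam[rows],
                   method="tsls_siblings")
    elif design == "siblings_fe":
        rows = cohort.offspring_rows
        est = tsls(y[rows], x[rows], score[rows], family=fam[rows],
                   family_fe=True, method="tsls_family_fe")
    else:
        raise ValueError(f"unknown design {design!r}")
    return est
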