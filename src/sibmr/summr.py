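"""Summary-data Mendelian randomization estimators.

Works on aligned per-SNP (beta_exposure, se_exposure, beta_outcome,
se_outcome) tables, as produced by any of the association estimators in
:mod:`sibmr.assoc` — including the within-family ones, which is the point:
within-family summary statistics can be fed to every standard two-sample
MR method.

Estimators: Wald ratio, random-effects IVW, MR-Egger, weighted median,
weighted mode; plus Cochran's Q, the unrelated-vs-within difference test,
and the seemingly-unrelated-regression style total-vs-within shrinkage.

Ratio standard errors use the first-order delta approximation ignoring the
exposure-side error (the NOME convention); a second-order option is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import InestimableError
from .famsim import FamilyCohort

__all__ = [
    "MREstimate",
    "ShrinkageResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "cochran_q",
    "p_diff",
    "shrinkage_sur",
    "make_summary_stats",
    "read_summary_stats",
    "write_mr_results",
]

REQUIRED_COLS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


@dataclass
class MREstimate:
    """A pooled causal-effect estimate from summary data."""

    method: str
    beta: float
    se: float
    p: float
    n_snps: int
    Q: float | None = None
    Q_p: float | None = None
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    def to_dict(self) -> dict:
        lo, hi = self.ci
        d = {"method": self.method, "beta": self.beta, "se": self.se,
             "ci_low": lo, "ci_high": hi, "p": self.p,
             "n_snps": self.n_snps, "Q": self.Q, "Q_p": self.Q_p}
        if self.intercept is not None:
            d.update(egger_intercept=self.intercept,
                     egger_intercept_se=self.intercept_se,
                     egger_intercept_p=self.intercept_p)
        return d


def _check(stats_df: pd.DataFrame, min_snps: int, method: str) -> pd.DataFrame:
    for col in REQUIRED_COLS:
        if col not in stats_df:
            raise ValueError(f"summary table lacks column {col!r}")
    df = stats_df.dropna(subset=list(REQUIRED_COLS))
    bad = df["beta_exposure"] == 0
    if bad.any():
        df = df[~bad]
    if len(df) < min_snps:
        raise InestimableError(
            f"{method} needs >= {min_snps} usable SNPs, got {len(df)}")
    return df


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan


# ---------------------------------------------------------------------------
# core estimators
# ---------------------------------------------------------------------------

def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate beta_y / beta_x.

    First-order SE ``se_y/|beta_x|`` (NOME); ``second_order`` adds the
    exposure-side term ``beta_y^2 se_x^2 / beta_x^4``.
    """
    if beta_x == 0:
        raise InestimableError("Wald ratio undefined for beta_exposure = 0")
    beta = beta_y / beta_x
    var = (se_y / beta_x) ** 2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    se = float(np.sqrt(var))
    return MREstimate(method="wald", beta=float(beta), se=se,
                      p=_normal_p(beta, se), n_snps=1)


def ivw(stats_df: pd.DataFrame, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted pooled Wald ratio.

    Equivalent to weighted least squares of beta_outcome on beta_exposure
    through the origin with weights 1/se_outcome^2.  Under
    ``random_effects`` the SE is inflated multiplicatively by
    ``max(1, sqrt(Q/(L-1)))`` (overdispersion scaling).  SNPs with
    beta_exposure = 0 are excluded.
    """
    df = _check(stats_df, 1, "IVW")
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = _floor_se(df["se_outcome"].to_numpy(dtype=float))
    w = (bx / sy) ** 2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    L = len(df)
    Q = float(np.sum(w * (r - beta) ** 2))
    Q_p = float(stats.chi2.sf(Q, L - 1)) if L > 1 else np.nan
    if random_effects and L > 1:
        se *= max(1.0, np.sqrt(Q / (L - 1)))
    return MREstimate(method="ivw", beta=beta, se=se, p=_normal_p(beta, se),
                      n_snps=L, Q=Q, Q_p=Q_p)


def mr_egger(stats_df: pd.DataFrame) -> MREstimate:
    """MR-Egger: weighted regression of beta_outcome on beta_exposure with
    an intercept (weights 1/se_outcome^2), SNPs oriented to positive
    beta_exposure.  The intercept estimates directional pleiotropy; the
    slope is the causal effect.  Multiplicative overdispersion scaling of
    both SEs when the fit is overdispersed."""
    df = _check(stats_df, 3, "MR-Egger")
    sign = np.sign(df["beta_exposure"].to_numpy(dtype=float))
    bx = df["beta_exposure"].to_numpy(dtype=float) * sign
    by = df["beta_outcome"].to_numpy(dtype=float) * sign
    sy = df["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy**2
    X = np.column_stack([bx, np.ones_like(bx)])
    WX = X * w[:, None]
    A = X.T @ WX
    coef = np.linalg.solve(A, WX.T @ by)
    resid = by - X @ coef
    L = len(df)
    phi = float(np.sum(w * resid**2) / (L - 2)) if L > 2 else 1.0
    cov = np.linalg.inv(A) * max(1.0, phi)
    slope, icept = float(coef[0]), float(coef[1])
    se_s, se_i = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    Q = float(np.sum(w * resid**2))
    Q_p = float(stats.chi2.sf(Q, L - 2)) if L > 2 else np.nan
    # t reference with L - 2 df, the usual Egger convention
    p_s = float(2.0 * stats.t.sf(abs(slope) / se_s, L - 2)) if se_s > 0 else np.nan
    p_i = float(2.0 * stats.t.sf(abs(icept) / se_i, L - 2)) if se_i > 0 else np.nan
    return MREstimate(method="egger", beta=slope, se=se_s, p=p_s, n_snps=L,
                      Q=Q, Q_p=Q_p, intercept=icept, intercept_se=se_i,
                      intercept_p=p_i)


def _floor_se(se: np.ndarray) -> np.ndarray:
    # exactly-deterministic inputs give se 0; keep the weight finite
    return np.maximum(se, 1e-150)


def _ratios_and_weights(df: pd.DataFrame):
    bx = df["beta_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = _floor_se(df["se_outcome"].to_numpy(dtype=float))
    return by / bx, (bx / sy) ** 2


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    """Weight-interpolated 50th percentile of the ratios."""
    order = np.argsort(r)
    r, w = r[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum = cum / np.sum(w)
    return float(np.interp(0.5, cum, r))


def _mode_point(r: np.ndarray, w: np.ndarray, bandwidth: float) -> float:
    """Weighted kernel-density mode of the ratios (Silverman-scaled)."""
    s = _weighted_mad(r, w)
    h = bandwidth * 0.9 * s * len(r) ** (-0.2)
    if h <= 0:
        return float(r[np.argmax(w)])
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    dens = np.zeros_like(grid)
    for rj, wj in zip(r, w):
        dens += wj * np.exp(-0.5 * ((grid - rj) / h) ** 2)
    return float(grid[np.argmax(dens)])


def _weighted_mad(r: np.ndarray, w: np.ndarray) -> float:
    med = _weighted_median_point(r, w)
    return 1.4826 * _weighted_median_point(np.abs(r - med), w)


def _bootstrap_se(point_fn, df: pd.DataFrame, n_boot: int,
                  seed) -> tuple[float, np.ndarray]:
    """Parametric bootstrap over the summary-statistic sampling error."""
    rng = np.random.default_rng(seed)
    bx = df["beta_exposure"].to_numpy(dtype=float)
    sx = df["se_exposure"].to_numpy(dtype=float)
    by = df["beta_outcome"].to_numpy(dtype=float)
    sy = df["se_outcome"].to_numpy(dtype=float)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(len(bx))
        byb = by + sy * rng.standard_normal(len(by))
        bxb[bxb == 0] = 1e-12
        reps[b] = point_fn(byb / bxb, (bxb / sy) ** 2)
    return float(reps.std(ddof=1)), reps


def weighted_median(stats_df: pd.DataFrame, n_boot: int = 1000,
                    seed: int | None = 0) -> MREstimate:
    """Weighted-median MR: consistent when >= 50% of the weight comes from
    valid instruments.  SE by seeded parametric bootstrap."""
    df = _check(stats_df, 3, "weighted median")
    r, w = _ratios_and_weights(df)
    beta = _weighted_median_point(r, w)
    se, _ = _bootstrap_se(_weighted_median_point, df, n_boot, seed)
    return MREstimate(method="weighted_median", beta=beta, se=se,
                      p=_normal_p(beta, se), n_snps=len(df))


def weighted_mode(stats_df: pd.DataFrame, bandwidth: float = 1.0,
                  n_boot: int = 1000, seed: int | None = 0) -> MREstimate:
    """Weighted-mode MR: the kernel-density mode of the Wald ratios,
    consistent when the largest weight cluster is valid (ZEMPA).  Bandwidth
    scales the Silverman rule; SE by seeded parametric bootstrap."""
    df = _check(stats_df, 3, "weighted mode")
    r, w = _ratios_and_weights(df)
    beta = _mode_point(r, w, bandwidth)
    se, _ = _bootstrap_se(lambda rr, ww: _mode_point(rr, ww, bandwidth),
                          df, n_boot, seed)
    return MREstimate(method="weighted_mode", beta=beta, se=se,
                      p=_normal_p(beta, se), n_snps=len(df))


def cochran_q(stats_df: pd.DataFrame,
              pooled_beta: float | None = None) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the Wald ratios about the pooled IVW
    estimate (or a supplied one).  Returns (Q, df, p)."""
    df = _check(stats_df, 2, "Cochran's Q")
    r, w = _ratios_and_weights(df)
    if pooled_beta is None:
        pooled_beta = float(np.sum(w * r) / np.sum(w))
    Q = float(np.sum(w * (r - pooled_beta) ** 2))
    dof = len(df) - 1
    return Q, dof, float(stats.chi2.sf(Q, dof))


def p_diff(est_a: MREstimate, est_b: MREstimate) -> float:
    """Two-sided normal test of equality of two independent MR estimates."""
    z = (est_a.beta - est_b.beta) / np.sqrt(est_a.se**2 + est_b.se**2)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# total-vs-within shrinkage
# ---------------------------------------------------------------------------

@dataclass
class ShrinkageResult:
    """Per-SNP and pooled attenuation of total to within-family slopes.

    ``percent`` = 100 * (total - within) / total, with delta-method SEs
    from the joint (cluster-robust) covariance of the two slopes.
    """

    per_snp: pd.DataFrame  # snp_id, beta_total, beta_within, ses, cov, percent, percent_se
    pooled_percent: float
    pooled_se: float
    pooled_ci: tuple[float, float]
    n_snps_used: int
    excluded: list = field(default_factory=list)


def shrinkage_sur(cohort: FamilyCohort, snps: list | None = None,
                  phenotype: str = "x") -> ShrinkageResult:
    """Joint total and within-family slope per SNP, with shrinkage.

    For each SNP the total (no fixed effect) and within (family fixed
    effect) sibling regressions are estimated on the same sample; their
    joint covariance comes from stacked estimating equations with scores
    summed by family (a sandwich, so valid under the cross-equation
    dependence that sharing the sample induces).  Per-SNP percent
    shrinkage uses the delta method; pooling is fixed-effect inverse
    variance.  SNPs with total slope indistinguishable from zero (|t| < 1)
    are excluded from pooling.
    """
    rows = cohort.offspring_rows
    fam = cohort.family_codes(rows)
    ph = cohort.phenotypes[phenotype].to_numpy()[rows]
    ids = cohort.snp_ids if snps is None else list(snps)
    jidx = [cohort.snp_ids.index(s) if isinstance(s, str) else int(s)
            for s in ids]
    D = cohort.dosages[rows][:, jidx].astype(float)
    G = int(fam.max()) + 1

    yw = ph - _gmean(ph, fam)
    recs, excluded = [], []
    for k, j in enumerate(jidx):
        g = D[:, k]
        gc = g - g.mean()
        yc = ph - ph.mean()
        sgg_t = np.sum(gc * gc)
        gw = g - _gmean(g, fam)
        sgg_w = np.sum(gw * gw)
        if sgg_t == 0 or sgg_w == 0:
            excluded.append(ids[k] if isinstance(ids[k], str)
                            else cohort.snp_ids[j])
            continue
        bt = np.sum(gc * yc) / sgg_t
        bw = np.sum(gw * yw) / sgg_w
        et = yc - bt * gc
        ew = yw - bw * gw
        # stacked per-family score sums -> 2x2 sandwich
        St = np.bincount(fam, weights=gc * et, minlength=G)
        Sw = np.bincount(fam, weights=gw * ew, minlength=G)
        c = G / (G - 1)
        v_t = c * np.sum(St**2) / sgg_t**2
        v_w = c * np.sum(Sw**2) / sgg_w**2
        cov_tw = c * np.sum(St * Sw) / (sgg_t * sgg_w)
        name = cohort.snp_ids[j]
        if abs(bt) < np.sqrt(v_t):  # total slope ~ 0: shrinkage undefined
            excluded.append(name)
            pct = pse = np.nan
        else:
            pct = 100.0 * (bt - bw) / bt
            # delta method: d/dbt = 100*bw/bt^2, d/dbw = -100/bt
            gvec = np.array([100.0 * bw / bt**2, -100.0 / bt])
            V = np.array([[v_t, cov_tw], [cov_tw, v_w]])
            pse = float(np.sqrt(gvec @ V @ gvec))
        recs.append({"snp_id": name, "beta_total": bt,
                     "se_total": np.sqrt(v_t), "beta_within": bw,
                     "se_within": np.sqrt(v_w), "cov_tw": cov_tw,
                     "percent": pct, "percent_se": pse})
    per_snp = pd.DataFrame(recs)
    usable = per_snp.dropna(subset=["percent"])
    usable = usable[usable["percent_se"] > 0]
    if len(usable) == 0:
        raise InestimableError("no SNP with estimable shrinkage")
    w = 1.0 / usable["percent_se"].to_numpy() ** 2
    pooled = float(np.sum(w * usable["percent"].to_numpy()) / np.sum(w))
    pse = float(np.sqrt(1.0 / np.sum(w)))
    return ShrinkageResult(per_snp=per_snp, pooled_percent=pooled,
                           pooled_se=pse,
                           pooled_ci=(pooled - 1.96 * pse,
                                      pooled + 1.96 * pse),
                           n_snps_used=len(usable), excluded=excluded)


def _gmean(v: np.ndarray, codes: np.ndarray) -> np.ndarray:
    sums = np.bincount(codes, weights=v)
    cnts = np.bincount(codes)
    return (sums / cnts)[codes]


# ---------------------------------------------------------------------------
# summary-statistic plumbing
# ---------------------------------------------------------------------------

def make_summary_stats(exposure_tab: pd.DataFrame,
                       outcome_tab: pd.DataFrame) -> pd.DataFrame:
    """Merge per-SNP exposure and outcome association tables on snp_id."""
    ex = exposure_tab.rename(columns={"beta": "beta_exposure",
                                      "se": "se_exposure"})
    ou = outcome_tab.rename(columns={"beta": "beta_outcome",
                                     "se": "se_outcome"})
    cols_e = ["snp_id", "beta_exposure", "se_exposure"]
    cols_o = ["snp_id", "beta_outcome", "se_outcome"]
    return ex[cols_e].merge(ou[cols_o], on="snp_id", how="inner")


def read_summary_stats(exposure_path: str, outcome_path: str) -> pd.DataFrame:
    """Read two per-phenotype TSVs (snp_id, beta, se, ...) and align them."""
    return make_summary_stats(pd.read_csv(exposure_path, sep="\t"),
                              pd.read_csv(outcome_path, sep="\t"))


def write_mr_results(estimates: list[MREstimate], path: str) -> None:
    """Write MR estimates as a tidy TSV (or JSON if the path ends .json)."""
    rows = [e.to_dict() for e in estimates]
    if path.endswith(".json"):
        pd.DataFrame(rows).to_json(path, orient="records", indent=2)
    else:
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
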