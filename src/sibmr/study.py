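"""The simulation study: FDR, power and bias of MR designs on a grid.

Replays the comparison of three Mendelian randomization study designs on
forward-simulated family cohorts:

``unrelated_ivw``
    one sibling per family, per-SNP OLS associations, IVW pooling — the
    standard unrelated-sample design, biased under dynastic effects;
``sibling_fe``
    family fixed-effects per-SNP associations on all siblings, IVW pooling;
``trio``
    parent-genotype-adjusted per-SNP associations on one offspring per
    family, IVW pooling.

Every design is evaluated at equal family counts.  Per cell of the
parameter grid the false discovery rate / power is the proportion of
iterations with two-sided p < 0.05, and bias is the mean of (estimate -
true standardized effect), the true effect being sqrt(b_xy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .assoc import InestimableError, cohort_assoc_table, cohort_assoc_tables
from .famsim import FamilyCohort, SimulationConfig, simulate_cohort
from .summr import MREstimate, ivw, make_summary_stats

logger = logging.getLogger("sibmr")

DESIGNS = ("unrelated_ivw", "sibling_fe", "trio")
_DESIGN_METHOD = {"unrelated_ivw": "unrelated", "sibling_fe": "family_fe",
                  "trio": "trio"}

__all__ = ["GridSpec", "run_cell", "run_grid", "split_sample_mr",
           "plot_grid", "DESIGNS"]


@dataclass
class GridSpec:
    """Cartesian parameter grid for the simulation study.

    Defaults follow the study conditions: sibling-pair counts 10k-100k,
    causal variance shares b_xy in {0, .001, .002, .005, .01, .05},
    dynastic shares b_ux in {0, 0.1, 0.2}, confounder shares c in
    {0, 0.1, 0.2}, 100 iterations per cell, all three designs.
    """

    n_families: tuple = (10_000, 20_000, 40_000, 60_000, 100_000)
    b_xy: tuple = (0.0, 0.001, 0.002, 0.005, 0.01, 0.05)
    b_ux: tuple = (0.0, 0.1, 0.2)
    c: tuple = (0.0, 0.1, 0.2)
    iterations: int = 100
    designs: tuple = DESIGNS
    base_config: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(n_families=1))
    seed: int = 0

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        unknown = set(self.designs) - set(DESIGNS)
        if unknown:
            raise ValueError(f"unknown designs: {sorted(unknown)}")
        for n, bxy, bux, c in self.cells():
            replace(self.base_config, n_families=n, b_xy=bxy, b_ux=bux,
                    c_x=c, c_y=c, seed=None).validate()

    def cells(self):
        return product(self.n_families, self.b_xy, self.b_ux, self.c)


def _design_estimate(cohort: FamilyCohort, design: str) -> MREstimate:
    """One causal estimate (per-SNP associations + IVW) for one design."""
    method = _DESIGN_METHOD[design]
    tabs = cohort_assoc_tables(cohort, method, ("x", "y"))
    ss = make_summary_stats(tabs["x"], tabs["y"])
    ss = ss.dropna()
    if len(ss) == 0:
        raise InestimableError(f"{design}: no estimable SNP association")
    return ivw(ss)


def run_cell(config: SimulationConfig, designs=DESIGNS, iterations: int = 100,
             seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Monte-Carlo evaluation of one grid cell.

    Per iteration a fresh cohort is simulated (child seed spawned from
    ``seed``) and each design produces one IVW causal estimate and p-value.
    Returns one row per design with the rejection proportion (``fdr_power``:
    FDR when b_xy = 0, power otherwise), mean bias about sqrt(b_xy), Monte
    Carlo standard errors, and exclusion accounting (inestimable iterations
    are logged and excluded from the proportions).
    """
    config.validate()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(iterations)
    true_beta = np.sqrt(config.b_xy)
    est = {d: [] for d in designs}
    rej = {d: [] for d in designs}
    excluded = {d: 0 for d in designs}
    for it in range(iterations):
        cohort = simulate_cohort(replace(config, seed=children[it]))
        for d in designs:
            try:
                e = _design_estimate(cohort, d)
            except InestimableError as err:
                excluded[d] += 1
                logger.warning("cell iteration %d design %s inestimable: %s",
                               it, d, err)
                continue
            est[d].append(e.beta)
            rej[d].append(e.p < 0.05)
    rows = []
    for d in designs:
        k = len(est[d])
        prop = float(np.mean(rej[d])) if k else np.nan
        bias = float(np.mean(est[d]) - true_beta) if k else np.nan
        rows.append({
            "design": d, "n_families": config.n_families,
            "b_xy": config.b_xy, "b_ux": config.b_ux, "c": config.c_x,
            "fdr_power": prop,
            "fdr_power_mc_se": (np.sqrt(prop * (1 - prop) / k)
                                if k else np.nan),
            "mean_bias": bias,
            "bias_mc_se": (float(np.std(est[d], ddof=1) / np.sqrt(k))
                           if k > 1 else np.nan),
            "iterations_used": k, "iterations_excluded": excluded[d],
            "iterations_requested": iterations,
        })
    return pd.DataFrame(rows)


def run_grid(spec: GridSpec) -> pd.DataFrame:
    """Run every cell of the grid; returns the tidy stacked result table.

    Per-cell seeds are spawned deterministically from the base seed in cell
    order, so any cell can be reproduced in isolation.  Failures inside a
    cell are recorded (via the per-iteration exclusion accounting) and
    never abort the grid.
    """
    spec.validate()
    base = np.random.SeedSequence(spec.seed)
    cells = list(spec.cells())
    cell_seeds = base.spawn(len(cells))
    frames = []
    for idx, (n, bxy, bux, c) in enumerate(cells):
        cfg = replace(spec.base_config, n_families=n, b_xy=bxy, b_ux=bux,
                      c_x=c, c_y=c, seed=None)
        logger.info("grid cell %d/%d: n=%d b_xy=%g b_ux=%g c=%g",
                    idx + 1, len(cells), n, bxy, bux, c)
        frames.append(run_cell(cfg, spec.designs, spec.iterations,
                               cell_seeds[idx]))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "cell", np.repeat(np.arange(len(cells)),
                                    len(spec.designs)))
    return out


def split_sample_mr(cohort: FamilyCohort, snps: list | None = None,
                    exposure: str = "x", outcome: str = "y",
                    method: str = "family_fe",
                    seed: int | np.random.SeedSequence = 0) -> MREstimate:
    """Split-sample two-sample MR on one cohort.

    Families are split 50/50 at random (seeded); SNP-exposure associations
    come from one half and SNP-outcome associations from the other, so the
    two summary sets share no sample (removing weak-instrument/overlap
    bias).  The role-swapped estimate is computed as well and the two are
    combined by fixed-effect inverse-variance meta-analysis.
    """
    rng = np.random.default_rng(seed)
    fams = cohort.samples["family_id"].unique()
    if len(fams) < 4:
        raise InestimableError("need >= 4 families to split")
    perm = rng.permutation(len(fams))
    half_a = set(fams[perm[:len(fams) // 2]])
    in_a = cohort.samples["family_id"].isin(half_a).to_numpy()
    part_a = _subset_cohort(cohort, in_a)
    part_b = _subset_cohort(cohort, ~in_a)

    def one_direction(expo_part, outc_part):
        ex = cohort_assoc_table(expo_part, method, exposure)
        ou = cohort_assoc_table(outc_part, method, outcome)
        ss = make_summary_stats(ex, ou).dropna()
        if snps is not None:
            keep = [s if isinstance(s, str) else cohort.snp_ids[s]
                    for s in snps]
            ss = ss[ss["snp_id"].isin(keep)]
        if len(ss) == 0:
            raise InestimableError("no estimable SNP in split half")
        return ivw(ss)

    e1 = one_direction(part_a, part_b)
    e2 = one_direction(part_b, part_a)
    w = np.array([1.0 / e1.se**2, 1.0 / e2.se**2])
    beta = float((w[0] * e1.beta + w[1] * e2.beta) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    from scipy import stats as _st
    return MREstimate(method="meta", beta=beta, se=se,
                      p=float(2.0 * _st.norm.sf(abs(beta) / se)),
                      n_snps=e1.n_snps)


def _subset_cohort(cohort: FamilyCohort, mask: np.ndarray) -> FamilyCohort:
    rows = np.flatnonzero(mask)
    return FamilyCohort(
        samples=cohort.samples.iloc[rows].reset_index(drop=True),
        phenotypes=cohort.phenotypes.iloc[rows].reset_index(drop=True),
        alleles=cohort.alleles[rows], transmission=cohort.transmission[rows],
        config=cohort.config, true_gamma=cohort.true_gamma,
        snp_ids=cohort.snp_ids)


def plot_grid(results: pd.DataFrame, value: str = "fdr_power",
              path: str | None = None):
    """Power/FDR (or bias) versus sample size by design, one panel per
    (b_xy, b_ux, c) combination present in the result table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos = results[["b_xy", "b_ux", "c"]].drop_duplicates()
    ncol = min(3, len(combos))
    nrow = int(np.ceil(len(combos) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False, sharey=True)
    for ax, (_, combo) in zip(axes.ravel(), combos.iterrows()):
        sub = results[(results["b_xy"] == combo["b_xy"]) &
                      (results["b_ux"] == combo["b_ux"]) &
                      (results["c"] == combo["c"])]
        for d, grp in sub.groupby("design"):
            grp = grp.sort_values("n_families")
            ax.plot(grp["n_families"], grp[value], marker="o", label=d)
        ax.set_title(f"b_xy={combo['b_xy']:g} b_ux={combo['b_ux']:g} "
                     f"c={combo['c']:g}", fontsize=9)
        ax.set_xlabel("families")
    axes[0, 0].set_ylabel(value)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
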