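"""Endogenous-control (reference-gene) selection and normalization.

Two complementary stability measures are provided:

* geNorm M — a gene's mean pairwise standard deviation of log2 expression
  ratios against every other candidate; genes with stable ratios to the
  rest of the panel score low.  The stepwise procedure removes the least
  stable candidate until two remain.
* NormFinder — a variance-decomposition estimate that separates a
  candidate's intergroup variation (systematic expression shifts between
  treatment groups) from its intragroup (replicate) variation; stability
  is the root of their sum, so a gene that tracks treatment is penalised
  even if its replicates are tight.

The selected controls (``Tfrc`` and ``B2m`` for the headline pipeline)
are then used to normalize each sample by the geometric mean of its
control-gene values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityRanking",
    "DEFAULT_REFERENCE_PANEL",
    "DEFAULT_CONTROL_GENES",
    "genorm_m",
    "genorm_rank",
    "normfinder_stability",
    "normalize_to_controls",
]

#: Housekeeping-like candidate panel used by the synthetic experiments.
DEFAULT_REFERENCE_PANEL = (
    "Tfrc", "B2m", "Actb", "Hprt1", "Rpl13a", "Ywhaz", "Ubc", "Ppia", "Tbp", "Gusb",
)

#: Endogenous controls of the headline pipeline.
DEFAULT_CONTROL_GENES = ("Tfrc", "B2m")


@dataclass
class StabilityRanking:
    method: str
    stability: pd.Series  # per-gene stability value, lower = more stable
    final_controls: tuple[str, ...]
    exclusion_order: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        ranked = self.stability.sort_values()
        return pd.DataFrame(
            {
                "gene": ranked.index,
                "method": self.method,
                "stability": ranked.values,
                "rank": np.arange(1, len(ranked) + 1),
            }
        )


def _check_candidates(expr: pd.DataFrame, min_genes: int) -> None:
    if len(expr.index) < min_genes:
        raise ValueError(f"need at least {min_genes} candidate genes, got {len(expr.index)}")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (expr.to_numpy(dtype=float) <= 0).any():
        raise ValueError("expression values must be strictly positive")


def genorm_m(expr: pd.DataFrame) -> pd.Series:
    """geNorm M value per candidate gene.

    M_j is the mean, over all other candidates k, of the sample standard
    deviation (n-1 denominator) of log2(x_j / x_k).  Computed through the
    pairwise covariance identity Var(L_j - L_k) = V_jj + V_kk - 2 V_jk.
    """
    _check_candidates(expr, min_genes=3)
    log2x = np.log2(expr.to_numpy(dtype=float))
    cov = np.cov(log2x, ddof=1)  # genes x genes
    diag = np.diag(cov)
    pair_var = diag[:, None] + diag[None, :] - 2 * cov
    pair_sd = np.sqrt(np.maximum(pair_var, 0.0))
    n = len(expr.index)
    m_values = (pair_sd.sum(axis=1)) / (n - 1)  # diagonal contributes 0
    return pd.Series(m_values, index=expr.index, name="M")


def genorm_rank(expr: pd.DataFrame) -> StabilityRanking:
    """Stepwise geNorm ranking: drop the highest-M candidate until two remain.

    Ties on the maximal M are broken by removing the lexicographically
    last gene id; every tie-break is recorded in ``notes``.  The reported
    per-gene stability value is the M at which a gene was excluded (or the
    final M of the surviving pair).
    """
    _check_candidates(expr, min_genes=3)
    remaining = expr.copy()
    exclusion_order: list[str] = []
    notes: list[str] = []
    stability: dict[str, float] = {}
    while len(remaining.index) > 2:
        m = genorm_m(remaining)
        worst_value = m.max()
        tied = sorted(m.index[m == worst_value])
        worst = tied[-1]
        if len(tied) > 1:
            notes.append(f"tie at M={worst_value:.6g} among {tied}; removed {worst!r}")
        stability[worst] = float(worst_value)
        exclusion_order.append(worst)
        remaining = remaining.drop(index=worst)
    final_m = genorm_m(expr)[remaining.index]  # M of survivors in the full panel
    for gene in remaining.index:
        stability[gene] = float(final_m[gene])
    final_pair = tuple(sorted(remaining.index))
    series = pd.Series(stability).reindex(expr.index)
    series.name = "M"
    return StabilityRanking(
        method="geNorm",
        stability=series,
        final_controls=final_pair,
        exclusion_order=exclusion_order,
        notes=notes,
    )


def normfinder_stability(expr: pd.DataFrame, design: pd.Series) -> StabilityRanking:
    """NormFinder-style stability from a two-way variance decomposition.

    log2 expression is decomposed into gene, group, gene-by-group and
    residual terms.  Per gene, the intergroup variation is the variance of
    the gene-by-group interaction effects, estimated by method of moments
    with the sampling noise of the cell means subtracted and negative
    estimates truncated to zero; the intragroup variation is the mean
    within-cell residual variance.  Stability is the square root of their
    sum — lowest is most stable.
    """
    _check_candidates(expr, min_genes=3)
    design = pd.Series(design)
    missing = [s for s in expr.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    groups = sorted(set(design[expr.columns]))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n_genes = len(expr.index)
    log2x = np.log2(expr.to_numpy(dtype=float))

    cell_mean = np.empty((n_genes, len(groups)))
    cell_mean_var = np.empty((n_genes, len(groups)))  # sampling var of the cell mean
    resid_var = np.empty((n_genes, len(groups)))
    for gi, g in enumerate(groups):
        cols = [i for i, s in enumerate(expr.columns) if design[s] == g]
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        block = log2x[:, cols]
        cell_mean[:, gi] = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        resid_var[:, gi] = v
        cell_mean_var[:, gi] = v / len(cols)

    n_groups = len(groups)
    intragroup = resid_var.mean(axis=1)
    # double-centred interaction effects
    d = (
        cell_mean
        - cell_mean.mean(axis=1, keepdims=True)
        - cell_mean.mean(axis=0, keepdims=True)
        + cell_mean.mean()
    )
    m_stat = (d**2).sum(axis=1) / (n_groups - 1)
    v_i = cell_mean_var.mean(axis=1)
    # moment correction for the double centring across J genes:
    # E[m] = (1 - 2/J) (tau_i^2 + v_i) + (taubar^2 + vbar)/J
    j = float(n_genes)
    u = m_stat - (1 - 2 / j) * v_i - v_i.mean() / j
    tau_bar = max(u.mean() / (1 - 1 / j), 0.0)
    intergroup = (u - tau_bar / j) / (1 - 2 / j)
    truncated = intergroup < 0
    notes = []
    if truncated.any():
        genes = list(expr.index[truncated])
        notes.append(f"negative intergroup variance truncated to 0 for {genes}")
        logger.info("NormFinder: %s", notes[-1])
    intergroup = np.maximum(intergroup, 0.0)
    stability = np.sqrt(intergroup + intragroup)
    series = pd.Series(stability, index=expr.index, name="stability")
    ranked = series.sort_values(kind="stable")
    return StabilityRanking(
        method="NormFinder",
        stability=series,
        final_controls=tuple(sorted(ranked.index[:2])),
        notes=notes,
    )


def normfinder_components(expr: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    """Expose the intra-/intergroup variance components behind the ranking."""
    ranking = normfinder_stability(expr, design)
    # recompute pieces for the audit frame
    design = pd.Series(design)
    groups = sorted(set(design[expr.columns]))
    log2x = np.log2(expr.to_numpy(dtype=float))
    resid = []
    for g in groups:
        cols = [i for i, s in enumerate(expr.columns) if design[s] == g]
        resid.append(log2x[:, cols].var(axis=1, ddof=1))
    intragroup = np.mean(resid, axis=0)
    stability = ranking.stability.to_numpy()
    intergroup = np.maximum(stability**2 - intragroup, 0.0)
    return pd.DataFrame(
        {"intergroup": intergroup, "intragroup": intragroup, "stability": stability},
        index=expr.index,
    )


def normalize_to_controls(
    expr: pd.DataFrame, control_genes: tuple[str, ...] = DEFAULT_CONTROL_GENES
) -> pd.DataFrame:
    """Divide each sample by the geometric mean of its control-gene values.

    Controls stay in the output; after normalization the geometric mean of
    the control genes is exactly 1 in every sample, which also makes the
    operation idempotent.
    """
    for gene in control_genes:
        if gene not in expr.index:
            raise KeyError(f"control gene {gene!r} absent from expression matrix")
    controls = expr.loc[list(control_genes)].to_numpy(dtype=float)
    if (controls <= 0).any():
        gi, si = np.argwhere(controls <= 0)[0]
        raise ValueError(
            f"control gene {control_genes[gi]!r} non-positive in sample "
            f"{expr.columns[si]!r}"
        )
    geo = np.exp(np.mean(np.log(controls), axis=0))
    return expr / geo
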