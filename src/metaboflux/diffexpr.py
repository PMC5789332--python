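"""Differential expression versus the control group.

Statistics run on log2-transformed normalized expression: per gene a
one-way fixed-effects ANOVA across all groups, followed by Tukey HSD
contrasts of each treated group against control (studentized-range
distribution, Tukey–Kramer standard error for unequal group sizes).
Tukey p-values are corrected per group contrast across genes with the
Benjamini–Hochberg step-up.  A gene is called ``up`` (``down``) in a
group when its linear fold change is >= 2 (<= 0.5) and both the omnibus
ANOVA p and the group's Tukey p are below 0.01 with BH q < 0.1;
otherwise ``nc`` (no change).

Fold changes are ratios of geometric means (consistent with the log-scale
tests); an arithmetic-mean variant is available for sensitivity checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fold_changes",
    "anova_tukey",
    "bh_fdr",
    "call_de",
    "de_table",
    "FC_CUTOFF",
    "P_CUTOFF",
    "FDR_CUTOFF",
]

FC_CUTOFF = 2.0
P_CUTOFF = 0.01
FDR_CUTOFF = 0.1


def _split_groups(
    expr: pd.DataFrame, design: pd.Series, control_group: str
) -> tuple[dict[str, list[str]], list[str]]:
    design = pd.Series(design)
    missing = [s for s in expr.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    groups: dict[str, list[str]] = {}
    for sample in expr.columns:
        groups.setdefault(str(design[sample]), []).append(sample)
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent from design")
    treated = [g for g in groups if g != control_group]
    return groups, treated


def fold_changes(
    expr: pd.DataFrame,
    design: pd.Series,
    control_group: str = "CTRL",
    method: str = "geometric",
) -> pd.DataFrame:
    """Linear fold change (treated mean / control mean) per gene and group.

    ``method='geometric'`` (default) uses geometric group means;
    ``'arithmetic'`` uses plain means.  Tidy output: gene, group, fc.
    """
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown method {method!r}")
    values = expr.to_numpy(dtype=float)
    if (values <= 0).any() or not np.isfinite(values).all():
        raise ValueError("expression must be strictly positive and finite; preprocess first")
    groups, treated = _split_groups(expr, design, control_group)

    def group_mean(cols: list[str]) -> np.ndarray:
        block = expr[cols].to_numpy(dtype=float)
        if method == "geometric":
            return np.exp(np.mean(np.log(block), axis=1))
        return block.mean(axis=1)

    ctrl = group_mean(groups[control_group])
    rows = []
    for g in treated:
        fc = group_mean(groups[g]) / ctrl
        rows.append(pd.DataFrame({"gene": expr.index, "group": g, "fc": fc}))
    return pd.concat(rows, ignore_index=True)


def anova_tukey(
    expr: pd.DataFrame, design: pd.Series, control_group: str = "CTRL"
) -> pd.DataFrame:
    """Per-gene one-way ANOVA plus Tukey HSD contrasts vs control.

    Input is linear-scale expression; tests run on log2 values.  Returns a
    tidy frame (gene, group, p_anova, p_tukey): the omnibus p is repeated
    across each gene's contrasts.
    """
    groups, treated = _split_groups(expr, design, control_group)
    singletons = [g for g, cols in groups.items() if len(cols) < 2]
    if singletons:
        raise ValueError(f"groups with fewer than 2 samples: {singletons}")
    log2x = np.log2(expr.to_numpy(dtype=float))
    order = list(groups)
    blocks = [log2x[:, [expr.columns.get_loc(s) for s in groups[g]]] for g in order]
    sizes = np.array([b.shape[1] for b in blocks])
    k = len(order)
    df_resid = int(sizes.sum() - k)

    p_anova = stats.f_oneway(*blocks, axis=1).pvalue

    means = np.column_stack([b.mean(axis=1) for b in blocks])
    sse = sum(((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for b in blocks)
    mse = sse / df_resid
    ctrl_idx = order.index(control_group)
    n_ctrl = sizes[ctrl_idx]

    rows = []
    for g in treated:
        gi = order.index(g)
        # Tukey-Kramer standard error for the pairwise contrast
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[gi] + 1.0 / n_ctrl))
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.abs(means[:, gi] - means[:, ctrl_idx]) / se
        p_tukey = stats.studentized_range.sf(q, k, df_resid)
        p_tukey = np.clip(np.nan_to_num(p_tukey, nan=1.0), 0.0, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "gene": expr.index,
                    "group": g,
                    "p_anova": p_anova,
                    "p_tukey": p_tukey,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def bh_fdr(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    fc: float,
    p: float,
    q: float,
    fc_cutoff: float = FC_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    fdr_cutoff: float = FDR_CUTOFF,
) -> str:
    """Three-way call from the fold-change / p / FDR thresholds."""
    if not all(np.isfinite([fc, p, q])):
        raise ValueError(f"non-finite inputs: fc={fc}, p={p}, q={q}")
    significant = p < p_cutoff and q < fdr_cutoff
    if significant and fc >= fc_cutoff:
        return "up"
    if significant and fc <= 1.0 / fc_cutoff:
        return "down"
    return "nc"


def de_table(
    expr: pd.DataFrame,
    design: pd.Series,
    control_group: str = "CTRL",
    fc_cutoff: float = FC_CUTOFF,
    p_cutoff: float = P_CUTOFF,
    fdr_cutoff: float = FDR_CUTOFF,
    fc_method: str = "geometric",
) -> pd.DataFrame:
    """Full DE table: fold change, ANOVA p, Tukey p, BH q and call per
    (gene, treated group).

    The BH family is the set of genes within one group-vs-control
    contrast, applied to the Tukey p-values.  The gate for a call is the
    larger of the omnibus and contrast p (both must clear ``p_cutoff``).
    """
    fc = fold_changes(expr, design, control_group, method=fc_method)
    tests = anova_tukey(expr, design, control_group)
    table = fc.merge(tests, on=["gene", "group"], validate="one_to_one")
    table["q"] = np.nan
    for g, idx in table.groupby("group").groups.items():
        table.loc[idx, "q"] = bh_fdr(table.loc[idx, "p_tukey"].to_numpy())
    gate_p = np.maximum(table["p_anova"], table["p_tukey"])
    table["call"] = [
        call_de(f, p, q, fc_cutoff, p_cutoff, fdr_cutoff)
        for f, p, q in zip(table["fc"], gate_p, table["q"])
    ]
    return table
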