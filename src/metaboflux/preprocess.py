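"""Raw one-color intensity preprocessing.

The stage order is fixed: per-array NormExp background correction, 75th
percentile inter-array scaling, pooled 30%-quantile low-expression
filtering, then probe-to-gene collapse by median.  Every stage maps a
strictly positive matrix to a strictly positive matrix.

The background model treats an observed spot intensity as the sum of a
normal background, ``B ~ N(mu, sigma^2)``, and an exponential true signal
``S ~ Exp(mean alpha)``.  The corrected intensity is the posterior mean
``E[S | X = x]``, which is strictly positive and strictly increasing in
``x`` — negative or zero corrected intensities never occur, so downstream
log-ratio statistics are always defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "NormexpParams",
    "normexp_moment_start",
    "normexp_fit",
    "normexp_correct",
    "normexp_correct_matrix",
    "percentile75_normalize",
    "filter_low_expression",
    "merge_probes",
]


@dataclass(frozen=True)
class NormexpParams:
    """Normal(mu, sigma) background + Exponential(mean alpha) signal."""

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


def normexp_moment_start(x: np.ndarray) -> NormexpParams:
    """Method-of-moments starting values for the NormExp fit.

    Uses E[X] = mu + alpha, Var[X] = sigma^2 + alpha^2 and the third
    central moment E[(X-EX)^3] = 2 alpha^3 (the normal part is symmetric).
    """
    x = np.asarray(x, dtype=float)
    m, v = x.mean(), x.var()
    m3 = np.mean((x - m) ** 3)
    alpha = max(m3 / 2.0, 1e-12) ** (1.0 / 3.0)
    mu = m - alpha
    s2 = v - alpha**2
    if s2 <= 0:
        s2 = max(0.01 * v, 1e-12)
    return NormexpParams(mu=float(mu), sigma=float(np.sqrt(s2)), alpha=float(alpha))


def _negloglik(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma, alpha = np.exp(log_sigma), np.exp(log_alpha)
    # log density of the Normal+Exponential convolution
    z = (x - mu) / sigma - sigma / alpha
    ll = -np.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(z)
    return -float(np.sum(ll))


def normexp_fit(column: np.ndarray | pd.Series, min_n: int = 50) -> NormexpParams:
    """Maximum-likelihood NormExp parameters for one array's intensities.

    Deterministic given the input: starting values come from moments and
    the convolution log-likelihood is optimised numerically (Nelder–Mead
    with a quasi-Newton polish).  Raises on degenerate (near-constant)
    input, where background and signal are not separable.
    """
    x = np.asarray(column, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} finite intensities, got {x.size}")
    if np.ptp(x) == 0 or x.std() < 1e-12 * max(1.0, abs(x.mean())):
        raise ValueError("constant intensity column: background and signal not separable")
    start = normexp_moment_start(x)
    theta0 = np.array([start.mu, np.log(start.sigma), np.log(start.alpha)])
    res = optimize.minimize(
        _negloglik, theta0, args=(x,), method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-10, maxiter=5000, maxfev=5000),
    )
    res = optimize.minimize(_negloglik, res.x, args=(x,), method="BFGS")
    mu, sigma, alpha = res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2]))
    return NormexpParams(mu=float(mu), sigma=sigma, alpha=alpha)


def normexp_correct(x: np.ndarray | float, params: NormexpParams) -> np.ndarray | float:
    """Posterior mean signal E[S | X = x] under the NormExp model.

    Closed form: with m = x - mu - sigma^2/alpha,
    E[S|x] = m + sigma * phi(m/sigma) / Phi(m/sigma).
    The Mills-ratio term is evaluated in log space so the result stays
    finite and positive far into the left tail.
    """
    arr = np.asarray(x, dtype=float)
    m = arr - params.mu - params.sigma**2 / params.alpha
    z = m / params.sigma
    mills = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    out = m + params.sigma * mills
    # guard exact-zero underflow in extreme tails
    out = np.maximum(out, np.finfo(float).tiny)
    return float(out) if np.isscalar(x) else out


def normexp_correct_matrix(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, NormexpParams]]:
    """Fit and apply NormExp background correction per array (column)."""
    corrected = {}
    fits: dict[str, NormexpParams] = {}
    for sample in matrix.columns:
        params = normexp_fit(matrix[sample].to_numpy())
        fits[sample] = params
        corrected[sample] = normexp_correct(matrix[sample].to_numpy(), params)
    out = pd.DataFrame(corrected, index=matrix.index)
    return out, fits


def percentile75_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each array so its 75th percentile matches the geometric mean
    of all arrays' 75th percentiles (absolute scale is retained)."""
    values = matrix.to_numpy(dtype=float)
    p75 = np.percentile(values, 75, axis=0)
    if (p75 <= 0).any():
        bad = [c for c, p in zip(matrix.columns, p75) if p <= 0]
        raise ValueError(f"columns with non-positive 75th percentile: {bad}")
    target = float(np.exp(np.mean(np.log(p75))))
    return matrix * (target / p75)


def filter_low_expression(
    matrix: pd.DataFrame, quantile: float = 0.30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows whose median intensity falls below the pooled quantile.

    The threshold is the ``quantile`` of all matrix entries pooled; a row
    survives if its median across samples is at or above the threshold.
    Returns the surviving matrix (row order preserved) and a removal log.
    """
    if not 0 <= quantile <= 1:
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    threshold = float(np.quantile(matrix.to_numpy(dtype=float), quantile))
    medians = matrix.median(axis=1)
    keep = medians >= threshold
    if not keep.any():
        raise ValueError(
            f"low-expression filter at quantile {quantile} removed every row "
            f"(threshold {threshold:g}); check upstream scaling"
        )
    removed = matrix.index[~keep]
    log = pd.DataFrame(
        {
            "gene_id": removed,
            "reason": [
                f"median {medians[g]:.6g} below pooled {quantile:.0%} quantile {threshold:.6g}"
                for g in removed
            ],
        }
    )
    return matrix.loc[keep], log


def merge_probes(matrix: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to gene level by per-sample median."""
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    unmapped = [p for p in matrix.index if p not in probe_to_gene]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} unmapped probes (e.g. {unmapped[:3]})",
            stacklevel=2,
        )
    mapped = matrix.loc[[p for p in matrix.index if p in probe_to_gene]]
    genes = pd.Index([probe_to_gene[p] for p in mapped.index], name="gene_id")
    merged = mapped.groupby(genes, sort=False).median()
    return merged
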