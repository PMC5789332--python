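"""Seeded synthetic one-color microarray experiments with known truth.

The generator emulates the study design: six treatment groups (control
CSF plus five disease forms), a small number of independent culture
replicates per group, and spot intensities that are the sum of a normal
scanner background and an exponentially distributed true signal — the
same convolution the NormExp background correction inverts.  Disease
effects are planted as per-gene linear fold changes versus control;
biological replicate variation is a log-normal multiplier on the signal
mean with a stated coefficient of variation.  Baseline (control)
expression is drawn log-uniformly over two decades so the low-expression
filter has genuine work to do.

Every sample is drawn independently (independent assays per group), so
the planted fold change is recovered exactly only in expectation; tests
of fold-change recovery are therefore convergence/Monte-Carlo tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cfi import PUBLISHED_PATHWAY_CFI, PUBLISHED_PATTERN, DEFAULT_PATHWAYS, GROUP_ORDER
from .cohort import load_table1_fixture  # noqa: F401  (re-exported fixture loader)
from .refgenes import DEFAULT_REFERENCE_PANEL

__all__ = [
    "DEFAULT_GROUPS",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_experiment",
    "table5_planted_fc",
    "reference_panel_fc",
    "load_table1_fixture",
]

DEFAULT_GROUPS = ("CTRL",) + GROUP_ORDER


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic microarray experiment.

    Intensity units are arbitrary scanner counts.  ``signal_alpha`` is
    the exponential signal mean for a gene at baseline expression 1;
    a gene's signal mean is ``signal_alpha * base_expression * fold_change``.
    """

    n_genes: int
    seed: int
    n_replicates_per_group: int = 4
    groups: tuple[str, ...] = DEFAULT_GROUPS
    background_mu: float = 100.0
    background_sigma: float = 10.0
    signal_alpha: float = 50.0
    planted_fc: dict[str, dict[str, float]] = field(default_factory=dict)
    stable_genes: tuple[str, ...] = ("Tfrc", "B2m")
    replicate_cv: float = 0.1
    base_expression_decades: float = 2.0
    probes_per_gene: int = 1
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates_per_group <= 0 or self.probes_per_gene <= 0:
            raise ValueError("dimensions must be positive")
        if not (self.background_sigma > 0):
            raise ValueError("background_sigma must be > 0")
        if not (self.signal_alpha > 0):
            raise ValueError("signal_alpha must be > 0")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if len(set(self.groups)) != len(self.groups) or "CTRL" not in self.groups:
            raise ValueError("groups must be unique and include CTRL")
        for group, genes in self.planted_fc.items():
            if group not in self.groups:
                raise ValueError(f"planted_fc group {group!r} not in groups")
            if group == "CTRL":
                raise ValueError("fold changes cannot be planted on the control group")
            for gene, fc in genes.items():
                if not (fc > 0):
                    raise ValueError(f"planted fold change must be > 0 ({gene}={fc})")
                if gene in self.stable_genes:
                    raise ValueError(f"stable gene {gene!r} cannot carry a planted fold change")
        if self.gene_ids is not None and len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene labels")

    def resolve_gene_ids(self) -> tuple[str, ...]:
        """Named genes first (stable, planted, reference panel), then filler."""
        if self.gene_ids is not None:
            if len(self.gene_ids) != self.n_genes:
                raise ValueError("gene_ids length must equal n_genes")
            return self.gene_ids
        named: list[str] = list(self.stable_genes)
        for genes in self.planted_fc.values():
            for gene in genes:
                if gene not in named:
                    named.append(gene)
        for gene in DEFAULT_REFERENCE_PANEL:
            if gene not in named and len(named) < self.n_genes:
                named.append(gene)
        if len(named) > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {len(named)} named genes"
            )
        filler = [f"G{i:04d}" for i in range(1, self.n_genes - len(named) + 1)]
        return tuple(named + filler)


@dataclass
class SyntheticTruth:
    """Ground truth: per-group linear fold change for every gene."""

    fold_changes: dict[str, dict[str, float]]
    stable_genes: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fold_changes": self.fold_changes,
            "stable_genes": list(self.stable_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            fold_changes=payload["fold_changes"],
            stable_genes=tuple(payload["stable_genes"]),
        )


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one log-normal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return np.exp(rng.normal(-s2 / 2.0, np.sqrt(s2), size=size))


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Draw one seeded experiment.

    Returns ``(matrix, design, truth)``: a probe/gene-by-sample intensity
    frame (non-negative, finite), the sample-to-group design, and the
    planted truth.  Identical configs (including seed) give identical
    output; a single RNG stream is used per call, no global state.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = config.resolve_gene_ids()
    n_genes = len(gene_ids)
    samples = [
        f"{group}_{r + 1}"
        for group in config.groups
        for r in range(config.n_replicates_per_group)
    ]
    design = pd.Series(
        [s.rsplit("_", 1)[0] for s in samples], index=samples, name="group"
    )

    # Named genes (stable, planted, candidate panel) sit in the upper decade
    # — measured genes are well expressed — while filler genes span the full
    # two-decade range so the low-expression filter has genuine work to do.
    named = set(config.stable_genes) | {
        g for genes in config.planted_fc.values() for g in genes
    } | set(DEFAULT_REFERENCE_PANEL)
    decades = config.base_expression_decades
    low = np.array([0.7 * decades if g in named else 0.0 for g in gene_ids])
    base = 10.0 ** rng.uniform(low, decades)
    fc_by_group = np.ones((n_genes, len(config.groups)))
    truth_fc: dict[str, dict[str, float]] = {}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for gi, group in enumerate(config.groups):
        planted = config.planted_fc.get(group, {})
        for gene, fc in planted.items():
            if gene not in gene_pos:
                raise ValueError(f"planted gene {gene!r} not among generated genes")
            fc_by_group[gene_pos[gene], gi] = fc
        truth_fc[group] = {g: float(fc_by_group[gene_pos[g], gi]) for g in gene_ids}

    # The exponential variate is each gene's latent baseline signal, drawn
    # once per experiment: conditional on it, replicates vary only by the
    # log-normal CV (plus background), while marginally every spot signal
    # is still Exponential with mean signal_alpha * base * fold_change —
    # the hierarchical reading of the background-correction convolution.
    latent = rng.exponential(1.0, size=n_genes)
    # The measured enzymes and candidate references are assayed because they
    # are reliably expressed: pin their latent baseline at the prior mean so
    # their abundance is set by base_expression alone, and leave the
    # exponential abundance spread to the background gene population.
    latent[[i for i, g in enumerate(gene_ids) if g in named]] = 1.0
    n_probe_rows = n_genes * config.probes_per_gene
    intensities = np.empty((n_probe_rows, len(samples)))
    for si, sample in enumerate(samples):
        gi = config.groups.index(design[sample])
        signal = config.signal_alpha * base * fc_by_group[:, gi] * latent
        signal = signal * _lognormal_multipliers(rng, config.replicate_cv, n_genes)
        signal = np.repeat(signal, config.probes_per_gene)
        if config.probes_per_gene > 1:
            # probe-level technical scatter at the same CV
            signal = signal * _lognormal_multipliers(
                rng, config.replicate_cv, n_probe_rows
            )
        background = rng.normal(config.background_mu, config.background_sigma, n_probe_rows)
        intensities[:, si] = np.maximum(background + signal, 0.0)

    if config.probes_per_gene > 1:
        index = pd.Index(
            [f"{g}::p{k + 1}" for g in gene_ids for k in range(config.probes_per_gene)],
            name="gene_id",
        )
    else:
        index = pd.Index(gene_ids, name="gene_id")
    matrix = pd.DataFrame(intensities, index=index, columns=samples)
    truth = SyntheticTruth(fold_changes=truth_fc, stable_genes=config.stable_genes)
    return matrix, design, truth


def probe_map(matrix: pd.DataFrame) -> dict[str, str]:
    """Probe-to-gene map for ``gene::pK``-style probe ids (identity otherwise)."""
    return {p: p.split("::", 1)[0] for p in matrix.index}


def table5_planted_fc(up_fc: float = 2.5) -> dict[str, dict[str, float]]:
    """Planted fold changes reproducing the published qualitative pattern.

    Directions follow the published per-form up/down gene lists.  Each
    upregulated gene is planted at ``up_fc``; downregulated genes in a
    pathway share the published pathway CFI equally on the log scale
    (after dividing out the upregulated factors), so the planted factor
    products match the published per-pathway indices wherever a pathway
    has any downregulated gene.
    """
    if up_fc < 2.0:
        raise ValueError("up_fc must be >= 2 to clear the fold-change cutoff")
    planted: dict[str, dict[str, float]] = {}
    for group in GROUP_ORDER:
        pattern = PUBLISHED_PATTERN[group]
        fc: dict[str, float] = {}
        for pi, pname in enumerate(("glycolysis", "tca", "etc")):
            pdef = DEFAULT_PATHWAYS[pname]
            ups = [g for g in pdef.genes if g in pattern["up"]]
            downs = [g for g in pdef.genes if g in pattern["down"]]
            for g in ups:
                fc[g] = up_fc
            if downs:
                residual = PUBLISHED_PATHWAY_CFI[group][pi] / up_fc ** len(ups)
                factor = residual ** (1.0 / len(downs))
                if factor > 0.5:
                    raise ValueError(
                        f"implied down factor {factor:.3f} for {group}/{pname} "
                        "does not clear the fold-change cutoff"
                    )
                for g in downs:
                    fc[g] = factor
        planted[group] = fc
    return planted


def reference_panel_fc(
    rng: np.random.Generator,
    panel: tuple[str, ...] = DEFAULT_REFERENCE_PANEL,
    stable: tuple[str, ...] = ("Tfrc", "B2m"),
    groups: tuple[str, ...] = GROUP_ORDER,
    log2_magnitude: tuple[float, float] = (0.5, 1.5),
    min_separation: float = 0.4,
    n_replicates: int = 4,
) -> dict[str, dict[str, float]]:
    """Group-specific perturbations for the non-control candidates.

    Each candidate outside ``stable`` receives, per disease group, a log2
    shift of random sign with magnitude drawn uniformly from
    ``log2_magnitude``.  Profiles are rejection-sampled so that every
    candidate's shift profile is at least ``min_separation`` (in
    across-sample log2 SD, control replicates anchored at zero) away both
    from flatness and from every other candidate's profile: each
    perturbed candidate genuinely tracks treatment, and no two candidates
    are spuriously co-regulated (a pairwise-ratio stability ranking would
    mistake a co-regulated pair for a stable one — a known failure mode
    of such rankings, not the scenario emulated here).
    """
    lo, hi = log2_magnitude
    if not 0 < lo < hi:
        raise ValueError("log2_magnitude must satisfy 0 < lo < hi")

    def anchored_sd(profile: np.ndarray) -> float:
        # population SD of the planted log2 offsets over all samples,
        # including the control replicates sitting at zero
        full = np.concatenate([np.zeros(n_replicates), np.repeat(profile, n_replicates)])
        return float(full.std())

    perturbed = [g for g in panel if g not in stable]
    profiles: list[np.ndarray] = []
    for _ in perturbed:
        for _attempt in range(1000):
            candidate = rng.choice((-1.0, 1.0), len(groups)) * rng.uniform(
                lo, hi, len(groups)
            )
            if anchored_sd(candidate) < min_separation:
                continue
            if all(anchored_sd(candidate - p) >= min_separation for p in profiles):
                profiles.append(candidate)
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not draw a separated perturbation profile")

    out: dict[str, dict[str, float]] = {g: {} for g in groups}
    for gene, profile in zip(perturbed, profiles):
        for group, shift in zip(groups, profile):
            out[group][gene] = float(2.0**shift)
    return out
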