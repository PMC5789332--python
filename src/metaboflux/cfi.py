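"""Cumulative Flux Index (CFI): a multiplicative pathway-collapse score.

The CFI integrates, over an ordered set of enzymes in a metabolic pathway,
the relative expression of each enzyme whose transcript is significantly
changed versus control.  Each differentially expressed enzyme contributes
its linear fold change as a factor; unchanged enzymes contribute 1.  The
pathway CFI is the product of these factors, and the total CFI of the
carbohydrate-metabolism network is the product over the three scored
pathways (glycolysis, TCA cycle, electron transport chain).

A CFI of 1 means the expected pathway flux is unchanged; values below 1
indicate a cumulative collapse of flux driven by downregulated enzymes,
and values above 1 an expansion.  The score is a simplified, linear
cumulative reading of flux control: each enzyme's transcript ratio is
treated as a local, independent scaling of its catalysed step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PathwayDef",
    "CFIResult",
    "DEFAULT_PATHWAYS",
    "GROUP_ORDER",
    "GROUP_LABELS",
    "PUBLISHED_PATHWAY_CFI",
    "PUBLISHED_PATTERN",
    "pathway_cfi",
    "total_cfi",
    "table5_report",
]


@dataclass(frozen=True)
class PathwayDef:
    """An ordered, duplicate-free set of enzyme-coding genes."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway {self.name!r} has duplicate genes")


#: The measured enzyme panel, per pathway.
DEFAULT_PATHWAYS: dict[str, PathwayDef] = {
    "glycolysis": PathwayDef("glycolysis", ("Hk1", "Gapdh", "Pgk1", "Pgam1", "Eno1", "Pkm")),
    "tca": PathwayDef("tca", ("Pdha1", "Aco2", "Mdh2")),
    "etc": PathwayDef("etc", ("Atp5a1", "Atp5b")),
}

PATHWAY_ORDER = ("glycolysis", "tca", "etc")

#: Disease groups in canonical report order (control excluded).
GROUP_ORDER = ("RMS_GMminus", "RMS_GMplus", "SPINAL", "PPMS", "NMO")

#: Human-readable clinical-form labels.
GROUP_LABELS = {
    "CTRL": "Control",
    "RMS_GMminus": "RMS (G+/M-)",
    "RMS_GMplus": "RMS (G+/M+)",
    "SPINAL": "Spinal MS",
    "PPMS": "PPMS",
    "NMO": "NMO",
}

#: Published per-pathway CFI values (glycolysis, tca, etc) per clinical form.
PUBLISHED_PATHWAY_CFI: dict[str, tuple[float, float, float]] = {
    "RMS_GMminus": (0.0296, 0.0960, 0.3300),
    "RMS_GMplus": (0.0007, 0.0690, 0.3300),
    "SPINAL": (0.0075, 0.0810, 0.1050),
    "PPMS": (0.3000, 0.0870, 0.1050),
    "NMO": (1.9656, 0.2174, 1.5867),
}

#: Published total CFI per clinical form (as printed, not recomputed).
PUBLISHED_TOTAL_CFI: dict[str, float] = {
    "RMS_GMminus": 9.3e-4,
    "RMS_GMplus": 1.4e-5,
    "SPINAL": 6.4e-5,
    "PPMS": 2.7e-3,
    "NMO": 0.6779,
}

#: Published qualitative regulation pattern: group -> {"up": [...], "down": [...]}.
PUBLISHED_PATTERN: dict[str, dict[str, tuple[str, ...]]] = {
    "RMS_GMminus": {
        "up": (),
        "down": ("Gapdh", "Pgam1", "Eno1", "Mdh2", "Pdha1", "Atp5b"),
    },
    "RMS_GMplus": {
        "up": (),
        "down": ("Hk1", "Gapdh", "Pgam1", "Pgk1", "Eno1", "Mdh2", "Pdha1", "Atp5b"),
    },
    "SPINAL": {
        "up": (),
        "down": ("Hk1", "Gapdh", "Eno1", "Pkm", "Mdh2", "Pdha1", "Atp5a1", "Atp5b"),
    },
    "PPMS": {
        "up": (),
        "down": ("Pgam1", "Mdh2", "Pdha1", "Atp5a1", "Atp5b"),
    },
    "NMO": {
        "up": ("Hk1", "Pgam1", "Eno1", "Pdha1", "Atp5a1", "Atp5b"),
        "down": ("Mdh2", "Aco2"),
    },
}


@dataclass
class CFIResult:
    """One clinical form's CFI summary row."""

    group: str
    pathway_cfi: dict[str, float]
    total: float
    factors: dict[str, dict[str, float]]
    up_genes: dict[str, list[str]] = field(default_factory=dict)
    down_genes: dict[str, list[str]] = field(default_factory=dict)


def _detable_lookup(detable: pd.DataFrame, group: str) -> pd.DataFrame:
    required = {"gene", "group", "fc", "call"}
    missing = required - set(detable.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    sub = detable[detable["group"] == group]
    return sub.set_index("gene")


def pathway_cfi(
    detable: pd.DataFrame, group: str, pathway: PathwayDef
) -> tuple[float, dict[str, float]]:
    """Compute one pathway's CFI for one disease group.

    Each pathway gene contributes its linear fold change versus control if
    it was called up- or downregulated, and 1.0 otherwise.  Returns the
    product together with the per-gene factors for audit.
    """
    sub = _detable_lookup(detable, group)
    factors: dict[str, float] = {}
    for gene in pathway.genes:
        if gene not in sub.index:
            raise KeyError(f"gene {gene!r} missing from DE table for group {group!r}")
        row = sub.loc[gene]
        fc = float(row["fc"])
        if not (fc > 0) or not math.isfinite(fc):
            raise ValueError(f"non-positive fold change for {gene!r} in {group!r}: {fc}")
        factors[gene] = fc if row["call"] in ("up", "down") else 1.0
    cfi = math.prod(factors.values())
    return cfi, factors


def total_cfi(glycolysis: float, tca: float, etc: float) -> float:
    """Total CFI of the network: product of the three pathway CFIs."""
    for name, value in (("glycolysis", glycolysis), ("tca", tca), ("etc", etc)):
        if not (value > 0) or not math.isfinite(value):
            raise ValueError(f"pathway CFI for {name} must be positive, got {value}")
    return glycolysis * tca * etc


def table5_report(
    detable: pd.DataFrame,
    pathways: dict[str, PathwayDef] | None = None,
    groups: tuple[str, ...] = GROUP_ORDER,
) -> list[CFIResult]:
    """Per-group CFI summary: up/down gene lists, pathway CFIs and totals.

    Rows follow the canonical clinical-form order (G+/M-, G+/M+, Spinal,
    PPMS, NMO) unless ``groups`` says otherwise.
    """
    if pathways is None:
        pathways = DEFAULT_PATHWAYS
    if set(pathways) != set(PATHWAY_ORDER):
        raise ValueError(f"pathways must be exactly {PATHWAY_ORDER}, got {sorted(pathways)}")
    results: list[CFIResult] = []
    for group in groups:
        per_pathway: dict[str, float] = {}
        factors: dict[str, dict[str, float]] = {}
        ups: dict[str, list[str]] = {}
        downs: dict[str, list[str]] = {}
        sub = _detable_lookup(detable, group)
        for pname in PATHWAY_ORDER:
            pdef = pathways[pname]
            per_pathway[pname], factors[pname] = pathway_cfi(detable, group, pdef)
            ups[pname] = [g for g in pdef.genes if sub.loc[g, "call"] == "up"]
            downs[pname] = [g for g in pdef.genes if sub.loc[g, "call"] == "down"]
        total = total_cfi(per_pathway["glycolysis"], per_pathway["tca"], per_pathway["etc"])
        results.append(
            CFIResult(
                group=group,
                pathway_cfi=per_pathway,
                total=total,
                factors=factors,
                up_genes=ups,
                down_genes=downs,
            )
        )
    return results


def report_to_frame(results: list[CFIResult]) -> pd.DataFrame:
    """Flatten CFI results into a tidy frame (one row per group)."""
    rows = []
    for r in results:
        row: dict[str, object] = {"group": r.group, "label": GROUP_LABELS.get(r.group, r.group)}
        for pname in PATHWAY_ORDER:
            row[f"up_{pname}"] = ", ".join(r.up_genes.get(pname, [])) or "-"
            row[f"down_{pname}"] = ", ".join(r.down_genes.get(pname, [])) or "-"
            row[f"cfi_{pname}"] = r.pathway_cfi[pname]
        row["total_cfi"] = r.total
        rows.append(row)
    return pd.DataFrame(rows)
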