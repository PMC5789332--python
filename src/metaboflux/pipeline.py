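"""End-to-end orchestration: simulate -> preprocess -> reference genes ->
differential expression -> CFI -> network -> cohort.

One JSON config drives the run; every default is echoed into the run
manifest so no silent parameters exist.  Identical config and seed give
byte-identical outputs (and therefore identical manifest checksums).
Validation is fail-fast: referenced files are checked before any stage
executes, and an aborted run leaves a ``MANIFEST.partial`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, cfi, cohort, diffexpr, io, network, preprocess, refgenes, synthetic

logger = logging.getLogger("metaboflux.pipeline")

ALL_STAGES = ("simulate", "preprocess", "refgenes", "diffexpr", "cfi", "network", "cohort")

DEFAULT_NETWORK_EDGES = Path(__file__).parent / "data" / "string_edges_synthetic.tsv"
DEFAULT_PATHWAYS_FILE = Path(__file__).parent / "data" / "pathways.json"


@dataclass
class RunConfig:
    out_dir: str
    seed: int | None = None
    stages: tuple[str, ...] = ALL_STAGES
    # simulation parameters (ignored when 'simulate' disabled)
    n_genes: int = 120
    n_replicates_per_group: int = 4
    replicate_cv: float = 0.1
    planted_pattern: str = "table5"  # or "none"
    probes_per_gene: int = 1
    # external inputs (required when 'simulate' disabled)
    signal_tsv: str | None = None
    design_tsv: str | None = None
    # stage parameters
    filter_quantile: float = 0.30
    control_genes: tuple[str, ...] = refgenes.DEFAULT_CONTROL_GENES
    control_group: str = "CTRL"
    fc_cutoff: float = diffexpr.FC_CUTOFF
    p_cutoff: float = diffexpr.P_CUTOFF
    fdr_cutoff: float = diffexpr.FDR_CUTOFF
    pathways_file: str = str(DEFAULT_PATHWAYS_FILE)
    network_edges: str = str(DEFAULT_NETWORK_EDGES)
    score_threshold: float = 0.4

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**payload)
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "simulate" in self.stages:
            if self.seed is None:
                raise ValueError("seed is mandatory when simulation is enabled")
        else:
            for label, p in (("signal_tsv", self.signal_tsv), ("design_tsv", self.design_tsv)):
                if p is None:
                    raise ValueError(f"{label} required when simulation is disabled")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label} not found: {p}")
        if "cfi" in self.stages and not Path(self.pathways_file).exists():
            raise FileNotFoundError(f"pathway file not found: {self.pathways_file}")
        if "network" in self.stages and not Path(self.network_edges).exists():
            raise FileNotFoundError(f"network edge list not found: {self.network_edges}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _frame_to_markdown(frame: pd.DataFrame) -> str:
    cells = frame.astype(str)
    header = "| " + " | ".join(cells.columns) + " |"
    rule = "| " + " | ".join("---" for _ in cells.columns) + " |"
    rows = ["| " + " | ".join(r) + " |" for r in cells.itertuples(index=False)]
    return "\n".join([header, rule, *rows]) + "\n"


def load_pathways(path: str | Path) -> dict[str, cfi.PathwayDef]:
    payload = json.loads(Path(path).read_text())
    return {name: cfi.PathwayDef(name, tuple(genes)) for name, genes in payload.items()}


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in fixed order and write a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial_marker = out / "MANIFEST.partial"
    partial_marker.write_text("run in progress\n")

    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
        "outputs": {},
    }

    current_stage = "startup"
    try:
        matrix = design = None
        if "simulate" in config.stages:
            current_stage = "simulate"
            logger.info("[simulate] seed=%s n_genes=%d", config.seed, config.n_genes)
            planted = (
                synthetic.table5_planted_fc() if config.planted_pattern == "table5" else {}
            )
            sim_cfg = synthetic.SyntheticConfig(
                n_genes=config.n_genes,
                seed=int(config.seed),
                n_replicates_per_group=config.n_replicates_per_group,
                replicate_cv=config.replicate_cv,
                planted_fc=planted,
                probes_per_gene=config.probes_per_gene,
            )
            matrix, design, truth = synthetic.generate_experiment(sim_cfg)
            io.write_signal_tsv(matrix, out / "signals.tsv")
            io.write_design_tsv(design, out / "design.tsv")
            truth.to_json(out / "truth.json")
            manifest["stages"]["simulate"] = {"rows": len(matrix), "samples": matrix.shape[1]}
        else:
            current_stage = "load"
            matrix = io.read_signal_tsv(config.signal_tsv)
            design = io.read_design_tsv(config.design_tsv)

        io.validate_matrix(matrix, design)

        if "preprocess" in config.stages:
            current_stage = "preprocess"
            logger.info("[preprocess] normexp + p75 + filter + merge")
            corrected, fits = preprocess.normexp_correct_matrix(matrix)
            scaled = preprocess.percentile75_normalize(corrected)
            filtered, removal_log = preprocess.filter_low_expression(
                scaled, config.filter_quantile
            )
            removal_log.to_csv(out / "removal_log.tsv", sep="\t", index=False,
                               lineterminator="\n")
            expr = preprocess.merge_probes(filtered, synthetic.probe_map(filtered))
            io.write_signal_tsv(expr, out / "expr.tsv")
            manifest["stages"]["preprocess"] = {
                "rows_in": len(matrix),
                "rows_filtered": len(filtered),
                "genes_out": len(expr),
                "normexp": {s: asdict(p) for s, p in fits.items()},
            }
        else:
            expr = matrix

        if "refgenes" in config.stages:
            current_stage = "refgenes"
            panel = [g for g in refgenes.DEFAULT_REFERENCE_PANEL if g in expr.index]
            rankings = []
            if len(panel) >= 3:
                rankings.append(refgenes.genorm_rank(expr.loc[panel]).to_frame())
                rankings.append(
                    refgenes.normfinder_stability(expr.loc[panel], design).to_frame()
                )
                pd.concat(rankings, ignore_index=True).to_csv(
                    out / "refgene_ranking.tsv", sep="\t", index=False, lineterminator="\n"
                )
            expr = refgenes.normalize_to_controls(expr, config.control_genes)
            io.write_signal_tsv(expr, out / "expr_normalized.tsv")
            manifest["stages"]["refgenes"] = {
                "panel": panel,
                "controls": list(config.control_genes),
            }

        detable = None
        if "diffexpr" in config.stages:
            current_stage = "diffexpr"
            logger.info("[diffexpr] ANOVA/Tukey/BH on %d genes", len(expr))
            detable = diffexpr.de_table(
                expr,
                design,
                control_group=config.control_group,
                fc_cutoff=config.fc_cutoff,
                p_cutoff=config.p_cutoff,
                fdr_cutoff=config.fdr_cutoff,
            )
            detable.to_csv(out / "detable.tsv", sep="\t", index=False, lineterminator="\n")
            manifest["stages"]["diffexpr"] = {
                "rows": len(detable),
                "calls": detable["call"].value_counts().to_dict(),
            }

        if "cfi" in config.stages:
            current_stage = "cfi"
            if detable is None:
                raise ValueError("cfi stage requires the diffexpr stage")
            pathways = load_pathways(config.pathways_file)
            groups = tuple(
                g for g in cfi.GROUP_ORDER if g in set(detable["group"])
            )
            results = cfi.table5_report(detable, pathways, groups)
            frame = cfi.report_to_frame(results)
            frame.to_csv(out / "cfi_report.tsv", sep="\t", index=False, lineterminator="\n")
            (out / "cfi_report.md").write_text(_frame_to_markdown(frame))
            manifest["stages"]["cfi"] = {"rows": len(results)}

        if "network" in config.stages:
            current_stage = "network"
            if detable is None:
                raise ValueError("network stage requires the diffexpr stage")
            graph = network.load_interactions(
                config.network_edges, score_threshold=config.score_threshold
            )
            for group in sorted(set(detable["group"])):
                annotated = network.annotate_regulation(graph.copy(), detable, group)
                network.export_graph(annotated, out / f"network_{group}.graphml")
            manifest["stages"]["network"] = {
                "nodes": graph.number_of_nodes(),
                "edges": graph.number_of_edges(),
            }

        if "cohort" in config.stages:
            current_stage = "cohort"
            patients = cohort.load_table1_fixture()
            for grouping in cohort.GROUPINGS:
                summary = cohort.summarize(patients, grouping)
                summary.to_csv(out / f"cohort_{grouping}.csv", index=False,
                               lineterminator="\n")
            manifest["stages"]["cohort"] = {"patients": len(patients)}
    except Exception as exc:
        logger.error("[%s] aborted: %s", current_stage, exc)
        raise RuntimeError(f"pipeline aborted in stage {current_stage!r}: {exc}") from exc

    current_stage = "manifest"
    for artifact in sorted(out.iterdir()):
        if artifact.name in ("manifest.json", "MANIFEST.partial"):
            continue
        manifest["outputs"][artifact.name] = _sha256(artifact)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    partial_marker.unlink()
    return manifest


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("metaboflux")
    root.handlers.clear()
    root.addHandler(handler)
    root.setLevel(logging.INFO if verbose else logging.WARNING)
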