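"""End-to-end pipeline: normalize -> differential tests -> screen ->
heatmap -> enrichment, with a machine-readable run manifest.

Every stage writes plain TSV/JSON into the output directory; identical
inputs, configuration and seed yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__, io
from .design import CONDITION_ORDER, condition_samples
from .detest import Contrast, estimate_common_dispersion, run_contrast
from .enrich import hypergeom_enrich, top_pathways
from .heatmap import allocate_groups, transform_values, write_heatmap
from .normalize import effective_library_sizes, normalize, tmm_factors
from .screen import ScreenConfig, relative_expression, run_screen

logger = logging.getLogger("gravscreen")


@dataclass
class PipelineConfig:
    """File paths and tuning knobs for one pipeline run."""

    counts: str
    design: str
    panel: str
    gene_sets: str | None = None
    output_dir: str = "gravscreen_out"
    alpha: float = 0.05
    fc_threshold: float = 2.0
    step2_threshold: float = 1000.0
    step2_scope: str = "all_standing"
    dispersion: float | None = None  # override; estimated when None
    bh: bool = False
    top_k: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "design", "panel"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.gene_sets is not None and not os.path.exists(self.gene_sets):
            raise FileNotFoundError(f"gene_sets file not found: {self.gene_sets}")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.step2_threshold <= 0 or self.fc_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineReport:
    output_dir: str
    manifest: dict
    screen_result: object = None
    de_tables: dict = field(default_factory=dict)


def _stage(name: str, manifest: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            status = "failed" if exc_type else "ok"
            # timings go to the log only: the manifest must be reproducible
            manifest["stages"][name] = {"status": status}
            logger.info("stage %s: %s (%.2fs)", name, status, dt)
            if exc_type:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and write the report bundle to ``output_dir``."""
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda *p: os.path.join(config.output_dir, *p)  # noqa: E731

    manifest: dict = {
        "tool": "gravscreen",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    counts = io.read_counts(config.counts)
    design = io.read_design(config.design)
    panel = io.read_panel(config.panel)
    gene_sets = io.read_gmt(config.gene_sets) if config.gene_sets else {}

    with _stage("normalize", manifest):
        factors = tmm_factors(counts)
        normalized = normalize(counts, factors)
        lib_sizes = effective_library_sizes(counts, factors)
        factors.rename_axis("sample_id").reset_index().to_csv(
            out("factors.tsv"), sep="\t", index=False
        )
        io.write_matrix(normalized, out("normalized.tsv"))
        manifest["outputs"]["factors"] = "factors.tsv"
        manifest["outputs"]["normalized"] = "normalized.tsv"

    with _stage("dispersion", manifest):
        if config.dispersion is not None:
            phi, method = float(config.dispersion), "override"
        else:
            groups = design.set_index("sample_id")["condition"]
            est = estimate_common_dispersion(counts, groups, lib_sizes=lib_sizes)
            phi, method = est.phi, est.method
        manifest["dispersion"] = {"phi": phi, "method": method}

    with _stage("detest", manifest):
        st = tuple(condition_samples(design, "ST"))
        de_tables: dict[str, pd.DataFrame] = {}
        for cond in CONDITION_ORDER:
            if cond == "ST":
                continue
            contrast = Contrast(
                name=f"{cond}_vs_ST",
                group_a=st,
                group_b=tuple(condition_samples(design, cond)),
            )
            table = run_contrast(
                counts,
                normalized,
                contrast,
                phi=phi,
                alpha=config.alpha,
                fc_threshold=config.fc_threshold,
                lib_sizes=lib_sizes,
                bh=config.bh,
            )
            de_tables[contrast.name] = table
            io.write_table(table, out(f"de_{contrast.name}.tsv"))
            manifest["outputs"][f"de_{contrast.name}"] = f"de_{contrast.name}.tsv"

    with _stage("screen", manifest):
        screen_config = ScreenConfig(
            panel=tuple(panel),
            step2_threshold=config.step2_threshold,
            alpha=config.alpha,
            step2_scope=config.step2_scope,
        )
        result = run_screen(counts, normalized, design, screen_config, phi, lib_sizes=lib_sizes)
        io.write_table(result.records, out("screen_records.tsv"))
        with open(out("selected_genes.json"), "w") as fh:
            json.dump(result.selected_summary(), fh, indent=2)
        if result.selected:
            rel = relative_expression(
                normalized, design, result.selected,
                counts=counts, phi=phi, alpha=config.alpha, lib_sizes=lib_sizes,
            )
            io.write_matrix(rel, out("relative_expression.tsv"))
            manifest["outputs"]["relative_expression"] = "relative_expression.tsv"
        manifest["outputs"]["screen_records"] = "screen_records.tsv"
        manifest["outputs"]["selected_genes"] = "selected_genes.json"
        manifest["screen"] = {k: len(v) for k, v in result.step_sets.items()}

    with _stage("heatmap", manifest):
        detected_panel = result.step_sets["step1"]
        matrix = transform_values(normalized, design, genes=detected_panel)
        allocate_groups(matrix)
        write_heatmap(matrix, out("heatmap.tsv"), out("heatmap_groups.tsv"))
        manifest["outputs"]["heatmap"] = "heatmap.tsv"
        manifest["outputs"]["heatmap_groups"] = "heatmap_groups.tsv"

    with _stage("enrich", manifest):
        if gene_sets:
            universe = counts.index[(counts > 0).any(axis=1)].tolist()
            frames = []
            for name, table in de_tables.items():
                for direction, mask in (
                    ("up", table["significant"] & (table["log2_fc"] > 0)),
                    ("down", table["significant"] & (table["log2_fc"] < 0)),
                ):
                    genes = table.loc[mask, "gene_id"].tolist()
                    if not genes:
                        continue
                    enr = hypergeom_enrich(genes, gene_sets, universe, bh=config.bh)
                    enr.insert(0, "direction", direction)
                    enr.insert(0, "contrast", name)
                    frames.append(enr)
            if frames:
                all_enr = pd.concat(frames, ignore_index=True)
                io.write_table(all_enr, out("enrichment.tsv"))
                manifest["outputs"]["enrichment"] = "enrichment.tsv"
                tops = (
                    all_enr.groupby(["contrast", "direction"], sort=True)
                    .apply(lambda df: top_pathways(df, k=config.top_k, alpha=config.alpha),
                           include_groups=False)
                    .reset_index()
                )
                io.write_table(
                    tops.drop(columns=[c for c in tops.columns if c.startswith("level_")]),
                    out("top_pathways.tsv"),
                )
                manifest["outputs"]["top_pathways"] = "top_pathways.tsv"

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for name, rel_path in manifest["outputs"].items():
        path = out(rel_path)
        if not os.path.exists(path) or os.path.getsize(path) == 0:
            raise RuntimeError(f"declared output {name} missing or empty: {path}")
    return PipelineReport(
        output_dir=config.output_dir,
        manifest=manifest,
        screen_result=result,
        de_tables=de_tables,
    )


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
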