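"""End-to-end analysis pipeline over one haplotype table.

Runs the full study sequence — forensic report, pairwise R_ST with
permutation p-values, PCA and MDS ordination of population allele
frequencies, neighbor-joining tree of the R_ST matrix, and (given a
labeled reference panel) haplogroup prediction — and writes every result
plus a reproducibility manifest into an output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .amova import pairwise_rst
from .errors import PipelineStageError, YstrkitError
from .forensic import forensic_report
from .haplogroup import haplogroup_spectrum, predict_table
from .io import (
    read_haplotype_table,
    read_reference_panel,
    write_distance_matrix,
    write_phylip_matrix,
)
from .ordination import build_frequency_matrix, mds_from_frequencies, pca
from .panel import DEFAULT_PANEL, PanelConfig
from .phylo import neighbor_joining, to_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    table_path: str | Path
    out_dir: str | Path
    seed: int
    panel_path: str | Path | None = None
    reference_panel_path: str | Path | None = None
    permutations: int = 999
    metric: str = "euclidean"
    axes: int = 2
    k_neighbors: int = 5
    min_confidence: float = 0.6
    overwrite: bool = False
    extra: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_ordination(ord_, path: Path) -> None:
    frame = ord_.coordinates.copy()
    frame.index.name = "population"
    frame.to_csv(path, sep="\t", float_format="%.6f")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage; returns the mapping output name -> path.

    Deterministic given the config and seed.  Any stage failure raises
    :class:`PipelineStageError` naming the stage.  Existing outputs are
    refused unless ``overwrite`` is set.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = {
        "per_locus": out / "forensic_per_locus.tsv",
        "summary": out / "forensic_summary.tsv",
        "rst": out / "rst_matrix.tsv",
        "rst_phylip": out / "rst_matrix.phy",
        "rst_p": out / "rst_pvalues.tsv",
        "pca": out / "pca_coordinates.tsv",
        "mds": out / "mds_coordinates.tsv",
        "tree": out / "nj_tree.nwk",
        "manifest": out / "manifest.json",
    }
    if cfg.reference_panel_path is not None:
        outputs["predictions"] = out / "haplogroup_predictions.tsv"
        outputs["haplogroup_spectrum"] = out / "haplogroup_spectrum.tsv"
    if not cfg.overwrite:
        clashes = [str(p) for p in outputs.values() if p.exists()]
        if clashes:
            raise PipelineStageError("setup", f"refusing to overwrite {clashes}")

    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    if not isinstance(exc, PipelineStageError):
                        raise PipelineStageError(name, str(exc)) from exc
                else:
                    logger.info("stage %s: done in %.3fs", name, timings[name])

        return _Timer()

    with stage("read"):
        panel = PanelConfig.from_file(cfg.panel_path) if cfg.panel_path else DEFAULT_PANEL
        table = read_haplotype_table(cfg.table_path, panel)

    with stage("forensic"):
        report = forensic_report(table)
        report.per_locus.to_csv(outputs["per_locus"], sep="\t", index=False, float_format="%.4f")
        report.summary.to_csv(outputs["summary"], sep="\t", index=False, float_format="%.4g")

    with stage("rst"):
        rst = pairwise_rst(table, n_permutations=cfg.permutations, seed=cfg.seed)
        write_distance_matrix(rst.distances, outputs["rst"])
        write_phylip_matrix(rst.distances, outputs["rst_phylip"])
        rst.p_values.to_csv(outputs["rst_p"], sep="\t", float_format="%.6g")

    with stage("ordination"):
        freq = build_frequency_matrix([table])
        axes = min(cfg.axes, len(table.populations) - 1, freq.shape[1])
        _write_ordination(pca(freq, axes), outputs["pca"])
        _write_ordination(mds_from_frequencies(freq, cfg.metric, axes), outputs["mds"])

    with stage("tree"):
        pops = sorted(table.populations)
        if len(pops) >= 3:
            newick = to_newick(neighbor_joining(rst.distances), precision=8)
        else:
            # two taxa: the unique tree splits the distance evenly
            half = rst.distances[pops[0], pops[1]] / 2.0
            newick = f"({pops[0]}:{half:.8g},{pops[1]}:{half:.8g});"
        outputs["tree"].write_text(newick + "\n")

    predictions_summary = None
    if cfg.reference_panel_path is not None:
        with stage("predict"):
            ref = read_reference_panel(cfg.reference_panel_path, table.panel)
            preds = predict_table(table, ref, cfg.k_neighbors, cfg.min_confidence)
            with open(outputs["predictions"], "w") as fh:
                fh.write("SampleID\tHaplogroup\tConfidence\tMeanDistance\n")
                for p in preds:
                    fh.write(
                        f"{p.sample_id}\t{p.haplogroup}\t{p.confidence:.4f}\t{p.mean_distance:.4f}\n"
                    )
            spec = haplogroup_spectrum(preds)
            spec.to_frame().to_csv(
                outputs["haplogroup_spectrum"], sep="\t", index=False, float_format="%.4f"
            )
            predictions_summary = {
                "n_assigned": spec.n_assigned,
                "n_unassigned": spec.n_unassigned,
                "assignment_rate_percent": round(spec.assignment_rate, 2),
            }

    with stage("manifest"):
        inputs = {"table": {"path": str(cfg.table_path), "sha256": _sha256(cfg.table_path)}}
        if cfg.panel_path:
            inputs["panel"] = {"path": str(cfg.panel_path), "sha256": _sha256(cfg.panel_path)}
        if cfg.reference_panel_path:
            inputs["reference_panel"] = {
                "path": str(cfg.reference_panel_path),
                "sha256": _sha256(cfg.reference_panel_path),
            }
        manifest = {
            "ystrkit_version": __version__,
            "seed": cfg.seed,
            "parameters": {
                "permutations": cfg.permutations,
                "metric": cfg.metric,
                "axes": cfg.axes,
                "k_neighbors": cfg.k_neighbors,
                "min_confidence": cfg.min_confidence,
            },
            "inputs": inputs,
            "outputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in outputs.items()
                if name != "manifest" and p.exists()
            },
            "predictions": predictions_summary,
            "stage_seconds": timings,
        }
        outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    missing = [str(p) for p in outputs.values() if not p.exists()]
    if missing:
        raise PipelineStageError("finalize", f"outputs not written: {missing}")
    return outputs
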