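"""Umbrella pipeline: simulate -> preprocess -> DE -> gene sets -> crossval.

Everything stochastic flows through the config's seed; two runs with the
same config produce byte-identical output trees.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .crossval import CONTEXTS, run_cross_validation, summarize
from .diffexpr import Thresholds, build_gene_sets
from .errors import DheascreenError
from .preprocess import (ExpressionMatrix, SpotTable, filter_low_signal,
                         floor_log_center, normalize, pca_view, qc_report,
                         validate_sample_sheet)
from .simulate import SimConfig, generate_experiment

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of one end-to-end run."""

    out_dir: Path
    spots_dir: Path | None = None        # existing spot tables, or None to simulate
    sample_sheet: Path | None = None
    sim: SimConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_perm: int = 1000
    weight: float = 1.0
    seed: int = 0
    external_gmt: Path | None = None

    @classmethod
    def from_dict(cls, d: dict, out_dir: str | Path) -> "PipelineConfig":
        thr = Thresholds(**d.get("thresholds", {}))
        sim = SimConfig(**d["sim"]) if "sim" in d else None
        return cls(
            out_dir=Path(out_dir),
            spots_dir=Path(d["spots_dir"]) if d.get("spots_dir") else None,
            sample_sheet=(Path(d["sample_sheet"])
                          if d.get("sample_sheet") else None),
            sim=sim,
            thresholds=thr,
            n_perm=int(d.get("n_perm", 1000)),
            weight=float(d.get("weight", 1.0)),
            seed=int(d.get("seed", 0)),
            external_gmt=(Path(d["external_gmt"])
                          if d.get("external_gmt") else None),
        )


def preprocess_tables(
    tables: list[SpotTable], floor: float
) -> tuple[ExpressionMatrix, dict]:
    """filter -> normalize -> floor -> log2 -> center, plus the QC record."""
    filtered = [filter_low_signal(t) for t in tables]
    normalized = normalize(filtered)
    matrix = floor_log_center(normalized, floor=floor)
    return matrix, qc_report(filtered, matrix)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing all artifacts under ``config.out_dir``.

    Returns the crossval summary dict. Raises a stage-named
    :class:`DheascreenError` on failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: input -------------------------------------------------
    if config.spots_dir is not None:
        if config.sample_sheet is None:
            raise DheascreenError("input: sample_sheet required with spots_dir")
        if not Path(config.sample_sheet).exists():
            raise DheascreenError(
                f"input: sample sheet not found: {config.sample_sheet}")
        tables = io.read_spot_tables(config.spots_dir)
        samples = io.read_sample_sheet(config.sample_sheet)
    else:
        sim = config.sim or SimConfig(seed=config.seed)
        if sim.seed != config.seed:
            sim = dataclasses.replace(sim, seed=config.seed)
        tables, samples, truth = generate_experiment(sim)
        io.write_spot_tables(tables, out / "spots")
        io.write_sample_sheet(samples, out / "samples.tsv")
        (out / "truth.json").write_text(truth.to_json() + "\n")
    validate_sample_sheet(samples)

    # --- stage: preprocess --------------------------------------------
    matrix, qc = preprocess_tables(tables, floor=config.thresholds.floor)
    io.write_expression_matrix(matrix, out / "matrix.tsv")
    pca = pca_view(matrix)
    qc["pca_variance_fractions"] = pca.variance_fractions[:5]
    io.write_json(qc, out / "qc.json")

    # --- stage: crossval (DE + gene sets + GSEA) ----------------------
    external = (io.read_gmt(config.external_gmt)
                if config.external_gmt else [])
    table = run_cross_validation(
        matrix, samples,
        thresholds=config.thresholds,
        n_perm=config.n_perm,
        seed=config.seed,
        weight=config.weight,
        external_sets=external,
    )
    for ctx, sel in table.selections.items():
        io.write_de_selection(sel, out / f"de_{ctx[0]}_vs_{ctx[1]}.tsv")
    derived = []
    for sel in table.selections.values():
        up, down = build_gene_sets(sel)
        derived.extend(gs for gs in (up, down) if gs is not None)
    if derived:
        io.write_gmt(derived, out / "gene_sets.gmt")
    table.to_frame().to_csv(out / "validation_table.tsv", sep="\t",
                            index=False)

    # --- stage: report ------------------------------------------------
    summary = summarize(table)
    params = {
        "seed": config.seed,
        "n_perm": config.n_perm,
        "weight": config.weight,
        "thresholds": dataclasses.asdict(config.thresholds),
    }
    if config.sim is not None or config.spots_dir is None:
        sim = config.sim or SimConfig(seed=config.seed)
        params["sim"] = {**dataclasses.asdict(sim),
                         "group_sizes": dict(sim.group_sizes)}
    io.write_json({"parameters": params, **summary}, out / "summary.json")
    log.info("pipeline complete: %d/%d cross-control cells significant",
             summary["cross_control_significant"],
             summary["cross_control_total"])
    return summary
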