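"""Cross-control-group / cross-route validation of derived gene sets.

Each of the four (route x control) comparisons yields an UP and a DOWN gene
set; every set is then evaluated by GSEA in every context except the one it
was derived from. Cells are partitioned into cross_control (same route,
other control group), cross_route (the other route) and self (no result),
and summarized per partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import (DESelection, GeneSet, Thresholds, build_gene_sets,
                       select_de, set_name)
from .errors import DesignError, EvaluationError
from .gsea import (GseaResult, enrichment_score, nes_and_fdr, nominal_p,
                   permutation_null, signal_to_noise_rank)
from .preprocess import ExpressionMatrix, samples_in_group, validate_sample_sheet

log = logging.getLogger(__name__)

ROUTES = ("IM", "PO")
CONTROLS = ("CTR1", "CTR3")

#: The four evaluation contexts, (treated group, control group).
CONTEXTS: tuple[tuple[str, str], ...] = tuple(
    (r, c) for r in ROUTES for c in CONTROLS)

PARTITIONS = ("self", "cross_control", "cross_route", "external")


@dataclass
class Cell:
    """One (gene set, context) cell of the validation table."""

    partition: str  # self | cross_control | cross_route | external
    kind: str       # self | empty | unmatched | result
    result: GseaResult | None = None


@dataclass
class ValidationTable:
    """Table-shaped record of every gene set evaluated in every context."""

    set_names: list[str]
    set_sizes: dict[str, int]
    derived_from: dict[str, tuple[str, str] | None]
    contexts: list[tuple[str, str]]
    cells: dict[tuple[str, tuple[str, str]], Cell]
    selections: dict[tuple[str, str], DESelection]

    def cell(self, name: str, context: tuple[str, str]) -> Cell:
        return self.cells[(name, context)]

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready view: one row per set with p/FDR per context;
        self cells print '-' as in the published layout."""
        rows = []
        for name in self.set_names:
            row: dict[str, object] = {
                "set_name": name,
                "n_genes": self.set_sizes[name],
            }
            for ctx in self.contexts:
                label = f"{ctx[0]}_vs_{ctx[1]}"
                c = self.cells[(name, ctx)]
                if c.kind == "result":
                    row[f"p_{label}"] = f"{c.result.p_nominal:.3f}"
                    row[f"fdr_{label}"] = f"{c.result.fdr_q:.3f}"
                elif c.kind == "self":
                    row[f"p_{label}"] = "-"
                    row[f"fdr_{label}"] = "-"
                else:
                    row[f"p_{label}"] = f"set {c.kind}"
                    row[f"fdr_{label}"] = f"set {c.kind}"
            rows.append(row)
        return pd.DataFrame(rows)


def partition_of(
    derived: tuple[str, str] | None, context: tuple[str, str]
) -> str:
    if derived is None:
        return "external"
    if derived == context:
        return "self"
    if derived[0] == context[0]:
        return "cross_control"
    return "cross_route"


def run_cross_validation(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    thresholds: Thresholds | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    external_sets: Sequence[GeneSet] = (),
    collapse: str = "max_mean",
) -> ValidationTable:
    """Derive the 8 route x control x direction sets and cross-evaluate them.

    GSEA is run once per context (one ranking, shared permutation nulls per
    set size); NES/FDR are pooled over the sets evaluated in that context.
    Deterministic given the seed. Empty gene sets keep their row, with every
    cell marked ``empty``.
    """
    thresholds = thresholds or Thresholds()
    validate_sample_sheet(samples)
    for g in ROUTES + CONTROLS:
        if len(samples_in_group(samples, g)) < 2:
            raise DesignError(f"group {g} needs >=2 samples")

    selections: dict[tuple[str, str], DESelection] = {}
    sets: list[tuple[str, GeneSet | None, tuple[str, str] | None]] = []
    for route, ctrl in CONTEXTS:
        sel = select_de(
            matrix,
            treated=samples_in_group(samples, route),
            controls=samples_in_group(samples, ctrl),
            thresholds=thresholds,
            treated_label=route,
            control_label=ctrl,
        )
        selections[(route, ctrl)] = sel
        up, down = build_gene_sets(sel)
        for direction, gs in (("up", up), ("down", down)):
            name = set_name(route, ctrl, direction)
            sets.append((name, gs, (route, ctrl)))
    for gs in external_sets:
        sets.append((gs.name, gs, None))

    set_names = [name for name, _, _ in sets]
    set_sizes = {name: (len(gs) if gs is not None else 0)
                 for name, gs, _ in sets}
    derived_from = {name: src for name, _, src in sets}

    rng_root = np.random.SeedSequence(seed)
    ctx_seeds = rng_root.spawn(len(CONTEXTS))
    cells: dict[tuple[str, tuple[str, str]], Cell] = {}

    for ctx, ctx_seed in zip(CONTEXTS, ctx_seeds):
        route, ctrl = ctx
        ranked = signal_to_noise_rank(
            matrix,
            samples_in_group(samples, route),
            samples_in_group(samples, ctrl),
            collapse=collapse,
        )
        rng = np.random.default_rng(ctx_seed)
        null_cache: dict[int, np.ndarray] = {}
        entries = []
        entry_names = []
        for name, gs, src in sets:
            part = partition_of(src, ctx)
            if part == "self":
                cells[(name, ctx)] = Cell(partition="self", kind="self")
                continue
            if gs is None:
                cells[(name, ctx)] = Cell(partition=part, kind="empty")
                continue
            matched = int(np.isin(ranked.genes, list(gs.members)).sum())
            if matched == 0 or matched == len(ranked):
                log.warning("set %r cannot be evaluated in context %s "
                            "(matched=%d)", name, ctx, matched)
                cells[(name, ctx)] = Cell(partition=part, kind="unmatched")
                continue
            profile = enrichment_score(ranked, gs, weight=weight)
            size = len(profile.hit_positions)
            if size not in null_cache:
                null_cache[size] = permutation_null(
                    ranked, size, n_perm=n_perm, seed=rng, weight=weight)
            p = nominal_p(profile.es, null_cache[size])
            entries.append((name, ctx, profile.es, null_cache[size], p, size))
            entry_names.append((name, part))
        if entries:
            results = nes_and_fdr(entries, p_max=thresholds.p_max,
                                  fdr_max=thresholds.fdr_max)
            for (name, part), res in zip(entry_names, results):
                cells[(name, ctx)] = Cell(partition=part, kind="result",
                                          result=res)

    return ValidationTable(
        set_names=set_names,
        set_sizes=set_sizes,
        derived_from=derived_from,
        contexts=list(CONTEXTS),
        cells=cells,
        selections=selections,
    )


def summarize(table: ValidationTable) -> dict:
    """Significant-cell counts per partition plus a flat cell listing.

    The cross-control count (significant / 8 with the default design) is the
    primary summary line; cross-route and external counts are reported
    separately because the partitions are not interchangeable.
    """
    counts = {p: {"significant": 0, "evaluated": 0, "total": 0}
              for p in PARTITIONS}
    flat = []
    for (name, ctx), cell in table.cells.items():
        counts[cell.partition]["total"] += 1
        entry = {
            "set_name": name,
            "context": f"{ctx[0]}_vs_{ctx[1]}",
            "partition": cell.partition,
            "kind": cell.kind,
        }
        if cell.kind == "result":
            counts[cell.partition]["evaluated"] += 1
            entry.update({
                "es": cell.result.es,
                "nes": cell.result.nes,
                "p_nominal": cell.result.p_nominal,
                "fdr_q": cell.result.fdr_q,
                "significant": cell.result.significant,
            })
            if cell.result.significant:
                counts[cell.partition]["significant"] += 1
        flat.append(entry)
    flat.sort(key=lambda e: (e["set_name"], e["context"]))
    cc = counts["cross_control"]
    return {
        "cross_control_significant": cc["significant"],
        "cross_control_total": cc["evaluated"],
        "per_partition": counts,
        "cells": flat,
    }


def evaluate_external_set(
    matrix: ExpressionMatrix,
    samples: pd.DataFrame,
    gene_set: GeneSet,
    contexts: Sequence[tuple[str, str]] = CONTEXTS,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    thresholds: Thresholds | None = None,
    collapse: str = "max_mean",
) -> dict[tuple[str, str], GseaResult]:
    """Evaluate a literature gene set in each requested context.

    Reports the matched-member count per context; raises when no member
    matches the gene universe anywhere.
    """
    thresholds = thresholds or Thresholds()
    validate_sample_sheet(samples)
    rng_root = np.random.SeedSequence(seed)
    out: dict[tuple[str, str], GseaResult] = {}
    any_matched = False
    for ctx, ctx_seed in zip(contexts, rng_root.spawn(len(contexts))):
        route, ctrl = ctx
        ranked = signal_to_noise_rank(
            matrix,
            samples_in_group(samples, route),
            samples_in_group(samples, ctrl),
            collapse=collapse,
        )
        matched = int(np.isin(ranked.genes, list(gene_set.members)).sum())
        if matched == 0:
            continue
        any_matched = True
        profile = enrichment_score(ranked, gene_set, weight=weight)
        null = permutation_null(ranked, matched, n_perm=n_perm,
                                seed=np.random.default_rng(ctx_seed),
                                weight=weight)
        p = nominal_p(profile.es, null)
        out[ctx] = nes_and_fdr(
            [(gene_set.name, ctx, profile.es, null, p, matched)],
            p_max=thresholds.p_max, fdr_max=thresholds.fdr_max)[0]
    if not any_matched:
        raise EvaluationError(
            f"gene set {gene_set.name!r}: no member matches the gene universe")
    return out
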