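"""Replicate-wise fold-change differential expression selection.

A spot is called regulated when the two-sample t-test gives p below the
threshold AND every treated replicate is displaced from the control-group
mean by more than the log2 fold-change bound, all in the same direction.
Selected spots are collapsed to unique genes, and direction-split gene sets
are built from them for downstream enrichment analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Selection and significance thresholds.

    ``fc_log2_min`` defaults to the exact log2(1.5) = 0.58496 rather than the
    rounded 0.6 sometimes quoted alongside the 1.5-fold rule; pass
    ``fc_log2_min=0.6`` to use the rounded variant.
    """

    p_max: float = 0.05
    fc_log2_min: float = math.log2(1.5)
    floor: float = 130.0
    fdr_max: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must be in (0, 1)")
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError("fdr_max must be in (0, 1)")
        if self.fc_log2_min <= 0:
            raise ValueError("fc_log2_min must be positive")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass(frozen=True)
class GeneSet:
    """Named collection of unique gene ids with provenance."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a name")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DESelection:
    """Outcome of one treated-vs-control selection.

    ``records`` holds one row per selected spot: ``probe_id``, ``gene_id``,
    ``p_value``, one ``fc_<animal>`` column per treated replicate (log2
    displacement from the control mean), and ``direction`` (up/down).
    """

    treated_label: str
    control_label: str
    thresholds: Thresholds
    records: pd.DataFrame
    treated_samples: tuple[str, ...] = ()
    control_samples: tuple[str, ...] = ()

    @property
    def n_spots(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        """Unique genes, first-appearance order."""
        return list(dict.fromkeys(self.records["gene_id"]))

    def genes_in_direction(self, direction: str) -> list[str]:
        sub = self.records[self.records["direction"] == direction]
        return list(dict.fromkeys(sub["gene_id"]))

    @property
    def comparison(self) -> tuple[str, str]:
        return (self.treated_label, self.control_label)


def gene_ttest(
    matrix: ExpressionMatrix,
    treated: Sequence[str],
    controls: Sequence[str],
    welch: bool = False,
) -> pd.Series:
    """Two-sided two-sample t-test p-value per row.

    Student's pooled-variance test by default (``welch=True`` switches to the
    unequal-variance form). Missing values are dropped per row; a row with
    fewer than 2 usable samples on either side gets NaN. Rows with zero
    pooled variance give p=1 when the means agree and the smallest positive
    float when they differ.
    """
    if len(treated) < 2 or len(controls) < 2:
        raise DesignError("t-test needs at least 2 samples per side")
    a = matrix.values[list(treated)].to_numpy(dtype=float)
    b = matrix.values[list(controls)].to_numpy(dtype=float)

    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    usable = (na >= 2) & (nb >= 2)
    n_bad = int((~usable).sum())
    if n_bad:
        log.info("t-test: %d rows with <2 usable samples on a side (masked)",
                 n_bad)

    import warnings
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(a, axis=1)
        mb = np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
        if welch:
            sea2 = va / na
            seb2 = vb / nb
            se = np.sqrt(sea2 + seb2)
            df = (sea2 + seb2) ** 2 / (
                sea2**2 / (na - 1) + seb2**2 / (nb - 1))
        else:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = na + nb - 2
        t = (ma - mb) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    zero_se = usable & np.isfinite(ma) & np.isfinite(mb) & (se == 0)
    if zero_se.any():
        log.warning("t-test: %d rows with zero variance on both sides",
                    int(zero_se.sum()))
        same = zero_se & (ma == mb)
        diff = zero_se & (ma != mb)
        p[same] = 1.0
        p[diff] = np.finfo(float).tiny
    p[~usable] = np.nan
    return pd.Series(p, index=matrix.values.index, name="p_value")


def select_de(
    matrix: ExpressionMatrix,
    treated: Sequence[str],
    controls: Sequence[str],
    thresholds: Thresholds | None = None,
    treated_label: str = "treated",
    control_label: str = "control",
    welch: bool = False,
) -> DESelection:
    """Apply the three-part selection rule at spot level.

    A spot passes iff p < p_max, every treated replicate's log2 displacement
    from the control mean exceeds fc_log2_min in magnitude, and all
    displacements share one sign. An empty selection is a valid outcome.
    """
    thresholds = thresholds or Thresholds()
    matrix.require_stage("centered")
    p = gene_ttest(matrix, treated, controls, welch=welch)

    tvals = matrix.values[list(treated)].to_numpy(dtype=float)
    cvals = matrix.values[list(controls)].to_numpy(dtype=float)
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        ctrl_mean = np.nanmean(cvals, axis=1)
    disp = tvals - ctrl_mean[:, None]

    complete = ~np.isnan(disp).any(axis=1)
    big = np.abs(disp) > thresholds.fc_log2_min
    all_up = (disp > 0).all(axis=1)
    all_down = (disp < 0).all(axis=1)
    passes = (
        complete
        & (p.to_numpy() < thresholds.p_max)
        & big.all(axis=1)
        & (all_up | all_down)
    )

    idx = np.flatnonzero(passes)
    gene_map = matrix.gene_map
    records = pd.DataFrame({
        "probe_id": matrix.values.index[idx],
        "gene_id": (
            gene_map.iloc[idx].to_numpy()
            if gene_map is not None
            else matrix.values.index[idx]
        ),
        "p_value": p.to_numpy()[idx],
        **{
            f"fc_{s}": disp[idx, k]
            for k, s in enumerate(treated)
        },
        "direction": np.where(all_up[idx], "up", "down"),
    })
    log.info("DE %s vs %s: %d spots / %d genes selected",
             treated_label, control_label, len(records),
             records["gene_id"].nunique())
    return DESelection(
        treated_label=treated_label,
        control_label=control_label,
        thresholds=thresholds,
        records=records,
        treated_samples=tuple(treated),
        control_samples=tuple(controls),
    )


def set_name(treated_label: str, control_label: str, direction: str) -> str:
    return f"DHEA_{treated_label}_vs_{control_label}_{direction.upper()}"


def build_gene_sets(
    selection: DESelection,
) -> tuple[GeneSet | None, GeneSet | None]:
    """Split a selection into the UP and DOWN gene sets.

    Gene ids are collapsed across spots. A gene whose probes disagree in
    direction lands in both sets, with a warning. An empty direction yields
    ``None`` for that set (logged).
    """
    up_genes = selection.genes_in_direction("up")
    down_genes = selection.genes_in_direction("down")
    conflict = set(up_genes) & set(down_genes)
    if conflict:
        log.warning(
            "genes with probes selected in both directions "
            "(kept in both sets): %s", sorted(conflict))
    provenance = (
        f"derived from {selection.treated_label} vs "
        f"{selection.control_label}; p<{selection.thresholds.p_max}, "
        f"|log2FC|>{selection.thresholds.fc_log2_min:.5f} per replicate"
    )
    out: list[GeneSet | None] = []
    for direction, members in (("up", up_genes), ("down", down_genes)):
        name = set_name(selection.treated_label, selection.control_label,
                        direction)
        if not members:
            log.info("no %s-regulated genes for %s; set omitted",
                     direction, name)
            out.append(None)
        else:
            out.append(GeneSet(name=name, members=tuple(members),
                               description=provenance))
    return out[0], out[1]


def venn_compare(
    selections: Sequence[DESelection],
    labels: Sequence[str] | None = None,
) -> dict[frozenset[str], int]:
    """Exclusive overlap counts of unique genes across selections.

    Returns one entry per non-empty region label subset (2^k - 1 regions for
    k selections); the count is the number of genes in exactly that subset.
    """
    if len(selections) < 2:
        raise DesignError("venn comparison needs at least 2 selections")
    if labels is None:
        labels = [f"{s.treated_label}_vs_{s.control_label}"
                  for s in selections]
    if len(labels) != len(selections):
        raise ValueError("labels must match selections")
    gene_sets = {lab: set(sel.genes) for lab, sel in zip(labels, selections)}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(gene_sets[c] for c in combo))
            outside = set.union(
                set(), *(gene_sets[c] for c in labels if c not in combo))
            regions[frozenset(combo)] = len(inside - outside)
    return regions
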