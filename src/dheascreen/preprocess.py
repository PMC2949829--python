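"""Spot-level two-channel preprocessing.

Turns per-array spot tables (Cy5 sample channel vs pooled Cy3 common
reference) into an analysis-ready log2, gene-mean-centred expression matrix:

    filter (2x background) -> normalize -> floor -> log2 -> center

plus the two unsupervised views used for QC: PCA over samples and
average-linkage hierarchical clustering over genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, DesignError, FormatError

log = logging.getLogger(__name__)

#: Required columns of a spot table, in canonical order.
SPOT_COLUMNS = ("probe_id", "gene_id", "cy5", "cy3", "bg5", "bg3")

#: Valid treatment/control group labels.
GROUPS = ("IM", "PO", "CTR1", "CTR3")

#: Processing stages in pipeline order.
STAGES = ("normalized", "floored", "log2", "centered")

DEFAULT_FLOOR = 130.0

#: Genes missing in more than this fraction of samples are dropped.
MAX_MISSING_FRACTION = 0.5


@dataclass
class SpotTable:
    """Spot-level intensities of one array (one animal/sample).

    ``data`` holds one row per spot with columns ``probe_id``, ``gene_id``,
    ``cy5``, ``cy3``, ``bg5``, ``bg3`` and, after :func:`filter_low_signal`,
    a boolean ``excluded`` column.
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(
                f"spot table {self.sample_id!r} lacks columns {missing}"
            )
        if self.data["probe_id"].duplicated().any():
            dup = self.data["probe_id"][self.data["probe_id"].duplicated()].iloc[0]
            raise FormatError(
                f"spot table {self.sample_id!r} has duplicate probe_id {dup!r}"
            )
        for c in ("cy5", "cy3", "bg5", "bg3"):
            if (self.data[c].to_numpy() < 0).any():
                raise FormatError(
                    f"spot table {self.sample_id!r}: negative values in {c!r}"
                )

    @property
    def n_spots(self) -> int:
        return len(self.data)

    @property
    def n_excluded(self) -> int:
        if "excluded" not in self.data.columns:
            return 0
        return int(self.data["excluded"].sum())


@dataclass
class ExpressionMatrix:
    """Probe- or gene-level expression values at a declared processing stage.

    ``values`` is indexed by probe (or gene) id with one column per sample;
    NaN marks missing values (excluded spots). ``gene_map`` maps probe ids to
    gene ids and is ``None`` once rows are genes.
    """

    values: pd.DataFrame
    stage: str
    gene_map: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.index.duplicated().any():
            raise FormatError("duplicated row ids in expression matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise DesignError(
                f"expected matrix at stage {stage!r}, got {self.stage!r}"
            )


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-animal metadata table.

    Requires columns ``animal_id``, ``group``, ``batch``; control groups must
    sit in their home batch (CTR1 in batch 1, CTR3 in batch 3).
    """
    for col in ("animal_id", "group", "batch"):
        if col not in samples.columns:
            raise FormatError(f"sample sheet lacks column {col!r}")
    bad = set(samples["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}")
    if samples["animal_id"].duplicated().any():
        raise FormatError("duplicate animal ids in sample sheet")
    ctr1 = samples.loc[samples["group"] == "CTR1", "batch"]
    ctr3 = samples.loc[samples["group"] == "CTR3", "batch"]
    if len(ctr1) and not (ctr1 == 1).all():
        raise FormatError("CTR1 animals must belong to batch 1")
    if len(ctr3) and not (ctr3 == 3).all():
        raise FormatError("CTR3 animals must belong to batch 3")
    return samples


def samples_in_group(samples: pd.DataFrame, group: str) -> list[str]:
    """Animal ids of one group, in sheet order."""
    if group not in GROUPS:
        raise DesignError(f"unknown group {group!r}")
    return list(samples.loc[samples["group"] == group, "animal_id"])


# ---------------------------------------------------------------------------
# Stage 1: low-signal filter
# ---------------------------------------------------------------------------

def filter_low_signal(spots: SpotTable) -> SpotTable:
    """Flag spots whose foreground is below twice the background.

    The rule is applied per channel; a spot is excluded when *either* channel
    fails (strictly below: cy < 2*bg). Values are retained but masked in all
    downstream computation.
    """
    d = spots.data
    for c in ("bg5", "bg3"):
        if c not in d.columns:
            raise FormatError(f"spot table {spots.sample_id!r} lacks {c!r}")
    excluded = (d["cy5"].to_numpy() < 2.0 * d["bg5"].to_numpy()) | (
        d["cy3"].to_numpy() < 2.0 * d["bg3"].to_numpy()
    )
    out = d.copy()
    out["excluded"] = excluded
    log.info(
        "array %s: %d/%d spots excluded by the 2x-background rule",
        spots.sample_id, int(excluded.sum()), len(out),
    )
    return SpotTable(sample_id=spots.sample_id, data=out)


# ---------------------------------------------------------------------------
# Stage 2: two-step median-ratio normalization (common reference design)
# ---------------------------------------------------------------------------

def normalize(spot_tables: Sequence[SpotTable]) -> ExpressionMatrix:
    """Normalize a set of common-reference arrays into one matrix.

    Step 1 (random error): each spot's Cy5 is rescaled by the ratio of the
    across-array median Cy3 of that spot to the spot's own Cy3, cancelling
    per-spot reference variation::

        R[i, j] = cy5[i, j] * median_j'(cy3[i, j']) / cy3[i, j]

    Step 2 (systematic error): each array is rescaled so its median R matches
    the overall median::

        N[i, j] = R[i, j] * M / m5[j],  m5[j] = median_i R[i, j],
                                        M = median of all R

    Excluded spots propagate as NaN and are skipped by every median.
    """
    if len(spot_tables) < 2:
        raise DesignError("normalization needs at least 2 arrays")

    first = spot_tables[0].data
    probes = first["probe_id"].to_numpy()
    probe_set = set(probes)
    sample_ids = []
    cy5_cols, cy3_cols = [], []
    for st in spot_tables:
        d = st.data
        if set(d["probe_id"]) != probe_set:
            raise DesignError(
                f"array {st.sample_id!r} does not share the probe universe"
            )
        d = d.set_index("probe_id").reindex(probes)
        excluded = d["excluded"].to_numpy(dtype=bool) if "excluded" in d else (
            np.zeros(len(d), dtype=bool)
        )
        cy5 = d["cy5"].to_numpy(dtype=float).copy()
        cy3 = d["cy3"].to_numpy(dtype=float).copy()
        zero_ref = (~excluded) & (cy3 == 0)
        if zero_ref.any():
            i = int(np.flatnonzero(zero_ref)[0])
            raise ComputationError(
                f"array {st.sample_id!r}: retained spot {probes[i]!r} "
                "has zero Cy3 reference signal"
            )
        cy5[excluded] = np.nan
        cy3[excluded] = np.nan
        sample_ids.append(st.sample_id)
        cy5_cols.append(cy5)
        cy3_cols.append(cy3)

    cy5_m = np.column_stack(cy5_cols)
    cy3_m = np.column_stack(cy3_cols)

    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN spot rows
        m3 = np.nanmedian(cy3_m, axis=1, keepdims=True)  # per-spot reference
        ratio = cy5_m * m3 / cy3_m
        m5 = np.nanmedian(ratio, axis=0)  # per-array level
        overall = np.nanmedian(ratio)
    if np.isnan(m5).any():
        j = int(np.flatnonzero(np.isnan(m5))[0])
        raise ComputationError(
            f"array {sample_ids[j]!r}: all spots excluded, no array median"
        )
    normalized = ratio * (overall / m5)

    values = pd.DataFrame(normalized, index=pd.Index(probes, name="probe_id"),
                          columns=sample_ids)
    gene_map = first.set_index("probe_id")["gene_id"].reindex(probes)
    return ExpressionMatrix(values=values, stage="normalized",
                            gene_map=gene_map)


# ---------------------------------------------------------------------------
# Stage 3: floor -> log2 -> center
# ---------------------------------------------------------------------------

def floor_matrix(matrix: ExpressionMatrix, floor: float = DEFAULT_FLOOR) -> ExpressionMatrix:
    """Raise every intensity below ``floor`` to ``floor``."""
    matrix.require_stage("normalized")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return replace(matrix, values=matrix.values.clip(lower=floor), stage="floored")


def log2_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    matrix.require_stage("floored")
    vals = matrix.values.to_numpy()
    assert np.nanmin(vals) > 0, "flooring guarantees positive intensities"
    return replace(matrix, values=np.log2(matrix.values), stage="log2")


def center_matrix(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each row's mean over non-missing samples."""
    matrix.require_stage("log2")
    centered = matrix.values.sub(matrix.values.mean(axis=1, skipna=True), axis=0)
    return replace(matrix, values=centered, stage="centered")


def floor_log_center(
    matrix: ExpressionMatrix,
    floor: float = DEFAULT_FLOOR,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> ExpressionMatrix:
    """Run floor -> log2 -> per-gene mean centering.

    Rows missing in more than ``max_missing_fraction`` of samples are dropped
    first (and logged); remaining NaNs stay masked.
    """
    matrix.require_stage("normalized")
    frac_missing = matrix.values.isna().mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d rows missing in >%.0f%% of samples",
                 n_drop, 100 * max_missing_fraction)
    trimmed = replace(
        matrix,
        values=matrix.values.loc[keep],
        gene_map=None if matrix.gene_map is None else matrix.gene_map.loc[keep],
    )
    return center_matrix(log2_matrix(floor_matrix(trimmed, floor=floor)))


# ---------------------------------------------------------------------------
# Unsupervised views
# ---------------------------------------------------------------------------

@dataclass
class PcaView:
    """Per-sample principal component scores and variance fractions."""

    scores: pd.DataFrame           # samples x components
    variance_fractions: np.ndarray
    n_rows_used: int


def pca_view(matrix: ExpressionMatrix) -> PcaView:
    """PCA of samples on the centred matrix (no extra scaling).

    Rows containing missing values are dropped (and logged). Components are
    sorted by decreasing variance; signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    matrix.require_stage("centered")
    if matrix.values.shape[1] < 2:
        raise DesignError("PCA needs at least 2 samples")
    complete = matrix.values.dropna(axis=0)
    dropped = len(matrix.values) - len(complete)
    if dropped:
        log.info("PCA: dropped %d rows with missing values", dropped)
    if complete.empty:
        raise DesignError("PCA: no complete rows available")

    x = complete.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[k])))
        if vt[k, i] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    total = float((s ** 2).sum())
    fractions = (s ** 2) / total if total > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        u * s,
        index=matrix.values.columns,
        columns=[f"PC{k + 1}" for k in range(len(s))],
    )
    return PcaView(scores=scores, variance_fractions=fractions,
                   n_rows_used=len(complete))


@dataclass
class Dendrogram:
    """Average-linkage tree over genes.

    ``merges`` is a scipy-style linkage matrix: each row
    ``(id_a, id_b, height, size)`` merges two clusters into a new cluster with
    id ``n_leaves + row_index``. ``genes`` lists the leaf order (leaf ``i`` is
    ``genes[i]``).
    """

    genes: list[str]
    merges: np.ndarray


def hca_genes(matrix: ExpressionMatrix, gene_ids: Sequence[str]) -> Dendrogram:
    """Agglomerative average-linkage clustering of the selected genes.

    Distance is 1 - Pearson correlation across samples. Ties in the merge
    order are broken by the lowest (i, j) cluster-id pair. Zero-variance
    genes are dropped with a warning; rows with missing values are dropped.
    """
    missing_ids = [g for g in gene_ids if g not in matrix.values.index]
    if missing_ids:
        raise DesignError(f"genes not in matrix: {missing_ids[:5]}")
    sub = matrix.values.loc[list(gene_ids)]
    complete = sub.dropna(axis=0)
    if len(complete) < len(sub):
        log.warning("HCA: dropped %d genes with missing values",
                    len(sub) - len(complete))
    var = complete.var(axis=1, ddof=0)
    flat = var[var == 0].index.tolist()
    if flat:
        log.warning("HCA: dropped %d zero-variance genes: %s",
                    len(flat), flat[:5])
        complete = complete.drop(index=flat)
    n = len(complete)
    if n < 2:
        raise DesignError("HCA needs at least 2 usable genes")

    x = complete.to_numpy()
    corr = np.corrcoef(x)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)

    # straightforward O(n^3) agglomeration; n is a DE gene list, small
    total = 2 * n - 1
    d = np.full((total, total), np.inf)
    d[:n, :n] = dist
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = (np.inf, -1, -1)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                if d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        h, i, j = best
        new = n + step
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = (
                sizes[i] * d[i, k] + sizes[j] * d[j, k]
            ) / (sizes[i] + sizes[j])
        sizes[new] = sizes[i] + sizes[j]
        active.remove(i)
        active.remove(j)
        active.append(new)
        merges[step] = (i, j, h, sizes[new])
    return Dendrogram(genes=list(complete.index), merges=merges)


def qc_report(spot_tables: Sequence[SpotTable], matrix: ExpressionMatrix) -> dict:
    """Per-array exclusion counts and medians, for the QC JSON sidecar."""
    per_array = {}
    for st in spot_tables:
        d = st.data
        per_array[st.sample_id] = {
            "n_spots": int(len(d)),
            "n_excluded": st.n_excluded,
            "median_cy5": float(d["cy5"].median()),
            "median_cy3": float(d["cy3"].median()),
        }
    return {
        "n_arrays": len(spot_tables),
        "n_rows_matrix": int(matrix.values.shape[0]),
        "stage": matrix.stage,
        "per_array": per_array,
    }
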