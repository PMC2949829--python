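"""Shared file formats: spot tables, sample sheets, expression matrices (TSV),
gene sets (GMT), truth/summary sidecars (JSON).

Every tabular artifact is plain TSV; expression matrices carry their
processing stage and the tool version in a leading ``#`` comment line so a
round trip restores the full object.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import DESelection, GeneSet
from .errors import ParseError
from .preprocess import SPOT_COLUMNS, ExpressionMatrix, SpotTable

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...).

    Duplicate members within a line are dropped with a warning; a line with
    fewer than 3 fields is a parse error naming the line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                log.warning("%s:%d: set %r has duplicate members (deduped)",
                            path, lineno, name)
            sets.append(GeneSet(name=name, members=tuple(unique),
                                description=desc))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "na",
                                *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """TSV with row ids in column 1 (plus a gene_id column for probe-level
    matrices) and the stage recorded in a leading comment line."""
    with open(path, "w") as fh:
        fh.write(f"# dheascreen={__version__}\tstage={matrix.stage}\n")
        out = matrix.values.copy()
        out.index.name = out.index.name or "id"
        if matrix.gene_map is not None:
            out.insert(0, "gene_id", matrix.gene_map.reindex(out.index))
        out.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: missing stage comment line")
        meta = dict(
            part.split("=", 1) for part in header[1:].strip().split("\t")
            if "=" in part)
        stage = meta.get("stage")
        if stage is None:
            raise ParseError(f"{path}: stage missing from header comment")
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"])
    df.index.name = None  # writer re-adds the generic "id" label
    gene_map = None
    if "gene_id" in df.columns:
        gene_map = df["gene_id"]
        df = df.drop(columns=["gene_id"])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated row id {dup!r}")
    bad = df.columns[~df.dtypes.map(
        lambda t: np.issubdtype(t, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                       & df[col].notna()]
        where = f"row {row[0]!r}, " if len(row) else ""
        raise ParseError(f"{path}: non-numeric cell ({where}column {col!r})")
    return ExpressionMatrix(values=df.astype(float), stage=stage,
                            gene_map=gene_map)


# ---------------------------------------------------------------------------
# Spot tables and sample sheets
# ---------------------------------------------------------------------------

def write_spot_table(spots: SpotTable, path: str | Path) -> None:
    cols = [c for c in (*SPOT_COLUMNS, "excluded") if c in spots.data.columns]
    spots.data[cols].to_csv(path, sep="\t", index=False,
                            float_format=_FLOAT_FMT)


def read_spot_table(path: str | Path, sample_id: str | None = None) -> SpotTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing spot columns {missing}")
    sid = sample_id or Path(path).stem
    return SpotTable(sample_id=sid, data=df)


def write_spot_tables(tables: Sequence[SpotTable], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for st in tables:
        p = out_dir / f"{st.sample_id}.spots.tsv"
        write_spot_table(st, p)
        paths.append(p)
    return paths


def read_spot_tables(spots_dir: str | Path) -> list[SpotTable]:
    paths = sorted(Path(spots_dir).glob("*.spots.tsv"))
    if not paths:
        raise ParseError(f"no *.spots.tsv files in {spots_dir}")
    return [read_spot_table(p, sample_id=p.name.removesuffix(".spots.tsv"))
            for p in paths]


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "animal_id" not in df.columns:
        raise ParseError(f"{path}: missing column 'animal_id'")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


# ---------------------------------------------------------------------------
# DE selections and JSON sidecars
# ---------------------------------------------------------------------------

def write_de_selection(selection: DESelection, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# dheascreen={__version__}"
            f"\ttreated={selection.treated_label}"
            f"\tcontrol={selection.control_label}"
            f"\tp_max={selection.thresholds.p_max}"
            f"\tfc_log2_min={selection.thresholds.fc_log2_min:.10g}\n")
        selection.records.to_csv(fh, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)


def write_json(obj: dict, path: str | Path) -> None:
    payload = {"dheascreen": __version__, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
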