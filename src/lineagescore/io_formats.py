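"""Readers/writers for expression matrices and clinical tables.

All matrices are genes-as-rows, samples-as-columns, tab-delimited UTF-8
with a header row. Scoring inputs must be complete: the reader rejects
missing and non-numeric cells rather than imputing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum fraction of reference genes that must match the patient platform
#: before scoring is allowed to proceed.
DEFAULT_MATCH_FLOOR = 0.5


class ExpressionTableError(ValueError):
    """Raised for malformed expression matrices."""


def read_expression_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Parameters
    ----------
    path
        Tab-delimited file: first column gene/probe identifiers, remaining
        columns one per sample. ``dialect="gct-like"`` skips the two
        leading header lines of GCT-style exports and drops a Description
        column if present.

    Returns
    -------
    pandas.DataFrame
        Numeric matrix indexed by gene/probe id. Duplicate probe ids are
        permitted (they are resolved later by :func:`collapse_probes`);
        duplicate sample ids are an error.
    """
    path = Path(path)
    if dialect not in ("tsv", "gct-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    skiprows = 2 if dialect == "gct-like" else 0
    # pandas silently renames duplicate header fields; check them raw first
    with open(path, encoding="utf-8") as fh:
        for _ in range(skiprows):
            fh.readline()
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    fields = header.rstrip("\n").split("\t")[1:]
    if len(set(fields)) != len(fields):
        dups = sorted({f for f in fields if fields.count(f) > 1})
        raise ExpressionTableError(f"{path}: duplicate sample ids {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows, comment="#",
                     float_precision="round_trip")
    if dialect == "gct-like" and len(df.columns) and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ExpressionTableError(f"{path}: no data rows/columns (header only?)")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ExpressionTableError(f"{path}: duplicate sample ids {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ExpressionTableError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ExpressionTableError(
                f"{path}: missing value at row {row!r}, column {col!r}"
            )
        df[col] = coerced.astype(float)
    values = df.to_numpy()
    if not np.isfinite(values).all():
        raise ExpressionTableError(f"{path}: non-finite values present")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_expression_table(
    table: pd.DataFrame, path: str | Path, header_comments: list[str] | None = None
) -> None:
    """Write a genes x samples matrix as TSV, with optional ``#`` comment lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", float_format="%.17g")


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical table (one row per sample).

    Required columns: ``sample_id``, ``time`` (non-negative, one unit
    throughout), ``event`` (1 = death/event, 0 = censored). Any remaining
    columns are carried as covariates.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: clinical table lacks required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in clinical table")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative survival times")
    if not df["event"].isin((0, 1)).all():
        raise ValueError(f"{path}: event indicator must be 0/1")
    return df.set_index("sample_id")


def collapse_probes(table: pd.DataFrame, probe_to_gene: dict[str, str]) -> pd.DataFrame:
    """Collapse probe-level rows to gene symbols.

    For each gene, the probe with the highest mean intensity across all
    samples is retained; ties are broken by lexicographically smallest
    probe id. Probes absent from the mapping are dropped (count logged).
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    mapped = table.index.to_series().map(probe_to_gene)
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    kept = table.loc[mapped.notna()]
    genes = mapped.dropna()
    means = kept.mean(axis=1)
    # highest mean wins; ties -> smallest probe id (sort keys make the
    # winner the first row within each gene after a stable sort)
    order = pd.DataFrame({"gene": genes, "mean": means, "probe": kept.index})
    order = order.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    winners = order.drop_duplicates("gene", keep="first")["probe"]
    out = kept.loc[winners]
    out.index = pd.Index(order.drop_duplicates("gene", keep="first")["gene"], name="gene")
    return out.sort_index()


def harmonize_symbols(
    ref_genes: list[str],
    patient_genes: list[str],
    match_floor: float = DEFAULT_MATCH_FLOOR,
) -> list[tuple[str, str]]:
    """Match reference to patient gene symbols case-insensitively.

    Murine symbols ("Cd8a") match their human counterparts ("CD8A") by
    exact identity after upper-casing; no ortholog lookup is attempted.
    Duplicate symbols after case-folding keep the first occurrence.

    Returns the list of (reference symbol, patient symbol) pairs, in
    reference order. Raises if fewer than ``match_floor`` of the reference
    genes match, which usually signals a symbol-version mismatch.
    """
    if not ref_genes or not patient_genes:
        raise ValueError("gene lists must be non-empty")

    def _fold(genes: list[str], label: str) -> dict[str, str]:
        out: dict[str, str] = {}
        dups = 0
        for g in genes:
            key = g.upper()
            if key in out:
                dups += 1
            else:
                out[key] = g
        if dups:
            logger.info("harmonize_symbols: %d duplicate %s symbols after case fold", dups, label)
        return out

    ref_map = _fold(list(ref_genes), "reference")
    pat_map = _fold(list(patient_genes), "patient")
    pairs = [(ref_map[k], pat_map[k]) for k in ref_map if k in pat_map]
    frac = len(pairs) / len(ref_map)
    logger.info("harmonize_symbols: matched %d/%d reference genes (%.1f%%)",
                len(pairs), len(ref_map), 100 * frac)
    if frac < match_floor:
        raise ValueError(
            f"only {frac:.1%} of reference genes matched the patient platform "
            f"(floor {match_floor:.0%}); audit gene symbol versions"
        )
    return pairs


def read_replicate_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping replicate sample id -> lineage."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: replicate map needs two columns (replicate, lineage)")
    rep_col, lin_col = df.columns[:2]
    if df[rep_col].duplicated().any():
        raise ValueError(f"{path}: replicate ids must be unique")
    return dict(zip(df[rep_col], df[lin_col]))


def read_lineage_meta(path: str | Path) -> pd.DataFrame:
    """Read lineage metadata: lineage id, group, subtype (TSV)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "lineage" not in df.columns:
        raise ValueError(f"{path}: lineage metadata needs a 'lineage' column")
    return df.set_index("lineage")


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a simple ``key = value`` config file mirroring the CLI flags."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line not of the form key = value: {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
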