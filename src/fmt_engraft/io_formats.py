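"""Readers and writers for the pipeline's external artifacts.

Everything tabular is TSV: tab separator, ``.`` decimal, UTF-8, one header
row — the dialect of the mOTU/metaSNV tool ecosystem these tables emulate.
Missing values are written as the empty string and accepted on read as
``""``, ``"NA"`` or ``"NaN"`` where the schema allows missingness at all.
Correlation networks are exported as GraphML or SIF; the consolidated
report is JSON.  No science lives here, only parsing and validation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError
from .types import AbundanceTable, ClinicalTable, CohortManifest, SNVTable

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV structure
        raise ParseError(f"{path}: cannot read TSV ({exc})") from exc


def _to_float(raw: str, path, row_label, col_label, allow_missing: bool) -> float:
    text = raw.strip()
    if text in MISSING_TOKENS:
        if allow_missing:
            return float("nan")
        raise ParseError(
            f"{path}: non-numeric cell {raw!r} at row {row_label!r}, column {col_label!r}"
        )
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric cell {raw!r} at row {row_label!r}, column {col_label!r}"
        ) from None


# ---------------------------------------------------------------------------
# abundance


def read_abundance_table(path, taxa_orientation: str = "rows") -> AbundanceTable:
    """Read a taxa x samples relative-abundance TSV.

    ``taxa_orientation`` is ``"rows"`` when taxa are rows (first column =
    taxon id) or ``"columns"`` when the matrix is transposed on disk.
    Columns are not renormalised and all-zero taxa are retained.
    """
    if taxa_orientation not in ("rows", "columns"):
        raise ConfigError(f"taxa_orientation must be 'rows' or 'columns', got {taxa_orientation!r}")
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected an id column plus >=1 numeric column")
    ids = raw.iloc[:, 0]
    body = raw.iloc[:, 1:]
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        for i, cell in enumerate(body[col]):
            values[i, j] = _to_float(cell, path, ids.iloc[i], col, allow_missing=False)
    df = pd.DataFrame(values, index=pd.Index(ids, name=raw.columns[0]), columns=body.columns)
    if taxa_orientation == "columns":
        df = df.T
    df.index = df.index.astype(str)
    df.index.name = "taxon_id"
    df.columns = df.columns.astype(str)
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SNV


def read_snv_table(path) -> SNVTable:
    """Read a metaSNV-style flattened variant TSV.

    Expected columns: ``species_id``, ``position``, ``ref_allele``,
    ``alt_allele``, then one ``<sample>:cov`` / ``<sample>:freq`` pair per
    sample.  Rows with coverage 0 keep their frequency as missing.
    """
    raw = _read_tsv(path)
    meta_cols = ["species_id", "position", "ref_allele", "alt_allele"]
    missing = [c for c in meta_cols if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    rest = [c for c in raw.columns if c not in meta_cols]
    samples: list[str] = []
    for col in rest:
        if col.endswith(":cov"):
            name = col[:-4]
            if f"{name}:freq" not in rest:
                raise ParseError(f"{path}: sample {name!r} has coverage but no frequency column")
            samples.append(name)
        elif not col.endswith(":freq"):
            raise ParseError(f"{path}: unrecognised column {col!r}")
    if not samples:
        raise ParseError(f"{path}: no sample columns found")

    try:
        positions = raw["position"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer position ({exc})") from None
    idx = pd.MultiIndex.from_arrays(
        [raw["species_id"].astype(str), positions], names=["species_id", "position"]
    )
    loci = pd.DataFrame(
        {"ref_allele": raw["ref_allele"].values, "alt_allele": raw["alt_allele"].values},
        index=idx,
    )
    cov = pd.DataFrame(index=idx)
    freq = pd.DataFrame(index=idx)
    for name in samples:
        cov_vals = np.empty(len(raw), dtype=int)
        freq_vals = np.empty(len(raw), dtype=float)
        for i in range(len(raw)):
            c = _to_float(raw[f"{name}:cov"].iloc[i], path, idx[i], f"{name}:cov", False)
            if c < 0 or c != int(c):
                raise ValidationError(f"{path}: coverage must be a nonnegative integer, got {c}")
            cov_vals[i] = int(c)
            freq_vals[i] = _to_float(
                raw[f"{name}:freq"].iloc[i], path, idx[i], f"{name}:freq", True
            )
        cov[name] = cov_vals
        freq[name] = freq_vals
    fr = freq.to_numpy()
    with np.errstate(invalid="ignore"):
        if ((fr < 0) | (fr > 1)).any():
            raise ValidationError(f"{path}: alt_frequency outside [0, 1]")
    return SNVTable(loci=loci, coverage=cov, freq=freq)


def write_snv_table(snv: SNVTable, path) -> None:
    out = snv.loci.reset_index()
    for name in snv.sample_ids:
        out[f"{name}:cov"] = snv.coverage[name].values
        out[f"{name}:freq"] = snv.freq[name].values
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# manifest / clinical


def read_manifest(path) -> CohortManifest:
    raw = _read_tsv(path)
    missing = [c for c in CohortManifest.REQUIRED if c not in raw.columns and c != "day"]
    if "timepoint" in raw.columns and "day" not in raw.columns:
        raw = raw.rename(columns={"timepoint": "day"})
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if "day" not in raw.columns:
        raise ParseError(f"{path}: missing 'day' (or 'timepoint') column")
    return CohortManifest(raw[list(CohortManifest.REQUIRED)])


def write_manifest(manifest: CohortManifest, path) -> None:
    manifest.records.to_csv(path, sep="\t", index=False, na_rep="")


def read_clinical(path) -> ClinicalTable:
    raw = _read_tsv(path)
    missing = [c for c in ClinicalTable.REQUIRED if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    values = [
        _to_float(v, path, i, "value", allow_missing=True) for i, v in enumerate(raw["value"])
    ]
    df = raw[["subject_id", "day", "index_name"]].copy()
    df["value"] = values
    df = df[~np.isnan(df["value"].to_numpy())]
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.records.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# network / report


def export_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Serialise a correlation network for external graph tools.

    ``graphml`` writes standard GraphML; ``sif`` writes Cytoscape's simple
    interaction format (``source<TAB>relation<TAB>target``) with the edge
    sign as the relation, plus a ``.sif.attrs.tsv`` side file carrying rho
    and q per edge.  An empty graph is valid.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "sif":
        lines = []
        for u, v, attrs in sorted(graph.edges(data=True)):
            rel = attrs.get("sign", "assoc")
            lines.append(f"{u}\t{rel}\t{v}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
        attr_lines = ["source\ttarget\trho\tq"]
        for u, v, attrs in sorted(graph.edges(data=True)):
            attr_lines.append(f"{u}\t{v}\t{attrs.get('rho', '')}\t{attrs.get('q', '')}")
        Path(str(path) + ".attrs.tsv").write_text("\n".join(attr_lines) + "\n", encoding="utf-8")
    else:
        raise ConfigError(f"unknown network format {format!r} (use 'graphml' or 'sif')")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_report(report: dict, out_dir) -> Path:
    """Write the consolidated engraftment report as deterministic JSON.

    Keys are sorted and floats use ``repr`` precision so identical inputs
    produce byte-identical files.  Returns the path written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, na_rep="")
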