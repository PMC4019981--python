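"""Readers and writers for the delimited-table and network formats.

Run tables are long format (one row per run x protein) because AP-MS count
matrices are sparse; precursor-intensity lists are ";"-joined inside one
cell.  Column orders are documented in ``docs/file_formats.md``.  Networks
export as tab-delimited edge tables, SIF or GraphML.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .datamodel import (
    Dataset,
    Edge,
    InteractionNetwork,
    ProteinRecord,
    PurificationRun,
    canonical_pair,
)
from .errors import SchemaError, ValidationError

RUN_COLUMNS = ["run_id", "bait_id", "replicate", "condition", "protein_id", "spc", "intensities"]
PROTEIN_COLUMNS = ["protein_id", "length", "is_bait"]
REFERENCE_COLUMNS = ["protein_a", "protein_b", "n_publications"]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input table not found: {path}")
    # TSV by default; fall back to comma when the header has no tabs
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return df


def _parse_intensities(cell: str) -> list[float]:
    cell = cell.strip()
    if not cell:
        return []
    return [float(tok) for tok in cell.split(";")]


def read_dataset(run_table: str | Path, protein_table: str | Path) -> Dataset:
    """Load a :class:`Dataset` from a long-format run table and a protein table.

    Rows whose ``bait_id`` carries the ``CONTROL:`` token become control
    runs.  Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` (naming the offending row) for negative counts
    or lengths.
    """
    prot_df = _read_table(protein_table, PROTEIN_COLUMNS[:2])
    proteins: dict[str, ProteinRecord] = {}
    for i, row in prot_df.iterrows():
        try:
            length = int(row["length"])
        except ValueError as exc:
            raise ValidationError(
                f"{protein_table} row {i}: non-integer length {row['length']!r}"
            ) from exc
        if length < 1:
            raise ValidationError(
                f"{protein_table} row {i}: length must be >= 1, got {length}"
            )
        pid = row["protein_id"]
        if pid in proteins:
            raise ValidationError(f"{protein_table} row {i}: duplicate protein {pid!r}")
        is_bait = str(row.get("is_bait", "")).strip().lower() in ("1", "true", "yes")
        proteins[pid] = ProteinRecord(pid, length, is_bait)

    run_df = _read_table(run_table, RUN_COLUMNS)
    runs: dict[str, PurificationRun] = {}
    for i, row in run_df.iterrows():
        rid = row["run_id"]
        if rid not in runs:
            try:
                rep = int(row["replicate"])
            except ValueError as exc:
                raise ValidationError(
                    f"{run_table} row {i}: non-integer replicate {row['replicate']!r}"
                ) from exc
            runs[rid] = PurificationRun(
                run_id=rid,
                bait_id=row["bait_id"],
                replicate_index=rep,
                condition=row["condition"],
            )
        run = runs[rid]
        try:
            spc = int(row["spc"])
        except ValueError as exc:
            raise ValidationError(
                f"{run_table} row {i}: non-integer spectral count {row['spc']!r}"
            ) from exc
        if spc < 0:
            raise ValidationError(
                f"{run_table} row {i}: negative spectral count {spc}"
            )
        pid = row["protein_id"]
        run.counts[pid] = spc
        vals = _parse_intensities(row["intensities"])
        if vals:
            run.intensities[pid] = vals

    sample = [r for r in runs.values() if not r.is_control]
    control = [r for r in runs.values() if r.is_control]
    return Dataset(proteins=proteins, runs=sample, control_runs=control)


def write_dataset(dataset: Dataset, run_table: str | Path, protein_table: str | Path) -> None:
    """Write a dataset back to the long-format tables (UTF-8, tab, LF)."""
    prot_rows = [
        {"protein_id": p.protein_id, "length": p.length, "is_bait": int(p.is_bait)}
        for p in dataset.proteins.values()
    ]
    pd.DataFrame(prot_rows, columns=PROTEIN_COLUMNS).to_csv(
        protein_table, sep="\t", index=False, lineterminator="\n"
    )
    run_rows = []
    for run in list(dataset.runs) + list(dataset.control_runs):
        for pid in sorted(run.counts):
            run_rows.append(
                {
                    "run_id": run.run_id,
                    "bait_id": run.bait_id,
                    "replicate": run.replicate_index,
                    "condition": run.condition,
                    "protein_id": pid,
                    "spc": run.counts[pid],
                    "intensities": ";".join(
                        repr(v) for v in run.intensities.get(pid, [])
                    ),
                }
            )
    pd.DataFrame(run_rows, columns=RUN_COLUMNS).to_csv(
        run_table, sep="\t", index=False, lineterminator="\n"
    )


NETWORK_FORMATS = ("edge-table", "sif", "graphml")

#: Edge attributes always present in exports, in column order.
EDGE_ATTR_ORDER = ["wdn", "enrichment", "rescued", "module", "rel_abundance"]


def write_network(network: InteractionNetwork, path: str | Path, format: str = "edge-table") -> None:
    """Export a network as ``edge-table`` (TSV), ``sif`` or ``graphml``.

    SIF rows read ``bait pp prey``; the edge table and GraphML carry all
    edge attributes.  Unknown format tokens raise :class:`SchemaError`.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise SchemaError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )
    path = Path(path)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for e in network:
                fh.write(f"{e.bait}\tpp\t{e.prey}\n")
        return
    if fmt == "graphml":
        g = nx.Graph()
        for e in network:
            attrs = {
                k: v for k, v in e.attrs.items() if v is not None
            }
            g.add_edge(e.bait, e.prey, **attrs)
        nx.write_graphml(g, path)
        return
    rows = []
    extra_keys: list[str] = []
    for e in network:
        row = {"bait": e.bait, "prey": e.prey}
        for k in EDGE_ATTR_ORDER:
            row[k] = e.attrs.get(k, "")
        for k, v in e.attrs.items():
            if k not in EDGE_ATTR_ORDER:
                row[k] = v
                if k not in extra_keys:
                    extra_keys.append(k)
        rows.append(row)
    cols = ["bait", "prey"] + EDGE_ATTR_ORDER + extra_keys
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_network(path: str | Path) -> InteractionNetwork:
    """Read an edge-table TSV written by :func:`write_network`."""
    df = _read_table(path, ["bait", "prey"])
    net = InteractionNetwork()
    for _, row in df.iterrows():
        attrs = {}
        for k in df.columns:
            if k in ("bait", "prey"):
                continue
            val = row[k]
            if val == "":
                continue
            try:
                num = float(val)
                attrs[k] = int(num) if num == int(num) and k in ("module",) else num
            except ValueError:
                attrs[k] = val
        net.add_edge(Edge(row["bait"], row["prey"], attrs))
    return net


def read_reference_ppi(path: str | Path) -> dict[tuple[str, str], int]:
    """Load a public-PPI reference as canonical undirected pairs.

    Returns a mapping ``(a, b) -> n_publications`` with ``a <= b``.
    Duplicate pairs merge by the maximum publication count; self-edges are
    kept with a warning.
    """
    df = _read_table(path, REFERENCE_COLUMNS)
    edges: dict[tuple[str, str], int] = {}
    for i, row in df.iterrows():
        a, b = row["protein_a"], row["protein_b"]
        try:
            npub = int(row["n_publications"])
        except ValueError as exc:
            raise ValidationError(
                f"{path} row {i}: non-integer n_publications {row['n_publications']!r}"
            ) from exc
        if npub < 1:
            raise ValidationError(
                f"{path} row {i}: n_publications must be >= 1, got {npub}"
            )
        if a == b:
            warnings.warn(f"{path} row {i}: self-edge on {a!r} kept", stacklevel=2)
        key = canonical_pair(a, b)
        edges[key] = max(edges.get(key, 0), npub)
    return edges


__all__ = [
    "EDGE_ATTR_ORDER",
    "NETWORK_FORMATS",
    "PROTEIN_COLUMNS",
    "REFERENCE_COLUMNS",
    "RUN_COLUMNS",
    "read_dataset",
    "read_network",
    "read_reference_ppi",
    "write_dataset",
    "write_network",
]
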