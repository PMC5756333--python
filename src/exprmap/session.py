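"""Whole-session persistence and report assembly.

A session archive is a single zip file with a JSON manifest (format
version, data-map structure, operation records, recipes) plus one TSV
payload per node matrix and the markdown/TSV payloads of every attached
report.  Payloads are checksummed; the byte layout is deterministic given
identical inputs and frozen timestamps, so ``save → load → save`` is
byte-identical and archives diff cleanly.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from pathlib import Path

import pandas as pd

from .datamap import DataMap, DataMapNode, _default_clock
from .matrix import ExpressionMatrix
from .records import AnalysisRecipe, OperationRecord, Report

__all__ = ["FORMAT_VERSION", "save_state", "load_state", "assemble_report"]

FORMAT_VERSION = 1

_FIXED_DATE = (1980, 1, 1, 0, 0, 0)  # frozen zip member timestamp


def _matrix_bytes(matrix: ExpressionMatrix) -> bytes:
    buf = io.StringIO()
    # 17 significant digits → exact float64 round trip
    matrix.values.to_csv(buf, sep="\t", float_format="%.17g")
    return buf.getvalue().encode()


def _table_bytes(table: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    table.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    return buf.getvalue().encode()


def save_state(dmap: DataMap, path: str | Path) -> None:
    """Write the whole data map (structure, matrices, reports) to one file."""
    payloads: dict[str, bytes] = {}
    nodes_manifest = []
    for nid, node in dmap.nodes.items():
        mpath = f"matrices/{nid}.tsv"
        payloads[mpath] = _matrix_bytes(node.matrix)
        reports_manifest = []
        for report in node.reports:
            rbase = f"reports/{nid}/{report.recipe_id}"
            payloads[f"{rbase}.md"] = report.body.encode()
            tables_manifest = {}
            for name, table in report.tables.items():
                tpath = f"{rbase}.{name}.tsv"
                payloads[tpath] = _table_bytes(table)
                tables_manifest[name] = tpath
            reports_manifest.append(
                {
                    "recipe_id": report.recipe_id,
                    "ok": report.ok,
                    "body": f"{rbase}.md",
                    "tables": tables_manifest,
                }
            )
        nodes_manifest.append(
            {
                "node_id": nid,
                "label": node.label,
                "note": node.note,
                "kind": node.matrix.kind,
                "n_features": node.n_features,
                "n_samples": node.n_samples,
                "timestamp": dmap._timestamps.get(nid, ""),
                "matrix": mpath,
                "checksum": hashlib.sha256(payloads[mpath]).hexdigest(),
                "reports": reports_manifest,
            }
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "root_id": dmap.root_id,
        "active_id": dmap.active_id,
        "counter": dmap._counter,
        "nodes": nodes_manifest,
        "edges": [
            {"parent": p, "child": c, "op": op.to_dict()} for p, c, op in dmap.edges
        ],
        "recipes": [r.to_dict() for r in dmap.recipes],
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        items = [("manifest.json", json.dumps(manifest, sort_keys=True, indent=1).encode())]
        items += sorted(payloads.items())
        for name, data in items:
            info = zipfile.ZipInfo(name, date_time=_FIXED_DATE)
            zf.writestr(info, data)


def load_state(path: str | Path) -> DataMap:
    """Reconstruct a data map from an archive; verifies version and checksums."""
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported archive format version {version!r} "
                f"(this build reads version {FORMAT_VERSION})"
            )
        names = set(zf.namelist())
        dmap = DataMap.__new__(DataMap)
        dmap.clock = _default_clock
        dmap.nodes = {}
        dmap.edges = []
        dmap.recipes = []
        dmap._timestamps = {}
        dmap._counter = manifest["counter"]
        for entry in manifest["nodes"]:
            nid = entry["node_id"]
            mpath = entry["matrix"]
            if mpath not in names:
                raise ValueError(f"archive is missing the matrix payload for node {nid!r}")
            raw = zf.read(mpath)
            if hashlib.sha256(raw).hexdigest() != entry["checksum"]:
                raise ValueError(f"checksum mismatch for node {nid!r}")
            df = pd.read_csv(
                io.BytesIO(raw), sep="\t", index_col=0, float_precision="round_trip"
            )
            matrix = ExpressionMatrix(df, kind=entry["kind"])
            node = DataMapNode(nid, entry["label"], matrix, note=entry.get("note", ""))
            for rep in entry.get("reports", []):
                tables = {
                    name: pd.read_csv(
                        io.BytesIO(zf.read(tpath)), sep="\t", float_precision="round_trip"
                    )
                    for name, tpath in rep["tables"].items()
                }
                node.reports.append(
                    Report(
                        recipe_id=rep["recipe_id"],
                        produced_on=nid,
                        body=zf.read(rep["body"]).decode(),
                        tables=tables,
                        ok=rep.get("ok", True),
                    )
                )
            dmap.nodes[nid] = node
            dmap._timestamps[nid] = entry.get("timestamp", "")
        dmap.edges = [
            (e["parent"], e["child"], OperationRecord.from_dict(e["op"]))
            for e in manifest["edges"]
        ]
        dmap.recipes = [AnalysisRecipe.from_dict(r) for r in manifest["recipes"]]
        dmap.root_id = manifest["root_id"]
        dmap.active_id = manifest["active_id"]
    for nid in (dmap.root_id, dmap.active_id):
        if nid not in dmap.nodes:
            raise ValueError(f"archive manifest references missing node {nid!r}")
    dmap._check_acyclic()
    return dmap


def assemble_report(dmap: DataMap, node_id: str) -> str:
    """Concatenate a node's reports into one markdown document.

    Each report section is prefixed by its recipe name and full parameter
    record; the document opens with the node's lineage path from the root.
    """
    node = dmap._check_node(node_id)
    recipe_by_id = {r.recipe_id: r for r in dmap.recipes}
    lines = [f"# Report for node {node_id} ({node.label})", ""]
    if node.note:
        lines += [f"> {node.note}", ""]
    lines.append("## Lineage")
    lines.append("")
    for nid in dmap.lineage_path(node_id):
        step = dmap.nodes[nid]
        op = dmap.incoming_op(nid)
        op_desc = f"{op.op_name} {json.dumps(op.params, sort_keys=True)}" if op else "root"
        lines.append(
            f"- {nid} ({step.label}): {op_desc} — "
            f"{step.n_features} features x {step.n_samples} samples"
        )
    lines.append("")
    for report in sorted(
        node.reports,
        key=lambda r: list(recipe_by_id).index(r.recipe_id)
        if r.recipe_id in recipe_by_id
        else len(recipe_by_id),
    ):
        recipe = recipe_by_id.get(report.recipe_id)
        name = recipe.analysis_name if recipe else report.recipe_id
        params = json.dumps(recipe.params, sort_keys=True) if recipe else "{}"
        lines.append(f"## Recipe {report.recipe_id}: {name}")
        lines.append("")
        lines.append(f"Parameters: `{params}`")
        lines.append("")
        lines.append(report.body.rstrip())
        lines.append("")
    return "\n".join(lines) + "\n"
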