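"""File formats: matrix TSV, bicluster JSON interchange, ground-truth JSON
and the metrics CSV.

Matrix TSV: header row of time-point labels (first cell is the row-label
column name), one line per region starting with its label; decimal point,
UTF-8.  Bicluster JSON carries 0-based ascending indices and provenance,
one file per (scan, algorithm) — this is also the import adapter through
which outputs of external biclustering tools enter the evaluation.  All
writers are deterministic and newline-terminated so outputs can be golden-
file tested byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    Bicluster,
    BiclusterSet,
    DataMatrix,
    Provenance,
    materialize_bicluster,
)
from .metrics import MetricsRecord, records_to_frame
from .synthetic import PlantedBicluster

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_bicluster_json",
    "write_bicluster_json",
    "read_ground_truth_json",
    "write_ground_truth_json",
    "write_metrics_csv",
    "read_metrics_csv",
]


def read_matrix(path: str | Path) -> DataMatrix:
    """Parse a Region x Time TSV; errors name the offending line/column."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: need a header and at least 2 data rows")
    header = lines[0].split("\t")
    col_labels = header[1:]
    p = len(col_labels)
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != p + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {p + 1} fields, found {len(cells)}"
            )
        row_labels.append(cells[0])
        parsed = []
        for j, cell in enumerate(cells[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column "
                    f"{col_labels[j]!r}"
                ) from None
        rows.append(parsed)
    if len(row_labels) != len(set(row_labels)):
        raise ValueError(f"{path}: duplicate region labels")
    if len(col_labels) != len(set(col_labels)):
        raise ValueError(f"{path}: duplicate time-point labels")
    return DataMatrix(
        values=np.array(rows, dtype=float),
        row_labels=tuple(row_labels),
        col_labels=tuple(col_labels),
        matrix_id=path.stem,
    )


def write_matrix(matrix: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("region\t" + "\t".join(matrix.col_labels) + "\n")
        for label, row in zip(matrix.row_labels, matrix.values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def write_bicluster_json(bset: BiclusterSet, path: str | Path) -> None:
    """Serialize a per-(scan, algorithm) bicluster set."""
    first = bset.biclusters[0].provenance if len(bset) else Provenance()
    matrix_id = bset.biclusters[0].matrix_id if len(bset) else ""
    doc = {
        "collection": bset.collection_id,
        "matrix_id": matrix_id,
        "algorithm": first.algorithm,
        "run": first.run,
        "biclusters": [
            {"rows": list(b.rows), "cols": list(b.cols)} for b in bset
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_bicluster_json(path: str | Path, matrix: DataMatrix) -> BiclusterSet:
    """Load (and materialize against ``matrix``) a bicluster JSON file.

    Out-of-range or negative indices are rejected at load time, making this
    safe as an import adapter for external tools' outputs.
    """
    path = Path(path)
    doc = json.loads(path.read_text(encoding="utf-8"))
    prov = Provenance(
        algorithm=str(doc.get("algorithm", "")),
        run=int(doc.get("run", 0)),
        scan=str(doc.get("matrix_id", "")) or matrix.matrix_id,
    )
    biclusters = [
        materialize_bicluster(matrix, entry["rows"], entry["cols"], provenance=prov)
        for entry in doc.get("biclusters", [])
    ]
    return BiclusterSet(biclusters, collection_id=str(doc.get("collection", "")))


def write_ground_truth_json(truth: list[PlantedBicluster], path: str | Path) -> None:
    doc = {
        "planted": [
            {
                "rows": list(t.rows),
                "cols": list(t.cols),
                "type": t.pattern_type,
                "row_effects": list(t.row_effects),
                "col_effects": list(t.col_effects),
                "base_level": t.base_level,
            }
            for t in truth
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")


def read_ground_truth_json(path: str | Path, matrix_id: str = "") -> list[PlantedBicluster]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        PlantedBicluster(
            rows=tuple(entry["rows"]),
            cols=tuple(entry["cols"]),
            pattern_type=entry["type"],
            row_effects=tuple(entry.get("row_effects", [])),
            col_effects=tuple(entry.get("col_effects", [])),
            base_level=float(entry.get("base_level", 0.0)),
            matrix_id=matrix_id,
        )
        for entry in doc["planted"]
    ]


def write_metrics_csv(
    records: list[MetricsRecord], path: str | Path, seed: int | None = None
) -> None:
    """Write the per-bicluster metrics table (undefined SMSR as empty field).

    The master seed, when given, is recorded in a comment header so every
    derived table documents its provenance.
    """
    frame = records_to_frame(records)
    with Path(path).open("w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
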