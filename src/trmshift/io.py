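"""Readers and writers for the package's on-disk formats.

Tabular files are TSV (tab-delimited, header row, UTF-8, '.' decimal);
count matrices are Matrix-Market coordinate files (1-based) accompanied by
``genes.tsv`` and ``barcodes.tsv``; gene signatures are GMT (one set per
line: name, description, genes); configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import io as scio
from scipy import sparse

from .annotate import Signature
from .errors import ValidationError
from .permutation import AbundanceReport
from .simulate import COMPARTMENTS, GROUPS, UNASSIGNED, CountMatrix

CELL_COLUMNS = ["cell_id", "group", "compartment", "subset"]
_GROUP_ALIASES = {"WT": "WT", "TG": "TG", "3xTg-AD": "TG", "3xTg": "TG"}


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.loc[:, CELL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell TSV; the TG group may be spelled ``3xTg-AD``."""
    cells = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CELL_COLUMNS if c not in cells.columns and c != "subset"]
    if missing:
        raise ValidationError(f"cell table {path} missing columns {missing}")
    if "subset" not in cells.columns:
        cells["subset"] = UNASSIGNED
    cells["group"] = cells["group"].map(_GROUP_ALIASES)
    if cells["group"].isna().any():
        raise ValidationError(
            f"cell table {path}: group must be one of {sorted(_GROUP_ALIASES)}"
        )
    bad = set(cells["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValidationError(
            f"cell table {path}: unknown compartments {sorted(bad)}"
        )
    if cells["cell_id"].duplicated().any():
        raise ValidationError(f"cell table {path}: duplicate cell ids")
    return cells[CELL_COLUMNS]


def write_count_matrix(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write ``matrix.mtx`` (integer coordinate MTX), genes.tsv, barcodes.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(out_dir / "matrix.mtx", counts.matrix.tocoo(), field="integer")
    (out_dir / "genes.tsv").write_text("".join(g + "\n" for g in counts.genes))
    (out_dir / "barcodes.tsv").write_text("".join(b + "\n" for b in counts.barcodes))


def read_count_matrix(
    mtx: str | Path, genes: str | Path, barcodes: str | Path
) -> CountMatrix:
    matrix = sparse.csr_matrix(scio.mmread(mtx))
    gene_list = Path(genes).read_text().split()
    barcode_list = Path(barcodes).read_text().split()
    if matrix.shape != (len(gene_list), len(barcode_list)):
        raise ValidationError(
            f"matrix {matrix.shape} does not match {len(gene_list)} genes "
            f"x {len(barcode_list)} barcodes"
        )
    if (matrix.data < 0).any():
        raise ValidationError("count matrix has negative entries")
    return CountMatrix(matrix=matrix, genes=gene_list, barcodes=barcode_list)


def read_gmt(path: str | Path) -> list[Signature]:
    signatures = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{path}:{lineno}: GMT lines need name, description and >= 1 gene"
            )
        name, _description, *genes = parts
        genes = [g for g in genes if g]
        signatures.append(Signature(name=name, genes=tuple(genes)))
    if not signatures:
        raise ValidationError(f"no signatures in {path}")
    return signatures


def write_gmt(signatures: Sequence[Signature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.rename_axis("signature").to_csv(path, sep="\t")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: expected a YAML mapping")
    return data


def write_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_report_tsv(report: AbundanceReport, path: str | Path) -> None:
    report.table.to_csv(path, sep="\t", index=False)


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_report_json(report: AbundanceReport, path: str | Path) -> None:
    """JSON report embedding config, per-subset rows and null percentiles."""
    payload = {
        "seed": report.seed,
        "n_perm": report.n_perm,
        "rows": _jsonable(report.table.to_dict(orient="records")),
        "null_summary": _jsonable(report.null_summary.to_dict(orient="records")),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, list):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj
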