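"""Readers, writers and provenance for screen tables.

Well tables travel as CSV with the canonical columns (plate, row, col,
replicate, temperature, amplicon_id, gene, cell_count).  The published
per-well screen table ships as XLSX; its exact column headers are isolated in
a dialect mapping so the loader fails loudly on anything unmapped.  All grid
coordinates are 0-based internally; conventional well names ("A1".."P24") are
accepted and emitted at the I/O boundary.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WELL_COLUMNS = [
    "plate",
    "row",
    "col",
    "replicate",
    "temperature",
    "amplicon_id",
    "gene",
    "cell_count",
]

CANONICAL_REPLICATES = ("17_repl1", "17_repl2", "27_repl1", "27_repl2")

#: Column-name dialect for the supplementary per-well XLSX.  The headers are a
#: best guess pending inspection of the actual file; unmapped required columns
#: make the loader fail with their names.
SUPPLEMENTARY_DIALECT = {
    "plate": "plate",
    "well": "well",
    "replicate": "replicate",
    "gene": "target_gene",
    "cell_count": "number_of_nuclei",
    "bscore": "bscore",
    "p1": "P1",
    "p2": "P2",
    "p3": "P3",
    "p1_to_p2": "P1_to_P2",
    "z_p1": "z_P1",
    "z_p2": "z_P2",
    "z_p3": "z_P3",
    "z_p1_to_p2": "z_P1_to_P2",
}


@dataclass
class ScreenDataset:
    """Normalized per-well screen data with provenance."""

    wells: pd.DataFrame
    provenance: str = "unknown"
    stored_scores: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        dup = self.wells.duplicated(subset=["plate", "row", "col", "replicate"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (plate, row, col, replicate) wells")
        bad = set(self.wells["replicate"].unique()) - set(CANONICAL_REPLICATES)
        if bad:
            raise ValueError(f"non-canonical replicate labels: {sorted(bad)}")


def well_name(row: int, col: int) -> str:
    """0-based (row, col) to conventional name: (0, 0) -> 'A1'."""
    if not (0 <= row < 26):
        raise ValueError(f"row {row} out of range")
    return f"{chr(ord('A') + row)}{col + 1}"


def parse_well_name(name: str) -> tuple[int, int]:
    """Conventional well name to 0-based (row, col): 'P24' -> (15, 23)."""
    name = name.strip().upper()
    if not name or not name[0].isalpha() or not name[1:].isdigit():
        raise ValueError(f"malformed well name {name!r}")
    return ord(name[0]) - ord("A"), int(name[1:]) - 1


def write_well_table(wells: pd.DataFrame, path: str | Path) -> Path:
    """Serialize a well table to CSV, adding the conventional well name."""
    path = Path(path)
    out = wells.copy()
    out.insert(3, "well", [well_name(r, c) for r, c in zip(out["row"], out["col"])])
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def read_well_table(path: str | Path) -> pd.DataFrame:
    """Read a well-table CSV, accepting either 0-based row/col or well names."""
    df = pd.read_csv(path)
    if "row" not in df.columns or "col" not in df.columns:
        if "well" not in df.columns:
            raise ValueError("well table needs either row/col or well columns")
        rc = [parse_well_name(w) for w in df["well"]]
        df["row"] = [r for r, _ in rc]
        df["col"] = [c for _, c in rc]
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing required column(s): {missing}")
    df = df.drop(columns=[c for c in ("well",) if c in df.columns])
    df["gene"] = df["gene"].where(df["gene"].notna(), None)
    return df


def read_supplementary_table(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    expected_wells_per_replicate: int | None = 23040,
) -> ScreenDataset:
    """Ingest the published per-well XLSX into a :class:`ScreenDataset`.

    Stored B-scores and cell-cycle fractions/Z-scores are retained in
    ``stored_scores`` alongside the normalized well table, so recomputed
    values can be cross-checked against them.  Missing required columns, or a
    truncated file when ``expected_wells_per_replicate`` is set, raise rather
    than loading partially.
    """
    dialect = dialect or SUPPLEMENTARY_DIALECT
    raw = pd.read_excel(path)
    required = ["plate", "well", "replicate", "gene", "cell_count"]
    missing = [k for k in required if dialect[k] not in raw.columns]
    if missing:
        raise ValueError(
            "supplementary table missing required column(s): "
            + ", ".join(dialect[k] for k in missing)
        )
    rc = [parse_well_name(w) for w in raw[dialect["well"]]]
    wells = pd.DataFrame(
        {
            "plate": raw[dialect["plate"]].astype(str),
            "row": [r for r, _ in rc],
            "col": [c for _, c in rc],
            "replicate": raw[dialect["replicate"]].astype(str),
            "temperature": [f"{r.split('_')[0]}C" for r in raw[dialect["replicate"]].astype(str)],
            "amplicon_id": raw[dialect.get("amplicon", "amplicon")]
            if dialect.get("amplicon", "amplicon") in raw.columns
            else raw[dialect["gene"]].astype(str),
            "gene": raw[dialect["gene"]],
            "cell_count": raw[dialect["cell_count"]].astype(float),
        }
    )
    if expected_wells_per_replicate is not None:
        counts = wells.groupby("replicate").size()
        short = counts[counts != expected_wells_per_replicate]
        if len(short):
            raise ValueError(
                f"truncated supplementary table; wells per replicate: {counts.to_dict()}"
            )
    stored_cols = {
        k: dialect[k]
        for k in ("bscore", "p1", "p2", "p3", "p1_to_p2", "z_p1", "z_p2", "z_p3", "z_p1_to_p2")
        if dialect.get(k) in raw.columns
    }
    stored = raw[list(stored_cols.values())].rename(
        columns={v: k for k, v in stored_cols.items()}
    ) if stored_cols else None
    return ScreenDataset(wells=wells, provenance=str(path), stored_scores=stored)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write CSV tables plus a JSON run manifest; returns the manifest.

    The manifest records the configuration hash, the seed of any stochastic
    stage, package versions and a checksum per output file, so a rerun with
    the same config and inputs is verifiable as identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config": config or {},
        "config_hash": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True).encode()
        ).hexdigest(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": {},
    }
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        manifest["files"][path.name] = {"sha256": _sha256(path), "n_rows": int(len(table))}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
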