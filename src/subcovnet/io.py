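"""Reading, validating and writing subject tables and result tables."""

from __future__ import annotations

import datetime as _dt
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .nodes import NodeSet, sanitize_label

#: columns every cohort table must carry besides the node volumes
REQUIRED_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education_years",
    "tiv",
)

#: columns that may be absent or contain missing values
OPTIONAL_COLUMNS: tuple[str, ...] = ("followup_outcome", "followup_days", "scanner")


class CohortValidationError(ValueError):
    """Raised with the full list of validation violations."""

    def __init__(self, issues: list[str]):
        self.issues = list(issues)
        super().__init__(
            "cohort table failed validation:\n  - " + "\n  - ".join(self.issues)
        )


def validate_cohort(
    table: pd.DataFrame,
    node_set: NodeSet,
    required: tuple[str, ...] = REQUIRED_COLUMNS,
) -> pd.DataFrame:
    """Validate a cohort table against the schema; collects *all*
    violations before raising.  Returns the table with columns reordered
    to schema order (required, nodes, then the rest)."""
    issues: list[str] = []
    for col in required:
        if col not in table.columns:
            issues.append(f"missing required column {col!r}")
    for node in node_set:
        if node not in table.columns:
            issues.append(f"missing node volume column {node!r}")
    if "subject_id" in table.columns:
        dup = table["subject_id"][table["subject_id"].duplicated()].unique()
        if dup.size:
            issues.append(f"duplicate subject id(s): {list(dup)}")
    for node in node_set:
        if node not in table.columns:
            continue
        col = pd.to_numeric(table[node], errors="coerce")
        bad = table.loc[col.isna(), "subject_id"] if "subject_id" in table else []
        if len(bad):
            issues.append(f"non-numeric volume in {node!r} for subject(s) {list(bad)}")
        neg = table.loc[col.notna() & (col <= 0), "subject_id"] if "subject_id" in table else []
        if len(neg):
            issues.append(f"non-positive volume in {node!r} for subject(s) {list(neg)}")
        missing = col.isna() & table[node].isna()
        if missing.any():
            issues.append(f"missing volume in {node!r} ({int(missing.sum())} subject(s))")
    if issues:
        raise CohortValidationError(issues)
    ordered = [c for c in required if c in table.columns]
    ordered += [n for n in node_set if n not in ordered]
    ordered += [c for c in table.columns if c not in ordered]
    out = table.loc[:, ordered].copy()
    for node in node_set:
        out[node] = pd.to_numeric(out[node])
    return out


def read_cohort(
    path: str | Path,
    node_set: NodeSet,
    required: tuple[str, ...] = REQUIRED_COLUMNS,
) -> pd.DataFrame:
    """Read a comma-separated cohort table (header row, UTF-8, one row
    per subject) and validate it against the schema."""
    table = pd.read_csv(path, encoding="utf-8")
    return validate_cohort(table, node_set, required)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# matrices and result tables
# ---------------------------------------------------------------------------


def write_matrix(matrix: np.ndarray, node_set: NodeSet, path: str | Path) -> None:
    """Square CSV with node names on both axes."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(matrix, index=list(node_set), columns=list(node_set)).to_csv(path)


def write_edge_list(matrix: np.ndarray, node_set: NodeSet, path: str | Path) -> None:
    """Three-column edge list (node_i, node_j, weight) of the upper triangle."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    names = node_set.names
    iu, ju = np.triu_indices(len(names), k=1)
    pd.DataFrame(
        {
            "node_i": [names[i] for i in iu],
            "node_j": [names[j] for j in ju],
            "weight": np.asarray(matrix)[iu, ju],
        }
    ).to_csv(path, index=False)


def _versions() -> dict[str, str]:
    import numpy, scipy, pandas, numba  # noqa: PLC0415

    return {
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "numba": numba.__version__,
    }


def write_report_tables(
    results: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    warnings_log: list[dict] | None = None,
) -> dict:
    """Write one CSV per result table plus a machine-readable run log.

    Table names are sanitized for the filesystem.  Returns the manifest:
    config echo, file list, versions and warnings; also written to
    ``run_log.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, frame in results.items():
        fname = sanitize_label(name) + ".csv"
        frame.to_csv(out / fname, index=False, encoding="utf-8")
        files[name] = fname
    manifest = {
        "written_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "config": config or {},
        "files": files,
        "versions": _versions(),
        "warnings": warnings_log or [],
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["files"]["run_log"] = "run_log.json"
    return manifest
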