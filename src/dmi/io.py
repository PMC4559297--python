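"""Readers and writers for the plain-text formats used by the pipeline.

Expression matrices are tab-delimited (first column gene ids, header row of
sample ids); gene sets use the GMT dialect (set name, description, members,
tab-separated); results and ground-truth tables are TSV; run manifests are
JSON.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_list",
    "read_results",
    "write_results",
    "write_manifest",
    "file_digest",
]


def read_expression_matrix(path) -> pd.DataFrame:
    """Read and validate a genes x samples expression matrix.

    Rejects duplicate gene or sample identifiers and non-numeric cells,
    naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return numeric.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered ``{set name: members}`` mapping.

    Duplicate members within a line are dropped with a warning; a line with
    fewer than 3 fields is a parse error.
    """
    sets: dict[str, list[str]] = {}
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"{path}: empty gene-set file", RuntimeWarning, stacklevel=2)
        return sets
    for lineno, line in enumerate(lines, start=1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and at "
                f"least one member ({len(fields)} fields found)"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        deduped = list(dict.fromkeys(members))
        if len(deduped) < len(members):
            warnings.warn(
                f"{path}:{lineno}: duplicate members in set {name!r} removed",
                RuntimeWarning, stacklevel=2,
            )
        sets[name] = deduped
    return sets


def write_gene_sets(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gene_list(path) -> list[str]:
    """Gene ids from a plain text file (one per line) or the first GMT set."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets = read_gene_sets(path)
        if not sets:
            raise ValueError(f"{path}: no gene sets found")
        return next(iter(sets.values()))
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not genes:
        raise ValueError(f"{path}: no gene identifiers found")
    return list(dict.fromkeys(genes))


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, config: dict, inputs: dict[str, str] | None = None) -> None:
    """Record everything needed to reproduce a run: config echo, seeds,
    input digests, software version and a timestamp."""
    from . import __version__

    manifest = {
        "software": {"name": "dmi", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": {
            name: {"path": str(p), "sha256": file_digest(p)}
            for name, p in (inputs or {}).items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
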