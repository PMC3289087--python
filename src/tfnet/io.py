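"""Readers and writers for the TSV/JSON artifacts of the pipeline.

Conventions: tab-separated everywhere, genes as rows of expression matrices
(microarray convention), '#' comment lines allowed in edge lists.  Tables are
written at 6 significant digits; a JSON sidecar keeps full precision where it
matters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ExpressionMatrix
from .results import NonnegativeFactorResults
from .simulate import SyntheticSystem

__all__ = [
    "read_expression",
    "write_expression",
    "read_edges",
    "write_edges",
    "write_results",
    "write_truth_bundle",
    "read_truth_bundle",
]

_EDGE_HEADERS = {"gene", "tf", "gene_id", "tf_id", "target", "source", "regulator"}


def read_expression(path) -> ExpressionMatrix:
    """Expression TSV: header row of sample labels, first column gene labels."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene label {dup!r}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{path}: duplicate sample labels")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(numeric.at[r, c])
        )
        raise ValueError(f"{path}: non-numeric or missing value at gene {row!r}, sample {col!r}")
    return ExpressionMatrix.from_frame(numeric)


def write_expression(path, expr: ExpressionMatrix) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def read_edges(path) -> set[tuple[str, str]]:
    """Two-column TSV of (gene, tf); optional header, '#' comments, blank lines."""
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    rows: list[tuple[str, str]] = []
    with open(path, newline=None) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns, got {len(fields)}")
            rows.append((fields[0].strip(), fields[1].strip()))
    if rows and rows[0][0].lower() in _EDGE_HEADERS:
        rows = rows[1:]
    edges = set(rows)
    if not edges:
        import warnings

        warnings.warn(f"{path}: empty edge list")
    return edges


def write_edges(path, edges) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttf\n")
        for g, t in sorted(edges):
            fh.write(f"{g}\t{t}\n")


def write_results(outdir, res: NonnegativeFactorResults) -> list[Path]:
    """Write the fit artifacts: edge table, factor matrix, clustering, run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "edges.tsv"
    res.edge_table().to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)

    p = outdir / "factors.tsv"
    res.factor_table().to_csv(p, sep="\t", float_format="%.6g")
    written.append(p)

    p = outdir / "clustering.tsv"
    res.clustering_table().to_csv(p, sep="\t", index=False)
    written.append(p)

    cfg = res.config
    p = outdir / "posterior.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "edge_prob": res.edge_prob.tolist(),
                "A_mean": res.A_mean.tolist(),
                "X_mean": res.X_mean.tolist(),
                "c_est": res.c_est.tolist(),
                "mu_x": res.mu_x.tolist(),
                "mu_y": res.mu_y.tolist(),
                "cofreq": res.cofreq.tolist(),
                "clustering": res.clustering.tolist(),
                "n_samples_used": res.n_samples_used,
                "gene_labels": res.gene_labels,
                "tf_labels": res.tf_labels,
                "sample_labels": res.sample_labels,
            },
            fh,
        )
    written.append(p)

    p = outdir / "runlog.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "seed": getattr(cfg, "seed", None),
                "config": {
                    k: (v if isinstance(v, (int, float, str)) else repr(v))
                    for k, v in (vars(cfg).items() if cfg is not None else [])
                },
                "n_samples_used": res.n_samples_used,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    written.append(p)
    return written


def write_truth_bundle(outdir, system: SyntheticSystem, seed: int | None = None) -> list[Path]:
    """Write a simulated system: expression TSV, database edges TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "expression.tsv"
    write_expression(p, system.Y)
    written.append(p)
    p = outdir / "database_edges.tsv"
    write_edges(p, system.database_edges)
    written.append(p)
    p = outdir / "truth.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "seed": seed,
                "A_true": system.A_true.tolist(),
                "X_true": system.X_true.tolist(),
                "labels_true": system.labels_true.tolist(),
                "c_true": system.c_true.tolist(),
                "noise_var": system.noise_var,
                "true_edges": sorted(map(list, system.true_edges)),
                "database_edges": sorted(map(list, system.database_edges)),
                "gene_labels": system.Y.gene_labels,
                "tf_labels": system.tf_labels,
                "sample_labels": system.Y.sample_labels,
            },
            fh,
        )
    written.append(p)
    return written


def read_truth_bundle(path) -> dict:
    """Load a truth JSON written by :func:`write_truth_bundle`."""
    with open(path) as fh:
        d = json.load(fh)
    for key in ("A_true", "X_true", "c_true"):
        d[key] = np.asarray(d[key], dtype=float)
    d["labels_true"] = np.asarray(d["labels_true"], dtype=int)
    d["true_edges"] = {tuple(e) for e in d["true_edges"]}
    d["database_edges"] = {tuple(e) for e in d["database_edges"]}
    return d
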