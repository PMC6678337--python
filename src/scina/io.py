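"""File I/O: expression matrices, fit results, QC export.

Matrices are genes x cells everywhere.  CSV/TSV carry a header row of
cell IDs and a first column of gene IDs; MatrixMarket (MTX) files need
``genes.tsv`` and ``barcodes.tsv`` sidecars in the same directory (first
column = ID), following the common cell-ranger style layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .em import FitOptions, FitResult, ModelParams
from .matrix import ExpressionMatrix
from .signatures import SignatureSet

__all__ = [
    "read_expression",
    "write_expression",
    "write_results",
    "read_model",
    "qc_export",
]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def read_expression(path, format: str = None) -> ExpressionMatrix:
    """Load a genes x cells matrix from CSV, TSV or MTX (+sidecars).

    No transformation is applied: values are taken as the caller's
    log-scale, normalised expression.  Duplicate IDs are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    format = format or _infer_format(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression file")
        if df.columns.has_duplicates:
            raise ValueError("duplicate cell IDs in expression file")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix.from_dataframe(df)
    if format == "mtx":
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        genes = _read_sidecar(path.parent / "genes.tsv")
        cells = _read_sidecar(path.parent / "barcodes.tsv")
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"MTX shape {m.shape} does not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
        return ExpressionMatrix(gene_ids=genes, cell_ids=cells, values=np.asarray(m, dtype=float))
    raise ValueError(f"unknown expression format {format!r}")


def _read_sidecar(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing MTX sidecar: {path}")
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).to_numpy(dtype=object)
    return ids


def write_expression(expr: ExpressionMatrix, path, format: str = None) -> None:
    """Write CSV/TSV, or MTX with genes.tsv/barcodes.tsv sidecars."""
    path = Path(path)
    format = format or _infer_format(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        expr.to_dataframe().to_csv(path, sep=sep)
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.values))
        pd.Series(list(expr.gene_ids)).to_csv(path.parent / "genes.tsv", sep="\t",
                                              index=False, header=False)
        pd.Series(list(expr.cell_ids)).to_csv(path.parent / "barcodes.tsv", sep="\t",
                                              index=False, header=False)
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

def write_results(result: FitResult, outdir, opts: FitOptions = None) -> dict:
    """Serialise a fit: labels.csv, posterior.csv, model.json, run.log.

    Returns the paths written.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_ids = (
        result.cell_ids
        if result.cell_ids is not None
        else np.asarray([f"cell{i}" for i in range(len(result.labels))], dtype=object)
    )
    labels_path = outdir / "labels.csv"
    pd.DataFrame(
        {
            "cell_id": cell_ids,
            "label": result.labels,
            "max_posterior": result.posterior.max(axis=1),
        }
    ).to_csv(labels_path, index=False)

    post_path = outdir / "posterior.csv"
    pd.DataFrame(result.posterior, index=list(cell_ids), columns=result.class_names).to_csv(
        post_path, index_label="cell_id"
    )

    model_path = outdir / "model.json"
    p = result.params
    model = {
        "package_version": __version__,
        "genes": list(p.genes),
        "class_names": list(p.class_names),
        "mu_high": p.mu_high.tolist(),
        "mu_low": p.mu_low.tolist(),
        "sd_high": p.sd_high.tolist(),
        "sd_low": p.sd_low.tolist(),
        "tau": p.tau.tolist(),
        "loglik_trace": [float(v) for v in result.loglik_trace],
        "converged": bool(result.converged),
        "n_iter": int(result.n_iter),
        "options": vars(opts) if opts is not None else None,
    }
    model_path.write_text(json.dumps(model, indent=2))

    log_path = outdir / "run.log"
    lines = [
        f"cells: {len(result.labels)}",
        f"classes: {', '.join(result.class_names)}",
        f"iterations: {result.n_iter} (converged: {result.converged})",
        f"final log-likelihood: {result.loglik_trace[-1]:.6f}",
        *result.validation.warnings,
    ]
    log_path.write_text("\n".join(lines) + "\n")
    return {"labels": labels_path, "posterior": post_path, "model": model_path, "log": log_path}


def read_model(path) -> ModelParams:
    """Reload the parameters written by :func:`write_results`."""
    model = json.loads(Path(path).read_text())
    return ModelParams(
        genes=model["genes"],
        class_names=model["class_names"],
        mu_high=np.asarray(model["mu_high"]),
        mu_low=np.asarray(model["mu_low"]),
        sd_high=np.asarray(model["sd_high"]),
        sd_low=np.asarray(model["sd_low"]),
        tau=np.asarray(model["tau"]),
    )


# ---------------------------------------------------------------------------
# QC export
# ---------------------------------------------------------------------------

def qc_export(expr: ExpressionMatrix, sigs: SignatureSet, labels):
    """Tidy table + per-gene bimodality summary for heatmap-style QC.

    The tidy table has one row per (signature gene, cell) with the cell's
    assigned class, ordered by class so a heatmap of it shows the block
    structure.  The summary estimates, per signature gene, the separation
    between its two empirical modes — mean difference in pooled-sd units —
    where the "high" cells are those assigned to a type whose signature
    contains the gene.  Genes with (near-)zero overall variance or with
    one empty mode are flagged uninformative.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != expr.n_cells:
        raise ValueError("labels length must equal number of cells")
    genes = [g for g in sigs.all_effective_genes() if g in expr]
    order = np.argsort(labels, kind="stable")

    tidy = []
    for g in genes:
        vals = expr.gene_values(g)[order]
        tidy.append(
            pd.DataFrame(
                {
                    "gene": g,
                    "cell": expr.cell_ids[order],
                    "class": labels[order],
                    "value": vals,
                }
            )
        )
    tidy_df = pd.concat(tidy, ignore_index=True) if tidy else pd.DataFrame(
        columns=["gene", "cell", "class", "value"]
    )

    marking = {g: set() for g in genes}
    for lab in sigs.labels:
        for g in sigs.effective_genes(lab):
            if g in marking:
                marking[g].add(lab)

    rows = []
    for g in genes:
        vals = expr.gene_values(g)
        hi_mask = np.isin(labels, list(marking[g]))
        n_hi = int(hi_mask.sum())
        n_lo = int((~hi_mask).sum())
        overall_sd = float(vals.std())
        if overall_sd < 1e-12 or n_hi == 0 or n_lo == 0:
            rows.append({"gene": g, "mode_separation": 0.0, "n_high": n_hi,
                         "n_low": n_lo, "informative": False})
            continue
        mu_hi, mu_lo = float(vals[hi_mask].mean()), float(vals[~hi_mask].mean())
        pooled = float(np.sqrt((vals[hi_mask].var() + vals[~hi_mask].var()) / 2.0))
        sep = (mu_hi - mu_lo) / max(pooled, 1e-12)
        rows.append({"gene": g, "mode_separation": sep, "n_high": n_hi,
                     "n_low": n_lo, "informative": bool(sep >= 1.0)})
    summary = pd.DataFrame(rows)
    return tidy_df, summary
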