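"""Marker-gene signature sets: parsing, validation and low-marker inversion.

A signature set maps each cell-type label to the genes whose HIGH
expression identifies that type.  A gene whose LOW expression is the
marker (e.g. a surface protein absent from one lineage) is written with a
prefix (default ``low_``) in the input lists; its values are negated into
a pseudo-gene row so that the mixture model can treat it like any other
high-expression marker.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import ExpressionMatrix

__all__ = [
    "SignatureSet",
    "ValidationReport",
    "read_signatures",
    "write_signatures",
    "invert_low_markers",
    "validate_signatures",
]

DEFAULT_LOW_PREFIX = "low_"


@dataclass
class SignatureSet:
    """Ordered mapping of cell-type label -> marker-gene list.

    ``genes_per_label`` holds base gene names (prefix stripped); the
    parallel ``low_flags`` marks low-expression markers.  The *effective*
    name of a low marker -- the name the model and the inverted expression
    matrix use -- is ``low_prefix + gene``.
    """

    genes_per_label: dict
    low_flags: dict = None
    low_prefix: str = DEFAULT_LOW_PREFIX

    def __post_init__(self) -> None:
        if self.low_flags is None:
            self.low_flags = {
                lab: [False] * len(genes) for lab, genes in self.genes_per_label.items()
            }
        labels = list(self.genes_per_label)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate cell-type labels")
        for lab in labels:
            genes = self.genes_per_label[lab]
            flags = self.low_flags[lab]
            if len(genes) == 0:
                raise ValueError(f"signature for label {lab!r} has no genes")
            if len(genes) != len(flags):
                raise ValueError(f"low_flags length mismatch for label {lab!r}")
            eff = self.effective_genes(lab)
            if len(set(eff)) != len(eff):
                raise ValueError(f"duplicate gene within signature {lab!r}")

    @classmethod
    def from_raw_names(cls, raw: dict, low_prefix: str = DEFAULT_LOW_PREFIX) -> "SignatureSet":
        """Build from lists that may contain prefixed names like ``low_CD4``."""
        genes, flags = {}, {}
        for lab, names in raw.items():
            genes[lab] = [n[len(low_prefix):] if n.startswith(low_prefix) else n for n in names]
            flags[lab] = [n.startswith(low_prefix) for n in names]
        return cls(genes_per_label=genes, low_flags=flags, low_prefix=low_prefix)

    # -- views --------------------------------------------------------------
    @property
    def labels(self) -> list:
        return list(self.genes_per_label)

    def __len__(self) -> int:
        return len(self.genes_per_label)

    def effective_genes(self, label: str) -> list:
        """Gene names as the model sees them (low markers prefixed)."""
        return [
            self.low_prefix + g if low else g
            for g, low in zip(self.genes_per_label[label], self.low_flags[label])
        ]

    def raw_names(self, label: str) -> list:
        """Names as written in the input lists (identical to effective names)."""
        return self.effective_genes(label)

    def all_effective_genes(self) -> list:
        """Union of effective genes over all labels, first-seen order."""
        seen, out = set(), []
        for lab in self.labels:
            for g in self.effective_genes(lab):
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def low_marker_bases(self) -> list:
        """Base names of all low-flagged genes, first-seen order, deduplicated."""
        seen, out = set(), []
        for lab in self.labels:
            for g, low in zip(self.genes_per_label[lab], self.low_flags[lab]):
                if low and g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def membership(self, gene_order) -> np.ndarray:
        """Boolean matrix (labels x genes): label k marks effective gene g."""
        idx = {g: i for i, g in enumerate(gene_order)}
        m = np.zeros((len(self), len(gene_order)), dtype=bool)
        for k, lab in enumerate(self.labels):
            for g in self.effective_genes(lab):
                if g in idx:
                    m[k, idx[g]] = True
        return m

    # -- derived sets -------------------------------------------------------
    def subset_labels(self, keep) -> "SignatureSet":
        keep = list(keep)
        return SignatureSet(
            genes_per_label={lab: list(self.genes_per_label[lab]) for lab in keep},
            low_flags={lab: list(self.low_flags[lab]) for lab in keep},
            low_prefix=self.low_prefix,
        )

    def with_genes(self, label: str, genes, flags=None) -> "SignatureSet":
        """Copy with one label's gene list replaced."""
        g = {lab: list(v) for lab, v in self.genes_per_label.items()}
        f = {lab: list(v) for lab, v in self.low_flags.items()}
        g[label] = list(genes)
        f[label] = list(flags) if flags is not None else [False] * len(g[label])
        return SignatureSet(genes_per_label=g, low_flags=f, low_prefix=self.low_prefix)


@dataclass
class ValidationReport:
    """Warnings and removals produced while reconciling signatures with a matrix."""

    warnings: list = field(default_factory=list)
    dropped_genes: dict = field(default_factory=dict)

    def add_drop(self, label: str, gene: str, reason: str) -> None:
        self.warnings.append(f"{label}: dropped {gene!r} ({reason})")
        self.dropped_genes.setdefault(label, []).append(gene)

    @property
    def n_dropped(self) -> int:
        return sum(len(v) for v in self.dropped_genes.values())

    def to_json(self) -> str:
        return json.dumps(
            {"warnings": self.warnings, "dropped_genes": self.dropped_genes}, indent=2
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_signatures(path, format: str = None, low_prefix: str = DEFAULT_LOW_PREFIX) -> SignatureSet:
    """Read a signature set from CSV (one column per label) or GMT.

    CSV columns may be ragged; blank cells are ignored.  GMT is the
    standard tab-separated format: label, description, then genes.
    The format is inferred from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "csv"
    if format == "csv":
        raw = _read_signatures_csv(path)
    elif format == "gmt":
        raw = _read_signatures_gmt(path)
    else:
        raise ValueError(f"unknown signature format {format!r}")
    for lab, genes in raw.items():
        if not genes:
            raise ValueError(f"signature for label {lab!r} is empty")
    return SignatureSet.from_raw_names(raw, low_prefix=low_prefix)


def _read_signatures_csv(path: Path) -> dict:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if not rows:
        raise ValueError(f"empty signature file: {path}")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        raise ValueError("duplicate cell-type labels in signature CSV header")
    raw = {lab: [] for lab in header}
    for row in rows[1:]:
        for lab, cell in zip(header, row):
            cell = cell.strip()
            if cell:
                raw[lab].append(cell)
    return raw


def _read_signatures_gmt(path: Path) -> dict:
    raw = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line!r}")
            lab = fields[0].strip()
            if lab in raw:
                raise ValueError(f"duplicate cell-type label in GMT: {lab!r}")
            raw[lab] = [g.strip() for g in fields[2:] if g.strip()]
    if not raw:
        raise ValueError(f"empty signature file: {path}")
    return raw


def write_signatures(sigs: SignatureSet, path, format: str = None) -> None:
    """Write a signature set as CSV (ragged columns) or GMT."""
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "csv"
    if format == "csv":
        cols = {lab: sigs.raw_names(lab) for lab in sigs.labels}
        depth = max(len(v) for v in cols.values())
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(sigs.labels)
            for i in range(depth):
                w.writerow([cols[lab][i] if i < len(cols[lab]) else "" for lab in sigs.labels])
    elif format == "gmt":
        with open(path, "w") as fh:
            for lab in sigs.labels:
                fh.write("\t".join([lab, "na", *sigs.raw_names(lab)]) + "\n")
    else:
        raise ValueError(f"unknown signature format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def invert_low_markers(expr: ExpressionMatrix, sigs: SignatureSet) -> ExpressionMatrix:
    """Append negated pseudo-gene rows for every low-expression marker.

    A gene X flagged as a low marker gets a new row named
    ``low_prefix + X`` whose per-cell values are ``-X``; the original row
    is untouched.  Signatures already refer to the pseudo-name through
    :meth:`SignatureSet.effective_genes`, so after this call every
    signature reference resolves in the returned matrix.
    """
    bases = sigs.low_marker_bases()
    if not bases:
        return expr.copy()
    missing = [g for g in bases if g not in expr]
    if missing:
        raise ValueError(
            f"low-expression markers absent from the expression matrix: {missing}; "
            "run validate_signatures first to drop them"
        )
    new_names = [sigs.low_prefix + g for g in bases]
    clash = [n for n in new_names if n in expr]
    if clash:
        raise ValueError(f"pseudo-gene names already present in matrix: {clash}")
    new_rows = np.vstack([-expr.gene_values(g) for g in bases])
    return expr.with_rows(new_names, new_rows)


def validate_signatures(
    sigs: SignatureSet, expr: ExpressionMatrix, drop_overlap: bool = False
):
    """Reconcile a signature set with an expression matrix.

    Genes absent from the matrix are dropped with a warning (low markers
    are checked by their base name, since inversion creates the pseudo-row
    later).  With ``drop_overlap``, a gene claimed by more than one label
    is removed from all of them.  A label left empty is a hard error.

    Returns the cleaned :class:`SignatureSet` and a :class:`ValidationReport`.
    """
    report = ValidationReport()
    genes = {lab: list(sigs.genes_per_label[lab]) for lab in sigs.labels}
    flags = {lab: list(sigs.low_flags[lab]) for lab in sigs.labels}

    if drop_overlap:
        counts = {}
        for lab in sigs.labels:
            for eff in set(sigs.effective_genes(lab)):
                counts[eff] = counts.get(eff, 0) + 1
        shared = {g for g, c in counts.items() if c > 1}
    else:
        shared = set()

    for lab in sigs.labels:
        kept_g, kept_f = [], []
        for g, low in zip(genes[lab], flags[lab]):
            eff = sigs.low_prefix + g if low else g
            if eff in shared:
                report.add_drop(lab, eff, "shared between multiple signatures")
                continue
            if g not in expr:
                report.add_drop(lab, eff, "gene not found in expression matrix")
                continue
            kept_g.append(g)
            kept_f.append(low)
        if not kept_g:
            raise ValueError(f"label {lab!r} has no usable signature genes left")
        genes[lab], flags[lab] = kept_g, kept_f

    cleaned = SignatureSet(genes_per_label=genes, low_flags=flags, low_prefix=sigs.low_prefix)
    return cleaned, report
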