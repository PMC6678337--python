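"""Synthetic expression generator with ground truth and noise injections.

The generator emulates the benchmark used to validate marker-driven
cell-type assignment: R cell types get signature lists of uniformly drawn
sizes; cells are allocated to types (plus an "unknown" type carrying no
signature) proportionally to uniformly drawn weights; each signature gene
is bimodal Gaussian -- a high mode (mean ~ U(3,5)) in the cells of the
type(s) it marks and a near-zero low mode (mean ~ U(1e-6, 1e-3))
everywhere else, both with sd ~ U(1e-5, 3).  Unknown cells draw every
gene from its low mode.  Alongside the signature genes the matrix carries
an equal-sized pool of decoy genes simulated entirely from low-mode
parameters; they feed the signature-padding noise injection and are
ignored by the model otherwise.

Four noise injections challenge the prior information: phantom extra
signatures for types that received no cells, removal of true signatures
from the input lists, padding signatures with decoy genes, and dropout
(high-mode draws replaced by low-mode draws).  Every stage draws from its
own child of the master seed, so each injection is reproducible
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import ExpressionMatrix
from .signatures import SignatureSet

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "NoiseSpec",
    "simulate_dataset",
    "noise_extra_signatures",
    "noise_remove_signatures",
    "noise_pad_signatures",
    "noise_dropout",
    "combined_noise",
]

UNKNOWN_LABEL = "unknown"

# child-seed spawn keys, one per stage; fixed so that applying one noise
# method alone or inside a combination consumes identical random streams
_STAGE_STRUCTURE = 0
_STAGE_EXPRESSION = 1
_STAGE_EXTRA = 2
_STAGE_REMOVE = 3
_STAGE_PAD = 4
_STAGE_DROPOUT = 5


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the benchmark's stated conditions: 30 types, signature
    sizes U{2..10}, type weights U(1,50), unknown weight U(5,15), high
    mode mean U(3,5), low mode mean U(1e-6,1e-3), both sds U(1e-5,3).
    n_decoy_genes=None means "as many decoys as signature genes".
    allocation is largest-remainder by default; "multinomial" draws the
    class counts instead.
    """

    r: int = 30
    n_cells: int = 10_000
    sig_size_range: tuple = (2, 10)
    weight_range: tuple = (1.0, 50.0)
    unknown_weight_range: tuple = (5.0, 15.0)
    high_mean_range: tuple = (3.0, 5.0)
    high_sd_range: tuple = (1e-5, 3.0)
    low_mean_range: tuple = (1e-6, 1e-3)
    low_sd_range: tuple = (1e-5, 3.0)
    include_unknown: bool = True
    n_decoy_genes: int | None = None
    allocation: str = "largest_remainder"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.n_cells < self.r:
            raise ValueError("n_cells must be >= r")
        for name in (
            "sig_size_range",
            "weight_range",
            "unknown_weight_range",
            "high_mean_range",
            "high_sd_range",
            "low_mean_range",
            "low_sd_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds must satisfy lower <= upper")
        if self.allocation not in ("largest_remainder", "multinomial"):
            raise ValueError("allocation must be 'largest_remainder' or 'multinomial'")


@dataclass
class SimulationTruth:
    """Ground truth: labels, generating signatures and mode parameters."""

    true_labels: np.ndarray  # per cell, includes "unknown"
    true_signatures: SignatureSet
    gene_mu_high: dict  # gene -> high-mode mean (decoys: low-mode params twice)
    gene_sd_high: dict
    gene_mu_low: dict
    gene_sd_low: dict
    gene_type: dict  # signature gene -> marking label; decoys -> None
    weights: dict  # label -> drawn weight (unknown included)
    counts: dict  # label -> realised cell count
    decoy_genes: list = field(default_factory=list)
    high_mask: np.ndarray = None  # signature-genes x cells: entry drawn from high mode
    removed_labels: list = field(default_factory=list)
    noise_log: dict = field(default_factory=dict)
    n_dropped_out: int = 0


@dataclass
class SimulatedDataset:
    expression: ExpressionMatrix
    signatures: SignatureSet
    truth: SimulationTruth
    config: SimulationConfig


@dataclass
class _Structure:
    """Stage-0 draws: everything decided before cells are realised."""

    labels: list
    sig_genes: dict  # label -> gene names
    gene_order: list  # signature genes in matrix order
    decoy_order: list
    mu_high: np.ndarray
    sd_high: np.ndarray
    mu_low: np.ndarray
    sd_low: np.ndarray
    decoy_mu: np.ndarray
    decoy_sd: np.ndarray
    weights: np.ndarray  # length r (+1 with unknown, last)


def _draw_structure(config: SimulationConfig) -> _Structure:
    rng = _stage_rng(config.seed, _STAGE_STRUCTURE)
    labels = [f"C{i + 1:02d}" for i in range(config.r)]
    lo, hi = config.sig_size_range
    sizes = rng.integers(lo, hi + 1, size=config.r)
    sig_genes = {}
    gene_order = []
    for lab, s in zip(labels, sizes):
        genes = [f"{lab}_g{i + 1}" for i in range(s)]
        sig_genes[lab] = genes
        gene_order.extend(genes)
    g = len(gene_order)
    mu_high = rng.uniform(*config.high_mean_range, size=g)
    sd_high = rng.uniform(*config.high_sd_range, size=g)
    mu_low = rng.uniform(*config.low_mean_range, size=g)
    sd_low = rng.uniform(*config.low_sd_range, size=g)
    n_decoy = g if config.n_decoy_genes is None else config.n_decoy_genes
    decoy_order = [f"noise_g{i + 1}" for i in range(n_decoy)]
    decoy_mu = rng.uniform(*config.low_mean_range, size=n_decoy)
    decoy_sd = rng.uniform(*config.low_sd_range, size=n_decoy)
    weights = rng.uniform(*config.weight_range, size=config.r)
    if config.include_unknown:
        w0 = rng.uniform(*config.unknown_weight_range)
        weights = np.append(weights, w0)
    return _Structure(
        labels=labels,
        sig_genes=sig_genes,
        gene_order=gene_order,
        decoy_order=decoy_order,
        mu_high=mu_high,
        sd_high=sd_high,
        mu_low=mu_low,
        sd_low=sd_low,
        decoy_mu=decoy_mu,
        decoy_sd=decoy_sd,
        weights=weights,
    )


def _allocate(weights: np.ndarray, n: int, method: str, rng: np.random.Generator) -> np.ndarray:
    """Cell counts per class summing exactly to n."""
    total = weights.sum()
    if total <= 0:
        raise ValueError("all class weights are zero")
    p = weights / total
    if method == "multinomial":
        return rng.multinomial(n, p)
    exact = n * p
    counts = np.floor(exact).astype(int)
    short = n - counts.sum()
    # largest fractional remainders get the leftover cells
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def _realize(config: SimulationConfig, struct: _Structure, zero_types=()) -> SimulatedDataset:
    """Stage-1 draws: allocate cells and sample the expression matrix."""
    rng = _stage_rng(config.seed, _STAGE_EXPRESSION)
    class_names = list(struct.labels)
    if config.include_unknown:
        class_names.append(UNKNOWN_LABEL)
    weights = struct.weights.copy()
    for lab in zero_types:
        weights[struct.labels.index(lab)] = 0.0
    counts = _allocate(weights, config.n_cells, config.allocation, rng)
    labels_vec = np.repeat(np.asarray(class_names, dtype=object), counts)
    cell_ids = np.asarray([f"cell{i + 1:05d}" for i in range(config.n_cells)], dtype=object)

    g = len(struct.gene_order)
    n = config.n_cells
    # one standard-normal panel per mode keeps the draw count independent
    # of which cells are high, so zeroing type weights stays reproducible
    z_low = rng.standard_normal((g, n))
    z_high = rng.standard_normal((g, n))
    low = struct.mu_low[:, None] + struct.sd_low[:, None] * z_low
    high = struct.mu_high[:, None] + struct.sd_high[:, None] * z_high

    gene_type = {}
    high_mask = np.zeros((g, n), dtype=bool)
    gi = 0
    for lab in struct.labels:
        in_type = labels_vec == lab
        for _ in struct.sig_genes[lab]:
            gene_type[struct.gene_order[gi]] = lab
            high_mask[gi] = in_type
            gi += 1
    values = np.where(high_mask, high, low)

    n_decoy = len(struct.decoy_order)
    z_decoy = rng.standard_normal((n_decoy, n))
    decoy_vals = struct.decoy_mu[:, None] + struct.decoy_sd[:, None] * z_decoy

    expr = ExpressionMatrix(
        gene_ids=np.asarray(struct.gene_order + struct.decoy_order, dtype=object),
        cell_ids=cell_ids,
        values=np.vstack([values, decoy_vals]),
    )
    sigs = SignatureSet(genes_per_label={lab: list(struct.sig_genes[lab]) for lab in struct.labels})
    w = dict(zip(struct.labels, struct.weights[: config.r]))
    if config.include_unknown:
        w[UNKNOWN_LABEL] = float(struct.weights[-1])
    truth = SimulationTruth(
        true_labels=labels_vec,
        true_signatures=sigs,
        gene_mu_high={**dict(zip(struct.gene_order, struct.mu_high)),
                      **dict(zip(struct.decoy_order, struct.decoy_mu))},
        gene_sd_high={**dict(zip(struct.gene_order, struct.sd_high)),
                      **dict(zip(struct.decoy_order, struct.decoy_sd))},
        gene_mu_low={**dict(zip(struct.gene_order, struct.mu_low)),
                     **dict(zip(struct.decoy_order, struct.decoy_mu))},
        gene_sd_low={**dict(zip(struct.gene_order, struct.sd_low)),
                     **dict(zip(struct.decoy_order, struct.decoy_sd))},
        gene_type={**gene_type, **{d: None for d in struct.decoy_order}},
        weights=w,
        counts=dict(zip(class_names, counts.tolist())),
        decoy_genes=list(struct.decoy_order),
        high_mask=high_mask,
    )
    return SimulatedDataset(expression=expr, signatures=sigs, truth=truth, config=config)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate an expression matrix, its signatures and the ground truth.

    The same seed reproduces bit-identical output.
    """
    return _realize(config, _draw_structure(config))


# ---------------------------------------------------------------------------
# noise injections
# ---------------------------------------------------------------------------

def noise_extra_signatures(ds: SimulatedDataset, n: int) -> SimulatedDataset:
    """Phantom signatures: n types keep their signature but get no cells.

    The expression matrix is regenerated with those type weights zeroed;
    the signature list still contains all R entries, so n of them describe
    cell types absent from the data.
    """
    r = ds.config.r
    if n == 0:
        return ds
    if not 1 <= n <= r - 1:
        raise ValueError(f"n must be in [1, {r - 1}]")
    rng = _stage_rng(ds.config.seed, _STAGE_EXTRA)
    struct = _draw_structure(ds.config)
    phantom = [struct.labels[i] for i in rng.choice(r, size=n, replace=False)]
    out = _realize(ds.config, struct, zero_types=phantom)
    out.truth.noise_log = dict(ds.truth.noise_log)
    out.truth.noise_log["extra_signatures"] = {"n": n, "phantom_labels": phantom}
    return out


def noise_remove_signatures(ds: SimulatedDataset, n: int) -> SimulatedDataset:
    """Hide the signatures of n types from the input lists.

    Cells of those types remain in the matrix; a correct method should
    call them "unknown".  The removed labels are recorded in the truth so
    the scorer can treat unknown as the right answer for them.
    """
    if n == 0:
        return ds
    if not 1 <= n <= len(ds.signatures) - 1:
        raise ValueError(f"n must be in [1, {len(ds.signatures) - 1}]")
    rng = _stage_rng(ds.config.seed, _STAGE_REMOVE)
    labels = ds.signatures.labels
    removed = [labels[i] for i in sorted(rng.choice(len(labels), size=n, replace=False))]
    kept = [lab for lab in labels if lab not in removed]
    truth = replace(
        ds.truth,
        removed_labels=list(ds.truth.removed_labels) + removed,
        noise_log={**ds.truth.noise_log, "remove_signatures": {"n": n, "removed": removed}},
    )
    return SimulatedDataset(
        expression=ds.expression,
        signatures=ds.signatures.subset_labels(kept),
        truth=truth,
        config=ds.config,
    )


def noise_pad_signatures(ds: SimulatedDataset, n: int) -> SimulatedDataset:
    """Double n signatures with decoy genes that are low-mode everywhere."""
    if n == 0:
        return ds
    if not 1 <= n <= len(ds.signatures):
        raise ValueError(f"n must be in [1, {len(ds.signatures)}]")
    rng = _stage_rng(ds.config.seed, _STAGE_PAD)
    labels = ds.signatures.labels
    padded = [labels[i] for i in sorted(rng.choice(len(labels), size=n, replace=False))]
    need = sum(len(ds.signatures.genes_per_label[lab]) for lab in padded)
    pool = list(ds.truth.decoy_genes)
    if need > len(pool):
        raise ValueError(
            f"decoy pool too small: need {need} noise genes, have {len(pool)}"
        )
    picks = rng.choice(len(pool), size=need, replace=False)
    sigs = ds.signatures
    cursor = 0
    for lab in padded:
        genes = list(sigs.genes_per_label[lab])
        k = len(genes)
        extra = [pool[i] for i in picks[cursor : cursor + k]]
        cursor += k
        sigs = sigs.with_genes(lab, genes + extra)
    truth = replace(
        ds.truth,
        noise_log={**ds.truth.noise_log, "pad_signatures": {"n": n, "padded": padded}},
    )
    return SimulatedDataset(expression=ds.expression, signatures=sigs, truth=truth, config=ds.config)


def noise_dropout(ds: SimulatedDataset, n: int) -> SimulatedDataset:
    """Dropout: each high-mode draw is replaced by a fresh low-mode draw
    with probability n x 3.33% (n in 1..10, so up to 33.3%)."""
    if n == 0:
        return ds
    if not 1 <= n <= 10:
        raise ValueError("n must be in [1, 10]")
    p = n * 3.33 / 100.0
    rng = _stage_rng(ds.config.seed, _STAGE_DROPOUT)
    high_mask = ds.truth.high_mask
    g, ncell = high_mask.shape
    hit = (rng.random((g, ncell)) < p) & high_mask
    z = rng.standard_normal((g, ncell))
    sig_genes = [gene for gene in ds.expression.gene_ids[:g]]
    mu = np.asarray([ds.truth.gene_mu_low[gene] for gene in sig_genes])
    sd = np.asarray([ds.truth.gene_sd_low[gene] for gene in sig_genes])
    values = ds.expression.values.copy()
    repl = mu[:, None] + sd[:, None] * z
    values[:g][hit] = repl[hit]
    expr = ExpressionMatrix(ds.expression.gene_ids.copy(), ds.expression.cell_ids.copy(), values)
    truth = replace(
        ds.truth,
        high_mask=high_mask & ~hit,
        n_dropped_out=int(hit.sum()),
        noise_log={
            **ds.truth.noise_log,
            "dropout": {"n": n, "p": p, "n_dropped": int(hit.sum()),
                        "n_high_draws": int(high_mask.sum())},
        },
    )
    return SimulatedDataset(expression=expr, signatures=ds.signatures, truth=truth, config=ds.config)


@dataclass
class NoiseSpec:
    """Per-method noise levels for a combined challenge (0 = off)."""

    extra: int = 0
    remove: int = 0
    pad: int = 0
    dropout: int = 0


def combined_noise(ds: SimulatedDataset, spec: NoiseSpec) -> SimulatedDataset:
    """Apply the four noise methods in their canonical order.

    The proportion of signatures obscured by the list-level methods,
    (extra + remove + pad) / R, must not exceed one half.  Each method
    uses its own child seed, so any single-method spec reproduces that
    method applied alone.
    """
    obscured = (spec.extra + spec.remove + spec.pad) / ds.config.r
    if obscured > 0.5:
        raise ValueError(
            f"obscured signature proportion {obscured:.2f} exceeds the 0.5 bound"
        )
    out = ds
    if spec.extra:
        out = noise_extra_signatures(out, spec.extra)
    if spec.remove:
        out = noise_remove_signatures(out, spec.remove)
    if spec.pad:
        out = noise_pad_signatures(out, spec.pad)
    if spec.dropout:
        out = noise_dropout(out, spec.dropout)
    return out
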