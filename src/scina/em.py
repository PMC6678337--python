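"""EM-fitted bimodal mixture model for semi-supervised cell-type assignment.

Model
-----
Restrict the expression matrix to the union of signature genes.  Each
signature gene g carries a bimodal Gaussian assumption: a high mode
(mu_high_g, sd_high_g) realised in the cell type(s) whose signature
contains g, and a low mode (mu_low_g, sd_low_g) everywhere else.  With R
labelled types plus an optional "unknown" class (low mode on every gene),
the likelihood of cell j under class k is the product over signature
genes of the matching mode density, and the marginal is the tau-weighted
mixture over the R+1 classes.  EM alternates posterior responsibilities
(E) with responsibility-weighted moment updates of the per-gene modes and
the class priors (M).  Genes are conditionally independent given class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .matrix import ExpressionMatrix
from .signatures import SignatureSet, ValidationReport, invert_low_markers, validate_signatures

__all__ = [
    "UNKNOWN_LABEL",
    "FitOptions",
    "ModelParams",
    "FitResult",
    "fit",
    "e_step",
    "m_step",
    "assign",
    "log_likelihood",
]

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "unknown"

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class FitOptions:
    """Knobs for the EM fit.

    conv_tol is a relative parameter-change tolerance; convergence is
    declared after conv_checks consecutive iterations below it.  sd_floor
    bounds every mode standard deviation away from zero (log-expression
    units).  seed is accepted for interface symmetry; the initialisation
    is deterministic and does not consume randomness.
    """

    max_iter: int = 100
    conv_tol: float = 1e-4
    conv_checks: int = 3
    allow_unknown: bool = True
    sd_floor: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.conv_tol <= 0:
            raise ValueError("conv_tol must be positive")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")


@dataclass
class ModelParams:
    """Per-gene bimodal parameters plus class priors.

    genes fixes the gene order of all per-gene arrays; class_names fixes
    the class order of tau (the unknown class, when present, is last).
    """

    genes: list
    class_names: list
    mu_high: np.ndarray
    mu_low: np.ndarray
    sd_high: np.ndarray
    sd_low: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        g = len(self.genes)
        for name in ("mu_high", "mu_low", "sd_high", "sd_low"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if arr.shape != (g,):
                raise ValueError(f"{name} must have one entry per gene")
        self.tau = np.asarray(self.tau, dtype=np.float64)
        if self.tau.shape != (len(self.class_names),):
            raise ValueError("tau must have one entry per class")
        if np.any(self.tau < 0) or not np.isclose(self.tau.sum(), 1.0):
            raise ValueError("tau must be a probability vector")
        if np.any(self.sd_high <= 0) or np.any(self.sd_low <= 0):
            raise ValueError("standard deviations must be positive")

    def flat(self) -> np.ndarray:
        return np.concatenate([self.mu_high, self.mu_low, self.sd_high, self.sd_low, self.tau])


@dataclass
class FitResult:
    params: ModelParams
    posterior: np.ndarray  # cells x classes, rows sum to 1
    labels: np.ndarray  # per-cell assigned class name
    loglik_trace: list
    converged: bool
    n_iter: int
    cell_ids: np.ndarray = None
    validation: ValidationReport = field(default_factory=ValidationReport)

    @property
    def class_names(self) -> list:
        return self.params.class_names


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _normal_logpdf(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x - mu[:, None]) / sd[:, None]
    return -0.5 * z * z - np.log(sd)[:, None] - 0.5 * _LOG_2PI


def _class_loglik(params: ModelParams, x: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Log p(cell | class) for every class; shape (K, N).

    member is the (K x G) boolean signature-membership matrix; the
    unknown class, if present, is an all-False row (low mode everywhere).
    """
    lhigh = _normal_logpdf(x, params.mu_high, params.sd_high)
    llow = _normal_logpdf(x, params.mu_low, params.sd_low)
    base = llow.sum(axis=0)
    return base[None, :] + member.astype(np.float64) @ (lhigh - llow)


def _member_matrix(params: ModelParams, sigs: SignatureSet) -> np.ndarray:
    member = np.zeros((len(params.class_names), len(params.genes)), dtype=bool)
    sig_member = sigs.membership(params.genes)
    lab_index = {lab: i for i, lab in enumerate(sigs.labels)}
    for k, name in enumerate(params.class_names):
        if name == UNKNOWN_LABEL and name not in lab_index:
            continue
        member[k] = sig_member[lab_index[name]]
    return member


def _log_posterior(params: ModelParams, x: np.ndarray, member: np.ndarray):
    cls_ll = _class_loglik(params, x, member)
    with np.errstate(divide="ignore"):
        log_joint = np.log(params.tau)[:, None] + cls_ll
    log_marginal = logsumexp(log_joint, axis=0)
    bad = ~np.isfinite(log_marginal)
    if np.any(bad):
        j = int(np.nonzero(bad)[0][0])
        # most extreme per-gene contribution under the best class is the suspect
        k = int(np.argmax(cls_ll[:, j]))
        contrib = _normal_logpdf(x[:, j : j + 1], params.mu_low, params.sd_low)[:, 0]
        g = params.genes[int(np.argmin(contrib))] if len(params.genes) else "?"
        raise FloatingPointError(
            f"non-finite log-likelihood for cell index {j} "
            f"(best class index {k}, suspect gene {g!r})"
        )
    return log_joint - log_marginal[None, :], float(log_marginal.sum())


def _restrict(expr: ExpressionMatrix, genes) -> np.ndarray:
    missing = [g for g in genes if g not in expr]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    return np.vstack([expr.gene_values(g) for g in genes])


# ---------------------------------------------------------------------------
# public E/M pieces
# ---------------------------------------------------------------------------

def e_step(params: ModelParams, expr: ExpressionMatrix, sigs: SignatureSet) -> np.ndarray:
    """Posterior class probabilities, cells x classes (rows sum to 1).

    Computed in log space with log-sum-exp normalisation.
    """
    x = _restrict(expr, params.genes)
    member = _member_matrix(params, sigs)
    log_post, _ = _log_posterior(params, x, member)
    return np.exp(log_post).T


def log_likelihood(params: ModelParams, expr: ExpressionMatrix, sigs: SignatureSet) -> float:
    """Total log marginal likelihood sum_j log sum_k tau_k prod_g N(x_gj)."""
    x = _restrict(expr, params.genes)
    member = _member_matrix(params, sigs)
    _, ll = _log_posterior(params, x, member)
    return ll


def m_step(
    posterior: np.ndarray,
    expr: ExpressionMatrix,
    sigs: SignatureSet,
    params: ModelParams,
    sd_floor: float = 1e-4,
) -> ModelParams:
    """Responsibility-weighted moment update of mode parameters and priors.

    params supplies the gene/class ordering and the fallback values kept
    when a mode's total responsibility underflows (< 1e-12).  The
    ordering mu_high > mu_low is restored by swapping the two modes of a
    gene when violated.
    """
    posterior = np.asarray(posterior, dtype=np.float64)
    if posterior.shape != (expr.n_cells, len(params.class_names)):
        raise ValueError("posterior shape must be cells x classes")
    if not np.allclose(posterior.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")

    x = _restrict(expr, params.genes)
    member = _member_matrix(params, sigs)
    # responsibility of the high mode of gene g for cell j: total posterior
    # mass on the classes whose signature contains g
    r_high = member.astype(np.float64).T @ posterior.T  # (G, N)
    r_low = 1.0 - r_high

    mu_high, sd_high = _weighted_moments(x, r_high, params.mu_high, params.sd_high, sd_floor)
    mu_low, sd_low = _weighted_moments(x, r_low, params.mu_low, params.sd_low, sd_floor)

    # keep the modes ordered; swap a gene's components if they crossed
    swap = mu_high <= mu_low
    if np.any(swap):
        mu_high[swap], mu_low[swap] = mu_low[swap], mu_high[swap].copy()
        sd_high[swap], sd_low[swap] = sd_low[swap], sd_high[swap].copy()

    tau = posterior.mean(axis=0)
    tau = tau / tau.sum()
    return ModelParams(
        genes=params.genes,
        class_names=params.class_names,
        mu_high=mu_high,
        mu_low=mu_low,
        sd_high=sd_high,
        sd_low=sd_low,
        tau=tau,
    )


def _weighted_moments(x, w, mu_prev, sd_prev, sd_floor):
    tot = w.sum(axis=1)
    ok = tot > 1e-12
    if not np.all(ok):
        logger.warning(
            "mode responsibility underflow for %d gene(s); keeping previous parameters",
            int((~ok).sum()),
        )
    safe_tot = np.where(ok, tot, 1.0)
    mu = np.where(ok, (w * x).sum(axis=1) / safe_tot, mu_prev)
    var = np.where(ok, (w * (x - mu[:, None]) ** 2).sum(axis=1) / safe_tot, sd_prev**2)
    sd = np.sqrt(np.maximum(var, sd_floor**2))
    return mu, sd


def assign(posterior: np.ndarray, class_names, allow_unknown: bool = True) -> np.ndarray:
    """Per-cell label = argmax of the posterior row.

    Ties go to the lowest class index; the unknown class is ordered last,
    so a known class always wins an exact tie with unknown.  With
    allow_unknown off the posterior must not contain an unknown column.
    """
    posterior = np.asarray(posterior, dtype=np.float64)
    class_names = list(class_names)
    if not allow_unknown and UNKNOWN_LABEL in class_names:
        raise ValueError("posterior contains an unknown column but allow_unknown is off")
    if UNKNOWN_LABEL in class_names and class_names[-1] != UNKNOWN_LABEL:
        raise ValueError("the unknown class must be ordered last")
    idx = np.argmax(posterior, axis=1)  # first max -> lowest index wins ties
    names = np.asarray(class_names, dtype=object)
    return names[idx]


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def _initial_params(x, genes, class_names, sd_floor, hi_quantile=0.75):
    """Deterministic, label-free initialisation.

    Cells at or above a gene's hi_quantile seed its high mode, the rest
    the low mode; tau starts uniform.
    """
    q = np.quantile(x, hi_quantile, axis=1)
    hi = x >= q[:, None]
    n_hi = hi.sum(axis=1)
    n_lo = (~hi).sum(axis=1)
    mu_high = np.where(n_hi > 0, (x * hi).sum(axis=1) / np.maximum(n_hi, 1), x.max(axis=1))
    mu_low = np.where(n_lo > 0, (x * ~hi).sum(axis=1) / np.maximum(n_lo, 1), x.min(axis=1))
    var_high = (hi * (x - mu_high[:, None]) ** 2).sum(axis=1) / np.maximum(n_hi, 1)
    var_low = (~hi * (x - mu_low[:, None]) ** 2).sum(axis=1) / np.maximum(n_lo, 1)
    sd_high = np.sqrt(np.maximum(var_high, sd_floor**2))
    sd_low = np.sqrt(np.maximum(var_low, sd_floor**2))
    # degenerate split (all values equal up the quantile): nudge apart
    flat = mu_high <= mu_low
    mu_high[flat] = mu_low[flat] + sd_floor
    tau = np.full(len(class_names), 1.0 / len(class_names))
    return ModelParams(
        genes=genes,
        class_names=class_names,
        mu_high=mu_high,
        mu_low=mu_low,
        sd_high=sd_high,
        sd_low=sd_low,
        tau=tau,
    )


def fit(
    expr: ExpressionMatrix,
    sigs: SignatureSet,
    opts: FitOptions = None,
    validate: bool = True,
) -> FitResult:
    """Fit the mixture by EM and assign every cell a type (or "unknown").

    With ``validate`` (default) the signatures are first reconciled with
    the matrix and low markers inverted into pseudo-genes; pass False when
    the caller has already done both.  Signature genes with zero variance
    across all cells are dropped with a warning before fitting.
    """
    opts = opts or FitOptions()
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells to fit")

    report = ValidationReport()
    if validate:
        sigs, report = validate_signatures(sigs, expr)
        expr = invert_low_markers(expr, sigs)

    genes = sigs.all_effective_genes()
    x_all = _restrict(expr, genes)

    # drop constant genes: a single-point distribution breaks the bimodal fit
    variable = x_all.std(axis=1) > 0
    if not np.all(variable):
        dead = [g for g, v in zip(genes, variable) if not v]
        logger.warning("dropping zero-variance signature gene(s): %s", dead)
        for g in dead:
            report.warnings.append(f"dropped zero-variance signature gene {g!r}")
        genes = [g for g, v in zip(genes, variable) if v]
        if not genes:
            raise ValueError("all signature genes have zero variance; nothing to fit")
        keep_eff = set(genes)
        pruned_g, pruned_f = {}, {}
        for lab in sigs.labels:
            pairs = [
                (g, low)
                for g, low in zip(sigs.genes_per_label[lab], sigs.low_flags[lab])
                if (sigs.low_prefix + g if low else g) in keep_eff
            ]
            if not pairs:
                raise ValueError(f"label {lab!r} lost all genes to zero-variance filtering")
            pruned_g[lab] = [p[0] for p in pairs]
            pruned_f[lab] = [p[1] for p in pairs]
        sigs = SignatureSet(pruned_g, pruned_f, low_prefix=sigs.low_prefix)
        x_all = _restrict(expr, genes)

    class_names = list(sigs.labels)
    if opts.allow_unknown:
        class_names.append(UNKNOWN_LABEL)

    params = _initial_params(x_all, genes, class_names, opts.sd_floor)
    member = _member_matrix(params, sigs)

    trace: list = []
    converged = False
    passes = 0
    n_iter = 0
    for n_iter in range(1, opts.max_iter + 1):
        log_post, ll = _log_posterior(params, x_all, member)
        trace.append(ll)
        posterior = np.exp(log_post).T
        new_params = m_step(posterior, _as_matrix(expr, genes, x_all), sigs, params, opts.sd_floor)
        rel = np.abs(new_params.flat() - params.flat()) / (np.abs(params.flat()) + 1e-12)
        params = new_params
        if rel.max() < opts.conv_tol:
            passes += 1
            if passes >= opts.conv_checks:
                converged = True
                break
        else:
            passes = 0

    log_post, ll = _log_posterior(params, x_all, member)
    trace.append(ll)
    posterior = np.exp(log_post).T
    labels = assign(posterior, class_names, allow_unknown=opts.allow_unknown)
    return FitResult(
        params=params,
        posterior=posterior,
        labels=labels,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
        cell_ids=expr.cell_ids.copy(),
        validation=report,
    )


def _as_matrix(expr: ExpressionMatrix, genes, x: np.ndarray) -> ExpressionMatrix:
    # cheap wrapper so m_step sees a matrix already restricted to the model genes
    em = ExpressionMatrix.__new__(ExpressionMatrix)
    em.gene_ids = np.asarray(genes, dtype=object)
    em.cell_ids = expr.cell_ids
    em.values = x
    em._gene_index = {g: i for i, g in enumerate(genes)}
    return em
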