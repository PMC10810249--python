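"""Cohort merging and parametric empirical-Bayes batch adjustment.

Merging expression matrices from different studies introduces non-biological
location/scale differences per gene (batch effects).  The adjustment here is
the standard parametric empirical-Bayes procedure: per-gene standardization
against a batch-weighted grand mean and pooled variance (with the class
label as an optional covariate so biology is not absorbed into the batch
term), normal/inverse-gamma shrinkage of per-batch location (gamma) and
scale (delta) estimates, then removal of the shrunk batch terms.

A two-component PCA diagnostic mirrors the usual before/after visual check:
pre-adjustment, PC1 separates batches; post-adjustment it should not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gwolfsel.io_prep import ExpressionDataError, ExpressionMatrix


@dataclass
class BatchAdjustment:
    """Audit record of one empirical-Bayes batch adjustment."""

    batches: list
    batch_sizes: list[int]
    grand_mean: np.ndarray          # per gene (incl. covariate offset at baseline)
    pooled_sd: np.ndarray           # per gene
    gamma_star: np.ndarray          # batches x genes, EB-shrunk locations
    delta_star: np.ndarray          # batches x genes, EB-shrunk scales (>0)

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise ValueError("EB scale estimates must be strictly positive")


@dataclass
class PCAResult:
    scores: np.ndarray              # samples x k
    variance_fraction: np.ndarray   # length k, non-increasing, in [0,1]
    sample_ids: list[str] = field(default_factory=list)


def merge_expression(ms: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cohorts on their common genes; batch = source index.

    The gene universe of the merged matrix is the sorted intersection of the
    input gene sets (a union would create missing values the downstream
    fitness oracle cannot represent).
    """
    if len(ms) < 2:
        raise ValueError("merging requires at least two matrices")
    common = set(ms[0].gene_ids)
    for m in ms[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ExpressionDataError("empty gene intersection across inputs")
    genes = sorted(common)

    all_samples: list[str] = []
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    batch: list[np.ndarray] = []
    have_labels = all(m.labels is not None for m in ms)
    for b, m in enumerate(ms):
        order = {g: i for i, g in enumerate(m.gene_ids)}
        idx = [order[g] for g in genes]
        blocks.append(m.values[idx, :])
        all_samples.extend(m.sample_ids)
        if have_labels:
            labels.append(m.labels)
        batch.append(np.full(m.n_samples, b))
    if len(set(all_samples)) != len(all_samples):
        raise ExpressionDataError("sample id collision between inputs")
    return ExpressionMatrix(
        values=np.hstack(blocks),
        gene_ids=genes,
        sample_ids=all_samples,
        labels=np.concatenate(labels) if have_labels else None,
        batch=np.concatenate(batch),
    )


def combat_adjust(
    m: ExpressionMatrix,
    use_labels: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[ExpressionMatrix, BatchAdjustment | None]:
    """Remove per-batch location/scale effects by parametric EB shrinkage.

    ``use_labels`` includes the class label as a covariate in the
    standardization design so class-associated signal survives adjustment
    when batches differ in class composition.  With a single batch the input
    is returned unchanged (nothing to adjust).
    """
    if m.batch is None:
        raise ExpressionDataError("batch labels are required for adjustment")
    batches, batch_idx = np.unique(m.batch, return_inverse=True)
    n_batch = len(batches)
    if n_batch == 1:
        return m.copy(), None
    sizes = np.bincount(batch_idx)
    if np.any(sizes < 2):
        small = batches[sizes < 2]
        raise ExpressionDataError(f"batches with <2 samples: {list(small)}")

    X = m.values                      # genes x samples
    n_genes, n_samples = X.shape

    # design: batch indicators (full rank, no intercept) + optional covariate
    design_cols = [(batch_idx == b).astype(float) for b in range(n_batch)]
    if use_labels and m.labels is not None:
        y = m.labels.astype(float)
        design_cols.append(y - y.mean())   # centered so batch terms absorb the mean
    D = np.column_stack(design_cols)       # samples x p
    DtD = D.T @ D
    if np.linalg.matrix_rank(DtD) < D.shape[1]:
        raise ExpressionDataError("singular standardization design")
    # per-gene OLS: coefficients p x genes
    B = np.linalg.solve(DtD, D.T @ X.T)

    batch_effects = B[:n_batch, :]                       # batches' fitted means
    grand_mean = (sizes / n_samples) @ batch_effects     # per gene
    fitted_full = (D @ B).T                              # genes x samples
    resid = X - fitted_full
    pooled_var = (resid**2).mean(axis=1)                 # per gene, n denominator
    pooled_var = np.maximum(pooled_var, 1e-12)
    pooled_sd = np.sqrt(pooled_var)

    covar_offset = np.zeros_like(X)
    if D.shape[1] > n_batch:
        covar_offset = (D[:, n_batch:] @ B[n_batch:, :]).T

    # standardized data: remove grand mean and covariate effect, unit scale
    Z = (X - grand_mean[:, None] - covar_offset) / pooled_sd[:, None]

    gamma_hat = np.empty((n_batch, n_genes))
    delta_hat = np.empty((n_batch, n_genes))
    for b in range(n_batch):
        Zb = Z[:, batch_idx == b]
        gamma_hat[b] = Zb.mean(axis=1)
        delta_hat[b] = Zb.var(axis=1, ddof=1)
    delta_hat = np.maximum(delta_hat, 1e-12)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(n_batch):
        gamma_star[b], delta_star[b] = _eb_shrink(
            Z[:, batch_idx == b], gamma_hat[b], delta_hat[b], max_iter, tol
        )

    # adjust: remove shrunk batch location, rescale, restore gene scale/mean
    Z_adj = Z.copy()
    for b in range(n_batch):
        cols = batch_idx == b
        Z_adj[:, cols] = (Z[:, cols] - gamma_star[b][:, None]) / np.sqrt(
            delta_star[b][:, None]
        )
    X_adj = Z_adj * pooled_sd[:, None] + grand_mean[:, None] + covar_offset

    adjusted = ExpressionMatrix(
        values=X_adj,
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        labels=None if m.labels is None else m.labels.copy(),
        batch=m.batch.copy(),
    )
    record = BatchAdjustment(
        batches=list(batches),
        batch_sizes=[int(s) for s in sizes],
        grand_mean=grand_mean,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta_star=delta_star,
    )
    return adjusted, record


def _eb_shrink(
    Zb: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normal / inverse-gamma shrinkage of per-gene batch moments.

    Hyperpriors are fit by the method of moments across genes; the joint
    posterior modes are found by the usual fixed-point iteration.
    """
    n_b = Zb.shape[1]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    d_mean = delta_hat.mean()
    d_var = delta_hat.var(ddof=1)
    if d_var <= 0 or tau2 <= 0:   # degenerate spread: keep raw moments
        return gamma_hat.copy(), delta_hat.copy()
    a_prior = (2 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * tau2 * gamma_hat + delta * gamma_bar) / (
            n_b * tau2 + delta
        )
        sq = ((Zb - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * sq + b_prior) / (n_b / 2 + a_prior - 1)
        change = max(
            np.abs(gamma_new - gamma).max(), np.abs(delta_new - delta).max()
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, np.maximum(delta, 1e-12)


def pca_scores(m: ExpressionMatrix, k: int = 2) -> PCAResult:
    """Scores of the (gene-centered) samples on the top-k principal axes."""
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds sample count {m.n_samples}")
    # samples are observations, genes are variables
    A = m.values.T - m.values.mean(axis=1)
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    total = float((s**2).sum())
    frac = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = U[:, :k] * s[:k]
    return PCAResult(
        scores=scores, variance_fraction=frac, sample_ids=list(m.sample_ids)
    )
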