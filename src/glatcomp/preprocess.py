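"""Pre-analysis processing: quantile normalisation, chip-batch adjustment,
technical-replicate merging and PCA-based outlier screening.

All stages preserve probe/sample identifiers and operate on log2 intensities.
The batch adjustment protects treatment-associated differences by supplying
the treatment label as a covariate; chip batch is the batch variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ExpressionMatrix, SampleMetadata, Treatment, validate_pairing

__all__ = [
    "quantile_normalize",
    "adjust_batch",
    "merge_technical_replicates",
    "pca_outlier_check",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    After normalisation each column's sorted values equal the across-column
    mean of order statistics.  Tied values receive the mean of the implicated
    order-statistic means (average-rank convention).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation requires at least 2 samples")
    X = matrix.values
    ref = np.sort(X, axis=0).mean(axis=1)
    cref = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        rmin = rankdata(col, method="min").astype(np.intp)
        rmax = rankdata(col, method="max").astype(np.intp)
        out[:, j] = (cref[rmax] - cref[rmin - 1]) / (rmax - rmin + 1)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )


def _recenter_to(original: np.ndarray, adjusted: np.ndarray) -> np.ndarray:
    """Restore each probe's grand mean after a location/scale adjustment."""
    shift = original.mean(axis=1, keepdims=True) - adjusted.mean(axis=1, keepdims=True)
    return adjusted + shift


def _combat(matrix: ExpressionMatrix, meta: SampleMetadata) -> np.ndarray:
    # parametric empirical-Bayes location/scale adjustment via scanpy,
    # treatment supplied as protected covariate
    import anndata
    import scanpy as sc

    obs = pd.DataFrame(index=pd.Index(matrix.sample_ids, name="sample"))
    obs["chip_batch"] = pd.Categorical(
        [str(meta.table.loc[s, "chip_batch"]) for s in matrix.sample_ids]
    )
    treats = np.array(
        [meta.table.loc[s, "treatment"].value for s in matrix.sample_ids]
    )
    # reference-coded numeric dummies keep the batch+covariate design full rank
    covs = []
    for level in sorted(set(treats))[1:]:
        col = f"treat_{level}"
        obs[col] = (treats == level).astype(float)
        covs.append(col)
    adata = anndata.AnnData(X=matrix.values.T.copy(), obs=obs)
    covs = covs or None
    import warnings

    with warnings.catch_warnings():
        # the EB iteration's convergence ratio can hit 0/0 harmlessly
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        sc.pp.combat(adata, key="chip_batch", covariates=covs, inplace=True)
    return np.asarray(adata.X, dtype=float).T


def _simple_batch_adjust(matrix: ExpressionMatrix, meta: SampleMetadata) -> np.ndarray:
    # per-batch mean-centering of treatment-adjusted residuals
    X = matrix.values.copy()
    treatments = np.array(
        [meta.table.loc[s, "treatment"].value for s in matrix.sample_ids]
    )
    batches = np.array([str(meta.table.loc[s, "chip_batch"]) for s in matrix.sample_ids])
    fitted = np.zeros_like(X)
    for t in np.unique(treatments):
        cols = treatments == t
        fitted[:, cols] = X[:, cols].mean(axis=1, keepdims=True)
    resid = X - fitted
    for b in np.unique(batches):
        cols = batches == b
        resid[:, cols] -= resid[:, cols].mean(axis=1, keepdims=True)
    return fitted + resid


def adjust_batch(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    method: str = "combat",
) -> ExpressionMatrix:
    """Remove additive/multiplicative chip-batch effects.

    method='combat' uses a parametric empirical-Bayes location/scale model
    with treatment as protected covariate; 'simple' mean-centres
    treatment-adjusted residuals per batch; 'none' passes through.  Each
    probe's grand mean is preserved exactly.  A batch with a single sample is
    an error (merge it or exclude the sample first).
    """
    if method == "none":
        return ExpressionMatrix(matrix.data.copy())
    validate_pairing(matrix, meta)
    batches = pd.Series(
        [str(meta.table.loc[s, "chip_batch"]) for s in matrix.sample_ids]
    )
    counts = batches.value_counts()
    singletons = sorted(counts.index[counts < 2])
    if singletons:
        raise ValueError(
            f"chip batch(es) with a single sample: {singletons}; merge these "
            "batches or exclude the samples before adjustment"
        )
    if counts.size == 1:
        return ExpressionMatrix(matrix.data.copy())
    if method == "combat":
        adjusted = _combat(matrix, meta)
    elif method == "simple":
        adjusted = _simple_batch_adjust(matrix, meta)
    else:
        raise ValueError(f"unknown batch adjustment method {method!r}")
    adjusted = _recenter_to(matrix.values, adjusted)
    return ExpressionMatrix(
        pd.DataFrame(adjusted, index=matrix.data.index, columns=matrix.data.columns)
    )


def merge_technical_replicates(
    matrix: ExpressionMatrix, meta: SampleMetadata
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Average technical replicates into one column per replicate group.

    The merged column is the arithmetic mean of member columns and takes the
    replicate-group label as its sample ID.  Members of a group must agree on
    treatment (and product batch); chip batches may differ across technical
    replicates and are concatenated with '+'.
    """
    validate_pairing(matrix, meta)
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for s in matrix.sample_ids:
        g = str(meta.table.loc[s, "replicate_group"])
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(s)

    cols = {}
    rows = []
    for g in order:
        members = groups[g]
        tr = {meta.table.loc[s, "treatment"] for s in members}
        if len(tr) > 1:
            raise ValueError(
                f"replicate group {g!r} spans multiple treatments: "
                f"{sorted(t.value for t in tr)}"
            )
        cols[g] = matrix.data[members].mean(axis=1)
        chip = "+".join(
            sorted({str(meta.table.loc[s, "chip_batch"]) for s in members})
        )
        rows.append(
            {
                "sample_id": g,
                "treatment": next(iter(tr)),
                "chip_batch": chip,
                "product_batch": str(meta.table.loc[members[0], "product_batch"]),
                "replicate_group": g,
            }
        )
    merged = ExpressionMatrix(pd.DataFrame(cols, index=matrix.data.index))
    merged_meta = SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
    return merged, merged_meta


def pca_outlier_check(
    matrix: ExpressionMatrix, k_sd: float = 4.0
) -> pd.DataFrame:
    """Flag samples far from the centroid in PC1/PC2 space.

    Samples are projected onto the first two principal components of the
    per-probe-centred data (centering only, no scaling).  Each PC score is
    standardised by a robust SD (1.4826·MAD, so an extreme sample cannot
    mask itself by inflating the scale); a sample whose Euclidean distance
    from the centroid exceeds ``k_sd`` in these units is flagged.  Flagged
    samples are reported, never auto-removed.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA outlier check requires at least 3 samples")
    from sklearn.decomposition import PCA

    X = matrix.values.T  # samples × probes
    Xc = X - X.mean(axis=0, keepdims=True)
    n_comp = min(2, Xc.shape[0] - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    import warnings

    with warnings.catch_warnings():
        # all-identical samples make explained-variance ratios 0/0
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        scores = pca.fit_transform(Xc)
    if n_comp < 2:
        scores = np.column_stack([scores, np.zeros(len(scores))])
    center = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - center), axis=0)
    sds = np.where(mad > 0, 1.4826 * mad, scores.std(axis=0, ddof=1))
    z = np.divide(
        scores - center, sds, out=np.zeros_like(scores), where=sds > 0
    )
    dist = np.sqrt((z**2).sum(axis=1))
    return pd.DataFrame(
        {
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
            "distance_sd": dist,
            "outlier": dist > k_sd,
        },
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
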