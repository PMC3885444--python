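"""Differential expression by five procedures and their consensus.

Per probe: one-way ANOVA, a moderated-t linear-model fit (empirical-Bayes
variance shrinkage), an ordinary two-sample t-test, a signal-to-noise-ratio
(SNR) marker statistic with label-permutation significance, and the Wilcoxon
rank-sum test.  All p-values are Benjamini–Hochberg adjusted; a probe enters
the consensus set only if all four parametric tests are significant at the
adjusted threshold with a consistent effect direction.  Wilcoxon-only sets
are reported separately (they feed the functional-enrichment stage).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .core import ExpressionMatrix, SampleMetadata, Treatment

__all__ = [
    "bh_adjust",
    "anova_per_probe",
    "ModeratedFitResult",
    "moderated_linear_fit",
    "snr_scores",
    "snr_test",
    "two_sample_t",
    "wilcoxon_rank_sum",
    "build_differential_table",
    "consensus_significant",
    "fold_change_ranking",
    "DOUBLE_DIFFERENCE_CONTRAST",
    "CONVENTIONAL_CONTRAST",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Monotone-enforced, capped at 1; input order preserved.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _groups_values(
    matrix: ExpressionMatrix, meta: SampleMetadata, groups: list[Treatment]
) -> list[np.ndarray]:
    out = []
    for g in groups:
        ids = [s for s in meta.samples_with(g) if s in matrix.data.columns]
        if len(ids) < 2:
            raise ValueError(f"group {g.value} has fewer than 2 samples")
        out.append(matrix.data[ids].to_numpy())
    return out


def anova_per_probe(
    matrix: ExpressionMatrix, meta: SampleMetadata, groups: list[Treatment]
) -> pd.Series:
    """One-way fixed-effects ANOVA p-value per probe across treatment groups."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    arrays = _groups_values(matrix, meta, groups)
    res = stats.f_oneway(*arrays, axis=1)
    return pd.Series(res.pvalue, index=pd.Index(matrix.probe_ids, name="probe_id"))


# ----------------------------------------------------------------------------
# moderated linear model (empirical-Bayes variance shrinkage)
# ----------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_scaled_inv_chisq(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the variance prior on log residual variances.

    Models s²_g | σ²_g ~ σ²_g χ²_d/d with σ²_g from a scaled inverse
    chi-square prior (d₀, s₀²); returns (d₀, s₀²).  d₀ = inf means the
    observed log-variances are no more dispersed than sampling alone
    explains (complete shrinkage is appropriate).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(pos)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_2


@dataclass
class ModeratedFitResult:
    """Per-probe moderated contrast fit."""

    effect: pd.Series
    t: pd.Series
    p: pd.Series
    prior_df: float
    prior_var: float
    residual_df: float


def _aliased_columns(design: np.ndarray) -> list[int]:
    aliased = []
    rank = 0
    for j in range(design.shape[1]):
        r = np.linalg.matrix_rank(design[:, : j + 1])
        if r == rank:
            aliased.append(j)
        rank = r
    return aliased


def moderated_linear_fit(
    matrix: ExpressionMatrix,
    design: np.ndarray,
    contrast: np.ndarray,
    prior_df: float | None = None,
) -> ModeratedFitResult:
    """Per-probe least squares with empirical-Bayes variance moderation.

    Residual variances are shrunk toward a common prior
    s̃² = (d₀·s₀² + d_g·s²_g)/(d₀ + d_g), with the prior df d₀ and prior
    variance s₀² estimated by method of moments on the log residual
    variances (pass ``prior_df`` to override: 0 recovers the ordinary
    per-probe t-test, inf uses the common s₀² everywhere).  The moderated
    t = contrast estimate / (s̃·√(cᵀ(XᵀX)⁻¹c)) is referred to a
    t-distribution with d₀ + d_g degrees of freedom.
    """
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, k = X.shape
    if c.shape != (k,):
        raise ValueError(f"contrast length {c.size} != {k} design columns")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError(
            f"design matrix is rank deficient; aliased column(s): "
            f"{_aliased_columns(X)}"
        )
    d_res = n - k
    if d_res < 1:
        raise ValueError("no residual degrees of freedom")
    Y = matrix.values  # probes × samples
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv  # probes × k
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / d_res
    unscaled = float(c @ xtx_inv @ c)
    effect = beta @ c

    if prior_df is None:
        d0, s0_2 = _fit_scaled_inv_chisq(s2, d_res)
    else:
        d0 = float(prior_df)
        _, s0_2 = _fit_scaled_inv_chisq(s2, d_res)
        if d0 == 0.0:
            s0_2 = float(np.nan)
    if d0 == 0.0:
        s2_post = s2
        df_total = float(d_res)
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d_res * s2) / (d0 + d_res)
        df_total = d0 + d_res
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(s2_post * unscaled)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    idx = pd.Index(matrix.probe_ids, name="probe_id")
    return ModeratedFitResult(
        effect=pd.Series(effect, index=idx),
        t=pd.Series(t, index=idx),
        p=pd.Series(p, index=idx),
        prior_df=d0,
        prior_var=s0_2,
        residual_df=float(d_res),
    )


#: double-difference contrast on (GA, generic, medium) group-mean
#: coefficients: (GA − generic) − (generic − medium) = GA − 2·generic + medium.
#: An unusual weighting (the generic enters twice) retained as the default
#: for fidelity to the original analysis this pipeline reproduces.
DOUBLE_DIFFERENCE_CONTRAST = np.array([1.0, -2.0, 1.0])
#: the conventional alternative: (GA − medium) − (generic − medium)
CONVENTIONAL_CONTRAST = np.array([1.0, -1.0, 0.0])


def design_for_groups(
    matrix: ExpressionMatrix, meta: SampleMetadata, groups: list[Treatment]
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Cell-means design (one indicator column per group), matrix restricted
    to those groups' samples in group order."""
    ids: list[str] = []
    cols: list[np.ndarray] = []
    for g in groups:
        g_ids = [s for s in meta.samples_with(g) if s in matrix.data.columns]
        if not g_ids:
            raise ValueError(f"no samples for group {g.value}")
        ids.extend(g_ids)
    X = np.zeros((len(ids), len(groups)))
    pos = 0
    for j, g in enumerate(groups):
        g_ids = [s for s in meta.samples_with(g) if s in matrix.data.columns]
        X[pos : pos + len(g_ids), j] = 1.0
        pos += len(g_ids)
    return matrix.subset_samples(ids), X


# ----------------------------------------------------------------------------
# SNR marker statistic with permutation significance
# ----------------------------------------------------------------------------


def _floored_sd(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    floor = np.maximum(0.2 * np.abs(mu), 0.2)
    return mu, np.maximum(sd, floor)


def snr_scores(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Signal-to-noise score (μ_A − μ_B)/(σ_A + σ_B) with sd flooring.

    Each class sd is floored at max(0.2·|μ|, 0.2) — the marker-selection
    convention that keeps near-constant probes from exploding the score.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    mu_a, sd_a = _floored_sd(a)
    mu_b, sd_b = _floored_sd(b)
    return (mu_a - mu_b) / (sd_a + sd_b)


def snr_test(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    class_a: Treatment,
    class_b: Treatment,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """SNR score per probe with two-sided class-label permutation p.

    Permutations re-assign class labels within the pooled samples; when the
    number of distinct label splits is ≤ 10,000 the test enumerates all of
    them exactly, otherwise it samples ``n_perm`` splits with the seeded RNG
    and applies add-one smoothing p = (b + 1)/(n_perm + 1).
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse",
                      stacklevel=2)
    a_vals, b_vals = _groups_values(matrix, meta, [class_a, class_b])
    n_a = a_vals.shape[1]
    combined = np.hstack([a_vals, b_vals])
    n_tot = combined.shape[1]
    obs = snr_scores(a_vals, b_vals)
    n_splits = math.comb(n_tot, n_a)
    if n_splits <= 10_000:
        exceed = np.zeros(len(obs), dtype=int)
        total = 0
        for idx_a in itertools.combinations(range(n_tot), n_a):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(idx_a)] = True
            perm = snr_scores(combined[:, mask], combined[:, ~mask])
            exceed += np.abs(perm) >= np.abs(obs) - 1e-12
            total += 1
        p = exceed / total
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(obs), dtype=int)
        for _ in range(n_perm):
            order = rng.permutation(n_tot)
            perm = snr_scores(
                combined[:, order[:n_a]], combined[:, order[n_a:]]
            )
            exceed += np.abs(perm) >= np.abs(obs) - 1e-12
        p = (exceed + 1) / (n_perm + 1)
    idx = pd.Index(matrix.probe_ids, name="probe_id")
    return pd.DataFrame({"snr_score": obs, "snr_p": p}, index=idx)


def two_sample_t(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    class_a: Treatment,
    class_b: Treatment,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per probe (Welch by default)."""
    a_vals, b_vals = _groups_values(matrix, meta, [class_a, class_b])
    res = stats.ttest_ind(a_vals, b_vals, axis=1, equal_var=equal_var)
    idx = pd.Index(matrix.probe_ids, name="probe_id")
    return pd.DataFrame({"t": res.statistic, "t_p": res.pvalue}, index=idx)


def wilcoxon_rank_sum(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    class_a: Treatment,
    class_b: Treatment,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test per probe.

    Exact null distribution when the combined sample size is ≤ 20 and the
    probe has no ties; normal approximation with continuity correction
    otherwise.
    """
    a_vals, b_vals = _groups_values(matrix, meta, [class_a, class_b])
    n_tot = a_vals.shape[1] + b_vals.shape[1]
    combined = np.hstack([a_vals, b_vals])
    has_ties = np.array(
        [len(np.unique(row)) < n_tot for row in combined]
    )
    W = np.empty(len(combined))
    p = np.empty(len(combined))
    if n_tot <= 20 and not has_ties.all():
        ok = ~has_ties
        if ok.any():
            res = stats.mannwhitneyu(
                a_vals[ok], b_vals[ok], axis=1, alternative="two-sided",
                method="exact",
            )
            W[ok], p[ok] = res.statistic, res.pvalue
        if has_ties.any():
            res = stats.mannwhitneyu(
                a_vals[has_ties], b_vals[has_ties], axis=1,
                alternative="two-sided", method="asymptotic",
            )
            W[has_ties], p[has_ties] = res.statistic, res.pvalue
    else:
        res = stats.mannwhitneyu(
            a_vals, b_vals, axis=1, alternative="two-sided", method="asymptotic"
        )
        W, p = res.statistic, res.pvalue
    idx = pd.Index(matrix.probe_ids, name="probe_id")
    return pd.DataFrame({"wilcoxon_w": W, "wilcoxon_p": p}, index=idx)


# ----------------------------------------------------------------------------
# table assembly, consensus and fold-change ranking
# ----------------------------------------------------------------------------


def build_differential_table(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    class_a: Treatment = Treatment.GA,
    class_b: Treatment = Treatment.GENERIC,
    adjust_for: Treatment = Treatment.MEDIUM,
    contrast: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Assemble the per-probe differential table across all five tests.

    class_a vs class_b (default branded vs generic); the moderated linear
    model additionally adjusts for the vehicle group using the
    double-difference contrast (A − B) − (B − vehicle) by default.
    """
    idx = pd.Index(matrix.probe_ids, name="probe_id")
    a_vals, b_vals = _groups_values(matrix, meta, [class_a, class_b])
    table = pd.DataFrame(index=idx)
    table[f"mean_{class_a.value}"] = a_vals.mean(axis=1)
    table[f"mean_{class_b.value}"] = b_vals.mean(axis=1)
    table["log2_fc"] = table[f"mean_{class_a.value}"] - table[f"mean_{class_b.value}"]

    table["anova_p"] = anova_per_probe(matrix, meta, [class_a, class_b])
    table["anova_q"] = bh_adjust(table["anova_p"].to_numpy())

    sub, X = design_for_groups(matrix, meta, [class_a, class_b, adjust_for])
    c = DOUBLE_DIFFERENCE_CONTRAST if contrast is None else np.asarray(contrast, float)
    fit = moderated_linear_fit(sub, X, c)
    table["limma_effect"] = fit.effect
    table["limma_t"] = fit.t
    table["limma_p"] = fit.p
    table["limma_q"] = bh_adjust(table["limma_p"].to_numpy())

    tt = two_sample_t(matrix, meta, class_a, class_b, equal_var=equal_var)
    table["t"] = tt["t"]
    table["t_p"] = tt["t_p"]
    table["t_q"] = bh_adjust(table["t_p"].to_numpy())

    snr = snr_test(matrix, meta, class_a, class_b, n_perm=n_perm, seed=seed)
    table["snr_score"] = snr["snr_score"]
    table["snr_p"] = snr["snr_p"]
    table["snr_q"] = bh_adjust(table["snr_p"].to_numpy())

    wil = wilcoxon_rank_sum(matrix, meta, class_a, class_b)
    table["wilcoxon_w"] = wil["wilcoxon_w"]
    table["wilcoxon_p"] = wil["wilcoxon_p"]
    table["wilcoxon_q"] = bh_adjust(table["wilcoxon_p"].to_numpy())

    higher_a, higher_b = consensus_significant(table)
    table["consensus_higher_a"] = table.index.isin(higher_a)
    table["consensus_higher_b"] = table.index.isin(higher_b)
    return table


_PARAMETRIC_Q = ("anova_q", "limma_q", "t_q", "snr_q")
_DIRECTION_COLS = ("log2_fc", "limma_effect", "t", "snr_score")


def consensus_significant(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Probes significant in all four parametric tests with agreeing direction.

    Returns (higher in class A, higher in class B).  The ANOVA direction is
    taken from the group-mean fold change; the moderated-model direction from
    its contrast estimate; t and SNR from their signed statistics.
    """
    missing = [c for c in _PARAMETRIC_Q if c not in table.columns]
    if missing:
        raise ValueError(f"table missing parametric q column(s): {missing}")
    sig = np.ones(len(table), dtype=bool)
    for c in _PARAMETRIC_Q:
        sig &= table[c].to_numpy() <= alpha
    signs = np.stack([np.sign(table[c].to_numpy()) for c in _DIRECTION_COLS])
    all_pos = (signs > 0).all(axis=0)
    all_neg = (signs < 0).all(axis=0)
    higher_a = list(table.index[sig & all_pos])
    higher_b = list(table.index[sig & all_neg])
    return higher_a, higher_b


def wilcoxon_significant(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Probes significant by the Wilcoxon test alone, split by direction."""
    sig = table["wilcoxon_q"].to_numpy() <= alpha
    fc = table["log2_fc"].to_numpy()
    return (
        list(table.index[sig & (fc > 0)]),
        list(table.index[sig & (fc < 0)]),
    )


def fold_change_ranking(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    class_a: Treatment,
    class_b: Treatment,
    k: int | None = None,
) -> pd.DataFrame:
    """Probes ranked by |mean(class A) − mean(class B)| descending.

    Signed fold change reported; ties break on probe ID.
    """
    a_vals, b_vals = _groups_values(matrix, meta, [class_a, class_b])
    fc = a_vals.mean(axis=1) - b_vals.mean(axis=1)
    df = pd.DataFrame({"probe_id": matrix.probe_ids, "log2_fc": fc})
    df["abs_fc"] = df["log2_fc"].abs()
    df = df.sort_values(
        ["abs_fc", "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if k is not None:
        df = df.head(k)
    return df.drop(columns="abs_fc")
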