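"""Batch-consistency and variability analysis.

The question this module answers: is the generic product's biological impact
as consistent across manufacturing batches as the branded product's?  Five
complementary views are provided:

* an F-test screen for probes whose variance under drug activation exceeds
  the vehicle (medium) variance — isolating biologically induced variability
  from assay noise ("activation-variable" probes);
* directional F-test counts comparing variability between the generic and
  branded arms on those probes;
* a process-control style tolerance method: per-probe acceptance ranges set
  by the min/max expression of the reference standard, and the percentage of
  product samples falling inside them;
* a per-probe variance-ratio ranking var(generic)/var(branded);
* coefficient-of-variation vs intensity summaries, and a subsampling
  sensitivity analysis equalising group sizes.

All variances are sample variances (denominator n−1), F-tests one-sided
("more variable than") unless requested otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SampleMetadata, Treatment, validate_pairing
from .preprocess import merge_technical_replicates

__all__ = [
    "VarianceTestResult",
    "GroupVariabilityCounts",
    "ToleranceResult",
    "variance_f_test",
    "activation_variable_probes",
    "compare_group_variability",
    "select_tolerance_probes",
    "tolerance_ranges",
    "tolerance_percentages",
    "count_failing",
    "variance_ratio_ranking",
    "coefficient_of_variation",
    "paired_difference_test",
    "subsample_sensitivity",
]


@dataclass(frozen=True)
class VarianceTestResult:
    """Two-sample variance comparison: F = s²_x / s²_y."""

    f: float
    dfn: int
    dfd: int
    p: float
    direction: str  # 'x' if x more variable, 'y' otherwise
    degenerate: bool = False


def variance_f_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "greater"
) -> VarianceTestResult:
    """F-test of var(x) vs var(y).

    ``alternative='greater'`` tests var(x) > var(y); ``'two_sided'`` doubles
    the smaller tail.  Zero variance in the denominator makes F undefined:
    p = 1 if x is also constant, else p = 0, both flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("variance_f_test needs at least 2 observations per group")
    if alternative not in {"greater", "two_sided"}:
        raise ValueError(f"invalid alternative {alternative!r}")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    dfn, dfd = x.size - 1, y.size - 1
    direction = "x" if vx >= vy else "y"
    if vy == 0.0:
        if vx == 0.0:
            return VarianceTestResult(np.nan, dfn, dfd, 1.0, direction, True)
        return VarianceTestResult(np.inf, dfn, dfd, 0.0, "x", True)
    f = vx / vy
    if alternative == "greater":
        p = float(stats.f.sf(f, dfn, dfd))
    else:
        tail = min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
        p = float(min(1.0, 2.0 * tail))
    return VarianceTestResult(float(f), dfn, dfd, p, direction)


def _group_values(
    matrix: ExpressionMatrix, meta: SampleMetadata, treatment: Treatment
) -> np.ndarray:
    ids = meta.samples_with(treatment)
    ids = [s for s in ids if s in matrix.data.columns]
    if not ids:
        raise ValueError(f"no samples with treatment {treatment.value} in matrix")
    return matrix.data[ids].to_numpy()


def _f_sf_vector(num: np.ndarray, den: np.ndarray, dfn: int, dfd: int) -> np.ndarray:
    """One-sided p for var(num-group) > var(den-group), elementwise."""
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    p = np.empty_like(f)
    ok = np.isfinite(f)
    p[ok] = stats.f.sf(f[ok], dfn, dfd)
    # den variance 0: p = 1 if num variance 0 too, else 0
    p[~ok] = np.where(num[~ok] == 0.0, 1.0, 0.0)
    return p


def activation_variable_probes(
    matrix: ExpressionMatrix, meta: SampleMetadata, alpha: float = 0.05
) -> list[str]:
    """Probes more variable under activation than under medium.

    Union of two one-sided F-test screens at ``alpha``: var(GA) > var(medium)
    and var(generic) > var(medium).  No multiplicity correction — the screen
    is a raw α-level filter by design.
    """
    validate_pairing(matrix, meta)
    ga = _group_values(matrix, meta, Treatment.GA)
    gen = _group_values(matrix, meta, Treatment.GENERIC)
    med = _group_values(matrix, meta, Treatment.MEDIUM)
    v_ga = ga.var(axis=1, ddof=1)
    v_gen = gen.var(axis=1, ddof=1)
    v_med = med.var(axis=1, ddof=1)
    p_ga = _f_sf_vector(v_ga, v_med, ga.shape[1] - 1, med.shape[1] - 1)
    p_gen = _f_sf_vector(v_gen, v_med, gen.shape[1] - 1, med.shape[1] - 1)
    mask = (p_ga < alpha) | (p_gen < alpha)
    return [p for p, m in zip(matrix.probe_ids, mask) if m]


@dataclass(frozen=True)
class GroupVariabilityCounts:
    n_generic_more_variable: int
    n_ga_more_variable: int

    @property
    def fold(self) -> float:
        if self.n_ga_more_variable == 0:
            return float("inf") if self.n_generic_more_variable else float("nan")
        return self.n_generic_more_variable / self.n_ga_more_variable


def compare_group_variability(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    probes: list[str],
    alpha: float = 0.05,
) -> GroupVariabilityCounts:
    """Count probes significantly more variable in each product arm.

    One-sided F-tests in both directions between the generic and GA groups at
    level ``alpha``, restricted to ``probes`` (typically the
    activation-variable set).
    """
    if not probes:
        raise ValueError("empty probe set")
    sub = matrix.subset_probes(probes)
    ga = _group_values(sub, meta, Treatment.GA)
    gen = _group_values(sub, meta, Treatment.GENERIC)
    v_ga = ga.var(axis=1, ddof=1)
    v_gen = gen.var(axis=1, ddof=1)
    p_gen = _f_sf_vector(v_gen, v_ga, gen.shape[1] - 1, ga.shape[1] - 1)
    p_ga = _f_sf_vector(v_ga, v_gen, ga.shape[1] - 1, gen.shape[1] - 1)
    return GroupVariabilityCounts(
        int((p_gen < alpha).sum()), int((p_ga < alpha).sum())
    )


def select_tolerance_probes(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    n_top: int = 1000,
    expr_floor: float = 6.0,
) -> list[str]:
    """Top probes by |log2 FC| of reference standard vs medium, expression-filtered.

    Probes upregulated by the reference standard must average ≥ ``expr_floor``
    in the reference standard; downregulated probes must average ≥
    ``expr_floor`` in medium.  This keeps the panel both strongly affected and
    well above the noise floor of lowly expressed probes.  Ranking ties break
    on probe ID for reproducibility.
    """
    validate_pairing(matrix, meta)
    rs = _group_values(matrix, meta, Treatment.REFERENCE_STANDARD)
    med = _group_values(matrix, meta, Treatment.MEDIUM)
    mean_rs = rs.mean(axis=1)
    mean_med = med.mean(axis=1)
    fc = mean_rs - mean_med
    up = fc >= 0
    passes = np.where(up, mean_rs >= expr_floor, mean_med >= expr_floor)
    df = pd.DataFrame(
        {"probe_id": matrix.probe_ids, "abs_fc": np.abs(fc)}
    )[passes]
    df = df.sort_values(["abs_fc", "probe_id"], ascending=[False, True])
    if len(df) < n_top:
        import warnings

        warnings.warn(
            f"only {len(df)} probes survive the expression floor; "
            f"returning all of them (requested {n_top})",
            stacklevel=2,
        )
        return df["probe_id"].tolist()
    return df["probe_id"].head(n_top).tolist()


@dataclass
class ToleranceResult:
    """Per-probe reference ranges and within-range percentages for one product.

    ``ranges`` has columns range_low/range_high (log2 intensity, inclusive
    bounds); ``pct_within`` is the percentage of product samples inside the
    range per probe; ``curve`` the same percentages sorted ascending (stable
    probe-ID tie-break) — the tolerance curve plotted against probe rank.
    """

    ranges: pd.DataFrame
    pct_within: pd.Series = field(default=None)  # type: ignore[assignment]
    curve: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    product: str | None = None


def tolerance_ranges(
    matrix: ExpressionMatrix, meta: SampleMetadata, probes: list[str]
) -> ToleranceResult:
    """Min/max expression over reference-standard samples per probe."""
    sub = matrix.subset_probes(probes)
    rs = _group_values(sub, meta, Treatment.REFERENCE_STANDARD)
    if rs.shape[1] < 2:
        raise ValueError("tolerance ranges need at least 2 reference-standard samples")
    ranges = pd.DataFrame(
        {"range_low": rs.min(axis=1), "range_high": rs.max(axis=1)},
        index=pd.Index(probes, name="probe_id"),
    )
    return ToleranceResult(ranges=ranges)


def tolerance_percentages(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    tol: ToleranceResult,
    product: Treatment,
) -> ToleranceResult:
    """Percentage of product samples within the reference range, per probe.

    Bounds are inclusive.  Also attaches the ascending sorted tolerance
    curve over probes.
    """
    probes = list(tol.ranges.index)
    sub = matrix.subset_probes(probes)
    vals = _group_values(sub, meta, product)
    lo = tol.ranges["range_low"].to_numpy()[:, None]
    hi = tol.ranges["range_high"].to_numpy()[:, None]
    inside = (vals >= lo) & (vals <= hi)
    pct = 100.0 * inside.sum(axis=1) / vals.shape[1]
    pct_s = pd.Series(pct, index=tol.ranges.index, name="pct_within")
    curve = (
        pct_s.rename_axis("probe_id")
        .reset_index()
        .sort_values(["pct_within", "probe_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return ToleranceResult(
        ranges=tol.ranges, pct_within=pct_s, curve=curve, product=product.value
    )


def count_failing(tol: ToleranceResult, threshold_pct: float) -> int:
    """Number of probes whose within-range percentage falls below a spec limit."""
    if not 0.0 <= threshold_pct <= 100.0:
        raise ValueError("threshold_pct must be in [0, 100]")
    if tol.pct_within is None:
        raise ValueError("tolerance percentages not computed")
    return int((tol.pct_within < threshold_pct).sum())


def variance_ratio_ranking(
    matrix: ExpressionMatrix, meta: SampleMetadata
) -> pd.DataFrame:
    """Per-probe r = var(generic)/var(GA), ranked descending.

    Zero GA variance yields an +inf sentinel sorted first and flagged.  Ties
    break lexicographically on probe ID.
    """
    ga = _group_values(matrix, meta, Treatment.GA)
    gen = _group_values(matrix, meta, Treatment.GENERIC)
    if ga.shape[1] < 2 or gen.shape[1] < 2:
        raise ValueError("variance ratio needs at least 2 samples per group")
    v_ga = ga.var(axis=1, ddof=1)
    v_gen = gen.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(v_ga > 0, v_gen / v_ga, np.inf)
    df = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "ratio": ratio,
            "degenerate": v_ga == 0.0,
        }
    )
    df = df.sort_values(
        ["ratio", "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def coefficient_of_variation(
    matrix: ExpressionMatrix, meta: SampleMetadata, group: Treatment
) -> pd.DataFrame:
    """Per-probe mean log2 intensity and CV = sd / mean within one group.

    Technical replicates should be merged beforehand so the CV reflects
    biological rather than technical variability.  A non-positive mean makes
    the CV undefined (NaN, flagged).
    """
    vals = _group_values(matrix, meta, group)
    if vals.shape[1] < 2:
        raise ValueError("CV needs at least 2 samples in the group")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"mean_log2": mean, "cv": cv, "undefined": mean <= 0},
        index=pd.Index(matrix.probe_ids, name="probe_id"),
    )


def paired_difference_test(differences: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test on paired differences.

    Returns (t, p, degenerate); all-zero differences make t undefined and
    are reported as p = 1 with the degenerate flag set.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return np.nan, 1.0, True
        return np.inf, 0.0, True
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue), False


def subsample_sensitivity(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    subset_size: int = 11,
    n_repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Equalised-size robustness check of the variability comparison.

    Technical replicates are merged, then ``n_repeats`` times a random subset
    of ``subset_size`` GA samples (without replacement) is compared against
    the full generic group: the activation-variable screen and directional
    F-test counts are recomputed on the subsampled data.  Returns the
    per-repeat count pairs (with the derived substream seed of each repeat)
    and the two-sided paired t-test p-value on the count differences.
    """
    merged, mmeta = merge_technical_replicates(matrix, meta)
    ga_ids = mmeta.samples_with(Treatment.GA)
    if len(ga_ids) < subset_size:
        raise ValueError(
            f"GA group has {len(ga_ids)} merged samples; need ≥ {subset_size}"
        )
    other_ids = [s for s in merged.sample_ids if s not in set(ga_ids)]
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(n_repeats)]
    rows = []
    for rep, sub_seed in enumerate(seeds):
        rng = np.random.default_rng(sub_seed)
        chosen = list(rng.choice(ga_ids, size=subset_size, replace=False))
        keep = other_ids + chosen
        sub_m = merged.subset_samples(keep)
        sub_meta = mmeta.subset(keep)
        act = activation_variable_probes(sub_m, sub_meta, alpha=alpha)
        if act:
            counts = compare_group_variability(sub_m, sub_meta, act, alpha=alpha)
            n_gen, n_ga = counts.n_generic_more_variable, counts.n_ga_more_variable
        else:
            n_gen = n_ga = 0
        rows.append(
            {
                "repeat": rep,
                "substream_seed": sub_seed,
                "n_generic_more_variable": n_gen,
                "n_ga_more_variable": n_ga,
            }
        )
    table = pd.DataFrame(rows)
    diffs = (
        table["n_generic_more_variable"] - table["n_ga_more_variable"]
    ).to_numpy(dtype=float)
    _, p, _ = paired_difference_test(diffs)
    return table, p
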