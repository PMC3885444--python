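"""Gene-set and cell-type enrichment.

Four tools: orthology mapping between species symbol namespaces; weighted
Kolmogorov–Smirnov gene-set enrichment (GSEA) with a permutation null and
the standard NES/FDR machinery; hypergeometric over-representation with a
minimum-overlap rule; and cell-type specificity enrichment against an
ImmGen-like reference compendium.

Specificity of a gene for a cell type is the margin by which its mean
expression in that cell type exceeds its maximum over all other cell types —
positive for exactly the gene's top cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CellTypeReference,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologyMap,
    ProbeAnnotation,
    SampleMetadata,
    Treatment,
)
from .differential import bh_adjust, snr_scores

__all__ = [
    "map_orthologs",
    "rank_genes_snr",
    "gsea_enrichment_score",
    "gsea",
    "gsea_phenotype",
    "hypergeometric_test",
    "enrich_collection",
    "celltype_specificity_scores",
    "celltype_enrichment",
    "EnrichmentRow",
]


def map_orthologs(
    genes: list[str], omap: OrthologyMap, policy: str = "one_to_one"
) -> tuple[list[str], list[str]]:
    """Translate gene symbols through an orthology map.

    Returns (mapped, unmapped).  Under ``one_to_one`` (default) only
    unambiguous pairs are used: a source with several targets, or a target
    claimed by several sources, is dropped.  ``all`` keeps every target of
    each source.  Symbols already in the target namespace pass through
    unchanged, which makes the mapping idempotent.
    """
    if policy not in {"one_to_one", "all"}:
        raise ValueError(f"unknown policy {policy!r}")
    fwd = omap.as_dict()
    target_sources: dict[str, set[str]] = {}
    for s, t in omap.pairs:
        target_sources.setdefault(t.upper(), set()).add(s.upper())
    target_names = {t.upper(): t for _, t in omap.pairs}

    mapped: list[str] = []
    unmapped: list[str] = []
    seen: set[str] = set()

    def emit(symbol: str) -> None:
        key = symbol.upper()
        if key not in seen:
            seen.add(key)
            mapped.append(symbol)

    for g in genes:
        key = g.upper()
        if key in fwd:
            targets = fwd[key]
            if policy == "one_to_one":
                if len(targets) == 1 and len(target_sources[targets[0].upper()]) == 1:
                    emit(targets[0])
                else:
                    unmapped.append(g)
            else:
                for t in targets:
                    emit(t)
        elif key in target_names:
            emit(target_names[key])
        else:
            unmapped.append(g)
    return mapped, unmapped


def rank_genes_snr(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    annotation: ProbeAnnotation,
    class_a: Treatment,
    class_b: Treatment,
) -> pd.Series:
    """Gene-level ranking scores: per-probe SNR collapsed by max-|score|.

    Probes without annotation are dropped; for genes with several probes the
    probe with the largest |SNR| represents the gene.  Sorted descending —
    positive scores mean higher expression in ``class_a``.
    """
    ids_a = [s for s in meta.samples_with(class_a) if s in matrix.data.columns]
    ids_b = [s for s in meta.samples_with(class_b) if s in matrix.data.columns]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both classes need at least 2 samples")
    scores = snr_scores(
        matrix.data[ids_a].to_numpy(), matrix.data[ids_b].to_numpy()
    )
    df = pd.DataFrame({"probe_id": matrix.probe_ids, "score": scores})
    df["gene"] = [annotation.symbol_of(p) for p in df["probe_id"]]
    df = df.dropna(subset=["gene"])
    df["gene"] = df["gene"].str.upper()
    df["abs"] = df["score"].abs()
    best = (
        df.sort_values(["abs", "probe_id"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("gene")
    )
    ranked = best.set_index("gene")["score"].sort_values(
        ascending=False, kind="mergesort"
    )
    ranked.name = "score"
    return ranked


# ----------------------------------------------------------------------------
# GSEA
# ----------------------------------------------------------------------------


def _es_from_hits(
    weights: np.ndarray, hit_positions: np.ndarray, n_genes: int
) -> tuple[float, int]:
    """Signed-max-deviation ES from sorted 0-based hit positions.

    ``weights`` are the hit increments |score|^p at those positions (in the
    same order).  Returns (ES, index into hit_positions of the extremum) —
    the index delimits the leading edge for positive ES.
    """
    k = hit_positions.size
    total = weights.sum()
    if total <= 0:
        cum_hit = np.arange(1, k + 1) / k
    else:
        cum_hit = np.cumsum(weights) / total
    if n_genes == k:
        j = int(np.argmax(cum_hit))
        return float(cum_hit[j]), j
    d = 1.0 / (n_genes - k)
    misses_before = hit_positions - np.arange(k)
    after = cum_hit - misses_before * d
    before = np.concatenate([[0.0], cum_hit[:-1]]) - misses_before * d
    j_pos = int(np.argmax(after))
    j_neg = int(np.argmin(before))
    es_pos = float(after[j_pos])
    es_neg = float(before[j_neg])
    if es_pos >= -es_neg:
        return es_pos, j_pos
    return es_neg, j_neg


def gsea_enrichment_score(
    ranked: pd.Series, geneset, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and full running sum.

    Walking the descending ranked list, set members increment the running
    sum by |score|^p (normalised so all hits sum to 1) and non-members
    decrement it by 1/(N − N_hits).  ES is the signed maximum deviation from
    zero.  A set with no member in the ranked list is an error.
    """
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    members = {g.upper() for g in geneset}
    hit = np.array([g.upper() in members for g in genes])
    k = int(hit.sum())
    n = genes.size
    if k == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    w = np.abs(scores) ** weight_p
    wh = w * hit
    total = wh.sum()
    if total > 0:
        inc = wh / total
    else:
        inc = hit / k
    if n == k:
        running = np.cumsum(inc)
        j = int(np.argmax(running))
        return float(running[j]), running
    dec = (~hit) / (n - k)
    running = np.cumsum(inc - dec)
    i_pos = int(np.argmax(running))
    i_neg = int(np.argmin(running))
    es = float(running[i_pos]) if running[i_pos] >= -running[i_neg] else float(running[i_neg])
    return es, running


def _perm_es_gene_set(
    weights_pow: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets."""
    n = weights_pow.size
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        out[i], _ = _es_from_hits(weights_pow[pos], pos, n)
    return out


def _nes(es: float, null: np.ndarray) -> float:
    same = null[null >= 0] if es >= 0 else null[null < 0]
    denom = np.abs(same).mean() if same.size else np.nan
    return es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan


def _nominal_p(es: float, null: np.ndarray) -> float:
    if es >= 0:
        same = null[null >= 0]
        b = int((same >= es).sum())
    else:
        same = null[null < 0]
        b = int((same <= es).sum())
    return (b + 1) / (same.size + 1)


def _gsea_fdr(nes_obs: np.ndarray, nes_null: list[np.ndarray]) -> np.ndarray:
    """FDR q per the GSEA procedure: ratio of normalised tail fractions."""
    all_null = np.concatenate([x[np.isfinite(x)] for x in nes_null]) \
        if nes_null else np.array([])
    q = np.empty(len(nes_obs))
    for i, v in enumerate(nes_obs):
        if not np.isfinite(v):
            q[i] = np.nan
            continue
        if v >= 0:
            null_same = all_null[all_null >= 0]
            obs_same = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            num = (null_same >= v).mean() if null_same.size else 1.0
            den = (obs_same >= v).mean() if obs_same.size else 1.0
        else:
            null_same = all_null[all_null < 0]
            obs_same = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
            num = (null_same <= v).mean() if null_same.size else 1.0
            den = (obs_same <= v).mean() if obs_same.size else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


def gsea(
    ranked: pd.Series,
    genesets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """GSEA over a ranked gene list with gene-set permutations.

    For each set: ES, NES (ES normalised by the mean |ES| of same-sign
    permutation scores), nominal p from the same-sign permutation tail, FDR
    q by the GSEA normalised-tail-ratio procedure (capped at 1), and the
    leading-edge genes.  Sets with no overlap are skipped with a warning.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse",
                      stacklevel=2)
    genes = ranked.index.to_numpy()
    genes_upper = np.array([g.upper() for g in genes])
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    rng = np.random.default_rng(seed)
    rows = []
    nes_null_all: list[np.ndarray] = []
    for name in genesets:
        members = genesets.members(name)
        hit = np.isin(genes_upper, list(members))
        k = int(hit.sum())
        if k == 0:
            warnings.warn(f"gene set {name!r} has no overlap; skipped",
                          stacklevel=2)
            continue
        es, running = gsea_enrichment_score(ranked, members, weight_p=weight_p)
        null = _perm_es_gene_set(w, k, n_perm, rng)
        nes = _nes(es, null)
        p = _nominal_p(es, null)
        null_nes = np.array([_nes(v, null) for v in null])
        nes_null_all.append(null_nes)
        if es >= 0:
            edge_end = int(np.argmax(running))
            edge = genes[: edge_end + 1][hit[: edge_end + 1]]
        else:
            edge_start = int(np.argmin(running))
            edge = genes[edge_start:][hit[edge_start:]]
        rows.append(
            {
                "set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "nominal_p": p,
                "leading_edge": ",".join(edge),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = _gsea_fdr(out["nes"].to_numpy(), nes_null_all)
        out = out[["set", "size", "es", "nes", "nominal_p", "fdr_q", "leading_edge"]]
    return out


def gsea_phenotype(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    annotation: ProbeAnnotation,
    class_a: Treatment,
    class_b: Treatment,
    genesets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """GSEA with phenotype (class-label) permutations.

    The SNR ranking is recomputed under each label permutation — the
    stricter null that preserves gene–gene correlation.  Small or unbalanced
    designs leave few distinct label splits; the gene-set permutation mode
    (:func:`gsea`) is the default in the pipeline.
    """
    ids_a = [s for s in meta.samples_with(class_a) if s in matrix.data.columns]
    ids_b = [s for s in meta.samples_with(class_b) if s in matrix.data.columns]
    sub = matrix.subset_samples(ids_a + ids_b)
    n_a = len(ids_a)
    rng = np.random.default_rng(seed)
    ranked = rank_genes_snr(matrix, meta, annotation, class_a, class_b)

    # per-permutation rankings
    vals = sub.values
    probe_ids = sub.probe_ids
    null_by_set: dict[str, list[float]] = {name: [] for name in genesets}
    gene_of = {p: annotation.symbol_of(p) for p in probe_ids}
    for _ in range(n_perm):
        order = rng.permutation(vals.shape[1])
        perm_scores = snr_scores(vals[:, order[:n_a]], vals[:, order[n_a:]])
        df = pd.DataFrame({"probe_id": probe_ids, "score": perm_scores})
        df["gene"] = [gene_of[p] for p in probe_ids]
        df = df.dropna(subset=["gene"])
        df["gene"] = df["gene"].str.upper()
        df["abs"] = df["score"].abs()
        perm_ranked = (
            df.sort_values(["abs", "probe_id"], ascending=[False, True],
                           kind="mergesort")
            .drop_duplicates("gene")
            .set_index("gene")["score"]
            .sort_values(ascending=False, kind="mergesort")
        )
        for name in genesets:
            try:
                es, _ = gsea_enrichment_score(
                    perm_ranked, genesets.members(name), weight_p=weight_p
                )
            except ValueError:
                continue
            null_by_set[name].append(es)

    rows = []
    nes_null_all: list[np.ndarray] = []
    genes = ranked.index.to_numpy()
    for name in genesets:
        members = genesets.members(name)
        hit = np.array([g.upper() in members for g in genes])
        k = int(hit.sum())
        if k == 0:
            warnings.warn(f"gene set {name!r} has no overlap; skipped",
                          stacklevel=2)
            continue
        es, running = gsea_enrichment_score(ranked, members, weight_p=weight_p)
        null = np.asarray(null_by_set[name], dtype=float)
        nes = _nes(es, null)
        p = _nominal_p(es, null)
        nes_null_all.append(np.array([_nes(v, null) for v in null]))
        if es >= 0:
            edge_end = int(np.argmax(running))
            edge = genes[: edge_end + 1][hit[: edge_end + 1]]
        else:
            edge_start = int(np.argmin(running))
            edge = genes[edge_start:][hit[edge_start:]]
        rows.append({"set": name, "size": k, "es": es, "nes": nes,
                     "nominal_p": p, "leading_edge": ",".join(edge)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = _gsea_fdr(out["nes"].to_numpy(), nes_null_all)
        out = out[["set", "size", "es", "nes", "nominal_p", "fdr_q", "leading_edge"]]
    return out


# ----------------------------------------------------------------------------
# hypergeometric over-representation
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRow:
    name: str
    overlap: int
    overlap_genes: tuple[str, ...]
    p: float
    excluded: bool  # True when overlap < min_overlap (row dropped before BH)


def hypergeometric_test(
    query: set[str] | list[str],
    reference_set: set[str] | list[str],
    universe: set[str] | list[str],
    min_overlap: int = 3,
    name: str = "",
) -> EnrichmentRow:
    """Upper-tail hypergeometric over-representation test.

    p = P(X ≥ k) with N = |universe|, K = |reference ∩ universe|,
    n = |query|, k = |query ∩ reference|.  Rows with overlap below
    ``min_overlap`` are marked excluded (they are dropped before BH at the
    collection level).  The query must be contained in the universe.
    """
    uni = {g.upper() for g in universe}
    q = {g.upper() for g in query}
    offenders = sorted(q - uni)
    if offenders:
        raise ValueError(f"query genes outside the universe: {offenders[:10]}")
    ref = {g.upper() for g in reference_set} & uni
    inter = sorted(q & ref)
    k = len(inter)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(ref), len(q)))
    return EnrichmentRow(
        name=name,
        overlap=k,
        overlap_genes=tuple(inter),
        p=p,
        excluded=k < min_overlap,
    )


def enrich_collection(
    query: list[str],
    genesets: GeneSetCollection,
    universe: list[str],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Hypergeometric test of a query list against every set, BH-adjusted.

    Sets with overlap < ``min_overlap`` are excluded before adjustment.
    """
    rows = []
    for nm in genesets:
        r = hypergeometric_test(
            query, genesets.members(nm), universe, min_overlap=min_overlap, name=nm
        )
        if not r.excluded:
            rows.append(
                {
                    "set": nm,
                    "overlap": r.overlap,
                    "overlap_genes": ",".join(r.overlap_genes),
                    "p": r.p,
                }
            )
    out = pd.DataFrame(rows, columns=["set", "overlap", "overlap_genes", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return out


# ----------------------------------------------------------------------------
# cell-type specificity
# ----------------------------------------------------------------------------


def celltype_specificity_scores(ref: CellTypeReference) -> pd.DataFrame:
    """Margin specificity: spec(g, c) = mean(g, c) − max over other cell types.

    At most one positive entry per gene (its top cell type); exact ties at
    the top give 0 for the tied types.
    """
    X = ref.data.to_numpy(dtype=float)
    order = np.sort(X, axis=1)
    top1 = order[:, -1][:, None]
    top2 = order[:, -2][:, None]
    other_max = np.where(X >= top1, top2, top1)
    spec = X - other_max
    return pd.DataFrame(spec, index=ref.data.index, columns=ref.data.columns)


def celltype_enrichment(
    query: list[str],
    spec: pd.DataFrame,
    tau: float = 1.0,
    universe: list[str] | None = None,
    min_overlap: int = 3,
    n_sum_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type enrichment of a query gene list.

    For each cell type the reference set is the genes with specificity
    margin > ``tau`` (log2 units); the query's overlap is tested with the
    upper-tail hypergeometric and BH-adjusted across cell types.  The summed
    specificity of the query for the cell type is reported descriptively;
    ``n_sum_permutations > 0`` additionally computes a permutation p-value
    on that summed score (random same-size queries from the universe).
    Cell types with an empty reference set are skipped with a note.
    """
    if tau < 0:
        raise ValueError("tau must be ≥ 0")
    universe = universe if universe is not None else list(spec.index)
    uni_upper = {g.upper() for g in universe}
    spec_u = spec.copy()
    spec_u.index = [g.upper() for g in spec_u.index]
    q = [g.upper() for g in query]
    missing = sorted(set(q) - uni_upper)
    if missing:
        raise ValueError(f"query genes outside the universe: {missing[:10]}")
    q_in_spec = [g for g in q if g in spec_u.index]
    rng = np.random.default_rng(seed)
    rows = []
    for c in spec.columns:
        ref_genes = set(spec_u.index[spec_u[c] > tau]) & uni_upper
        if not ref_genes:
            warnings.warn(
                f"cell type {c!r}: no gene exceeds specificity {tau}; skipped",
                stacklevel=2,
            )
            continue
        r = hypergeometric_test(q, ref_genes, uni_upper, min_overlap=0, name=c)
        summed = float(spec_u.loc[q_in_spec, c].sum()) if q_in_spec else 0.0
        row = {
            "cell_type": c,
            "reference_size": len(ref_genes),
            "overlap": r.overlap,
            "summed_specificity": summed,
            "p": r.p,
            "low_overlap": r.overlap < min_overlap,
        }
        if n_sum_permutations > 0:
            pool = [g for g in uni_upper if g in spec_u.index]
            b = 0
            for _ in range(n_sum_permutations):
                draw = rng.choice(pool, size=len(q_in_spec), replace=False)
                if float(spec_u.loc[draw, c].sum()) >= summed:
                    b += 1
            row["sum_perm_p"] = (b + 1) / (n_sum_permutations + 1)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p", "cell_type"], kind="mergesort").reset_index(
            drop=True
        )
    return out
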