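"""End-to-end orchestration: preprocessing → variability → differential →
patterns → enrichment, with a run manifest.

The effective configuration is a plain dictionary (usually loaded from a
YAML file); every stage writes TSV tables (and basic plots) into the output
directory, and the manifest records parameters, seeds, tool version and a
content hash of every artefact so deterministic stages can be verified
hash-stable across runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .core import ExpressionMatrix, ProbeAnnotation, SampleMetadata, Treatment
from .differential import build_differential_table, consensus_significant, wilcoxon_significant
from .enrichment import celltype_enrichment, celltype_specificity_scores, gsea, rank_genes_snr
from .patterns import classify_patterns
from .preprocess import adjust_batch, merge_technical_replicates, pca_outlier_check, quantile_normalize
from .variability import (
    activation_variable_probes,
    coefficient_of_variation,
    compare_group_variability,
    count_failing,
    select_tolerance_probes,
    subsample_sensitivity,
    tolerance_percentages,
    tolerance_ranges,
)

__all__ = ["DEFAULT_CONFIG", "run_full_comparison"]

DEFAULT_CONFIG: dict = {
    "log2_input": "auto",
    "batch_method": "combat",
    "merge_replicates": False,
    "pca_k_sd": 4.0,
    "alpha": 0.05,
    "tolerance": {"n_top": 1000, "floor": 6.0, "threshold": 75.0},
    "sensitivity": {"subset_size": 11, "n_repeats": 10},
    "diff": {"n_perm": 1000},
    "gsea": {"n_perm": 1000},
    "celltype": {"tau": 1.0},
    "seed": 0,
    "skip": [],
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_comparison(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    out_dir: str | Path,
    annotation: ProbeAnnotation | None = None,
    genesets=None,
    celltype_ref=None,
    config: dict | None = None,
) -> dict:
    """Run every stage and write all artefacts plus a manifest.

    ``config['skip']`` names stages to omit (prep, variability, tolerance,
    cv, sensitivity, differential, patterns, enrichment).  Any stage failure
    raises a stage-scoped error; artefacts written before the failure are
    retained.  Returns the manifest dictionary.
    """
    cfg = _merge_config(config)
    skip = set(cfg.get("skip") or [])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }

    def emit(df: pd.DataFrame, name: str, index_label: str | None = None,
             params: dict | None = None) -> None:
        path = out / name
        io.write_table(df, path, params=params, index_label=index_label)
        written.append(path)

    def run_stage(name: str, fn) -> None:
        if name in skip:
            return
        try:
            fn()
            manifest["stages"].append(name)
        except Exception as e:  # noqa: BLE001 - re-scoped with stage name
            raise StageError(name, e) from e

    state: dict = {"matrix": matrix, "meta": meta}

    def stage_prep() -> None:
        m = io.maybe_log2(state["matrix"], cfg["log2_input"])
        m = quantile_normalize(m)
        m = adjust_batch(m, state["meta"], method=cfg["batch_method"])
        if cfg["merge_replicates"]:
            m, state["meta"] = merge_technical_replicates(m, state["meta"])
        outliers = pca_outlier_check(m, k_sd=cfg["pca_k_sd"])
        state["matrix"] = m
        io.write_expression_matrix(m, out / "prep.tsv",
                                   params={"batch_method": cfg["batch_method"]})
        written.append(out / "prep.tsv")
        emit(outliers, "pca_outliers.tsv", index_label="sample_id")

    def stage_variability() -> None:
        m, md = state["matrix"], state["meta"]
        act = activation_variable_probes(m, md, alpha=cfg["alpha"])
        state["activation_set"] = act
        counts = compare_group_variability(m, md, act, alpha=cfg["alpha"]) if act else None
        summary = pd.DataFrame(
            [{
                "n_activation_variable": len(act),
                "n_generic_more_variable": counts.n_generic_more_variable if counts else 0,
                "n_ga_more_variable": counts.n_ga_more_variable if counts else 0,
                "fold": counts.fold if counts else np.nan,
            }]
        )
        emit(summary, "variability_summary.tsv")
        from .variability import variance_ratio_ranking

        emit(variance_ratio_ranking(m, md), "variance_ratio.tsv")

    def stage_tolerance() -> None:
        m, md = state["matrix"], state["meta"]
        tc = cfg["tolerance"]
        probes = select_tolerance_probes(m, md, n_top=tc["n_top"], expr_floor=tc["floor"])
        tol = tolerance_ranges(m, md, probes)
        results = {}
        rows = []
        for t in (Treatment.GA, Treatment.GENERIC):
            r = tolerance_percentages(m, md, tol, t)
            results[t.value] = r
            emit(r.curve, f"tolerance_curve_{t.value}.tsv")
            rows.append({
                "product": t.value,
                "n_failing": count_failing(r, tc["threshold"]),
                "worst_pct": float(r.pct_within.min()),
            })
        state["tolerance"] = results
        state["tolerance_ranges"] = tol.ranges
        emit(pd.DataFrame(rows), "tolerance_summary.tsv",
             params={"threshold": tc["threshold"]})
        from .plots import plot_tolerance_curves

        plot_tolerance_curves(results, out / "tolerance_curves.png")
        written.append(out / "tolerance_curves.png")

    def stage_cv() -> None:
        m, md = state["matrix"], state["meta"]
        mm, mmeta = merge_technical_replicates(m, md)
        cvs = {}
        for t in (Treatment.GA, Treatment.GENERIC):
            df = coefficient_of_variation(mm, mmeta, t)
            cvs[t.value] = df
            emit(df, f"cv_{t.value}.tsv", index_label="probe_id")
        from .plots import plot_cv

        plot_cv(cvs, out / "cv.png")
        written.append(out / "cv.png")

    def stage_sensitivity() -> None:
        m, md = state["matrix"], state["meta"]
        sc = cfg["sensitivity"]
        table, p = subsample_sensitivity(
            m, md, subset_size=sc["subset_size"], n_repeats=sc["n_repeats"],
            seed=cfg["seed"], alpha=cfg["alpha"],
        )
        table["paired_t_p"] = p
        emit(table, "sensitivity.tsv", params={"seed": cfg["seed"]})

    def stage_differential() -> None:
        m, md = state["matrix"], state["meta"]
        table = build_differential_table(
            m, md, n_perm=cfg["diff"]["n_perm"], seed=cfg["seed"]
        )
        state["diff_table"] = table
        emit(table, "differential.tsv", index_label="probe_id",
             params={"seed": cfg["seed"], "n_perm": cfg["diff"]["n_perm"]})

    def stage_patterns() -> None:
        m, md = state["matrix"], state["meta"]
        sets = classify_patterns(m, md, alpha=cfg["alpha"])
        state["patterns"] = sets
        rows = [
            {"pattern": name, "n_probes": len(probes), "probes": ",".join(probes)}
            for name, probes in sets.items()
        ]
        emit(pd.DataFrame(rows), "patterns.tsv")

    def stage_enrichment() -> None:
        if annotation is None:
            return
        m, md = state["matrix"], state["meta"]
        if genesets is not None:
            ranked = rank_genes_snr(m, md, annotation, Treatment.GA, Treatment.MEDIUM)
            res = gsea(ranked, genesets, n_perm=cfg["gsea"]["n_perm"],
                       seed=cfg["seed"])
            emit(res, "gsea_ga_vs_medium.tsv", params={"seed": cfg["seed"]})
        if genesets is not None and "diff_table" in state:
            # hypergeometric enrichment of the Wilcoxon-significant lists
            from .enrichment import enrich_collection

            universe = sorted(
                {annotation.symbol_of(p).upper() for p in m.probe_ids
                 if annotation.symbol_of(p)}
            )
            wil_a, wil_b = wilcoxon_significant(state["diff_table"],
                                                alpha=cfg["alpha"])
            for name, probes in (("wilcoxon_higher_GA", wil_a),
                                 ("wilcoxon_higher_generic", wil_b)):
                genes = sorted({
                    annotation.symbol_of(p).upper() for p in probes
                    if annotation.symbol_of(p)
                })
                if genes:
                    emit(enrich_collection(genes, genesets, universe),
                         f"enrich_{name}.tsv")
        if celltype_ref is not None and "diff_table" in state:
            spec = celltype_specificity_scores(celltype_ref)
            universe = sorted(
                {annotation.symbol_of(p).upper() for p in m.probe_ids
                 if annotation.symbol_of(p)}
            )
            higher_a, higher_b = consensus_significant(state["diff_table"],
                                                       alpha=cfg["alpha"])
            for name, probes in (("higher_GA", higher_a),
                                 ("higher_generic", higher_b)):
                genes = sorted({
                    annotation.symbol_of(p).upper() for p in probes
                    if annotation.symbol_of(p)
                })
                if not genes:
                    continue
                res = celltype_enrichment(
                    genes, spec, tau=cfg["celltype"]["tau"], universe=universe
                )
                emit(res, f"celltype_{name}.tsv")

    run_stage("prep", stage_prep)
    run_stage("variability", stage_variability)
    run_stage("tolerance", stage_tolerance)
    run_stage("cv", stage_cv)
    run_stage("sensitivity", stage_sensitivity)
    run_stage("differential", stage_differential)
    run_stage("patterns", stage_patterns)
    run_stage("enrichment", stage_enrichment)

    manifest["files"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
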