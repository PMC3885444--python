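"""Seeded generator of synthetic comparability studies.

Emulates the statistical structure the pipeline assumes: four treatment arms
(reference standard, branded product, generic, vehicle medium) with realistic
group sizes, chip-batch effects on log2 intensities, activation effects
shared by the branded product and its reference standard, generic-only
shifted probe sets, a variance-inflated probe subset in the generic arm,
optional technical replicates — plus matching cell-type reference compendia
and gene-set collections.  Ground truth (which probes/genes carry which
planted structure) is returned for recovery tests.

Noise is Gaussian on the log2 scale (all analyses operate on log2 values); a
heavier-tailed Student-t option supports robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CellTypeReference,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ProbeAnnotation,
    SampleMetadata,
    Treatment,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_study",
    "simulate_celltype_reference",
    "simulate_gene_sets",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Group sizes default to the study design this pipeline targets: 22
    reference-standard samples, 34 branded-product samples (30 product
    batches), 11 generic samples (5 product batches), 8 medium samples, on
    18 microarray chip batches.  Effects are on the log2 scale: baseline
    probe means ~N(baseline_mean, baseline_sd²), within-group noise sd
    ``noise_sd``, additive per-chip probe-specific batch effects of sd
    ``batch_sd``.  ``activation_effect`` shifts the activation-responsive
    probes in the reference-standard and branded arms; generic-only probe
    sets shift by ``generic_effect`` (default 2·noise_sd) in the generic arm
    only; ``gamma`` multiplies the generic-arm noise sd on the
    variance-inflated subset.
    """

    n_probes: int = 10_000
    n_rs: int = 22
    n_ga: int = 34
    n_generic: int = 11
    n_medium: int = 8
    n_ga_product_batches: int = 30
    n_generic_product_batches: int = 5
    n_chip_batches: int = 18
    batch_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    activation_effect: float = 1.0
    activation_fraction: float = 0.05
    generic_effect: float | None = None  # default 2*noise_sd
    n_generic_up: int = 100
    n_generic_down: int = 100
    gamma: float = 2.0
    n_inflated: int = 100
    technical_replicates: int = 1
    technical_sd: float = 0.1
    noise_df: float | None = None  # Student-t df for heavy-tailed noise
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_probes, self.n_rs, self.n_ga, self.n_generic, self.n_medium,
            self.n_chip_batches, self.technical_replicates,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.gamma < 1.0:
            raise ValueError("gamma must be ≥ 1")
        if not 0.0 <= self.activation_fraction <= 1.0:
            raise ValueError("activation_fraction must be in [0, 1]")
        n_act = int(round(self.activation_fraction * self.n_probes))
        if n_act + self.n_generic_up + self.n_generic_down + self.n_inflated > self.n_probes:
            raise ValueError("planted probe categories exceed the probe universe")

    @property
    def resolved_generic_effect(self) -> float:
        return (
            2.0 * self.noise_sd if self.generic_effect is None else self.generic_effect
        )


@dataclass
class SimulationTruth:
    """Planted structure of a simulated study, for recovery tests."""

    activation_up: list[str]
    activation_down: list[str]
    generic_up: list[str]
    generic_down: list[str]
    variance_inflated: list[str]
    gene_of_probe: dict[str, str]
    effects: dict[str, float] = field(default_factory=dict)

    def genes(self, probes: list[str]) -> list[str]:
        return [self.gene_of_probe[p] for p in probes]

    @property
    def all_planted(self) -> set[str]:
        return (
            set(self.activation_up)
            | set(self.activation_down)
            | set(self.generic_up)
            | set(self.generic_down)
            | set(self.variance_inflated)
        )


def _noise(rng: np.random.Generator, shape, sd: float, df: float | None) -> np.ndarray:
    if df is None:
        return rng.normal(0.0, sd, shape)
    # variance-matched Student t
    raw = rng.standard_t(df, shape)
    return raw * sd / np.sqrt(df / (df - 2.0))


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, ProbeAnnotation, SimulationTruth]:
    """Draw one full synthetic study; deterministic for a fixed config seed.

    log2 expression = probe baseline + chip-batch effect + treatment effect
    + noise; the reference standard and branded arms share the activation
    effects, the generic arm carries its own up/down sets and the
    variance-inflated subset (noise sd × γ).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_probes
    probes = [f"P{i:06d}" for i in range(1, n + 1)]
    genes = {p: f"GENE{i:06d}" for i, p in enumerate(probes, start=1)}

    # disjoint planted categories, allocated in blocks from a shuffled universe
    n_act = int(round(cfg.activation_fraction * n))
    n_act_up = n_act // 2
    n_act_down = n_act - n_act_up
    shuffled = list(rng.permutation(probes))
    take = lambda k: [shuffled.pop() for _ in range(k)]
    activation_up = sorted(take(n_act_up))
    activation_down = sorted(take(n_act_down))
    generic_up = sorted(take(cfg.n_generic_up))
    generic_down = sorted(take(cfg.n_generic_down))
    inflated = sorted(take(cfg.n_inflated))

    idx = {p: i for i, p in enumerate(probes)}
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    # keep planted tolerance-relevant probes comfortably expressed
    for cat in (activation_up, activation_down, generic_up, generic_down):
        for p in cat:
            baseline[idx[p]] = abs(baseline[idx[p]] - cfg.baseline_mean) + cfg.baseline_mean

    g_eff = cfg.resolved_generic_effect
    effect = {t: np.zeros(n) for t in Treatment if t is not Treatment.OTHER}
    for p in activation_up:
        for t in (Treatment.REFERENCE_STANDARD, Treatment.GA):
            effect[t][idx[p]] += cfg.activation_effect
    for p in activation_down:
        for t in (Treatment.REFERENCE_STANDARD, Treatment.GA):
            effect[t][idx[p]] -= cfg.activation_effect
    for p in generic_up:
        effect[Treatment.GENERIC][idx[p]] += g_eff
    for p in generic_down:
        effect[Treatment.GENERIC][idx[p]] -= g_eff

    sd_by_group = {t: np.full(n, cfg.noise_sd) for t in effect}
    for p in inflated:
        sd_by_group[Treatment.GENERIC][idx[p]] *= cfg.gamma

    # biological samples per arm
    plan = [
        (Treatment.REFERENCE_STANDARD, "RS", cfg.n_rs, 1),
        (Treatment.GA, "GA", cfg.n_ga, cfg.n_ga_product_batches),
        (Treatment.GENERIC, "GEN", cfg.n_generic, cfg.n_generic_product_batches),
        (Treatment.MEDIUM, "MED", cfg.n_medium, 1),
    ]
    bio_cols: list[np.ndarray] = []
    bio_info: list[dict] = []
    for treatment, prefix, count, n_batches in plan:
        for i in range(count):
            signal = (
                baseline
                + effect[treatment]
                + _noise(rng, n, 1.0, cfg.noise_df) * sd_by_group[treatment]
            )
            bio_cols.append(signal)
            bio_info.append(
                {
                    "bio_id": f"{prefix}{i + 1:02d}",
                    "treatment": treatment,
                    "product_batch": f"{prefix}_B{(i % n_batches) + 1:02d}",
                }
            )

    # arrays = biological samples × technical replicates, randomised on chips
    arrays: list[np.ndarray] = []
    rows: list[dict] = []
    for info, signal in zip(bio_info, bio_cols):
        for r in range(cfg.technical_replicates):
            sid = (
                info["bio_id"]
                if cfg.technical_replicates == 1
                else f"{info['bio_id']}r{r + 1}"
            )
            tech = (
                rng.normal(0.0, cfg.technical_sd, n)
                if cfg.technical_replicates > 1
                else 0.0
            )
            arrays.append(signal + tech)
            rows.append(
                {
                    "sample_id": sid,
                    "treatment": info["treatment"],
                    "product_batch": info["product_batch"],
                    "replicate_group": info["bio_id"],
                }
            )
    n_arrays = len(arrays)
    chip = rng.permutation(np.arange(n_arrays) % cfg.n_chip_batches)
    batch_effects = rng.normal(0.0, cfg.batch_sd, (cfg.n_chip_batches, n))
    X = np.column_stack(
        [a + batch_effects[chip[j]] for j, a in enumerate(arrays)]
    )
    for j, row in enumerate(rows):
        row["chip_batch"] = f"chip{chip[j] + 1:02d}"

    meta_df = pd.DataFrame(rows).set_index("sample_id")[
        ["treatment", "chip_batch", "product_batch", "replicate_group"]
    ]
    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=probes, columns=[r["sample_id"] for r in rows])
    )
    truth = SimulationTruth(
        activation_up=activation_up,
        activation_down=activation_down,
        generic_up=generic_up,
        generic_down=generic_down,
        variance_inflated=inflated,
        gene_of_probe=genes,
        effects={
            "activation_effect": cfg.activation_effect,
            "generic_effect": g_eff,
            "gamma": cfg.gamma,
        },
    )
    return matrix, SampleMetadata(meta_df), ProbeAnnotation(genes), truth


def simulate_celltype_reference(
    genes: list[str],
    n_celltypes: int,
    signature_size: int,
    margin: float,
    seed: int = 0,
    planted: dict[str, list[str]] | None = None,
    baseline: float = 3.0,
    noise_sd: float = 0.3,
) -> tuple[CellTypeReference, dict[str, list[str]]]:
    """Gene × cell-type reference with disjoint planted signatures.

    Signature genes sit ``margin`` log2 units above their level in every
    other cell type (± noise); background genes are flat.  ``planted`` maps
    cell-type names to explicit signature gene lists (must be disjoint);
    remaining cell types receive random disjoint signatures of
    ``signature_size`` genes.  Returns the reference and the full
    signature-membership truth.
    """
    planted = dict(planted or {})
    all_planted: list[str] = [g for gs in planted.values() for g in gs]
    if len(set(all_planted)) != len(all_planted):
        raise ValueError("planted signatures overlap")
    missing = [g for g in all_planted if g not in set(genes)]
    if missing:
        raise ValueError(f"planted signature genes outside universe: {missing[:5]}")
    n_random = n_celltypes - len(planted)
    if n_random < 0:
        raise ValueError("more planted signatures than cell types")
    if len(all_planted) + signature_size * n_random > len(genes):
        raise ValueError("signatures exceed the gene universe")

    rng = np.random.default_rng(seed)
    free = [g for g in genes if g not in set(all_planted)]
    free = list(rng.permutation(free))
    signatures: dict[str, list[str]] = {}
    for name, gs in planted.items():
        signatures[name] = list(gs)
    for i in range(n_random):
        signatures[f"celltype{i + 1:02d}"] = sorted(
            free.pop() for _ in range(signature_size)
        )

    names = list(signatures)
    X = baseline + rng.normal(0.0, noise_sd, (len(genes), len(names)))
    gi = {g: i for i, g in enumerate(genes)}
    for j, name in enumerate(names):
        for g in signatures[name]:
            X[gi[g], j] += margin
    ref = CellTypeReference(pd.DataFrame(X, index=list(genes), columns=names))
    return ref, signatures


def simulate_gene_sets(
    truth: SimulationTruth,
    n_decoy_sets: int = 10,
    set_size: int = 20,
    seed: int = 0,
) -> GeneSetCollection:
    """One gene set per planted probe category plus random decoy sets.

    Decoys are drawn from genes carrying no planted structure, so a
    calibrated enrichment method should score them at chance level.
    """
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    for name, probes in (
        ("activation_up", truth.activation_up),
        ("activation_down", truth.activation_down),
        ("generic_up", truth.generic_up),
        ("generic_down", truth.generic_down),
        ("variance_inflated", truth.variance_inflated),
    ):
        if probes:
            sets.append(
                GeneSet(name, f"planted {name} signature", tuple(truth.genes(probes)))
            )
    planted_genes = {truth.gene_of_probe[p] for p in truth.all_planted}
    pool = sorted(
        g for g in truth.gene_of_probe.values() if g not in planted_genes
    )
    for i in range(n_decoy_sets):
        members = tuple(sorted(rng.choice(pool, size=set_size, replace=False)))
        sets.append(GeneSet(f"decoy{i + 1:02d}", "random decoy set", members))
    return GeneSetCollection(sets)
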