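"""Basic diagnostic plots: tolerance curves, CV vs intensity, per-gene panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, ProbeAnnotation, SampleMetadata, Treatment
from .variability import ToleranceResult

__all__ = [
    "plot_tolerance_curves",
    "plot_cv",
    "plot_gene_panels",
]

_COLORS = {
    Treatment.GA: "tab:blue",
    Treatment.GENERIC: "tab:red",
    Treatment.REFERENCE_STANDARD: "tab:green",
    Treatment.MEDIUM: "tab:gray",
}


def plot_tolerance_curves(results: dict[str, ToleranceResult], path: str | Path) -> None:
    """Sorted within-range percentage per probe, one curve per product."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, tol in results.items():
        if tol.curve is None:
            raise ValueError(f"tolerance percentages not computed for {label}")
        y = tol.curve["pct_within"].to_numpy()
        ax.plot(np.arange(1, len(y) + 1), y, label=label)
    ax.set_xlabel("probe rank")
    ax.set_ylabel("% samples within reference range")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_cv(cv_by_group: dict[str, pd.DataFrame], path: str | Path) -> None:
    """CV against mean log2 intensity, one panel per group."""
    fig, axes = plt.subplots(
        1, len(cv_by_group), figsize=(4 * len(cv_by_group), 3.5), squeeze=False
    )
    for ax, (label, df) in zip(axes[0], cv_by_group.items()):
        ok = ~df["undefined"]
        ax.scatter(df.loc[ok, "mean_log2"], df.loc[ok, "cv"], s=2, alpha=0.3)
        ax.set_title(label)
        ax.set_xlabel("mean log2 intensity")
        ax.set_ylabel("CV")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _probe_for_gene(annotation: ProbeAnnotation, gene: str) -> str:
    probes = annotation.probes_for(gene)
    if not probes:
        raise ValueError(f"gene {gene!r} not present in the probe annotation")
    return sorted(probes)[0]


def _density(ax, values: np.ndarray, label: str, color: str) -> None:
    # Gaussian kernel, Silverman bandwidth with a floor for near-constant data
    if np.ptp(values) < 1e-9 or len(values) < 2:
        ax.axvline(values[0], color=color, label=label)
        return
    kde = stats.gaussian_kde(values, bw_method="silverman")
    if kde.factor * values.std(ddof=1) < 1e-3:
        kde.set_bandwidth(bw_method=1e-3 / values.std(ddof=1))
    xs = np.linspace(values.min() - 1, values.max() + 1, 200)
    ax.plot(xs, kde(xs), color=color, label=label)


def plot_gene_panels(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    annotation: ProbeAnnotation,
    genes: list[str],
    kinds: tuple[str, ...] = ("box", "density"),
    out_dir: str | Path = ".",
    ranges: pd.DataFrame | None = None,
) -> list[Path]:
    """Per-gene grouped boxplots / kernel densities, and pairwise scatters.

    ``kinds`` from {box, density, scatter_pair}; scatter_pair plots
    consecutive gene pairs with the reference-standard tolerance rectangle
    overlaid when per-probe ``ranges`` (range_low/range_high) are given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    treatments = [t for t in _COLORS if meta.samples_with(t)]

    for kind in kinds:
        if kind not in {"box", "density", "scatter_pair"}:
            raise ValueError(f"unknown panel kind {kind!r}")

    for gene in genes:
        probe = _probe_for_gene(annotation, gene)
        row = matrix.data.loc[probe]
        if "box" in kinds:
            fig, ax = plt.subplots(figsize=(4, 3.5))
            data = [row[meta.samples_with(t)].to_numpy() for t in treatments]
            ax.boxplot(data, tick_labels=[t.value for t in treatments])
            ax.set_ylabel(f"{gene} log2 expression")
            ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            p = out_dir / f"{gene}_box.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
        if "density" in kinds:
            fig, ax = plt.subplots(figsize=(4, 3.5))
            for t in treatments:
                _density(ax, row[meta.samples_with(t)].to_numpy(), t.value,
                         _COLORS[t])
            ax.set_xlabel(f"{gene} log2 expression")
            ax.set_ylabel("density")
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = out_dir / f"{gene}_density.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)

    if "scatter_pair" in kinds:
        for ga, gb in zip(genes[::2], genes[1::2]):
            pa, pb = _probe_for_gene(annotation, ga), _probe_for_gene(annotation, gb)
            fig, ax = plt.subplots(figsize=(4, 4))
            for t in treatments:
                ids = meta.samples_with(t)
                ax.scatter(
                    matrix.data.loc[pa, ids],
                    matrix.data.loc[pb, ids],
                    s=12,
                    color=_COLORS[t],
                    label=t.value,
                )
            if ranges is not None and pa in ranges.index and pb in ranges.index:
                from matplotlib.patches import Rectangle

                lo_a, hi_a = ranges.loc[pa, ["range_low", "range_high"]]
                lo_b, hi_b = ranges.loc[pb, ["range_low", "range_high"]]
                ax.add_patch(
                    Rectangle(
                        (lo_a, lo_b), hi_a - lo_a, hi_b - lo_b,
                        fill=False, edgecolor="red",
                    )
                )
            ax.set_xlabel(ga)
            ax.set_ylabel(gb)
            ax.legend(fontsize=7)
            fig.tight_layout()
            p = out_dir / f"{ga}_vs_{gb}_scatter.png"
            fig.savefig(p)
            plt.close(fig)
            written.append(p)
    return written
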