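"""Condition-pattern identification across the four treatment arms.

Each probe gets six pairwise two-group ANOVA p-values (all unordered pairs of
GA, generic, reference standard, medium).  A pattern template constrains each
pair to SIG (p < α), NS (p > α) or ANY, optionally plus a direction predicate
on group means vs medium; probes matching every constraint form the pattern
set.  The four built-in templates isolate probes affected only by the
generic (up/down) and probes affected only by the branded product and its
reference standard (up/down).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, SampleMetadata, Treatment
from .differential import bh_adjust

__all__ = [
    "Constraint",
    "PatternTemplate",
    "PAIR_ORDER",
    "pairwise_condition_pvalues",
    "group_means",
    "match_pattern",
    "builtin_templates",
    "classify_patterns",
]


class Constraint(enum.Enum):
    SIG = "SIG"  # p < alpha
    NS = "NS"  # p > alpha
    ANY = "ANY"


#: fixed, documented order of the six condition pairs
PAIR_ORDER: tuple[tuple[Treatment, Treatment], ...] = (
    (Treatment.GA, Treatment.GENERIC),
    (Treatment.GA, Treatment.REFERENCE_STANDARD),
    (Treatment.GA, Treatment.MEDIUM),
    (Treatment.GENERIC, Treatment.REFERENCE_STANDARD),
    (Treatment.GENERIC, Treatment.MEDIUM),
    (Treatment.REFERENCE_STANDARD, Treatment.MEDIUM),
)


def _pair_name(pair: tuple[Treatment, Treatment]) -> str:
    return f"{pair[0].value}~{pair[1].value}"


PAIR_NAMES = tuple(_pair_name(p) for p in PAIR_ORDER)


@dataclass(frozen=True)
class PatternTemplate:
    """Constraints on the six pairwise comparisons, plus direction predicates.

    ``constraints`` maps pair name (see :data:`PAIR_NAMES`) to a
    :class:`Constraint`; unmentioned pairs default to ANY.  ``directions``
    lists (treatment, sign) requirements on mean(treatment) − mean(medium):
    sign +1 requires the treatment mean above medium, −1 below.
    """

    name: str
    constraints: tuple[tuple[str, Constraint], ...]
    directions: tuple[tuple[Treatment, int], ...] = ()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.constraints]
        unknown = [n for n in names if n not in PAIR_NAMES]
        if unknown:
            raise ValueError(f"unknown pair name(s) {unknown}; valid: {PAIR_NAMES}")
        if len(set(names)) != len(names):
            raise ValueError("duplicate pair constraint")
        if all(c is Constraint.ANY for _, c in self.constraints) or not self.constraints:
            raise ValueError("template needs at least one non-ANY constraint")

    def constraint_for(self, pair_name: str) -> Constraint:
        for n, c in self.constraints:
            if n == pair_name:
                return c
        return Constraint.ANY


def pairwise_condition_pvalues(
    matrix: ExpressionMatrix, meta: SampleMetadata
) -> pd.DataFrame:
    """Six per-probe p-values, one per condition pair, in :data:`PAIR_ORDER`.

    Each is a two-group one-way ANOVA (equivalent to a pooled two-sided
    t-test, F = t²).  All four conditions must be present with ≥ 2 samples.
    """
    arrays: dict[Treatment, np.ndarray] = {}
    for t in (
        Treatment.GA,
        Treatment.GENERIC,
        Treatment.REFERENCE_STANDARD,
        Treatment.MEDIUM,
    ):
        ids = [s for s in meta.samples_with(t) if s in matrix.data.columns]
        if len(ids) < 2:
            raise ValueError(f"condition {t.value} absent or has < 2 samples")
        arrays[t] = matrix.data[ids].to_numpy()
    cols = {}
    for pair in PAIR_ORDER:
        res = stats.f_oneway(arrays[pair[0]], arrays[pair[1]], axis=1)
        cols[_pair_name(pair)] = res.pvalue
    return pd.DataFrame(cols, index=pd.Index(matrix.probe_ids, name="probe_id"))


def group_means(matrix: ExpressionMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Per-probe mean expression of each of the four conditions."""
    out = {}
    for t in (
        Treatment.GA,
        Treatment.GENERIC,
        Treatment.REFERENCE_STANDARD,
        Treatment.MEDIUM,
    ):
        ids = [s for s in meta.samples_with(t) if s in matrix.data.columns]
        if not ids:
            raise ValueError(f"condition {t.value} absent")
        out[t.value] = matrix.data[ids].to_numpy().mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(matrix.probe_ids, name="probe_id"))


def match_pattern(
    pvals: pd.DataFrame,
    template: PatternTemplate,
    alpha: float = 0.05,
    means: pd.DataFrame | None = None,
    adjust: bool = False,
) -> list[str]:
    """Probes matching a template: SIG pairs p < α, NS pairs p > α.

    p == α matches neither constraint.  Direction predicates require
    ``means`` (from :func:`group_means`).  ``adjust=True`` applies BH within
    each pair column before thresholding (off by default — the pattern
    method is defined on raw p-values).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    P = pvals.copy()
    if adjust:
        for c in P.columns:
            P[c] = bh_adjust(P[c].to_numpy())
    mask = np.ones(len(P), dtype=bool)
    for pair_name in PAIR_NAMES:
        c = template.constraint_for(pair_name)
        if c is Constraint.ANY:
            continue
        col = P[pair_name].to_numpy()
        mask &= (col < alpha) if c is Constraint.SIG else (col > alpha)
    if template.directions:
        if means is None:
            raise ValueError(
                f"template {template.name!r} has direction predicates; "
                "supply group means"
            )
        med = means[Treatment.MEDIUM.value].to_numpy()
        for t, sign in template.directions:
            diff = means[t.value].to_numpy() - med
            mask &= (diff > 0) if sign > 0 else (diff < 0)
    return list(P.index[mask])


def _only_generic(name: str, sign: int) -> PatternTemplate:
    return PatternTemplate(
        name=name,
        constraints=(
            ("GA~GENERIC", Constraint.SIG),
            ("GENERIC~REFERENCE_STANDARD", Constraint.SIG),
            ("GENERIC~MEDIUM", Constraint.SIG),
            ("GA~MEDIUM", Constraint.NS),
            ("GA~REFERENCE_STANDARD", Constraint.NS),
            ("REFERENCE_STANDARD~MEDIUM", Constraint.NS),
        ),
        directions=((Treatment.GENERIC, sign),),
    )


def _ga_and_rs_only(name: str, sign: int) -> PatternTemplate:
    return PatternTemplate(
        name=name,
        constraints=(
            ("GA~GENERIC", Constraint.SIG),
            ("GENERIC~REFERENCE_STANDARD", Constraint.SIG),
            ("GA~MEDIUM", Constraint.SIG),
            ("REFERENCE_STANDARD~MEDIUM", Constraint.SIG),
            ("GA~REFERENCE_STANDARD", Constraint.NS),
            ("GENERIC~MEDIUM", Constraint.NS),
        ),
        directions=((Treatment.GA, sign), (Treatment.REFERENCE_STANDARD, sign)),
    )


def builtin_templates() -> dict[str, PatternTemplate]:
    """The four named condition patterns.

    * UP_ONLY_GENERIC / DOWN_ONLY_GENERIC — probes shifted only by the
      generic relative to medium, with GA and the reference standard
      indistinguishable from medium;
    * UP_GA_AND_RS_ONLY / DOWN_GA_AND_RS_ONLY — probes shifted by the
      branded product and its reference standard (which agree with each
      other) but not by the generic.
    """
    return {
        "UP_ONLY_GENERIC": _only_generic("UP_ONLY_GENERIC", +1),
        "DOWN_ONLY_GENERIC": _only_generic("DOWN_ONLY_GENERIC", -1),
        "UP_GA_AND_RS_ONLY": _ga_and_rs_only("UP_GA_AND_RS_ONLY", +1),
        "DOWN_GA_AND_RS_ONLY": _ga_and_rs_only("DOWN_GA_AND_RS_ONLY", -1),
    }


def classify_patterns(
    matrix: ExpressionMatrix,
    meta: SampleMetadata,
    templates: dict[str, PatternTemplate] | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> dict[str, list[str]]:
    """Match every template against the data; convenience front door."""
    templates = templates or builtin_templates()
    pvals = pairwise_condition_pvalues(matrix, meta)
    means = group_means(matrix, meta)
    return {
        name: match_pattern(pvals, t, alpha=alpha, means=means, adjust=adjust)
        for name, t in templates.items()
    }
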