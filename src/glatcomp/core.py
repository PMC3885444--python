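"""Central data model: expression matrices, sample metadata, gene sets.

Everything downstream (normalisation, variability QC, differential testing,
enrichment) operates on these containers.  An :class:`ExpressionMatrix` is a
probe × sample table of log2 intensities backed by a pandas DataFrame;
:class:`SampleMetadata` carries the experimental design — which drug product
each splenocyte sample was activated with, which microarray chip (batch) it
ran on, which manufacturing batch of the product it came from and which
technical-replicate group it belongs to.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "ExpressionMatrix",
    "SampleMetadata",
    "ProbeAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "OrthologyMap",
    "CellTypeReference",
    "validate_pairing",
]


class Treatment(enum.Enum):
    """Activation condition of a sample.

    GA is the branded glatiramer acetate drug product, REFERENCE_STANDARD a
    fixed manufacturing standard batch of it, GENERIC the follow-on product,
    MEDIUM the vehicle control.  Anything else (other glatiramoids, degraded
    drug, mannitol, ...) maps to OTHER.
    """

    GA = "GA"
    REFERENCE_STANDARD = "REFERENCE_STANDARD"
    GENERIC = "GENERIC"
    MEDIUM = "MEDIUM"
    OTHER = "OTHER"


#: accepted spellings (lower-cased, stripped) for each treatment
_TREATMENT_ALIASES: dict[str, Treatment] = {
    "ga": Treatment.GA,
    "copaxone": Treatment.GA,
    "drug product": Treatment.GA,
    "reference standard": Treatment.REFERENCE_STANDARD,
    "reference_standard": Treatment.REFERENCE_STANDARD,
    "rs": Treatment.REFERENCE_STANDARD,
    "generic": Treatment.GENERIC,
    "medium": Treatment.MEDIUM,
    "vehicle": Treatment.MEDIUM,
    "other": Treatment.OTHER,
}


def parse_treatment(label: str) -> Treatment:
    """Map a free-text treatment label to the :class:`Treatment` enum.

    Unknown labels become ``OTHER`` with a warning, so that extra arms of a
    study (e.g. mannitol or deliberately degraded product) survive loading
    without being silently confused with a modelled condition.
    """
    key = str(label).strip().lower()
    if key in _TREATMENT_ALIASES:
        return _TREATMENT_ALIASES[key]
    warnings.warn(
        f"unknown treatment label {label!r}; mapping to OTHER", stacklevel=2
    )
    return Treatment.OTHER


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Probe × sample matrix of (log2) expression intensities."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(list(self.data.index), "probe IDs")
        _check_unique(list(self.data.columns), "sample IDs")
        if not np.all(np.isfinite(self.data.to_numpy())):
            bad = np.argwhere(~np.isfinite(self.data.to_numpy()))
            r, c = bad[0]
            raise ValueError(
                f"non-finite expression value at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data[list(sample_ids)].copy())

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(probe_ids)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


REQUIRED_SAMPLE_COLUMNS = (
    "sample_id",
    "treatment",
    "chip_batch",
    "product_batch",
    "replicate_group",
)


@dataclass
class SampleMetadata:
    """Per-sample design table, indexed by sample_id.

    Columns: ``treatment`` (a :class:`Treatment`), ``chip_batch``,
    ``product_batch``, ``replicate_group`` (categorical strings).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [
            c
            for c in ("treatment", "chip_batch", "product_batch", "replicate_group")
            if c not in self.table.columns
        ]
        if missing:
            raise ValueError(f"sample metadata missing required column(s): {missing}")
        _check_unique(list(self.table.index), "sample IDs")
        self.table.index = self.table.index.astype(str)
        bad = [
            t for t in self.table["treatment"] if not isinstance(t, Treatment)
        ]
        if bad:
            raise TypeError(
                f"treatment column must hold Treatment enum values, got {bad[:3]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def treatment_of(self, sample_id: str) -> Treatment:
        return self.table.loc[sample_id, "treatment"]

    def samples_with(self, treatment: Treatment) -> list[str]:
        mask = self.table["treatment"] == treatment
        return list(self.table.index[mask])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())

    def require_groups(self, *treatments: Treatment) -> dict[Treatment, list[str]]:
        """Return samples per treatment, raising if any group is absent."""
        out: dict[Treatment, list[str]] = {}
        for t in treatments:
            ids = self.samples_with(t)
            if not ids:
                raise ValueError(f"no samples with treatment {t.value}")
            out[t] = ids
        return out


def validate_pairing(matrix: ExpressionMatrix, meta: SampleMetadata) -> None:
    """Reject any sample present in exactly one of matrix and metadata."""
    m = set(matrix.sample_ids)
    s = set(meta.sample_ids)
    only_matrix = sorted(m - s)
    only_meta = sorted(s - m)
    if only_matrix or only_meta:
        raise ValueError(
            "matrix/metadata sample mismatch: "
            f"only in matrix {only_matrix}; only in metadata {only_meta}"
        )


@dataclass
class ProbeAnnotation:
    """probe_id → gene symbol map; probes without annotation simply absent."""

    mapping: dict[str, str]

    def symbol_of(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def probes_for(self, symbol: str) -> list[str]:
        sym = symbol.upper()
        return [p for p, s in self.mapping.items() if s.upper() == sym]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        extra = sorted(set(self.mapping) - set(matrix.probe_ids))
        if extra:
            raise ValueError(f"annotation references unknown probes: {extra[:10]}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


class GeneSetCollection(Mapping[str, GeneSet]):
    """Named gene sets (GMT semantics).

    Member symbols are case-normalised (default: upper case) for set
    operations; original spellings are retained on the :class:`GeneSet`
    objects for output.
    """

    def __init__(self, sets: Iterable[GeneSet], normalize_case: bool = True):
        self._sets: dict[str, GeneSet] = {}
        self._members: dict[str, frozenset[str]] = {}
        self.normalize_case = normalize_case
        for gs in sets:
            if gs.name in self._sets:
                raise ValueError(f"duplicate gene set name {gs.name!r}")
            self._sets[gs.name] = gs
            members = gs.genes
            if normalize_case:
                members = tuple(g.upper() for g in members)
            self._members[gs.name] = frozenset(members)

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def members(self, name: str) -> frozenset[str]:
        """Case-normalised member symbols of one set."""
        return self._members[name]


@dataclass
class OrthologyMap:
    """Source → target gene symbol pairs (e.g. human → mouse)."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        seen = set()
        for s, t in self.pairs:
            s, t = s.strip(), t.strip()
            if not s or not t:
                raise ValueError("orthology map contains an empty symbol")
            key = (s.upper(), t.upper())
            if key in seen:
                continue
            seen.add(key)
            cleaned.append((s, t))
        self.pairs = cleaned

    def targets_of(self, symbol: str) -> list[str]:
        sym = symbol.upper()
        return [t for s, t in self.pairs if s.upper() == sym]

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s.upper(), []).append(t)
        return out


@dataclass
class CellTypeReference:
    """Gene × cell-type mean log2 expression compendium (ImmGen-like)."""

    data: pd.DataFrame  # genes in rows, cell types in columns

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("cell-type reference needs at least 2 cell types")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("cell-type reference contains non-finite values")
        _check_unique(list(self.data.index), "gene symbols")
        _check_unique(list(self.data.columns), "cell types")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)
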