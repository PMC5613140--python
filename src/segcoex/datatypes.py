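"""Core in-memory containers.

The analysis revolves around four objects:

* :class:`ExpressionMatrix` — elements x samples intensities on a declared
  scale (``linear`` or ``log2``), with an optional set of background/random
  probe rows used for expression detection calls.
* :class:`SampleDesign` — the sample-to-condition map and the reference
  condition for differential contrasts.
* :class:`GenomeLayout` — the ordered (optionally circular) sequence of
  genomic elements, each with coordinates, strand and a kind
  (``gene`` or ``intergenic``).
* :class:`ReferenceOperons` — an external operon annotation used only for
  comparison against detected transcription units.

Coordinates are 1-based inclusive internally; BED-style output converts to
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DesignError

VALID_SCALES = ("linear", "log2")
VALID_STRANDS = ("+", "-")
VALID_KINDS = ("gene", "intergenic")


@dataclass
class ExpressionMatrix:
    """Elements x samples intensity table.

    Parameters
    ----------
    data
        DataFrame indexed by element id with one column per sample.
        Values must be finite; missing values are rejected (the supported
        platforms produce complete matrices).
    scale
        Declared scale of the values, ``"linear"`` or ``"log2"``.
    background_ids
        Element ids of background / random probes, a subset of the row
        index. May be empty.
    """

    data: pd.DataFrame
    scale: str = "linear"
    background_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise DataError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        idx = self.data.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate element id(s): {dups}")
        cols = self.data.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample id(s): {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression values must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise DataError(
                f"missing value at element {idx[r]!r}, sample {cols[c]!r}; "
                "missing data are not supported"
            )
        if np.isinf(values).any():
            r, c = np.argwhere(np.isinf(values))[0]
            raise DataError(f"non-finite value at element {idx[r]!r}, sample {cols[c]!r}")
        self.background_ids = frozenset(self.background_ids)
        unknown = self.background_ids - set(idx)
        if unknown:
            raise DataError(f"background id(s) not in matrix: {sorted(unknown)}")

    @property
    def element_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_elements(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene_ids(self) -> list[str]:
        """Element ids that are not background probes, in matrix order."""
        return [e for e in self.data.index if e not in self.background_ids]

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Return a copy holding ``values`` (same shape, ids, background)."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, scale or self.scale, self.background_ids)


@dataclass
class SampleDesign:
    """Sample-to-condition assignment with a declared reference condition."""

    condition_of: dict[str, str]
    reference_condition: str

    def __post_init__(self) -> None:
        if self.reference_condition not in set(self.condition_of.values()):
            raise DesignError(
                f"reference condition {self.reference_condition!r} has no samples"
            )

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.condition_of.values():
            seen.setdefault(c)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]

    def validate_against(self, matrix: ExpressionMatrix, min_replicates: int = 2) -> None:
        """Check every sample is mapped and conditions are replicated."""
        missing = [s for s in matrix.sample_ids if s not in self.condition_of]
        if missing:
            raise DesignError(f"samples without condition assignment: {missing}")
        for c in self.conditions:
            n = len([s for s in self.samples_of(c) if s in matrix.sample_ids])
            if 0 < n < min_replicates:
                raise DesignError(
                    f"condition {c!r} has {n} sample(s); at least {min_replicates} required"
                )


@dataclass(frozen=True)
class LayoutElement:
    id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    kind: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise DataError(f"element {self.id!r}: invalid strand {self.strand!r}")
        if self.kind not in VALID_KINDS:
            raise DataError(f"element {self.id!r}: invalid kind {self.kind!r}")
        if self.start < 1:
            raise DataError(f"element {self.id!r}: start must be >= 1 (1-based)")


@dataclass
class GenomeLayout:
    """Ordered sequence of genomic elements, optionally circular.

    Elements are stored sorted by start coordinate. On circular layouts the
    final element may wrap past the origin (``end < start``).
    """

    elements: list[LayoutElement]
    circular: bool = True
    genome_length: int | None = None
    chrom: str = "genome"

    def __post_init__(self) -> None:
        ids = [e.id for e in self.elements]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate layout id(s): {dups}")
        self.elements = sorted(self.elements, key=lambda e: (e.start, e.end))
        for i, e in enumerate(self.elements):
            wrapping_last = self.circular and i == len(self.elements) - 1
            if e.end < e.start and not wrapping_last:
                raise DataError(
                    f"element {e.id!r}: end < start only allowed for the final "
                    "element of a circular layout"
                )

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.elements]

    def __len__(self) -> int:
        return len(self.elements)

    def __getitem__(self, i: int) -> LayoutElement:
        return self.elements[i]

    def by_id(self, element_id: str) -> LayoutElement:
        try:
            return self._index[element_id]
        except AttributeError:
            self._index = {e.id: e for e in self.elements}
            return self._index[element_id]

    def ordered_ids(self, genes_only: bool = True) -> list[str]:
        """Element ids in genomic order, optionally genes only."""
        if genes_only:
            return [e.id for e in self.elements if e.kind == "gene"]
        return [e.id for e in self.elements]


@dataclass
class ReferenceOperons:
    """External operon annotation: ordered same-strand id lists of size >= 2."""

    operons: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        self.operons = [tuple(o) for o in self.operons]
        for o in self.operons:
            if len(o) < 2:
                raise DataError(f"operon {o} has fewer than 2 elements")

    def validate_against(self, layout: GenomeLayout) -> None:
        """Members must exist in the layout and be contiguous in gene order."""
        order = layout.ordered_ids(genes_only=True)
        pos = {g: i for i, g in enumerate(order)}
        n = len(order)
        for o in self.operons:
            unknown = [g for g in o if g not in pos]
            if unknown:
                raise DataError(f"operon member(s) not in layout: {unknown}")
            idx = sorted(pos[g] for g in o)
            span = idx[-1] - idx[0] + 1
            contiguous = span == len(o)
            if not contiguous and layout.circular:
                # allow wrap across the origin
                gaps = [(idx[i + 1] - idx[i]) for i in range(len(idx) - 1)]
                contiguous = max(gaps) == n - len(o) + 1 and sum(gaps) == idx[-1] - idx[0]
            if not contiguous:
                raise DataError(f"operon {o} is not contiguous in the layout")
            strands = {layout.by_id(g).strand for g in o}
            if len(strands) > 1:
                raise DataError(f"operon {o} mixes strands")

    def __len__(self) -> int:
        return len(self.operons)
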