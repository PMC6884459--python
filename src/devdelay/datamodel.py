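"""Domain types for the delay-analysis pipeline.

All containers are thin dataclasses over numpy arrays with eager validation:
a constructed object is always internally consistent. Expression values are
non-negative reals in either FPKM (length/depth-normalized) or raw-count
units; the developmental reference is a genes x time-bins matrix over
contiguous half-open hour intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Allowed expression units.
UNITS = ("FPKM", "count")

#: Differential-expression status labels.
NOT_DETECTED = "not_detected"
DETECTED_UNTESTED = "detected_untested"
TESTED = "tested"

#: Fold-direction labels (up/down require q < alpha).
UP = "up"
DOWN = "down"
NONE = "none"


def _check_gene_ids(gene_ids: Sequence[str]) -> list[str]:
    ids = [str(g) for g in gene_ids]
    if not ids:
        raise ValueError("at least one gene is required")
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            raise ValueError(f"duplicate gene id: {g!r}")
        seen.add(g)
    return ids


@dataclass
class ExpressionMatrix:
    """Per-gene, per-replicate expression values for one condition.

    Parameters
    ----------
    gene_ids : ordered unique gene identifiers (opaque, case-sensitive).
    values : (n_genes, n_replicates) array of non-negative reals.
    unit : "FPKM" or "count".
    condition_label : free-text condition name.
    """

    gene_ids: list[str]
    values: np.ndarray
    unit: str = "FPKM"
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = _check_gene_ids(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x replicates matrix")
        if self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{len(self.gene_ids)} gene ids but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] < 1:
            raise ValueError("at least one replicate is required")
        if np.isnan(self.values).any():
            raise ValueError("missing (NaN) expression values are not allowed")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at gene {self.gene_ids[i]!r}, "
                f"replicate column {j + 1}"
            )
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def gene_means(self) -> np.ndarray:
        """Per-gene mean across replicates."""
        return self.values.mean(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.unit == other.unit
            and self.condition_label == other.condition_label
            and np.array_equal(self.values, other.values)
        )


@dataclass
class TimeCourseReference:
    """Per-gene expression across ordered developmental time bins.

    Bins are half-open hour intervals [start, end), non-overlapping, sorted
    and contiguous (the conventional layout is 12 bins of 2 h covering
    [0, 24)). ``silent_set`` is the set of genes with zero expression in
    every bin — the candidates for derepression.
    """

    gene_ids: list[str]
    bins: list[tuple[float, float]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_gene_ids(self.gene_ids)
        self.bins = [(float(a), float(b)) for a, b in self.bins]
        if not self.bins:
            raise ValueError("at least one time bin is required")
        for a, b in self.bins:
            if not b > a:
                raise ValueError(f"bin [{a}, {b}) has non-positive width")
        starts = [a for a, _ in self.bins]
        if starts != sorted(starts):
            raise ValueError("bins must be sorted ascending by start")
        for (_, e_prev), (s_next, _) in zip(self.bins, self.bins[1:]):
            if s_next < e_prev:
                raise ValueError("bins overlap")
            if s_next > e_prev:
                raise ValueError("bins are not contiguous")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.bins)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.bins)} bins"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing (NaN) reference values are not allowed")
        if (self.values < 0).any():
            raise ValueError("negative reference expression values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_labels(self) -> list[str]:
        return [f"{_fmt_hour(a)}-{_fmt_hour(b)}" for a, b in self.bins]

    @property
    def silent_set(self) -> frozenset[str]:
        """Genes with zero expression in every bin (recomputed on access)."""
        mask = (self.values == 0).all(axis=1)
        return frozenset(g for g, m in zip(self.gene_ids, mask) if m)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in reference") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def window_columns(self, window: tuple[float, float]) -> list[int]:
        """Indices of the bins exactly tiling the half-open hour ``window``.

        Raises ValueError if the window edges do not coincide with bin
        boundaries.
        """
        a, b = float(window[0]), float(window[1])
        cols = [i for i, (s, e) in enumerate(self.bins) if s >= a and e <= b]
        if not cols or self.bins[cols[0]][0] != a or self.bins[cols[-1]][1] != b:
            raise ValueError(
                f"window [{a}, {b}) is not aligned to reference bin boundaries"
            )
        return cols

    def window_aggregate(
        self, window: tuple[float, float], aggregate: str = "mean"
    ) -> np.ndarray:
        """Per-gene aggregate (mean or max) of the bins inside ``window``."""
        cols = self.window_columns(window)
        if aggregate == "mean":
            return self.values[:, cols].mean(axis=1)
        if aggregate == "max":
            return self.values[:, cols].max(axis=1)
        raise ValueError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeCourseReference):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.bins == other.bins
            and np.array_equal(self.values, other.values)
        )


def _fmt_hour(h: float) -> str:
    return str(int(h)) if float(h).is_integer() else str(h)


@dataclass
class DEResult:
    """Per-gene differential-expression record.

    ``status`` is ``not_detected`` (zero in both conditions),
    ``detected_untested`` (detected but below the testability criterion) or
    ``tested``. ``log2_fold_change``, ``p_value`` and ``q_value`` are defined
    only for tested genes; ``direction`` is ``up``/``down`` only when the
    BH-adjusted q-value clears the significance threshold.
    """

    gene_id: str
    status: str
    mean_control: float
    mean_mutant: float
    log2_fold_change: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    direction: str = NONE

    def __post_init__(self) -> None:
        if self.status not in (NOT_DETECTED, DETECTED_UNTESTED, TESTED):
            raise ValueError(f"invalid status {self.status!r}")
        if self.direction not in (UP, DOWN, NONE):
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.mean_control < 0 or self.mean_mutant < 0:
            raise ValueError("condition means must be non-negative")
        if self.status == NOT_DETECTED and (
            self.mean_control != 0 or self.mean_mutant != 0
        ):
            raise ValueError("not_detected requires zero means in both conditions")
        if self.status != TESTED and self.direction != NONE:
            raise ValueError("direction requires a tested gene")
        for name in ("p_value", "q_value"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")

    @property
    def significant(self) -> bool:
        return self.direction in (UP, DOWN)


@dataclass(frozen=True)
class DeletionSummary:
    """Arithmetic summary of a coding-region deletion and its PCR signature."""

    codons_removed: int
    codons_total: int
    coding_loss_pct: int
    wt_amplicon_bp: int
    deletion_bp: int
    expected_mutant_amplicon_bp: int

    def __post_init__(self) -> None:
        if self.codons_total <= 0:
            raise ValueError("codons_total must be positive")
        if not (0 <= self.codons_removed <= self.codons_total):
            raise ValueError("codons_removed outside [0, codons_total]")
        if self.wt_amplicon_bp <= 0:
            raise ValueError("wt_amplicon_bp must be positive")
        if self.deletion_bp < 0:
            raise ValueError("deletion_bp must be non-negative")
        if self.expected_mutant_amplicon_bp < 0:
            raise ValueError("expected mutant amplicon length is negative")
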