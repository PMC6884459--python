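"""Core delay analysis.

A mutant embryo collected at a fixed chronological age can differ
transcriptomically from its control for two distinct reasons: genes it
regulates directly, or a global delay of the developmental program that
makes the sample resemble younger embryos. Given per-gene differential
expression results and a staged wild-type reference time-course, this
module

* tallies the dysregulation classes (detected / tested / significant,
  up / down) with the percentages conventionally reported;
* checks derepression — whether any up-regulated gene is silent across the
  whole reference (a change a delay can never produce);
* applies the low-expression filter (significant genes nearly absent from
  control samples);
* summarizes the developmental profile (per-bin median) of a gene set;
* classifies each dysregulated gene as explainable by delay or not, using
  the early-versus-late window rule: an up-regulated gene is delay-
  explainable when the reference expresses it more in the early window
  (hours 0-6) than in the late window (hours 6-12), a down-regulated gene
  when the reference expresses it less early than late, ties counting as
  NOT explainable;
* assigns a developmental stage to a sample by rank correlation against
  each reference bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .datamodel import (
    DOWN,
    NOT_DETECTED,
    TESTED,
    UP,
    DEResult,
    TimeCourseReference,
)


@dataclass(frozen=True)
class ClassTally:
    """Counts and percentages of differential-expression classes."""

    n_annotated: int
    n_detected: int
    n_tested: int
    n_significant: int
    n_up: int
    n_down: int
    pct_significant_of_tested: float
    pct_significant_of_annotated: float
    pct_up_of_significant: float
    pct_down_of_significant: float
    empty: bool = False

    @classmethod
    def from_counts(
        cls,
        n_annotated: int,
        n_detected: int,
        n_tested: int,
        n_up: int,
        n_down: int,
    ) -> "ClassTally":
        """Build a tally from raw class counts, rounding percentages to one
        decimal as conventionally reported."""
        n_significant = n_up + n_down
        if not 0 <= n_significant <= n_tested <= n_detected <= n_annotated:
            raise ValueError(
                "counts must nest: significant <= tested <= detected <= annotated "
                f"(got {n_significant}/{n_tested}/{n_detected}/{n_annotated})"
            )
        empty = n_significant == 0
        return cls(
            n_annotated=n_annotated,
            n_detected=n_detected,
            n_tested=n_tested,
            n_significant=n_significant,
            n_up=n_up,
            n_down=n_down,
            pct_significant_of_tested=(
                0.0 if n_tested == 0 else round(100.0 * n_significant / n_tested, 1)
            ),
            pct_significant_of_annotated=(
                0.0 if n_annotated == 0 else round(100.0 * n_significant / n_annotated, 1)
            ),
            pct_up_of_significant=(
                0.0 if empty else round(100.0 * n_up / n_significant, 1)
            ),
            pct_down_of_significant=(
                0.0 if empty else round(100.0 * n_down / n_significant, 1)
            ),
            empty=empty,
        )


def tally_expression_classes(
    de: Sequence[DEResult], n_annotated: int
) -> ClassTally:
    """Tally a differential-expression table against the annotated universe.

    ``n_annotated`` is the size of the annotation the experiment could in
    principle have detected; it must be at least the number of records.
    """
    records = list(de)
    if n_annotated < len(records):
        raise ValueError(
            f"{len(records)} DE records exceed the {n_annotated} annotated genes"
        )
    n_detected = sum(1 for r in records if r.status != NOT_DETECTED)
    n_tested = sum(1 for r in records if r.status == TESTED)
    n_up = sum(1 for r in records if r.direction == UP)
    n_down = sum(1 for r in records if r.direction == DOWN)
    return ClassTally.from_counts(n_annotated, n_detected, n_tested, n_up, n_down)


@dataclass(frozen=True)
class DerepressionReport:
    """Outcome of the silent-gene derepression check."""

    n_silent_upregulated: int
    offending_gene_ids: tuple[str, ...]
    genes_without_reference: tuple[str, ...]


def derepression_check(
    de: Sequence[DEResult], reference: TimeCourseReference
) -> DerepressionReport:
    """Find up-regulated genes that the reference calls silent.

    A developmental delay can only move expression along the wild-type
    trajectory, so activating a gene with zero expression in every
    reference bin (derepression) is evidence of a direct effect. Genes
    lacking a reference row cannot be judged and are reported separately.
    """
    silent = reference.silent_set
    offending = []
    missing = []
    for r in de:
        if r.direction != UP:
            continue
        if r.gene_id not in reference:
            missing.append(r.gene_id)
        elif r.gene_id in silent:
            offending.append(r.gene_id)
    return DerepressionReport(len(offending), tuple(offending), tuple(missing))


def low_expression_dysregulated(
    de: Sequence[DEResult], fpkm_threshold: float = 3.0
) -> tuple[int, float]:
    """Count significant genes with near-absent control expression.

    Returns (count, percent of significant genes rounded to two decimals).
    """
    if fpkm_threshold < 0:
        raise ValueError("fpkm_threshold must be non-negative")
    significant = [r for r in de if r.significant]
    count = sum(1 for r in significant if r.mean_control < fpkm_threshold)
    pct = 0.0 if not significant else round(100.0 * count / len(significant), 2)
    return count, pct


@dataclass(frozen=True)
class ProfileSummary:
    """Per-bin median developmental profile of a gene set."""

    bins: tuple[tuple[float, float], ...]
    median_expression: tuple[float, ...]
    n_genes: int
    peak_bin: tuple[float, float]
    trough_bin: tuple[float, float]


def profile_summary(
    gene_set: Iterable[str], reference: TimeCourseReference
) -> ProfileSummary:
    """Median reference expression per bin across a gene set.

    Also reports the bins of maximal and minimal median (earliest bin on
    ties). Every member must have a reference row.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set is empty")
    rows = []
    for g in genes:
        if g not in reference:
            raise ValueError(f"gene {g!r} is not in the reference time-course")
        rows.append(reference.row(g))
    medians = np.median(np.vstack(rows), axis=0)
    return ProfileSummary(
        bins=tuple(reference.bins),
        median_expression=tuple(float(m) for m in medians),
        n_genes=len(genes),
        peak_bin=reference.bins[int(np.argmax(medians))],
        trough_bin=reference.bins[int(np.argmin(medians))],
    )


@dataclass(frozen=True)
class DelayClassification:
    """Delay-explainability verdict for one dysregulated gene."""

    gene_id: str
    direction: str
    window_early_mean: float
    window_late_mean: float
    explained_by_delay: bool


@dataclass(frozen=True)
class DelayReport:
    """All per-gene delay classifications plus the headline counts."""

    classifications: tuple[DelayClassification, ...]
    n_up: int
    n_down: int
    n_up_unexplained: int
    n_down_unexplained: int
    genes_without_reference: tuple[str, ...]

    @property
    def n_up_explained(self) -> int:
        return self.n_up - self.n_up_unexplained

    @property
    def n_down_explained(self) -> int:
        return self.n_down - self.n_down_unexplained


def classify_delay_explainability(
    de: Sequence[DEResult],
    reference: TimeCourseReference,
    early_window: tuple[float, float] = (0.0, 6.0),
    late_window: tuple[float, float] = (6.0, 12.0),
    aggregate: str = "mean",
) -> DelayReport:
    """Classify each dysregulated gene as delay-explainable or not.

    A delayed embryo reads the wild-type program at an earlier age, so an
    up-regulated gene is consistent with delay only if the reference
    expresses it strictly more in the early window than the late window;
    a down-regulated gene only if strictly less. Equal window aggregates
    count as NOT explained. Windows must tile exactly onto reference bins;
    the aggregate over each window is the mean (or max) of its bin values.
    Genes without a reference row are excluded and reported separately.
    """
    early = reference.window_aggregate(early_window, aggregate)
    late = reference.window_aggregate(late_window, aggregate)
    index = {g: i for i, g in enumerate(reference.gene_ids)}

    classifications: list[DelayClassification] = []
    missing: list[str] = []
    n_up = n_down = n_up_unexpl = n_down_unexpl = 0
    for r in de:
        if r.direction not in (UP, DOWN):
            continue
        if r.gene_id not in index:
            missing.append(r.gene_id)
            continue
        i = index[r.gene_id]
        e, l = float(early[i]), float(late[i])
        if r.direction == UP:
            explained = e > l
            n_up += 1
            n_up_unexpl += not explained
        else:
            explained = e < l
            n_down += 1
            n_down_unexpl += not explained
        classifications.append(
            DelayClassification(r.gene_id, r.direction, e, l, explained)
        )
    return DelayReport(
        classifications=tuple(classifications),
        n_up=n_up,
        n_down=n_down,
        n_up_unexplained=n_up_unexpl,
        n_down_unexplained=n_down_unexpl,
        genes_without_reference=tuple(missing),
    )


@dataclass(frozen=True)
class StageAssignment:
    """Best-matching reference bin for a sample and the full correlation profile."""

    best_bin_index: int
    best_bin: tuple[float, float]
    correlations: tuple[float, ...]
    n_shared_genes: int


def stage_assignment(
    sample_means: Mapping[str, float],
    reference: TimeCourseReference,
    min_shared: int = 10,
) -> StageAssignment:
    """Assign a developmental stage to a sample by rank correlation.

    Spearman correlation is computed between the sample's per-gene mean
    expression and each reference bin column over the shared genes; the
    best bin is the argmax, with the earliest bin winning ties. Rank
    correlation is scale-free, so FPKM and count samples stage alike.
    """
    if reference.n_bins < 2:
        raise ValueError("reference must have at least two bins")
    shared = [g for g in reference.gene_ids if g in sample_means]
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} genes shared with the reference (need >= {min_shared})"
        )
    sample = np.array([float(sample_means[g]) for g in shared])
    if np.all(sample == sample[0]):
        raise ValueError("sample vector is constant; rank correlation is degenerate")
    rows = np.array([reference.row(g) for g in shared])
    correlations = []
    for j in range(reference.n_bins):
        col = rows[:, j]
        if np.all(col == col[0]):
            correlations.append(float("nan"))
            continue
        rho, _ = sps.spearmanr(sample, col)
        correlations.append(float(rho))
    arr = np.asarray(correlations)
    if np.isnan(arr).all():
        raise ValueError("every reference bin is constant; staging is degenerate")
    best = int(np.nanargmax(arr))  # argmax takes the earliest bin on ties
    return StageAssignment(
        best_bin_index=best,
        best_bin=reference.bins[best],
        correlations=tuple(correlations),
        n_shared_genes=len(shared),
    )
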