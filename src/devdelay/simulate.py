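"""Synthetic embryo-expression generator with known ground truth.

The generator emulates the downstream gene-level summaries of a staged
embryo RNA-seq experiment: a wild-type developmental reference time-course
(genes x 2-hour bins), and paired control/mutant replicate expression
matrices sampled from a collection window of that time-course. The mutant
condition can carry two kinds of injected signal:

* a rigid developmental delay — its collection window is shifted earlier by
  ``delay_hours``, so every gene's expected expression is read off the
  wild-type trajectory at a younger age;
* direct effects — disjoint gene sets multiplied by 2^(+-direct_effect_log2fc)
  independent of the trajectory.

Each non-silent background gene follows a smooth trajectory from one of
three shape classes (early-declining exponential, late-rising logistic, or
a Gaussian bump with random peak time) scaled by a log-normal amplitude;
direct-effect genes are given flat (stage-independent) trajectories so the
change injected into them cannot be mimicked by a delay; a configured
fraction of genes is silent (identically zero, the derepression
candidates). Replicate noise is log-normal (multiplicative, fixed CV)
followed by negative-binomial count sampling at a given library size, and
FPKM output rescales counts with a uniform 1 kb gene length. A single seed
drives every draw, so identical configurations give bitwise-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .datamodel import ExpressionMatrix, TimeCourseReference

SHAPE_SILENT = "silent"
SHAPE_FLAT = "flat"
SHAPE_EARLY = "early_declining"
SHAPE_LATE = "late_rising"
SHAPE_PEAKED = "peaked"

#: Default mix of trajectory shape classes among non-silent genes. The
#: reference panels this emulates are dominated by monotone early-high or
#: late-high profiles; peaked genes are a minority class.
SHAPE_PROBS: Mapping[str, float] = {
    SHAPE_EARLY: 0.4,
    SHAPE_LATE: 0.4,
    SHAPE_PEAKED: 0.2,
}

_GRID_POINTS = 33  # per-window quadrature resolution for trajectory means


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults describe the emulated study: ~19% of annotated genes silent in
    embryos, three biological replicates per condition, twelve 2-hour bins
    covering [0, 24) h, a [6, 12) h collection window (see
    ``generate_embryo_samples``), MiSeq-scale library depth and moderate
    biological variability.
    """

    n_genes: int = 2000
    n_bins: int = 12
    bin_hours: float = 2.0
    n_replicates: int = 3
    frac_silent: float = 0.19
    frac_direct_up: float = 0.0
    frac_direct_down: float = 0.0
    direct_effect_log2fc: float = 2.0
    delay_hours: float = 0.0
    biological_cv: float = 0.1
    nb_dispersion: float = 0.01
    library_size: int = 20_000_000
    output_unit: str = "FPKM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_bins <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes, n_bins and n_replicates must be positive")
        if self.bin_hours <= 0:
            raise ValueError("bin_hours must be positive")
        for name in ("frac_silent", "frac_direct_up", "frac_direct_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_silent + self.frac_direct_up + self.frac_direct_down > 1.0:
            raise ValueError(
                "frac_silent + frac_direct_up + frac_direct_down exceeds 1"
            )
        if self.direct_effect_log2fc <= 0:
            raise ValueError("direct_effect_log2fc must be positive")
        if self.delay_hours < 0:
            raise ValueError("delay_hours must be non-negative")
        if self.biological_cv < 0:
            raise ValueError("biological_cv must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.output_unit not in ("FPKM", "count"):
            raise ValueError("output_unit must be 'FPKM' or 'count'")

    @property
    def total_hours(self) -> float:
        return self.n_bins * self.bin_hours


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic experiment.

    Holds the injected delay, the disjoint silent / direct-effect gene
    sets, and every gene's trajectory parameters, so tests can evaluate
    noiseless expectations directly.
    """

    gene_ids: list[str]
    shapes: np.ndarray  # object array of shape-class labels
    amplitudes: np.ndarray
    param1: np.ndarray  # tau | midpoint | peak time, by shape class
    param2: np.ndarray  # unused | steepness | bump width
    silent_genes: frozenset[str]
    direct_up_genes: frozenset[str]
    direct_down_genes: frozenset[str]
    delay_hours: float
    seed: int

    def __post_init__(self) -> None:
        sets = [self.silent_genes, self.direct_up_genes, self.direct_down_genes]
        for i, a in enumerate(sets):
            for b in sets[i + 1 :]:
                if a & b:
                    raise ValueError("truth gene sets must be pairwise disjoint")

    def trajectory_values(self, t) -> np.ndarray:
        """Noiseless expression of every gene at hour(s) ``t``.

        Returns an (n_genes, len(t)) matrix (t is broadcast to 1-D).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((len(self.gene_ids), t.size))
        tt = t[None, :]

        def sub(mask):
            return (
                self.amplitudes[mask, None],
                self.param1[mask, None],
                self.param2[mask, None],
            )

        flat = self.shapes == SHAPE_FLAT
        early = self.shapes == SHAPE_EARLY
        late = self.shapes == SHAPE_LATE
        peak = self.shapes == SHAPE_PEAKED
        out[flat] = self.amplitudes[flat, None] * np.ones_like(tt)
        a, p1, _ = sub(early)
        out[early] = a * np.exp(-tt / p1)
        a, p1, p2 = sub(late)
        out[late] = a / (1.0 + np.exp(-(tt - p1) / p2))
        a, p1, p2 = sub(peak)
        out[peak] = a * np.exp(-((tt - p1) ** 2) / (2.0 * p2**2))
        return out

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Per-gene noiseless mean expression over the half-open hour window."""
        a, b = float(window[0]), float(window[1])
        if not b > a:
            raise ValueError(f"empty window [{a}, {b})")
        grid = np.linspace(a, b, _GRID_POINTS)
        traj = self.trajectory_values(grid)
        return np.trapezoid(traj, grid, axis=1) / (b - a)


def generate_reference(
    config: SimulationConfig,
) -> tuple[TimeCourseReference, SyntheticTruth]:
    """Draw the wild-type developmental reference and its ground truth.

    Gene roles (silent, direct-up, direct-down) are assigned first by exact
    fraction, then every non-silent gene gets a shape class, trajectory
    parameters and a log-normal amplitude. Reference bin values are the
    trajectory's average over each bin. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(len(str(n)), 4)
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    order = rng.permutation(n)
    n_silent = round(config.frac_silent * n)
    n_up = round(config.frac_direct_up * n)
    n_down = round(config.frac_direct_down * n)
    silent_idx = order[:n_silent]
    up_idx = order[n_silent : n_silent + n_up]
    down_idx = order[n_silent + n_up : n_silent + n_up + n_down]

    shapes = np.empty(n, dtype=object)
    shapes[:] = SHAPE_SILENT
    # Direct-effect genes ride flat (stage-independent) trajectories, so the
    # change injected into them is never attributable to the delay itself.
    shapes[up_idx] = SHAPE_FLAT
    shapes[down_idx] = SHAPE_FLAT
    background = np.ones(n, dtype=bool)
    background[silent_idx] = False
    background[up_idx] = False
    background[down_idx] = False
    labels = list(SHAPE_PROBS)
    probs = np.array([SHAPE_PROBS[s] for s in labels])
    shapes[background] = rng.choice(labels, size=int(background.sum()), p=probs)

    non_silent = shapes != SHAPE_SILENT
    amplitudes = np.zeros(n)
    amplitudes[non_silent] = rng.lognormal(
        mean=np.log(20.0), sigma=1.0, size=int(non_silent.sum())
    )
    param1 = np.zeros(n)
    param2 = np.ones(n)
    early = shapes == SHAPE_EARLY
    late = shapes == SHAPE_LATE
    peak = shapes == SHAPE_PEAKED
    param1[early] = rng.uniform(2.0, 6.0, early.sum())  # decay constant tau (h)
    param1[late] = rng.uniform(8.0, 18.0, late.sum())  # logistic midpoint (h)
    param2[late] = rng.uniform(1.0, 3.0, late.sum())  # logistic steepness (h)
    param1[peak] = rng.uniform(0.0, config.total_hours, peak.sum())  # peak time
    param2[peak] = rng.uniform(1.5, 4.0, peak.sum())  # bump width (h)

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        shapes=shapes,
        amplitudes=amplitudes,
        param1=param1,
        param2=param2,
        silent_genes=frozenset(gene_ids[i] for i in silent_idx),
        direct_up_genes=frozenset(gene_ids[i] for i in up_idx),
        direct_down_genes=frozenset(gene_ids[i] for i in down_idx),
        delay_hours=config.delay_hours,
        seed=config.seed,
    )

    bins = [
        (i * config.bin_hours, (i + 1) * config.bin_hours) for i in range(config.n_bins)
    ]
    values = np.column_stack([truth.window_mean(b) for b in bins])
    reference = TimeCourseReference(gene_ids, bins, values)
    return reference, truth


def expected_condition_means(
    truth: SyntheticTruth,
    config: SimulationConfig,
    window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expected FPKM per gene for the control and mutant conditions.

    Control reads the trajectory over ``window``; mutant reads it over the
    window shifted earlier by ``config.delay_hours`` and then applies the
    direct-effect fold changes.
    """
    a, b = float(window[0]), float(window[1])
    if a - config.delay_hours < 0:
        raise ValueError(
            f"delay of {config.delay_hours} h shifts the [{a}, {b}) window "
            "before time 0 (window would precede time 0)"
        )
    expected_control = truth.window_mean((a, b))
    expected_mutant = truth.window_mean(
        (a - config.delay_hours, b - config.delay_hours)
    ).copy()
    fold = 2.0**config.direct_effect_log2fc
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    for g in truth.direct_up_genes:
        expected_mutant[idx[g]] *= fold
    for g in truth.direct_down_genes:
        expected_mutant[idx[g]] /= fold
    return expected_control, expected_mutant


def generate_embryo_samples(
    reference: TimeCourseReference,
    truth: SyntheticTruth,
    config: SimulationConfig,
    window: tuple[float, float] = (6.0, 12.0),
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Sample control and mutant replicate expression matrices.

    Expected per-gene expression comes from :func:`expected_condition_means`;
    each replicate multiplies it by log-normal biological noise with CV
    ``config.biological_cv``, converts to counts through a negative-binomial
    sampler (variance mu + dispersion*mu^2) at ``config.library_size``
    mapped fragments, and — for FPKM output — rescales counts assuming a
    uniform 1 kb gene length.
    """
    if reference.gene_ids != truth.gene_ids:
        raise ValueError("reference and truth disagree on gene ids")
    expected_control, expected_mutant = expected_condition_means(truth, config, window)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    control = _sample_condition(expected_control, config, rng, "control")
    mutant = _sample_condition(expected_mutant, config, rng, "mutant")
    control = ExpressionMatrix(
        truth.gene_ids, control, unit=config.output_unit, condition_label="control"
    )
    mutant = ExpressionMatrix(
        truth.gene_ids, mutant, unit=config.output_unit, condition_label="mutant"
    )
    return control, mutant, truth


def _sample_condition(
    expected: np.ndarray, config: SimulationConfig, rng: np.random.Generator, label: str
) -> np.ndarray:
    n_genes = expected.size
    shape = (n_genes, config.n_replicates)
    noisy = np.broadcast_to(expected[:, None], shape).copy()
    cv = config.biological_cv
    if cv > 0:
        sigma2 = np.log1p(cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)
        noisy *= noise
    # counts at a uniform 1 kb gene length: FPKM == counts per million fragments
    mu = noisy * (config.library_size / 1e6)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    if config.output_unit == "count":
        return counts
    return counts * (1e6 / config.library_size)
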