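"""Seeded generators for every input the analysis consumes.

Three families of synthetic data:

* whole-genome binned sequencing coverage of a strain karyotype, with Poisson
  (or negative-binomial) count noise and a mappability mask that zeroes
  centromere bins by default;
* raw read start positions over a small region, to exercise the binning
  ingestion path;
* flow-cytometry datasets from the segregation branching process — a bulk
  time-course with daily passaging (population capped by hypergeometric
  subsampling) and a limiting-dilution clone assay in which each clone grows
  from a single cell carrying one expressing mini-chromosome.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cnv import BinnedCoverageTrack
from .karyotype import ConfigurationError, KaryotypeError, StrainKaryotype
from .segregation import (
    FlowSample,
    SegregationParams,
    State,
    _propagate_class_counts,
    classify_gfp,
)

__all__ = [
    "CoverageSimConfig",
    "CloneAssay",
    "expected_coverage",
    "simulate_binned_coverage",
    "simulate_read_positions",
    "simulate_flow_timecourse",
    "simulate_clone_assay",
]


@dataclass(frozen=True)
class CoverageSimConfig:
    """Coverage simulation settings.

    ``depth_per_copy`` is the expected number of reads per full-size bin per
    chromosome copy (default 10 at the default 10-kb bins).  ``mappability``
    lists extra weighted intervals ``(chrom, start, end, weight)`` with weight
    in [0, 1]; centromere intervals are weighted 0 by default
    (``mask_centromeres``) to mimic unmappable repeat arrays.  Noise is Poisson
    or negative-binomial with variance ``mu + dispersion * mu**2``.
    """

    depth_per_copy: float = 10.0
    bin_size: int = 10_000
    mask_centromeres: bool = True
    mappability: tuple[tuple[str, int, int, float], ...] = ()
    noise: str = "poisson"
    dispersion: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.depth_per_copy <= 0:
            raise ConfigurationError("depth_per_copy must be positive")
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ConfigurationError(f"unknown noise model {self.noise!r}")
        if self.noise == "negative_binomial" and self.dispersion <= 0:
            raise ConfigurationError("negative_binomial noise requires dispersion > 0")
        for entry in self.mappability:
            _chrom, s, e, w = entry
            if not (0 <= s < e) or not (0.0 <= w <= 1.0):
                raise ConfigurationError(f"invalid mappability interval {entry}")


@dataclass(eq=False)
class CloneAssay:
    """Per-clone GFP-class fractions from a limiting-dilution assay."""

    duration_days: float
    gfp_negative_fraction: np.ndarray
    gfp_double_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gfp_negative_fraction = np.asarray(self.gfp_negative_fraction, dtype=float)
        if self.gfp_negative_fraction.size < 1:
            raise ValueError("clone assay needs at least one clone")
        for arr in (self.gfp_negative_fraction, self.gfp_double_fraction):
            if arr is not None and (np.min(arr) < 0 or np.max(arr) > 1):
                raise ValueError("clone fractions must lie in [0, 1]")

    @property
    def n_clones(self) -> int:
        return int(self.gfp_negative_fraction.size)


def _mask_intervals(
    karyotype: StrainKaryotype, config: CoverageSimConfig
) -> dict[str, list[tuple[int, int, float]]]:
    masks: dict[str, list[tuple[int, int, float]]] = {}
    if config.mask_centromeres:
        for chrom in karyotype.genome:
            if chrom.centromere is not None:
                masks.setdefault(chrom.name, []).append((*chrom.centromere, 0.0))
    for chrom_name, s, e, w in config.mappability:
        masks.setdefault(chrom_name, []).append((int(s), int(e), float(w)))
    return masks


def expected_coverage(
    karyotype: StrainKaryotype, config: CoverageSimConfig | None = None
) -> dict[str, np.ndarray]:
    """Per-bin expected read counts: ``depth_per_copy`` times the copy-weighted
    covered fraction of the bin times the mappability weight.

    Serves both as the mean of the stochastic simulator and as the noiseless
    coverage model for consistency checks.
    """
    config = config if config is not None else CoverageSimConfig()
    masks = _mask_intervals(karyotype, config)
    out: dict[str, np.ndarray] = {}
    for chrom in karyotype.genome:
        nbins = math.ceil(chrom.length / config.bin_size)
        starts = np.arange(nbins, dtype=np.int64) * config.bin_size
        ends = np.minimum(starts + config.bin_size, chrom.length)
        covered = np.zeros(nbins)
        for copy in karyotype.copies.get(chrom.name, ()):
            for s, e in copy:
                overlap = np.minimum(ends, e) - np.maximum(starts, s)
                covered += np.clip(overlap, 0, None) / config.bin_size
        weights = np.ones(nbins)
        for s, e, w in masks.get(chrom.name, ()):
            overlap = np.clip(np.minimum(ends, e) - np.maximum(starts, s), 0, None)
            weights *= 1.0 - (overlap / (ends - starts)) * (1.0 - w)
        out[chrom.name] = config.depth_per_copy * covered * weights
    return out


def simulate_binned_coverage(
    karyotype: StrainKaryotype,
    config: CoverageSimConfig | None = None,
    seed: int | None = None,
) -> BinnedCoverageTrack:
    """Draw a noisy binned coverage track around :func:`expected_coverage`."""
    config = config if config is not None else CoverageSimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    lam = expected_coverage(karyotype, config)
    counts: dict[str, np.ndarray] = {}
    for chrom_name, mu in lam.items():
        if config.noise == "poisson":
            counts[chrom_name] = rng.poisson(mu)
        else:
            shape = 1.0 / config.dispersion
            p = shape / (shape + mu)
            counts[chrom_name] = rng.negative_binomial(shape, p)
    return BinnedCoverageTrack(
        strain=karyotype.strain, bin_size=config.bin_size, counts=counts
    )


def simulate_read_positions(
    karyotype: StrainKaryotype,
    region: tuple[str, int, int],
    config: CoverageSimConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Sample read start positions uniformly within the retained copies of a
    region, with Poisson counts at rate ``depth_per_copy / bin_size`` per base
    per copy and mappability thinning."""
    config = config if config is not None else CoverageSimConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    chrom_name, start, end = region
    chrom = karyotype.genome[chrom_name]
    if not (0 <= start < end <= chrom.length):
        raise KaryotypeError(
            f"region [{start}, {end}) outside {chrom_name} [0, {chrom.length})"
        )
    rate = config.depth_per_copy / config.bin_size
    chunks = []
    for copy in karyotype.copies.get(chrom_name, ()):
        for s, e in copy:
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                k = rng.poisson(rate * (hi - lo))
                chunks.append(rng.integers(lo, hi, size=k, dtype=np.int64))
    positions = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    for s, e, w in _mask_intervals(karyotype, config).get(chrom_name, ()):
        if w < 1.0 and positions.size:
            inside = (positions >= s) & (positions < e)
            drop = inside & (rng.random(positions.size) >= w)
            positions = positions[~drop]
    return np.sort(positions)


def simulate_flow_timecourse(
    params: SegregationParams,
    days: int = 25,
    sample_days: Sequence[int] | None = None,
    initial_cells: int = 100_000,
    max_cells: int = 1_000_000,
    seed: int | None = None,
) -> list[FlowSample]:
    """Bulk GFP time-course mirroring daily passaging.

    All cells start as ``(1 copy, expressing)`` — the state enforced by
    reporter-positive preselection (f0 = 1).  Each day the population divides
    ``divisions_per_day`` times; when it exceeds ``max_cells`` it is subsampled
    without replacement (multivariate hypergeometric), emulating the passage
    bottleneck.  GFP-class fractions are recorded at ``sample_days``.
    """
    if initial_cells < 1:
        raise ValueError("initial_cells must be >= 1")
    if sample_days is None:
        sample_days = sorted(set(range(0, days + 1, 5)) | {days})
    sample_set = set(int(d) for d in sample_days)
    if any(d < 0 or d > days for d in sample_set):
        raise ValueError(f"sample_days must lie within [0, {days}]")
    rng = np.random.default_rng(seed)
    counts: dict[State, int] = {(1, 1): int(initial_cells)}
    samples: list[FlowSample] = []
    if 0 in sample_set:
        samples.append(classify_gfp(counts, day=0.0))
    for day in range(1, days + 1):
        vec = {s: np.asarray([n], dtype=np.int64) for s, n in counts.items()}
        for _ in range(params.divisions_per_day):
            vec = _propagate_class_counts(vec, params, rng)
        counts = {s: int(v[0]) for s, v in vec.items()}
        total = sum(counts.values())
        if total > max_cells:
            states = list(counts)
            kept = rng.multivariate_hypergeometric(
                np.asarray([counts[s] for s in states], dtype=np.int64), max_cells
            )
            counts = {s: int(k) for s, k in zip(states, kept) if k > 0}
        if day in sample_set:
            samples.append(classify_gfp(counts, day=float(day)))
    return samples


def simulate_clone_assay(
    params: SegregationParams,
    n_clones: int,
    duration_days: float = 7.0,
    seed: int | None = None,
) -> CloneAssay:
    """Limiting-dilution clone assay: each clone grows from one ``(1, 1)`` cell
    for ``divisions_per_day * duration_days`` synchronous generations.

    Clonal expansions are propagated as per-generation multinomial draws over
    state counts (vectorized across clones), so 2^21-cell clones stay cheap.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    generations = int(round(duration_days * params.divisions_per_day))
    if generations > 60:
        raise ValueError(
            "clonal expansions beyond 60 generations overflow 64-bit cell counts"
        )
    counts: dict[State, np.ndarray] = {
        (1, 1): np.ones(n_clones, dtype=np.int64)
    }
    for _ in range(generations):
        counts = _propagate_class_counts(counts, params, rng)
    total = np.zeros(n_clones, dtype=np.int64)
    negative = np.zeros(n_clones, dtype=np.int64)
    double = np.zeros(n_clones, dtype=np.int64)
    for (c, e), n in counts.items():
        total += n
        if e == 0:
            negative += n
        elif e >= 2:
            double += n
    return CloneAssay(
        duration_days=duration_days,
        gfp_negative_fraction=negative / total,
        gfp_double_fraction=double / total,
    )
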