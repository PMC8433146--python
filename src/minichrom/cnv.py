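"""Control-normalized read-depth copy-number pipeline.

Binned read counts are normalized twice: each bin by the mean bin count of a
reference chromosome within the same sample (removing sequencing depth), and
the resulting per-bin ratio by the same quantity in a control strain (removing
positional bias shared by both strains).  The double-normalized score of a bin
is then proportional to its relative copy number, with a value of 1 meaning
"same copy number as the control".  Scores are segmented by median smoothing,
quantization to rational copy levels k/control_copies, and merging of short
runs; masked bins (control signal below a floor, e.g. unmappable centromere
repeats) are bridged, with segment boundaries placed at the first unmasked bin
of a discordant level.

All intervals are 0-based, half-open base pairs; bins of a track are
``[i * bin_size, (i+1) * bin_size)``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .karyotype import GenomeModel, KaryotypeError, build_dt40_genome

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedCoverageTrack",
    "RatioTrack",
    "ScoreTrack",
    "SegmentCall",
    "DifferentialRegion",
    "TrackError",
    "ParseError",
    "CopyNumberCaller",
    "bin_reads",
    "normalize_to_reference_chrom",
    "normalize_to_control",
    "chromosome_copy_table",
    "segment_score_track",
    "detect_mini_segment",
    "compare_strains",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_score_bedgraph",
    "write_segments_bed",
]


class TrackError(ValueError):
    """Mismatched or degenerate coverage/score tracks."""


class ParseError(ValueError):
    """Malformed track file."""


@dataclass(eq=False)
class BinnedCoverageTrack:
    """Non-negative integer read counts per fixed-width bin, per chromosome."""

    strain: str
    bin_size: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise TrackError(f"bin_size must be positive, got {self.bin_size}")
        clean = {}
        for chrom, values in self.counts.items():
            arr = np.asarray(values)
            if arr.size and arr.min() < 0:
                raise TrackError(f"{chrom}: negative bin counts")
            clean[chrom] = arr.astype(np.int64)
        self.counts = clean

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.counts)


@dataclass(eq=False)
class RatioTrack:
    """Per-bin counts divided by the sample's reference-chromosome mean.

    ``counts`` and ``ref_mean`` keep the source counts and the reference-
    chromosome mean so that downstream segmentation can fall back on the raw
    Poisson counts, which carry more positional information than the ratios.
    """

    strain: str
    bin_size: int
    reference_chromosome: str
    values: dict[str, np.ndarray]
    counts: dict[str, np.ndarray] | None = None
    ref_mean: float | None = None


@dataclass(eq=False)
class ScoreTrack:
    """Double-normalized copy-ratio scores; masked bins are NaN."""

    sample_strain: str
    control_strain: str
    reference_chromosome: str
    bin_size: int
    scores: dict[str, np.ndarray]
    sample_counts: dict[str, np.ndarray] | None = None
    sample_ref_mean: float | None = None
    _control_ratio: dict[str, np.ndarray] | None = None

    def mask(self, chromosome: str) -> np.ndarray:
        return np.isnan(self.scores[chromosome])

    def chromosome_mean(self, chromosome: str, weighted: bool = True) -> float:
        """Mean score of a chromosome over unmasked bins.

        The default control-weighted mean is the ratio of summed sample and
        control ratios, i.e. the whole-chromosome read-count ratio; it is free
        of the upward Jensen bias that the plain mean of per-bin Poisson
        ratios carries (1/E[Y] < E[1/Y]).
        """
        scores = self.scores[chromosome]
        unmasked = ~np.isnan(scores)
        if not unmasked.any():
            return float("nan")
        if not weighted or self._control_ratio is None:
            return float(scores[unmasked].mean())
        weights = self._control_ratio[chromosome][unmasked]
        return float((scores[unmasked] * weights).sum() / weights.sum())


@dataclass(frozen=True)
class SegmentCall:
    """A constant-copy-level stretch of a score track."""

    chromosome: str
    start: int
    end: int
    mean_score: float
    level: float
    copies: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise TrackError(f"segment start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DifferentialRegion:
    """Maximal interval on which two strains' quantized levels differ."""

    chromosome: str
    start: int
    end: int
    level_a: float
    level_b: float

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def direction(self) -> str:
        """Level change of strain A relative to strain B."""
        return "loss" if self.level_a < self.level_b else "gain"


# ---------------------------------------------------------------------------
# Binning and normalization

def bin_reads(
    read_positions: Mapping[str, Sequence[int] | np.ndarray],
    genome: GenomeModel,
    bin_size: int = 10_000,
    strain: str = "sample",
    strict: bool = False,
) -> BinnedCoverageTrack:
    """Count read start positions per half-open bin.

    Chromosomes of the genome without positions get all-zero vectors.
    Out-of-bounds positions are logged and skipped, or raise in strict mode.
    """
    counts: dict[str, np.ndarray] = {}
    for chrom in genome:
        nbins = math.ceil(chrom.length / bin_size)
        pos = np.asarray(read_positions.get(chrom.name, ()), dtype=np.int64)
        bad = (pos < 0) | (pos >= chrom.length)
        if bad.any():
            if strict:
                raise KaryotypeError(
                    f"{int(bad.sum())} read positions outside {chrom.name} [0, {chrom.length})"
                )
            logger.warning("%s: skipping %d out-of-bounds read positions", chrom.name, bad.sum())
            pos = pos[~bad]
        counts[chrom.name] = np.bincount(pos // bin_size, minlength=nbins)
    return BinnedCoverageTrack(strain=strain, bin_size=bin_size, counts=counts)


def normalize_to_reference_chrom(
    track: BinnedCoverageTrack, reference_chromosome: str = "chr1"
) -> RatioTrack:
    """Divide every bin count by the mean bin count of the reference chromosome."""
    if reference_chromosome not in track.counts:
        raise TrackError(f"reference chromosome {reference_chromosome!r} absent from track")
    ref_mean = float(track.counts[reference_chromosome].mean())
    if ref_mean <= 0:
        raise TrackError(f"reference chromosome {reference_chromosome!r} has zero mean coverage")
    values = {chrom: c / ref_mean for chrom, c in track.counts.items()}
    return RatioTrack(
        strain=track.strain,
        bin_size=track.bin_size,
        reference_chromosome=reference_chromosome,
        values=values,
        counts=track.counts,
        ref_mean=ref_mean,
    )


def _check_same_binning(a, b, values_a: Mapping[str, np.ndarray], values_b) -> None:
    if a.bin_size != b.bin_size:
        raise TrackError(f"bin sizes differ: {a.bin_size} vs {b.bin_size}")
    if set(values_a) != set(values_b):
        raise TrackError("tracks cover different chromosome sets")
    for chrom in values_a:
        if len(values_a[chrom]) != len(values_b[chrom]):
            raise TrackError(f"{chrom}: bin counts differ between tracks")


def normalize_to_control(
    sample_ratio: RatioTrack, control_ratio: RatioTrack, floor: float = 0.1
) -> ScoreTrack:
    """Divide the sample's per-bin ratios by the control's; bins where the
    control ratio falls below ``floor`` are masked (NaN)."""
    _check_same_binning(sample_ratio, control_ratio, sample_ratio.values, control_ratio.values)
    scores = {}
    for chrom, sample in sample_ratio.values.items():
        control = control_ratio.values[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(control >= floor, sample / control, np.nan)
        scores[chrom] = score
    return ScoreTrack(
        sample_strain=sample_ratio.strain,
        control_strain=control_ratio.strain,
        reference_chromosome=sample_ratio.reference_chromosome,
        bin_size=sample_ratio.bin_size,
        scores=scores,
        sample_counts=sample_ratio.counts,
        sample_ref_mean=sample_ratio.ref_mean,
        _control_ratio=dict(control_ratio.values),
    )


def chromosome_copy_table(score_track: ScoreTrack, genome: GenomeModel) -> pd.DataFrame:
    """Per-chromosome mean score and inferred copy number.

    ``copies_raw = control_copies * mean_score``, where the mean score is the
    control-weighted mean over unmasked bins (equivalently the whole-chromosome
    read-count ratio, unbiased for Poisson counts); ``copies_rounded``
    quantizes the mean score to the nearest k/control_copies, i.e. the nearest
    whole copy.  Fully masked chromosomes are reported with NaN.
    """
    rows = []
    for chrom in genome:
        scores = score_track.scores.get(chrom.name)
        if scores is None:
            continue
        n_unmasked = int((~np.isnan(scores)).sum())
        if n_unmasked == 0:
            mean = raw = np.nan
            rounded: float = np.nan
            n_used = 0
        else:
            mean = score_track.chromosome_mean(chrom.name)
            raw = chrom.control_copies * mean
            rounded = float(np.round(raw))
            n_used = n_unmasked
        rows.append(
            {
                "chromosome": chrom.name,
                "control_copies": chrom.control_copies,
                "mean_score": mean,
                "copies_raw": raw,
                "copies_rounded": rounded,
                "n_bins_used": n_used,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Segmentation

def _merge_short_runs(levels: np.ndarray, min_run: int) -> list[tuple[float, int]]:
    """Run-length encode and absorb runs shorter than min_run into the longer
    adjacent run (left neighbor on ties)."""
    runs: list[list] = []
    for lv in levels:
        if runs and runs[-1][0] == lv:
            runs[-1][1] += 1
        else:
            runs.append([lv, 1])
    while len(runs) > 1:
        short = [i for i, r in enumerate(runs) if r[1] < min_run]
        if not short:
            break
        i = min(short, key=lambda k: (runs[k][1], k))
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
        runs[j][1] += runs[i][1]
        del runs[i]
        coalesced: list[list] = []
        for lv, ln in runs:
            if coalesced and coalesced[-1][0] == lv:
                coalesced[-1][1] += ln
            else:
                coalesced.append([lv, ln])
        runs = coalesced
    return [(float(lv), int(ln)) for lv, ln in runs]


def _level_evidence(
    level: float,
    sl: slice,
    level_values: np.ndarray,
    comp_scores: np.ndarray,
    comp_counts: np.ndarray | None,
    baselines: np.ndarray | None,
) -> float:
    """Total log-evidence that the bins in ``sl`` sit at ``level``."""
    if comp_counts is not None and baselines is not None:
        b = max(float(baselines[level_values == level][0]), 1e-6)
        x = comp_counts[sl].astype(float)
        return float((x * np.log(b) - b).sum())
    s = comp_scores[sl]
    return float(-((s - level) ** 2).sum())


def _unit_evidence(
    u: float,
    v: float,
    level_values: np.ndarray,
    baselines: np.ndarray | None,
) -> float:
    """Noiseless per-bin evidence separating levels u and v (Poisson KL on
    counts when baselines are known, squared level gap on scores)."""
    if baselines is not None:
        bu = max(float(baselines[level_values == u][0]), 1e-6)
        bv = max(float(baselines[level_values == v][0]), 1e-6)
        return abs(bv * math.log(bv / bu) - (bv - bu))
    return (u - v) ** 2


def _reassign_run_levels(
    runs: list[tuple[float, int]],
    level_values: np.ndarray,
    comp_scores: np.ndarray,
    comp_counts: np.ndarray | None,
    baselines: np.ndarray | None,
) -> list[tuple[float, int]]:
    """Re-estimate each run's level from its own data and coalesce.

    With raw counts available, the level maximizing the per-bin Poisson
    log-likelihood of the run's mean count against the model baselines is
    chosen; this suppresses runs created by ratio noise (low control counts)
    whose read counts do not actually support a different copy level.  Without
    counts, the run's mean score is quantized instead.
    """
    out: list[list] = []
    start = 0
    for level, length in runs:
        if comp_counts is not None and baselines is not None:
            mean_count = float(comp_counts[start:start + length].mean())
            loglik = mean_count * np.log(baselines) - baselines
            new_level = float(level_values[int(np.argmax(loglik))])
        else:
            mean_score = float(comp_scores[start:start + length].mean())
            new_level = float(
                level_values[int(np.argmin(np.abs(level_values - mean_score)))]
            )
        start += length
        if out and out[-1][0] == new_level:
            out[-1][1] += length
        else:
            out.append([new_level, length])
    return [(lv, ln) for lv, ln in out]


def _margin_merge(
    runs: list[tuple[float, int]],
    level_values: np.ndarray,
    comp_scores: np.ndarray,
    comp_counts: np.ndarray | None,
    baselines: np.ndarray | None,
    merge_margin: float,
) -> list[tuple[float, int]]:
    """Absorb runs whose data do not support their level decisively.

    A run survives only if its total evidence exceeds the evidence under the
    best neighboring level by at least ``merge_margin`` noiseless bins'
    worth; otherwise it is merged into that neighbor.  This removes short
    runs created by chance count fluctuations while keeping any genuine
    feature a few bins wide.
    """
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        starts = np.concatenate([[0], np.cumsum([ln for _, ln in runs])])
        weakest: tuple[float, int, float] | None = None  # (margin, index, level)
        for i, (level, _length) in enumerate(runs):
            sl = slice(int(starts[i]), int(starts[i + 1]))
            own = _level_evidence(
                level, sl, level_values, comp_scores, comp_counts, baselines
            )
            neighbor_levels = {
                runs[j][0] for j in (i - 1, i + 1) if 0 <= j < len(runs)
            } - {level}
            for v in neighbor_levels:
                alt = _level_evidence(
                    v, sl, level_values, comp_scores, comp_counts, baselines
                )
                unit = _unit_evidence(level, v, level_values, baselines)
                margin = (own - alt) - merge_margin * unit
                if weakest is None or margin < weakest[0]:
                    weakest = (margin, i, v)
        if weakest is None or weakest[0] >= 0:
            break
        _, i, v = weakest
        runs[i][0] = v
        coalesced: list[list] = []
        for lv, ln in runs:
            if coalesced and coalesced[-1][0] == lv:
                coalesced[-1][1] += ln
            else:
                coalesced.append([lv, ln])
        runs = coalesced
    return [(float(lv), int(ln)) for lv, ln in runs]


def _refine_boundaries(
    runs: list[tuple[float, int]],
    level_values: np.ndarray,
    comp_scores: np.ndarray,
    comp_counts: np.ndarray | None,
    baselines: np.ndarray | None,
    idx: np.ndarray,
    refine_window: int,
    gap_margin: float = 0.8,
) -> list[int]:
    """Maximum-likelihood relocation of each run boundary.

    For the boundary between levels u (left) and v (right), candidate
    positions within ``refine_window`` unmasked bins of the coarse boundary
    (and inside the two adjacent runs) are scored by the per-bin evidence of
    belonging to the left side — Poisson log-likelihood on raw counts when
    available, squared-error on scores otherwise — and the prefix-sum argmax
    is taken.

    Candidates that sit at the far edge of a masked gap (the first unmasked
    bin after it) receive a bonus of ``gap_margin`` noiseless bins of
    evidence: a masked region (e.g. a centromere repeat array) is a far more
    plausible location for a structural boundary than any single flanking
    bin, and without the bonus one noisy bin next to the gap would relocate
    the boundary by the entire gap width.  The bonus is below one noiseless
    bin of evidence, so exact data are never overridden.

    Returns boundary positions in compressed (unmasked) indices.
    """
    starts = np.concatenate([[0], np.cumsum([ln for _, ln in runs])])
    bounds: list[int] = []
    prev = 0
    for j in range(1, len(runs)):
        b0 = int(starts[j])
        u, v = runs[j - 1][0], runs[j][0]
        lo = max(b0 - refine_window, int(starts[j - 1]) + 1, prev + 1)
        hi = min(b0 + refine_window, int(starts[j + 1]) - 1)
        if hi < lo:
            bounds.append(b0)
            prev = b0
            continue
        if comp_counts is not None and baselines is not None:
            bu = max(float(baselines[level_values == u][0]), 1e-6)
            bv = max(float(baselines[level_values == v][0]), 1e-6)
            x = comp_counts[lo : hi + 1].astype(float)
            evidence = x * np.log(bu / bv) - (bu - bv)
        else:
            s = comp_scores[lo : hi + 1]
            evidence = (s - v) ** 2 - (s - u) ** 2
        objective = np.concatenate([[0.0], np.cumsum(evidence)])
        candidates = np.arange(lo, hi + 2)
        at_gap_edge = (candidates > 0) & (candidates < len(idx))
        gap_sizes = np.where(
            at_gap_edge, np.diff(idx)[np.clip(candidates - 1, 0, len(idx) - 2)], 1
        )
        bonus = gap_margin * _unit_evidence(u, v, level_values, baselines)
        objective = objective + np.where(gap_sizes > 1, bonus, 0.0)
        refined = lo + int(np.argmax(objective))
        bounds.append(refined)
        prev = refined
    return bounds


def segment_score_track(
    score_track: ScoreTrack,
    genome: GenomeModel,
    smoothing_window: int = 15,
    min_run: int = 3,
    refine_window: int = 25,
    merge_margin: float = 5.0,
) -> list[SegmentCall]:
    """Segment each chromosome of a score track into constant-level calls.

    Stages, all deterministic:

    1. unmasked scores are median-smoothed (centered window over the unmasked
       subsequence) and quantized to the nearest level in
       ``{k / control_copies : k = 0..control_copies + 1}``;
    2. runs shorter than ``min_run`` bins are merged into neighbors;
    3. each run's level is re-estimated from its raw read counts (Poisson
       likelihood against model baselines derived from the sample's
       reference-chromosome depth) when the track carries them, removing
       runs created purely by control-denominator noise; runs whose evidence
       does not beat the best neighboring level by ``merge_margin`` noiseless
       bins are absorbed;
    4. every remaining boundary is relocated by a local maximum-likelihood
       changepoint search within ``refine_window`` unmasked bins.

    Masked bins are bridged: a segment extends through them until the first
    unmasked bin of a different level, where the boundary is placed.  Fully
    masked chromosomes yield no segments.
    """
    if smoothing_window < 1 or min_run < 1:
        raise ValueError("smoothing_window and min_run must be >= 1")
    ref_chrom = (
        genome[score_track.reference_chromosome]
        if score_track.reference_chromosome in genome
        else None
    )
    segments: list[SegmentCall] = []
    for chrom in genome:
        scores = score_track.scores.get(chrom.name)
        if scores is None:
            continue
        unmasked = ~np.isnan(scores)
        if not unmasked.any():
            continue
        idx = np.flatnonzero(unmasked)
        comp_scores = scores[idx]
        smoothed = (
            pd.Series(comp_scores)
            .rolling(smoothing_window, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        cc = chrom.control_copies
        level_values = np.arange(cc + 2) / cc
        quantized = level_values[
            np.argmin(np.abs(smoothed[:, None] - level_values[None, :]), axis=1)
        ]
        comp_counts = None
        baselines = None
        if (
            score_track.sample_counts is not None
            and chrom.name in score_track.sample_counts
            and score_track.sample_ref_mean is not None
            and ref_chrom is not None
        ):
            comp_counts = score_track.sample_counts[chrom.name][idx]
            depth_per_copy = score_track.sample_ref_mean / ref_chrom.control_copies
            baselines = np.maximum(level_values * cc * depth_per_copy, 1e-6)
        runs = _merge_short_runs(quantized, min_run)
        runs = _reassign_run_levels(runs, level_values, comp_scores, comp_counts, baselines)
        runs = _margin_merge(
            runs, level_values, comp_scores, comp_counts, baselines, merge_margin
        )
        comp_bounds = _refine_boundaries(
            runs, level_values, comp_scores, comp_counts, baselines, idx, refine_window
        )
        bounds_bp = (
            [0]
            + [int(idx[b]) * score_track.bin_size for b in comp_bounds]
            + [chrom.length]
        )
        for (level, _ln), start, end in zip(runs, bounds_bp[:-1], bounds_bp[1:]):
            b0 = start // score_track.bin_size
            b1 = math.ceil(end / score_track.bin_size)
            seg_scores = scores[b0:b1]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                mean = float(np.nanmean(seg_scores))
            segments.append(
                SegmentCall(
                    chromosome=chrom.name,
                    start=start,
                    end=end,
                    mean_score=mean,
                    level=level,
                    copies=int(round(level * cc)),
                )
            )
    return segments


def detect_mini_segment(
    segments: Sequence[SegmentCall],
    chromosome: str = "chr2",
    centromere: tuple[int, int] | None = None,
) -> SegmentCall | None:
    """Find the mini-chromosome: the interior segment whose level is strictly
    above both flanking levels, nearest the centromere if several qualify."""
    segs = sorted(
        (s for s in segments if s.chromosome == chromosome), key=lambda s: s.start
    )
    candidates = [
        segs[i]
        for i in range(1, len(segs) - 1)
        if segs[i].level > segs[i - 1].level and segs[i].level > segs[i + 1].level
    ]
    if not candidates:
        return None
    if centromere is not None and len(candidates) > 1:
        mid = 0.5 * (centromere[0] + centromere[1])
        candidates.sort(key=lambda s: abs(0.5 * (s.start + s.end) - mid))
    return candidates[0]


def _level_per_bin(
    segments: Sequence[SegmentCall], chrom_name: str, nbins: int, bin_size: int
) -> np.ndarray | None:
    levels = np.full(nbins, np.nan)
    for seg in segments:
        if seg.chromosome != chrom_name:
            continue
        b0 = seg.start // bin_size
        b1 = min(math.ceil(seg.end / bin_size), nbins)
        levels[b0:b1] = seg.level
    if np.isnan(levels).all():
        return None
    return levels


def compare_strains(
    score_a: ScoreTrack,
    score_b: ScoreTrack,
    genome: GenomeModel,
    smoothing_window: int = 15,
    min_run: int = 3,
    refine_window: int = 25,
    merge_margin: float = 5.0,
) -> list[DifferentialRegion]:
    """Maximal intervals on which the quantized copy levels of two strains
    differ, from independent segmentation of both score tracks."""
    _check_same_binning(score_a, score_b, score_a.scores, score_b.scores)
    segs_a = segment_score_track(
        score_a, genome, smoothing_window, min_run, refine_window, merge_margin
    )
    segs_b = segment_score_track(
        score_b, genome, smoothing_window, min_run, refine_window, merge_margin
    )
    regions: list[DifferentialRegion] = []
    for chrom in genome:
        if chrom.name not in score_a.scores:
            continue
        nbins = len(score_a.scores[chrom.name])
        la = _level_per_bin(segs_a, chrom.name, nbins, score_a.bin_size)
        lb = _level_per_bin(segs_b, chrom.name, nbins, score_b.bin_size)
        if la is None or lb is None:
            continue
        differ = la != lb
        i = 0
        while i < nbins:
            if not differ[i]:
                i += 1
                continue
            j = i
            while j < nbins and differ[j] and la[j] == la[i] and lb[j] == lb[i]:
                j += 1
            regions.append(
                DifferentialRegion(
                    chromosome=chrom.name,
                    start=i * score_a.bin_size,
                    end=min(j * score_a.bin_size, chrom.length),
                    level_a=float(la[i]),
                    level_b=float(lb[i]),
                )
            )
            i = j
    return regions


# ---------------------------------------------------------------------------
# sklearn-style pipeline front end

class CopyNumberCaller(BaseEstimator):
    """End-to-end copy-number caller over binned coverage of a sample strain
    and a control strain.

    ``fit(sample_track, control_track)`` runs reference-chromosome
    normalization, control normalization, segmentation, whole-chromosome copy
    estimation and mini-chromosome detection; results are exposed as fitted
    attributes (``score_track_``, ``segments_``, ``copy_table_``,
    ``mini_segment_``).
    """

    def __init__(
        self,
        genome: GenomeModel | None = None,
        reference_chromosome: str = "chr1",
        control_floor: float = 0.1,
        smoothing_window: int = 15,
        min_run: int = 3,
        refine_window: int = 25,
        merge_margin: float = 5.0,
        mini_chromosome: str = "chr2",
    ):
        self.genome = genome
        self.reference_chromosome = reference_chromosome
        self.control_floor = control_floor
        self.smoothing_window = smoothing_window
        self.min_run = min_run
        self.refine_window = refine_window
        self.merge_margin = merge_margin
        self.mini_chromosome = mini_chromosome

    def fit(self, X, y=None):
        """Fit on ``(sample_track, control_track)``; the control may also be
        passed as ``y``."""
        if y is not None:
            sample, control = X, y
        else:
            sample, control = X
        genome = self.genome if self.genome is not None else build_dt40_genome()
        self.genome_ = genome
        sample_ratio = normalize_to_reference_chrom(sample, self.reference_chromosome)
        control_ratio = normalize_to_reference_chrom(control, self.reference_chromosome)
        self.score_track_ = normalize_to_control(
            sample_ratio, control_ratio, self.control_floor
        )
        self.segments_ = segment_score_track(
            self.score_track_, genome, self.smoothing_window, self.min_run,
            self.refine_window, self.merge_margin,
        )
        self.copy_table_ = chromosome_copy_table(self.score_track_, genome)
        centromere = (
            genome[self.mini_chromosome].centromere
            if self.mini_chromosome in genome
            else None
        )
        self.mini_segment_ = detect_mini_segment(
            self.segments_, self.mini_chromosome, centromere
        )
        return self


# ---------------------------------------------------------------------------
# Plain-text IO

def write_counts_tsv(track: BinnedCoverageTrack, path) -> None:
    """Write a binned count track as TSV (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write(f"# strain={track.strain}\tbin_size={track.bin_size}\n")
        fh.write("chrom\tstart\tend\tcount\n")
        for chrom, counts in track.counts.items():
            bs = track.bin_size
            for i, c in enumerate(counts):
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{int(c)}\n")


def read_counts_tsv(path) -> BinnedCoverageTrack:
    """Read a binned count track written by :func:`write_counts_tsv`."""
    strain = "sample"
    bin_size: int | None = None
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, value = token.partition("=")
                        if key == "strain":
                            strain = value
                        elif key == "bin_size":
                            bin_size = int(value)
                continue
            fields = line.split("\t")
            if fields[0] == "chrom":
                continue
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns, got {len(fields)}")
            try:
                chrom, start, end, count = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if count < 0:
                raise ParseError(f"{path}: line {lineno}: negative count")
            if bin_size is None:
                bin_size = end - start
            bins = per_chrom.setdefault(chrom, [])
            if start != len(bins) * bin_size:
                raise ParseError(
                    f"{path}: line {lineno}: non-contiguous bin start {start} for {chrom}"
                )
            bins.append(count)
    if bin_size is None or not per_chrom:
        raise ParseError(f"{path}: no data lines found")
    return BinnedCoverageTrack(
        strain=strain,
        bin_size=bin_size,
        counts={chrom: np.asarray(v, dtype=np.int64) for chrom, v in per_chrom.items()},
    )


def write_score_bedgraph(score_track: ScoreTrack, path) -> None:
    """Write unmasked score bins as bedGraph; masked bins are omitted."""
    bs = score_track.bin_size
    with open(path, "w") as fh:
        for chrom, scores in score_track.scores.items():
            for i, s in enumerate(scores):
                if not np.isnan(s):
                    fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{s:.6g}\n")


def write_segments_bed(segments: Sequence[SegmentCall], path) -> None:
    """Write segment calls as BED4 with the quantized level as the name."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chromosome}\t{seg.start}\t{seg.end}\t{seg.level:.6g}\n")


def write_read_positions_bed(positions, chromosome: str, path) -> None:
    """Write read start positions as single-base BED intervals."""
    with open(path, "w") as fh:
        for p in np.asarray(positions, dtype=np.int64):
            fh.write(f"{chromosome}\t{p}\t{p + 1}\n")


def read_read_positions_bed(path) -> dict[str, np.ndarray]:
    """Read single-base BED intervals back into per-chromosome position arrays."""
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                per_chrom.setdefault(fields[0], []).append(int(fields[1]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return {chrom: np.asarray(v, dtype=np.int64) for chrom, v in per_chrom.items()}
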