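"""Targeted-panel sequencing performance metrics.

Covers the capture-design comparison statistics: fold-80 base penalty
(coverage uniformity; 1 is perfectly uniform), fraction of target bases at
>= 20x / 30x, duplicate and on-target read fractions, and the
commonly-uncovered-exon rule — flag coding exons covered less than 50% in at
least 95% of the batch samples. "Covered" means per-base depth >= 20 by
default; the depth floor is configurable since it is an interpretation, not
a universal constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import GenomicInterval, norm_chrom


@dataclass
class QcMetrics:
    sample_id: str
    total_reads: int = 0
    duplicate_fraction: float | None = None
    on_target_fraction: float | None = None
    mean_depth: float | None = None
    fold80: float | None = None
    pct_ge_20x: float | None = None
    pct_ge_30x: float | None = None
    flags: set[str] = field(default_factory=set)


@dataclass
class ExonCoverageSummary:
    exon: GenomicInterval
    covered_fraction: dict[str, float]
    flag_common_uncovered: bool
    n_samples_below: int = 0


class DepthTrack:
    """Run-length encoded per-base depth over one sample's targets.

    Built from 4-column BED-like rows (chrom, start0, end0, depth),
    mosdepth-style. Queries return one depth per base of a 1-based inclusive
    interval; bases outside every run raise, since an exon outside the track
    bounds cannot be assessed.
    """

    def __init__(self, runs: list[tuple[str, int, int, int]]):
        self.by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, start0, end0, depth in runs:
            if end0 <= start0:
                raise ValueError(f"empty depth run {chrom}:{start0}-{end0}")
            if depth < 0:
                raise ValueError("negative depth in track")
            self.by_chrom.setdefault(norm_chrom(chrom), []).append(
                (start0, end0, depth)
            )
        for c in self.by_chrom:
            self.by_chrom[c].sort()

    @classmethod
    def read(cls, path: str | Path) -> "DepthTrack":
        runs = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                chrom, s, e, d = line.split("\t")[:4]
                runs.append((chrom, int(s), int(e), int(d)))
        return cls(runs)

    def depths(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base depths over a 1-based inclusive interval."""
        runs = self.by_chrom.get(norm_chrom(interval.chrom))
        if runs is None:
            raise KeyError(
                f"interval {interval.label or interval.chrom} outside depth track"
            )
        want0, want1 = interval.start - 1, interval.end  # 0-based half-open
        out = np.full(want1 - want0, -1, dtype=int)
        for start0, end0, depth in runs:
            lo, hi = max(start0, want0), min(end0, want1)
            if lo < hi:
                out[lo - want0 : hi - want0] = depth
        if (out < 0).any():
            raise KeyError(
                f"interval {interval.label or interval.chrom}:"
                f"{interval.start}-{interval.end} not fully inside depth track"
            )
        return out

    def all_depths(self) -> np.ndarray:
        """Concatenated per-base depths over every run (the full target set)."""
        parts = [
            np.full(e - s, d, dtype=int)
            for runs in self.by_chrom.values()
            for (s, e, d) in runs
        ]
        return np.concatenate(parts) if parts else np.array([], dtype=int)


def fold80_base_penalty(per_base_depths) -> float | None:
    """Mean target depth divided by the 20th percentile of per-base depth.

    1.0 indicates perfectly uniform coverage; larger values mean a larger
    fraction of bases must be over-sequenced to lift the low tail. Undefined
    (None) when the 20th percentile is 0, i.e. when >= 20% of bases have no
    coverage at all. Percentile uses linear interpolation between closest
    ranks so the statistic is bit-reproducible.
    """
    d = np.asarray(per_base_depths, dtype=float)
    if d.size == 0:
        raise ValueError("fold80 needs a non-empty depth list")
    p20 = float(np.percentile(d, 20, method="linear"))
    if p20 == 0:
        return None
    return float(d.mean() / p20)


def coverage_fractions(per_base_depths, thresholds) -> dict[int, float]:
    """Fraction of target bases at or above each depth threshold."""
    d = np.asarray(per_base_depths, dtype=float)
    if d.size == 0:
        raise ValueError("coverage_fractions needs a non-empty depth list")
    return {int(t): float((d >= t).mean()) for t in thresholds}


def read_summary_metrics(
    sample_id: str, total_reads: int, duplicates: int, on_target: int
) -> QcMetrics:
    """Duplicate and on-target fractions from read counts."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if duplicates > total_reads or on_target > total_reads:
        raise ValueError("duplicates/on-target counts exceed total reads")
    if min(duplicates, on_target) < 0:
        raise ValueError("negative read counts")
    return QcMetrics(
        sample_id=sample_id,
        total_reads=total_reads,
        duplicate_fraction=duplicates / total_reads,
        on_target_fraction=on_target / total_reads,
    )


def sample_qc(
    sample_id: str,
    track: DepthTrack,
    total_reads: int | None = None,
    duplicates: int | None = None,
    on_target: int | None = None,
) -> QcMetrics:
    """Full per-sample QC row from a depth track plus optional read counts."""
    depths = track.all_depths()
    m = (
        read_summary_metrics(sample_id, total_reads, duplicates, on_target)
        if total_reads is not None
        else QcMetrics(sample_id=sample_id)
    )
    m.mean_depth = float(depths.mean())
    m.fold80 = fold80_base_penalty(depths)
    if m.fold80 is None:
        m.flags.add("FOLD80_UNDEFINED")
    frac = coverage_fractions(depths, [20, 30])
    m.pct_ge_20x = frac[20]
    m.pct_ge_30x = frac[30]
    return m


def find_common_uncovered_exons(
    exons: list[GenomicInterval],
    tracks: dict[str, DepthTrack],
    min_depth: int = 20,
    cover_frac_max: float = 0.5,
    sample_frac_min: float = 0.95,
) -> list[ExonCoverageSummary]:
    """Flag exons systematically missed by the capture across a batch.

    An exon is flagged when its covered fraction (bases at >= ``min_depth``)
    is strictly below ``cover_frac_max`` in at least ``sample_frac_min`` of
    the samples. The sample-proportion comparison is >= and the coverage
    comparison strict <, so an exon covered exactly 50% everywhere is never
    flagged.
    """
    if not tracks:
        raise ValueError("need >= 1 sample depth track")
    out: list[ExonCoverageSummary] = []
    n = len(tracks)
    for exon in exons:
        fractions = {
            sid: float((t.depths(exon) >= min_depth).mean())
            for sid, t in sorted(tracks.items())
        }
        below = sum(1 for f in fractions.values() if f < cover_frac_max)
        out.append(
            ExonCoverageSummary(
                exon=exon,
                covered_fraction=fractions,
                n_samples_below=below,
                flag_common_uncovered=(below / n) >= sample_frac_min,
            )
        )
    return out
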