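"""Per-sample copy-number feature distributions.

Six features summarize a filtered segmentation profile:

1. ``bkpt_per_10mb``   — CN breakpoints per 10 Mb window (counts, zeros kept)
2. ``segment_cn``      — absolute total copy number per segment
3. ``cn_jump``         — |CN difference| between adjacent segments
4. ``bkpt_per_arm``    — CN breakpoints per chromosome arm (zeros kept)
5. ``oscillation_len`` — lengths of oscillating CN segment chains
6. ``segment_size``    — segment length in bp

A CN breakpoint is the junction between two adjacent segments of one
chromosome with different total CN; its position is the start of the
right-hand segment.  Windows and arms with no breakpoints, and chromosomes
with no oscillating chain, contribute explicit zeros so that downstream
mixture fitting sees the zero mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import GenomeAssets, Segment, SegmentProfile

__all__ = [
    "FEATURE_NAMES",
    "CnFeatureValues",
    "breakpoints_per_10mb",
    "segment_cn_values",
    "cn_jumps",
    "breakpoints_per_arm",
    "oscillation_chain_lengths",
    "segment_sizes",
    "extract_features",
]

FEATURE_NAMES = (
    "bkpt_per_10mb",
    "segment_cn",
    "cn_jump",
    "bkpt_per_arm",
    "oscillation_len",
    "segment_size",
)

WINDOW_BP = 10_000_000


@dataclass
class CnFeatureValues:
    """The six per-sample feature value multisets (plain lists)."""

    sample_id: str
    values: dict[str, list[int]] = field(default_factory=dict)

    def __getitem__(self, feature: str) -> list[int]:
        return self.values[feature]


def _junction_positions(segs: Sequence[Segment]) -> list[int]:
    """Positions of CN breakpoints between adjacent segments of one chromosome."""
    return [
        segs[i].start
        for i in range(1, len(segs))
        if segs[i].total_cn != segs[i - 1].total_cn
    ]


def breakpoints_per_10mb(
    profile: SegmentProfile, assets: GenomeAssets, window_bp: int = WINDOW_BP
) -> list[int]:
    """Breakpoint counts in consecutive fixed 10 Mb tiles, zeros included.

    Tiles are anchored at position 1 on every included chromosome; the last
    partial tile is kept.  A junction exactly on a tile boundary counts in
    the left tile.
    """
    by_chrom = profile.by_chrom()
    out: list[int] = []
    for chrom in assets.included_chromosomes():
        length = assets.chrom_lengths[chrom]
        n_windows = -(-length // window_bp)
        counts = [0] * n_windows
        for pos in _junction_positions(by_chrom.get(chrom, [])):
            idx = min((pos - 1) // window_bp, n_windows - 1)
            counts[idx] += 1
        out.extend(counts)
    return out


def segment_cn_values(profile: SegmentProfile) -> list[int]:
    """One total-CN value per segment."""
    return [s.total_cn for s in profile.segments]


def cn_jumps(profile: SegmentProfile) -> list[int]:
    """|deltaCN| for each pair of adjacent segments within a chromosome."""
    out: list[int] = []
    for segs in profile.by_chrom().values():
        out.extend(
            abs(segs[i].total_cn - segs[i - 1].total_cn) for i in range(1, len(segs))
        )
    return out


def breakpoints_per_arm(profile: SegmentProfile, assets: GenomeAssets) -> list[int]:
    """Breakpoint counts per chromosome arm, zeros included.

    The arm split is the centromere interval; junctions falling inside the
    interval belong to neither arm and are dropped.
    """
    by_chrom = profile.by_chrom()
    out: list[int] = []
    for chrom in assets.included_chromosomes():
        cen_start, cen_end = assets.centromeres[chrom]
        p = q = 0
        for pos in _junction_positions(by_chrom.get(chrom, [])):
            if pos < cen_start:
                p += 1
            elif pos > cen_end:
                q += 1
        out.extend([p, q])
    return out


def _alternating_runs(cn: Sequence[int]) -> list[int]:
    """Maximal non-overlapping runs (>=3 segments) alternating between
    exactly two CN values, scanned left to right."""
    runs: list[int] = []
    i, n = 0, len(cn)
    while i <= n - 3:
        j = i + 2
        if cn[i + 1] != cn[i] and cn[j] == cn[i]:
            j += 1
            while j < n and cn[j] != cn[j - 1] and cn[j] == cn[j - 2]:
                j += 1
            runs.append(j - i)
            i = j
        else:
            i += 1
    return runs


def oscillation_chain_lengths(
    profile: SegmentProfile, assets: GenomeAssets | None = None
) -> list[int]:
    """Lengths of oscillating CN chains per chromosome; 0 when a chromosome
    has none.  With ``assets`` given, included chromosomes absent from the
    profile also contribute 0."""
    by_chrom = profile.by_chrom()
    chroms = (
        assets.included_chromosomes() if assets is not None else list(by_chrom)
    )
    out: list[int] = []
    for chrom in chroms:
        runs = _alternating_runs([s.total_cn for s in by_chrom.get(chrom, [])])
        out.extend(runs if runs else [0])
    return out


def segment_sizes(profile: SegmentProfile) -> list[int]:
    """Segment length (end - start + 1) per segment."""
    return [s.size for s in profile.segments]


def extract_features(profile: SegmentProfile, assets: GenomeAssets) -> CnFeatureValues:
    """All six feature multisets for one (already filtered) profile."""
    return CnFeatureValues(
        sample_id=profile.sample_id,
        values={
            "bkpt_per_10mb": breakpoints_per_10mb(profile, assets),
            "segment_cn": segment_cn_values(profile),
            "cn_jump": cn_jumps(profile),
            "bkpt_per_arm": breakpoints_per_arm(profile, assets),
            "oscillation_len": oscillation_chain_lengths(profile, assets),
            "segment_size": segment_sizes(profile),
        },
    )
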