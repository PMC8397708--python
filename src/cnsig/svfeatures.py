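"""Structural-variant annotation and the 32-feature SV count matrix.

Each SV breakpoint pair is annotated as clustered or non-clustered, then
tallied by type and, for intra-chromosomal events, by breakend-distance
size bin (1-10 kb, 10-100 kb, 100 kb-1 Mb, 1-10 Mb, >10 Mb).  The column
space is fixed: {clustered, non-clustered} x ({deletion, tandem-duplication,
inversion} x 5 size bins + translocation) = 32 categories.

Clustering follows the piecewise-constant-fit (PCF) criterion of the
rearrangement-signature literature: per chromosome, breakends are pooled
and sorted, each breakend is scored with its mean distance to its
neighbors, the score sequence is segmented by an exact penalized
least-squares fit (on log10 distances), and a breakend is clustered when
its segment's mean inter-breakend distance is at most ``fraction`` (default
0.1) of the sample's genome-wide mean.  A pair is clustered if either
breakend is.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SvBreakpointPair, SvCatalog

__all__ = [
    "SIZE_BIN_LABELS",
    "SV_CATEGORY_LABELS",
    "sv_size_bin",
    "detect_clustered",
    "build_sv_matrix",
    "annotate_pairs",
    "pcf_segments",
]

SIZE_BIN_EDGES = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)
SIZE_BIN_LABELS = ("1-10kb", "10-100kb", "100kb-1Mb", "1-10Mb", ">10Mb")

_TYPE_SHORT = {
    "deletion": "del",
    "tandem-duplication": "dup",
    "inversion": "inv",
    "translocation": "tra",
}


def _category_labels() -> list[str]:
    labels = []
    for clustered in ("clustered", "non-clustered"):
        for sv_type in ("deletion", "tandem-duplication", "inversion"):
            for size in SIZE_BIN_LABELS:
                labels.append(f"{clustered}:{_TYPE_SHORT[sv_type]}:{size}")
        labels.append(f"{clustered}:tra")
    return labels


SV_CATEGORY_LABELS = tuple(_category_labels())
assert len(SV_CATEGORY_LABELS) == 32


def sv_size_bin(pair: SvBreakpointPair) -> str | None:
    """Half-open [low, high) size bin of an intra-chromosomal pair.

    Translocations have no size and return None; a span below 1 kb is
    placed in the smallest bin with a warning.
    """
    span = pair.span
    if span is None:
        return None
    if span < SIZE_BIN_EDGES[0]:
        warnings.warn(f"SV {pair.id}: span {span} bp below 1 kb; using the 1-10kb bin")
        return SIZE_BIN_LABELS[0]
    for i in range(len(SIZE_BIN_EDGES) - 1):
        if SIZE_BIN_EDGES[i] <= span < SIZE_BIN_EDGES[i + 1]:
            return SIZE_BIN_LABELS[i]
    return SIZE_BIN_LABELS[-1]


# ---------------------------------------------------------------------------
# piecewise-constant segmentation (exact DP, O(n^2))


def pcf_segments(values: np.ndarray, gamma: float) -> list[tuple[int, int]]:
    """Exact penalized least-squares segmentation of a 1-D sequence.

    Minimizes sum of within-segment squared deviations + gamma per
    additional segment; returns half-open index intervals.
    """
    n = len(values)
    if n == 0:
        return []
    v = np.asarray(values, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csum2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def sse(i: int, j: int) -> float:  # cost of segment [i, j)
        s = csum[j] - csum[i]
        s2 = csum2[j] - csum2[i]
        return s2 - s * s / (j - i)

    best = np.full(n + 1, np.inf)
    best[0] = -gamma  # first segment carries no penalty
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + sse(i, j) + gamma
            if c < best[j]:
                best[j] = c
                back[j] = i
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j))
        j = i
    return bounds[::-1]


def detect_clustered(
    catalog: SvCatalog, gamma: float = 25.0, fraction: float = 0.1
) -> dict[str, bool]:
    """Flag each pair as clustered/non-clustered (see module docstring).

    Chromosomes with fewer than 2 breakends are entirely non-clustered, as
    is a catalog with a single SV.  Deterministic; invariant to pair-id
    relabeling and to whole-genome coordinate translation.
    """
    flags = {p.id: False for p in catalog.pairs}
    if len(catalog.pairs) < 2:
        return flags

    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for p in catalog.pairs:
        for chrom, pos in p.breakends():
            by_chrom.setdefault(chrom, []).append((pos, p.id))

    all_gaps: list[np.ndarray] = []
    prepared = {}
    for chrom, ends in by_chrom.items():
        ends.sort()
        pos = np.array([e[0] for e in ends], dtype=float)
        gaps = np.diff(pos)
        prepared[chrom] = (ends, gaps)
        if len(gaps):
            all_gaps.append(gaps)
    if not all_gaps:
        return flags
    genome_mean = float(np.concatenate(all_gaps).mean())
    if genome_mean <= 0:
        return flags
    threshold = fraction * genome_mean

    for chrom, (ends, gaps) in prepared.items():
        if len(ends) < 2:
            continue
        # per-breakend inter-rearrangement distance: mean of flanking gaps
        d = np.empty(len(ends))
        d[0], d[-1] = gaps[0], gaps[-1]
        for i in range(1, len(ends) - 1):
            d[i] = 0.5 * (gaps[i - 1] + gaps[i])
        logd = np.log10(np.maximum(d, 1.0))
        for i0, i1 in pcf_segments(logd, gamma):
            if float(d[i0:i1].mean()) <= threshold:
                for _, pid in ends[i0:i1]:
                    flags[pid] = True
    return flags


# ---------------------------------------------------------------------------
# matrix construction


def annotate_pairs(
    catalog: SvCatalog, gamma: float = 25.0, fraction: float = 0.1
) -> pd.DataFrame:
    """Per-pair annotation table: id, type, size bin, clustered flag, category."""
    flags = catalog.clustered or detect_clustered(catalog, gamma=gamma, fraction=fraction)
    rows = []
    for p in catalog.pairs:
        clustered = bool(flags.get(p.id, False))
        prefix = "clustered" if clustered else "non-clustered"
        size = sv_size_bin(p)
        category = (
            f"{prefix}:tra"
            if p.sv_type == "translocation"
            else f"{prefix}:{_TYPE_SHORT[p.sv_type]}:{size}"
        )
        rows.append(
            {
                "sample": catalog.sample_id,
                "id": p.id,
                "sv_type": p.sv_type,
                "size_bin": size or "",
                "clustered": int(clustered),
                "category": category,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "id", "sv_type", "size_bin", "clustered", "category"]
    )


def build_sv_matrix(
    cohort: Sequence[SvCatalog], gamma: float = 25.0, fraction: float = 0.1
) -> pd.DataFrame:
    """Samples x 32 SV-category count matrix (row sum = catalog size)."""
    rows = {}
    for catalog in cohort:
        counts = pd.Series(0, index=list(SV_CATEGORY_LABELS), dtype=int)
        ann = annotate_pairs(catalog, gamma=gamma, fraction=fraction)
        if len(ann):
            for cat, n in ann["category"].value_counts().items():
                counts[cat] += int(n)
        rows[catalog.sample_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index")[list(SV_CATEGORY_LABELS)]
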