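"""Breakpoint-interconnection graph and complex structural event classes.

SV pairs are nodes; two pairs are connected when any breakend of one lies
within ``link_bp`` (default 1 Mb) of any breakend of the other on the same
chromosome.  Each connected component receives exactly one class, applying
the definitions in strict priority order:

1. chromothripsis — more than 10 interconnected breakpoint pairs with
   oscillating copy number in the component footprint;
2. chromoplexy — breakpoints across more than 2 chromosomes with an
   associated copy-number loss;
3. templated insertion — translocation(s) with a focal copy-number gain
   spanning a translocation breakend (simple when 2 chromosomes are
   involved, complex when more);
4. complex, not otherwise specified — 3 or more interconnected pairs that
   fit none of the above;
5. single — anything smaller.

"Oscillating CN" means a run of at least ``min_osc`` (default 6)
consecutive segments in the footprint in which every adjacent pair differs
and at most ``max_osc_states`` (default 3) distinct copy-number values
occur.  "CN loss" means a member breakend abuts a segment below the
chromosome's length-weighted modal copy number; a "focal gain" is a
segment above the modal CN, no longer than ``focal_gain_max_bp`` (default
5 Mb), containing a translocation breakend.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import Segment, SegmentProfile, SvBreakpointPair, SvCatalog

__all__ = [
    "EventConfig",
    "ComplexEventCall",
    "build_event_graph",
    "oscillating_cn_in_footprint",
    "classify_components",
    "sample_has_chromothripsis",
    "calls_to_frame",
]

EVENT_CLASSES = (
    "chromothripsis",
    "chromoplexy",
    "templated_insertion_simple",
    "templated_insertion_complex",
    "complex_nos",
    "single",
)


@dataclass(frozen=True)
class EventConfig:
    link_bp: int = 1_000_000
    min_osc: int = 6
    max_osc_states: int = 3
    focal_gain_max_bp: int = 5_000_000
    min_chromothripsis_pairs: int = 11  # "more than 10"


@dataclass
class ComplexEventCall:
    sample_id: str
    event_id: str
    event_class: str
    member_ids: list[str]
    chromosomes: list[str]
    n_pairs: int
    oscillating_cn: bool
    cn_loss_associated: bool
    focal_gain_associated: bool


# ---------------------------------------------------------------------------
# interconnection graph


class _DisjointSet:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_event_graph(
    catalog: SvCatalog, config: EventConfig = EventConfig()
) -> list[list[SvBreakpointPair]]:
    """Connected components of the breakpoint-interconnection graph.

    Linking consecutive same-chromosome breakends within ``link_bp`` yields
    exactly the connected components of the full pairwise graph (any two
    breakends within range have only in-range consecutive steps between
    them).  Components are ordered deterministically by their smallest
    member id.
    """
    pairs = catalog.pairs
    if not pairs:
        return []
    dsu = _DisjointSet([p.id for p in pairs])
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for p in pairs:
        for chrom, pos in p.breakends():
            by_chrom.setdefault(chrom, []).append((pos, p.id))
    for ends in by_chrom.values():
        ends.sort()
        for (pos_a, id_a), (pos_b, id_b) in zip(ends, ends[1:]):
            if pos_b - pos_a <= config.link_bp:
                dsu.union(id_a, id_b)
    groups: dict[str, list[SvBreakpointPair]] = {}
    for p in pairs:
        groups.setdefault(dsu.find(p.id), []).append(p)
    components = [sorted(g, key=lambda p: p.id) for g in groups.values()]
    components.sort(key=lambda g: g[0].id)
    return components


# ---------------------------------------------------------------------------
# copy-number context


def _modal_cn(segs: Sequence[Segment]) -> int:
    """Length-weighted modal total CN of one chromosome (2 if empty)."""
    if not segs:
        return 2
    weight: Counter = Counter()
    for s in segs:
        weight[s.total_cn] += s.size
    return max(weight.items(), key=lambda kv: (kv[1], -kv[0]))[0]


def _segments_at(segs: Sequence[Segment], pos: int) -> list[Segment]:
    """Segments containing or directly abutting a breakend position."""
    return [s for s in segs if s.start - 1 <= pos <= s.end + 1]


def _footprints(
    component: Sequence[SvBreakpointPair], pad: int
) -> dict[str, tuple[int, int]]:
    spans: dict[str, tuple[int, int]] = {}
    for p in component:
        for chrom, pos in p.breakends():
            lo, hi = spans.get(chrom, (pos, pos))
            spans[chrom] = (min(lo, pos), max(hi, pos))
    return {c: (max(1, lo - pad), hi + pad) for c, (lo, hi) in spans.items()}


def _has_oscillating_window(cn: Sequence[int], min_osc: int, max_states: int) -> bool:
    n = len(cn)
    for i in range(n - min_osc + 1):
        win = cn[i : i + min_osc]
        if all(win[j] != win[j - 1] for j in range(1, min_osc)) and len(set(win)) <= max_states:
            return True
    return False


def oscillating_cn_in_footprint(
    profile: SegmentProfile,
    component: Sequence[SvBreakpointPair],
    config: EventConfig = EventConfig(),
) -> tuple[bool, dict[str, int]]:
    """Whether any chromosome of the component footprint shows an
    oscillating CN run of >= ``min_osc`` segments over <= ``max_osc_states``
    states.  Also returns the longest alternating run length per chromosome."""
    by_chrom = profile.by_chrom()
    longest: dict[str, int] = {}
    found = False
    for chrom, (lo, hi) in _footprints(component, config.link_bp).items():
        segs = [s for s in by_chrom.get(chrom, []) if s.end >= lo and s.start <= hi]
        cn = [s.total_cn for s in segs]
        best = 0
        for length in range(len(cn), 1, -1):
            for i in range(len(cn) - length + 1):
                win = cn[i : i + length]
                if all(win[j] != win[j - 1] for j in range(1, length)) and len(set(win)) <= config.max_osc_states:
                    best = length
                    break
            if best:
                break
        longest[chrom] = best
        if _has_oscillating_window(cn, config.min_osc, config.max_osc_states):
            found = True
    return found, longest


def _cn_loss_associated(
    component: Sequence[SvBreakpointPair],
    by_chrom: dict[str, list[Segment]],
    modal: dict[str, int],
) -> bool:
    for p in component:
        for chrom, pos in p.breakends():
            for s in _segments_at(by_chrom.get(chrom, []), pos):
                if s.total_cn < modal.get(chrom, 2):
                    return True
    return False


def _focal_gain_associated(
    component: Sequence[SvBreakpointPair],
    by_chrom: dict[str, list[Segment]],
    modal: dict[str, int],
    max_bp: int,
) -> bool:
    for p in component:
        if p.sv_type != "translocation":
            continue
        for chrom, pos in p.breakends():
            for s in _segments_at(by_chrom.get(chrom, []), pos):
                if s.total_cn > modal.get(chrom, 2) and s.size <= max_bp:
                    return True
    return False


# ---------------------------------------------------------------------------
# classification


def classify_components(
    catalog: SvCatalog,
    profile: SegmentProfile,
    config: EventConfig = EventConfig(),
) -> list[ComplexEventCall]:
    """Classify every interconnection component of one sample.

    Deterministic and invariant to the input ordering of pairs; every pair
    belongs to exactly one component and every component gets one class.
    """
    by_chrom = profile.by_chrom()
    modal = {c: _modal_cn(segs) for c, segs in by_chrom.items()}
    calls: list[ComplexEventCall] = []
    for idx, component in enumerate(build_event_graph(catalog, config)):
        chroms = sorted({c for p in component for c, _ in p.breakends()})
        n_pairs = len(component)
        osc, _ = oscillating_cn_in_footprint(profile, component, config)
        loss = _cn_loss_associated(component, by_chrom, modal)
        gain = _focal_gain_associated(component, by_chrom, modal, config.focal_gain_max_bp)
        has_tra = any(p.sv_type == "translocation" for p in component)
        if n_pairs >= config.min_chromothripsis_pairs and osc:
            cls = "chromothripsis"
        elif len(chroms) > 2 and loss:
            cls = "chromoplexy"
        elif has_tra and gain:
            cls = (
                "templated_insertion_complex"
                if len(chroms) > 2
                else "templated_insertion_simple"
            )
        elif n_pairs >= 3:
            cls = "complex_nos"
        else:
            cls = "single"
        calls.append(
            ComplexEventCall(
                sample_id=catalog.sample_id,
                event_id=f"{catalog.sample_id}:ev{idx}",
                event_class=cls,
                member_ids=[p.id for p in component],
                chromosomes=chroms,
                n_pairs=n_pairs,
                oscillating_cn=osc,
                cn_loss_associated=loss,
                focal_gain_associated=gain,
            )
        )
    return calls


def sample_has_chromothripsis(calls: Sequence[ComplexEventCall]) -> bool:
    return any(c.event_class == "chromothripsis" for c in calls)


def calls_to_frame(calls: Sequence[ComplexEventCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "event_id": c.event_id,
                "class": c.event_class,
                "n_pairs": c.n_pairs,
                "chromosomes": ",".join(c.chromosomes),
                "oscillating_cn": int(c.oscillating_cn),
                "cn_loss": int(c.cn_loss_associated),
                "focal_gain": int(c.focal_gain_associated),
                "members": ",".join(c.member_ids),
            }
            for c in calls
        ],
        columns=[
            "sample", "event_id", "class", "n_pairs", "chromosomes",
            "oscillating_cn", "cn_loss", "focal_gain", "members",
        ],
    )
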