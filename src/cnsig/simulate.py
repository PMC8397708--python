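"""Synthetic MM-like cohorts with planted complex events and truth labels.

Each simulated sample starts from a baseline karyotype (hyperdiploid with
whole-chromosome trisomies, or structurally quiet diploid), receives
passenger copy-number aberrations and scattered passenger SVs, and — with
configured probabilities — planted complex events:

* chromothripsis: n interconnected breakpoint pairs (n drawn with support
  strictly above 10; the default distribution matches a median of ~24
  breakpoint pairs with IQR roughly 12-35) whose footprint copy number
  oscillates between two adjacent integer states;
* chromoplexy: a ring of balanced translocations across >=3 chromosomes
  with deletion bridges at the junctions;
* templated insertion: translocation(s) with focal gains spanning the
  breakends (simple: 2 chromosomes; complex: 3);
* complex-NOS: 3-9 clustered intra-chromosomal pairs without oscillation.

Planted events and passengers are placed on disjoint chromosomes so the
planted truth is unambiguous; copy number respects a configurable cap
(default 9, the complexity envelope of myeloma genomes) and a 50 kb
segment floor.  Output is byte-identical for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GenomeAssets,
    Segment,
    SegmentProfile,
    SvBreakpointPair,
    SvCatalog,
    ValidationError,
    read_segments,
    read_sv_bedpe,
    write_segments,
    write_sv_bedpe,
)

__all__ = [
    "SimulationConfig",
    "PlantedEvent",
    "SimulatedCohort",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "scenario_presets",
    "coarsen_profile",
]

HYPERDIPLOID_TRISOMIES = ("3", "5", "7", "9", "11", "15", "19", "21")


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 100
    seed: int = 0
    chromothripsis_prevalence: float = 0.24
    chromoplexy_rate: float = 0.10
    templated_insertion_rate: float = 0.12
    complex_nos_rate: float = 0.15
    hyperdiploid_fraction: float = 0.55
    passenger_sv_mean: float = 8.0
    passenger_cna_mean: float = 4.0
    # chromothripsis breakpoint-pair count: clipped log-normal
    ct_pairs_log_mean: float = math.log(24.0)
    ct_pairs_log_sd: float = 0.55
    ct_min_pairs: int = 11
    ct_max_pairs: int = 60
    ct_spacing_min_bp: int = 60_000
    ct_spacing_max_bp: int = 900_000
    max_total_cn: int = 9
    min_seg_bp: int = 50_000
    sample_prefix: str = "SIM"

    def validate(self) -> None:
        if not 0.0 <= self.chromothripsis_prevalence <= 1.0:
            raise ValidationError("prevalence must be in [0, 1]")
        if self.chromothripsis_prevalence > 0 and self.ct_min_pairs <= 10:
            raise ValidationError(
                "chromothripsis pair-count support must exceed 10 pairs"
            )
        if self.ct_spacing_min_bp < self.min_seg_bp:
            raise ValidationError("breakend spacing below the segment-size floor")


@dataclass
class PlantedEvent:
    sample_id: str
    event_class: str
    chromosomes: list[str]
    n_pairs: int
    member_ids: list[str]


@dataclass
class SimulatedCohort:
    profiles: list[SegmentProfile]
    catalogs: list[SvCatalog]
    truth: pd.DataFrame  # index sample; columns chromothripsis, n_events, event_classes
    events: list[PlantedEvent]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# segment editing


def _set_cn(segs: list[list[int]], start: int, end: int, cn: int) -> None:
    """Overwrite [start, end] with copy number cn on a [start, end, cn] list."""
    out = []
    for s, e, c in segs:
        if e < start or s > end:
            out.append([s, e, c])
            continue
        if s < start:
            out.append([s, start - 1, c])
        if e > end:
            out.append([end + 1, e, c])
    out.append([start, end, cn])
    out.sort()
    segs[:] = out


class _SampleBuilder:
    def __init__(self, sample_id: str, assets: GenomeAssets, rng: np.random.Generator,
                 config: SimulationConfig):
        self.sample_id = sample_id
        self.assets = assets
        self.rng = rng
        self.config = config
        self.chrom_segs: dict[str, list[list[int]]] = {}
        self.pairs: list[SvBreakpointPair] = []
        self.used_chroms: set[str] = set()
        self._sv_counter = 0

    def base_cn(self, chrom: str) -> int:
        return self.chrom_segs[chrom][0][2] if len(self.chrom_segs[chrom]) == 1 else 2

    def next_id(self, tag: str) -> str:
        self._sv_counter += 1
        return f"{self.sample_id}_{tag}{self._sv_counter}"

    def free_chroms(self, min_arm_bp: int = 0) -> list[str]:
        out = []
        for chrom in self.assets.included_chromosomes():
            if chrom in self.used_chroms:
                continue
            if min_arm_bp and self._largest_arm(chrom)[1] < min_arm_bp:
                continue
            out.append(chrom)
        return out

    def _arms(self, chrom: str) -> list[tuple[int, int]]:
        cs, ce = self.assets.centromeres[chrom]
        length = self.assets.chrom_lengths[chrom]
        pad = 1_000_000
        arms = []
        if cs - pad > 2 * pad:
            arms.append((pad, cs - pad))
        if length - ce - pad > 2 * pad:
            arms.append((ce + pad, length - pad))
        return arms

    def _largest_arm(self, chrom: str) -> tuple[tuple[int, int], int]:
        arms = self._arms(chrom)
        best = max(arms, key=lambda a: a[1] - a[0])
        return best, best[1] - best[0]

    def _clear_of_mask(self, chrom: str, lo: int, hi: int) -> bool:
        return not any(
            c == chrom and s - 1_000_000 <= hi and e + 1_000_000 >= lo
            for c, s, e in self.assets.ig_mask
        )

    def sample_window(self, chrom: str, span: int) -> tuple[int, int] | None:
        """A [lo, hi] window of the given span on an arm, clear of the Ig mask."""
        arms = [a for a in self._arms(chrom) if a[1] - a[0] > span]
        for _ in range(30):
            if not arms:
                return None
            a = arms[self.rng.integers(0, len(arms))]
            lo = int(self.rng.integers(a[0], a[1] - span))
            if self._clear_of_mask(chrom, lo, lo + span):
                return lo, lo + span
        return None

    def add_pair(self, c1: str, p1: int, c2: str, p2: int, sv_type: str, tag: str) -> str:
        if c1 == c2 and p1 > p2:
            p1, p2 = p2, p1
        strands = self.rng.choice(["+", "-"], size=2)
        pid = self.next_id(tag)
        self.pairs.append(
            SvBreakpointPair(c1, int(p1), str(strands[0]), c2, int(p2), str(strands[1]),
                             sv_type, pid)
        )
        return pid

    # ---- event planting ------------------------------------------------

    def plant_chromothripsis(self) -> PlantedEvent | None:
        cfg = self.config
        n_pairs = int(np.clip(
            round(self.rng.lognormal(cfg.ct_pairs_log_mean, cfg.ct_pairs_log_sd)),
            cfg.ct_min_pairs, cfg.ct_max_pairs,
        ))
        n_bk = 2 * n_pairs
        spacing = self.rng.integers(cfg.ct_spacing_min_bp, cfg.ct_spacing_max_bp, n_bk - 1)
        span = int(spacing.sum()) + 2_000_000
        candidates = [c for c in self.free_chroms() if self._largest_arm(c)[1] > span]
        if not candidates:  # shrink spacing to fit the largest free arm
            candidates = self.free_chroms(min_arm_bp=n_bk * (cfg.ct_spacing_min_bp + 10_000))
            if not candidates:
                return None
            chrom = candidates[int(self.rng.integers(0, len(candidates)))]
            arm_span = self._largest_arm(chrom)[1] - 2_000_000
            hi = max(cfg.ct_spacing_min_bp + 1, arm_span // n_bk)
            spacing = self.rng.integers(cfg.ct_spacing_min_bp, hi, n_bk - 1)
            span = int(spacing.sum()) + 2_000_000
        else:
            chrom = candidates[int(self.rng.integers(0, len(candidates)))]
        window = self.sample_window(chrom, span)
        if window is None:
            return None
        lo, _ = window
        positions = lo + 1_000_000 + np.concatenate([[0], np.cumsum(spacing)])
        base = self.base_cn(chrom)
        hi_state = base + 1 if base + 1 <= self.config.max_total_cn else base - 1
        for i in range(len(positions) - 1):
            state = hi_state if i % 2 == 0 else base
            _set_cn(self.chrom_segs[chrom], int(positions[i]), int(positions[i + 1]) - 1, state)
        perm = self.rng.permutation(len(positions))
        ids = []
        for t in range(n_pairs):
            p1, p2 = int(positions[perm[2 * t]]), int(positions[perm[2 * t + 1]])
            sv_type = str(self.rng.choice(["deletion", "tandem-duplication", "inversion"]))
            ids.append(self.add_pair(chrom, p1, chrom, p2, sv_type, "ct"))
        self.used_chroms.add(chrom)
        return PlantedEvent(self.sample_id, "chromothripsis", [chrom], n_pairs, ids)

    def plant_chromoplexy(self) -> PlantedEvent | None:
        m = int(self.rng.integers(3, 6))
        chroms = self.free_chroms(min_arm_bp=10_000_000)
        if len(chroms) < m:
            return None
        picked = list(self.rng.choice(chroms, size=m, replace=False))
        bridges = []
        for chrom in picked:
            brlen = int(self.rng.integers(60_000, 400_000))
            window = self.sample_window(chrom, brlen + 2_000_000)
            if window is None:
                return None
            s = window[0] + 1_000_000
            e = s + brlen
            base = self.base_cn(chrom)
            _set_cn(self.chrom_segs[chrom], s, e - 1, max(base - 1, 0))
            bridges.append((chrom, s, e))
        ids = []
        for t in range(m):
            c1, _, e1 = bridges[t]
            c2, s2, _ = bridges[(t + 1) % m]
            ids.append(self.add_pair(c1, e1, c2, s2, "translocation", "cp"))
        self.used_chroms.update(picked)
        return PlantedEvent(self.sample_id, "chromoplexy", sorted(picked), m, ids)

    def plant_templated_insertion(self, complex_form: bool) -> PlantedEvent | None:
        m = 3 if complex_form else 2
        chroms = self.free_chroms(min_arm_bp=10_000_000)
        if len(chroms) < m:
            return None
        picked = list(self.rng.choice(chroms, size=m, replace=False))
        gains = []
        for chrom in picked:
            glen = int(self.rng.integers(100_000, 800_000))
            window = self.sample_window(chrom, glen + 2_000_000)
            if window is None:
                return None
            s = window[0] + 1_000_000
            e = s + glen
            base = self.base_cn(chrom)
            gain = base + 1 if base + 1 <= self.config.max_total_cn else base
            _set_cn(self.chrom_segs[chrom], s, e, gain)
            gains.append((chrom, s, e))
        ids = []
        if complex_form:
            for t in range(m):
                c1, _, e1 = gains[t]
                c2, s2, _ = gains[(t + 1) % m]
                ids.append(self.add_pair(c1, e1, c2, s2, "translocation", "ti"))
        else:
            (c1, s1, _), (c2, s2, _) = gains
            ids.append(self.add_pair(c1, s1, c2, s2, "translocation", "ti"))
        self.used_chroms.update(picked)
        cls = "templated_insertion_complex" if complex_form else "templated_insertion_simple"
        return PlantedEvent(self.sample_id, cls, sorted(picked), len(ids), ids)

    def plant_complex_nos(self) -> PlantedEvent | None:
        n_pairs = int(self.rng.integers(3, 10))
        n_bk = 2 * n_pairs
        spacing = self.rng.integers(60_000, 400_000, n_bk - 1)
        span = int(spacing.sum()) + 2_000_000
        candidates = [c for c in self.free_chroms() if self._largest_arm(c)[1] > span]
        if not candidates:
            return None
        chrom = candidates[int(self.rng.integers(0, len(candidates)))]
        window = self.sample_window(chrom, span)
        if window is None:
            return None
        positions = window[0] + 1_000_000 + np.concatenate([[0], np.cumsum(spacing)])
        # one focal gain in the middle keeps CN change without oscillation
        base = self.base_cn(chrom)
        gain = base + 1 if base + 1 <= self.config.max_total_cn else base
        mid = len(positions) // 2
        _set_cn(self.chrom_segs[chrom], int(positions[mid - 1]), int(positions[mid]) - 1, gain)
        ids = []
        perm = self.rng.permutation(len(positions))
        for t in range(n_pairs):
            p1, p2 = int(positions[perm[2 * t]]), int(positions[perm[2 * t + 1]])
            ids.append(self.add_pair(chrom, p1, chrom, p2, "inversion", "cx"))
        self.used_chroms.add(chrom)
        return PlantedEvent(self.sample_id, "complex_nos", [chrom], n_pairs, ids)

    # ---- passengers ----------------------------------------------------

    def add_passenger_cnas(self) -> None:
        n = int(self.rng.poisson(self.config.passenger_cna_mean))
        for _ in range(n):
            chroms = self.free_chroms(min_arm_bp=10_000_000)
            if not chroms:
                return
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            length = int(np.clip(self.rng.lognormal(math.log(2e6), 1.2),
                                 self.config.min_seg_bp * 2, 40e6))
            window = self.sample_window(chrom, length)
            if window is None:
                continue
            s = window[0]
            base = self.base_cn(chrom)
            delta = int(self.rng.choice([-1, 1]))
            cn = int(np.clip(base + delta, 0, self.config.max_total_cn))
            _set_cn(self.chrom_segs[chrom], s, s + length, cn)

    def add_passenger_svs(self) -> None:
        n = int(self.rng.poisson(self.config.passenger_sv_mean))
        for _ in range(n):
            chroms = self.free_chroms(min_arm_bp=10_000_000)
            if len(chroms) < 2:
                return
            if self.rng.random() < 0.2:  # translocation
                c1, c2 = self.rng.choice(chroms, size=2, replace=False)
                w1 = self.sample_window(str(c1), 100_000)
                w2 = self.sample_window(str(c2), 100_000)
                if w1 and w2:
                    self.add_pair(str(c1), w1[0], str(c2), w2[0], "translocation", "psv")
            else:
                chrom = str(chroms[int(self.rng.integers(0, len(chroms)))])
                span = int(np.clip(self.rng.lognormal(math.log(5e5), 1.5), 2_000, 30e6))
                window = self.sample_window(chrom, span + 10_000)
                if window:
                    sv_type = str(self.rng.choice(["deletion", "tandem-duplication", "inversion"]))
                    self.add_pair(chrom, window[0], chrom, window[0] + span, sv_type, "psv")

    # ---- assembly ------------------------------------------------------

    def build(self) -> tuple[SegmentProfile, SvCatalog]:
        segs = []
        for chrom in self.assets.included_chromosomes():
            for s, e, c in self.chrom_segs[chrom]:
                segs.append(Segment(chrom, int(s), int(e), int(c), minor_cn=int(c) // 2))
        profile = SegmentProfile(self.sample_id, segs).normalized()
        return profile, SvCatalog(self.sample_id, list(self.pairs))


def simulate_cohort(
    config: SimulationConfig, assets: GenomeAssets | None = None
) -> SimulatedCohort:
    """Generate a cohort per the configuration; fully seed-reproducible."""
    config.validate()
    assets = assets or GenomeAssets.grch37()
    rng = np.random.default_rng(config.seed)
    profiles, catalogs, events = [], [], []
    truth_rows = []
    for i in range(config.n_samples):
        sample_id = f"{config.sample_prefix}{i:04d}"
        b = _SampleBuilder(sample_id, assets, rng, config)
        hyperdiploid = rng.random() < config.hyperdiploid_fraction
        trisomies = set()
        if hyperdiploid:
            k = int(rng.integers(4, 1 + len(HYPERDIPLOID_TRISOMIES)))
            trisomies = set(rng.choice(HYPERDIPLOID_TRISOMIES, size=k, replace=False))
        for chrom in assets.included_chromosomes():
            base = 3 if chrom in trisomies else 2
            b.chrom_segs[chrom] = [[1, assets.chrom_lengths[chrom], base]]
        sample_events: list[PlantedEvent] = []
        if rng.random() < config.chromothripsis_prevalence:
            ev = b.plant_chromothripsis()
            if ev:
                sample_events.append(ev)
        if rng.random() < config.chromoplexy_rate:
            ev = b.plant_chromoplexy()
            if ev:
                sample_events.append(ev)
        if rng.random() < config.templated_insertion_rate:
            ev = b.plant_templated_insertion(complex_form=bool(rng.random() < 0.3))
            if ev:
                sample_events.append(ev)
        if rng.random() < config.complex_nos_rate:
            ev = b.plant_complex_nos()
            if ev:
                sample_events.append(ev)
        b.add_passenger_cnas()
        b.add_passenger_svs()
        profile, catalog = b.build()
        profiles.append(profile)
        catalogs.append(catalog)
        events.extend(sample_events)
        truth_rows.append(
            {
                "sample": sample_id,
                "chromothripsis": int(any(e.event_class == "chromothripsis" for e in sample_events)),
                "n_events": len(sample_events),
                "event_classes": ",".join(sorted(e.event_class for e in sample_events)),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("sample")
    return SimulatedCohort(profiles, catalogs, truth, events, config)


def coarsen_profile(profile: SegmentProfile, floor_bp: int = 100_000,
                    assets: GenomeAssets | None = None) -> SegmentProfile:
    """Emulate lower-resolution (exome-like) segmentation by dissolving CN
    changes shorter than ``floor_bp``."""
    from .io import apply_filters

    assets = assets or GenomeAssets.grch37()
    filtered, _ = apply_filters(profile, None, assets, min_seg_bp=floor_bp)
    return filtered


# ---------------------------------------------------------------------------
# disk round-trip


def write_cohort(cohort: SimulatedCohort, directory: str | Path, force: bool = False) -> None:
    """Write segments.tsv, one BEDPE per sample, and truth.tsv.

    Refuses a non-empty target directory unless ``force``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True)")
    write_segments(cohort.profiles, directory / "segments.tsv")
    for catalog in cohort.catalogs:
        write_sv_bedpe(catalog, directory / f"{catalog.sample_id}.bedpe")
    cohort.truth.to_csv(directory / "truth.tsv", sep="\t")


def read_cohort(directory: str | Path) -> tuple[list[SegmentProfile], list[SvCatalog], pd.DataFrame]:
    directory = Path(directory)
    profiles = read_segments(directory / "segments.tsv")
    catalogs = []
    for bedpe in sorted(directory.glob("*.bedpe")):
        catalogs.extend(read_sv_bedpe(bedpe))
    truth = pd.read_csv(directory / "truth.tsv", sep="\t", index_col="sample")
    truth.index = truth.index.astype(str)
    return profiles, catalogs, truth


def scenario_presets(name: str, n_samples: int = 100, seed: int = 0) -> SimulationConfig:
    """Named study conditions: ``mm_like`` (defaults; total CN capped at 9),
    ``quiet`` (no complex events), ``solid_like`` (higher CN ceiling, larger
    chromothripsis events, hence longer oscillation chains)."""
    if name == "mm_like":
        return SimulationConfig(n_samples=n_samples, seed=seed)
    if name == "quiet":
        return SimulationConfig(
            n_samples=n_samples, seed=seed,
            chromothripsis_prevalence=0.0, chromoplexy_rate=0.0,
            templated_insertion_rate=0.0, complex_nos_rate=0.0,
            passenger_sv_mean=3.0, passenger_cna_mean=2.0,
        )
    if name == "solid_like":
        return SimulationConfig(
            n_samples=n_samples, seed=seed,
            max_total_cn=20,
            ct_pairs_log_mean=math.log(45.0), ct_max_pairs=120,
            chromothripsis_prevalence=0.5,
        )
    raise ValueError(f"unknown scenario {name!r}")
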