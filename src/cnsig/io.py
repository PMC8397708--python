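"""Reading, writing and filtering of copy-number segment tables and SV catalogs.

Internal coordinate convention is 1-based inclusive for both segment
boundaries and SV breakend positions.  BEDPE files are read and written in
the standard 0-based half-open dialect.  Chromosome names are normalized by
stripping a leading ``chr`` prefix, so ``chr14`` and ``14`` refer to the
same chromosome.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "SegmentProfile",
    "SvBreakpointPair",
    "SvCatalog",
    "GenomeAssets",
    "FormatError",
    "ValidationError",
    "read_segments",
    "write_segments",
    "read_sv_bedpe",
    "write_sv_bedpe",
    "apply_filters",
    "read_matrix",
    "write_matrix",
]

SV_TYPES = ("deletion", "tandem-duplication", "inversion", "translocation")

_SV_TYPE_ALIASES = {
    "del": "deletion",
    "deletion": "deletion",
    "dup": "tandem-duplication",
    "tandem-duplication": "tandem-duplication",
    "tandem_duplication": "tandem-duplication",
    "tds": "tandem-duplication",
    "inv": "inversion",
    "inversion": "inversion",
    "tra": "translocation",
    "trans": "translocation",
    "translocation": "translocation",
    "bnd": "translocation",
    "ctx": "translocation",
}


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Input values violate a domain invariant."""


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


_CANONICAL_ORDER = {str(i): i for i in range(1, 23)}
_CANONICAL_ORDER.update({"X": 23, "Y": 24})


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: 1..22, X, Y, then lexicographic."""
    return (_CANONICAL_ORDER.get(chrom, 99), chrom)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Segment:
    """A constant-copy-number genomic interval (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.total_cn < 0:
            raise ValidationError(f"negative total_cn {self.total_cn}")
        if self.minor_cn is not None and not (0 <= self.minor_cn <= self.total_cn):
            raise ValidationError(
                f"minor_cn {self.minor_cn} outside [0, total_cn={self.total_cn}]"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentProfile:
    """One sample's genome-wide copy-number segmentation.

    Segments are kept sorted by chromosome (natural order) and start, are
    non-overlapping within a chromosome, and adjacent equal-CN segments are
    merged on construction via :meth:`normalized`.
    """

    sample_id: str
    segments: list[Segment] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    def chromosomes(self) -> list[str]:
        return sorted({s.chrom for s in self.segments}, key=chrom_sort_key)

    def normalized(self) -> "SegmentProfile":
        """Sort, check overlap, and merge adjacent equal-CN segments."""
        segs = sorted(self.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start))
        merged: list[Segment] = []
        for seg in segs:
            if merged and merged[-1].chrom == seg.chrom:
                prev = merged[-1]
                if seg.start <= prev.end:
                    raise ValidationError(
                        f"{self.sample_id}: overlapping segments on {seg.chrom} "
                        f"({prev.start}-{prev.end} and {seg.start}-{seg.end})"
                    )
                if prev.total_cn == seg.total_cn:
                    merged[-1] = replace(prev, end=seg.end)
                    continue
            merged.append(seg)
        return SegmentProfile(self.sample_id, merged)


@dataclass(frozen=True)
class SvBreakpointPair:
    """One structural-variant breakpoint pair (two breakends)."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_type: str
    id: str

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValidationError(f"unknown sv_type {self.sv_type!r}")
        inter = self.chrom1 != self.chrom2
        if inter != (self.sv_type == "translocation"):
            raise ValidationError(
                f"{self.id}: sv_type {self.sv_type} inconsistent with "
                f"chromosomes {self.chrom1}/{self.chrom2}"
            )
        if not inter and self.pos1 >= self.pos2:
            raise ValidationError(f"{self.id}: intra-chromosomal pair needs pos1 < pos2")

    @property
    def span(self) -> int | None:
        """Breakend distance for intra-chromosomal pairs, None otherwise."""
        if self.chrom1 != self.chrom2:
            return None
        return self.pos2 - self.pos1

    def breakends(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]


@dataclass
class SvCatalog:
    """One sample's list of SV breakpoint pairs."""

    sample_id: str
    pairs: list[SvBreakpointPair] = field(default_factory=list)
    clustered: dict[str, bool] | None = None

    def __post_init__(self):
        ids = [p.id for p in self.pairs]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"{self.sample_id}: duplicate SV pair ids")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GenomeAssets:
    """Chromosome lengths, arm boundaries, Ig-locus mask and exclusions."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]]
    ig_mask: list[tuple[str, int, int]]
    excluded_chroms: set[str] = field(default_factory=lambda: {"X", "Y"})

    def __post_init__(self):
        for chrom, s, e in self.ig_mask:
            if chrom in self.chrom_lengths and e > self.chrom_lengths[chrom]:
                raise ValidationError(f"mask interval {chrom}:{s}-{e} beyond chromosome end")

    def included_chromosomes(self) -> list[str]:
        return sorted(
            (c for c in self.chrom_lengths if c not in self.excluded_chroms),
            key=chrom_sort_key,
        )

    def in_mask(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.ig_mask)

    @classmethod
    def load(
        cls,
        chrom_sizes: str | Path,
        centromeres: str | Path,
        ig_mask: str | Path,
        excluded_chroms: Iterable[str] = ("X", "Y"),
    ) -> "GenomeAssets":
        sizes: dict[str, int] = {}
        for line in Path(chrom_sizes).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            sizes[normalize_chrom(name)] = int(length)
        cents: dict[str, tuple[int, int]] = {}
        for line in Path(centromeres).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, s, e = line.split()[:3]
            cents[normalize_chrom(name)] = (int(s) + 1, int(e))  # BED -> 1-based
        mask: list[tuple[str, int, int]] = []
        for line in Path(ig_mask).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            mask.append((normalize_chrom(fields[0]), int(fields[1]) + 1, int(fields[2])))
        return cls(sizes, cents, mask, set(normalize_chrom(c) for c in excluded_chroms))

    @classmethod
    def grch37(cls, excluded_chroms: Iterable[str] = ("X", "Y")) -> "GenomeAssets":
        """Packaged GRCh37 chromosome sizes, centromeres and Ig loci."""
        root = importlib.resources.files("cnsig") / "assets"
        return cls.load(
            root / "grch37.chrom.sizes",
            root / "grch37_centromeres.bed",
            root / "grch37_ig_loci.bed",
            excluded_chroms,
        )


# ---------------------------------------------------------------------------
# segment table IO


_SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]
_ALLELE_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn"]


def read_segments(path: str | Path, dialect: str = "seg_tsv") -> list[SegmentProfile]:
    """Read a segment TSV into one :class:`SegmentProfile` per sample.

    ``seg_tsv`` expects columns sample, chrom, start, end, total_cn and an
    optional minor_cn; ``allele_specific_tsv`` expects major_cn + minor_cn
    and derives total_cn as their sum.  Rows violating start < end are
    reported with their 1-based file line numbers.
    """
    if dialect not in ("seg_tsv", "allele_specific_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    required = _SEG_COLUMNS if dialect == "seg_tsv" else _ALLELE_COLUMNS
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if dialect == "allele_specific_tsv":
        df["total_cn"] = df["major_cn"] + df["minor_cn"]
    bad = df.index[df["start"] >= df["end"]].tolist()
    if bad:
        lines = ", ".join(str(i + 2) for i in bad)  # +2: header + 1-based
        raise ValidationError(f"{path}: start >= end on line(s) {lines}")
    profiles: list[SegmentProfile] = []
    for sample, group in df.groupby("sample", sort=False):
        segs = [
            Segment(
                chrom=normalize_chrom(r.chrom),
                start=int(r.start),
                end=int(r.end),
                total_cn=int(r.total_cn),
                minor_cn=int(r.minor_cn) if "minor_cn" in df.columns and pd.notna(r.minor_cn) else None,
            )
            for r in group.itertuples()
        ]
        profiles.append(SegmentProfile(str(sample), segs).normalized())
    return profiles


def write_segments(profiles: Sequence[SegmentProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for s in prof.segments:
            rows.append(
                {
                    "sample": prof.sample_id,
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "total_cn": s.total_cn,
                    "minor_cn": s.minor_cn if s.minor_cn is not None else "",
                }
            )
    pd.DataFrame(rows, columns=_SEG_COLUMNS + ["minor_cn"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BEDPE IO


def read_sv_bedpe(path: str | Path, sample_id: str | None = None) -> list[SvCatalog]:
    """Read a 10+ column BEDPE (+type column, optional sample column).

    BEDPE 0-based half-open breakend intervals are converted to internal
    1-based positions (the interval start + 1).  Inter-chromosomal rows are
    forced to sv_type translocation.  Returns one catalog per sample; if no
    sample column is present the file stem (or ``sample_id``) names the
    single catalog.  An empty file yields an empty list.
    """
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise FormatError(f"{path}:{lineno}: expected >= 11 BEDPE columns, got {len(fields)}")
        rows.append((lineno, fields))
    if not rows:
        return []
    catalogs: dict[str, list[SvBreakpointPair]] = {}
    default_sample = sample_id or path.stem
    for lineno, f in rows:
        c1, s1 = normalize_chrom(f[0]), int(f[1])
        c2, s2 = normalize_chrom(f[3]), int(f[4])
        name, strand1, strand2 = f[6], f[8], f[9]
        token = f[10].strip().lower()
        if token not in _SV_TYPE_ALIASES:
            raise FormatError(f"{path}:{lineno}: unknown sv_type token {f[10]!r}")
        sv_type = _SV_TYPE_ALIASES[token]
        sample = f[11] if len(f) > 11 and f[11].strip() else default_sample
        pos1, pos2 = s1 + 1, s2 + 1
        if c1 != c2:
            sv_type = "translocation"
        else:
            if sv_type == "translocation":
                raise FormatError(
                    f"{path}:{lineno}: translocation type on intra-chromosomal pair"
                )
            if pos1 > pos2:
                pos1, pos2 = pos2, pos1
                strand1, strand2 = strand2, strand1
        catalogs.setdefault(sample, []).append(
            SvBreakpointPair(c1, pos1, strand1, c2, pos2, strand2, sv_type, name)
        )
    return [SvCatalog(s, pairs) for s, pairs in catalogs.items()]


_SV_TYPE_TOKENS = {
    "deletion": "DEL",
    "tandem-duplication": "DUP",
    "inversion": "INV",
    "translocation": "TRA",
}


def write_sv_bedpe(catalog: SvCatalog, path: str | Path, sample_column: bool = False) -> None:
    """Write a catalog as 0-based half-open BEDPE (exact coordinate round-trip)."""
    lines = []
    for p in catalog.pairs:
        fields = [
            p.chrom1, str(p.pos1 - 1), str(p.pos1),
            p.chrom2, str(p.pos2 - 1), str(p.pos2),
            p.id, ".", p.strand1, p.strand2, _SV_TYPE_TOKENS[p.sv_type],
        ]
        if sample_column:
            fields.append(catalog.sample_id)
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# artefact filters


def _merge_equal_neighbors(segs: list[Segment]) -> list[Segment]:
    out: list[Segment] = []
    for seg in segs:
        if out and out[-1].total_cn == seg.total_cn:
            out[-1] = replace(out[-1], end=seg.end)
        else:
            out.append(seg)
    return out


def _dissolve_masked_junctions(segs: list[Segment], assets: GenomeAssets) -> list[Segment]:
    """Merge segment pairs whose CN breakpoint falls in an Ig mask interval."""
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i in range(1, len(segs)):
            left, right = segs[i - 1], segs[i]
            if assets.in_mask(right.chrom, right.start):
                keep = left if left.size >= right.size else right
                merged = replace(keep, start=left.start, end=right.end)
                segs = segs[: i - 1] + [merged] + segs[i + 1 :]
                changed = True
                break
    return segs


def _remove_short_segments(segs: list[Segment], min_seg_bp: int) -> list[Segment]:
    """Merge sub-threshold segments into the flanking neighbor with closer CN.

    Tie on |deltaCN| goes to the preceding neighbor; an edge segment merges
    into its only neighbor; a lone segment on a chromosome is retained (it
    is a baseline, not a CN change).
    """
    while len(segs) > 1:
        short = [(s.size, i) for i, s in enumerate(segs) if s.size < min_seg_bp]
        if not short:
            break
        _, i = min(short)
        seg = segs[i]
        if i == 0:
            neighbor = 1
        elif i == len(segs) - 1:
            neighbor = i - 1
        else:
            d_prev = abs(segs[i - 1].total_cn - seg.total_cn)
            d_next = abs(segs[i + 1].total_cn - seg.total_cn)
            neighbor = i - 1 if d_prev <= d_next else i + 1
        if neighbor < i:
            segs[neighbor] = replace(segs[neighbor], end=seg.end)
        else:
            segs[neighbor] = replace(segs[neighbor], start=seg.start)
        del segs[i]
        segs = _merge_equal_neighbors(segs)
    return segs


def apply_filters(
    profile: SegmentProfile,
    catalog: SvCatalog | None,
    assets: GenomeAssets,
    min_seg_bp: int = 50_000,
) -> tuple[SegmentProfile, SvCatalog | None]:
    """Apply the artefact filters: drop excluded chromosomes, dissolve CN
    breakpoints inside the Ig mask, remove CN changes shorter than
    ``min_seg_bp`` (merging them into the closer-CN flank), and drop SV
    pairs touching the mask or an excluded chromosome.

    Idempotent: applying twice equals applying once.
    """
    prof = profile.normalized()
    out_segs: list[Segment] = []
    for chrom, segs in prof.by_chrom().items():
        if chrom in assets.excluded_chroms:
            continue
        segs = _dissolve_masked_junctions(list(segs), assets)
        segs = _remove_short_segments(segs, min_seg_bp)
        out_segs.extend(_merge_equal_neighbors(segs))
    filtered_profile = SegmentProfile(prof.sample_id, out_segs).normalized()

    filtered_catalog = None
    if catalog is not None:
        kept = [
            p
            for p in catalog.pairs
            if not any(
                c in assets.excluded_chroms or assets.in_mask(c, pos)
                for c, pos in p.breakends()
            )
        ]
        filtered_catalog = SvCatalog(catalog.sample_id, kept)
    return filtered_profile, filtered_catalog


# ---------------------------------------------------------------------------
# matrix IO


def write_matrix(matrix: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    """Write a labelled samples x categories matrix as TSV (lossless round-trip)."""
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValidationError("duplicated row or column labels")
    if matrix.size and not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValidationError("matrix contains non-finite values")
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        matrix.to_csv(fh, sep="\t", index_label="sample")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample", comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicated row or column labels")
    return df
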