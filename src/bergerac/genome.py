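"""Coordinate system, sequence/annotation I/O and interval algebra.

All coordinates are 0-based half-open (BED convention). Annotation
categories (recombination domains, chromatin states, exon/intron models)
are represented as :class:`FeatureTrack` objects: merged, sorted,
non-overlapping interval sets whose covered-bp totals feed the
enrichment expectations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeBuild",
    "Interval",
    "FeatureTrack",
    "read_fasta",
    "read_bed",
    "write_bed",
    "read_gff3_exons",
    "merge_intervals",
    "subtract_intervals",
    "count_overlaps",
    "assign_windows",
]


class GenomeBuild:
    """Ordered chromosome names with their lengths in bp."""

    def __init__(self, lengths: Mapping[str, int]):
        names = list(lengths)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for name, length in lengths.items():
            if not name:
                raise ValueError("empty chromosome name")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths = dict(lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeBuild) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeBuild({self._lengths!r})"

    def total_bp(self) -> int:
        return sum(self._lengths.values())


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self, build: GenomeBuild) -> None:
        if self.chrom not in build:
            raise ValueError(f"chromosome {self.chrom!r} not in build")
        if self.end > build.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {build.length(self.chrom)}"
            )


@dataclass
class FeatureTrack:
    """A named annotation category as a normalized set of intervals.

    Intervals are sorted and non-overlapping within each chromosome
    (touching intervals merged), so a base is covered at most once and
    ``covered_bp`` is an unambiguous exposure measure.
    """

    label: str
    intervals: list[Interval] = field(default_factory=list)

    @classmethod
    def from_intervals(cls, label: str, intervals: Iterable[Interval]) -> "FeatureTrack":
        return merge_intervals(intervals, label=label)

    @property
    def covered_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def __len__(self) -> int:
        return len(self.intervals)


def read_fasta(path: str | Path) -> tuple[dict[str, str], GenomeBuild]:
    """Read a multi-record FASTA; sequences are uppercased.

    Returns the name->sequence mapping and the implied :class:`GenomeBuild`.
    Duplicate headers and empty sequences are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        seqs[rec.id] = seq
    if not seqs:
        raise ValueError(f"no records in FASTA {path}")
    build = GenomeBuild({name: len(s) for name, s in seqs.items()})
    return seqs, build


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path, build: GenomeBuild | None = None) -> list[Interval]:
    """Read BED3/BED6 (tab-delimited, 0-based half-open), order preserved.

    Malformed lines and intervals outside *build* are rejected with the
    offending line number.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            try:
                iv = Interval(chrom, start, end, name=name, strand=strand)
                if build is not None:
                    iv.validate(build)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write BED3+name (name '.' when unset)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\n")


def read_gff3_exons(path: str | Path, build: GenomeBuild | None = None) -> list[Interval]:
    """Extract exon features from a GFF3 file as 0-based half-open intervals."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.features_of_type("exon"):
        iv = Interval(feat.seqid, feat.start - 1, feat.end, name="exon",
                      strand=feat.strand if feat.strand in "+-" else None)
        if build is not None:
            iv.validate(build)
        out.append(iv)
    return out


def merge_intervals(intervals: Iterable[Interval], label: str = "merged") -> FeatureTrack:
    """Merge overlapping and touching intervals into a normalized track."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or touching
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return FeatureTrack(label=label, intervals=merged)


def subtract_intervals(track_a: FeatureTrack, track_b: FeatureTrack,
                       label: str | None = None) -> FeatureTrack:
    """Bases covered by A and not by B (both tracks normalized)."""
    b_by_chrom = track_b.by_chrom()
    out: list[Interval] = []
    for iv in track_a.intervals:
        pieces = [(iv.start, iv.end)]
        for b in b_by_chrom.get(iv.chrom, []):
            if b.end <= iv.start or b.start >= iv.end:
                continue
            new_pieces = []
            for s, e in pieces:
                if b.end <= s or b.start >= e:
                    new_pieces.append((s, e))
                    continue
                if b.start > s:
                    new_pieces.append((s, b.start))
                if b.end < e:
                    new_pieces.append((b.end, e))
            pieces = new_pieces
        out.extend(Interval(iv.chrom, s, e) for s, e in pieces)
    return FeatureTrack(label=label or f"{track_a.label}-minus-{track_b.label}",
                        intervals=out)


def _tree_index(track: FeatureTrack) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in track.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def count_overlaps(queries: Sequence[Interval], track: FeatureTrack) -> int:
    """Number of query intervals overlapping >= 1 bp of the track.

    Each query counts at most once regardless of how many track intervals
    it touches.
    """
    trees = _tree_index(track)
    n = 0
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is not None and tree.overlaps(q.start, q.end):
            n += 1
    return n


def overlap_mask(queries: Sequence[Interval], track: FeatureTrack) -> list[bool]:
    """Per-query boolean overlap flags against the track."""
    trees = _tree_index(track)
    return [
        (trees.get(q.chrom) is not None and trees[q.chrom].overlaps(q.start, q.end))
        for q in queries
    ]


def assign_windows(intervals: Sequence[Interval], window_size: int) -> set[tuple[str, int]]:
    """Assign each interval to every fixed-size window its span overlaps.

    Window index = floor(coordinate / window_size); an interval spanning a
    window boundary lands in every window it touches.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        first = iv.start // window_size
        last = (iv.end - 1) // window_size
        for w in range(first, last + 1):
            out.add((iv.chrom, w))
    return out
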