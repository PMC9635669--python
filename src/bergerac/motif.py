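"""IUPAC degenerate-motif scanning and insertion-site consensus derivation.

Tc1, a mariner-family DNA transposon, inserts strictly at TA
dinucleotides inside an A/T-rich consensus (5'-AYATATRT-3' as an 8-mer,
CAYATATRTG as a 10-mer). This module scans genomes for degenerate
motifs, extracts flanking-base matrices around insertion points, and
derives an IUPAC consensus from per-position base frequencies.

Conventions: an insertion point is stored as the 0-based coordinate of
the T of the TA target; the flank "center" is the T|A boundary, so
column -1 of a flank matrix is the T and column +1 the A. Ambiguity
codes in the scanned genome (e.g. N runs in assemblies) never match any
motif position, including N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IUPAC_CODES",
    "IUPACMotif",
    "FlankMatrix",
    "revcomp",
    "scan_motif",
    "extract_flanks",
    "derive_consensus",
    "TC1_MOTIF_8MER",
    "TC1_MOTIF_10MER",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {bases: code for code, bases in IUPAC_CODES.items()}
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: default genome-scan motif: the 8-bp Tc1 insertion consensus
TC1_MOTIF_8MER = "AYATATRT"
#: the extended 10-bp consensus
TC1_MOTIF_10MER = "CAYATATRTG"

# base -> small integer; index 4 = "anything else" (never matches)
_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


def revcomp(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (R<->Y, K<->M, B<->V, D<->H)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC character {exc.args[0]!r}") from exc


class IUPACMotif:
    """A degenerate motif with per-position allowed base sets."""

    def __init__(self, pattern: str):
        pattern = pattern.upper()
        if not pattern:
            raise ValueError("empty motif")
        for c in pattern:
            if c not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC character {c!r} in motif")
        self.pattern = pattern
        self.allowed: list[frozenset[str]] = [IUPAC_CODES[c] for c in pattern]

    def __len__(self) -> int:
        return len(self.pattern)

    def __repr__(self) -> str:
        return f"IUPACMotif({self.pattern!r})"

    def revcomp(self) -> "IUPACMotif":
        return IUPACMotif(revcomp(self.pattern))

    def is_palindromic(self) -> bool:
        return self.pattern == revcomp(self.pattern)


def _scan_one_strand(enc: np.ndarray, motif: IUPACMotif) -> np.ndarray:
    m = len(motif)
    n = enc.size
    if m > n:
        return np.empty(0, dtype=np.int64)
    # 5-wide lookup per motif position; index 4 (non-ACGT) always False
    ok = np.ones(n - m + 1, dtype=bool)
    for j, bases in enumerate(motif.allowed):
        table = np.zeros(5, dtype=bool)
        for b in bases:
            table["ACGT".index(b)] = True
        ok &= table[enc[j : j + n - m + 1]]
    return np.flatnonzero(ok).astype(np.int64)


def scan_motif(sequence: str, motif: IUPACMotif | str,
               strand_policy: str = "forward_only") -> np.ndarray:
    """All (overlapping, step-1) match start positions of *motif* in *sequence*.

    ``strand_policy='both_dedup'`` also scans the reverse complement and
    reports each genomic footprint once (union of start positions). For
    reverse-complement-symmetric motifs such as AYATATRT both policies
    give identical results.
    """
    if strand_policy not in ("forward_only", "both_dedup"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    enc = _BASE_INDEX[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    hits = _scan_one_strand(enc, motif)
    if strand_policy == "both_dedup" and not motif.is_palindromic():
        rc_hits = _scan_one_strand(enc, motif.revcomp())
        hits = np.union1d(hits, rc_hits)
    return hits


def scan_genome(seqs: Mapping[str, str], motif: IUPACMotif | str,
                strand_policy: str = "forward_only") -> dict[str, np.ndarray]:
    """Per-chromosome match start positions over a whole genome."""
    return {name: scan_motif(seq, motif, strand_policy) for name, seq in seqs.items()}


@dataclass
class FlankMatrix:
    """Per-position base counts around insertion points.

    ``counts`` is indexed by flank position (-k..-1, +1..+k; no position
    0 — the center is the T|A boundary) with columns A, C, G, T.
    """

    counts: pd.DataFrame
    n_sites: int
    n_excluded: int = 0

    @property
    def k(self) -> int:
        return int(self.counts.index.max())

    def frequencies(self) -> pd.DataFrame:
        if self.n_sites == 0:
            raise ValueError("flank matrix has no contributing sites")
        return self.counts / self.n_sites

    def to_table(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.index.name = "position"
        return out.reset_index()


def extract_flanks(seqs: Mapping[str, str],
                   insertion_points: Iterable[tuple[str, int]],
                   k: int = 25) -> FlankMatrix:
    """Base-count matrix for positions +/-k around each T|A insertion point.

    *insertion_points* are (chromosome, t_position) pairs where
    t_position is the 0-based coordinate of the T of the TA target.
    Sites closer than k to a contig edge (or outside the contig) are
    excluded and counted in ``n_excluded``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    positions = [p for p in range(-k, k + 1) if p != 0]
    counts = pd.DataFrame(0, index=positions, columns=list("ACGT"), dtype=int)
    n_sites = 0
    n_excluded = 0
    for chrom, t_pos in insertion_points:
        seq = seqs.get(chrom)
        if seq is None or t_pos < 0 or t_pos >= len(seq):
            n_excluded += 1
            continue
        # column -1 is the T at t_pos, +1 the A at t_pos+1
        lo = t_pos - k + 1
        hi = t_pos + k
        if lo < 0 or hi >= len(seq):
            n_excluded += 1
            continue
        for p in positions:
            # -1 maps to the T at t_pos, +1 to the A at t_pos + 1
            idx = t_pos + p + 1 if p < 0 else t_pos + p
            base = seq[idx]
            if base in "ACGT":
                counts.at[p, base] += 1
        n_sites += 1
    return FlankMatrix(counts=counts, n_sites=n_sites, n_excluded=n_excluded)


def derive_consensus(flank_matrix: FlankMatrix, freq_threshold: float = 0.2) -> str:
    """IUPAC consensus across flank positions at a base-frequency threshold.

    A base enters the per-position IUPAC set when its frequency is >=
    *freq_threshold*; the center is rendered as the invariant "TA" of the
    target-site duplication. The default 0.2 reproduces two-base codes
    (Y, R) at ~50/50 positions while suppressing noise.
    """
    if not 0 < freq_threshold < 1:
        raise ValueError("freq_threshold must be in (0, 1)")
    if flank_matrix.n_sites == 0:
        raise ValueError("flank matrix has no contributing sites")
    freqs = flank_matrix.frequencies()
    codes = []
    for pos in freqs.index:
        bases = frozenset(b for b in "ACGT" if freqs.at[pos, b] >= freq_threshold)
        codes.append(_SET_TO_CODE.get(bases, "N") if bases else "N")
    k = flank_matrix.k
    # positions -k..-1 then +1..+k; force the invariant TA at the center
    left = codes[: k - 1]
    right = codes[k + 1 :]
    return "".join(left) + "TA" + "".join(right)
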