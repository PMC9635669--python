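"""Multi-caller TE insertion-call consensus and copy-number aggregation.

TE-detection callers (ngs_te_mapper2, RelocaTE, TEMP2, RetroSeq, TEFLoN
in the study this mirrors) disagree on exact breakpoints, so calls are
compared on fixed genomic windows: nonreference insertions on 1,000-bp
windows, reference elements (which span several kb) on 100,000-bp
windows, pooled into one window universe per strain. Per-window support
is the number of distinct callers with at least one call in the window.

Copy-number summaries pool the per-caller call counts with a
read-depth-based estimate (mean depth over the element divided by
genome-wide mean depth) into range/mean/median rows, mirroring the
publication-table layout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBuild, Interval, assign_windows, read_bed

__all__ = [
    "TECallSet",
    "AgreementTable",
    "CopyNumberSummary",
    "DepthProfile",
    "consensus_windows",
    "support_fractions",
    "summarize_copy_number",
    "coverage_copy_estimate",
    "round_half_up",
]

NONREF_WINDOW_BP = 1000
REF_WINDOW_BP = 100_000


def round_half_up(x: float) -> int:
    """Display rounding: 451.5 -> 452 (banker's rounding would give 452 too,
    but 0.5 cases must always round away from zero here)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class TECallSet:
    """One caller's insertion calls for one strain.

    Calls are 0-based intervals; nonreference insertion points may be
    stored as 1-bp intervals at the reported TA position, reference
    elements as full-length spans.
    """

    strain: str
    caller: str
    nonreference: list[Interval] = field(default_factory=list)
    reference: list[Interval] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path: str | Path, strain: str, caller: str,
                 build: GenomeBuild | None = None) -> "TECallSet":
        """Read a caller BED whose name column carries the call class
        ('reference' or 'nonreference'; unlabeled calls are nonreference)."""
        nonref, ref = [], []
        for iv in read_bed(path, build):
            if iv.name == "reference":
                ref.append(iv)
            else:
                nonref.append(iv)
        return cls(strain=strain, caller=caller, nonreference=nonref, reference=ref)

    @property
    def n_calls(self) -> int:
        return len(self.nonreference) + len(self.reference)


@dataclass
class AgreementTable:
    """Windowed multi-caller agreement for one strain.

    ``support`` maps pooled window keys (kind, chromosome, window index)
    to the set of callers with a call in that window.
    """

    strain: str
    callers: list[str]
    support: dict[tuple[str, str, int], frozenset[str]]

    @property
    def n_windows(self) -> int:
        return len(self.support)

    def support_counts(self) -> dict[int, int]:
        """Number of windows at each support level 1..C."""
        levels = Counter(len(s) for s in self.support.values())
        return {lvl: levels.get(lvl, 0) for lvl in range(1, len(self.callers) + 1)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (kind, chrom, idx), callers in sorted(self.support.items()):
            row = {"kind": kind, "chrom": chrom, "window": idx, "support": len(callers)}
            for c in self.callers:
                row[c] = int(c in callers)
            rows.append(row)
        return pd.DataFrame(rows)


def consensus_windows(callsets: Sequence[TECallSet],
                      nonref_window_bp: int = NONREF_WINDOW_BP,
                      ref_window_bp: int = REF_WINDOW_BP) -> AgreementTable:
    """Pool per-caller calls into windows and tally per-window support.

    A caller contributing several calls to one window counts once. All
    callsets must come from the same strain.
    """
    if not callsets:
        raise ValueError("no callsets supplied")
    strains = {cs.strain for cs in callsets}
    if len(strains) > 1:
        raise ValueError(f"callsets from multiple strains: {sorted(strains)}")
    callers = [cs.caller for cs in callsets]
    if len(set(callers)) != len(callers):
        raise ValueError("duplicate caller labels")
    support: dict[tuple[str, str, int], set[str]] = {}
    for cs in callsets:
        windows: set[tuple[str, str, int]] = set()
        for chrom, idx in assign_windows(cs.nonreference, nonref_window_bp):
            windows.add(("nonref", chrom, idx))
        for chrom, idx in assign_windows(cs.reference, ref_window_bp):
            windows.add(("ref", chrom, idx))
        for key in windows:
            support.setdefault(key, set()).add(cs.caller)
    return AgreementTable(
        strain=callsets[0].strain,
        callers=callers,
        support={k: frozenset(v) for k, v in support.items()},
    )


def support_fractions(table: AgreementTable) -> tuple[float, float]:
    """Fractions of windows supported by all C callers and by >= C-1.

    Returned as fractions in [0, 1]; display as whole percent with
    :func:`round_half_up`.
    """
    if table.n_windows == 0:
        raise ValueError("empty agreement table")
    c = len(table.callers)
    levels = [len(s) for s in table.support.values()]
    full = sum(1 for s in levels if s == c) / table.n_windows
    near = sum(1 for s in levels if s >= c - 1) / table.n_windows
    return full, near


@dataclass
class DepthProfile:
    """Per-base read depth over the TE consensus plus genome-wide mean depth."""

    element_depths: np.ndarray
    genome_mean_depth: float

    def __post_init__(self):
        self.element_depths = np.asarray(self.element_depths, dtype=float)
        if self.element_depths.size == 0:
            raise ValueError("empty depth profile")
        if np.any(self.element_depths < 0):
            raise ValueError("negative depths")


def coverage_copy_estimate(profile: DepthProfile) -> float:
    """Copies = mean depth over the element / genome-wide mean depth."""
    if profile.genome_mean_depth <= 0:
        raise ValueError("genome-wide mean depth must be positive")
    return float(profile.element_depths.mean() / profile.genome_mean_depth)


@dataclass
class CopyNumberSummary:
    """Range/mean/median over pooled per-caller + coverage estimates."""

    strain: str
    per_caller: dict[str, float]
    coverage_estimate: float | None
    ddpcr: float | None
    values: list[float]
    min: float
    max: float
    mean: float
    median: float

    @property
    def mean_display(self) -> int:
        return round_half_up(self.mean)

    @property
    def median_display(self) -> int:
        return round_half_up(self.median)

    def to_row(self) -> dict:
        row = {"strain": self.strain, **self.per_caller}
        row["coverage"] = self.coverage_estimate
        row["range"] = f"{round_half_up(self.min)}-{round_half_up(self.max)}"
        row["mean"] = self.mean_display
        row["median"] = self.median_display
        row["ddpcr"] = self.ddpcr
        return row


def summarize_copy_number(per_caller_counts: Mapping[str, float] | Sequence[float],
                          coverage_estimate: float | None = None,
                          strain: str = "",
                          ddpcr: float | None = None) -> CopyNumberSummary:
    """Pool per-caller counts with the coverage estimate into a summary row.

    The median of an even-length pool is the mean of the middle two
    values; display rounding is half-up (451.5 -> 452).
    """
    if isinstance(per_caller_counts, Mapping):
        per_caller = {k: float(v) for k, v in per_caller_counts.items()}
    else:
        per_caller = {f"caller{i+1}": float(v) for i, v in enumerate(per_caller_counts)}
    if any(v < 0 for v in per_caller.values()):
        raise ValueError("negative call counts")
    values = list(per_caller.values())
    if coverage_estimate is not None:
        values.append(float(coverage_estimate))
    if not values:
        raise ValueError("no copy-number values supplied")
    arr = np.asarray(values, dtype=float)
    return CopyNumberSummary(
        strain=strain,
        per_caller=per_caller,
        coverage_estimate=coverage_estimate,
        ddpcr=ddpcr,
        values=values,
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
    )
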