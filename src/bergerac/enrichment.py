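"""Observed-vs-expected insertion statistics across genomic categories.

Expectations can be built from two exposure models: category length in
covered bp ("how much genome is there") or the count of insertion-motif
sites per category ("how much insertable genome is there"). Contrasting
the two reproduces the key analytical move of correcting apparent
enrichment for the availability of the TA-rich integration consensus.

Test machinery: chi-squared goodness of fit (no continuity correction),
the G likelihood-ratio test on contingency tables, Fisher's exact test
for 2x2 tables, and Holm-Bonferroni step-down adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import FeatureTrack, Interval, overlap_mask, subtract_intervals

__all__ = [
    "CategoryCounts",
    "EnrichmentResult",
    "expected_from_exposure",
    "chisq_gof",
    "g_test",
    "fisher_exact_2x2",
    "holm_bonferroni",
    "classify_sites",
    "fold_enrichment",
    "r_squared",
    "enrich_test",
    "binary_category_counts",
]


@dataclass
class CategoryCounts:
    """Observed insertion counts with per-category exposures.

    ``model`` records which exposure was used: 'length' (covered bp) or
    'motif_sites' (number of consensus-motif matches in the category).
    """

    labels: list[str]
    observed: np.ndarray
    exposure: np.ndarray
    model: str = "length"

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate category labels")
        if not (len(self.labels) == self.observed.size == self.exposure.size):
            raise ValueError("labels/observed/exposure length mismatch")
        if np.any(self.observed < 0):
            raise ValueError("negative observed counts")
        if np.any(self.exposure <= 0):
            raise ValueError("exposures must be positive")


@dataclass
class EnrichmentResult:
    """Chi-squared goodness-of-fit result against exposure expectations."""

    labels: list[str]
    observed: np.ndarray
    expected: np.ndarray
    fold: np.ndarray
    chi2: float
    df: int
    p: float
    p_adjusted: float | None = None
    model: str = "length"


def expected_from_exposure(counts: CategoryCounts) -> np.ndarray:
    """expected_i = total observed x exposure_i / total exposure."""
    total = counts.observed.sum()
    if total <= 0:
        raise ValueError("no observed insertions")
    return total * counts.exposure / counts.exposure.sum()


def chisq_gof(observed: Sequence[float], expected: Sequence[float]) -> tuple[float, int, float]:
    """Pearson chi-squared goodness of fit, df = k - 1, no continuity correction."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.size != exp.size:
        raise ValueError("observed/expected length mismatch")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    if np.any(exp < 5):
        warnings.warn("some expected counts are below 5; chi-squared may be inaccurate")
    stat, p = stats.chisquare(obs, f_exp=exp * obs.sum() / exp.sum())
    return float(stat), obs.size - 1, float(p)


def g_test(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Likelihood-ratio G test of independence on an r x c table.

    G = 2 sum O ln(O/E) with E from row/column margins; zero cells
    contribute zero. No Williams or continuity correction.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("negative cell counts")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margins (all-zero row or column)")
    g, p, df, _ = stats.chi2_contingency(arr, correction=False, lambda_="log-likelihood")
    return float(g), int(df), float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact p for a 2x2 table (two-sided by the point-probability rule)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("cell counts must be integers")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ValueError("negative cell counts")
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def classify_sites(calls: Sequence[Interval], exon_track: FeatureTrack,
                   intron_track: FeatureTrack) -> dict[str, int]:
    """Assign each call to exon > intron-exclusive > intergenic.

    A site inside an exon of any transcript is exonic even if it is
    intronic in another isoform; intronic sites are those in
    intron-minus-exon space only.
    """
    intron_exclusive = subtract_intervals(intron_track, exon_track, label="intron_exclusive")
    in_exon = overlap_mask(calls, exon_track)
    in_intron = overlap_mask(calls, intron_exclusive)
    counts = {"exon": 0, "intron": 0, "intergenic": 0}
    for e, i in zip(in_exon, in_intron):
        if e:
            counts["exon"] += 1
        elif i:
            counts["intron"] += 1
        else:
            counts["intergenic"] += 1
    return counts


def binary_category_counts(calls: Sequence[Interval], track: FeatureTrack,
                           genome_bp: int, label: str,
                           exposure_inside: float | None = None,
                           exposure_outside: float | None = None,
                           model: str = "length") -> CategoryCounts:
    """Observed in/out counts for one annotation category (e.g. one
    chromatin state), with length or motif-site exposures."""
    inside = sum(overlap_mask(calls, track))
    outside = len(calls) - inside
    if exposure_inside is None:
        exposure_inside = track.covered_bp
        exposure_outside = genome_bp - track.covered_bp
    return CategoryCounts(
        labels=[label, f"not_{label}"],
        observed=np.array([inside, outside], dtype=float),
        exposure=np.array([exposure_inside, exposure_outside], dtype=float),
        model=model,
    )


def fold_enrichment(observed: Sequence[float], expected: Sequence[float]) -> np.ndarray:
    """fold_i = O_i / E_i; percent excess is (fold - 1) x 100."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected counts must be positive")
    return obs / exp


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    r = stats.pearsonr(x, y)[0]
    return float(r * r)


def enrich_test(counts: CategoryCounts) -> EnrichmentResult:
    """Chi-squared goodness of fit of observed counts against the
    exposure-model expectation, with per-category folds."""
    expected = expected_from_exposure(counts)
    chi2, df, p = chisq_gof(counts.observed, expected)
    return EnrichmentResult(
        labels=list(counts.labels),
        observed=counts.observed.copy(),
        expected=expected,
        fold=fold_enrichment(counts.observed, expected),
        chi2=chi2,
        df=df,
        p=min(p, 1.0),
        model=counts.model,
    )
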