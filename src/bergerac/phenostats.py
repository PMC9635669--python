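"""Nested and one-way ANOVA, Tukey-Kramer HSD and relative-trait summaries.

The fitness assays have a two-level hierarchy: strains (fixed
treatments) contain independently founded lines, each propagated as
several sublines; one trait value is observed per subline. The
two-level nested ANOVA with unequal sample sizes (after Sokal & Rohlf's
unbalanced nested design) partitions variance into among-strain,
among-line-within-strain and within-line (subline) components.

Because line is a random effect, the strain mean square has expectation
sigma2_e + nb0*sigma2_line + n0*sigma2_strain with unequal-n
coefficients, so the strain effect is tested two ways, as the source
tables print both:

* F_s  = MS_groups / MS_within (exact only when sigma2_line = 0), and
* F_s' = MS_groups over a synthesized denominator
  c*MS_lines + (1-c)*MS_within with c = nb0/n0', whose degrees of
  freedom come from Satterthwaite's approximation. In a balanced design
  c = 1 and F_s' reduces to MS_groups/MS_lines.

Coefficient bookkeeping (groups i = 1..a with subgroup counts b_i,
subgroup (i,j) with n_ij observations, group totals N_i, grand total N,
B = sum b_i):

    n0' = [N - sum_i (sum_j n_ij^2)/N_i] / (B - a)      (sigma2_line in E[MS_lines])
    nb0 = [sum_i (sum_j n_ij^2)/N_i - (sum_ij n_ij^2)/N] / (a - 1)
    n0  = [N - (sum_i N_i^2)/N] / (a - 1)               (sigma2_strain in E[MS_groups])
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NestedAnovaTable",
    "PairwiseComparison",
    "nested_anova",
    "tukey_kramer",
    "oneway_anova",
    "pearson_test",
    "relative_change",
]


@dataclass
class NestedAnovaTable:
    """Two-level nested ANOVA decomposition with both strain-level F ratios."""

    ss_groups: float
    ss_subgroups: float
    ss_within: float
    df_groups: int
    df_subgroups: int
    df_within: int
    ms_groups: float
    ms_subgroups: float
    ms_within: float
    f_s: float
    p_groups_fs: float
    f_s_prime: float
    df_denom_prime: float
    p_groups_fs_prime: float
    f_subgroups: float
    p_subgroups: float
    n0_prime: float
    nb0: float
    n0: float

    @property
    def ss_total(self) -> float:
        return self.ss_groups + self.ss_subgroups + self.ss_within

    def variance_components(self) -> dict[str, float]:
        """Method-of-moments estimates (may be negative by sampling noise)."""
        s2_e = self.ms_within
        s2_b = (self.ms_subgroups - self.ms_within) / self.n0_prime
        s2_a = (self.ms_groups - self.ms_within - self.nb0 * s2_b) / self.n0
        return {"group": s2_a, "subgroup": s2_b, "error": s2_e}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Source": ["Among groups", "Among lines", "Within lines (error)", "Total"],
                "df": [self.df_groups, self.df_subgroups, self.df_within,
                       self.df_groups + self.df_subgroups + self.df_within],
                "SS": [self.ss_groups, self.ss_subgroups, self.ss_within, self.ss_total],
                "MS": [self.ms_groups, self.ms_subgroups, self.ms_within, np.nan],
                "F_s": [self.f_s, self.f_subgroups, np.nan, np.nan],
                "F_s_prime": [self.f_s_prime, np.nan, np.nan, np.nan],
                "p": [self.p_groups_fs, self.p_subgroups, np.nan, np.nan],
            }
        )


def _prepare(records: pd.DataFrame, value_col: str, trait: str | None) -> pd.DataFrame:
    df = records.copy()
    if trait is not None and "trait" in df.columns:
        df = df[df["trait"] == trait]
    df = df.dropna(subset=[value_col])
    if df.empty:
        raise ValueError("no observations after filtering")
    return df


def nested_anova(records: pd.DataFrame, trait: str | None = None,
                 value_col: str = "value", group_col: str = "strain",
                 subgroup_col: str = "line") -> NestedAnovaTable:
    """Two-level nested Model I ANOVA with unequal sample sizes.

    *records* is a long table with one row per subline observation.
    Requires >= 2 groups and > 1 observation per group; raises on zero
    total variance (F undefined).
    """
    df = _prepare(records, value_col, trait)
    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    n_total = y.size
    if df[group_col].nunique() < 2:
        raise ValueError("need at least 2 groups")
    group_sizes = df.groupby(group_col, observed=True)[value_col].size()
    if (group_sizes < 2).any():
        bad = group_sizes[group_sizes < 2].index.tolist()
        raise ValueError(f"groups with a single observation: {bad}")
    if np.allclose(y, grand):
        raise ValueError("zero total variance: F undefined")

    cells = df.groupby([group_col, subgroup_col], observed=True)[value_col].agg(["mean", "size"])
    groups = df.groupby(group_col, observed=True)[value_col].agg(["mean", "size"])
    a = len(groups)
    b_total = len(cells)

    ss_groups = float((groups["size"] * (groups["mean"] - grand) ** 2).sum())
    group_mean_of = groups["mean"].to_dict()
    cell_group_means = np.array([group_mean_of[g] for g, _ in cells.index])
    ss_sub = float((cells["size"] * (cells["mean"].to_numpy() - cell_group_means) ** 2).sum())
    cell_means = df.set_index([group_col, subgroup_col]).join(
        cells["mean"].rename("cell_mean"), on=[group_col, subgroup_col]
    )["cell_mean"].to_numpy()
    ss_within = float(((y - cell_means) ** 2).sum())

    df_groups = a - 1
    df_sub = b_total - a
    df_within = n_total - b_total
    if df_within <= 0:
        raise ValueError("no within-subgroup replication: error MS undefined")
    if df_sub <= 0:
        raise ValueError("no subgroup replication within groups")

    ms_groups = ss_groups / df_groups
    ms_sub = ss_sub / df_sub
    ms_within = ss_within / df_within
    if ms_within == 0:
        raise ValueError("zero within-subgroup variance: F undefined")

    # unequal-n expected-MS coefficients
    nij = cells["size"].to_numpy(dtype=float)
    cell_groups = np.array([g for g, _ in cells.index])
    ni = groups["size"].to_numpy(dtype=float)
    sum_nij2_over_ni = sum(
        (nij[cell_groups == g] ** 2).sum() / group_sizes[g] for g in groups.index
    )
    n0_prime = (n_total - sum_nij2_over_ni) / df_sub
    nb0 = (sum_nij2_over_ni - (nij ** 2).sum() / n_total) / df_groups
    n0 = (n_total - (ni ** 2).sum() / n_total) / df_groups

    f_s = ms_groups / ms_within
    p_fs = float(stats.f.sf(f_s, df_groups, df_within))
    f_sub = ms_sub / ms_within
    p_sub = float(stats.f.sf(f_sub, df_sub, df_within))

    c = nb0 / n0_prime
    ms_denom = c * ms_sub + (1 - c) * ms_within
    df_denom = ms_denom ** 2 / (
        (c * ms_sub) ** 2 / df_sub + ((1 - c) * ms_within) ** 2 / df_within
    )
    f_s_prime = ms_groups / ms_denom
    p_fs_prime = float(stats.f.sf(f_s_prime, df_groups, df_denom))

    return NestedAnovaTable(
        ss_groups=ss_groups, ss_subgroups=ss_sub, ss_within=ss_within,
        df_groups=df_groups, df_subgroups=df_sub, df_within=df_within,
        ms_groups=ms_groups, ms_subgroups=ms_sub, ms_within=ms_within,
        f_s=f_s, p_groups_fs=p_fs,
        f_s_prime=f_s_prime, df_denom_prime=float(df_denom), p_groups_fs_prime=p_fs_prime,
        f_subgroups=f_sub, p_subgroups=p_sub,
        n0_prime=float(n0_prime), nb0=float(nb0), n0=float(n0),
    )


@dataclass
class PairwiseComparison:
    """One Tukey-Kramer pairwise strain contrast."""

    group_a: str
    group_b: str
    diff: float
    se: float
    q: float
    p: float
    significant: bool


def tukey_kramer(records: pd.DataFrame, error_ms: float, error_df: float,
                 trait: str | None = None, value_col: str = "value",
                 group_col: str = "strain", alpha: float = 0.05) -> list[PairwiseComparison]:
    """Tukey-Kramer HSD for unequal sample sizes at an experiment-wise alpha.

    q_ij = |mean_i - mean_j| / sqrt((MS_err/2)(1/n_i + 1/n_j)); p from the
    studentized-range distribution with k groups and the supplied error df
    (use the within-lines MS/df from the nested table for fitness traits).
    """
    df = _prepare(records, value_col, trait)
    groups = df.groupby(group_col, observed=True)[value_col].agg(["mean", "size"])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (groups["size"] == 0).any():
        raise ValueError("empty group")
    k = len(groups)
    out = []
    for ga, gb in itertools.combinations(groups.index, 2):
        ma, na = groups.loc[ga, "mean"], groups.loc[ga, "size"]
        mb, nb = groups.loc[gb, "mean"], groups.loc[gb, "size"]
        se = np.sqrt((error_ms / 2.0) * (1.0 / na + 1.0 / nb))
        q = abs(ma - mb) / se
        p = float(stats.studentized_range.sf(q, k, error_df))
        out.append(PairwiseComparison(
            group_a=str(ga), group_b=str(gb), diff=float(ma - mb),
            se=float(se), q=float(q), p=min(p, 1.0), significant=p < alpha,
        ))
    return out


def oneway_anova(records: pd.DataFrame, trait: str | None = None,
                 value_col: str = "value", group_col: str = "strain"
                 ) -> tuple[float, tuple[int, int], float, pd.DataFrame]:
    """One-way fixed-effects ANOVA; returns (F, (df1, df2), p, source table)."""
    df = _prepare(records, value_col, trait)
    y = df[value_col].to_numpy(dtype=float)
    grand = y.mean()
    groups = df.groupby(group_col, observed=True)[value_col].agg(["mean", "size"])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if (groups["size"] < 2).any():
        raise ValueError("need >= 2 observations per group")
    ss_between = float((groups["size"] * (groups["mean"] - grand) ** 2).sum())
    group_means = df.groupby(group_col, observed=True)[value_col].transform("mean").to_numpy()
    ss_within = float(((y - group_means) ** 2).sum())
    df1, df2 = len(groups) - 1, y.size - len(groups)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("zero total variance: F undefined")
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    ms_between, ms_within = ss_between / df1, ss_within / df2
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df1, df2))
    table = pd.DataFrame({
        "Source": ["Among groups", "Within lines (error)", "Total"],
        "df": [df1, df2, df1 + df2],
        "SS": [ss_between, ss_within, ss_between + ss_within],
        "MS": [ms_between, ms_within, np.nan],
        "F_s": [f, np.nan, np.nan],
        "p": [p, np.nan, np.nan],
    })
    return f, (df1, df2), p, table


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided t-transform p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of size >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def relative_change(treatment_mean: float, control_mean: float,
                    direction: str = "reduction") -> float:
    """Percent change of a treatment mean relative to control.

    'reduction' = (1 - treatment/control) x 100;
    'increase'  = (treatment/control - 1) x 100.
    """
    if control_mean == 0:
        raise ValueError("control mean is zero")
    ratio = treatment_mean / control_mean
    if direction == "reduction":
        return (1.0 - ratio) * 100.0
    if direction == "increase":
        return (ratio - 1.0) * 100.0
    raise ValueError(f"unknown direction {direction!r}")
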