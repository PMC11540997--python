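"""STAMP-style two-group post-hoc comparisons of genus-level relative abundance.

Each genus present in either group is tested with Welch's two-sided t-test
(unequal variances, Welch-Satterthwaite degrees of freedom); the confidence
interval of the mean difference is obtained by inverting the Welch statistic.
Raw p-values are reported without multiplicity correction by default, matching
common post-hoc reporting practice; Benjamini-Hochberg adjustment is available
behind a flag and its use is logged prominently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import FeatureTable, SampleMetadata, TaxonomyTable, aggregate_taxon

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    taxon: str
    mean_a: float
    mean_b: float
    t_statistic: float
    df_welch: float
    p_two_sided: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    n_a: int = 0
    n_b: int = 0

    @property
    def mean_difference(self) -> float:
        return self.mean_a - self.mean_b


def welch_test(values_a: Sequence[float], values_b: Sequence[float],
               ci_level: float = 0.95, taxon: str = "") -> GroupComparison:
    """Welch's two-sample t-test with an inverted-statistic confidence interval.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b); df by Welch-Satterthwaite;
    CI = difference +/- t_{df, 1-(1-ci_level)/2} * SE.  The degenerate case of
    zero variance in both groups with equal means yields t=0, p=1 rather than
    an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must lie in (0, 1)")
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = ma - mb
    if se2 == 0:
        if diff == 0:
            return GroupComparison(taxon, ma, mb, 0.0, float(na + nb - 2), 1.0,
                                   0.0, 0.0, ci_level, na, nb)
        raise ValueError("zero variance in both groups with unequal means")
    se = np.sqrt(se2)
    t = diff / se
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(1.0 - (1.0 - ci_level) / 2.0, df))
    return GroupComparison(taxon, float(ma), float(mb), float(t), float(df), p,
                           float(diff - tcrit * se), float(diff + tcrit * se),
                           ci_level, na, nb)


def compare_groups(table: FeatureTable, taxonomy: TaxonomyTable,
                   metadata: SampleMetadata, contrast: tuple[dict, dict],
                   rank: str = "genus", ci_level: float = 0.95,
                   fdr: bool = False) -> pd.DataFrame:
    """One Welch comparison per taxon at ``rank`` between two sample groups.

    ``contrast`` is a pair of metadata-criteria dicts, e.g.
    ``({"habitat": "gut", "sex": "female"}, {"habitat": "gut", "sex": "male"})``.
    Aggregation to ``rank`` happens on the percent scale before testing; taxa
    absent from both groups are dropped.  Output is sorted by p-value.
    """
    crit_a, crit_b = contrast
    samples_a = metadata.samples_where(**crit_a)
    samples_b = metadata.samples_where(**crit_b)
    samples_a = [s for s in samples_a if s in table.sample_ids]
    samples_b = [s for s in samples_b if s in table.sample_ids]
    if not samples_a or not samples_b:
        empty = crit_a if not samples_a else crit_b
        raise ValueError(f"contrast selects an empty group: {empty}")
    if set(samples_a) & set(samples_b):
        raise ValueError("contrast groups overlap")

    agg = aggregate_taxon(table, taxonomy, rank)
    df = agg.to_dataframe()
    va, vb = df[samples_a], df[samples_b]
    keep = (va.sum(axis=1) > 0) | (vb.sum(axis=1) > 0)

    rows = []
    for taxon in df.index[keep]:
        cmp = welch_test(va.loc[taxon], vb.loc[taxon], ci_level=ci_level, taxon=taxon)
        rows.append({
            "taxon": taxon, "mean_a": cmp.mean_a, "mean_b": cmp.mean_b,
            "difference": cmp.mean_difference, "t_statistic": cmp.t_statistic,
            "df_welch": cmp.df_welch, "p_two_sided": cmp.p_two_sided,
            "ci_low": cmp.ci_low, "ci_high": cmp.ci_high,
            "n_a": cmp.n_a, "n_b": cmp.n_b,
        })
    out = pd.DataFrame(rows).sort_values("p_two_sided", kind="mergesort")
    out = out.reset_index(drop=True)
    if fdr and len(out):
        logger.warning("applying Benjamini-Hochberg FDR correction to %d taxa", len(out))
        out["q_bh"] = _benjamini_hochberg(out["p_two_sided"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_i in range(n, 0, -1):
        i = order[rank_i - 1]
        prev = min(prev, p[i] * n / rank_i)
        q[i] = prev
    return q


def write_comparisons(df: pd.DataFrame, path: str | Path) -> None:
    """Write comparisons as a STAMP-compatible tab-separated profile."""
    df.to_csv(path, sep="\t", index=False)
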