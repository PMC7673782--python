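"""Replicate-aware KO-vs-WT comparison of editing profiles.

The unit of replication is the mouse: each sample contributes one per-site
editing percentage and one proportion per isoform, and groups are compared
with a normality-gated two-sample test -- Student's t-test when both
groups pass a Shapiro-Wilk check (alpha_norm = 0.05), Mann-Whitney
otherwise (and always when a group has fewer than three values or is
constant).  Differences are reported as KO mean - WT mean in percentage
points; isoform effects as the KO/WT ratio of group mean proportions.
Multiple-testing correction is off by default (matching the raw p < 0.05
convention of the source tables) and available as Benjamini-Hochberg per
region.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference import N_PATTERNS, SITE_ORDER, index_pattern, pattern_label
from .profiling import SampleEditingProfile

logger = logging.getLogger(__name__)

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"


def normality_gate(
    group1: Sequence[float],
    group2: Sequence[float],
    alpha_norm: float = 0.05,
) -> str:
    """Choose the two-sample test per the stated policy.

    Student's t-test iff both groups pass Shapiro-Wilk at ``alpha_norm``;
    Mann-Whitney otherwise, and by default when either group has fewer
    than three values or is constant (Shapiro-Wilk is undefined there).
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    if len(g1) < 3 or len(g2) < 3:
        return MANN_WHITNEY
    for g in (g1, g2):
        if np.ptp(g) == 0:
            logger.warning("constant group encountered; using Mann-Whitney")
            return MANN_WHITNEY
        if stats.shapiro(g).pvalue <= alpha_norm:
            return MANN_WHITNEY
    return T_TEST


def gated_test(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[str, float]:
    """Run the normality-gated test; returns (test name, two-sided p).

    Mann-Whitney uses the exact null distribution for small untied
    samples and the tie-corrected normal approximation otherwise; two
    identical constant groups carry no evidence and give p = 1.
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    test = normality_gate(g1, g2)
    if test == T_TEST:
        p = stats.ttest_ind(g1, g2).pvalue
    else:
        pooled = np.concatenate([g1, g2])
        if np.ptp(pooled) == 0:
            return MANN_WHITNEY, 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue
    return test, float(p)


def _split_groups(
    profiles: Iterable[SampleEditingProfile],
    genotypes: tuple[str, str],
) -> dict[str, dict[str, list[SampleEditingProfile]]]:
    """region -> genotype -> profiles."""
    out: dict[str, dict[str, list[SampleEditingProfile]]] = {}
    for p in profiles:
        if p.genotype not in genotypes:
            raise ValueError(f"sample {p.sample_id}: unknown genotype {p.genotype!r}")
        region = p.region or "all"
        out.setdefault(region, {g: [] for g in genotypes})[p.genotype].append(p)
    return out


def compare_sites(
    profiles: Iterable[SampleEditingProfile],
    alpha: float = 0.05,
    genotypes: tuple[str, str] = ("WT", "KO"),
) -> pd.DataFrame:
    """Per region x site differential table (one frequency per mouse).

    Columns: region, site, n_wt, n_ko, mean_wt, mean_ko, diff (KO - WT,
    percentage points), test, p, significant.  Samples missing a site
    (NaN percentage) are excluded from that site with a warning.
    """
    groups = _split_groups(profiles, genotypes)
    wt_name, ko_name = genotypes
    rows = []
    for region, by_geno in sorted(groups.items()):
        for site in SITE_ORDER:
            vals = {}
            for geno in genotypes:
                v = np.array([p.site_pct(site) for p in by_geno[geno]])
                if np.isnan(v).any():
                    logger.warning(
                        "region %s site %s: excluding %d sample(s) with no coverage",
                        region, site, int(np.isnan(v).sum()),
                    )
                    v = v[~np.isnan(v)]
                vals[geno] = v
            wt, ko = vals[wt_name], vals[ko_name]
            test, p = gated_test(wt, ko)
            rows.append(
                {
                    "region": region,
                    "site": site,
                    "n_wt": len(wt),
                    "n_ko": len(ko),
                    "mean_wt": wt.mean(),
                    "mean_ko": ko.mean(),
                    "diff": ko.mean() - wt.mean(),
                    "test": test,
                    "p": p,
                    "significant": p < alpha,
                }
            )
    df = pd.DataFrame(rows)
    order = {s: i for i, s in enumerate(SITE_ORDER)}
    return df.sort_values(
        ["region", "site"], key=lambda c: c.map(order) if c.name == "site" else c
    ).reset_index(drop=True)


def compare_isoforms(
    profiles: Iterable[SampleEditingProfile],
    alpha: float = 0.05,
    genotypes: tuple[str, str] = ("WT", "KO"),
    low_abundance_pct: float = 5.0,
) -> pd.DataFrame:
    """Per region x isoform differential table.

    Each mouse contributes one proportion (% of its complete reads) per
    pattern; the effect size is the KO/WT ratio of group mean proportions.
    Patterns absent from every sample in a region are omitted (logged);
    rows with WT mean abundance below ``low_abundance_pct`` are flagged
    ``low_abundance`` rather than dropped.
    """
    groups = _split_groups(profiles, genotypes)
    wt_name, ko_name = genotypes
    rows = []
    for region, by_geno in sorted(groups.items()):
        props = {
            g: np.vstack([p.isoform_proportions() for p in by_geno[g]])
            for g in genotypes
        }
        for idx in range(N_PATTERNS):
            wt = props[wt_name][:, idx]
            ko = props[ko_name][:, idx]
            if np.nansum(wt) == 0 and np.nansum(ko) == 0:
                logger.info(
                    "region %s: pattern %s absent in all samples, omitted",
                    region, pattern_label(index_pattern(idx)),
                )
                continue
            test, p = gated_test(wt, ko)
            mean_wt, mean_ko = wt.mean(), ko.mean()
            rows.append(
                {
                    "region": region,
                    "pattern": pattern_label(index_pattern(idx)),
                    "bits": "".join(map(str, index_pattern(idx))),
                    "n_wt": len(wt),
                    "n_ko": len(ko),
                    "wt_mean_pct": mean_wt,
                    "ko_wt_ratio": mean_ko / mean_wt if mean_wt > 0 else np.nan,
                    "test": test,
                    "p": p,
                    "significant": p < alpha,
                    "low_abundance": mean_wt < low_abundance_pct,
                }
            )
    return pd.DataFrame(rows)


def multiple_testing(
    table: pd.DataFrame, method: str = "none", alpha: float = 0.05
) -> pd.DataFrame:
    """Add an adjusted-p column: ``none`` copies raw p, ``bh`` applies
    Benjamini-Hochberg within each region."""
    out = table.copy()
    if method == "none":
        out["p_adj"] = out["p"]
    elif method == "bh":
        out["p_adj"] = np.nan
        for _, idx in out.groupby("region").groups.items():
            out.loc[idx, "p_adj"] = multipletests(
                out.loc[idx, "p"].values, alpha=alpha, method="fdr_bh"
            )[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out
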