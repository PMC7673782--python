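"""RiboMeth-seq 2'-O-methylation scoring from 5'-end count profiles.

Alkaline degradation cleaves RNA at random phosphodiester bonds; a
2'-O-methyl at nucleotide m protects the bond 3' of m, so sequencing read
5'-ends are depleted at position m + 1.  The score quantifies that local
deficit: with n_i the end count at position i,

    score(p) = max(0, 1 - n_p / w),

where w is the weighted mean of the neighbor counts at offsets +-1..+-k
(default k = 6) with linearly decreasing weights k, k-1, ..., 1, the
neighborhood excluding positions that belong to other annotated
methylation sites.  A fully protected position scores 1.0; a flat profile
scores 0; the score is invariant to global scaling of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import gated_test

#: A methyl at nucleotide m suppresses read ends at m + CLEAVAGE_OFFSET.
CLEAVAGE_OFFSET = 1


@dataclass
class EndCountProfile:
    """Per-position 5'-end read counts with annotated methylation sites."""

    name: str
    counts: np.ndarray
    sites: dict[int, str] = field(default_factory=dict)  # position -> label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("end counts must be non-negative")
        for pos in self.sites:
            if not 0 <= pos < len(self.counts):
                raise ValueError(f"annotated site {pos} out of range")

    def __len__(self) -> int:
        return len(self.counts)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"position": np.arange(len(self.counts)), "count": self.counts}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, name: str | None = None, sites: dict[int, str] | None = None
    ) -> "EndCountProfile":
        df = pd.read_csv(path, sep="\t")
        counts = np.zeros(int(df["position"].max()) + 1, dtype=np.int64)
        counts[df["position"].to_numpy()] = df["count"].to_numpy()
        return cls(name=name or Path(path).stem, counts=counts, sites=sites or {})


def read_site_annotation(path: str | Path) -> dict[int, str]:
    """Site annotation TSV with columns ``position`` and ``label``."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["position"].astype(int), df["label"].astype(str)))


def meth_score(
    profile: EndCountProfile, pos: int, k: int = 6
) -> float | None:
    """Protection score at end-count position ``pos`` (see module docs).

    Positions at ``site + CLEAVAGE_OFFSET`` of *other* annotated sites are
    excluded from the neighborhood.  Returns None (missing) when the
    weighted neighbor mean is zero; raises for an out-of-range position.
    """
    n = profile.counts
    if not 0 <= pos < len(n):
        raise IndexError(f"position {pos} outside profile of length {len(n)}")
    if pos - 1 < 0 or pos + 1 >= len(n):
        raise IndexError(f"position {pos} needs at least one neighbor each side")
    excluded = {
        s + CLEAVAGE_OFFSET for s in profile.sites if s + CLEAVAGE_OFFSET != pos
    }
    wsum = wtot = 0.0
    for offset in range(1, k + 1):
        weight = k + 1 - offset
        for j in (pos - offset, pos + offset):
            if 0 <= j < len(n) and j not in excluded:
                wsum += weight * float(n[j])
                wtot += weight
    if wtot == 0:
        return None
    w = wsum / wtot
    if w == 0:
        return None
    return max(0.0, 1.0 - float(n[pos]) / w)


def score_sites(profile: EndCountProfile, k: int = 6) -> pd.DataFrame:
    """Score every annotated methylation site of a profile.

    The score for a site at nucleotide m is evaluated at end-count
    position m + CLEAVAGE_OFFSET.
    """
    rows = []
    for pos in sorted(profile.sites):
        rows.append(
            {
                "position": pos,
                "label": profile.sites[pos],
                "score": meth_score(profile, pos + CLEAVAGE_OFFSET, k=k),
            }
        )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    for thresh, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < thresh:
            return mark
    return "ns"


def compare_meth(
    wt_profiles: Sequence[EndCountProfile],
    ko_profiles: Sequence[EndCountProfile],
    sites: dict[int, str] | None = None,
    k: int = 6,
) -> pd.DataFrame:
    """Per-site genotype comparison of replicate methylation scores.

    Uses the same normality-gated two-sample test as the editing module;
    replicates in which a site's score is missing are excluded from that
    site.  Significance tiers are annotated as *, **, *** at 0.05 / 0.01 /
    0.001.
    """
    if len(wt_profiles) < 2 or len(ko_profiles) < 2:
        raise ValueError("at least two replicates per group required")
    if sites is None:
        sites = wt_profiles[0].sites
    rows = []
    for pos in sorted(sites):
        scores = {}
        for name, group in (("wt", wt_profiles), ("ko", ko_profiles)):
            vals = [meth_score(p, pos + CLEAVAGE_OFFSET, k=k) for p in group]
            scores[name] = np.array([v for v in vals if v is not None])
        test, p = gated_test(scores["wt"], scores["ko"])
        rows.append(
            {
                "position": pos,
                "label": sites[pos],
                "mean_wt": scores["wt"].mean(),
                "mean_ko": scores["ko"].mean(),
                "test": test,
                "p": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)
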