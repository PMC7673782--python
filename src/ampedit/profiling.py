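"""Per-read editing calls, per-sample profiles, isoform tables, recoding.

This is the heart of the pipeline.  For every aligned read, each of the
five editing sites is called EDITED (base 'G'), UNEDITED (base 'A') or
MASKED -- a site is masked when the base quality is below the gate
(default Q20), when the observed base is neither A nor G (a sequencing
error to C/T carries no editing information), or when the read does not
cover the site.  Per-site percentages use every read that covers the site;
the 32-class isoform table uses only *complete* reads (all five sites
called), because a partial read cannot be assigned to one of the 32
classes without imputation.

Translating each pattern through the three recoded codons (residues 156,
158, 160) collapses the 32 mRNA classes onto 24 distinct protein variants,
from unedited INI to fully edited VGV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .align import AlignedRead
from .reference import (
    DISPLAY_ORDER,
    N_PATTERNS,
    N_SITES,
    SITE_ORDER,
    AmpliconRef,
    Pattern,
    all_patterns,
    index_pattern,
    pattern_index,
    pattern_label,
)

logger = logging.getLogger(__name__)

EDITED, UNEDITED, MASKED = 1, 0, -1
_CALL_NAMES = {EDITED: "EDITED", UNEDITED: "UNEDITED", MASKED: "MASKED"}


@dataclass(frozen=True)
class ReadSiteCalls:
    """One read's call vector over the five sites (genomic order A,B,E,C,D)."""

    read_id: str
    calls: tuple[int, int, int, int, int]

    @property
    def complete(self) -> bool:
        return MASKED not in self.calls

    @property
    def pattern(self) -> Pattern:
        """Editing pattern; only meaningful when ``complete``."""
        return tuple(int(c == EDITED) for c in self.calls)


def call_sites(
    ar: AlignedRead, ref: AmpliconRef, min_q: int = 20
) -> ReadSiteCalls:
    """Quality-gated editing call at each site for one aligned read."""
    calls = []
    for offset in ref.site_offsets:
        if not ar.covers(offset):
            calls.append(MASKED)
            continue
        base = ar.base_at(offset)
        if ar.qual_at(offset) < min_q:
            calls.append(MASKED)
        elif base == "G":
            calls.append(EDITED)
        elif base == "A":
            calls.append(UNEDITED)
        else:
            calls.append(MASKED)
    return ReadSiteCalls(read_id=ar.read_id, calls=tuple(calls))


def site_frequencies(calls: Iterable[ReadSiteCalls]) -> pd.DataFrame:
    """Per-site coverage and editing percentage over a collection of reads.

    Returns a DataFrame indexed by site name (genomic order) with columns
    ``n_covered``, ``n_edited`` and ``pct``; a site covered by no read gets
    ``pct = NaN`` (missing, not 0%).
    """
    mat = np.array([c.calls for c in calls], dtype=np.int8)
    if mat.size == 0:
        raise ValueError("site_frequencies requires at least one read")
    n_covered = (mat != MASKED).sum(axis=0)
    n_edited = (mat == EDITED).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_covered > 0, 100.0 * n_edited / n_covered, np.nan)
    return pd.DataFrame(
        {"n_covered": n_covered, "n_edited": n_edited, "pct": pct},
        index=pd.Index(SITE_ORDER, name="site"),
    )


def isoform_counts(
    calls: Iterable[ReadSiteCalls],
) -> tuple[np.ndarray, int]:
    """32-bin tally of complete reads; returns (counts, n_incomplete)."""
    counts = np.zeros(N_PATTERNS, dtype=np.int64)
    n_incomplete = 0
    for c in calls:
        if c.complete:
            counts[pattern_index(c.pattern)] += 1
        else:
            n_incomplete += 1
    return counts, n_incomplete


# ---------------------------------------------------------------------------
# Protein recoding
# ---------------------------------------------------------------------------


def build_recoding_table(ref: AmpliconRef) -> dict[Pattern, str]:
    """Map each of the 32 editing patterns to its protein tripeptide.

    For every pattern, each recoded codon is rewritten with 'G' at its
    edited site offsets and translated with the standard genetic code;
    the result is the residue triplet at positions (156, 158, 160).
    """
    table: dict[Pattern, str] = {}
    residues = sorted(ref.codon_map)
    for pattern in all_patterns():
        peptide = []
        for residue in residues:
            start, codon = ref.codon_map[residue]
            bases = list(codon)
            for site_i in ref.sites_in_codon(residue):
                if pattern[site_i]:
                    bases[ref.site_offsets[site_i] - start] = "G"
            peptide.append(str(Seq("".join(bases)).translate()))
        table[pattern] = "".join(peptide)
    return table


def translate_pattern(pattern: Sequence[int], table: dict[Pattern, str]) -> str:
    return table[tuple(int(b) for b in pattern)]


# ---------------------------------------------------------------------------
# Sample profiles
# ---------------------------------------------------------------------------


@dataclass
class SampleEditingProfile:
    """Per-sample per-site frequencies plus the 32-class isoform tally."""

    sample_id: str
    genotype: str | None = None
    region: str | None = None
    site_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    isoform_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(N_PATTERNS, dtype=np.int64)
    )
    n_incomplete: int = 0

    @property
    def n_complete(self) -> int:
        return int(self.isoform_counts.sum())

    def site_pct(self, site: str) -> float:
        return float(self.site_table.loc[site, "pct"])

    def isoform_proportions(self) -> np.ndarray:
        """Isoform proportions as % of complete reads (NaN if none)."""
        total = self.isoform_counts.sum()
        if total == 0:
            return np.full(N_PATTERNS, np.nan)
        return 100.0 * self.isoform_counts / total

    def complete_read_marginal(self) -> np.ndarray:
        """Per-site editing % computed from complete reads only."""
        props = self.isoform_proportions()
        patterns = np.array([index_pattern(i) for i in range(N_PATTERNS)])
        return patterns.T @ props

    # -- TSV round trip ----------------------------------------------------

    def write_tsv(
        self,
        outdir: str | Path,
        recoding: dict[Pattern, str] | None = None,
    ) -> tuple[Path, Path]:
        """Write ``<sample>.sites.tsv`` and ``<sample>.isoforms.tsv``.

        Percentages are printed with 2 decimals (full precision is kept in
        memory); isoform rows are in binary pattern order and carry the
        protein tripeptide when a recoding table is supplied.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sites_path = outdir / f"{self.sample_id}.sites.tsv"
        iso_path = outdir / f"{self.sample_id}.isoforms.tsv"
        sites = self.site_table.copy()
        sites["pct"] = sites["pct"].round(2)
        # display in the conventional A,B,C,D,E naming order
        sites.loc[list(DISPLAY_ORDER)].to_csv(sites_path, sep="\t")
        rows = []
        props = self.isoform_proportions()
        for idx in range(N_PATTERNS):
            pattern = index_pattern(idx)
            row = {
                "pattern": pattern_label(pattern),
                "bits": "".join(map(str, pattern)),
                "count": int(self.isoform_counts[idx]),
                "pct": round(float(props[idx]), 2) if self.n_complete else np.nan,
            }
            if recoding is not None:
                row["tripeptide"] = recoding[pattern]
            rows.append(row)
        pd.DataFrame(rows).to_csv(iso_path, sep="\t", index=False)
        return sites_path, iso_path

    @classmethod
    def read_tsv(
        cls,
        outdir: str | Path,
        sample_id: str,
        genotype: str | None = None,
        region: str | None = None,
    ) -> "SampleEditingProfile":
        outdir = Path(outdir)
        sites = pd.read_csv(outdir / f"{sample_id}.sites.tsv", sep="\t", index_col=0)
        sites = sites.loc[list(SITE_ORDER)]
        iso = pd.read_csv(outdir / f"{sample_id}.isoforms.tsv", sep="\t")
        counts = np.zeros(N_PATTERNS, dtype=np.int64)
        for _, row in iso.iterrows():
            bits = tuple(int(ch) for ch in str(row["bits"]).zfill(N_SITES))
            counts[pattern_index(bits)] = int(row["count"])
        return cls(
            sample_id=sample_id,
            genotype=genotype,
            region=region,
            site_table=sites,
            isoform_counts=counts,
        )


def profile_sample(
    aligned_reads: Iterable[AlignedRead],
    ref: AmpliconRef,
    sample_id: str,
    genotype: str | None = None,
    region: str | None = None,
    min_q: int = 20,
) -> SampleEditingProfile:
    """Run site calling, frequency and isoform tabulation for one sample."""
    calls = [call_sites(ar, ref, min_q=min_q) for ar in aligned_reads]
    if not calls:
        raise ValueError(f"sample {sample_id!r}: zero accepted reads")
    sites = site_frequencies(calls)
    counts, n_incomplete = isoform_counts(calls)
    logger.info(
        "sample %s: %d reads, %d complete, %d incomplete",
        sample_id,
        len(calls),
        int(counts.sum()),
        n_incomplete,
    )
    return SampleEditingProfile(
        sample_id=sample_id,
        genotype=genotype,
        region=region,
        site_table=sites,
        isoform_counts=counts,
        n_incomplete=n_incomplete,
    )


def profile_from_counts(
    sample_id: str,
    counts: np.ndarray,
    genotype: str | None = None,
    region: str | None = None,
) -> SampleEditingProfile:
    """Build a profile directly from a 32-class isoform tally.

    Used when replicate-level statistics are simulated at the sampling
    layer (every read complete); the site table is the exact marginal of
    the tally.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    patterns = np.array([index_pattern(i) for i in range(N_PATTERNS)])
    n_edited = patterns.T @ counts
    site_table = pd.DataFrame(
        {
            "n_covered": np.full(N_SITES, total),
            "n_edited": n_edited,
            "pct": 100.0 * n_edited / total if total else np.nan,
        },
        index=pd.Index(SITE_ORDER, name="site"),
    )
    return SampleEditingProfile(
        sample_id=sample_id,
        genotype=genotype,
        region=region,
        site_table=site_table,
        isoform_counts=counts,
    )
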