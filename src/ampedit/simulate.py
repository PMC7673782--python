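"""Synthetic amplicon reads, cohorts, and RiboMeth-seq end-count profiles.

The read generator emulates the statistical structure of deep amplicon
sequencing of the Htr2c editing locus: each read is one cDNA molecule whose
editing pattern over the five sites is drawn from a 32-class isoform
distribution, rendered as A->G substitutions on the reference, then
corrupted with uniform substitution errors and assigned Phred qualities.
Cohorts add mouse-level replication: each mouse gets its own true per-site
editing probabilities jittered around the group mean (between-mouse sd
~1 percentage point, matching the low inter-animal variability of the real
data), and each genotype group has 6-12 mice sequenced to 10^4-10^6 reads.

The RiboMeth-seq generator draws per-position 5'-end counts from a Poisson
around a smooth coverage profile; a 2'-O-methyl at nucleotide m protects
the bond 3' of m, suppressing read ends at position m+1 by a protection
factor in [0, 1] (the cleavage-offset convention is shared with the scorer
via :data:`ampedit.ribomethseq.CLEAVAGE_OFFSET`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .reference import (
    N_PATTERNS,
    N_SITES,
    AmpliconRef,
    ConfigurationError,
    all_patterns,
    index_pattern,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")


@dataclass(frozen=True)
class QualityModel:
    """Gaussian Phred-score model with a low-quality dropout fraction.

    Per-base qualities are drawn Normal(mean, sd), rounded and clipped to
    [2, 41]; with probability ``dropout`` a base instead gets a quality
    drawn uniformly from [2, 19], i.e. below the Q20 calling gate.
    """

    mean: float = 35.0
    sd: float = 3.0
    dropout: float = 0.01

    def sample(self, rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
        q = np.rint(rng.normal(self.mean, self.sd, size=shape))
        q = np.clip(q, 2, 41).astype(np.int16)
        low = rng.random(shape) < self.dropout
        q[low] = rng.integers(2, 20, size=int(low.sum()))
        return q


@dataclass(frozen=True)
class SimulationConfig:
    """Per-sample simulation parameters.

    ``per_site_probs`` are the marginal editing probabilities in genomic
    site order (A, B, E, C, D).  In ``independent`` linkage mode sites are
    edited independently; in ``explicit_haplotypes`` mode the 32-vector
    ``haplotype_freqs`` (binary pattern order) is used verbatim.
    """

    per_site_probs: tuple[float, ...] = (0.6, 0.5, 0.1, 0.15, 0.35)
    linkage_mode: str = "independent"
    haplotype_freqs: tuple[float, ...] | None = None
    n_reads: int = 50_000
    read_length: int | None = None  # None -> full amplicon span
    base_error_rate: float = 0.001
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_site_probs) != N_SITES:
            raise ConfigurationError("per_site_probs must have five entries")
        if not all(0.0 <= p <= 1.0 for p in self.per_site_probs):
            raise ConfigurationError("per_site_probs must lie in [0, 1]")
        if self.linkage_mode not in ("independent", "explicit_haplotypes"):
            raise ConfigurationError(f"unknown linkage_mode {self.linkage_mode!r}")
        if self.linkage_mode == "explicit_haplotypes":
            if self.haplotype_freqs is None:
                raise ConfigurationError(
                    "explicit_haplotypes mode requires haplotype_freqs"
                )
            if len(self.haplotype_freqs) != N_PATTERNS:
                raise ConfigurationError("haplotype_freqs must have 32 entries")
            if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
                raise ConfigurationError("haplotype_freqs must sum to 1")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise ConfigurationError("base_error_rate must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth attached to one simulated sample."""

    sample_id: str
    per_site_freqs: np.ndarray        # generating marginals, genomic order
    isoform_freqs: np.ndarray         # generating 32-vector
    sampled_pattern_counts: np.ndarray  # realized multinomial tally (32 ints)

    def __post_init__(self) -> None:
        marg = marginalize(self.isoform_freqs)
        if not np.allclose(marg, self.per_site_freqs, atol=1e-9):
            raise ConfigurationError(
                "per-site frequencies inconsistent with isoform frequencies"
            )


def isoform_distribution(cfg: SimulationConfig) -> np.ndarray:
    """32-vector of isoform frequencies implied by the configuration.

    In independent mode the frequency of pattern b in {0,1}^5 is
    prod_i p_i^{b_i} (1-p_i)^{1-b_i}; in explicit mode the configured
    haplotype frequencies are returned verbatim.
    """
    if cfg.linkage_mode == "explicit_haplotypes":
        return np.asarray(cfg.haplotype_freqs, dtype=float)
    p = np.asarray(cfg.per_site_probs, dtype=float)
    freqs = np.empty(N_PATTERNS)
    for idx, pattern in enumerate(all_patterns()):
        b = np.asarray(pattern)
        freqs[idx] = np.prod(np.where(b == 1, p, 1.0 - p))
    return freqs


def marginalize(isoform_freqs: np.ndarray) -> np.ndarray:
    """Per-site marginal frequencies of a 32-vector (genomic site order)."""
    freqs = np.asarray(isoform_freqs, dtype=float)
    patterns = np.array([index_pattern(i) for i in range(N_PATTERNS)])
    return patterns.T @ freqs


def generate_reads(
    ref: AmpliconRef,
    cfg: SimulationConfig,
    fastq_path: str | Path,
    sample_id: str = "sample",
) -> TruthRecord:
    """Simulate one sample's FASTQ (Phred+33) and return its ground truth.

    Each read: sample an isoform pattern, substitute 'G' at the edited site
    offsets, apply i.i.d. substitution errors at ``base_error_rate``, and
    assign per-base qualities from the quality model.  Byte-identical
    output for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    L = len(ref)
    read_len = cfg.read_length if cfg.read_length is not None else L
    if read_len > L or read_len < 1:
        raise ConfigurationError("read_length must lie in [1, amplicon length]")

    freqs = isoform_distribution(cfg)
    pattern_ids = rng.choice(N_PATTERNS, size=cfg.n_reads, p=freqs)
    tally = np.bincount(pattern_ids, minlength=N_PATTERNS)

    ref_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    reads = np.tile(ref_arr[:read_len], (cfg.n_reads, 1))
    pattern_matrix = np.array([index_pattern(i) for i in range(N_PATTERNS)])
    edited_bits = pattern_matrix[pattern_ids]  # (n_reads, 5)
    for site_i, offset in enumerate(ref.site_offsets):
        if offset < read_len:
            rows = edited_bits[:, site_i] == 1
            reads[rows, offset] = _G

    if cfg.base_error_rate > 0:
        err = rng.random(reads.shape) < cfg.base_error_rate
        # draw a uniformly random *different* base at each error position
        shift = rng.integers(1, 4, size=int(err.sum()))
        idx = np.searchsorted(_BASES, reads[err])
        reads[err] = _BASES[(idx + shift) % 4]

    quals = cfg.quality_model.sample(rng, reads.shape)

    with open(fastq_path, "w") as fh:
        qual_bytes = (quals + 33).astype(np.uint8)
        for i in range(cfg.n_reads):
            fh.write(
                f"@{sample_id}:{i}\n{reads[i].tobytes().decode()}\n+\n"
                f"{qual_bytes[i].tobytes().decode()}\n"
            )

    return TruthRecord(
        sample_id=sample_id,
        per_site_freqs=marginalize(freqs),
        isoform_freqs=freqs,
        sampled_pattern_counts=tally,
    )


def sample_pattern_counts(
    cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one sample's 32-class isoform tally, Multinomial(n_reads, freqs).

    This is the read generator's sampling layer without base-level
    rendering; downstream replicate-level statistics see the same
    distribution either way.
    """
    return rng.multinomial(cfg.n_reads, isoform_distribution(cfg))


def jitter_probs(
    probs: Sequence[float], sd: float, rng: np.random.Generator
) -> tuple[float, ...]:
    """Mouse-level jitter: Normal(p, sd) truncated to [0, 1] per site."""
    p = np.clip(np.asarray(probs, float) + rng.normal(0.0, sd, N_SITES), 0.0, 1.0)
    return tuple(p)


# ---------------------------------------------------------------------------
# RiboMeth-seq end-count simulation
# ---------------------------------------------------------------------------


def generate_endcounts(
    n_positions: int,
    methylated_sites: dict[int, float],
    coverage: float = 1000.0,
    seed: int = 0,
    modulation: float = 0.2,
):
    """Simulate per-position 5'-end read counts on an rRNA reference.

    Counts are Poisson around a smooth sinusoidally modulated coverage
    level.  A methylated nucleotide m (with protection factor f in [0, 1])
    suppresses the expected end count at position m + CLEAVAGE_OFFSET by
    (1 - f); protection 1.0 yields an exact zero count.

    Returns an :class:`ampedit.ribomethseq.EndCountProfile` annotated with
    the methylated sites.
    """
    from .ribomethseq import CLEAVAGE_OFFSET, EndCountProfile

    rng = np.random.default_rng(seed)
    pos = np.arange(n_positions)
    lam = coverage * (1.0 + modulation * np.sin(2 * np.pi * pos / max(n_positions, 1)))
    for site, protection in methylated_sites.items():
        target = site + CLEAVAGE_OFFSET
        if not (0 <= site < n_positions and 0 <= target < n_positions):
            raise ConfigurationError(f"methylated site {site} out of range")
        if not 0.0 <= protection <= 1.0:
            raise ConfigurationError("protection factor must lie in [0, 1]")
        lam[target] *= 1.0 - protection
    counts = rng.poisson(lam)
    sites = {p: f"site_{p}" for p in methylated_sites}
    return EndCountProfile(name="synthetic_rRNA", counts=counts, sites=sites)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    """One mouse's sample in a cohort configuration."""

    sample_id: str
    genotype: str
    region: str
    per_site_probs: tuple[float, ...]
    n_reads: int
    seed: int


def build_cohort_specs(
    regions: dict[str, Sequence[float]],
    n_mice: int = 10,
    n_reads: int = 50_000,
    mouse_sd: float = 0.01,
    ko_shift: dict[str, Sequence[float]] | None = None,
    seed: int = 0,
) -> list[SampleSpec]:
    """Expand a two-genotype cohort into per-mouse sample specs.

    ``regions`` maps region name -> WT per-site editing probabilities
    (genomic site order); ``ko_shift`` optionally maps region -> additive
    per-site shift applied to the KO group.  Each mouse's true
    probabilities are jittered with sd ``mouse_sd`` around the group mean;
    per-sample seeds are expanded from the root seed.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    specs: list[SampleSpec] = []
    child_seeds = iter(ss.generate_state(2 * len(regions) * n_mice) % (2**31))
    for region, wt_probs in regions.items():
        for genotype in ("WT", "KO"):
            base = np.asarray(wt_probs, dtype=float)
            if genotype == "KO" and ko_shift and region in ko_shift:
                base = np.clip(base + np.asarray(ko_shift[region], float), 0, 1)
            for m in range(n_mice):
                specs.append(
                    SampleSpec(
                        sample_id=f"{genotype}_{region}_m{m + 1}",
                        genotype=genotype,
                        region=region,
                        per_site_probs=jitter_probs(base, mouse_sd, rng),
                        n_reads=n_reads,
                        seed=int(next(child_seeds)),
                    )
                )
    return specs


def spec_to_config(spec: SampleSpec, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(
        per_site_probs=tuple(spec.per_site_probs),
        n_reads=spec.n_reads,
        seed=spec.seed,
    )
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
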