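"""Anchored gapless alignment of amplicon reads, plus SAM ingestion.

Amplicon reads come from a single PCR product, so placement is a 1-D
search: every offset of the read (and of its reverse complement) along the
reference is scored by mismatch count and the best placement wins.  The
five editing-site columns are excluded from the mismatch count so that
heavily edited reads are not penalized for their A->G conversions.  Reads
whose best placement still exceeds ``max_mismatch_frac`` x read length are
rejected with a reason code.

Externally aligned reads (SAM/BAM restricted to the amplicon locus) can be
ingested instead; both routes yield the same :class:`AlignedRead` records
and therefore identical downstream site calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
from numpy.lib.stride_tricks import sliding_window_view

from .reference import AmpliconRef

logger = logging.getLogger(__name__)

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT).decode()[::-1]


@dataclass
class AlignedRead:
    """A read placed gaplessly on the amplicon reference (forward strand)."""

    read_id: str
    start: int                 # 0-based offset on the reference
    sequence: str              # reference-strand bases
    qualities: np.ndarray      # per-base Phred scores, same length
    n_mismatches: int = 0
    source: str = "internal"   # {internal, sam}
    strand: str = "+"          # original read orientation

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("alignment start must be >= 0")
        if len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must equal sequence length")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    def covers(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def base_at(self, pos: int) -> str:
        return self.sequence[pos - self.start]

    def qual_at(self, pos: int) -> int:
        return int(self.qualities[pos - self.start])


@dataclass(frozen=True)
class Rejection:
    """A read the aligner refused, with a machine-readable reason."""

    read_id: str
    reason: str  # {"empty", "too_long", "too_many_mismatches"}


class AmpliconAligner:
    """Scans all gapless placements of a read against one amplicon."""

    def __init__(self, ref: AmpliconRef, max_mismatch_frac: float = 0.1):
        self.ref = ref
        self.max_mismatch_frac = max_mismatch_frac
        self._ref_arr = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
        self._site_offsets = np.asarray(ref.site_offsets)

    def _best_placement(self, read_arr: np.ndarray) -> tuple[int, int]:
        """(offset, mismatches excluding site columns) of the best placement."""
        L, l = len(self._ref_arr), len(read_arr)
        windows = sliding_window_view(self._ref_arr, l)      # (L-l+1, l)
        mism = windows != read_arr
        counts = mism.sum(axis=1)
        offsets = np.arange(L - l + 1)
        for s in self._site_offsets:
            cols = s - offsets
            valid = (cols >= 0) & (cols < l)
            counts[valid] -= mism[offsets[valid], cols[valid]]
        best = int(np.argmin(counts))
        return best, int(counts[best])

    def align(
        self, read_id: str, sequence: str, qualities: np.ndarray
    ) -> AlignedRead | Rejection:
        if not sequence:
            return Rejection(read_id, "empty")
        if len(sequence) > len(self.ref):
            return Rejection(read_id, "too_long")
        fwd = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
        rc_seq = revcomp(sequence.upper())
        rev = np.frombuffer(rc_seq.encode(), dtype=np.uint8)
        off_f, mm_f = self._best_placement(fwd)
        off_r, mm_r = self._best_placement(rev)
        if mm_f <= mm_r:
            start, mm, strand = off_f, mm_f, "+"
            seq, quals = sequence.upper(), np.asarray(qualities)
        else:
            start, mm, strand = off_r, mm_r, "-"
            seq, quals = rc_seq, np.asarray(qualities)[::-1]
        if mm > self.max_mismatch_frac * len(sequence):
            return Rejection(read_id, "too_many_mismatches")
        return AlignedRead(
            read_id=read_id,
            start=start,
            sequence=seq,
            qualities=quals,
            n_mismatches=mm,
            source="internal",
            strand=strand,
        )

    def align_fastq(self, path: str | Path) -> Iterator[AlignedRead | Rejection]:
        with pysam.FastxFile(str(path)) as fh:
            for entry in fh:
                quals = np.array(entry.get_quality_array(), dtype=np.int16)
                yield self.align(entry.name, entry.sequence, quals)


def align_read(
    read_id: str,
    sequence: str,
    qualities: np.ndarray,
    ref: AmpliconRef,
    max_mismatch_frac: float = 0.1,
) -> AlignedRead | Rejection:
    """Convenience single-read wrapper around :class:`AmpliconAligner`."""
    return AmpliconAligner(ref, max_mismatch_frac).align(read_id, sequence, qualities)


def align_fastq(
    fastq: str | Path, ref: AmpliconRef, max_mismatch_frac: float = 0.1
) -> tuple[list[AlignedRead], list[Rejection]]:
    """Align a whole FASTQ; returns (accepted, rejected) with counts logged."""
    aligner = AmpliconAligner(ref, max_mismatch_frac)
    accepted: list[AlignedRead] = []
    rejected: list[Rejection] = []
    for res in aligner.align_fastq(fastq):
        (accepted if isinstance(res, AlignedRead) else rejected).append(res)
    logger.info(
        "aligned %d reads, rejected %d (%s)",
        len(accepted),
        len(rejected),
        fastq,
    )
    return accepted, rejected


def merge_mates(
    r1: AlignedRead, r2: AlignedRead, min_disagree_q: int = 20
) -> AlignedRead:
    """Merge two overlapping mates into one reference-strand read.

    At each overlapping position the base from the higher-quality mate is
    taken; if the mates disagree and both qualities are >= ``min_disagree_q``
    the position is masked ('N', quality 0).  Reference positions covered by
    neither mate inside the merged span are also masked.
    """
    start = min(r1.start, r2.start)
    end = max(r1.end, r2.end)
    seq = np.full(end - start, ord("N"), dtype=np.uint8)
    qual = np.zeros(end - start, dtype=np.int16)
    for r in (r1, r2):
        arr = np.frombuffer(r.sequence.encode(), dtype=np.uint8)
        sl = slice(r.start - start, r.end - start)
        better = np.asarray(r.qualities) > qual[sl]
        seq[sl] = np.where(better, arr, seq[sl])
        qual[sl] = np.where(better, r.qualities, qual[sl])
    lo, hi = max(r1.start, r2.start), min(r1.end, r2.end)
    if lo < hi:  # overlap: mask confident disagreements
        a1 = np.frombuffer(r1.sequence.encode(), dtype=np.uint8)[
            lo - r1.start : hi - r1.start
        ]
        a2 = np.frombuffer(r2.sequence.encode(), dtype=np.uint8)[
            lo - r2.start : hi - r2.start
        ]
        q1 = np.asarray(r1.qualities)[lo - r1.start : hi - r1.start]
        q2 = np.asarray(r2.qualities)[lo - r2.start : hi - r2.start]
        conflict = (a1 != a2) & (q1 >= min_disagree_q) & (q2 >= min_disagree_q)
        seq[lo - start : hi - start][conflict] = ord("N")
        qual[lo - start : hi - start][conflict] = 0
    return AlignedRead(
        read_id=r1.read_id,
        start=start,
        sequence=seq.tobytes().decode(),
        qualities=qual,
        n_mismatches=r1.n_mismatches + r2.n_mismatches,
        source=r1.source,
        strand="+",
    )


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) to 0-based half-open."""
    chrom, _, span = region.partition(":")
    lo, _, hi = span.partition("-")
    return chrom, int(lo) - 1, int(hi)


def load_sam(
    path: str | Path,
    ref: AmpliconRef,
    region: str | None = None,
) -> Iterator[AlignedRead]:
    """Yield primary mapped alignments from a SAM/BAM in amplicon coordinates.

    If ``region`` (``chrom:start-end``, 1-based inclusive) is given, only
    alignments overlapping it are kept and coordinates are shifted so the
    region start maps to amplicon position 0; otherwise alignments are
    expected on the amplicon reference itself.  Secondary, supplementary
    and unmapped records are skipped.  Deletions relative to the reference
    become masked positions ('N', quality 0); insertions are dropped.
    """
    shift = 0
    target = ref.name
    if region is not None:
        target, lo, hi = parse_region(region)
        shift = lo
    kept = skipped = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            if rec.reference_name != target:
                skipped += 1
                continue
            if region is not None and (rec.reference_end <= lo or rec.reference_start >= hi):
                skipped += 1
                continue
            start = rec.reference_start - shift
            span = rec.reference_end - rec.reference_start
            seq = np.full(span, ord("N"), dtype=np.uint8)
            qual = np.zeros(span, dtype=np.int16)
            query = rec.query_sequence
            quals = rec.query_qualities
            nm = 0
            for qpos, rpos in rec.get_aligned_pairs(matches_only=False):
                if rpos is None or not (rec.reference_start <= rpos < rec.reference_end):
                    continue
                i = rpos - rec.reference_start
                if qpos is not None and query is not None:
                    seq[i] = ord(query[qpos])
                    qual[i] = quals[qpos] if quals is not None else 0
            if start < 0:  # clip to amplicon window
                seq, qual = seq[-start:], qual[-start:]
                start = 0
            end = min(start + len(seq), len(ref))
            seq, qual = seq[: end - start], qual[: end - start]
            if len(seq) == 0:
                skipped += 1
                continue
            sequence = seq.tobytes().decode()
            ref_slice = ref.sequence[start : start + len(sequence)]
            nm = sum(
                1
                for i, (a, b) in enumerate(zip(sequence, ref_slice))
                if a != b and (start + i) not in ref.site_offsets
            )
            kept += 1
            yield AlignedRead(
                read_id=rec.query_name,
                start=start,
                sequence=sequence,
                qualities=qual,
                n_mismatches=nm,
                source="sam",
                strand="-" if rec.is_reverse else "+",
            )
    logger.info("load_sam(%s): kept %d, skipped %d", path, kept, skipped)


def write_sam(
    reads: Iterable[AlignedRead], ref: AmpliconRef, path: str | Path
) -> int:
    """Write internally aligned reads as a SAM file on the amplicon reference."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.read_id
            seg.query_sequence = r.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(int(q) + 33) for q in r.qualities)
            )
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.cigarstring = f"{len(r.sequence)}M"
            seg.mapping_quality = 60
            seg.flag = 16 if r.strand == "-" else 0
            out.write(seg)
            n += 1
    return n
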