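"""Amplicon reference model for the Htr2c editing locus.

The amplicon is a 249-nt cDNA segment spanning the spliced exon IV/exon V
junction of mouse *Htr2c*.  Exon V carries five editable adenosines -- the
A, B, C, D and E sites -- whose genomic 5'->3' order along the transcript
is A, B, E, C, D.  The sites fall inside three codons of the receptor's
second intracellular loop:

    residue 156  AUA (Ile)   sites A (codon pos 1) and B (codon pos 3)
    residue 158  AAU (Asn)   sites E (codon pos 1) and C (codon pos 2)
    residue 160  AUU (Ile)   site  D (codon pos 1)

A-to-I editing is read as A->G, so the 2^5 = 32 editing patterns recode
these residues; the unedited receptor is INI, the fully edited one VGV.

All coordinates are 0-based, half-open.  The codon/site table lives in
:class:`AmpliconRef` as data so that alternative recoding tables can be
injected without touching code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Site names in genomic (5'->3') order along the amplicon.
SITE_ORDER: tuple[str, ...] = ("A", "B", "E", "C", "D")

#: Site names in the conventional naming/display order.
DISPLAY_ORDER: tuple[str, ...] = ("A", "B", "C", "D", "E")

N_SITES = len(SITE_ORDER)
N_PATTERNS = 2 ** N_SITES

#: Fixed seed for the deterministic filler sequence around the codons.
_FILLER_SEED = 20200249


class ConfigurationError(ValueError):
    """Raised when reference or simulation options are inconsistent."""


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon plus editing-site and recoded-codon annotation.

    Parameters
    ----------
    name : str
        Sequence identifier (FASTA header).
    sequence : str
        Uppercase DNA sequence of length ``L``.
    site_offsets : tuple of int
        0-based offsets of the five sites, in genomic order
        ``SITE_ORDER`` = (A, B, E, C, D); strictly increasing.
    codon_map : dict
        ``residue index -> (codon start offset, reference codon)`` for the
        three recoded residues 156, 158 and 160.
    junction_offset : int
        Position of the exon IV/exon V splice junction within the amplicon.
    """

    name: str
    sequence: str
    site_offsets: tuple[int, int, int, int, int]
    codon_map: dict[int, tuple[int, str]] = field(
        default_factory=dict, hash=False, compare=False
    )
    junction_offset: int = 0

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if len(self.site_offsets) != N_SITES:
            raise ConfigurationError("exactly five site offsets required")
        if list(self.site_offsets) != sorted(set(self.site_offsets)):
            raise ConfigurationError("site offsets must be strictly increasing")
        if not all(0 <= o < L for o in self.site_offsets):
            raise ConfigurationError("site offsets must lie within the sequence")
        for o in self.site_offsets:
            if self.sequence[o] != "A":
                raise ConfigurationError(
                    f"reference base at site offset {o} is "
                    f"{self.sequence[o]!r}, expected 'A'"
                )
        for residue, (start, codon) in self.codon_map.items():
            if self.sequence[start : start + 3] != codon:
                raise ConfigurationError(
                    f"codon_map for residue {residue} does not match sequence"
                )
        if not 0 <= self.junction_offset < L:
            raise ConfigurationError("junction offset out of range")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def site_names(self) -> tuple[str, ...]:
        return SITE_ORDER

    def sites_in_codon(self, residue: int) -> list[int]:
        """Indices (into genomic site order) of the sites inside a codon."""
        start, _ = self.codon_map[residue]
        return [
            i
            for i, off in enumerate(self.site_offsets)
            if start <= off < start + 3
        ]

    def to_fasta(self, path: str | Path) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([record], str(path), "fasta")


def build_reference(
    length: int = 249,
    name: str = "Htr2c_amplicon",
    junction_offset: int = 100,
    codon156_offset: int = 120,
) -> AmpliconRef:
    """Construct the default amplicon reference.

    The three recoded codons are embedded back-to-back with the intervening
    Arg-157 (CGG) and Pro-159 (CCG) codons; everything else is a fixed,
    deterministic filler sequence (the pipeline never depends on filler
    identity, so any non-repetitive string serves).

    Raises
    ------
    ConfigurationError
        If ``length`` cannot accommodate the junction and the codon block.
    """
    codon_block = "ATA" + "CGG" + "AAT" + "CCG" + "ATT"  # residues 156..160
    block_end = codon156_offset + len(codon_block)
    if length < block_end or not (0 <= junction_offset <= codon156_offset):
        raise ConfigurationError(
            f"length {length} too short for codon block ending at {block_end} "
            f"or junction offset {junction_offset} misplaced"
        )
    rng = np.random.default_rng(_FILLER_SEED)
    seq = rng.choice(list("ACGT"), size=length)
    seq[codon156_offset:block_end] = list(codon_block)
    sequence = "".join(seq)

    site_offsets = (
        codon156_offset,      # A: codon 156 pos 1
        codon156_offset + 2,  # B: codon 156 pos 3
        codon156_offset + 6,  # E: codon 158 pos 1
        codon156_offset + 7,  # C: codon 158 pos 2
        codon156_offset + 12, # D: codon 160 pos 1
    )
    codon_map = {
        156: (codon156_offset, "ATA"),
        158: (codon156_offset + 6, "AAT"),
        160: (codon156_offset + 12, "ATT"),
    }
    return AmpliconRef(
        name=name,
        sequence=sequence,
        site_offsets=site_offsets,
        codon_map=codon_map,
        junction_offset=junction_offset,
    )


# ---------------------------------------------------------------------------
# Editing patterns: binary vectors over the five sites, in genomic bit order
# (site A is the most significant bit).
# ---------------------------------------------------------------------------

Pattern = tuple[int, int, int, int, int]


def all_patterns() -> Iterator[Pattern]:
    """All 32 editing patterns in binary order (A = most significant bit)."""
    return itertools.product((0, 1), repeat=N_SITES)


def pattern_index(pattern: Sequence[int]) -> int:
    """Bin index of a pattern; inverse of :func:`index_pattern`."""
    idx = 0
    for bit in pattern:
        idx = (idx << 1) | int(bit)
    return idx


def index_pattern(idx: int) -> Pattern:
    return tuple((idx >> (N_SITES - 1 - i)) & 1 for i in range(N_SITES))


def pattern_label(pattern: Sequence[int]) -> str:
    """Human-readable label: edited site letters in A,B,C,D,E naming order."""
    letters = sorted(
        name for name, bit in zip(SITE_ORDER, pattern) if bit
    )
    return "".join(letters) if letters else "none"
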