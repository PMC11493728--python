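"""Genotype calling and count tables for amplicon selection sequencing.

Reads are aligned to the reference amplicon, the targeted codon windows are
extracted through the alignment (so upstream indels cannot shift a window),
translated, and reported as protein-level genotypes.  Coordinates follow the
field's convention: protein positions are 1-based (``L-403-P``), nucleotide
intervals are 0-based half-open internally.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import edlib
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: complete 64-entry codon -> amino acid map, stops as "*"
CODON2AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON2AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

REJECT_INDEL = "indel-in-window"
REJECT_AMBIGUOUS = "ambiguous-base"
REJECT_STOP = "stop-codon"
REJECT_ALIGN = "alignment-fail"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconReference:
    """Reference amplicon with targeted, in-frame codon positions.

    ``coding_frame_offset`` is the 0-based index of the first base of the
    first complete codon; that codon encodes protein position
    ``first_codon_position`` (1-based protein coordinates).
    """

    sequence: str
    coding_frame_offset: int
    targeted_positions: tuple[int, ...]
    first_codon_position: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty reference sequence")
        if not 0 <= self.coding_frame_offset < len(self.sequence):
            raise ValueError("coding_frame_offset outside the amplicon")
        object.__setattr__(
            self, "targeted_positions", tuple(self.targeted_positions)
        )
        if list(self.targeted_positions) != sorted(set(self.targeted_positions)):
            raise ValueError("targeted positions must be strictly increasing")
        for start, end in self.codon_windows:
            if start < 0 or end > len(self.sequence):
                raise ValueError(
                    f"codon window [{start}, {end}) outside the amplicon"
                )

    @property
    def codon_windows(self) -> tuple[tuple[int, int], ...]:
        """0-based half-open nucleotide interval of each targeted codon."""
        windows = []
        for pos in self.targeted_positions:
            start = self.coding_frame_offset + 3 * (pos - self.first_codon_position)
            windows.append((start, start + 3))
        return tuple(windows)

    @property
    def coding_region(self) -> tuple[int, int]:
        n_codons = (len(self.sequence) - self.coding_frame_offset) // 3
        start = self.coding_frame_offset
        return (start, start + 3 * n_codons)

    def wt_codon(self, position: int) -> str:
        start = self.coding_frame_offset + 3 * (position - self.first_codon_position)
        return self.sequence[start : start + 3]

    def wt_aa(self, position: int) -> str:
        return CODON2AA[self.wt_codon(position)]

    @property
    def wt_aas(self) -> tuple[str, ...]:
        return tuple(self.wt_aa(p) for p in self.targeted_positions)


@dataclass(frozen=True)
class VariantGenotype:
    """Protein-level genotype at the targeted positions.

    ``substitutions`` holds ``(position, wt_aa, variant_aa)`` triples at the
    positions that deviate from wild type; the wild type itself is the empty
    tuple, labelled ``"WT"``.
    """

    substitutions: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        positions = [pos for pos, _, _ in self.substitutions]
        if positions != sorted(set(positions)):
            raise ValueError("substitution positions must be strictly increasing")
        for _, wt, aa in self.substitutions:
            if aa not in AA_ALPHABET or wt not in AA_ALPHABET:
                raise ValueError(f"amino acid outside the 20-letter alphabet: {wt}->{aa}")

    @property
    def label(self) -> str:
        if not self.substitutions:
            return "WT"
        return "; ".join(f"{wt}-{pos}-{aa}" for pos, wt, aa in self.substitutions)


@dataclass(frozen=True)
class GenotypeCall:
    """Outcome of calling one read: a genotype, or a rejection reason."""

    genotype: VariantGenotype | None = None
    rejection: str | None = None

    def __post_init__(self) -> None:
        if (self.genotype is None) == (self.rejection is None):
            raise ValueError("exactly one of genotype/rejection must be set")

    @property
    def ok(self) -> bool:
        return self.genotype is not None

    @property
    def label(self) -> str | None:
        return self.genotype.label if self.genotype is not None else None


@lru_cache(maxsize=32)
def _masked_reference(ref: AmpliconReference) -> str:
    """Reference with targeted windows wildcarded to 'N' for alignment.

    Variant codons then align at zero cost, so the aligner cannot trade a
    multi-substitution codon change for an equal-cost indel pair that would
    spuriously disrupt the window.
    """
    seq = list(ref.sequence)
    for start, end in ref.codon_windows:
        seq[start:end] = "NNN"
    return "".join(seq)


_N_EQUALITIES = [("N", b) for b in "ACGT"]


def load_reads(path) -> list[str]:
    """Read sequences from a FASTQ file (gzip transparent), in file order."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    reads: list[str] = []
    with opener(path, "rt") as fh:
        record = []
        for line in fh:
            record.append(line.rstrip("\n"))
            if len(record) == 4:
                header, seq, plus, qual = record
                index = len(reads)
                if not header.startswith("@") or not plus.startswith("+"):
                    raise ValueError(f"malformed FASTQ record at index {index}")
                if len(qual) != len(seq):
                    raise ValueError(
                        f"quality/sequence length mismatch at record {index}"
                    )
                reads.append(seq.upper())
                record = []
        if record:
            raise ValueError(
                f"truncated FASTQ record at index {len(reads)} ({len(record)} lines)"
            )
    return reads


def _extract_windows(
    read: str,
    cigar: str,
    windows: Sequence[tuple[int, int]],
    guard: int = 3,
) -> list[str] | None:
    """Map each reference window through the alignment to read bases.

    Returns one read-base string per window, or ``None`` if any window is
    disrupted by an indel.  The indel check uses the window expanded by
    ``guard`` bases on each side: optimal alignments place a gap anywhere
    of equal cost, so a deletion physically inside a (wildcard-masked)
    codon can surface at the window boundary — indels that close are
    ambiguous and the read is rejected rather than miscalled.
    """
    codons: list[list[str]] = [[] for _ in windows]
    guarded = [(s - guard, e + guard) for s, e in windows]
    last = max(e for _, e in guarded)
    ref_pos = 0
    read_pos = 0
    for length_s, op in _CIGAR_RE.findall(cigar):
        length = int(length_s)
        if op in ("=", "X", "M"):
            for i, (s, e) in enumerate(windows):
                lo = max(s, ref_pos)
                hi = min(e, ref_pos + length)
                if lo < hi:
                    off = read_pos + (lo - ref_pos)
                    codons[i].extend(read[off : off + (hi - lo)])
            ref_pos += length
            read_pos += length
        elif op == "D":  # gap in read: reference bases ref_pos..ref_pos+length-1 deleted
            for s, e in guarded:
                if ref_pos < e and ref_pos + length > s:
                    return None
            ref_pos += length
        elif op == "I":  # extra read bases between ref_pos-1 and ref_pos
            for s, e in guarded:
                if s < ref_pos < e:
                    return None
            read_pos += length
        if ref_pos >= last and all(len(c) == 3 for c in codons):
            break
    if any(len(c) != 3 for c in codons):
        return None
    return ["".join(c) for c in codons]


def call_genotype(
    read: str,
    ref: AmpliconReference,
    max_edit_frac: float = 0.3,
    try_revcomp: bool = True,
) -> GenotypeCall:
    """Call the protein genotype of one read at the targeted codons.

    The read is globally aligned to the reference (edit distance), each
    targeted codon window is extracted through the alignment and translated.
    Rejections (indel in a window, ambiguity code in a window, stop codon at
    a targeted position, unalignable read) are data, not errors.
    """
    if not read:
        return GenotypeCall(rejection=REJECT_ALIGN)
    target = _masked_reference(ref)
    result = edlib.align(
        read, target, task="path", mode="NW", additionalEqualities=_N_EQUALITIES
    )
    if try_revcomp:
        rc = reverse_complement(read)
        alt = edlib.align(
            rc, target, task="path", mode="NW", additionalEqualities=_N_EQUALITIES
        )
        if alt["editDistance"] < result["editDistance"]:
            result, read = alt, rc
    if result["editDistance"] > max_edit_frac * len(ref.sequence):
        return GenotypeCall(rejection=REJECT_ALIGN)
    codons = _extract_windows(read, result["cigar"], ref.codon_windows)
    if codons is None:
        return GenotypeCall(rejection=REJECT_INDEL)
    substitutions = []
    for pos, codon, wt_aa in zip(ref.targeted_positions, codons, ref.wt_aas):
        aa = CODON2AA.get(codon)
        if aa is None:
            return GenotypeCall(rejection=REJECT_AMBIGUOUS)
        if aa == "*":
            return GenotypeCall(rejection=REJECT_STOP)
        if aa != wt_aa:
            substitutions.append((pos, wt_aa, aa))
    return GenotypeCall(genotype=VariantGenotype(tuple(substitutions)))


def call_reads(
    reads: Iterable[str], ref: AmpliconReference, **kwargs
) -> list[GenotypeCall]:
    return [call_genotype(r, ref, **kwargs) for r in reads]


def call_labels(reads: Iterable[str], ref: AmpliconReference, **kwargs) -> list[str | None]:
    """Per-read genotype labels; ``None`` marks rejected reads."""
    return [c.label for c in call_reads(reads, ref, **kwargs)]


@dataclass
class VariantCountTable:
    """Per-genotype counts and frequencies for the pre (r0) and post (r1) rounds.

    Frequencies are over callable reads only, so they sum to 1 per round.
    """

    df: pd.DataFrame = field(repr=False)
    n_r0: int = 0
    n_r1: int = 0

    def to_tsv(self, path) -> None:
        out = self.df.reset_index().rename(columns={"index": "genotype_label"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantCountTable":
        df = pd.read_csv(path, sep="\t").set_index("genotype_label")
        return cls(df=df, n_r0=int(df["count_r0"].sum()), n_r1=int(df["count_r1"].sum()))


def _as_labels(calls: Iterable) -> list[str | None]:
    out = []
    for c in calls:
        out.append(c.label if isinstance(c, GenotypeCall) else c)
    return out


def build_count_table(calls_r0: Iterable, calls_r1: Iterable) -> VariantCountTable:
    """Tabulate per-genotype counts and frequencies for both rounds.

    Accepts sequences of :class:`GenotypeCall` or plain label strings
    (``None`` = uncallable read).  Variants absent in one round get count 0.
    """
    counts = []
    totals = []
    for calls in (calls_r0, calls_r1):
        labels = [lab for lab in _as_labels(calls) if lab is not None]
        if not labels:
            raise ValueError("zero callable reads in a round")
        counts.append(Counter(labels))
        totals.append(len(labels))
    genotypes = sorted(set(counts[0]) | set(counts[1]))
    df = pd.DataFrame(
        {
            "count_r0": [counts[0].get(g, 0) for g in genotypes],
            "count_r1": [counts[1].get(g, 0) for g in genotypes],
        },
        index=pd.Index(genotypes, name="genotype_label"),
    )
    df["freq_r0"] = df["count_r0"] / totals[0]
    df["freq_r1"] = df["count_r1"] / totals[1]
    return VariantCountTable(df=df, n_r0=totals[0], n_r1=totals[1])
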