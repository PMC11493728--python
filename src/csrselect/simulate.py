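"""Synthetic saturation-mutagenesis libraries, selection, and read simulation.

The generator emulates an emulsion self-replication (CSR) selection over a
saturation-mutagenesis polymerase library: each variant amplifies its own
gene with a per-cycle efficiency ``w``, so after ``cycles`` rounds its
expected abundance is proportional to ``pre_freq * (1 + w) ** cycles``.
Sequencing reads are full-length amplicons carrying the variant's codons,
mutated by a per-variant polymerase error spectrum (post-selection reads)
plus baseline sequencing/PCR noise (all reads).  Every emitted read is
tracked in a truth table so downstream estimates can be checked against the
generating parameters.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    AA_ALPHABET,
    CODON2AA,
    AmpliconReference,
    VariantGenotype,
)

BASES = "ACGT"
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE2IDX = {b: i for i, b in enumerate(BASES)}

#: NNK degenerate codons (N = any base, K = G/T); TAG is the single stop.
NNK_CODONS = tuple(
    a + b + c for a in BASES for b in BASES for c in "GT"
)
_ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def _representative_codons(codons: Sequence[str]) -> dict[str, str]:
    rep: dict[str, str] = {}
    for codon in sorted(codons):
        aa = CODON2AA[codon]
        if aa != "*" and aa not in rep:
            rep[aa] = codon
    return rep

_REP_CODON = {
    "NNK": _representative_codons(NNK_CODONS),
    "NNN": _representative_codons(_ALL_CODONS),
    "exhaustive-AA": _representative_codons(_ALL_CODONS),
}


@dataclass(frozen=True)
class LibrarySpec:
    """A saturation-mutagenesis library over targeted codon positions.

    ``theoretical_size`` is the protein-variant count excluding stop codons:
    20**k for k targeted positions (400 for k=2, 3.2e6 for k=5).
    """

    wt_amplicon: str
    coding_frame_offset: int
    targeted_positions: tuple[int, ...]
    codon_scheme: str = "NNK"
    first_codon_position: int = 1

    def __post_init__(self) -> None:
        if self.codon_scheme not in _REP_CODON:
            raise ValueError(f"unknown codon scheme {self.codon_scheme!r}")
        object.__setattr__(
            self, "targeted_positions", tuple(self.targeted_positions)
        )
        self.reference()  # validates frame and window bounds

    @property
    def theoretical_size(self) -> int:
        return 20 ** len(self.targeted_positions)

    def reference(self) -> AmpliconReference:
        return AmpliconReference(
            sequence=self.wt_amplicon,
            coding_frame_offset=self.coding_frame_offset,
            targeted_positions=self.targeted_positions,
            first_codon_position=self.first_codon_position,
        )


@dataclass
class Library:
    """Enumerated (or lazily enumerable) protein-variant library."""

    spec: LibrarySpec
    variants: list[tuple[str, ...]] | None

    @property
    def theoretical_size(self) -> int:
        return self.spec.theoretical_size

    def iter_variants(self) -> Iterator[tuple[str, ...]]:
        if self.variants is not None:
            yield from self.variants
        else:
            yield from itertools.product(
                AA_ALPHABET, repeat=len(self.spec.targeted_positions)
            )

    def genotype(self, aa_tuple: tuple[str, ...]) -> VariantGenotype:
        ref = self.spec.reference()
        subs = tuple(
            (pos, wt, aa)
            for pos, wt, aa in zip(ref.targeted_positions, ref.wt_aas, aa_tuple)
            if aa != wt
        )
        return VariantGenotype(subs)

    def label(self, aa_tuple: tuple[str, ...]) -> str:
        return self.genotype(aa_tuple).label

    @property
    def labels(self) -> list[str]:
        if self.variants is None:
            raise ValueError("library too large to enumerate labels")
        return [self.label(v) for v in self.variants]

    def variant_sequence(self, aa_tuple: tuple[str, ...]) -> str:
        """Amplicon sequence of a variant: WT with targeted codons replaced.

        The wild-type codon is kept where the variant amino acid equals WT;
        otherwise the scheme's lowest-sorting codon for that amino acid is
        used.
        """
        ref = self.spec.reference()
        rep = _REP_CODON[self.spec.codon_scheme]
        seq = list(self.spec.wt_amplicon)
        for (start, end), wt, aa in zip(ref.codon_windows, ref.wt_aas, aa_tuple):
            if aa != wt:
                seq[start:end] = rep[aa]
        return "".join(seq)


def build_library(spec: LibrarySpec, max_enumerate: int = 1_000_000) -> Library:
    """Enumerate every protein variant at the targeted positions (no stops).

    Libraries larger than ``max_enumerate`` are returned un-enumerated;
    ``theoretical_size`` and ``iter_variants`` remain available.
    """
    k = len(spec.targeted_positions)
    if spec.theoretical_size > max_enumerate:
        return Library(spec=spec, variants=None)
    variants = list(itertools.product(AA_ALPHABET, repeat=k))
    return Library(spec=spec, variants=variants)


# ---------------------------------------------------------------------------
# selection dynamics

def expected_post_frequencies(
    pre_frequencies: Mapping[str, float],
    fitness: Mapping[str, float],
    cycles: int,
) -> dict[str, float]:
    """Deterministic exponential-amplification expectation.

    Post frequency of variant m is proportional to
    ``pre_m * (1 + w_m) ** cycles``; variants absent from ``fitness`` get
    w = 0.
    """
    if not pre_frequencies:
        raise ValueError("empty library")
    for m, w in fitness.items():
        if w < 0:
            raise ValueError(f"negative fitness for {m!r}")
    weights = {
        m: f * (1.0 + fitness.get(m, 0.0)) ** cycles
        for m, f in pre_frequencies.items()
    }
    total = sum(weights.values())
    return {m: v / total for m, v in weights.items()}


def true_enrichment(
    pre_frequencies: Mapping[str, float],
    fitness: Mapping[str, float],
    cycles: int,
) -> dict[str, float]:
    """Closed-form enrichment ln(post_freq / pre_freq) under the model."""
    post = expected_post_frequencies(pre_frequencies, fitness, cycles)
    return {
        m: float(np.log(post[m] / f)) for m, f in pre_frequencies.items() if f > 0
    }


def simulate_selection(
    pre_frequencies: Mapping[str, float],
    fitness: Mapping[str, float],
    cycles: int,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> dict[str, int]:
    """Sample post-selection read counts: multinomial at the expected post
    frequencies."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    total = sum(pre_frequencies.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"pre frequencies sum to {total}, expected 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    post = expected_post_frequencies(pre_frequencies, fitness, cycles)
    labels = sorted(post)
    draws = rng.multinomial(depth, [post[m] for m in labels])
    return {m: int(c) for m, c in zip(labels, draws)}


# ---------------------------------------------------------------------------
# read emission

@dataclass(frozen=True)
class ErrorModel:
    """Per-base error process applied to emitted reads.

    Rates are per base; a substitution is a transition with probability
    ``ts_bias / (1 + ts_bias)`` — so ``ts_bias`` is the expected
    transition:transversion count ratio (default 2:1) — otherwise one of
    the two transversions, equiprobably.  ``del_rate``/``ins_rate`` are
    indel *bases* per reference base; a fraction ``frameshift_frac`` of the
    indel events are emitted at ``indel_length`` (frame-shifting unless that
    is a multiple of 3) and the remainder as 3-bp, frame-preserving events,
    mirroring how real amplicon indel bases are dominated by in-frame events
    while only a small fraction of reads end up frameshifted.
    """

    sub_rate: float = 0.0
    del_rate: float = 0.0
    ins_rate: float = 0.0
    ts_bias: float = 2.0
    indel_length: int = 1
    frameshift_frac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "del_rate", "ins_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {rate}")
        if self.ts_bias < 0:
            raise ValueError("ts_bias must be non-negative")
        if not 0.0 <= self.frameshift_frac <= 1.0:
            raise ValueError("frameshift_frac outside [0, 1]")


#: Baseline sequencing/PCR noise: per-type rates anchored to the published
#: pre-selection (R0) amplicon error spectrum (~7.9e-4 errors/bp total);
#: frameshift_frac calibrated so ~0.5% of reads frameshift, as observed.
DEFAULT_SEQUENCING_ERROR = ErrorModel(
    sub_rate=5.60e-4, del_rate=2.20e-4, ins_rate=9.69e-6, frameshift_frac=0.04
)

#: Default polymerase error spectrum for post-selection reads, sized so the
#: raw post-selection total (~8e-3 errors/bp) sits in the published range.
DEFAULT_POLYMERASE_ERROR = ErrorModel(
    sub_rate=7.15e-3, del_rate=1.50e-4, ins_rate=7.50e-5, frameshift_frac=0.04
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated selection."""

    per_variant_fitness: dict[str, float] = field(default_factory=dict)
    cycles: int = 20
    pre_depth: int = 100_000
    post_depth: int = 100_000
    polymerase_error: ErrorModel = DEFAULT_POLYMERASE_ERROR
    per_variant_error: dict[str, ErrorModel] = field(default_factory=dict)
    sequencing_error: ErrorModel = DEFAULT_SEQUENCING_ERROR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pre_depth <= 0 or self.post_depth <= 0:
            raise ValueError("read depths must be positive")
        if self.cycles < 0:
            raise ValueError("cycles must be non-negative")


@dataclass
class ReadSet:
    """Emitted reads for one round plus per-read provenance."""

    round_name: str
    sequences: list[str]
    provenance: pd.DataFrame  # read_id, variant, n_sub, ins_bases, del_bases, frameshift

    def write_fastq(self, path) -> None:
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        ids = self.provenance["read_id"].tolist()
        with opener(path, "wt") as fh:
            for read_id, seq in zip(ids, self.sequences):
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _apply_indels(
    row: np.ndarray,
    events: list[tuple[int, int]],  # (+length insertion, -length deletion)
    coding: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int, bool]:
    seq = list(row)
    ins_bases = del_bases = 0
    shift = 0  # net indel bases inside the coding region
    for kind, length in events:
        if kind < 0:  # deletion of `length` reference bases
            if len(seq) <= length:
                continue
            pos = int(rng.integers(0, len(seq) - length + 1))
            del seq[pos : pos + length]
            del_bases += length
            if pos >= coding[0]:
                shift -= length
        else:  # insertion of `length` random bases
            pos = int(rng.integers(0, len(seq) + 1))
            insert = rng.integers(0, 4, size=length).astype(np.uint8)
            seq[pos:pos] = list(insert)
            ins_bases += length
            if pos >= coding[0]:
                shift += length
    frameshift = shift % 3 != 0
    return np.asarray(seq, dtype=np.uint8), ins_bases, del_bases, frameshift


def _emit_reads(
    base: np.ndarray,
    n: int,
    models: Sequence[ErrorModel],
    coding: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Emit ``n`` reads of one variant under the combined error layers."""
    length = base.size
    sub_rate = min(1.0, sum(m.sub_rate for m in models))
    if sub_rate > 0:
        weights = [max(m.sub_rate, 0.0) for m in models]
        ts_bias = sum(w * m.ts_bias for w, m in zip(weights, models)) / sum(weights) \
            if sum(weights) else 2.0
    else:
        ts_bias = 2.0
    p_ts = ts_bias / (1.0 + ts_bias)

    mat = np.repeat(base[None, :], n, axis=0)
    mask = rng.random((n, length)) < sub_rate
    k = int(mask.sum())
    if k:
        u = rng.random(k)
        flip = np.where(u < p_ts, 2, np.where(u < p_ts + (1 - p_ts) / 2, 1, 3))
        mat[mask] ^= flip.astype(np.uint8)
    n_sub = mask.sum(axis=1).astype(np.int64)

    # indel events per read, per layer (rare; handled read-by-read);
    # rates are indel bases/bp, so event rates divide by the event length
    events_per_read: dict[int, list[tuple[int, int]]] = {}
    for model in models:
        for kind, rate in ((-1, model.del_rate), (+1, model.ins_rate)):
            if rate <= 0:
                continue
            classes = [
                (model.frameshift_frac / model.indel_length, model.indel_length),
                ((1.0 - model.frameshift_frac) / 3.0, 3),
            ]
            for frac_rate, event_len in classes:
                event_rate = rate * frac_rate
                if event_rate <= 0:
                    continue
                counts = rng.binomial(length, event_rate, size=n)
                for i in np.nonzero(counts)[0]:
                    events_per_read.setdefault(int(i), []).extend(
                        [(kind, event_len)] * int(counts[i])
                    )

    ins_bases = np.zeros(n, dtype=np.int64)
    del_bases = np.zeros(n, dtype=np.int64)
    frameshift = np.zeros(n, dtype=bool)
    ascii_mat = _ASCII[mat]
    sequences: list[str] = []
    for i in range(n):
        if i in events_per_read:
            row, ins, dele, fs = _apply_indels(
                mat[i], events_per_read[i], coding, rng
            )
            ins_bases[i], del_bases[i], frameshift[i] = ins, dele, fs
            sequences.append(_ASCII[row].tobytes().decode("ascii"))
        else:
            sequences.append(ascii_mat[i].tobytes().decode("ascii"))
    return sequences, n_sub, ins_bases, del_bases, frameshift


@dataclass
class SimulationResult:
    """Reads plus ground truth for one simulated selection."""

    library: Library
    config: SimulationConfig
    r0: ReadSet
    r1: ReadSet
    truth: pd.DataFrame  # per-variant: counts, expected freqs, fitness, E_true, rates

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_reads(
    pre_counts: Mapping[str, int],
    post_counts: Mapping[str, int],
    library: Library,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ReadSet, ReadSet]:
    """Emit FASTQ-ready reads for both rounds.

    Pre-selection reads carry only baseline sequencing noise; post-selection
    reads additionally carry the (per-variant) polymerase error spectrum.
    Emission order is deterministic (variants sorted by label), so a fixed
    seed yields byte-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref = library.spec.reference()
    coding = ref.coding_region
    seq_by_label = {
        library.label(v): library.variant_sequence(v) for v in library.iter_variants()
    }
    readsets = []
    for round_name, counts, polymerase in (
        ("r0", pre_counts, None),
        ("r1", post_counts, config.polymerase_error),
    ):
        sequences: list[str] = []
        rows = []
        read_no = 0
        for label in sorted(counts):
            n = int(counts[label])
            if n < 0:
                raise ValueError(f"negative count for {label!r}")
            if n == 0:
                continue
            base = np.array(
                [_BASE2IDX[b] for b in seq_by_label[label]], dtype=np.uint8
            )
            models = [config.sequencing_error]
            if polymerase is not None:
                models.append(config.per_variant_error.get(label, polymerase))
            seqs, n_sub, insb, delb, fs = _emit_reads(base, n, models, coding, rng)
            sequences.extend(seqs)
            for i in range(n):
                rows.append(
                    (
                        f"{round_name}_{read_no + i:07d}",
                        label,
                        int(n_sub[i]),
                        int(insb[i]),
                        int(delb[i]),
                        bool(fs[i]),
                    )
                )
            read_no += n
        provenance = pd.DataFrame(
            rows,
            columns=["read_id", "variant", "n_sub", "ins_bases", "del_bases", "frameshift"],
        )
        readsets.append(ReadSet(round_name, sequences, provenance))
    return readsets[0], readsets[1]


def simulate_dataset(
    library: Library,
    config: SimulationConfig,
    pre_frequencies: Mapping[str, float] | None = None,
) -> SimulationResult:
    """End-to-end simulation: library -> selection -> reads -> truth tables."""
    rng = np.random.default_rng(config.seed)
    labels = library.labels
    if pre_frequencies is None:
        pre_frequencies = {m: 1.0 / len(labels) for m in labels}
    order = sorted(pre_frequencies)
    pre_draw = rng.multinomial(
        config.pre_depth, [pre_frequencies[m] for m in order]
    )
    pre_counts = {m: int(c) for m, c in zip(order, pre_draw)}
    post_counts = simulate_selection(
        pre_frequencies, config.per_variant_fitness, config.cycles,
        config.post_depth, rng,
    )
    r0, r1 = simulate_reads(pre_counts, post_counts, library, config, rng)
    post_freq = expected_post_frequencies(
        pre_frequencies, config.per_variant_fitness, config.cycles
    )
    e_true = true_enrichment(
        pre_frequencies, config.per_variant_fitness, config.cycles
    )
    rows = []
    for m in order:
        err = config.per_variant_error.get(m, config.polymerase_error)
        rows.append(
            (
                m,
                pre_counts[m],
                post_counts[m],
                pre_frequencies[m],
                post_freq[m],
                config.per_variant_fitness.get(m, 0.0),
                e_true.get(m, float("nan")),
                err.sub_rate,
                err.del_rate,
                err.ins_rate,
            )
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "variant", "pre_count", "post_count", "pre_freq_expected",
            "post_freq_expected", "fitness", "E_true",
            "poly_sub_rate", "poly_del_rate", "poly_ins_rate",
        ],
    )
    return SimulationResult(library=library, config=config, r0=r0, r1=r1, truth=truth)


# ---------------------------------------------------------------------------
# default study conditions

_AMPLICON_LENGTH = 664
_FRAME_OFFSET = 2
_FIRST_CODON = 343
_FIXED_CODONS = {  # KOD-style residues around the catalytic aspartate
    403: "CTG",  # L
    404: "GAT",  # D
    405: "TTT",  # F
    406: "CGT",  # R
    408: "CTG",  # L
    409: "TAT",  # Y
}


def synthetic_wt_amplicon() -> str:
    """Fixed synthetic 664-bp amplicon with KOD-style residues at 403-409.

    The backbone is pseudo-random with a frozen internal seed; only the
    targeted-region codons are pinned, so genotype labels echo the familiar
    L403/D404 coordinates.
    """
    rng = np.random.default_rng(664403404)
    seq = list(_ASCII[rng.integers(0, 4, size=_AMPLICON_LENGTH)].tobytes().decode())
    for pos, codon in _FIXED_CODONS.items():
        start = _FRAME_OFFSET + 3 * (pos - _FIRST_CODON)
        seq[start : start + 3] = codon
    return "".join(seq)


def two_point_spec(positions: tuple[int, int] = (403, 404)) -> LibrarySpec:
    return LibrarySpec(
        wt_amplicon=synthetic_wt_amplicon(),
        coding_frame_offset=_FRAME_OFFSET,
        targeted_positions=positions,
        codon_scheme="NNK",
        first_codon_position=_FIRST_CODON,
    )


def five_point_spec(
    positions: tuple[int, ...] = (403, 404, 405, 408, 409)
) -> LibrarySpec:
    return LibrarySpec(
        wt_amplicon=synthetic_wt_amplicon(),
        coding_frame_offset=_FRAME_OFFSET,
        targeted_positions=positions,
        codon_scheme="NNK",
        first_codon_position=_FIRST_CODON,
    )


def default_scenario(
    seed: int = 0,
    n_winners: int = 10,
    winner_fitness: tuple[float, float] = (0.12, 0.30),
    pre_depth: int = 100_000,
    post_depth: int = 100_000,
    cycles: int = 20,
) -> tuple[Library, SimulationConfig]:
    """The package's reference study conditions.

    A 400-variant 2-point library with a uniform pre-selection pool and
    ``n_winners`` designated winners whose per-cycle amplification advantage
    is linearly spaced over ``winner_fitness``; everything else is neutral
    (w = 0).  After 20 cycles the winners jointly take roughly 60% of the
    post-selection pool, leaving the background at realistic residual
    frequencies.
    """
    library = build_library(two_point_spec())
    rng = np.random.default_rng(seed)
    non_wt = sorted(lab for lab in library.labels if lab != "WT")
    winners = sorted(rng.choice(non_wt, size=n_winners, replace=False).tolist())
    fitness = {
        m: float(w)
        for m, w in zip(winners, np.linspace(*winner_fitness, n_winners))
    }
    config = SimulationConfig(
        per_variant_fitness=fitness,
        cycles=cycles,
        pre_depth=pre_depth,
        post_depth=post_depth,
        seed=seed,
    )
    return library, config
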