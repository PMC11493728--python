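"""Alignment, error tallying, profiles, and substitution spectra."""

from __future__ import annotations

import numpy as np
import pytest

import csrselect as cs
from csrselect.fidelity import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH_SCORE,
    MISMATCH_SCORE,
    aggregate_profile,
    align_to_reference,
    profile_from_rates,
    substitution_spectrum,
    tally_errors,
    tally_read,
)

NEG = -1e18


def gotoh_oracle(ref: str, read: str):
    """Independent affine-gap DP (Gotoh): returns (score, subs, ins, dels).

    Same scoring as the package aligner: a length-k gap costs
    -(GAP_OPEN + (k-1) * GAP_EXTEND) in magnitude; traceback prefers
    match/mismatch over deletion over insertion.
    """
    n, m = len(ref), len(read)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in read (deletion)
    Y = np.full((n + 1, m + 1), NEG)  # gap in ref (insertion)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH_SCORE if ref[i - 1] == read[j - 1] else MISMATCH_SCORE
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, Y[i - 1, j] + GAP_OPEN,
                          X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, X[i, j - 1] + GAP_OPEN,
                          Y[i, j - 1] + GAP_EXTEND)
    i, j = n, m
    score = max(M[n, m], X[n, m], Y[n, m])
    state = "M" if M[n, m] == score else ("X" if X[n, m] == score else "Y")
    subs = dels = inss = 0
    while i > 0 or j > 0:
        if state == "M":
            s = MATCH_SCORE if ref[i - 1] == read[j - 1] else MISMATCH_SCORE
            if ref[i - 1] != read[j - 1]:
                subs += 1
            target = M[i, j] - s
            for st, v in (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                          ("Y", Y[i - 1, j - 1])):
                if abs(v - target) < 1e-9:
                    state = st
                    break
            i -= 1
            j -= 1
        elif state == "X":
            dels += 1
            cur = X[i, j]
            for st, v in (("M", M[i - 1, j] + GAP_OPEN),
                          ("X", X[i - 1, j] + GAP_EXTEND),
                          ("Y", Y[i - 1, j] + GAP_OPEN)):
                if abs(v - cur) < 1e-9:
                    state = st
                    break
            i -= 1
        else:
            inss += 1
            cur = Y[i, j]
            for st, v in (("M", M[i, j - 1] + GAP_OPEN),
                          ("X", X[i, j - 1] + GAP_EXTEND),
                          ("Y", Y[i, j - 1] + GAP_OPEN)):
                if abs(v - cur) < 1e-9:
                    state = st
                    break
            j -= 1
    return score, subs, inss, dels


def mutate(ref: str, rng, n_events: int):
    """Random sparse substitutions/indels; returns the mutated read."""
    bases = "ACGT"
    read = list(ref)
    for _ in range(n_events):
        p = int(rng.integers(0, len(read)))
        op = int(rng.integers(0, 3))
        if op == 0:
            read[p] = bases[int(rng.integers(0, 4))]
        elif op == 1 and len(read) > 10:
            del read[p]
        else:
            read.insert(p, bases[int(rng.integers(0, 4))])
    return "".join(read)


class TestAlignment:
    def test_identical_sequences_align_without_gaps(self):
        aln = align_to_reference("ACGTACGT", "ACGTACGT")
        assert aln.score == 8
        t = tally_errors(aln)
        assert t.total_errors == 0 and t.bases_analyzed == 8

    def test_single_internal_deletion_recovered(self):
        ref = "ACGTACGTACGT"
        read = ref[:5] + ref[6:]
        t = tally_read(read, ref)
        assert (t.deletion_bases, t.insertion_bases, t.substitutions) == (1, 0, 0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference("", "ACGT")

    def test_oracle_equivalence_on_random_mutated_reads(self):
        """Edit-operation counts agree with an independent Gotoh DP oracle."""
        rng = np.random.default_rng(17)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=90))
        for _ in range(40):
            read = mutate(ref, rng, int(rng.integers(0, 5)))
            aln = align_to_reference(read, ref)
            t = tally_errors(aln)
            score, subs, inss, dels = gotoh_oracle(ref, read)
            assert aln.score == pytest.approx(score)
            assert (t.substitutions, t.insertion_bases, t.deletion_bases) == (
                subs, inss, dels)


class TestTallyErrors:
    def test_one_mismatch_in_hundred_bases(self):
        rng = np.random.default_rng(1)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        read = ("G" if ref[50] != "G" else "C") + ref[1:]
        read = ref[:50] + ("G" if ref[50] != "G" else "C") + ref[51:]
        t = tally_read(read, ref)
        assert t.substitutions == 1 and t.bases_analyzed == 100

    def test_frameshift_flag_follows_indel_length(self):
        ref = "ATGAAACCCGGGTTTAAACCCGGG"
        two_bp = ref[:9] + ref[11:]
        three_bp = ref[:9] + ref[12:]
        assert tally_read(two_bp, ref, coding_region=(0, 24)).frameshift
        assert not tally_read(three_bp, ref, coding_region=(0, 24)).frameshift

    def test_conservation_matches_plus_subs_plus_dels(self):
        """Aligned reference columns partition into matches, substitutions,
        and deleted bases."""
        rng = np.random.default_rng(2)
        ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
        for _ in range(20):
            read = mutate(ref, rng, int(rng.integers(0, 6)))
            t = tally_read(read, ref)
            assert t.bases_analyzed + t.deletion_bases == len(ref)

    def test_excluded_windows_carry_no_errors_or_bases(self):
        ref = "AAACCCGGGTTT"
        read = "AAACTCGGGTTT"  # mismatch at position 4, inside (3, 6)
        t = tally_read(read, ref, exclude_windows=[(3, 6)])
        assert t.substitutions == 0
        assert t.bases_analyzed == len(ref) - 3

    def test_simulator_truth_recovered_exactly(self, two_point_library):
        """Injected error counts are recovered read-by-read (collision-free
        sparse regime)."""
        config = cs.SimulationConfig(
            pre_depth=300, post_depth=10, seed=13,
            sequencing_error=cs.ErrorModel(sub_rate=2e-3, del_rate=5e-4),
            polymerase_error=cs.ErrorModel(),
        )
        sim = cs.simulate_dataset(two_point_library, config)
        ref = two_point_library.spec.reference()
        coding = ref.coding_region
        exact = 0
        rows = list(sim.r0.provenance.itertuples())
        for seq, row in zip(sim.r0.sequences, rows):
            t = tally_read(seq, ref.sequence, coding_region=coding,
                           exclude_windows=ref.codon_windows)
            if (t.substitutions, t.deletion_bases, t.frameshift) == (
                    row.n_sub, row.del_bases, row.frameshift):
                exact += 1
        # substitutions inside the excluded targeted windows are invisible
        # to the tally, so allow those rare reads to differ
        assert exact >= 0.97 * len(rows)


class TestProfiles:
    def test_published_style_corrected_total_and_fold(self):
        baseline = profile_from_rates(10**7, 2.20e-4, 9.69e-6, 5.60e-4)
        sel = profile_from_rates(10**7, 3.66e-4, 8.62e-5, 7.71e-3,
                                 baseline=baseline)
        assert sel.corrected_total == pytest.approx(
            sel.rate_total - baseline.rate_total)
        assert sel.fold == 10

    def test_self_baseline_gives_zero_corrected_and_fold_one(self):
        p = profile_from_rates(10**6, 1e-4, 1e-5, 5e-4)
        corrected = p.with_baseline(p)
        assert corrected.corrected_total == pytest.approx(0.0)
        assert corrected.fold == 1

    def test_rate_total_is_sum_of_parts(self):
        p = profile_from_rates(10**6, 1.1e-4, 2.2e-5, 3.3e-4)
        assert p.rate_total == pytest.approx(p.rate_del + p.rate_ins + p.rate_sub)

    def test_frameshifted_reads_excluded_from_rates_but_counted(self):
        ref = "ATGAAACCCGGGTTTAAACCCGGG"
        clean = tally_read(ref, ref, coding_region=(0, 24))
        fs = tally_read(ref[:9] + ref[11:], ref, coding_region=(0, 24))
        profile = aggregate_profile([clean, clean, clean, fs])
        assert profile.frameshift_freq == pytest.approx(0.25)
        assert profile.rate_del == 0.0  # the frameshifted read's dels don't count
        assert profile.total_bases == 3 * len(ref)

    def test_adding_error_free_read_never_increases_rates(self):
        ref = "ATGAAACCCGGGTTTAAACCCGGG"
        noisy = tally_read(ref[:5] + "T" + ref[6:], ref)
        before = aggregate_profile([noisy])
        after = aggregate_profile([noisy, tally_read(ref, ref)])
        assert after.rate_sub <= before.rate_sub
        assert after.rate_total <= before.rate_total

    def test_library_rate_is_weighted_mean_of_genotype_rates(self, small_sim,
                                                             reference):
        reads = small_sim.r1.sequences[:400]
        labels = cs.call_labels(reads, reference)
        coding = reference.coding_region
        tallies = [
            tally_read(r, reference.sequence, coding_region=coding,
                       exclude_windows=reference.codon_windows)
            for r in reads
        ]
        kept = [(l, t) for l, t in zip(labels, tallies)
                if l is not None and not t.frameshift]
        per_genotype = cs.mutant_error_rates(kept)
        total_err = sum(p.rate_total * p.total_bases for p in per_genotype.values())
        total_bases = sum(p.total_bases for p in per_genotype.values())
        pooled = aggregate_profile([t for _, t in kept])
        assert pooled.rate_total == pytest.approx(total_err / total_bases)

    def test_per_genotype_recovery_of_distinct_error_rates(self, two_point_library):
        """Two variants simulated at 1e-3 vs 1e-2 substitution rates are
        recovered within 3 binomial SE of truth."""
        lib = two_point_library
        fast, slow = "L-403-F", "D-404-E"
        config = cs.SimulationConfig(
            per_variant_fitness={},
            pre_depth=10, post_depth=400, seed=23,
            sequencing_error=cs.ErrorModel(),
            polymerase_error=cs.ErrorModel(sub_rate=1e-3),
            per_variant_error={slow: cs.ErrorModel(sub_rate=1e-2)},
        )
        pre = {m: 0.0 for m in lib.labels}
        pre[fast] = 0.5
        pre[slow] = 0.5
        sim = cs.simulate_dataset(lib, config, pre_frequencies=pre)
        ref = lib.spec.reference()
        labels = cs.call_labels(sim.r1.sequences, ref)
        tallies = [
            tally_read(r, ref.sequence, coding_region=ref.coding_region,
                       exclude_windows=ref.codon_windows)
            for r in sim.r1.sequences
        ]
        profiles = cs.mutant_error_rates(zip(labels, tallies))
        for label, rate in ((fast, 1e-3), (slow, 1e-2)):
            est = profiles[label].rate_sub
            n = profiles[label].total_bases
            se = np.sqrt(rate * (1 - rate) / n)
            assert abs(est - rate) < 3 * se


class TestSpectrum:
    def test_pure_transition_events_have_zero_transversion_rate(self):
        ref = "CCCCCCCCCC"
        read = "CCCTCCCCCC"  # C->T transition
        counts, rates, ts_rate, tv_rate = substitution_spectrum(
            [tally_read(read, ref)])
        assert tv_rate == 0.0
        assert ts_rate == pytest.approx(0.1)
        assert counts.loc["C", "T"] == 1

    def test_matrix_offdiagonal_sums_equal_substitution_count(self, small_sim):
        ref_seq = small_sim.library.spec.wt_amplicon
        tallies = [tally_read(r, ref_seq) for r in small_sim.r1.sequences[:150]]
        counts, _, _, _ = substitution_spectrum(tallies)
        offdiag = counts.to_numpy().sum() - np.trace(counts.to_numpy())
        total_subs = sum(t.substitutions for t in tallies if not t.frameshift)
        assert offdiag == total_subs

    def test_configured_ts_bias_recovered(self, two_point_library):
        """Simulated 2:1 transition:transversion weight is recovered within
        3 SE of the multinomial expectation."""
        config = cs.SimulationConfig(
            pre_depth=2_000, post_depth=10, seed=29,
            sequencing_error=cs.ErrorModel(sub_rate=5e-3, ts_bias=2.0),
            polymerase_error=cs.ErrorModel(),
        )
        sim = cs.simulate_dataset(two_point_library, config)
        ref = two_point_library.spec.reference()
        # exclude the targeted codons: variant-defining changes are not errors
        tallies = [
            tally_read(r, ref.sequence, exclude_windows=ref.codon_windows)
            for r in sim.r0.sequences
        ]
        _, _, ts_rate, tv_rate = substitution_spectrum(tallies)
        n_events = sum(t.substitutions for t in tallies if not t.frameshift)
        ratio = ts_rate / tv_rate
        p = 2 / 3  # P(transition) at a 2:1 count ratio
        se_p = np.sqrt(p * (1 - p) / n_events)
        # delta method on the odds p/(1-p) at p=2/3: d(odds)/dp = 9
        assert abs(ratio - 2.0) < 3 * 9 * se_p
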