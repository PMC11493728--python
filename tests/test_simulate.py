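"""Library construction, selection dynamics, and read emission."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

import csrselect as cs
from csrselect.simulate import ErrorModel


class TestBuildLibrary:
    def test_two_point_library_has_400_protein_variants(self):
        lib = cs.build_library(cs.two_point_spec())
        assert lib.theoretical_size == 400
        assert len(lib.variants) == 400
        labels = lib.labels
        assert "WT" in labels
        assert len(set(labels)) == 400

    def test_five_point_library_size_excluding_stops(self):
        lib = cs.build_library(cs.five_point_spec())
        assert lib.theoretical_size == 3_200_000
        assert lib.variants is None  # too large to enumerate eagerly
        first = next(lib.iter_variants())
        assert len(first) == 5

    def test_zero_targeted_positions_gives_wt_only(self):
        spec = cs.LibrarySpec(
            wt_amplicon=cs.synthetic_wt_amplicon(),
            coding_frame_offset=2,
            targeted_positions=(),
            first_codon_position=343,
        )
        lib = cs.build_library(spec)
        assert lib.theoretical_size == 1
        assert lib.labels == ["WT"]

    def test_position_outside_amplicon_rejected(self):
        with pytest.raises(ValueError):
            cs.LibrarySpec(
                wt_amplicon=cs.synthetic_wt_amplicon(),
                coding_frame_offset=2,
                targeted_positions=(9999,),
                first_codon_position=343,
            )

    def test_variant_sequences_differ_only_at_targeted_codons(self):
        lib = cs.build_library(cs.two_point_spec())
        ref = lib.spec.reference()
        wt = lib.spec.wt_amplicon
        seq = lib.variant_sequence(("P", "D"))  # L403P, WT at 404
        (s1, e1), (s2, e2) = ref.codon_windows
        assert seq[:s1] == wt[:s1] and seq[e1:] == wt[e1:]
        assert cs.genotypes.CODON2AA[seq[s1:e1]] == "P"


class TestSimulateSelection:
    def test_neutral_fitness_preserves_frequencies(self):
        pre = {"A": 0.25, "B": 0.75}
        post = cs.expected_post_frequencies(pre, {"A": 0.3, "B": 0.3}, cycles=20)
        assert post == pytest.approx(pre)

    def test_single_cycle_doubling_gives_two_to_one(self):
        pre = {"A": 0.5, "B": 0.5}
        post = cs.expected_post_frequencies(pre, {"A": 1.0, "B": 0.0}, cycles=1)
        assert post["A"] / post["B"] == pytest.approx(2.0)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            cs.expected_post_frequencies({"A": 1.0}, {"A": -0.1}, 1)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            cs.expected_post_frequencies({}, {}, 1)

    def test_realized_log_ratio_matches_true_enrichment(self):
        """Mean realized ln(freq ratio) over seeds stays within 3 SE of the
        closed-form expectation for designated winners."""
        lib, config = cs.default_scenario(seed=0)
        labels = lib.labels
        pre = {m: 1.0 / len(labels) for m in labels}
        e_true = cs.true_enrichment(pre, config.per_variant_fitness, config.cycles)
        post_expected = cs.expected_post_frequencies(
            pre, config.per_variant_fitness, config.cycles
        )
        depth = 100_000
        winners = sorted(config.per_variant_fitness)
        realized = {m: [] for m in winners}
        for seed in range(10):
            counts = cs.simulate_selection(
                pre, config.per_variant_fitness, config.cycles, depth, seed=seed
            )
            for m in winners:
                realized[m].append(np.log(counts[m] / depth / pre[m]))
        for m in winners:
            p = post_expected[m]
            se_count = np.sqrt(depth * p * (1 - p))
            se_log = se_count / (depth * p)  # delta method on ln(freq)
            mean = np.mean(realized[m])
            assert abs(mean - e_true[m]) < 3 * se_log


class TestSimulateReads:
    def test_zero_error_rates_reproduce_exact_amplicons(self, two_point_library):
        lib = two_point_library
        config = cs.SimulationConfig(
            pre_depth=300, post_depth=300, seed=4,
            sequencing_error=ErrorModel(), polymerase_error=ErrorModel(),
        )
        sim = cs.simulate_dataset(lib, config)
        expected = {lib.label(v): lib.variant_sequence(v) for v in lib.iter_variants()}
        for seq, variant in zip(sim.r0.sequences, sim.r0.provenance["variant"]):
            assert seq == expected[variant]
        for seq, variant in zip(sim.r1.sequences, sim.r1.provenance["variant"]):
            assert seq == expected[variant]

    def test_read_counts_sum_to_requested_depth(self, small_sim):
        assert len(small_sim.r0.sequences) == small_sim.config.pre_depth
        assert len(small_sim.r1.sequences) == small_sim.config.post_depth
        assert small_sim.truth["pre_count"].sum() == small_sim.config.pre_depth
        assert small_sim.truth["post_count"].sum() == small_sim.config.post_depth

    def test_fixed_seed_is_byte_identical(self, tmp_path, two_point_library):
        config = cs.SimulationConfig(pre_depth=500, post_depth=500, seed=9)
        digests = []
        for run in range(2):
            sim = cs.simulate_dataset(two_point_library, config)
            path = tmp_path / f"run{run}.fastq"
            sim.r0.write_fastq(path)
            digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
        assert digests[0] == digests[1]

    def test_realized_substitution_rate_converges(self, two_point_library):
        """Realized base substitution rate within 3 binomial SE of the
        configured 1e-3 across seeds (~1e6 bases per seed)."""
        rate = 1e-3
        config_base = dict(
            pre_depth=1_500, post_depth=10,
            sequencing_error=ErrorModel(sub_rate=rate),
            polymerase_error=ErrorModel(),
        )
        realized = []
        n_bases = 1_500 * len(two_point_library.spec.wt_amplicon)
        for seed in range(10):
            sim = cs.simulate_dataset(
                two_point_library, cs.SimulationConfig(seed=seed, **config_base)
            )
            realized.append(sim.r0.provenance["n_sub"].sum() / n_bases)
        se = np.sqrt(rate * (1 - rate) / n_bases) / np.sqrt(10)
        assert abs(np.mean(realized) - rate) < 3 * se

    def test_two_bp_deletions_drive_frameshift_frequency(self, two_point_library):
        """A 2-bp deletion hitting ~1% of reads yields frameshift freq ~1%."""
        length = len(two_point_library.spec.wt_amplicon)
        config = cs.SimulationConfig(
            pre_depth=5_000, post_depth=10, seed=2,
            sequencing_error=ErrorModel(
                del_rate=0.01 * 2 / length, indel_length=2, frameshift_frac=1.0
            ),
            polymerase_error=ErrorModel(),
        )
        sim = cs.simulate_dataset(two_point_library, config)
        freq = sim.r0.provenance["frameshift"].mean()
        assert freq == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / 5_000))

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(sub_rate=1.5)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            cs.SimulationConfig(pre_depth=0, post_depth=10)
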