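"""Tandem-repeat and palindrome detection, hr calling and summaries."""

import numpy as np
import pytest

from baculoscan.genome_io import CircularSequence, reverse_complement
from baculoscan.hr_detection import (HrLocus, PalindromeHit, RepeatLocus,
                                     call_hrs, detect_palindromes,
                                     detect_tandem_repeats, summarize_hrs)
from baculoscan.synthetic_data import SimConfig, simulate_genome


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, s, rate):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestDetectTandemRepeats:
    def test_exact_array_recovered(self):
        rng = np.random.default_rng(1)
        unit = _random_dna(rng, 80)
        flanks = (_random_dna(rng, 400), _random_dna(rng, 400))
        seq = flanks[0] + unit * 4 + flanks[1]
        loci = detect_tandem_repeats(seq)
        assert len(loci) == 1
        loc = loci[0]
        assert loc.unit_length == 80
        assert loc.copy_number == pytest.approx(4.0, abs=0.2)
        assert loc.unit_identity >= 0.99

    def test_mutated_array_recovered(self):
        rng = np.random.default_rng(2)
        unit = _random_dna(rng, 80)
        array = "".join(_mutate(rng, unit, 0.05) for _ in range(4))
        seq = _random_dna(rng, 300) + array + _random_dna(rng, 300)
        loci = detect_tandem_repeats(seq)
        assert len(loci) == 1
        loc = loci[0]
        assert abs(loc.unit_length - 80) <= 2
        assert loc.copy_number >= 3.5
        assert loc.unit_identity >= 0.9

    def test_random_sequence_has_no_arrays(self):
        rng = np.random.default_rng(3)
        seq = _random_dna(rng, 500)
        loci = detect_tandem_repeats(seq, period_min=60, period_max=120,
                                     min_copies=2.5, min_unit_identity=0.8)
        assert loci == []

    def test_period_range_must_fit_sequence(self):
        with pytest.raises(ValueError):
            detect_tandem_repeats("ACGT" * 10, period_min=60, period_max=120)

    def test_rotation_invariance_on_circular_genome(self):
        genome, truth = simulate_genome(SimConfig(
            genome_length=12000, n_orfs=4, orf_length_aa=(60, 120),
            n_hrs=2, seed=9))
        L = len(genome.sequence)
        residues = genome.sequence.residues
        base = detect_tandem_repeats(genome.sequence)
        shift = 5000
        rot = CircularSequence(id="rot", residues=residues[shift:]
                               + residues[:shift])
        rotated = detect_tandem_repeats(rot)
        def key(loc):
            return ((loc.start - 1) % L, loc.unit_length)
        base_keys = {key(l) for l in base}
        rot_keys = {((l.start - 1 + shift) % L, l.unit_length)
                    for l in rotated}
        assert rot_keys == base_keys

    def test_reported_loci_pass_naive_verifier(self):
        """Every reported locus re-checks against its own thresholds with a
        naive column-wise comparison to the consensus."""
        genome, _ = simulate_genome(SimConfig(
            genome_length=15000, n_orfs=4, orf_length_aa=(60, 120),
            n_hrs=3, seed=4))
        for loc in detect_tandem_repeats(genome.sequence):
            dna = genome.sequence.fetch(loc.start, loc.end)
            period = loc.unit_length
            copies = [dna[i:i + period] for i in range(0, len(dna), period)]
            idents = []
            for c in copies:
                if len(c) < period // 4:
                    continue
                matches = sum(1 for k, ch in enumerate(c)
                              if ch == loc.consensus_unit[k])
                idents.append(matches / len(c))
            assert len(dna) / period >= 2.5
            assert float(np.mean(idents)) >= 0.6
            span = loc.end - loc.start + 1
            assert abs(span - period * loc.copy_number) <= period + 1


class TestDetectPalindromes:
    def test_canonical_perfect_palindrome(self):
        hits = detect_palindromes("GAATTC", min_arm=3, max_mismatches=0,
                                  max_loop=0)
        assert hits == [PalindromeHit(offset_in_unit=1, arm_length=3,
                                      loop_length=0, mismatches=0)]

    def test_homopolymer_is_not_palindromic(self):
        assert detect_palindromes("AAAAAA", min_arm=3) == []

    def test_imperfect_hit_matches_exhaustive_oracle(self):
        dna = "GAATATTTTC"
        hits = detect_palindromes(dna, min_arm=5, max_mismatches=1,
                                  max_loop=0)
        assert len(hits) == 1
        assert hits[0].arm_length == 5 and hits[0].mismatches == 1
        # exhaustive arm/loop enumeration oracle
        comp = dict(zip("ACGT", "TGCA"))
        found = []
        for arm in range(5, len(dna) // 2 + 1):
            for start in range(0, len(dna) - 2 * arm + 1):
                left = dna[start:start + arm]
                right = dna[start + arm:start + 2 * arm]
                mism = sum(1 for i in range(arm)
                           if left[i] != comp[right[arm - 1 - i]])
                if mism <= 1:
                    found.append((start + 1, arm, mism))
        assert (hits[0].offset_in_unit, hits[0].arm_length,
                hits[0].mismatches) in found

    def test_min_arm_validation(self):
        with pytest.raises(ValueError):
            detect_palindromes("ACGT", min_arm=2)


class TestCallHrs:
    def _planted(self, seed=5, n_hrs=2):
        return simulate_genome(SimConfig(
            genome_length=12000, n_orfs=4, orf_length_aa=(60, 120),
            n_hrs=n_hrs, seed=seed))

    def test_planted_hr_promoted_with_two_palindromes(self):
        genome, truth = self._planted()
        hrs = call_hrs(detect_tandem_repeats(genome.sequence),
                       genome.sequence)
        assert len(hrs) == 2
        for hr in hrs:
            assert len(hr.palindromes) >= 2
            assert hr.name.startswith("hr")

    def test_repeat_without_palindromes_not_promoted(self):
        rng = np.random.default_rng(17)
        # build a non-palindromic unit explicitly
        while True:
            unit = _random_dna(rng, 80)
            if not detect_palindromes(unit * 2):
                break
        seq = CircularSequence(
            id="s", residues=_random_dna(rng, 500) + unit * 4
            + _random_dna(rng, 500), topology="linear")
        repeats = detect_tandem_repeats(seq)
        assert len(repeats) == 1
        assert call_hrs(repeats, seq) == []

    def test_empty_repeat_list(self):
        seq = CircularSequence(id="s", residues="ACGT" * 100)
        assert call_hrs([], seq) == []


class TestSummarizeHrs:
    def test_length_range_from_planted_truth(self):
        rng = np.random.default_rng(6)
        unit = None
        genome, truth = simulate_genome(SimConfig(
            genome_length=15000, n_orfs=4, orf_length_aa=(60, 120),
            n_hrs=3, hr_copies=(3, 7), seed=6))
        hrs = call_hrs(detect_tandem_repeats(genome.sequence),
                       genome.sequence)
        summary = summarize_hrs(hrs, genome)
        assert summary.count == 3
        truth_lengths = sorted(h.end - h.start + 1 for h in truth.hrs)
        assert sorted(summary.lengths) == pytest.approx(truth_lengths,
                                                        abs=40)
        assert summary.length_range == (min(summary.lengths),
                                        max(summary.lengths))
        assert summary.consensus_msa is not None
        assert len(summary.consensus_msa.rows) == 3

    def test_all_at_locus_has_pooled_at_one(self):
        seq = CircularSequence(id="s", residues="A" * 200 + "CG" * 50)
        rep = RepeatLocus(start=1, end=200, unit_length=80, copy_number=2.5,
                          unit_identity=1.0, consensus_unit="A" * 80)
        hr = HrLocus(repeat=rep, palindromes=[], at_fraction=1.0, name="hr1")
        summary = summarize_hrs([hr], seq)
        assert summary.pooled_at_fraction == pytest.approx(1.0)

    def test_empty_input(self):
        seq = CircularSequence(id="s", residues="ACGT")
        summary = summarize_hrs([], seq)
        assert summary.count == 0 and summary.length_range is None
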