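"""Repeat counter: anchor placement vs a DP oracle, counting, SNP reading."""

import numpy as np
import pytest

from amplistr.counting import (
    AnchorHit,
    CounterParams,
    call_snp_base,
    count_repeats,
    locate_anchor,
    observe_read,
    observe_reads,
    orient_read,
)
from amplistr.locus import build_amplicon
from amplistr.simulate import SimRead, SimulationConfig, reverse_complement, simulate_sample


def semiglobal_oracle(anchor: str, read: str) -> tuple[int, int]:
    """Full-DP semi-global alignment: (min edit distance, leftmost end).

    Row-wise DP with the in-row (insertion-in-read) dependency resolved by a
    prefix-minimum pass; independent of the production aligner.
    """
    a = np.frombuffer(anchor.encode(), dtype=np.uint8)
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    m, n = len(a), len(r)
    prev = np.zeros(n + 1, dtype=np.int64)  # free start in read
    for i in range(1, m + 1):
        sub = prev[:-1] + (a[i - 1] != r)
        vert = prev[1:] + 1
        cand = np.minimum(sub, vert)
        cand = np.concatenate(([i], cand))
        # left-gap relaxation: cur[j] = min_k<=j cand[k] + (j - k)
        idx = np.arange(n + 1)
        cur = np.minimum.accumulate(cand - idx) + idx
        prev = cur
    best = int(prev.min())
    end = int(np.argmin(prev))
    return best, end


class TestLocateAnchor:
    def test_exact_substring_found_with_zero_edits(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        read = "".join(rng.choice(bases, 300))
        anchor = read[100:130]
        hit = locate_anchor(read, anchor)
        assert hit == AnchorHit(start=100, end=130, edits=0)

    def test_two_substitutions_found_at_known_offset(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        read = list("".join(rng.choice(bases, 300)))
        anchor = "".join(read[120:150])
        for pos in (125, 140):  # substitute inside the anchor span
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        hit = locate_anchor(read, anchor)
        assert hit is not None
        assert hit.edits == 2
        assert hit.start == 120
        assert hit.edits == semiglobal_oracle(anchor, read)[0]

    def test_random_read_without_anchor_returns_absent(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        read = "".join(rng.choice(bases, 500))
        anchor = "".join(rng.choice(bases, 30))
        oracle_edits, _ = semiglobal_oracle(anchor, read)
        hit = locate_anchor(read, anchor, max_edit_frac=0.25)
        if oracle_edits > 7:
            assert hit is None
        else:  # rare lucky placement: must agree with the oracle
            assert hit is not None and hit.edits == oracle_edits

    def test_matches_full_dp_oracle_on_randomized_cases(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(100):
            read = "".join(rng.choice(bases, int(rng.integers(50, 300))))
            if rng.random() < 0.5:
                start = int(rng.integers(0, len(read) - 30))
                anchor = list(read[start : start + 30])
                for _ in range(int(rng.integers(0, 6))):
                    pos = int(rng.integers(0, 30))
                    anchor[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[anchor[pos]]
                anchor = "".join(anchor)
            else:
                anchor = "".join(rng.choice(bases, 30))
            oracle_edits, _ = semiglobal_oracle(anchor, read)
            hit = locate_anchor(read, anchor, max_edit_frac=0.25)
            if oracle_edits <= 7:
                assert hit is not None and hit.edits == oracle_edits
            else:
                assert hit is None

    def test_short_anchor_rejected(self):
        with pytest.raises(ValueError):
            locate_anchor("ACGT" * 20, "ACGTACGT")


class TestOrientAndCount:
    def test_forward_read_keeps_plus_strand(self, locus):
        read = build_amplicon(locus, 12)
        oriented, strand = orient_read(read, locus)
        assert strand == "+"
        assert oriented == read

    def test_reverse_complement_read_counted_identically(self, locus):
        read = build_amplicon(locus, 12)
        obs_fwd = observe_read(SimRead("f", read, "I" * len(read)), locus)
        rc = reverse_complement(read)
        obs_rev = observe_read(SimRead("r", rc, "I" * len(rc)), locus)
        assert obs_rev.strand == "-"
        assert obs_fwd.repeat_count == obs_rev.repeat_count == 12
        assert obs_fwd.snp_calls == obs_rev.snp_calls

    def test_scrambled_flanks_make_read_uncountable(self, locus):
        rng = np.random.default_rng(4)
        seq = list(build_amplicon(locus, 12))
        rng.shuffle(seq)
        obs = observe_read(SimRead("x", "".join(seq), "I" * len(seq)), locus)
        assert obs.repeat_count is None

    def test_error_free_count_equals_construction(self, locus):
        for n in (5, 10, 24, 137):
            obs = observe_read(
                SimRead("r", build_amplicon(locus, n), "I" * len(build_amplicon(locus, n))),
                locus,
            )
            assert obs.repeat_count == n

    def test_single_deletion_in_tract_rounds_to_nearest_unit(self, locus):
        n = 10
        amp = build_amplicon(locus, n)
        cut = len(locus.left_flank) + 4  # delete one base inside the tract
        read = amp[:cut] + amp[cut + 1 :]
        obs = observe_read(SimRead("r", read, "I" * len(read)), locus)
        assert obs.repeat_count == n  # span 3n-1 rounds back to n

    def test_crossed_anchors_are_uncountable(self):
        left = AnchorHit(start=100, end=130, edits=0)
        right = AnchorHit(start=90, end=120, edits=0)
        assert count_repeats(left, right) is None


class TestSnpCalls:
    def test_error_free_read_reports_flank_base(self, locus):
        site = locus.snp_sites[0]
        read = build_amplicon(locus, 20)
        obs = observe_read(SimRead("r", read, "I" * len(read)), locus)
        assert obs.snp_calls[site.rsid] == "G"

    def test_alt_allele_read_reports_alt_base(self, locus):
        site = locus.snp_sites[0]
        read = build_amplicon(locus, 20, snp_bases={site.rsid: "A"})
        obs = observe_read(SimRead("r", read, "I" * len(read)), locus)
        assert obs.snp_calls[site.rsid] == "A"

    def test_insertion_between_anchor_and_site_still_recovered(self, locus):
        site = locus.snp_sites[0]
        amp = build_amplicon(locus, 20)
        pos = locus.snp_position(site)
        insert_at = pos + 100  # between the site and the left anchor
        read = amp[:insert_at] + "T" + amp[insert_at:]
        obs = observe_read(SimRead("r", read, "I" * len(read)), locus)
        assert obs.snp_calls[site.rsid] == "G"

    def test_obliterated_context_returns_absent(self, locus):
        site = locus.snp_sites[0]
        rng = np.random.default_rng(5)
        amp = list(build_amplicon(locus, 20))
        pos = locus.snp_position(site)
        scrambled = rng.permutation(np.array(amp[pos - 40 : pos + 40]))
        amp[pos - 40 : pos + 40] = list(scrambled)
        read = "".join(amp)
        obs = observe_read(SimRead("r", read, "I" * len(read)), locus)
        assert obs.snp_calls[site.rsid] is None


class TestParameterRecovery:
    def test_default_error_rates_count_within_size_proportional_band(self, locus):
        """Per-read sizing error under span-division counting grows like
        sqrt(n) from tract-internal indels and carries an O(1%) net-length
        bias; >=95% of reads must land within +/-(2 + 2% of n) units of
        their truth, up to 150-unit alleles.  (Allele-level modal calls are
        far tighter; see the calling tests.)"""
        config = SimulationConfig(
            genotype=(30, 150), n_reads=200, seed=17, artefact_fraction=0.0, mosaic_sd=0.0
        )
        reads, truths = simulate_sample(locus, config)
        observations = observe_reads(reads, locus)
        hits = sum(
            1
            for obs, truth in zip(observations, truths)
            if obs.repeat_count is not None
            and abs(obs.repeat_count - truth.true_units) <= 2 + 0.02 * truth.true_units
        )
        assert hits / len(truths) >= 0.95

    def test_small_allele_reads_count_within_two_units(self, locus):
        """For alleles up to ~50 units the +/-2 band itself holds per read."""
        config = SimulationConfig(
            genotype=(16, 50), n_reads=200, seed=19, artefact_fraction=0.0, mosaic_sd=0.0
        )
        reads, truths = simulate_sample(locus, config)
        observations = observe_reads(reads, locus)
        hits = sum(
            1
            for obs, truth in zip(observations, truths)
            if obs.repeat_count is not None
            and abs(obs.repeat_count - truth.true_units) <= 2
        )
        assert hits / len(truths) >= 0.95
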