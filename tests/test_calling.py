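"""Allele caller: artefact floor, modal calling, depth gate, phasing, mosaicism."""

import random

import pytest

from amplistr.calling import (
    CallerParams,
    Mode,
    NoCallError,
    RepeatHistogram,
    build_histogram,
    call_genotype,
    call_modes,
    classify_allele,
    flag_mosaicism,
    phase_and_refine,
)
from amplistr.counting import observe_reads
from amplistr.readqc import filter_reads
from amplistr.simulate import SimulationConfig, simulate_sample


def _hist(counts: dict[int, int]) -> RepeatHistogram:
    return build_histogram(
        [size for size, n in counts.items() for _ in range(n)]
    )


class TestBuildHistogram:
    def test_artefact_floor_excludes_below_five(self):
        h = _hist({3: 7, 16: 20})
        assert h.counts == {16: 20}
        assert h.artefact_reads == 7
        assert h.total_reads == 20

    def test_exactly_five_survives_the_floor(self):
        h = _hist({5: 1})
        assert h.counts == {5: 1}

    def test_empty_input_gives_empty_histogram(self):
        h = build_histogram([])
        assert h.counts == {} and h.total_reads == 0

    def test_uncountable_reads_tallied_separately(self):
        h = build_histogram([None, None, 20])
        assert h.uncountable_reads == 2
        assert h.counts == {20: 1}


class TestCallModes:
    def test_two_normal_peaks_sixteen_and_thirtyfive(self):
        h = _hist({15: 5, 16: 30, 17: 6, 34: 4, 35: 25, 36: 5})
        modes = call_modes(h)
        assert [m.size for m in modes] == [16, 35]

    def test_two_expanded_peaks_sixtytwo_and_seventyeight(self):
        h = _hist({61: 6, 62: 28, 63: 7, 77: 5, 78: 22, 79: 6})
        modes = call_modes(h)
        assert [m.size for m in modes] == [62, 78]

    def test_single_peak_is_unimodal(self):
        h = _hist({28: 6, 29: 30, 30: 4})
        modes = call_modes(h)
        assert [m.size for m in modes] == [29]
        assert modes[0].depth == 40

    def test_adjacent_equal_bins_break_toward_window_mass_then_smaller(self):
        # 18 contributes extra +/-2-window mass around 20 only, so 20 wins.
        h = _hist({18: 4, 20: 15, 21: 15})
        assert call_modes(h)[0].size == 20
        # Pure tie with symmetric surroundings: smaller size wins.
        h2 = _hist({20: 15, 21: 15})
        assert call_modes(h2)[0].size == 20

    def test_peaks_closer_than_min_separation_merge(self):
        h = _hist({60: 20, 61: 3, 63: 18})
        modes = call_modes(h)
        assert len(modes) == 1

    def test_depth_gate_drops_thin_second_peak(self):
        h = _hist({16: 40, 90: 10})  # 10 reads is not > 10
        modes = call_modes(h)
        assert [m.size for m in modes] == [16]

    def test_eleven_reads_pass_the_gate(self):
        h = _hist({16: 40, 90: 11})
        assert [m.size for m in call_modes(h)] == [16, 90]

    def test_all_modes_failing_gate_is_a_no_call(self):
        with pytest.raises(NoCallError):
            call_modes(_hist({16: 5, 40: 4}))
        with pytest.raises(NoCallError):
            call_modes(build_histogram([]))

    def test_every_reported_mode_exceeds_depth_gate(self):
        h = _hist({16: 30, 35: 12, 90: 8})
        for mode in call_modes(h):
            assert mode.depth > 10


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "size,expected",
        [(5, "normal"), (34, "normal"), (35, "intermediate"),
         (49, "intermediate"), (50, "expanded"), (137, "expanded")],
    )
    def test_band_boundaries(self, size, expected):
        assert classify_allele(size) == expected

    def test_below_artefact_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_allele(1)


class TestFlagMosaicism:
    def test_tight_peak_not_flagged(self):
        h = _hist({89: 10, 90: 40, 91: 12})
        mode = Mode(size=90, depth=62, basin=(89, 90, 91))
        assert flag_mosaicism(h, mode) is False

    def test_secondary_bump_at_35pct_height_flagged(self):
        h = _hist({85: 3, 90: 40, 97: 14, 98: 2})  # 14/40 = 35%
        mode = Mode(size=90, depth=59, basin=(85, 90, 97, 98))
        assert flag_mosaicism(h, mode) is True

    def test_broad_scatter_flagged(self):
        counts = {s: 3 for s in range(70, 110, 3)}
        counts[90] = 5
        h = _hist(counts)
        mode = Mode(size=90, depth=h.total_reads, basin=tuple(sorted(counts)))
        assert flag_mosaicism(h, mode) is True

    def test_high_mosaicism_simulations_mostly_flagged(self, locus):
        flags = []
        for seed in range(8):
            config = SimulationConfig(genotype=(20, 90), n_reads=200, seed=seed, mosaic_sd=0.15)
            reads, _ = simulate_sample(locus, config)
            h = build_histogram(observe_reads(reads, locus))
            big = max(call_modes(h), key=lambda m: m.size)
            flags.append(flag_mosaicism(h, big))
        assert sum(flags) >= 6


class TestPhaseAndRefine:
    def test_similar_sized_alleles_resolved_by_snp_phasing(self, locus):
        site = locus.snp_sites[0]
        config = SimulationConfig(
            genotype=(60, 63), n_reads=200, seed=11,
            snp_haplotypes={site.rsid: ("A", "G")},
        )
        reads, _ = simulate_sample(locus, config)
        genotype = call_genotype(observe_reads(reads, locus), locus, "phased")
        assert genotype.zygosity == "heterozygous"
        sizes = [a.size for a in genotype.alleles]
        assert abs(sizes[0] - 60) <= 2 and abs(sizes[1] - 63) <= 2
        assert sizes[0] < sizes[1]
        assert [a.phase_base for a in genotype.alleles] == ["A", "G"]

    def test_homozygous_normal_sample(self, locus):
        config = SimulationConfig(genotype=(22, 22), n_reads=200, seed=5)
        reads, _ = simulate_sample(locus, config)
        genotype = call_genotype(observe_reads(reads, locus), locus, "hom")
        assert genotype.zygosity == "homozygous"
        assert [a.size for a in genotype.alleles] == [22, 22]

    def test_one_normal_one_expanded_heterozygote(self, locus):
        config = SimulationConfig(genotype=(29, 93), n_reads=200, seed=23)
        reads, _ = simulate_sample(locus, config)
        kept, _ = filter_reads(reads)
        genotype = call_genotype(observe_reads(kept, locus), locus, "s553")
        assert genotype.zygosity == "heterozygous"
        a1, a2 = genotype.alleles
        assert a1.classification == "normal" and a2.classification == "expanded"
        assert genotype.expansion_carrier

    def test_genotype_invariant_to_read_order(self, locus):
        config = SimulationConfig(genotype=(16, 35), n_reads=150, seed=31)
        reads, _ = simulate_sample(locus, config)
        observations = observe_reads(reads, locus)
        first = call_genotype(observations, locus, "s")
        shuffled = observations[:]
        random.Random(99).shuffle(shuffled)
        second = call_genotype(shuffled, locus, "s")
        assert first.alleles == second.alleles
        assert first.zygosity == second.zygosity

    def test_every_reported_allele_has_depth_above_gate(self, locus):
        for seed in (41, 42, 43):
            config = SimulationConfig(genotype=(16, 35), n_reads=120, seed=seed)
            reads, _ = simulate_sample(locus, config)
            genotype = call_genotype(observe_reads(reads, locus), locus, "s")
            for allele in genotype.alleles:
                assert allele.depth > 10

    def test_carrier_status_rederives_from_allele_sizes(self, locus):
        for geno, seed in [((16, 35), 51), ((29, 93), 52), ((62, 78), 53)]:
            config = SimulationConfig(genotype=geno, n_reads=200, seed=seed)
            reads, _ = simulate_sample(locus, config)
            genotype = call_genotype(observe_reads(reads, locus), locus, "s")
            assert genotype.expansion_carrier == any(a.size >= 50 for a in genotype.alleles)

    def test_no_modes_raises(self, locus):
        with pytest.raises(NoCallError):
            phase_and_refine([], [], locus)
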