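"""Insert-size extraction filters, profiles, peaks, periodicity, fractions."""

import numpy as np
import pysam
import pytest

from fragkin.errors import AnalysisError, SpecificationError
from fragkin.fragmentomics import (
    CETrace,
    FractionBins,
    FragmentProfile,
    build_profile,
    ce_summary,
    detect_peaks,
    estimate_periodicity,
    extract_insert_sizes,
    nucleosomal_fractions,
    read_fragment_tsv,
)
from fragkin.synthetic.alignments import (
    Contamination,
    emit_aligned_pairs,
    make_header,
    write_sam,
)
from fragkin.synthetic.populations import healthy_population, sample_fragment_lengths


def _pair(header, name, chrom, pos, length, mapq, **flags):
    recs = []
    tid = header.references.index(chrom)
    for read1 in (True, False):
        seg = pysam.AlignedSegment(header)
        seg.query_name = name
        seg.reference_id = seg.next_reference_id = tid
        seg.cigarstring = "100M"
        seg.mapping_quality = mapq
        seg.is_paired = True
        seg.is_proper_pair = True
        seg.is_read1 = read1
        seg.is_read2 = not read1
        seg.reference_start = pos if read1 else pos + length - 100
        seg.next_reference_start = pos + length - 100 if read1 else pos
        seg.is_reverse = not read1
        seg.mate_is_reverse = read1
        seg.template_length = length if read1 else -length
        for attr, value in flags.items():
            setattr(seg, attr, value)
        recs.append(seg)
    return recs


class TestExtractionFilters:
    header = make_header()

    def test_mapq_threshold_is_inclusive_at_20(self):
        recs = _pair(self.header, "a", "chr1", 1000, 167, 19) + _pair(
            self.header, "b", "chr1", 2000, 167, 20
        )
        assert extract_insert_sizes(recs).tolist() == [167]

    def test_pair_counted_once_via_positive_tlen(self):
        recs = _pair(self.header, "a", "chr1", 1000, 167, 60)
        assert extract_insert_sizes(recs).tolist() == [167]

    @pytest.mark.parametrize(
        "flags", [{"is_duplicate": True}, {"is_secondary": True}, {"is_supplementary": True}]
    )
    def test_flagged_records_excluded(self, flags):
        recs = _pair(self.header, "a", "chr1", 1000, 200, 60, **flags)
        assert extract_insert_sizes(recs).size == 0

    def test_size_window_half_open(self):
        recs = (
            _pair(self.header, "a", "chr1", 1000, 1000, 60)
            + _pair(self.header, "b", "chr1", 5000, 1001, 60)
            + _pair(self.header, "c", "chr1", 9000, 1, 60)
        )
        assert sorted(extract_insert_sizes(recs).tolist()) == [1, 1000]

    def test_chromosome_filter_retains_only_requested(self):
        recs = []
        for i in range(100):
            recs += _pair(self.header, f"y{i}", "chrY", 1000 + 500 * i, 167, 60)
        for i in range(50):
            recs += _pair(self.header, f"a{i}", "chr1", 1000 + 500 * i, 167, 60)
        assert extract_insert_sizes(recs, chrom_filter={"chrY"}).size == 100

    def test_filtering_is_idempotent(self):
        recs, _ = emit_aligned_pairs(
            [150, 350, 560], ["chrY"] * 3, seed=0, contamination=Contamination(low_mapq=0.5)
        )
        once = extract_insert_sizes(recs)
        # re-emitting the surviving lengths and re-filtering changes nothing
        recs2, _ = emit_aligned_pairs(once, ["chrY"] * once.size, seed=1)
        twice = extract_insert_sizes(recs2)
        assert sorted(once.tolist()) == sorted(twice.tolist())

    def test_unpaired_stream_warns_and_returns_empty(self):
        seg = pysam.AlignedSegment(self.header)
        seg.query_name = "solo"
        seg.reference_id = 0
        seg.reference_start = 100
        seg.mapping_quality = 60
        seg.cigarstring = "100M"
        seg.template_length = 0
        with pytest.warns(UserWarning, match="no paired records"):
            assert extract_insert_sizes([seg]).size == 0


class TestRoundTrip:
    def test_emission_round_trip_with_contamination(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(50, 900, 100)
        recs, _ = emit_aligned_pairs(
            lengths,
            ["chrY"] * 100,
            seed=6,
            contamination=Contamination(duplicates=0.1, supplementary=0.05, low_mapq=0.1),
        )
        got = extract_insert_sizes(recs)
        assert sorted(got.tolist()) == sorted(lengths.tolist())

    def test_three_clean_fragments_three_pairs(self):
        recs, _ = emit_aligned_pairs([167, 350, 560], ["chrY", "chr1", "chrY"], seed=0)
        assert len(recs) == 6
        assert sorted(extract_insert_sizes(recs).tolist()) == [167, 350, 560]
        by_chrom = {r.reference_name for r in recs if r.template_length == 350}
        assert by_chrom == {"chr1"}

    def test_sam_file_round_trip(self, tmp_path):
        lengths = [167, 167, 350]
        recs, header = emit_aligned_pairs(lengths, ["chrY"] * 3, seed=1)
        path = tmp_path / "frags.sam"
        write_sam(recs, header, path)
        assert sorted(extract_insert_sizes(path).tolist()) == sorted(lengths)

    def test_tsv_duplicate_triples_collapse(self, tmp_path):
        path = tmp_path / "frags.tsv"
        path.write_text(
            "chrom\tlength\tstart\nchrY\t167\t100\nchrY\t167\t100\nchrY\t167\t900\n"
        )
        assert read_fragment_tsv(path).tolist() == [167, 167]


class TestProfiles:
    def test_counts_and_frequencies(self):
        prof = build_profile([167, 167, 350])
        assert prof.counts[167 - 1] == 2 and prof.counts[350 - 1] == 1
        freqs = prof.normalize().counts
        assert freqs[167 - 1] == pytest.approx(2 / 3)
        assert freqs[350 - 1] == pytest.approx(1 / 3)

    def test_normalization_idempotent_and_preserves_proportions(self):
        prof = build_profile([100, 100, 100, 200]).normalize()
        again = prof.normalize()
        assert again is prof
        assert prof.counts[100 - 1] / prof.counts[200 - 1] == pytest.approx(3.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(AnalysisError):
            build_profile([])

    def test_profile_mode_matches_generator_mode(self):
        lengths = sample_fragment_lengths(healthy_population(), 1_000_000, seed=9)
        prof = build_profile(lengths)
        assert prof.lengths[np.argmax(prof.counts)] == 167


class TestPeaks:
    def test_healthy_profile_first_peak_at_167(self):
        lengths = sample_fragment_lengths(healthy_population(), 100_000, seed=10)
        peaks = detect_peaks(build_profile(lengths))
        assert peaks.positions()[0] == 167

    def test_well_separated_modes_all_recovered(self):
        lengths = sample_fragment_lengths(healthy_population(), 1_000_000, seed=11)
        # low prominence threshold so the faint trinucleosome mode qualifies
        positions = detect_peaks(build_profile(lengths), min_prominence=0.005).positions()
        assert positions[0] == 167
        assert any(abs(p - 350) <= 2 for p in positions)
        assert any(abs(p - 560) <= 3 for p in positions)

    def test_single_point_profile(self):
        peaks = detect_peaks(build_profile([42, 42, 42]))
        assert peaks.positions() == [42]
        assert peaks.peaks[0].prominence == pytest.approx(1.0)

    def test_equal_peaks_tie_breaks_to_smaller_length(self):
        counts = np.zeros(300)
        counts[160 - 1] = counts[170 - 1] = 50
        counts[:] += 1
        prof = FragmentProfile(counts, 1, 300)
        assert detect_peaks(prof, smooth_window=1).positions()[0] == 160

    def test_flat_profile_yields_no_peaks(self):
        prof = FragmentProfile(np.ones(500), 1, 500)
        assert len(detect_peaks(prof)) == 0


class TestPeriodicity:
    @pytest.mark.parametrize("period", [10, 11])
    def test_constructed_sawtooth_period_recovered(self, period):
        counts = np.full(1000, 1e-4)
        x = np.arange(41, 167)
        counts[x - 1] = np.exp((x - 166) / 45.0) * (1 + 2.5 * (np.mod(x - 8, period) / (period - 1)))
        prof = FragmentProfile(counts, 1, 1000)
        assert estimate_periodicity(prof) == period

    def test_monotone_profile_has_no_periodicity(self):
        prof = FragmentProfile(np.linspace(1, 3, 1000), 1, 1000)
        assert estimate_periodicity(prof) is None

    def test_window_must_lie_within_support(self):
        prof = build_profile([100, 150], min_len=50, max_len=200)
        with pytest.raises(SpecificationError):
            estimate_periodicity(prof, window=(41, 300))


class TestFractions:
    def test_point_mass_at_167_is_all_mono(self):
        fr = nucleosomal_fractions(build_profile([167] * 10))
        assert fr["mono"] == pytest.approx(1.0)
        assert fr["di"] == fr["tri"] == fr["long"] == 0.0

    def test_uniform_profile_fractions_proportional_to_widths(self):
        prof = FragmentProfile(np.ones(1000), 1, 1000)
        bins = FractionBins()
        fr = nucleosomal_fractions(prof, bins)
        width_overall = bins.overall_range[1] - bins.overall_range[0] + 1
        for key, rng_ in (
            ("mono", bins.mono_range),
            ("di", bins.di_range),
            ("tri", bins.tri_range),
            ("long", bins.long_range),
        ):
            assert fr[key] == pytest.approx((rng_[1] - rng_[0] + 1) / width_overall)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_normalization_state(self):
        lengths = sample_fragment_lengths(healthy_population(), 20_000, seed=12)
        prof = build_profile(lengths)
        raw = nucleosomal_fractions(prof)
        norm = nucleosomal_fractions(prof.normalize())
        for key in raw:
            assert raw[key] == pytest.approx(norm[key], abs=1e-12)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(SpecificationError):
            FractionBins(mono_range=(20, 300), di_range=(260, 459))


class TestCESummary:
    def test_point_mass_in_range(self):
        sizes = np.arange(50, 50_001, 10.0)
        signals = np.zeros_like(sizes)
        signals[np.searchsorted(sizes, 8600)] = 5.0
        frac, mean = ce_summary(CETrace(sizes, signals))
        assert frac == pytest.approx(1.0)
        assert mean == pytest.approx(8600, abs=10)

    def test_all_signal_below_range_reports_absent_mean(self):
        sizes = np.arange(50, 50_001, 10.0)
        signals = np.zeros_like(sizes)
        signals[np.searchsorted(sizes, 170)] = 5.0
        frac, mean = ce_summary(CETrace(sizes, signals))
        assert frac == 0.0
        assert mean is None

    def test_two_equal_masses_mean_midpoint(self):
        sizes = np.arange(50, 50_001, 10.0)
        signals = np.zeros_like(sizes)
        signals[np.searchsorted(sizes, 2000)] = 3.0
        signals[np.searchsorted(sizes, 4000)] = 3.0
        frac, mean = ce_summary(CETrace(sizes, signals))
        assert mean == pytest.approx(3000, abs=10)

    def test_trapezoid_agrees_with_analytic_triangle(self):
        """Triangular pulse centered at 5000: closed-form mean equals center."""
        sizes = np.arange(1000.0, 10_001.0, 1.0)
        signals = np.maximum(0.0, 1.0 - np.abs(sizes - 5000) / 500.0)
        frac, mean = ce_summary(CETrace(sizes, signals))
        assert frac == pytest.approx(1.0, abs=1e-9)
        assert mean == pytest.approx(5000.0, abs=1e-6)

    def test_zero_signal_is_an_error(self):
        trace = CETrace(np.arange(100.0, 20_000.0, 100.0), np.zeros(199))
        with pytest.raises(AnalysisError):
            ce_summary(trace)
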