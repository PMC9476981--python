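"""Histogram construction, peak detection, doubling-series assignment,
event gating and measurement QC."""

import numpy as np
import pytest

from endoflow import simulate
from endoflow.errors import (
    DomainError,
    EmptyInputError,
    FormatError,
    NoPeakError,
)
from endoflow.gating import (
    EventSample,
    Histogram,
    Peak,
    PeakSet,
    PloidyCounts,
    SampleMeta,
    assign_doubling_series,
    build_histogram,
    detect_peaks,
    gate_events,
    gate_sample,
    qc_check,
)
from endoflow.io import EventDialect, read_event_table, write_event_table


class TestEventIO:
    def test_toy_file_identity_readback(self, tmp_path):
        p = tmp_path / "toy.tsv"
        p.write_text("intensity\n100\n200\n400\n")
        sample = read_event_table(p)
        assert len(sample) == 3
        np.testing.assert_allclose(sample.intensities, [100, 200, 400])

    def test_write_read_roundtrip(self, tmp_path, mixture_sample):
        p = tmp_path / "events.tsv"
        write_event_table(mixture_sample, p)
        back = read_event_table(p)
        np.testing.assert_allclose(back.intensities, mixture_sample.intensities)
        assert back.meta.species == "P. murinii"
        assert back.meta.organ == "root"

    def test_non_numeric_rows_rejected_with_warning(self, tmp_path, rng):
        vals = rng.uniform(50, 500, size=1000).astype(object)
        vals[137] = "smudge"
        p = tmp_path / "dirty.tsv"
        p.write_text("intensity\n" + "\n".join(map(str, vals)) + "\n")
        with pytest.warns(UserWarning, match="rejected 1 "):
            sample = read_event_table(p)
        assert len(sample) == 999

    def test_missing_intensity_column(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("fluo\n100\n")
        with pytest.raises(FormatError):
            read_event_table(p)

    def test_zero_usable_rows(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("intensity\nx\ny\n")
        with pytest.warns(UserWarning), pytest.raises(EmptyInputError):
            read_event_table(p)

    def test_custom_delimiter(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("intensity\n5\n7\n")
        sample = read_event_table(p, EventDialect(delimiter=","))
        assert len(sample) == 2


class TestBuildHistogram:
    def test_constant_events_single_bin(self):
        s = EventSample(np.full(100, 42.0))
        h = build_histogram(s, n_bins=64)
        assert (h.counts > 0).sum() == 1
        assert h.counts.sum() == 100

    def test_gaussian_argmax_near_mean(self, rng):
        x = rng.normal(200, 6, 10_000)
        h = build_histogram(EventSample(x), n_bins=256, scale="log")
        i = int(np.argmax(h.counts))
        assert h.bin_edges[i] <= 200 <= h.bin_edges[i + 2]

    def test_bimodal_two_local_maxima(self, rng):
        x = np.concatenate([rng.normal(200, 6, 5000), rng.normal(400, 12, 5000)])
        h = build_histogram(EventSample(x), n_bins=128, scale="log")
        pk = detect_peaks(h)
        pos = pk.positions
        assert len(pos) == 2
        assert abs(pos[0] - 200) / 200 < 0.05
        assert abs(pos[1] - 400) / 400 < 0.05

    def test_log_bins_uniform_in_log(self, mixture_sample):
        h = build_histogram(mixture_sample, n_bins=64, scale="log")
        ratios = h.bin_edges[1:] / h.bin_edges[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_floor_excludes_and_reports(self, rng):
        x = np.concatenate([rng.uniform(1, 10, 50), rng.normal(200, 6, 1000)])
        h = build_histogram(EventSample(x), n_bins=64, floor=50.0)
        assert h.n_below_floor == 50
        assert h.counts.sum() == 1000

    def test_too_few_bins(self, mixture_sample):
        with pytest.raises(DomainError):
            build_histogram(mixture_sample, n_bins=8)


class TestDetectPeaks:
    def test_single_gaussian_one_peak_within_2pc(self, rng):
        x = rng.normal(200, 6, 10_000)
        h = build_histogram(EventSample(x), n_bins=256)
        pk = detect_peaks(h, events=x)
        assert len(pk.peaks) == 1
        assert abs(pk.peaks[0].position - 200) / 200 < 0.02
        assert 1.5 < pk.peaks[0].cv_percent < 4.5

    def test_ratio_two_mixture_two_peaks(self, rng):
        x = np.concatenate([rng.normal(200, 6, 5000), rng.normal(400, 12, 5000)])
        h = build_histogram(EventSample(x), n_bins=256)
        pk = detect_peaks(h, events=x)
        assert len(pk.peaks) == 2
        ratio = pk.peaks[1].position / pk.peaks[0].position
        assert 1.9 <= ratio <= 2.1

    def test_flat_histogram_no_peak(self):
        h = Histogram(np.linspace(10, 100, 65), np.full(64, 5), scale="linear")
        with pytest.raises(NoPeakError):
            detect_peaks(h)

    def test_empty_histogram_no_peak(self):
        h = Histogram(np.linspace(10, 100, 65), np.zeros(64), scale="linear")
        with pytest.raises(NoPeakError):
            detect_peaks(h)


def _peakset(positions, heights=None):
    heights = heights or [100.0] * len(positions)
    return PeakSet([Peak(p, h, 3.0) for p, h in zip(positions, heights)])


class TestAssignDoublingSeries:
    @pytest.mark.parametrize(
        "positions, expected",
        [
            ([100, 200, 400], [2, 4, 8]),
            ([100, 205, 395], [2, 4, 8]),  # within 10 % of the doublings
            ([100, 150], [2, None]),  # 150 is not ~200
        ],
    )
    def test_assignment(self, positions, expected):
        out = assign_doubling_series(_peakset(positions), tolerance_fraction=0.10)
        assert [p.c_level for p in out.peaks] == expected

    def test_unmatched_peaks_reported_not_dropped(self):
        out = assign_doubling_series(_peakset([100, 150, 200]))
        assert len(out.peaks) == 3
        assert [p.c_level for p in out.peaks] == [2, None, 4]
        assert len(out.unassigned()) == 1

    def test_sub_anchor_debris_peak_skipped_by_chain_rule(self):
        # tall debris bump at 60 has no doubling partner; 100-200-400 does
        out = assign_doubling_series(
            _peakset([60, 100, 200, 400], heights=[500, 300, 200, 50])
        )
        levels = {round(p.position): p.c_level for p in out.peaks}
        assert levels == {60: None, 100: 2, 200: 4, 400: 8}

    def test_tallest_anchor_when_no_chain(self):
        out = assign_doubling_series(
            _peakset([100, 150], heights=[10, 500]), tolerance_fraction=0.05
        )
        levels = {round(p.position): p.c_level for p in out.peaks}
        assert levels == {150: 2, 100: None}


class TestGateEvents:
    def test_events_at_peak_positions(self):
        peaks = assign_doubling_series(_peakset([100, 200, 400]))
        s = EventSample(np.array([100.0] * 3 + [200.0] * 2 + [400.0]))
        c = gate_events(s, peaks)
        assert c.counts == {2: 3.0, 4: 2.0, 8: 1.0}
        assert c.debris == 0

    def test_recovery_within_2pc(self, mixture_sample):
        counts, _ = gate_sample(mixture_sample)
        p = counts.proportions()
        for level, truth in [(2, 0.6), (4, 0.3), (8, 0.1)]:
            assert abs(p.get(level, 0.0) - truth) < 0.02

    def test_nearest_log_peak_oracle_equivalence(self, rng):
        """Geometric-midpoint gates equal nearest-assigned-peak-in-log-space
        assignment for events inside the outer boundaries."""
        for _ in range(100):
            n_peaks = rng.integers(2, 5)
            anchor = rng.uniform(50, 300)
            positions = [anchor * 2.0**k * rng.uniform(0.97, 1.03)
                         for k in range(n_peaks)]
            peaks = assign_doubling_series(_peakset(positions))
            lo = positions[0] * 2**-0.45
            hi = positions[-1] * 2**0.45
            x = np.exp(rng.uniform(np.log(lo), np.log(hi), 200))
            c = gate_events(EventSample(x), peaks)
            # oracle: nearest assigned peak in log space
            logp = np.log([p.position for p in peaks.assigned()])
            levels = [p.c_level for p in peaks.assigned()]
            nearest = np.argmin(np.abs(np.log(x)[:, None] - logp[None, :]), axis=1)
            oracle = {lv: 0.0 for lv in levels}
            for i in nearest:
                oracle[levels[i]] += 1.0
            assert {k: v for k, v in c.counts.items()} == {
                k: v for k, v in oracle.items()
            }

    def test_conservation(self, rng):
        s = simulate.simulate_events(
            [0.5, 0.4, 0.1], n=4000, cv_percent=3.0, debris_fraction=0.1, rng=rng
        )
        counts, _ = gate_sample(s)
        assert counts.total + counts.debris == len(s)

    def test_scale_equivariance(self, rng, mixture_sample):
        counts1, _ = gate_sample(mixture_sample)
        for c in (0.037, 12.5):
            scaled = EventSample(mixture_sample.intensities * c,
                                 meta=mixture_sample.meta)
            counts2, _ = gate_sample(scaled)
            assert counts1.counts == counts2.counts

    def test_recovery_across_study_templates(self, rng, prop_table):
        """Mean absolute class-proportion error < 1 percentage point over 50
        seeded simulations at n = 5000, CV <= 4 %."""
        errors = []
        rows = prop_table.to_dict("records")
        for seed in range(50):
            row = rows[seed % len(rows)]
            truth = np.array([row[f"{c}C"] for c in (2, 4, 8, 16, 32, 64)])
            truth = truth / truth.sum()
            r = np.random.default_rng(seed)
            s = simulate.simulate_events(truth, n=5000, cv_percent=3.5,
                                         debris_fraction=0.0, rng=r)
            counts, _ = gate_sample(s)
            got = {lv: v / counts.total for lv, v in counts.counts.items()}
            for k, t in enumerate(truth):
                if t > 0:
                    errors.append(abs(got.get(2 * 2**k, 0.0) - t))
        assert np.mean(errors) < 0.01


class TestQC:
    def test_genome_size_pass(self):
        c = PloidyCounts({2: 5000})
        pk = _peakset([100, 200])
        pk.peaks[0].cv_percent = 4.9
        pk.peaks[1].cv_percent = 4.2
        report = qc_check(c, pk, mode="genome_size")
        assert report.passed

    def test_min_nuclei_boundary(self):
        report = qc_check(PloidyCounts({2: 2999}), mode="endopolyploidy")
        assert not report.passed
        assert "2999" in report.violations[0]
        assert qc_check(PloidyCounts({2: 3000}), mode="endopolyploidy").passed

    def test_cv_boundary(self):
        pk = _peakset([100])
        pk.peaks[0].cv_percent = 5.1
        report = qc_check(peaks=pk, mode="genome_size")
        assert not report.passed and "CV" in report.violations[0]
        pk.peaks[0].cv_percent = 5.0
        assert qc_check(peaks=pk, mode="genome_size").passed


class TestTypes:
    def test_non_positive_intensities_rejected(self):
        with pytest.raises(DomainError):
            EventSample(np.array([1.0, -2.0]))

    def test_ploidy_counts_invalid_level(self):
        with pytest.raises(DomainError):
            PloidyCounts({3: 10.0})

    def test_ploidy_counts_proportions_sum_to_one(self, rng):
        from conftest import random_counts

        c = random_counts(rng)
        assert abs(sum(c.proportions().values()) - 1.0) < 1e-9
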