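"""The synthetic-data generator and its ground-truth guarantees."""

import numpy as np
import pytest

from phagecensor import (
    CensoredSeq,
    FilterSpec,
    SyntheticSpec,
    confidence_interval,
    detect_bias,
    filter_reads,
    generate_fastq,
    generate_library,
    ingest_fastq,
    measure_fraction,
    planted_survival_counts,
    sum_total,
    uni_count,
)
from phagecensor.synthetic import write_truth_csv


class TestGenerateLibrary:
    def test_ramp_law_totals(self):
        lib, truth = generate_library(SyntheticSpec(n_unique=1000, seed=0))
        assert sum_total(lib) == 500_500
        assert uni_count(lib) == 1000
        assert len(truth) == 1000
        assert (truth["planted_B"] == 1.0).all()

    def test_explicit_toy_counts(self):
        spec = SyntheticSpec(n_unique=4, copy_law=[1, 2, 3, 4], seed=1)
        lib, _ = generate_library(spec)
        assert list(lib.counts) == [1, 2, 3, 4]

    def test_log_uniform_spans_orders_of_magnitude(self):
        spec = SyntheticSpec(
            n_unique=2000, copy_law=("log_uniform", 1, 10**6), seed=2
        )
        lib, _ = generate_library(spec)
        assert lib.counts.max() / lib.counts.min() >= 10**5

    def test_inserts_are_unique_21mers(self):
        lib, _ = generate_library(SyntheticSpec(n_unique=500, seed=3))
        assert len(set(lib.sequences)) == 500
        assert all(len(s) == 21 for s in lib.sequences)

    def test_truth_records_planted_censorship(self):
        spec = SyntheticSpec(
            n_unique=10,
            copy_law=[100] * 10,
            censored_set=(CensoredSeq(2, 0.25, (4, 5, 6)),),
            degraded_read_rate=0.1,
            seed=4,
        )
        _, truth = generate_library(spec)
        assert truth.loc[2, "planted_B"] == 0.25
        assert truth.loc[2, "cluster_positions"] == "4;5;6"
        assert truth.loc[2, "survival_prob"] == pytest.approx(0.25 * 0.9)
        assert truth.loc[0, "survival_prob"] == pytest.approx(0.9)

    def test_bad_law_rejected(self):
        with pytest.raises(ValueError):
            generate_library(
                SyntheticSpec(n_unique=5, copy_law=("log_uniform", 10, 1))
            )
        with pytest.raises(ValueError):
            CensoredSeq(0, 1.5, (1, 2, 3))
        with pytest.raises(ValueError):
            CensoredSeq(0, 0.5, (1, 2))  # fewer than 3 cluster positions


class TestGenerateFastq:
    def test_round_trip_identity_without_effects(self, tmp_path):
        spec = SyntheticSpec(n_unique=40, copy_law=("log_uniform", 1, 50), seed=5)
        lib, truth = generate_library(spec)
        path = tmp_path / "clean.fastq"
        generate_fastq(lib, spec, path, truth)
        ms, reads, report = ingest_fastq(path, spec.adapter)
        filtered = filter_reads(reads, FilterSpec("min_phred", 13))
        assert report.perfect == report.total == sum_total(lib)
        recovered = {s: int(c) for s, c in zip(filtered.sequences, filtered.counts)}
        assert recovered == {
            s: int(c) for s, c in zip(lib.sequences, lib.counts)
        }

    def test_censored_survival_matches_planted_bias(self, tmp_path):
        b, count = 0.5, 10_000
        spec = SyntheticSpec(
            n_unique=2,
            copy_law=[count, 500],
            censored_set=(CensoredSeq(0, b, (10, 11, 12, 13)),),
            seed=6,
        )
        lib, truth = generate_library(spec)
        path = tmp_path / "cens.fastq"
        generate_fastq(lib, spec, path, truth)
        _, reads, _ = ingest_fastq(path, spec.adapter)
        n13 = filter_reads(reads, FilterSpec("min_phred", 13))
        surviving = n13.count_of(lib.sequences[0])
        sigma = np.sqrt(count * b * (1 - b))
        assert abs(surviving - b * count) <= 3 * sigma

    def test_flawed_adapter_rate_recovered(self, tmp_path):
        rate, total = 0.2, 3000
        spec = SyntheticSpec(
            n_unique=30, copy_law=[total // 30] * 30,
            flawed_adapter_rate=rate, seed=7,
        )
        lib, truth = generate_library(spec)
        path = tmp_path / "flawed.fastq"
        generate_fastq(lib, spec, path, truth)
        _, _, report = ingest_fastq(path, spec.adapter)
        sigma = np.sqrt(total * rate * (1 - rate))
        assert abs(report.flawed - rate * total) <= 3 * sigma

    def test_degraded_read_rate_sets_survival(self, tmp_path):
        rate, total = 0.1, 5000
        spec = SyntheticSpec(
            n_unique=10, copy_law=[total // 10] * 10,
            degraded_read_rate=rate, seed=8,
        )
        lib, truth = generate_library(spec)
        path = tmp_path / "deg.fastq"
        generate_fastq(lib, spec, path, truth)
        _, reads, _ = ingest_fastq(path, spec.adapter)
        n1 = filter_reads(reads, FilterSpec("min_phred", 1))
        n13 = filter_reads(reads, FilterSpec("min_phred", 13))
        f = measure_fraction(n1, n13)
        sigma = np.sqrt(rate * (1 - rate) / total)
        assert abs(f - (1 - rate)) <= 3 * sigma

    def test_truth_sidecar_csv(self, tmp_path):
        spec = SyntheticSpec(n_unique=3, copy_law=[1, 2, 3], seed=9)
        _, truth = generate_library(spec)
        p = tmp_path / "truth.csv"
        write_truth_csv(truth, p)
        header = p.read_text().splitlines()[0]
        assert header.split(",")[:3] == ["sequence", "true_count", "planted_B"]


class TestBinomialShortcut:
    def test_matches_fastq_pipeline_in_distribution(self, tmp_path):
        """planted_survival_counts must agree with the full generate ->
        ingest -> filter path: same survival law per sequence."""
        b = 0.4
        spec = SyntheticSpec(
            n_unique=3,
            copy_law=[4000, 4000, 4000],
            censored_set=(CensoredSeq(0, b, (1, 2, 3)),),
            degraded_read_rate=0.1,
            seed=10,
        )
        lib, truth = generate_library(spec)
        path = tmp_path / "x.fastq"
        generate_fastq(lib, spec, path, truth)
        _, reads, _ = ingest_fastq(path, spec.adapter)
        via_fastq = filter_reads(reads, FilterSpec("min_phred", 13))
        via_binom = planted_survival_counts(lib, truth, np.random.default_rng(11))
        p_expected = truth["survival_prob"].to_numpy()
        for i, seq in enumerate(lib.sequences):
            n = int(lib.counts[i])
            sigma = np.sqrt(n * p_expected[i] * (1 - p_expected[i]))
            assert abs(via_fastq.count_of(seq) - n * p_expected[i]) <= 4 * sigma
            assert abs(int(via_binom.counts[i]) - n * p_expected[i]) <= 4 * sigma


class TestEndToEndCensorshipRecovery:
    def test_planted_censorship_recovered_through_fastq(self, tmp_path):
        """Flagship integration: generate reads with planted censorship,
        ingest, filter at two cutoffs, build the sampling band and recover
        the planted censored sequences."""
        planted = {
            5: CensoredSeq(5, 0.10, (7, 8, 9)),
            17: CensoredSeq(17, 0.20, (20, 21, 22, 23)),
        }
        spec = SyntheticSpec(
            n_unique=60,
            copy_law=[800] * 60,
            censored_set=tuple(planted.values()),
            degraded_read_rate=0.1,
            seed=12,
        )
        lib, truth = generate_library(spec)
        path = tmp_path / "e2e.fastq"
        generate_fastq(lib, spec, path, truth)
        _, reads, _ = ingest_fastq(path, spec.adapter)
        n1 = filter_reads(reads, FilterSpec("min_phred", 1))
        n13 = filter_reads(reads, FilterSpec("min_phred", 13))
        f = measure_fraction(n1, n13)
        band = confidence_interval(n1, f, k=3000, seed=13)
        bias = detect_bias(n1, n13, band)
        flagged = {
            n1.sequences[i] for i in np.flatnonzero(bias.censored_mask)
        }
        planted_seqs = {lib.sequences[i] for i in planted}
        assert planted_seqs <= flagged
        # recovered B close to planted (binomial noise at count 800)
        for i, c in planted.items():
            j = n1.sequences.index(lib.sequences[i])
            assert bias.bias[j] == pytest.approx(c.bias, rel=0.35)
        # no unbiased sequence misflagged
        assert flagged == planted_seqs
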