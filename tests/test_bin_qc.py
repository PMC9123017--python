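"""Bin QC cascade: structural filters, marker conflicts, self-overlap,
coverage evenness and the composite viral decision rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from jumbophage import bin_qc, synthetic
from jumbophage.bin_qc import ClassifierScores, QcThresholds
from jumbophage.containers import Contig, CoverageMatrix, GenomeBin


def make_bin(bin_id: str, lengths: list[int], seqs: list[str] | None = None) -> GenomeBin:
    contigs = [
        Contig(f"{bin_id}_c{i}", L, seqs[i] if seqs else None)
        for i, L in enumerate(lengths)
    ]
    return GenomeBin(bin_id, contigs)


T = QcThresholds(evenness_threshold=0.2)


@pytest.mark.parametrize(
    "lengths, expect_pass, reason_bit",
    [
        ([202_000], True, ""),  # single-contig jumbo bin
        ([100_000, 102_000], True, ""),
        ([66_700] * 6, False, "contig_count"),
        ([100_000, 99_999], False, "total_length"),
        ([196_000, 4_999], False, "below"),
    ],
)
def test_structure_screen(lengths, expect_pass, reason_bit):
    res = bin_qc.screen_structure(make_bin("b", lengths), T)
    assert res.passed is expect_pass
    if not expect_pass:
        assert reason_bit in res.reason


def test_structure_screen_empty_bin_rejected():
    with pytest.raises(ValueError):
        bin_qc.screen_structure(GenomeBin("b", []), T)


def marker_table(ribo: int, ncldv_markers: int, phage: int, ncldv: int) -> pd.DataFrame:
    n = max(ribo + ncldv_markers, phage + ncldv, 1)
    rows = []
    for i in range(phage):
        rows.append({"is_ribosomal": i < ribo, "is_ncldv_marker": False,
                     "best_hit_kingdom": "phage"})
    for i in range(ncldv):
        rows.append({"is_ribosomal": False, "is_ncldv_marker": i < ncldv_markers,
                     "best_hit_kingdom": "NCLDV"})
    return pd.DataFrame(rows)


@pytest.mark.parametrize(
    "ribo, markers, phage, ncldv, expect",
    [
        (0, 0, 40, 2, True),
        (2, 0, 40, 2, False),  # more than one ribosomal protein
        (0, 2, 40, 2, False),  # more than one NCLDV marker
        (0, 0, 3, 3, False),  # "fewer" is strict
    ],
)
def test_marker_conflicts(ribo, markers, phage, ncldv, expect):
    res = bin_qc.count_marker_conflicts(marker_table(ribo, markers, phage, ncldv), T)
    assert res.passed is expect


def test_marker_conflicts_missing_table_passes_vacuously():
    res = bin_qc.count_marker_conflicts(None, T)
    assert res.passed and res.skipped


@pytest.mark.parametrize(
    "scores, checkv, vibrant, expect",
    [
        ([0.95], "not-determined", False, True),  # mean > 0.9
        ([0.6], "medium", False, True),  # 0.5 gate + CheckV branch
        ([0.6], "low", True, True),  # 0.5 gate + VIBRANT branch
        ([0.6], "low", False, False),  # neither branch
        ([0.4], "high", True, False),  # fails the 0.5 gate
        ([0.9], "not-determined", False, False),  # 0.9 is strict
    ],
)
def test_viral_decision_rule(scores, checkv, vibrant, expect):
    cs = ClassifierScores("b", scores, checkv, vibrant)
    assert bin_qc.classify_viral(cs, T).passed is expect


def test_viral_rule_is_contig_order_invariant():
    a = ClassifierScores("b", [0.5, 0.9, 0.95], "medium", False)
    b = ClassifierScores("b", [0.95, 0.5, 0.9], "medium", False)
    assert bin_qc.classify_viral(a, T).passed == bin_qc.classify_viral(b, T).passed


def coverage_for(bin_: GenomeBin, grid: np.ndarray) -> CoverageMatrix:
    samples = [f"s{j}" for j in range(grid.shape[1])]
    values = pd.DataFrame(grid, index=[c.contig_id for c in bin_.contigs], columns=samples)
    return CoverageMatrix(values, bin_.contig_lengths(),
                          {c.contig_id: bin_.bin_id for c in bin_.contigs})


def test_evenness_zero_for_equal_coverages():
    b = make_bin("b", [10_000, 20_000, 30_000])
    cov = coverage_for(b, np.full((3, 4), 7.0))
    assert bin_qc.evenness_statistic(b, cov) == 0.0


def test_evenness_single_contig_is_zero():
    b = make_bin("b", [250_000])
    cov = coverage_for(b, np.array([[3.0]]))
    assert bin_qc.evenness_statistic(b, cov) == 0.0


def test_evenness_hand_value_two_equal_contigs():
    # coverages (10, 30), equal lengths: mean 20, sd 10, CV = 0.5
    b = make_bin("b", [10_000, 10_000])
    cov = coverage_for(b, np.array([[10.0], [30.0]]))
    assert bin_qc.evenness_statistic(b, cov) == pytest.approx(0.5)


def test_evenness_scale_invariant_per_sample(rng):
    b = make_bin("b", [10_000, 25_000, 40_000])
    grid = rng.uniform(2.0, 10.0, size=(3, 6))
    base = bin_qc.evenness_statistic(b, coverage_for(b, grid))
    scaled = grid * rng.uniform(1.0, 5.0, size=6)  # per-sample rescaling
    assert bin_qc.evenness_statistic(b, coverage_for(b, scaled)) == pytest.approx(base)


def test_evenness_requires_covered_sample():
    b = make_bin("b", [10_000, 10_000])
    cov = coverage_for(b, np.full((2, 3), 0.01))
    with pytest.raises(bin_qc.InsufficientCoverageError):
        bin_qc.evenness_statistic(b, cov)


def test_calibration_zero_noise_gives_zero_threshold():
    refs = synthetic.reference_fragment_bins(25, seed=3)
    cov = synthetic.simulate_coverage(refs, 10, noise_cv=0.0, seed=4)
    assert bin_qc.calibrate_evenness_threshold(refs, cov) == 0.0


def test_calibration_is_the_empirical_quantile():
    refs = synthetic.reference_fragment_bins(30, seed=5)
    cov = synthetic.simulate_coverage(refs, 20, noise_cv=0.1, seed=6)
    stats = [bin_qc.evenness_statistic(b, cov) for b in refs]
    expected = float(np.quantile(stats, 0.95))
    assert bin_qc.calibrate_evenness_threshold(refs, cov) == pytest.approx(expected)


def test_calibration_needs_enough_references():
    refs = synthetic.reference_fragment_bins(10, seed=7)
    cov = synthetic.simulate_coverage(refs, 10, noise_cv=0.1, seed=8)
    with pytest.raises(ValueError):
        bin_qc.calibrate_evenness_threshold(refs, cov)


# ---------------------------------------------------------------- overlap


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate_seq(rng, seq, rate):
    bases = "ACGT"
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = bases[(bases.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def test_overlap_identical_contigs_fail(rng):
    s = _random_seq(rng, 10_000)
    b = make_bin("b", [10_000, 10_000], [s, s])
    res = bin_qc.detect_self_overlap(b, T)
    assert not res.passed
    hit = res.value[0]
    assert hit["identity"] == pytest.approx(1.0, abs=0.01)
    assert hit["span"] == pytest.approx(1.0, abs=0.05)


def test_overlap_unrelated_contigs_pass(rng):
    b = make_bin("b", [10_000, 10_000],
                 [_random_seq(rng, 10_000), _random_seq(rng, 10_000)])
    assert bin_qc.detect_self_overlap(b, T).passed


def test_overlap_partial_high_identity_duplication_fails(rng):
    # contig B repeats 60% of contig A at ~97% identity -> two strains binned
    a = _random_seq(rng, 20_000)
    b_seq = _mutate_seq(rng, a[:12_000], 0.03) + _random_seq(rng, 8_000)
    b = make_bin("b", [20_000, 20_000], [a, b_seq])
    res = bin_qc.detect_self_overlap(b, T)
    assert not res.passed
    hit = res.value[0]
    assert hit["identity"] >= 0.95
    assert hit["span"] >= 0.5


def test_overlap_reverse_complement_detected(rng):
    from jumbophage.containers import revcomp

    a = _random_seq(rng, 15_000)
    b = make_bin("b", [15_000, 15_000], [a, revcomp(a)])
    res = bin_qc.detect_self_overlap(b, T)
    assert not res.passed
    assert res.value[0]["strand"] == "-"


def test_overlap_estimate_matches_full_alignment_oracle(rng):
    """On small fixtures the banded estimate agrees with a full edlib NW."""
    import edlib

    a = _random_seq(rng, 4_000)
    b_seq = _mutate_seq(rng, a, 0.04)
    res = bin_qc.detect_self_overlap(
        make_bin("b", [4_000, 4_000], [a, b_seq]), T
    )
    assert not res.passed  # 96% identity over the full length
    full = edlib.align(a, b_seq, mode="NW", task="distance")
    oracle_identity = 1.0 - full["editDistance"] / 4_000
    assert res.value[0]["identity"] == pytest.approx(oracle_identity, abs=0.01)


def test_overlap_skipped_without_sequences():
    b = make_bin("b", [10_000, 10_000])
    res = bin_qc.detect_self_overlap(b, T)
    assert res.passed and res.skipped


def test_single_contig_bin_trivially_passes_overlap():
    b = make_bin("b", [200_000])
    assert bin_qc.detect_self_overlap(b, T).passed


# ---------------------------------------------------------------- run_qc


def test_run_qc_empty_bin_list():
    assert bin_qc.run_qc([], T) == []


def test_run_qc_computes_all_checks_even_after_failure():
    b = make_bin("b", [50_000])  # fails structure
    reports = bin_qc.run_qc([b], T)
    assert set(reports[0].checks) == {"structure", "markers", "overlap", "evenness", "viral"}
    assert not reports[0].overall_pass
    assert not reports[0].checks["structure"].passed


def test_relaxing_thresholds_is_monotone(small_world):
    """A bin passing under strict thresholds also passes under looser ones."""
    strict = QcThresholds(evenness_threshold=0.15)
    loose = QcThresholds(
        min_total_bp=150_000, max_contigs=5, min_contig_bp=4_000,
        max_ribosomal_proteins=2, max_ncldv_markers=2, evenness_threshold=0.5,
        vs2_high=0.85, vs2_low=0.4,
    )
    w = small_world
    kw = dict(coverage=w.coverage, annotations=w.marker_tables,
              classifier_scores=w.classifier_scores)
    pass_strict = {r.bin_id for r in bin_qc.run_qc(w.bins, strict, **kw) if r.overall_pass}
    pass_loose = {r.bin_id for r in bin_qc.run_qc(w.bins, loose, **kw) if r.overall_pass}
    assert pass_strict <= pass_loose
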