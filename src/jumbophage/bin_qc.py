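"""Quality control of candidate jumbo phage bins.

A metagenome bin is accepted as a jumbo phage genome only if it survives a
cascade of checks:

1. structure   -- total length >= 200 kb, <= 5 contigs, every contig >= 5 kb;
2. markers     -- at most one ribosomal protein, at most one NCLDV (giant
                  virus) marker gene, and strictly more phage than NCLDV
                  best hits;
3. overlap     -- no pair of contigs aligns at high identity across the
                  majority of the shorter contig (two strains binned together);
4. evenness    -- contig coverages co-vary across samples; the per-sample
                  length-weighted coefficient of variation (median over
                  sufficiently covered samples) must not exceed a threshold
                  calibrated on artificially fragmented reference genomes;
5. viral       -- composite classifier rule: mean dsDNA-phage score > 0.9, or
                  mean score > 0.5 together with CheckV quality >= medium or a
                  VIBRANT consensus viral call.

All checks are always computed (no short-circuiting) so a failing bin still
gets a complete report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CoverageMatrix, GenomeBin, revcomp
from .overlap import find_best_overlap

logger = logging.getLogger(__name__)

CHECKV_ORDER = {"not-determined": 0, "low": 1, "medium": 2, "high": 3, "complete": 4}


class InsufficientCoverageError(ValueError):
    """No sample reaches the minimum mean coverage for the evenness statistic."""


@dataclass
class QcThresholds:
    min_total_bp: int = 200_000
    max_contigs: int = 5
    min_contig_bp: int = 5_000
    max_ribosomal_proteins: int = 1
    max_ncldv_markers: int = 1
    overlap_identity_min: float = 0.95
    overlap_span_min: float = 0.50
    evenness_threshold: float | None = None  # calibrated, see calibrate_evenness_threshold
    min_mean_coverage: float = 1.0
    vs2_high: float = 0.9
    vs2_low: float = 0.5

    def __post_init__(self) -> None:
        if self.vs2_low >= self.vs2_high:
            raise ValueError("vs2_low must be < vs2_high")
        for name in ("min_total_bp", "max_contigs", "min_contig_bp",
                     "overlap_identity_min", "overlap_span_min", "vs2_low", "vs2_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be nonnegative")


@dataclass
class ClassifierScores:
    """External viral-classifier outputs for one bin (consumed as a table)."""

    bin_id: str
    dsdna_scores_per_contig: list[float]
    checkv_quality: str = "not-determined"
    vibrant_consensus_viral: bool = False

    def __post_init__(self) -> None:
        if not self.dsdna_scores_per_contig:
            raise ValueError(f"bin {self.bin_id}: no classifier scores")
        if any(not 0.0 <= s <= 1.0 for s in self.dsdna_scores_per_contig):
            raise ValueError(f"bin {self.bin_id}: scores must lie in [0, 1]")
        if self.checkv_quality not in CHECKV_ORDER:
            raise ValueError(f"bin {self.bin_id}: unknown CheckV quality {self.checkv_quality!r}")

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.dsdna_scores_per_contig))


@dataclass
class CheckResult:
    name: str
    passed: bool
    value: object = None
    reason: str = ""
    skipped: bool = False


@dataclass
class QcReport:
    bin_id: str
    checks: dict[str, CheckResult] = field(default_factory=dict)

    def add(self, check: CheckResult) -> None:
        self.checks[check.name] = check

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.checks.values())

    @property
    def failure_reasons(self) -> list[str]:
        return [c.reason for c in self.checks.values() if not c.passed]

    def to_row(self) -> dict:
        row: dict = {"bin_id": self.bin_id, "overall_pass": self.overall_pass}
        for name, c in self.checks.items():
            row[f"{name}_pass"] = c.passed
            row[f"{name}_value"] = c.value
        row["failure_reasons"] = ";".join(self.failure_reasons)
        return row


def screen_structure(bin: GenomeBin, t: QcThresholds) -> CheckResult:
    """Structural filter: total size, contig count, minimum contig size."""
    if not bin.contigs:
        raise ValueError(f"bin {bin.bin_id} has no contigs")
    reasons = []
    if bin.total_length < t.min_total_bp:
        reasons.append(f"total_length {bin.total_length} < {t.min_total_bp}")
    if bin.n_contigs > t.max_contigs:
        reasons.append(f"contig_count {bin.n_contigs} > {t.max_contigs}")
    short = [c.contig_id for c in bin.contigs if c.length < t.min_contig_bp]
    if short:
        reasons.append(f"contigs below {t.min_contig_bp} bp: {','.join(short)}")
    return CheckResult(
        "structure",
        passed=not reasons,
        value={"total_length": bin.total_length, "n_contigs": bin.n_contigs},
        reason="; ".join(reasons),
    )


def count_marker_conflicts(annotations: pd.DataFrame | None, t: QcThresholds) -> CheckResult:
    """Marker-gene contamination check on an annotation hit table.

    Expects boolean columns ``is_ribosomal`` and ``is_ncldv_marker`` and a
    ``best_hit_kingdom`` column in {phage, NCLDV, other}. A missing table
    passes vacuously (counts of zero) with a logged warning.
    """
    if annotations is None or len(annotations) == 0:
        logger.warning("no annotation table; marker check passes vacuously")
        return CheckResult("markers", passed=True,
                           value={"ribosomal": 0, "ncldv_markers": 0, "phage_hits": 0, "ncldv_hits": 0},
                           skipped=True)
    ribo = int(annotations["is_ribosomal"].sum())
    ncldv_markers = int(annotations["is_ncldv_marker"].sum())
    kingdoms = annotations["best_hit_kingdom"]
    phage_hits = int((kingdoms == "phage").sum())
    ncldv_hits = int((kingdoms == "NCLDV").sum())
    reasons = []
    if ribo > t.max_ribosomal_proteins:
        reasons.append(f"{ribo} ribosomal proteins")
    if ncldv_markers > t.max_ncldv_markers:
        reasons.append(f"{ncldv_markers} NCLDV marker genes")
    if not ncldv_hits < phage_hits:  # "fewer" is strict
        reasons.append(f"NCLDV hits ({ncldv_hits}) not fewer than phage hits ({phage_hits})")
    return CheckResult(
        "markers",
        passed=not reasons,
        value={"ribosomal": ribo, "ncldv_markers": ncldv_markers,
               "phage_hits": phage_hits, "ncldv_hits": ncldv_hits},
        reason="; ".join(reasons),
    )


def detect_self_overlap(bin: GenomeBin, t: QcThresholds) -> CheckResult:
    """Flag bins whose contigs align to each other across most of their length.

    Such bins likely combine two strains of a smaller phage. Overlaps are
    sought on both strands with a seeded k-mer anchor chain refined by an
    edit-distance alignment of the banded region.
    """
    if bin.n_contigs < 2:
        return CheckResult("overlap", passed=True, value=[])
    if any(c.sequence is None for c in bin.contigs):
        logger.warning("bin %s: contig sequences absent, overlap check skipped", bin.bin_id)
        return CheckResult("overlap", passed=True, value=[], skipped=True)
    hits = []
    contigs = bin.contigs
    for i in range(len(contigs)):
        for j in range(i + 1, len(contigs)):
            a, b = contigs[i], contigs[j]
            short, long_ = (a, b) if a.length <= b.length else (b, a)
            for strand, qseq in (("+", short.sequence), ("-", revcomp(short.sequence))):
                ov = find_best_overlap(qseq, long_.sequence)
                if ov is None:
                    continue
                identity, span = ov
                if identity >= t.overlap_identity_min and span >= t.overlap_span_min:
                    hits.append({"contig_a": short.contig_id, "contig_b": long_.contig_id,
                                 "strand": strand, "identity": identity, "span": span})
    reason = "; ".join(
        f"{h['contig_a']}~{h['contig_b']} id={h['identity']:.3f} span={h['span']:.2f}"
        for h in hits
    )
    return CheckResult("overlap", passed=not hits, value=hits, reason=reason)


def evenness_statistic(
    bin: GenomeBin, coverage: CoverageMatrix, min_mean_cov: float = 1.0
) -> float:
    """Coverage-evenness statistic of a bin.

    Per sample whose length-weighted mean bin coverage reaches
    ``min_mean_cov``, compute the length-weighted coefficient of variation of
    contig mean coverages; return the median across qualifying samples.
    Single-contig bins return 0. Raises :class:`InsufficientCoverageError`
    when no sample qualifies (the bin then fails QC conservatively).
    """
    if bin.n_contigs == 1:
        return 0.0
    sub = coverage.bin_submatrix(bin.bin_id)
    if len(sub) != bin.n_contigs:
        raise ValueError(f"bin {bin.bin_id}: coverage rows missing for some contigs")
    lengths = np.array([coverage.lengths[c] for c in sub.index], dtype=float)
    w = lengths / lengths.sum()
    x = sub.to_numpy(dtype=float)  # contigs x samples
    mu = w @ x
    qualifying = mu >= min_mean_cov
    if not qualifying.any():
        raise InsufficientCoverageError(
            f"bin {bin.bin_id}: no sample with mean coverage >= {min_mean_cov}"
        )
    mu_q = mu[qualifying]
    dev = x[:, qualifying] - mu_q
    var = np.einsum("c,cs->s", w, dev**2)
    cv = np.sqrt(var) / mu_q
    return float(np.median(cv))


def calibrate_evenness_threshold(
    reference_bins: list[GenomeBin],
    coverage: CoverageMatrix,
    quantile: float = 0.95,
    min_mean_cov: float = 1.0,
) -> float:
    """Empirical evenness threshold from artificially fragmented references.

    The references are clean genomes fragmented exactly as bins are; the
    threshold is the ``quantile`` of their evenness-statistic distribution.
    Bins whose statistic is <= the threshold pass the evenness check.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    if len(reference_bins) < 20:
        raise ValueError(f"need >= 20 reference genomes for calibration, got {len(reference_bins)}")
    stats = []
    for b in reference_bins:
        try:
            stats.append(evenness_statistic(b, coverage, min_mean_cov))
        except InsufficientCoverageError:
            warnings.warn(f"reference {b.bin_id} dropped from calibration (no coverage)")
    if len(stats) < 20:
        raise ValueError("fewer than 20 references with usable coverage")
    return float(np.quantile(stats, quantile))


def classify_viral(scores: ClassifierScores, t: QcThresholds) -> CheckResult:
    """Composite viral decision rule over external classifier scores."""
    mean = scores.mean_score
    checkv_ok = CHECKV_ORDER[scores.checkv_quality] >= CHECKV_ORDER["medium"]
    if mean > t.vs2_high:
        return CheckResult("viral", True, value=mean, reason=f"mean score {mean:.3f} > {t.vs2_high}")
    if mean > t.vs2_low and (checkv_ok or scores.vibrant_consensus_viral):
        branch = "CheckV >= medium" if checkv_ok else "VIBRANT viral"
        return CheckResult("viral", True, value=mean,
                           reason=f"mean score {mean:.3f} > {t.vs2_low} and {branch}")
    return CheckResult("viral", False, value=mean,
                       reason=f"mean score {mean:.3f}: no decision branch satisfied")


def run_qc(
    bins: list[GenomeBin],
    t: QcThresholds,
    coverage: CoverageMatrix | None = None,
    annotations: dict[str, pd.DataFrame] | None = None,
    classifier_scores: dict[str, ClassifierScores] | None = None,
) -> list[QcReport]:
    """Apply the full QC cascade to every bin.

    Checks run in fixed order (structure, markers, overlap, evenness, viral)
    and are all computed regardless of earlier failures. A check whose inputs
    are absent is skipped where the contract allows (markers, overlap, viral)
    or fails conservatively (evenness without coverage evidence).
    """
    reports = []
    for b in bins:
        rep = QcReport(bin_id=b.bin_id)
        rep.add(screen_structure(b, t))
        ann = None if annotations is None else annotations.get(b.bin_id)
        rep.add(count_marker_conflicts(ann, t))
        rep.add(detect_self_overlap(b, t))
        if coverage is None or t.evenness_threshold is None:
            logger.warning("bin %s: evenness check skipped (no coverage or threshold)", b.bin_id)
            rep.add(CheckResult("evenness", passed=True, skipped=True))
        else:
            try:
                stat = evenness_statistic(b, coverage, t.min_mean_coverage)
                rep.add(CheckResult(
                    "evenness", passed=stat <= t.evenness_threshold, value=stat,
                    reason="" if stat <= t.evenness_threshold
                    else f"evenness {stat:.3f} > threshold {t.evenness_threshold:.3f}",
                ))
            except InsufficientCoverageError as exc:
                rep.add(CheckResult("evenness", passed=False, value=None,
                                    reason=f"insufficient coverage evidence ({exc})"))
        if classifier_scores is None or b.bin_id not in classifier_scores:
            logger.warning("bin %s: no classifier scores, viral check skipped", b.bin_id)
            rep.add(CheckResult("viral", passed=True, skipped=True))
        else:
            rep.add(classify_viral(classifier_scores[b.bin_id], t))
        reports.append(rep)
    return reports


def reports_to_frame(reports: list[QcReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])
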