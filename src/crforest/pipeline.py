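"""Orchestration: scan -> classify -> filter -> report.

Every candidate that reaches classification is returned with full
provenance (label, tree-vote fraction, per-rule filter outcomes and the
stage that rejected it, if any), so a filter-heavy pipeline can be
audited.  A candidate is *valid* only when the classifier labels its
repeat "repeat", every filter passes, and the array keeps at least three
direct repeats (two spacers).
"""

from __future__ import annotations

from dataclasses import dataclass

from .classifier import LABEL_REPEAT, ClassifierModel, classify_candidate
from .filters import FilterReport, FilterThresholds, apply_filters
from .repeat_scan import CandidateArray, ScanParams, scan_genome
from .seqio import SeqRecord

MIN_VALID_REPEATS = 3


@dataclass
class ValidatedArray:
    candidate: CandidateArray
    label: str
    vote: float
    filter_report: FilterReport | None
    status: str                      # "valid" | "rejected"
    rejection_stage: str | None = None

    def __post_init__(self) -> None:
        if self.status == "valid":
            assert self.label == LABEL_REPEAT
            assert self.filter_report is not None and self.filter_report.overall
            assert self.candidate.n_repeats >= MIN_VALID_REPEATS


def validate_candidate(candidate: CandidateArray, model: ClassifierModel,
                       thresholds: FilterThresholds = FilterThresholds(),
                       classify_mode: str = "consensus",
                       classify_first: bool = True) -> ValidatedArray:
    """Classify and filter one candidate; both stages always run so the
    report is complete regardless of which one rejects."""
    try:
        label, vote = classify_candidate(model, candidate, mode=classify_mode)
    except ValueError:
        return ValidatedArray(candidate=candidate, label="random", vote=0.0,
                              filter_report=None, status="rejected",
                              rejection_stage="classifier:unfeaturizable")
    report = apply_filters(candidate, thresholds)
    stage = None
    if candidate.n_repeats < MIN_VALID_REPEATS:
        stage = "min_repeats"
    elif classify_first and label != LABEL_REPEAT:
        stage = "classifier"
    elif not report.overall:
        failed = [k for k, r in report.rules.items() if not r.passed]
        stage = "filters:" + ",".join(failed)
    elif label != LABEL_REPEAT:
        stage = "classifier"
    return ValidatedArray(candidate=candidate, label=label, vote=vote,
                          filter_report=report,
                          status="valid" if stage is None else "rejected",
                          rejection_stage=stage)


def detect_crisprs(genomes: list[SeqRecord], model: ClassifierModel,
                   scan: ScanParams = ScanParams(),
                   thresholds: FilterThresholds = FilterThresholds(),
                   classify_mode: str = "consensus",
                   ) -> list[ValidatedArray]:
    """Run the full detection workflow over every genome record
    independently; results sorted by (genome order, array start)."""
    results: list[ValidatedArray] = []
    for genome in genomes:
        for cand in scan_genome(genome, scan):
            results.append(validate_candidate(
                cand, model, thresholds, classify_mode=classify_mode))
    return results


def valid_arrays(results: list[ValidatedArray]) -> list[ValidatedArray]:
    return [r for r in results if r.status == "valid"]


def stage_counts(results: list[ValidatedArray]) -> dict[str, int]:
    """Candidate counts per pipeline stage (monotone non-increasing)."""
    n_cand = len(results)
    n_repeat = sum(r.label == LABEL_REPEAT for r in results)
    n_valid = sum(r.status == "valid" for r in results)
    return {"candidates": n_cand, "classified_repeat": n_repeat,
            "valid": n_valid}
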