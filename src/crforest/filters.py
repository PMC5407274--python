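"""Post-classification filtration of candidate arrays.

Three rules, always all evaluated so the report is complete:

* k-mer diversity — the fraction of distinct k-mers (k = 3 by default)
  among all windows; tandem and low-complexity sequence scores low.
  Thresholds 0.2 (consensus repeat), 0.2 (each spacer), 0.25 (whole
  array span).  The statistic itself is a reconstruction: the printed
  thresholds only make sense for a "distinct k-mer fraction" that is low
  on repetitive sequence.
* tandem periodicity score — an internal short-period self-match scan
  standing in for an external tandem-repeat finder: for each period
  p <= 10, score +1 per position matching the one p back and -5 per
  mismatch with the running score clamped at 0 (Smith-Waterman-style);
  a best run score >= 10 over the array span flags a tandem repeat.
  The mismatch penalty mirrors the default of the dedicated tandem
  finders this score substitutes for; a milder -1 penalty lets chance
  periodicity in a few percent of genuine array spans random-walk past
  the threshold.  True CRISPR periodicity (repeat + spacer >= ~39 nt)
  is invisible at these short periods.
* spacer similarity — arrays whose spacers are near-copies of each other
  are degenerate; any spacer pair more than 50% identical (positional
  matches over the shared prefix, normalized by the longer length) kills
  the candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from .repeat_scan import CandidateArray


@dataclass(frozen=True)
class FilterThresholds:
    kmer_k: int = 3
    kmer_repeat: float = 0.2
    kmer_spacer: float = 0.2
    kmer_array: float = 0.25
    tandem_score_min: float = 10
    tandem_max_period: int = 10
    tandem_mismatch: float = -5.0
    spacer_sim_max: float = 0.5

    def __post_init__(self) -> None:
        for name in ("kmer_repeat", "kmer_spacer", "kmer_array",
                     "spacer_sim_max"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.kmer_k < 1:
            raise ValueError("kmer_k must be >= 1")
        if self.tandem_score_min < 0:
            raise ValueError("tandem_score_min must be >= 0")


@dataclass
class RuleOutcome:
    passed: bool
    statistic: float
    detail: str = ""


@dataclass
class FilterReport:
    rules: dict[str, RuleOutcome] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(r.passed for r in self.rules.values())


def kmer_diversity(seq: str, k: int = 3) -> float:
    """(distinct k-mers) / min(k-mer windows, 4^k); in (0, 1].

    Low on tandem and low-complexity sequence.  The denominator is capped
    at the alphabet's 4^k possible words: without the cap no sequence
    longer than 4^k + k - 1 could ever reach the whole-array threshold,
    since at most 4^k distinct words exist.  For repeat- and spacer-length
    sequences the cap is inactive and the statistic is simply the distinct
    fraction of windows.
    """
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k = {k}")
    windows = len(seq) - k + 1
    return len({seq[i:i + k] for i in range(windows)}) / min(windows, 4 ** k)


def kmer_filter(candidate: CandidateArray,
                t: FilterThresholds = FilterThresholds()) -> RuleOutcome:
    """Fails when the consensus repeat, any spacer, or the whole array
    span has k-mer diversity below its threshold."""
    rep_div = kmer_diversity(candidate.consensus_repeat, t.kmer_k)
    spacer_div = min((kmer_diversity(s, t.kmer_k)
                      for s in candidate.spacer_seqs), default=1.0)
    array_div = kmer_diversity(candidate.array_seq(), t.kmer_k)
    failed = []
    if rep_div < t.kmer_repeat:
        failed.append(f"repeat {rep_div:.3f} < {t.kmer_repeat}")
    if spacer_div < t.kmer_spacer:
        failed.append(f"spacer {spacer_div:.3f} < {t.kmer_spacer}")
    if array_div < t.kmer_array:
        failed.append(f"array {array_div:.3f} < {t.kmer_array}")
    return RuleOutcome(passed=not failed,
                       statistic=min(rep_div, spacer_div, array_div),
                       detail="; ".join(failed) or
                       f"min diversity {min(rep_div, spacer_div, array_div):.3f}")


def tandem_score(seq: str, max_period: int = 10,
                 mismatch: float = -5.0) -> float:
    """Best clamped self-match run score over periods 1..max_period."""
    if len(seq) < 2:
        raise ValueError("sequence too short for a periodicity scan")
    best = 0.0
    for p in range(1, min(max_period, len(seq) - 1) + 1):
        run = 0.0
        for i in range(p, len(seq)):
            run = max(0.0, run + (1 if seq[i] == seq[i - p] else mismatch))
            best = max(best, run)
    return best


def tandem_filter(candidate: CandidateArray,
                  t: FilterThresholds = FilterThresholds()) -> RuleOutcome:
    """Flags the candidate as a tandem repeat when the short-period score
    of the full array span reaches the threshold."""
    score = tandem_score(candidate.array_seq(), t.tandem_max_period,
                         t.tandem_mismatch)
    passed = score < t.tandem_score_min or math.isinf(t.tandem_score_min)
    return RuleOutcome(passed=passed, statistic=score,
                       detail=f"periodicity score {score:g} "
                              f"(threshold {t.tandem_score_min:g})")


def spacer_similarity(a: str, b: str) -> float:
    """Positional matches over the first min(len) positions, normalized by
    the longer length; symmetric, penalizes length mismatch."""
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def spacer_similarity_filter(candidate: CandidateArray,
                             t: FilterThresholds = FilterThresholds()
                             ) -> RuleOutcome:
    """Fails when any spacer pair exceeds the similarity ceiling."""
    if len(candidate.spacer_seqs) < 2:
        raise ValueError("spacer similarity needs at least 2 spacers")
    worst = 0.0
    offenders: tuple[int, int] | None = None
    for (i, a), (j, b) in combinations(enumerate(candidate.spacer_seqs), 2):
        sim = spacer_similarity(a, b)
        if sim > worst:
            worst, offenders = sim, (i, j)
    passed = worst <= t.spacer_sim_max
    detail = f"max pairwise similarity {worst:.3f}"
    if not passed and offenders is not None:
        detail += f" (spacers {offenders[0]} and {offenders[1]})"
    return RuleOutcome(passed=passed, statistic=worst, detail=detail)


def apply_filters(candidate: CandidateArray,
                  t: FilterThresholds = FilterThresholds()) -> FilterReport:
    """Run every rule (no short-circuit); overall passes iff all do."""
    report = FilterReport()
    report.rules["kmer_diversity"] = kmer_filter(candidate, t)
    report.rules["tandem_periodicity"] = tandem_filter(candidate, t)
    report.rules["spacer_similarity"] = spacer_similarity_filter(candidate, t)
    return report
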