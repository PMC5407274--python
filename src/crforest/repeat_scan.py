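"""Candidate CRISPR array detection by exact k-mer seed chaining and
consensus-threshold extension.

The scanner nucleates candidates on short exact seed words that recur at
array-like periods (repeat + spacer length), then grows each seed interval
outward one column at a time while the flanking column is conserved across
instances: the 5' flank must be >= 75% identical, the 3' flank only >= 60%,
reflecting the greater variability of repeat 3' ends.  A short seed (5 nt)
plus the lenient 3' threshold trades boundary sharpness on small arrays for
sensitivity to degenerate repeats.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .seqio import SeqRecord

_ALPHA = "ACGT"


@dataclass(frozen=True)
class ScanParams:
    """Seed/extension parameters: 5 nt seeds, 0.75 / 0.60 directional
    extension thresholds, repeats 20-55 nt, spacers 19-60 nt."""

    seed_len: int = 5
    ext5_threshold: float = 0.75
    ext3_threshold: float = 0.60
    min_repeats: int = 3
    min_repeat_len: int = 20
    max_repeat_len: int = 55
    min_spacer_len: int = 19
    max_spacer_len: int = 60
    #: instances whose identity to the candidate consensus is below this are
    #: dropped after extension (spurious chain members from chance seed hits)
    min_instance_identity: float = 0.70

    def __post_init__(self) -> None:
        if not 0 < self.seed_len <= self.min_repeat_len:
            raise ValueError("seed_len must be in (0, min_repeat_len]")
        for t in (self.ext5_threshold, self.ext3_threshold):
            if not 0 < t <= 1:
                raise ValueError("extension thresholds must be in (0, 1]")
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_spacer_len > self.max_spacer_len:
            raise ValueError("min_spacer_len > max_spacer_len")
        if self.min_repeats < 3:
            raise ValueError("min_repeats must be >= 3")

    @property
    def min_period(self) -> int:
        # seeds may sit at slightly different offsets once instances carry
        # mismatches, hence the seed_len slack below the exact minimum period
        return self.min_repeat_len + self.min_spacer_len - self.seed_len

    @property
    def max_period(self) -> int:
        return self.max_repeat_len + self.max_spacer_len

    def min_genome_len(self) -> int:
        return (self.min_repeats * self.min_repeat_len
                + (self.min_repeats - 1) * self.min_spacer_len)


@dataclass(frozen=True)
class SeedChain:
    """Ordered start positions of one recurring seed word."""

    positions: tuple[int, ...]
    seed_len: int


@dataclass
class CandidateArray:
    """One putative CRISPR locus: alternating repeat and spacer intervals
    (0-based half-open) plus the per-column consensus repeat."""

    genome_id: str
    repeat_intervals: list[tuple[int, int]]
    spacer_intervals: list[tuple[int, int]]
    repeat_seqs: list[str]
    spacer_seqs: list[str]
    consensus_repeat: str

    @property
    def start(self) -> int:
        return self.repeat_intervals[0][0]

    @property
    def end(self) -> int:
        return self.repeat_intervals[-1][1]

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_intervals)

    def array_seq(self) -> str:
        parts = []
        for i, r in enumerate(self.repeat_seqs):
            parts.append(r)
            if i < len(self.spacer_seqs):
                parts.append(self.spacer_seqs[i])
        return "".join(parts)

    def validate(self, params: ScanParams | None = None) -> None:
        """Assert the structural invariants of an array."""
        nr, ns = len(self.repeat_intervals), len(self.spacer_intervals)
        assert ns == nr - 1, "spacer count must be repeat count - 1"
        prev_end = None
        for i, (rs, re) in enumerate(self.repeat_intervals):
            assert rs < re, "empty repeat interval"
            if prev_end is not None:
                ss, se = self.spacer_intervals[i - 1]
                assert ss == prev_end and se == rs, \
                    "repeats and spacers must alternate without gaps"
            prev_end = re
        lens = [re - rs for rs, re in self.repeat_intervals]
        assert len(set(lens)) >= 1
        assert len(self.consensus_repeat) == Counter(lens).most_common(1)[0][0]
        if params is not None:
            for s, e in self.spacer_intervals:
                assert params.min_spacer_len <= e - s <= params.max_spacer_len
            for ln in lens:
                assert params.min_repeat_len <= ln <= params.max_repeat_len


def consensus(seqs: list[str]) -> str:
    """Per-column modal nucleotide; ties broken A < C < G < T; N ignored
    unless a column is all-N."""
    if not seqs:
        return ""
    length = Counter(len(s) for s in seqs).most_common(1)[0][0]
    cols = []
    for j in range(length):
        counts = Counter(s[j] for s in seqs if len(s) > j and s[j] != "N")
        if not counts:
            cols.append("N")
            continue
        best = max(counts.values())
        cols.append(min(c for c in counts if counts[c] == best))
    return "".join(cols)


def _chain_positions(pos: list[int], lo: int, hi: int,
                     min_members: int) -> list[list[int]]:
    chains: list[list[int]] = []
    used: set[int] = set()
    n = len(pos)
    for i in range(n):
        if pos[i] in used:
            continue
        chain = [pos[i]]
        cur = pos[i]
        for j in range(i + 1, n):
            gap = pos[j] - cur
            if gap < lo:
                continue
            if gap > hi:
                break
            chain.append(pos[j])
            used.add(pos[j])
            cur = pos[j]
        if len(chain) >= min_members:
            chains.append(chain)
    return chains


def _merge_chains(chains: list[list[int]]) -> list[tuple[int, ...]]:
    """Merge chains sharing >= 2 positions (union of their positions)."""
    merged: list[set[int]] = []
    for chain in chains:
        cs = set(chain)
        while True:
            hit = next((m for m in merged if len(m & cs) >= 2), None)
            if hit is None:
                break
            merged.remove(hit)
            cs |= hit
        merged.append(cs)
    return sorted(tuple(sorted(m)) for m in merged)


def find_seed_chains(genome: SeqRecord, params: ScanParams = ScanParams()
                     ) -> list[SeedChain]:
    """All maximal chains of >= min_repeats identical seed words recurring
    at gaps within the admissible array period.  Seed windows containing N
    never seed."""
    seq = genome.sequence
    k = params.seed_len
    if len(seq) < params.min_genome_len():
        return []
    by_kmer: dict[str, list[int]] = defaultdict(list)
    run_without_n = 0
    for i, ch in enumerate(seq):
        run_without_n = run_without_n + 1 if ch != "N" else 0
        if run_without_n >= k:
            start = i - k + 1
            by_kmer[seq[start:start + k]].append(start)
    chains: list[list[int]] = []
    for positions in by_kmer.values():
        if len(positions) < params.min_repeats:
            continue
        chains.extend(_chain_positions(positions, params.min_period,
                                       params.max_period, params.min_repeats))
    return [SeedChain(positions=c, seed_len=k) for c in _merge_chains(chains)]


def _identity(a: str, b: str) -> float:
    return sum(x == y and x != "N" for x, y in zip(a, b)) / max(len(a), len(b))


def extend_chain(genome: SeqRecord, chain: SeedChain,
                 params: ScanParams = ScanParams()) -> CandidateArray | None:
    """Grow the seed interval of every chain instance in lockstep.

    A flank column is added while the modal nucleotide across instances
    reaches the directional threshold (5': ext5_threshold, 3':
    ext3_threshold); extension also stops at sequence ends, instance
    collisions, or max_repeat_len.  After extension, instances diverging
    from the consensus are pruned; returns None when the result violates
    repeat-length or spacer-length bounds.
    """
    if len(chain.positions) < params.min_repeats:
        return None
    seq = genome.sequence
    pos = list(chain.positions)
    k = chain.seed_len
    off5, off3 = 0, 0  # instance i occupies [pos[i]+off5, pos[i]+k+off3)

    def column_ok(delta5: int, delta3: int, threshold: float) -> bool:
        chars = []
        for idx, p in enumerate(pos):
            if delta5:  # probing one column left of the current 5' edge
                j = p + off5 - 1
                if j < 0 or (idx > 0 and j < pos[idx - 1] + k + off3):
                    return False
            else:  # one column right of the current 3' edge
                j = p + k + off3
                if j >= len(seq) or (idx + 1 < len(pos)
                                     and j >= pos[idx + 1] + off5):
                    return False
            chars.append(seq[j])
        counts = Counter(c for c in chars if c != "N")
        if not counts:
            return False
        return max(counts.values()) / len(chars) >= threshold

    while k + off3 - off5 < params.max_repeat_len and \
            column_ok(1, 0, params.ext5_threshold):
        off5 -= 1
    while k + off3 - off5 < params.max_repeat_len and \
            column_ok(0, 1, params.ext3_threshold):
        off3 += 1

    length = k + off3 - off5
    if length < params.min_repeat_len:
        return None
    intervals = [(p + off5, p + k + off3) for p in pos]
    seqs = [seq[s:e] for s, e in intervals]

    # prune instances that diverge from the consensus (chance seed hits)
    cons = consensus(seqs)
    keep = [i for i, s in enumerate(seqs)
            if _identity(s, cons) >= params.min_instance_identity]
    if len(keep) < params.min_repeats:
        return None
    intervals = [intervals[i] for i in keep]
    seqs = [seqs[i] for i in keep]

    spacers = []
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if not params.min_spacer_len <= s2 - e1 <= params.max_spacer_len:
            return None
        spacers.append((e1, s2))
    cand = CandidateArray(
        genome_id=genome.id,
        repeat_intervals=intervals,
        spacer_intervals=spacers,
        repeat_seqs=seqs,
        spacer_seqs=[seq[s:e] for s, e in spacers],
        consensus_repeat=consensus(seqs),
    )
    cand.validate(params)
    return cand


def scan_genome(genome: SeqRecord, params: ScanParams = ScanParams()
                ) -> list[CandidateArray]:
    """Full scan: chains found, extended, pruned of nulls; overlapping
    candidates resolved (more repeats > longer span > leftmost) and the
    survivors returned sorted by start."""
    candidates: list[CandidateArray] = []
    seen: set[tuple] = set()
    for chain in find_seed_chains(genome, params):
        cand = extend_chain(genome, chain, params)
        if cand is None:
            continue
        key = tuple(cand.repeat_intervals)
        if key in seen:
            continue
        seen.add(key)
        candidates.append(cand)
    # overlap resolution
    ranked = sorted(candidates,
                    key=lambda c: (-c.n_repeats, -(c.end - c.start), c.start))
    kept: list[CandidateArray] = []
    for cand in ranked:
        if all(cand.end <= other.start or cand.start >= other.end
               for other in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    for cand in kept:
        cand.validate(params)
    return kept
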