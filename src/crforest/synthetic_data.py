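"""Synthetic fixtures: stem-loop repeats, genomes with planted arrays, and
tandem-repeat decoys.

The generator emulates the anatomy of genuine loci — direct repeats of
20-55 nt carrying a palindromic stem (so structural features carry class
signal), separated by unique spacers of similar length — embedded in an
i.i.d. uniform background (GC 0.5 by default, adjustable).  It is a test
harness, not a sequence-evolution model: no cas-gene context, no leader,
no phage-derived spacer content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repeat_scan import CandidateArray, consensus
from .seqio import SeqRecord

_NT = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

#: loop length of the planted hairpin
_LOOP_LEN = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_NT[i] for i in rng.choice(4, size=n, p=p))


@dataclass(frozen=True)
class PlantSpec:
    """Geometry of one planted array.

    Defaults describe a typical genuine locus: a 32 nt largely palindromic
    repeat (stem arm ~40% of the length, so the hairpin spans most of the
    repeat), around a dozen copies, spacers 24-40 nt.  ``stem_len=None``
    selects the proportional arm; ``stem_len=0`` plants unstructured
    repeats.
    """

    repeat_len: int = 32
    n_copies: int = 12
    spacer_len_range: tuple[int, int] = (24, 40)
    repeat_mutation_rate: float = 0.0
    stem_len: int | None = None
    rng_seed: int = 0

    @property
    def arm_len(self) -> int:
        if self.stem_len is None:
            return max(6, int(0.4 * self.repeat_len))
        return self.stem_len

    def __post_init__(self) -> None:
        if not 20 <= self.repeat_len <= 55:
            raise ValueError("repeat_len must be in [20, 55]")
        if self.n_copies < 2:
            raise ValueError("n_copies must be >= 2")
        lo, hi = self.spacer_len_range
        if lo > hi or lo < 1:
            raise ValueError("spacer_len_range must be ordered and positive")
        if not 0 <= self.repeat_mutation_rate < 1:
            raise ValueError("repeat_mutation_rate must be in [0, 1)")
        if self.arm_len < 0 or (
                self.arm_len > 0
                and 2 * self.arm_len + _LOOP_LEN > self.repeat_len):
            raise ValueError("stem geometry exceeds repeat_len")


def _hairpin_repeat(rng: np.random.Generator, spec: PlantSpec) -> str:
    """One repeat: random prefix + stem arm + loop + arm' + random suffix."""
    if spec.arm_len == 0:
        return _random_seq(rng, spec.repeat_len)
    arm = _random_seq(rng, spec.arm_len)
    core = arm + _random_seq(rng, _LOOP_LEN) + reverse_complement(arm)
    slack = spec.repeat_len - len(core)
    left = int(rng.integers(slack + 1))
    return _random_seq(rng, left) + core + _random_seq(rng, slack - left)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _NT[(_NT.index(chars[i]) +
                            int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def make_positive_repeats(n: int, spec: PlantSpec = PlantSpec()) -> list[str]:
    """*n* independent stem-loop-bearing repeats of spec.repeat_len, with
    per-base substitutions at spec.repeat_mutation_rate; seeded."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(spec.rng_seed)
    return [_mutate(rng, _hairpin_repeat(rng, spec),
                    spec.repeat_mutation_rate) for _ in range(n)]


def make_training_repeats(n: int, rng_seed: int = 0,
                          lengths: tuple[int, ...] = (24, 28, 30, 32, 36, 40),
                          stem_len: int | None = None,
                          mutation_rate: float = 0.02) -> list[str]:
    """A mixed-length positive training pool, cycling over typical repeat
    lengths so models generalize across the repeat-length range."""
    out: list[str] = []
    for i in range(n):
        spec = PlantSpec(repeat_len=lengths[i % len(lengths)],
                         stem_len=stem_len,
                         repeat_mutation_rate=mutation_rate,
                         rng_seed=rng_seed + i)
        out.extend(make_positive_repeats(1, spec))
    return out


def _build_array(rng: np.random.Generator, spec: PlantSpec
                 ) -> tuple[str, list[int], list[int]]:
    """Array sequence plus repeat/spacer lengths (offsets resolved later)."""
    base = _hairpin_repeat(rng, spec)
    lo, hi = spec.spacer_len_range
    repeats = [_mutate(rng, base, spec.repeat_mutation_rate)
               for _ in range(spec.n_copies)]
    spacers = [_random_seq(rng, int(rng.integers(lo, hi + 1)))
               for _ in range(spec.n_copies - 1)]
    parts = []
    for i, r in enumerate(repeats):
        parts.append(r)
        if i < len(spacers):
            parts.append(spacers[i])
    return "".join(parts), [len(r) for r in repeats], [len(s) for s in spacers]


def plant_arrays(genome_len: int, specs: list[PlantSpec], rng_seed: int,
                 genome_id: str = "synthetic", gc: float = 0.5,
                 min_separation: int = 100, max_tries: int = 1000,
                 ) -> tuple[SeqRecord, list[CandidateArray]]:
    """An i.i.d. background genome with the requested arrays planted at
    non-overlapping positions at least *min_separation* apart; returns the
    genome and the exact truth intervals, asserted against the genome."""
    rng = np.random.default_rng(rng_seed)
    built = [_build_array(rng, spec) for spec in specs]
    if sum(len(b[0]) for b in built) > genome_len / 2:
        raise ValueError("total planted span exceeds half the genome")
    background = list(_random_seq(rng, genome_len))
    placed: list[tuple[int, int]] = []
    truth: list[CandidateArray] = []
    for arr_seq, rep_lens, sp_lens in built:
        span = len(arr_seq)
        for _ in range(max_tries):
            start = int(rng.integers(0, genome_len - span + 1))
            if all(start >= e + min_separation or start + span + min_separation <= s
                   for s, e in placed):
                break
        else:
            raise ValueError("could not place arrays without overlap; "
                             "increase genome_len")
        placed.append((start, start + span))
        background[start:start + span] = arr_seq
        rep_iv, sp_iv = [], []
        pos = start
        for i, rl in enumerate(rep_lens):
            rep_iv.append((pos, pos + rl))
            pos += rl
            if i < len(sp_lens):
                sp_iv.append((pos, pos + sp_lens[i]))
                pos += sp_lens[i]
        rep_seqs = [arr_seq[s - start:e - start] for s, e in rep_iv]
        truth.append(CandidateArray(
            genome_id=genome_id, repeat_intervals=rep_iv,
            spacer_intervals=sp_iv, repeat_seqs=rep_seqs,
            spacer_seqs=[arr_seq[s - start:e - start] for s, e in sp_iv],
            consensus_repeat=consensus(rep_seqs)))
    genome = SeqRecord(id=genome_id, sequence="".join(background))
    for t in truth:  # generator output must satisfy its own truth record
        for (s, e), seq in zip(t.repeat_intervals, t.repeat_seqs):
            assert genome.sequence[s:e] == seq
        for (s, e), seq in zip(t.spacer_intervals, t.spacer_seqs):
            assert genome.sequence[s:e] == seq
        t.validate()
    truth.sort(key=lambda t: t.start)
    return genome, truth


def make_tandem_decoy(unit: str, n_units: int) -> str:
    """The unit repeated n_units times — a short-period tandem repeat."""
    if not unit:
        raise ValueError("unit must be non-empty")
    if n_units < 2:
        raise ValueError("n_units must be >= 2")
    return unit * n_units


def insert_decoys(genome: SeqRecord, truth: list[CandidateArray],
                  decoys: list[str], rng_seed: int,
                  min_separation: int = 100, max_tries: int = 1000,
                  ) -> tuple[SeqRecord, list[tuple[int, int]]]:
    """Overwrite background windows with decoy sequences, away from the
    planted arrays; returns the new genome and the decoy intervals."""
    rng = np.random.default_rng(rng_seed)
    seq = list(genome.sequence)
    keepout = [(t.start, t.end) for t in truth]
    intervals: list[tuple[int, int]] = []
    for decoy in decoys:
        span = len(decoy)
        for _ in range(max_tries):
            start = int(rng.integers(0, len(seq) - span + 1))
            if all(start >= e + min_separation
                   or start + span + min_separation <= s
                   for s, e in keepout + intervals):
                break
        else:
            raise ValueError("could not place decoy without overlap")
        seq[start:start + span] = decoy
        intervals.append((start, start + span))
    return SeqRecord(id=genome.id, sequence="".join(seq),
                     description=genome.description), intervals
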