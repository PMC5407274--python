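"""Secondary-structure prediction and triplet-element featurization.

Candidate repeats are folded as RNA (T read as U) and each sequence is
summarized by 32 normalized *triplet elements*: a length-3 window slides
over the dot-bracket string with brackets collapsed to a single "paired"
status, and every window contributes one count to the (middle nucleotide,
window pattern) cell.  4 nucleotides x 8 binary patterns = 32 features,
normalized by the number of windows (L - 2), so each vector is a frequency
distribution that mixes base composition with local pairing context — the
signal that separates stem-loop-bearing CRISPR repeats from background.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

try:  # ViennaRNA python bindings; optional
    import RNA as _vienna
except ImportError:  # pragma: no cover - environment dependent
    _vienna = None

#: the 8 collapsed structural window patterns, in canonical order
PATTERNS: tuple[str, ...] = ("(((", "((.", "(..", "(.(",
                             ".((", ".(.", "..(", "...")
NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")
#: canonical nucleotide-major feature order; versioned into model files
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{nt}|{pat}" for nt in NUCLEOTIDES for pat in PATTERNS)
N_FEATURES = len(FEATURE_NAMES)  # 32

_FEATURE_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}

_MIN_LOOP = 3
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
          ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class DotBracket:
    """A balanced, properly nested dot-bracket structure string."""

    structure: str
    engine: str = "unknown"

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.structure:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket structure")
            elif ch != ".":
                raise ValueError(f"invalid structure character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket structure")

    def __len__(self) -> int:
        return len(self.structure)

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


def default_engine() -> str:
    """'viennarna' when the bindings are importable, else 'nussinov'."""
    return "viennarna" if _vienna is not None else "nussinov"


def _nussinov(seq: str) -> str:
    """Maximum base-pairing structure (Watson-Crick + GU, min loop 3).

    Bundled thermodynamic-free fallback folder; deterministic traceback
    preferring the unpaired branch, then the shortest-range pair.
    """
    n = len(seq)
    rna = seq.replace("T", "U")

    def can_pair(i: int, j: int) -> bool:
        return (rna[i], rna[j]) in _PAIRS

    best = [[0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            score = best[i][j - 1]  # j unpaired
            for k in range(i, j - _MIN_LOOP):
                if can_pair(k, j):
                    left = best[i][k - 1] if k > i else 0
                    cand = left + 1 + (best[k + 1][j - 1]
                                       if k + 1 <= j - 1 else 0)
                    if cand > score:
                        score = cand
            best[i][j] = score

    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_LOOP:
            continue
        if best[i][j] == best[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - _MIN_LOOP):
            if can_pair(k, j):
                left = best[i][k - 1] if k > i else 0
                inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner == best[i][j]:
                    struct[k], struct[j] = "(", ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return "".join(struct)


@functools.lru_cache(maxsize=65536)
def _fold_cached(seq: str, engine: str) -> str:
    if engine == "viennarna":
        structure, _mfe = _vienna.fold(seq)
        return structure
    return _nussinov(seq)


def fold_sequence(seq: str, engine: str = "auto") -> DotBracket:
    """Minimum-free-energy (ViennaRNA) or maximum-pairing (Nussinov
    fallback) structure of *seq* folded as RNA; N is unpairable."""
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)!r}")
    if engine == "auto":
        engine = default_engine()
    if engine == "viennarna" and _vienna is None:
        raise RuntimeError("ViennaRNA bindings are not importable")
    if engine not in ("viennarna", "nussinov"):
        raise ValueError(f"unknown folding engine {engine!r}")
    structure = _fold_cached(seq, engine)
    return DotBracket(structure=structure, engine=engine)


def triplet_features(seq: str, structure: DotBracket | str) -> np.ndarray:
    """The 32-vector of normalized triplet elements for one sequence.

    ')' collapses to '(' first (two structural statuses per position);
    window i contributes to cell (seq[i+1], pattern).  Windows whose middle
    nucleotide is N stay in the denominator but increment no cell, keeping
    vectors comparable across sequences with assembly gaps.
    """
    struct = structure.structure if isinstance(structure, DotBracket) \
        else structure
    if len(seq) != len(struct):
        raise ValueError("sequence and structure lengths differ")
    if len(seq) < 3:
        raise ValueError("sequence shorter than the window (3 nt)")
    collapsed = struct.replace(")", "(")
    vec = np.zeros(N_FEATURES)
    n_windows = len(seq) - 2
    for i in range(n_windows):
        mid = seq[i + 1]
        if mid == "N":
            continue
        vec[_FEATURE_INDEX[f"{mid}|{collapsed[i:i + 3]}"]] += 1
    return vec / n_windows


def featurize_batch(seqs: Sequence[str], engine: str = "auto") -> np.ndarray:
    """Fold and featurize a batch; returns an (n, 32) matrix, row order
    preserved, folding cached by sequence string."""
    rows = []
    for idx, seq in enumerate(seqs):
        try:
            db = fold_sequence(seq, engine=engine)
            rows.append(triplet_features(seq, db))
        except ValueError as exc:
            raise ValueError(f"sequence {idx}: {exc}") from None
    if not rows:
        return np.empty((0, N_FEATURES))
    return np.vstack(rows)


def write_feature_tsv(seqs: Sequence[str], matrix: np.ndarray,
                      path: str) -> None:
    """Headered TSV export of a feature matrix for inspection."""
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(FEATURE_NAMES) + "\n")
        for seq, row in zip(seqs, matrix):
            fh.write(seq + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
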