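"""Sequence and result I/O.

Genomes and repeat sets come in as FASTA (via Biopython); detection results
go out as GFF3, JSON and per-array FASTA files.  All *reported* coordinates
are 1-based inclusive, matching the convention of CRISPR text reports;
internal coordinates throughout the package are 0-based half-open, and the
conversion happens only here.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO as _BioSeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ValidatedArray

#: IUPAC one-letter ambiguity codes other than N; all collapse to N on input.
_AMBIGUITY = set("RYSWKMBDHV")
_VALID = set("ACGTN")


class FastaFormatError(ValueError):
    """Raised for empty, malformed or duplicate-id FASTA input."""


@dataclass(frozen=True)
class SeqRecord:
    """A sanitized nucleotide sequence over {A, C, G, T, N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(raw: str) -> str:
    """Uppercase, map ambiguity codes (R, Y, S, W, K, M, B, D, H, V) to N.

    Characters outside the IUPAC nucleotide alphabet raise ``ValueError``;
    soft-masking (lowercase) is erased.
    """
    out = []
    for ch in raw.upper():
        if ch in _VALID:
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
        elif ch == "U":
            out.append("T")
        else:
            raise ValueError(f"non-nucleotide character {ch!r}")
    return "".join(out)


def _locate_bad_char(path: str | os.PathLike, bad: str) -> int:
    """Line number (1-based) of the first occurrence of *bad* in sequence text."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if bad in line.upper() or bad in line:
                return lineno
    return -1


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into sanitized :class:`SeqRecord` objects.

    Wrapped sequence lines are joined, input order is preserved, lowercase
    is uppercased and non-N ambiguity codes become N.  Empty files,
    duplicate ids and non-nucleotide characters (digits, ``*`` ...) raise
    :class:`FastaFormatError`; the character error names the line.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            seq = sanitize_sequence(str(rec.seq))
        except ValueError as exc:
            bad = str(exc).split("'")[1]
            lineno = _locate_bad_char(path, bad)
            raise FastaFormatError(
                f"{path}: line {lineno}: {exc} in record {rec.id!r}"
            ) from None
        records.append(SeqRecord(id=rec.id, sequence=seq,
                                 description=rec.description))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# result writing

def _array_span(va: "ValidatedArray") -> tuple[int, int]:
    cand = va.candidate
    return cand.repeat_intervals[0][0], cand.repeat_intervals[-1][1]


def _validated_to_dict(va: "ValidatedArray") -> dict:
    """JSON form of a ValidatedArray; coordinates 1-based inclusive."""
    cand = va.candidate
    one = lambda iv: [iv[0] + 1, iv[1]]  # 0-based half-open -> 1-based inclusive
    return {
        "genome_id": cand.genome_id,
        "repeat_intervals": [one(iv) for iv in cand.repeat_intervals],
        "spacer_intervals": [one(iv) for iv in cand.spacer_intervals],
        "repeat_seqs": list(cand.repeat_seqs),
        "spacer_seqs": list(cand.spacer_seqs),
        "consensus_repeat": cand.consensus_repeat,
        "label": va.label,
        "vote": va.vote,
        "status": va.status,
        "rejection_stage": va.rejection_stage,
        "filter_report": dataclasses.asdict(va.filter_report)
        if va.filter_report is not None else None,
    }


def results_from_json(path: str | os.PathLike) -> list[dict]:
    """Load a results JSON document back to dicts with internal coordinates."""
    with open(path) as fh:
        doc = json.load(fh)
    for entry in doc["arrays"]:
        for key in ("repeat_intervals", "spacer_intervals"):
            entry[key] = [(a - 1, b) for a, b in entry[key]]
    return doc["arrays"]


def _write_gff3(arrays: Sequence["ValidatedArray"], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, va in enumerate(arrays, start=1):
            cand = va.candidate
            s0, e0 = _array_span(va)
            aid = f"crispr_array_{i}"
            attrs = (f"ID={aid};n_repeats={len(cand.repeat_intervals)};"
                     f"consensus={cand.consensus_repeat};status={va.status}")
            fh.write("\t".join([cand.genome_id, "crforest", "repeat_region",
                                str(s0 + 1), str(e0), ".", "+", ".",
                                attrs]) + "\n")
            for j, (rs, re_) in enumerate(cand.repeat_intervals, start=1):
                fh.write("\t".join([cand.genome_id, "crforest", "direct_repeat",
                                    str(rs + 1), str(re_), ".", "+", ".",
                                    f"ID={aid}.repeat{j};Parent={aid}"]) + "\n")
            for j, (ss, se) in enumerate(cand.spacer_intervals, start=1):
                fh.write("\t".join([cand.genome_id, "crforest", "spacer",
                                    str(ss + 1), str(se), ".", "+", ".",
                                    f"ID={aid}.spacer{j};Parent={aid}"]) + "\n")


def write_results(arrays: Sequence["ValidatedArray"], out_dir: str | os.PathLike,
                  formats: set[str] = frozenset({"gff3", "json", "fasta"}),
                  ) -> list[str]:
    """Write detection results under *out_dir* in the requested formats.

    Returns the list of file paths written.  GFF3 carries one
    ``repeat_region`` per array with ``direct_repeat``/``spacer`` children;
    JSON mirrors the full record including the filter report; FASTA emits
    per-array repeat and spacer files.
    """
    unknown = set(formats) - {"gff3", "json", "fasta"}
    if unknown:
        raise ValueError(f"unknown output formats: {sorted(unknown)}")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []
    if "gff3" in formats:
        p = os.path.join(out_dir, "arrays.gff3")
        _write_gff3(arrays, p)
        written.append(p)
    if "json" in formats:
        p = os.path.join(out_dir, "arrays.json")
        with open(p, "w") as fh:
            json.dump({"coordinates": "1-based inclusive",
                       "arrays": [_validated_to_dict(v) for v in arrays]},
                      fh, indent=1)
            fh.write("\n")
        written.append(p)
    if "fasta" in formats:
        for i, va in enumerate(arrays, start=1):
            cand = va.candidate
            aid = f"crispr_array_{i}"
            rp = os.path.join(out_dir, f"{aid}.repeats.fasta")
            write_fasta([SeqRecord(id=f"{aid}.repeat{j}", sequence=s)
                         for j, s in enumerate(cand.repeat_seqs, start=1)], rp)
            written.append(rp)
            if cand.spacer_seqs:
                sp = os.path.join(out_dir, f"{aid}.spacers.fasta")
                write_fasta([SeqRecord(id=f"{aid}.spacer{j}", sequence=s)
                             for j, s in enumerate(cand.spacer_seqs, start=1)],
                            sp)
                written.append(sp)
    return written
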