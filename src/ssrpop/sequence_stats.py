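"""Assembly-style summary statistics over sequence length sets.

N50/N90 use the cumulative-coverage convention: sort lengths in descending
order and take the first length at which the running total reaches at least
50% (90%) of the summed bases.  Some tools use a strict ``>`` threshold
instead; the difference only matters on exact ties at the percentile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "LengthSummary",
    "compute_length_summary",
    "gc_content",
    "rounded_mean_bp",
    "read_fasta_lengths",
]


@dataclass(frozen=True)
class LengthSummary:
    """Summary of a set of sequence lengths (all length fields in bp)."""

    n_sequences: int
    total_bp: int
    mean_bp: float
    median_bp: float
    min_bp: int
    max_bp: int
    n50_bp: int
    n90_bp: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        keys = list(d)
        return "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"


def rounded_mean_bp(total_bp: int, n_sequences: int) -> int:
    """Mean length rounded half-away-from-zero to whole bp.

    This is the rounding that reproduces printed per-assembly mean lengths
    (Python's builtin ``round`` is banker's rounding, which differs on .5).
    """
    if n_sequences <= 0:
        raise ValueError("n_sequences must be positive")
    mean = total_bp / n_sequences
    return int(math.floor(mean + 0.5)) if mean >= 0 else -int(math.floor(-mean + 0.5))


def compute_length_summary(lengths: Sequence[int] | Iterable[int]) -> LengthSummary:
    """Compute n, total, mean, median, min/max and N50/N90 for a length set.

    Parameters
    ----------
    lengths
        Positive sequence lengths in bp; must be non-empty.
    """
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty set of lengths")
    if np.any(arr <= 0):
        raise ValueError("all lengths must be positive")

    total = int(arr.sum())
    desc = np.sort(arr)[::-1]
    cum = np.cumsum(desc)
    # first index where cumulative coverage reaches the threshold
    n50 = int(desc[np.searchsorted(cum, 0.5 * total)])
    n90 = int(desc[np.searchsorted(cum, 0.9 * total)])
    return LengthSummary(
        n_sequences=int(arr.size),
        total_bp=total,
        mean_bp=float(arr.mean()),
        median_bp=float(np.median(arr)),
        min_bp=int(arr.min()),
        max_bp=int(arr.max()),
        n50_bp=n50,
        n90_bp=n90,
    )


def gc_content(sequence: str) -> float:
    """GC fraction of a nucleotide string; ``N`` is excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    gc = s.count("G") + s.count("C")
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N; GC content undefined")
    return gc / denom


def read_fasta_lengths(path) -> list[int]:
    """Sequence lengths of every record in a (wrapped or unwrapped) FASTA file."""
    return [len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
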