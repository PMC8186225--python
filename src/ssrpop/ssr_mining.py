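"""MISA-compatible detection of perfect and compound microsatellites (SSRs).

Search thresholds follow the convention used for EST-SSR surveys: a tract is
reported when it reaches at least 10 repeats for mono-, 6 for di- and 5 for
tri- through hexa-nucleotide motifs.  "At least" matches MISA's documented
defaults; a strict-greater reading is available via ``strict_greater``.

Conventions
-----------
* Coordinates are 1-based inclusive, matching MISA's tabular output.
* Only whole repeat units count: a tract of 6.5 di-units is reported with
  ``n_repeats = 6`` and a length of 12 bp.
* A tract reportable at several unit lengths is reported once, at the
  smallest unit length whose motif is primitive — (AT)x6 is a di-repeat,
  never (ATAT)x3.
* ``N`` breaks any tract and never participates in a repeat; IUPAC ambiguity
  codes other than N are rejected.  Lowercase (soft-masked) input is
  uppercased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SSRSearchConfig",
    "SSRLocus",
    "RepeatClassSummary",
    "FlankRecord",
    "find_perfect_ssrs",
    "merge_compound",
    "canonical_motif_class",
    "is_primitive",
    "summarize_ssrs",
    "extract_flanks",
    "mine_fasta",
    "loci_to_misa_table",
]

_DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRSearchConfig:
    """Search thresholds: minimum repeat count per motif length (1..6 bp)."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(_DEFAULT_MIN_REPEATS)
    )
    max_interruption_bp: int = 100
    strict_greater: bool = False

    def __post_init__(self):
        if set(self.min_repeats) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("min_repeats must map motif lengths exactly 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must all be >= 2")

    def threshold(self, unit: int) -> int:
        base = self.min_repeats[unit]
        return base + 1 if self.strict_greater else base


@dataclass(frozen=True)
class SSRLocus:
    """One detected repeat tract (1-based inclusive coordinates)."""

    seq_id: str
    motif: str
    n_repeats: int
    start: int
    end: int
    is_compound: bool = False

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def canonical_class(self) -> str:
        if self.is_compound:
            return "compound"
        return canonical_motif_class(self.motif)


@dataclass(frozen=True)
class FlankRecord:
    """Primer-ready extract: left flank + SSR tract + right flank."""

    locus: SSRLocus
    left_flank: str
    ssr: str
    right_flank: str
    left_truncated: bool
    right_truncated: bool

    @property
    def sequence(self) -> str:
        return self.left_flank + self.ssr + self.right_flank


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _rotations(motif: str) -> set[str]:
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def canonical_motif_class(motif: str) -> str:
    """Strand/rotation-invariant class label for a primitive motif.

    The class is the set of cyclic rotations of the motif together with the
    rotations of its reverse complement.  The label joins the
    lexicographically smallest rotation on each strand, smaller first
    (e.g. CGG -> "CCG/CGG"); self-complementary classes collapse to a single
    label (e.g. AT -> "AT").
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1..6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    fwd = min(_rotations(motif))
    rc = motif.translate(_COMPLEMENT)[::-1]
    rev = min(_rotations(rc))
    if fwd == rev:
        return fwd
    a, b = sorted((fwd, rev))
    return f"{a}/{b}"


def _validate_sequence(sequence: str) -> str:
    s = sequence.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"unsupported characters (only ACGTN allowed): {sorted(bad)}")
    return s


def find_perfect_ssrs(
    sequence: str, seq_id: str, config: SSRSearchConfig | None = None
) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the per-unit-length minima.

    Each qualifying tract is reported exactly once, at the smallest unit
    length with a primitive motif, with 1-based inclusive coordinates and
    whole repeat units only.  Loci are sorted by start position (ties by
    unit length).
    """
    config = config or SSRSearchConfig()
    s = _validate_sequence(sequence)
    loci: list[SSRLocus] = []
    for unit in range(1, 7):
        k = config.threshold(unit)
        pattern = re.compile(r"([ACGT]{%d})\1{%d,}" % (unit, k - 1))
        pos = 0
        while True:
            m = pattern.search(s, pos)
            if m is None:
                break
            motif = m.group(1)
            if is_primitive(motif):
                n_rep = (m.end() - m.start()) // unit
                loci.append(
                    SSRLocus(
                        seq_id=seq_id,
                        motif=motif,
                        n_repeats=n_rep,
                        start=m.start() + 1,
                        end=m.start() + n_rep * unit,
                    )
                )
                pos = m.start() + n_rep * unit
            else:
                # covered at a smaller unit length; skip a single base so a
                # shifted primitive tract overlapping here is still found
                pos = m.start() + 1
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def merge_compound(
    loci: Sequence[SSRLocus], config: SSRSearchConfig | None = None
) -> list[SSRLocus]:
    """Additionally report chains of nearby perfect loci as compound loci.

    Perfect loci separated by at most ``max_interruption_bp`` are chained
    (transitively) into one compound locus spanning the whole chain; the
    perfect members are retained in the output.
    """
    config = config or SSRSearchConfig()
    perfect = sorted((l for l in loci if not l.is_compound), key=lambda l: l.start)
    out: list[SSRLocus] = list(perfect)
    chain: list[SSRLocus] = []
    for loc in perfect:
        if chain and loc.start - chain[-1].end - 1 <= config.max_interruption_bp:
            chain.append(loc)
        else:
            if len(chain) > 1:
                out.append(_compound_from(chain))
            chain = [loc]
    if len(chain) > 1:
        out.append(_compound_from(chain))
    out.sort(key=lambda l: (l.start, -l.length_bp))
    return out


def _compound_from(chain: list[SSRLocus]) -> SSRLocus:
    return SSRLocus(
        seq_id=chain[0].seq_id,
        motif="+".join(l.motif for l in chain),
        n_repeats=sum(l.n_repeats for l in chain),
        start=chain[0].start,
        end=chain[-1].end,
        is_compound=True,
    )


@dataclass(frozen=True)
class RepeatClassSummary:
    """Mining-run summary: counts per unit length and canonical class."""

    counts_by_unit_length: dict[int, int]
    counts_by_canonical_class: dict[str, int]
    n_ssrs_total: int
    n_sequences_with_ssr: int
    n_sequences_with_multiple_ssr: int
    bp_scanned: int
    kb_per_ssr: float | None

    def class_table(self) -> pd.DataFrame:
        rows = sorted(
            self.counts_by_canonical_class.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return pd.DataFrame(rows, columns=["canonical_class", "count"])


def summarize_ssrs(
    all_loci: Iterable[SSRLocus], sequence_lengths: Mapping[str, int]
) -> RepeatClassSummary:
    """Distribution summary over a full mining run (perfect loci only).

    ``kb_per_ssr`` is total scanned bp per SSR in kb (one SSR per X kb);
    it is ``None`` when no SSRs were found rather than a division error.
    """
    perfect = [l for l in all_loci if not l.is_compound]
    by_unit = {u: 0 for u in range(1, 7)}
    by_class: dict[str, int] = {}
    per_seq: dict[str, int] = {}
    for loc in perfect:
        by_unit[loc.unit_length] += 1
        lab = loc.canonical_class
        by_class[lab] = by_class.get(lab, 0) + 1
        per_seq[loc.seq_id] = per_seq.get(loc.seq_id, 0) + 1
    n_total = len(perfect)
    bp = int(sum(sequence_lengths.values()))
    return RepeatClassSummary(
        counts_by_unit_length=by_unit,
        counts_by_canonical_class=by_class,
        n_ssrs_total=n_total,
        n_sequences_with_ssr=len(per_seq),
        n_sequences_with_multiple_ssr=sum(1 for v in per_seq.values() if v > 1),
        bp_scanned=bp,
        kb_per_ssr=(bp / n_total / 1000) if n_total else None,
    )


def extract_flanks(sequence: str, locus: SSRLocus, flank_bp: int) -> FlankRecord:
    """Extract the SSR tract with up to ``flank_bp`` of sequence on each side.

    Flanks are truncated at the sequence ends; truncation flags record when
    the full requested flank was not available.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    s = sequence.upper()
    if not (1 <= locus.start <= locus.end <= len(s)):
        raise ValueError(
            f"locus {locus.start}..{locus.end} outside sequence of length {len(s)}"
        )
    left_start = max(0, locus.start - 1 - flank_bp)
    right_end = min(len(s), locus.end + flank_bp)
    return FlankRecord(
        locus=locus,
        left_flank=s[left_start : locus.start - 1],
        ssr=s[locus.start - 1 : locus.end],
        right_flank=s[locus.end : right_end],
        left_truncated=locus.start - 1 < flank_bp,
        right_truncated=len(s) - locus.end < flank_bp,
    )


def mine_fasta(
    path, config: SSRSearchConfig | None = None, with_compound: bool = True
) -> tuple[list[SSRLocus], dict[str, int]]:
    """Run the miner over every record of a FASTA file.

    Returns the loci (perfect, plus compound when requested) and a map of
    sequence id to length for downstream summaries.
    """
    from Bio import SeqIO

    config = config or SSRSearchConfig()
    loci: list[SSRLocus] = []
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        lengths[rec.id] = len(seq)
        found = find_perfect_ssrs(seq, rec.id, config)
        if with_compound:
            found = merge_compound(found, config)
        loci.extend(found)
    return loci, lengths


def loci_to_misa_table(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """MISA-style table: ID, SSR nr., SSR type (p1..p6/c), SSR, size, start, end."""
    rows = []
    counter: dict[str, int] = {}
    for loc in sorted(loci, key=lambda l: (l.seq_id, l.start)):
        counter[loc.seq_id] = counter.get(loc.seq_id, 0) + 1
        if loc.is_compound:
            ssr_type = "c"
            ssr = "+".join(
                f"({m})" for m in loc.motif.split("+")
            )
        else:
            ssr_type = f"p{loc.unit_length}"
            ssr = f"({loc.motif}){loc.n_repeats}"
        rows.append(
            {
                "ID": loc.seq_id,
                "SSR nr.": counter[loc.seq_id],
                "SSR type": ssr_type,
                "SSR": ssr,
                "size": loc.length_bp,
                "start": loc.start,
                "end": loc.end,
            }
        )
    return pd.DataFrame(
        rows, columns=["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"]
    )
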