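"""Informativeness statistics for dominant (presence/absence) SSR markers.

A band matrix scores each accession x amplified fragment as 1 (band present)
or 0 (absent); fragments are grouped by the primer pair that amplified them.
Per fragment with presence frequency f:

    PIC_i = 2 f (1 - f)            polymorphic information content
    Ib    = 1 - 2 |0.5 - f|        fragment informativeness

and per primer pair:

    PIC  = mean of PIC_i over its fragments
    NPF  = number of polymorphic fragments (0 < f < 1)
    PP   = NPF / number of fragments          (proportion, 0..1)
    EMR  = PP x NPF                            effective multiplex ratio
    MI   = PIC x EMR                           marker index
    Rp   = sum of Ib over its fragments        resolving power

PP enters EMR as a proportion, not a percent.  Panel tables report
unweighted means of per-primer values within each group of primers; those
group means are not recomputable from one another's means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "PrimerReport",
    "fragment_frequency",
    "pic_fragment",
    "fragment_informativeness",
    "primer_pic",
    "polymorphism_counts",
    "marker_index",
    "resolving_power",
    "primer_report",
    "panel_report",
    "panel_summary",
]


@dataclass
class BandMatrix:
    """Binary accessions x fragments table with fragment->primer map and metadata.

    Parameters
    ----------
    values
        DataFrame indexed by accession, columns are fragment ids, entries
        strictly 0/1.
    primer_of_fragment
        Map from fragment id to primer id; every column must be mapped.
    accession_meta
        Optional DataFrame indexed by accession with columns such as
        ``origin`` (continent) and ``status`` (breeding status).
    """

    values: pd.DataFrame
    primer_of_fragment: dict[str, str]
    accession_meta: pd.DataFrame | None = None

    def __post_init__(self):
        v = self.values
        arr = v.to_numpy()
        if arr.size == 0:
            raise ValueError("band matrix is empty")
        if not np.isin(arr, [0, 1]).all():
            bad = np.argwhere(~np.isin(arr, [0, 1]))[0]
            raise ValueError(
                f"non-binary cell at accession {v.index[bad[0]]!r}, "
                f"fragment {v.columns[bad[1]]!r}: {arr[bad[0], bad[1]]!r}"
            )
        self.values = v.astype(np.int8)
        missing = [f for f in v.columns if f not in self.primer_of_fragment]
        if missing:
            raise ValueError(f"fragments without a primer mapping: {missing}")
        if self.accession_meta is not None:
            unknown = set(v.index) - set(self.accession_meta.index)
            if unknown:
                raise ValueError(f"accessions missing from metadata: {sorted(unknown)}")

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def fragments(self) -> list[str]:
        return list(self.values.columns)

    @property
    def primers(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fragments:
            seen.setdefault(self.primer_of_fragment[f], None)
        return list(seen)

    def fragments_of(self, primer: str) -> list[str]:
        frags = [f for f in self.fragments if self.primer_of_fragment[f] == primer]
        if not frags:
            raise KeyError(f"unknown primer {primer!r}")
        return frags

    def frequencies(self) -> pd.Series:
        """Band presence frequency per fragment."""
        return self.values.mean(axis=0)

    def subset_accessions(self, accessions: Sequence[str]) -> "BandMatrix":
        meta = (
            self.accession_meta.loc[list(accessions)]
            if self.accession_meta is not None
            else None
        )
        return BandMatrix(
            self.values.loc[list(accessions)], dict(self.primer_of_fragment), meta
        )

    # -- TSV dialect: first header row fragment ids, second row primer ids,
    #    then one row per accession of 0/1 values.
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\t" + "\t".join(self.fragments) + "\n")
            fh.write(
                "primer\t"
                + "\t".join(self.primer_of_fragment[f] for f in self.fragments)
                + "\n"
            )
            for acc in self.accessions:
                row = self.values.loc[acc]
                fh.write(acc + "\t" + "\t".join(str(int(x)) for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path, meta_path=None) -> "BandMatrix":
        lines = Path(path).read_text().splitlines()
        if len(lines) < 3:
            raise ValueError("band matrix TSV needs 2 header rows and >=1 accession")
        frag_header = lines[0].rstrip("\n").split("\t")
        primer_header = lines[1].rstrip("\n").split("\t")
        fragments = frag_header[1:]
        primers = primer_header[1:]
        if len(primers) != len(fragments):
            raise ValueError("fragment and primer header rows differ in length")
        rows, index = [], []
        for ln_no, line in enumerate(lines[2:], start=3):
            if not line.strip():
                continue
            parts = line.split("\t")
            index.append(parts[0])
            vals = []
            for col, tok in enumerate(parts[1:], start=1):
                if tok not in ("0", "1"):
                    raise ValueError(
                        f"non-binary cell at line {ln_no}, column "
                        f"{frag_header[col]!r}: {tok!r}"
                    )
                vals.append(int(tok))
            rows.append(vals)
        values = pd.DataFrame(rows, index=index, columns=fragments)
        meta = None
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(values, dict(zip(fragments, primers)), meta)


@dataclass(frozen=True)
class PrimerReport:
    """Per-primer informativeness summary."""

    primer: str
    n_fragments: int
    npf: int
    pp: float
    pic: float
    emr: float
    mi: float
    rp: float


def fragment_frequency(band_matrix: BandMatrix, fragment: str) -> float:
    if fragment not in band_matrix.values.columns:
        raise KeyError(f"unknown fragment {fragment!r}")
    return float(band_matrix.values[fragment].mean())


def pic_fragment(f: float) -> float:
    """PIC of one dominant fragment: 2 f (1 - f), in [0, 0.5]."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency must be in [0,1], got {f}")
    return 2.0 * f * (1.0 - f)


def fragment_informativeness(p: float) -> float:
    """Band informativeness Ib = 1 - 2|0.5 - p|, in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0,1], got {p}")
    return 1.0 - 2.0 * abs(0.5 - p)


def primer_pic(band_matrix: BandMatrix, primer: str) -> float:
    """Unweighted mean fragment PIC over the primer's fragments."""
    frags = band_matrix.fragments_of(primer)
    return float(
        np.mean([pic_fragment(fragment_frequency(band_matrix, f)) for f in frags])
    )


def polymorphism_counts(band_matrix: BandMatrix, primer: str) -> tuple[int, float]:
    """(NPF, PP): polymorphic fragment count and its proportion for a primer.

    A fragment is polymorphic iff its presence frequency is strictly between
    0 and 1.  Monomorphic fragments (including all-absent ones, which were
    still scored lanes) stay in the denominator.
    """
    frags = band_matrix.fragments_of(primer)
    freqs = [fragment_frequency(band_matrix, f) for f in frags]
    npf = sum(1 for f in freqs if 0.0 < f < 1.0)
    return npf, npf / len(frags)


def marker_index(band_matrix: BandMatrix, primer: str) -> tuple[float, float]:
    """(EMR, MI) for a primer; EMR = PP x NPF with PP as a proportion."""
    npf, pp = polymorphism_counts(band_matrix, primer)
    emr = pp * npf
    return emr, primer_pic(band_matrix, primer) * emr


def resolving_power(band_matrix: BandMatrix, primer: str) -> float:
    """Rp = sum of Ib over the primer's fragments."""
    frags = band_matrix.fragments_of(primer)
    return float(
        sum(fragment_informativeness(fragment_frequency(band_matrix, f)) for f in frags)
    )


def primer_report(band_matrix: BandMatrix, primer: str) -> PrimerReport:
    frags = band_matrix.fragments_of(primer)
    npf, pp = polymorphism_counts(band_matrix, primer)
    pic = primer_pic(band_matrix, primer)
    emr = pp * npf
    return PrimerReport(
        primer=primer,
        n_fragments=len(frags),
        npf=npf,
        pp=pp,
        pic=pic,
        emr=emr,
        mi=pic * emr,
        rp=resolving_power(band_matrix, primer),
    )


def panel_report(band_matrix: BandMatrix) -> pd.DataFrame:
    """One PrimerReport row per primer in the panel."""
    rows = [primer_report(band_matrix, p).__dict__ for p in band_matrix.primers]
    return pd.DataFrame(rows).set_index("primer")


def panel_summary(
    band_matrix: BandMatrix,
    primer_annotations: Mapping[str, str] | pd.Series,
    primers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group-level marker-parameter table (mean NP/ANF/APF/PP/PIC/Rp/MI).

    ``primer_annotations`` maps each primer to a group label (its SSR repeat
    type or repeat number).  Means are unweighted over primers within each
    group; a ``Total`` row averages over all primers.  Empty groups are
    simply absent (there is no primer to average).
    """
    ann = pd.Series(dict(primer_annotations))
    use = list(primers) if primers is not None else band_matrix.primers
    missing = [p for p in use if p not in ann.index]
    if missing:
        raise ValueError(f"primers without annotation: {missing}")
    per_primer = panel_report(band_matrix).loc[use]
    per_primer = per_primer.assign(group=ann.loc[use].to_numpy())

    def _agg(df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "NP": len(df),
                "ANF": df["n_fragments"].mean(),
                "APF": df["npf"].mean(),
                "PP_pct": 100.0 * df["pp"].mean(),
                "PIC": df["pic"].mean(),
                "Rp": df["rp"].mean(),
                "MI": df["mi"].mean(),
            }
        )

    groups = (
        per_primer.groupby("group", sort=True)
        .apply(_agg, include_groups=False)
        .astype({"NP": int})
    )
    total = _agg(per_primer).to_frame(name="Total").T.astype({"NP": int})
    out = pd.concat([groups, total])
    out.index.name = "group"
    return out
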