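"""Group-level genetic diversity indices for dominant markers.

Each fragment (locus) is treated as biallelic: a band(+) allele with
frequency p and a null allele with frequency q = 1 - p.  Because dominant
markers hide heterozygotes, p and q must be inferred from the band-presence
proportion P among accessions.  Two conventions are provided:

* ``dominant_hwe`` (default): assume Hardy-Weinberg, so the band-absent
  fraction is q^2 and q = sqrt(1 - P).  This is the standard treatment of
  dominant data in GenAlEx-style analyses.
* ``phenotypic``: take the band itself as the allele, p = P.  Useful when
  per-accession HWE is doubtful (e.g. bulked DNA from pooled plants).

Per-locus indices (natural log for Shannon's I):

    Na = number of alleles with frequency > 0 (1 or 2)
    Ne = 1 / (p^2 + q^2)
    I  = -sum over alleles with freq > 0 of freq * ln(freq)
    He = 2 p q

Group tables compute within-group band proportions per locus, then report
unweighted means of each index over loci; the overall row is the unweighted
mean over groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_stats import BandMatrix

__all__ = [
    "LocusAlleleFreqs",
    "GroupDiversity",
    "estimate_allele_freqs",
    "locus_indices",
    "group_diversity",
]

_MODELS = ("dominant_hwe", "phenotypic")


@dataclass(frozen=True)
class LocusAlleleFreqs:
    p: float  # band(+) allele
    q: float  # null allele
    model: str

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if not (0.0 <= self.p <= 1.0 and abs(self.p + self.q - 1.0) < 1e-12):
            raise ValueError("require p in [0,1] and p + q = 1")


@dataclass(frozen=True)
class GroupDiversity:
    group: str
    n_accessions: int
    na_mean: float
    ne_mean: float
    i_mean: float
    he_mean: float


def estimate_allele_freqs(P: float, model: str = "dominant_hwe") -> LocusAlleleFreqs:
    """Allele frequencies from the band-presence proportion P among accessions."""
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"band proportion must be in [0,1], got {P}")
    if model == "dominant_hwe":
        q = math.sqrt(1.0 - P)
        return LocusAlleleFreqs(p=1.0 - q, q=q, model=model)
    if model == "phenotypic":
        return LocusAlleleFreqs(p=P, q=1.0 - P, model=model)
    raise ValueError(f"model must be one of {_MODELS}")


def locus_indices(freqs: LocusAlleleFreqs) -> tuple[int, float, float, float]:
    """(Na, Ne, I, He) for one biallelic locus."""
    p, q = freqs.p, freqs.q
    na = int(p > 0.0) + int(q > 0.0)
    ne = 1.0 / (p * p + q * q)
    i = -sum(f * math.log(f) for f in (p, q) if f > 0.0)
    he = 2.0 * p * q
    return na, ne, i, he


def _indices_over_loci(values: pd.DataFrame, model: str) -> tuple[float, ...]:
    P = values.mean(axis=0).to_numpy()
    per_locus = np.array(
        [locus_indices(estimate_allele_freqs(float(x), model)) for x in P]
    )
    return tuple(per_locus.mean(axis=0))


def group_diversity(
    band_matrix: BandMatrix,
    grouping: str | pd.Series = "origin",
    model: str = "dominant_hwe",
) -> pd.DataFrame:
    """Diversity table with one row per group plus an unweighted Mean row.

    Parameters
    ----------
    band_matrix
        Scored panel; its ``accession_meta`` must carry the grouping column
        unless an explicit accession->group Series is given.
    grouping
        Metadata column name (e.g. ``"origin"`` or ``"status"``) or a Series
        mapping every accession to exactly one group.
    model
        Allele-frequency model, ``dominant_hwe`` or ``phenotypic``.
    """
    if isinstance(grouping, str):
        if band_matrix.accession_meta is None:
            raise ValueError("band matrix has no accession metadata")
        if grouping not in band_matrix.accession_meta.columns:
            raise KeyError(f"metadata has no column {grouping!r}")
        groups = band_matrix.accession_meta.loc[band_matrix.accessions, grouping]
    else:
        groups = grouping.loc[band_matrix.accessions]
    if groups.isna().any():
        raise ValueError("every accession must be assigned to exactly one group")

    rows = []
    for label, members in groups.groupby(groups).groups.items():
        accs = list(members)
        if len(accs) == 1:
            warnings.warn(f"group {label!r} has a single accession", stacklevel=2)
        na, ne, i, he = _indices_over_loci(band_matrix.values.loc[accs], model)
        rows.append(
            GroupDiversity(
                group=str(label),
                n_accessions=len(accs),
                na_mean=na,
                ne_mean=ne,
                i_mean=i,
                he_mean=he,
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows]).set_index("group")
    mean_row = table.mean(axis=0)
    mean_row["n_accessions"] = table["n_accessions"].sum()
    table.loc["Mean"] = mean_row
    table["n_accessions"] = table["n_accessions"].astype(int)
    return table.rename(
        columns={
            "n_accessions": "N",
            "na_mean": "Na",
            "ne_mean": "Ne",
            "i_mean": "I",
            "he_mean": "He",
        }
    )
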