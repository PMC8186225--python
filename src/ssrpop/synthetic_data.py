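"""Ground-truth generators for transcriptomes, band matrices and trait tables.

Three layers mirror the data an EST-SSR diversity study consumes:

1. **Transcriptome** — random-background transcripts (configurable GC and
   length range) with perfect SSR tracts planted at a chosen density.  The
   bases flanking each planted tract are chosen to break the repeat, so a
   miner reports exactly the planted coordinates; the truth table records
   every plant.
2. **Band matrix** — K divergent subpopulations under a dominant-marker
   Hardy-Weinberg model.  Per fragment an ancestral band-allele frequency
   p0 is drawn, then each group's frequency from the Balding–Nichols
   distribution Beta(p0 (1-θ)/θ, (1-p0)(1-θ)/θ), so a single θ in (0,1)
   controls divergence (θ -> 0: panmixia; larger θ: stronger structure).
   An accession shows the band with probability 1 - q_g^2, the same
   inverse mapping the diversity module assumes, making parameter recovery
   a closed loop.  Optional admixture mixes group frequencies per accession.
3. **Phenotypes** — each trait is w x (standardized linear score of a
   random subset of band columns) + (1-w) x Gaussian noise, so the genetic
   weight w in [0,1] tunes the expected Mantel correlation from ~0 (pure
   noise) upward.

All generators are seed-deterministic and emit machine-readable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marker_stats import BandMatrix

__all__ = [
    "SimTranscriptomeSpec",
    "SimPopulationSpec",
    "SimPhenotypeSpec",
    "simulate_transcriptome",
    "simulate_band_matrix",
    "simulate_phenotypes",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# tri-class weighting loosely follows grass transcriptomes, where C/G-rich
# tri-repeats dominate coding sequence
_DEFAULT_MOTIF_WEIGHTS = {
    "A": 0.20,
    "AG": 0.10,
    "AC": 0.05,
    "CCG": 0.25,
    "AGG": 0.15,
    "AGC": 0.10,
    "AAG": 0.05,
    "AAAG": 0.04,
    "ATCC": 0.03,
    "AAAAG": 0.02,
    "ACGTAG": 0.01,
}


@dataclass(frozen=True)
class SimTranscriptomeSpec:
    """Transcript collection with planted SSRs at a given density."""

    n_sequences: int = 200
    min_length: int = 300
    max_length: int = 3000
    gc: float = 0.5
    ssr_per_kb: float = 1.0 / 7.8  # about one SSR per 7.8 kb of transcript
    motif_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MOTIF_WEIGHTS)
    )
    min_repeats: dict[int, int] = field(
        default_factory=lambda: {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )
    max_extra_repeats: int = 6
    seed: int | None = None


@dataclass(frozen=True)
class SimPopulationSpec:
    """K divergent groups scored on a dominant-marker panel."""

    n_groups: int = 3
    accessions_per_group: int = 8
    n_primers: int = 52
    mean_fragments_per_primer: float = 3.0
    theta: float = 0.2
    ancestral_beta: tuple[float, float] = (1.0, 1.0)
    admixture: float = 0.0  # 0 = pure ancestry, else Dirichlet mixing weight
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be strictly in (0,1)")
        if self.n_groups < 1:
            raise ValueError("need at least one group")


@dataclass(frozen=True)
class SimPhenotypeSpec:
    """Trait table whose genetic component (and hence Mantel r) is tunable."""

    n_traits: int = 11
    genetic_weight: float = 0.5
    noise_sd: float = 1.0
    loci_per_trait: int = 20
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.genetic_weight <= 1.0:
            raise ValueError("genetic_weight must be in [0,1]")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def simulate_transcriptome(
    spec: SimTranscriptomeSpec,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate sequences and the exact truth table of planted SSR tracts.

    Returns ``(sequences, truth)`` where truth has columns seq_id, motif,
    n_repeats, start, end (1-based inclusive).
    """
    rng = np.random.default_rng(spec.seed)
    motifs = list(spec.motif_weights)
    weights = np.array([spec.motif_weights[m] for m in motifs], dtype=float)
    weights = weights / weights.sum()
    max_tract = max(
        len(m) * (spec.min_repeats[len(m)] + spec.max_extra_repeats) for m in motifs
    )
    # each plant consumes at most the tract plus its random spacing
    if spec.ssr_per_kb * (max_tract + 70) > 1000.0:
        raise ValueError(
            f"plant density infeasible: {spec.ssr_per_kb:.3g} SSR/kb with tracts "
            f"up to {max_tract} bp cannot fit"
        )
    seqs: dict[str, str] = {}
    truth_rows = []
    for i in range(spec.n_sequences):
        seq_id = f"unigene_{i + 1:05d}"
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        arr = _random_background(rng, length, spec.gc)
        n_plants = rng.poisson(spec.ssr_per_kb * length / 1000.0)
        cursor = 10  # keep a margin from the ends
        planted = 0
        for _ in range(n_plants):
            motif = motifs[rng.choice(len(motifs), p=weights)]
            k = len(motif)
            n_rep = spec.min_repeats[k] + int(rng.integers(0, spec.max_extra_repeats + 1))
            tract = motif * n_rep
            start0 = cursor + int(rng.integers(5, 60))  # 0-based insert position
            if start0 + len(tract) + 10 > length:
                break  # sequence saturated; truth stays exact
            arr[start0 : start0 + len(tract)] = list(tract)
            # break the repeat on both sides so the tract is exactly maximal
            arr[start0 - 1] = _breaking_base(rng, (motif[-1], tract[0]))
            arr[start0 + len(tract)] = _breaking_base(rng, (motif[0], tract[-1]))
            truth_rows.append(
                {
                    "seq_id": seq_id,
                    "motif": motif,
                    "n_repeats": n_rep,
                    "start": start0 + 1,
                    "end": start0 + len(tract),
                }
            )
            cursor = start0 + len(tract) + 1
            planted += 1
        seqs[seq_id] = "".join(arr)
    truth = pd.DataFrame(
        truth_rows, columns=["seq_id", "motif", "n_repeats", "start", "end"]
    )
    return seqs, truth


def _breaking_base(rng: np.random.Generator, avoid: tuple[str, ...]) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_band_matrix(
    spec: SimPopulationSpec,
) -> tuple[BandMatrix, dict]:
    """Dominant band matrix from K Balding–Nichols-divergent groups.

    Returns ``(band_matrix, truth)``; truth carries the per-group band-allele
    frequencies (loci x groups), group assignments and admixture proportions.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_groups
    n_acc = K * spec.accessions_per_group
    frag_per_primer = np.maximum(
        1, rng.poisson(spec.mean_fragments_per_primer, size=spec.n_primers)
    )
    fragments, primer_of_fragment = [], {}
    for p in range(spec.n_primers):
        primer = f"ESP-{p + 1:03d}"
        for b in range(frag_per_primer[p]):
            frag = f"{primer}_b{b + 1}"
            fragments.append(frag)
            primer_of_fragment[frag] = primer
    n_frag = len(fragments)

    a0, b0 = spec.ancestral_beta
    p0 = rng.beta(a0, b0, size=n_frag)
    p0 = np.clip(p0, 0.02, 0.98)  # keep loci informative
    th = spec.theta
    group_p = np.empty((n_frag, K))
    for g in range(K):
        group_p[:, g] = rng.beta(p0 * (1 - th) / th, (1 - p0) * (1 - th) / th)

    groups = np.repeat(np.arange(K), spec.accessions_per_group)
    if spec.admixture > 0:
        alpha = np.full(K, spec.admixture)
        Q = np.stack(
            [rng.dirichlet(alpha + (np.arange(K) == g) * 1.0) for g in groups]
        )
    else:
        Q = np.eye(K)[groups]
    # accession-level band-allele frequency, then dominant HWE presence prob
    acc_p = Q @ group_p.T  # (n_acc, n_frag)
    q = 1.0 - acc_p
    band_prob = 1.0 - q**2
    X = (rng.random((n_acc, n_frag)) < band_prob).astype(np.int8)

    accessions = [f"ACC_{g + 1}_{i + 1:03d}" for g, i in zip(
        groups, np.concatenate([np.arange(spec.accessions_per_group)] * K)
    )]
    continents = ["South America", "Asia", "Europe", "North America"]
    statuses = ["Wild material", "Cultivar", "Uncertain"]
    meta = pd.DataFrame(
        {
            "origin": [continents[g % len(continents)] for g in groups],
            "status": [statuses[g % len(statuses)] for g in groups],
            "group": [f"G{g + 1}" for g in groups],
        },
        index=accessions,
    )
    values = pd.DataFrame(X, index=accessions, columns=fragments)
    truth = {
        "group_p": pd.DataFrame(
            group_p, index=fragments, columns=[f"G{g + 1}" for g in range(K)]
        ),
        "groups": pd.Series([f"G{g + 1}" for g in groups], index=accessions),
        "admixture": pd.DataFrame(
            Q, index=accessions, columns=[f"G{g + 1}" for g in range(K)]
        ),
        "ancestral_p": pd.Series(p0, index=fragments),
    }
    return BandMatrix(values, primer_of_fragment, meta), truth


def simulate_phenotypes(
    band_matrix: BandMatrix, spec: SimPhenotypeSpec
) -> tuple[pd.DataFrame, dict]:
    """Trait table with a controllable genetic component.

    Each trait is ``w * standardized genetic score + (1 - w) * noise`` with
    the genetic score a random +/-1-weighted sum over a random subset of
    band columns.  Returns ``(traits, truth)`` with the chosen loci and
    weights per trait.
    """
    rng = np.random.default_rng(spec.seed)
    X = band_matrix.values.to_numpy(dtype=float)
    n_acc, n_frag = X.shape
    w = spec.genetic_weight
    names = [f"T{j + 1:02d}" for j in range(spec.n_traits)]
    cols, chosen = {}, {}
    for name in names:
        k = min(spec.loci_per_trait, n_frag)
        loci = rng.choice(n_frag, size=k, replace=False)
        beta = rng.choice([-1.0, 1.0], size=k)
        score = X[:, loci] @ beta
        sd = score.std()
        score = (score - score.mean()) / sd if sd > 0 else np.zeros(n_acc)
        noise = rng.normal(0.0, spec.noise_sd, size=n_acc)
        cols[name] = w * score + (1.0 - w) * noise
        chosen[name] = {"loci": [band_matrix.fragments[i] for i in loci],
                        "weights": beta.tolist()}
    traits = pd.DataFrame(cols, index=band_matrix.accessions)
    return traits, {"per_trait": chosen, "genetic_weight": w}
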