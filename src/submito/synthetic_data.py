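"""Synthetic fixtures: motif-planted proteomes, profiles, votes, GO worlds.

Every stage of the toolkit can be exercised without downloading anything:

* :func:`generate_proteome` plants one compartment-specific sequence
  motif per class into uniform-random background sequences — a signal the
  19-wide convolution filters can straddle, making the generated data a
  direct probe of the convolutional layer.
* :func:`generate_pssm` emulates the shape of an iterative-profile-search
  PSSM: a strong positive log-odds score on the observed residue and
  noisy negative scores elsewhere.
* :func:`generate_go_world` builds sequence families by point-mutating
  founders (so identity/coverage clustering recovers them) and plants one
  over-represented GO term per family against a decoy background.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn_model import CompartmentLabel
from .io_formats import GOAnnotation, PSSM_ALPHABET, ProteinRecord, PSSMProfile, ToolVoteTable

AA = PSSM_ALPHABET  # 20 standard residues

#: one 11-mer consensus motif per compartment, pairwise distinct
DEFAULT_MOTIFS: dict[CompartmentLabel, str] = {
    CompartmentLabel.outer_membrane: "WFYWRKWFYWR",
    CompartmentLabel.inner_membrane: "LILVMLILVML",
    CompartmentLabel.intermembrane_space: "CPCGHCPCGHC",
    CompartmentLabel.matrix: "DENQSDENQSD",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic labelled proteome."""

    n_per_class: int = 60
    length_range: tuple[int, int] = (60, 120)
    motifs: dict[CompartmentLabel, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS)
    )
    substitution_rate: float = 0.1
    pssm_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.length_range
        longest = max(len(m) for m in self.motifs.values())
        if lo > hi or lo < longest:
            raise ValueError(
                f"length range {self.length_range} must be ordered and >= the "
                f"longest motif ({longest})"
            )
        if len(set(self.motifs.values())) != len(self.motifs):
            raise ValueError("motifs must be pairwise distinct")
        if not all(8 <= len(m) <= 15 for m in self.motifs.values()):
            raise ValueError("motifs must be 8-15 residues")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution rate must be in [0, 1]")
        if self.pssm_noise < 0:
            raise ValueError("pssm_noise must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AA[rng.integers(20)]
    return "".join(out)


def generate_proteome(
    spec: SyntheticSpec,
) -> list[tuple[ProteinRecord, CompartmentLabel]]:
    """Labelled proteome: uniform background with the class motif embedded.

    Each sequence gets its compartment's consensus motif, point-mutated at
    ``substitution_rate``, at a uniformly random position.  Class counts
    are exact and output order is by class then index.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    out = []
    for label in CompartmentLabel:
        motif = spec.motifs[label]
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = list(_random_sequence(rng, length))
            planted = _mutate(rng, motif, spec.substitution_rate)
            start = int(rng.integers(0, length - len(motif) + 1))
            seq[start : start + len(motif)] = planted
            rec = ProteinRecord(id=f"{label.name}_{i:04d}", sequence="".join(seq))
            out.append((rec, label))
    return out


def generate_pssm(record: ProteinRecord, noise: float = 1.0, seed: int = 0) -> PSSMProfile:
    """A profile consistent with its sequence: +7 log-odds on the observed
    residue, Gaussian-perturbed negatives (mean -2) elsewhere, integer-rounded."""
    rng = np.random.default_rng(seed)
    L = len(record)
    matrix = np.rint(rng.normal(-2.0, noise, size=(L, 20))).astype(np.int64)
    col_index = {aa: j for j, aa in enumerate(AA)}
    for i, aa in enumerate(record.sequence):
        j = col_index.get(aa)
        if j is not None:
            matrix[i, j] = 7
    return PSSMProfile(protein_id=record.id, matrix=matrix)


def generate_profiles(
    records: list[ProteinRecord], noise: float = 1.0, seed: int = 0
) -> dict[str, PSSMProfile]:
    """One profile per record, each with a distinct seed derived from ``seed``."""
    return {
        rec.id: generate_pssm(rec, noise=noise, seed=seed + i)
        for i, rec in enumerate(records)
    }


def generate_votes(
    records: list[ProteinRecord],
    mito_fraction: float = 0.3,
    flip_rate: float = 0.1,
    seed: int = 0,
) -> ToolVoteTable:
    """Three-tool vote table: a latent mitochondrial status per protein with
    per-tool flip noise."""
    rng = np.random.default_rng(seed)
    table = ToolVoteTable()
    for rec in records:
        truth = rng.random() < mito_fraction
        for tool in table.tools:
            vote = (not truth) if rng.random() < flip_rate else truth
            table.add(rec.id, tool, bool(vote))
    return table


def generate_go_world(
    n_clusters: int = 3,
    cluster_size: int = 8,
    background_size: int = 200,
    inside_freq: float = 0.9,
    outside_freq: float = 0.05,
    n_decoy_terms: int = 10,
    decoy_freq: float = 0.2,
    founder_length: int = 120,
    mutation_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[ProteinRecord], list[GOAnnotation], dict[str, str]]:
    """A GO world with planted enrichment.

    Returns (records, annotations, truth) where truth maps each planted
    term to the id prefix of its family.  Family members are point
    mutants of a founder so identity/coverage clustering recovers the
    families; each family's planted term is annotated at ``inside_freq``
    within the family and ``outside_freq`` elsewhere, and decoy terms are
    spread uniformly at ``decoy_freq``.
    """
    if not (0.0 <= outside_freq < inside_freq <= 1.0):
        raise ValueError("need 0 <= outside_freq < inside_freq <= 1")
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    annotations: list[GOAnnotation] = []
    truth: dict[str, str] = {}

    family_members: list[list[str]] = []
    for c in range(n_clusters):
        founder = _random_sequence(rng, founder_length)
        members = []
        for i in range(cluster_size):
            seq = _mutate(rng, founder, mutation_rate)
            pid = f"fam{c}_{i:03d}"
            records.append(ProteinRecord(id=pid, sequence=seq))
            members.append(pid)
        family_members.append(members)
    background_ids = []
    for i in range(background_size):
        pid = f"bg_{i:04d}"
        records.append(ProteinRecord(id=pid, sequence=_random_sequence(rng, founder_length)))
        background_ids.append(pid)

    all_ids = [r.id for r in records]
    planted_terms = [f"GO:{1000000 + c:07d}" for c in range(n_clusters)]
    decoy_terms = [f"GO:{2000000 + d:07d}" for d in range(n_decoy_terms)]

    for c, term in enumerate(planted_terms):
        truth[term] = f"fam{c}"
        inside = set(family_members[c])
        for pid in all_ids:
            freq = inside_freq if pid in inside else outside_freq
            if rng.random() < freq:
                annotations.append(
                    GOAnnotation(pid, term, "BP", "EXP", "GOA_manual")
                )
    for term in decoy_terms:
        for pid in all_ids:
            if rng.random() < decoy_freq:
                annotations.append(
                    GOAnnotation(pid, term, "MF", "IEA", "GOA_IEA")
                )
    return records, annotations, truth
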