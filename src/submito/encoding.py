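"""Input encoding: map a protein and its profile to an Lx30 feature matrix.

Each residue contributes 30 channels: the 20 position-specific log-odds
scores squashed into (0, 1) by the logistic function, followed by the 10
Kidera physico-chemical factors for the residue letter.  Non-standard
letters (X, B, Z, U, O) get the all-zero Kidera vector; their profile row
is used as parsed.

The channel layout is fixed (profile first, Kidera second) and recorded
in the encoded bundle so that models and encoders can be checked for
compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from ._kidera import KIDERA_FACTORS, NONSTANDARD_RESIDUES
from .io_formats import ProteinRecord, PSSMProfile

CHANNEL_LAYOUT = "pssm_logistic[0:20]+kidera[20:30]"
N_CHANNELS = 30

_ZERO10 = np.zeros(10)


@dataclass(frozen=True)
class EncodedProtein:
    """L x 30 real matrix consumed by the convolutional network."""

    protein_id: str
    matrix: np.ndarray  # (L, 30) float64

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[1] != N_CHANNELS:
            raise ValueError(
                f"{self.protein_id}: encoded matrix must be Lx{N_CHANNELS}, got {m.shape}"
            )
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]


def kidera_vector(aa: str) -> np.ndarray:
    """The 10 Kidera factors for one residue letter.

    Standard residues map to their published factor row; tolerated
    non-standard letters map to the neutral all-zero vector.
    """
    if not (isinstance(aa, str) and len(aa) == 1 and aa.isalpha()):
        raise ValueError(f"expected a single amino-acid letter, got {aa!r}")
    aa = aa.upper()
    if aa in KIDERA_FACTORS:
        return np.array(KIDERA_FACTORS[aa])
    if aa in NONSTANDARD_RESIDUES:
        return _ZERO10.copy()
    raise ValueError(f"unknown amino-acid letter {aa!r}")


def scale_pssm(profile: PSSMProfile) -> np.ndarray:
    """Squash integer log-odds elementwise with the logistic 1/(1+e^-x).

    Strictly monotone, bounded in the open interval (0, 1); zero maps to
    exactly 0.5.
    """
    x = profile.matrix.astype(np.float64)
    return 1.0 / (1.0 + np.exp(-x))


def encode_protein(
    record: ProteinRecord,
    profile: PSSMProfile,
    squash: Callable[[PSSMProfile], np.ndarray] = scale_pssm,
) -> EncodedProtein:
    """Assemble the Lx30 input matrix: scaled profile then Kidera channels."""
    if len(profile) != len(record):
        raise ValueError(
            f"{record.id}: profile has {len(profile)} rows but sequence length "
            f"is {len(record)}"
        )
    pssm_block = squash(profile)
    kidera_block = np.stack([kidera_vector(aa) for aa in record.sequence])
    return EncodedProtein(
        protein_id=record.id,
        matrix=np.hstack([pssm_block, kidera_block]),
    )


def encode_dataset(
    records: Sequence[ProteinRecord], profiles: dict[str, PSSMProfile]
) -> list[EncodedProtein]:
    """Encode every record, pairing each with its profile by protein id."""
    out = []
    for rec in records:
        if rec.id not in profiles:
            raise KeyError(f"no profile for protein {rec.id!r}")
        out.append(encode_protein(rec, profiles[rec.id]))
    return out


def save_encoded(path: str | Path, encoded: Iterable[EncodedProtein]) -> None:
    """Write an NPZ tensor bundle with an index manifest and channel metadata."""
    encoded = list(encoded)
    arrays = {f"x_{i}": e.matrix for i, e in enumerate(encoded)}
    arrays["index"] = np.array([e.protein_id for e in encoded])
    arrays["channel_layout"] = np.array(CHANNEL_LAYOUT)
    np.savez_compressed(path, **arrays)


def load_encoded(path: str | Path) -> list[EncodedProtein]:
    with np.load(path, allow_pickle=False) as bundle:
        layout = str(bundle["channel_layout"])
        if layout != CHANNEL_LAYOUT:
            raise ValueError(
                f"incompatible channel layout {layout!r}; expected {CHANNEL_LAYOUT!r}"
            )
        ids = [str(s) for s in bundle["index"]]
        return [
            EncodedProtein(protein_id=pid, matrix=bundle[f"x_{i}"])
            for i, pid in enumerate(ids)
        ]
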