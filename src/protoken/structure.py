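"""Backbone structure container.

A protein backbone is represented by the four heavy atoms N, CA, C, O of each
residue.  This is the sole input of the structure encoder and the output of the
token decoder; side chains are never represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Atom order of the per-residue coordinate block.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: One-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for an unknown residue identity.
UNKNOWN_AA = "X"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: CA-CA distance above which two consecutive residues are treated as a chain
#: break (dihedrals spanning the gap are flagged invalid, never an error).
CHAIN_BREAK_CA_DISTANCE = 4.5


class ProtokenError(Exception):
    """Base class for all package errors."""


class ValidationError(ProtokenError, ValueError):
    """Invalid user input (shapes, token bounds, alphabets, masks)."""


class DegenerateGeometryError(ProtokenError, ValueError):
    """Geometry that admits no residue frame (e.g. collinear N/CA/C)."""


class FormatError(ProtokenError, ValueError):
    """Unparseable or out-of-contract file content."""


class CapacityError(ProtokenError, ValueError):
    """Input exceeds a configured model capacity (e.g. maximum length)."""


@dataclass
class BackboneStructure:
    """Per-residue N/CA/C/O coordinates of a single protein chain.

    Parameters
    ----------
    coords
        Array of shape ``(n_res, 4, 3)`` holding Angstrom positions in the
        atom order :data:`BACKBONE_ATOMS`.
    residue_names
        Optional one-letter amino-acid symbols per residue (``"X"`` for
        unknown).  ``None`` means the chain carries no sequence annotation.
    chain_id
        Label carried through I/O; has no geometric meaning.
    """

    coords: np.ndarray
    residue_names: list[str] | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValidationError(
                f"coords must have shape (n_res, 4, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 2:
            raise ValidationError("a backbone needs at least 2 residues")
        if not np.isfinite(self.coords).all():
            raise ValidationError("coords contain non-finite values")
        if self.residue_names is not None:
            self.residue_names = [str(r).upper() for r in self.residue_names]
            if len(self.residue_names) != self.n_res:
                raise ValidationError(
                    f"residue_names length {len(self.residue_names)} != n_res {self.n_res}"
                )
            bad = sorted(
                {r for r in self.residue_names if r not in AMINO_ACIDS and r != UNKNOWN_AA}
            )
            if bad:
                raise ValidationError(f"unknown residue symbols: {bad}")

    @property
    def n_res(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0] * 4

    @property
    def ca(self) -> np.ndarray:
        """CA coordinates, shape ``(n_res, 3)``."""
        return self.coords[:, 1, :]

    @property
    def sequence(self) -> str | None:
        if self.residue_names is None:
            return None
        return "".join(self.residue_names)

    def atom(self, name: str) -> np.ndarray:
        return self.coords[:, BACKBONE_ATOMS.index(name), :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        """Return a copy moved by the rigid motion ``x -> R x + t``."""
        rotation = np.asarray(rotation, dtype=np.float64)
        translation = np.asarray(translation, dtype=np.float64)
        new = self.coords @ rotation.T + translation
        return BackboneStructure(new, residue_names=self.residue_names, chain_id=self.chain_id)

    def chain_break_mask(self) -> np.ndarray:
        """Boolean array of length ``n_res - 1``; True where a break follows residue i."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        return d > CHAIN_BREAK_CA_DISTANCE

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(
            self.coords.copy(),
            residue_names=None if self.residue_names is None else list(self.residue_names),
            chain_id=self.chain_id,
        )


def require_same_length(a: BackboneStructure, b: BackboneStructure) -> int:
    if a.n_res != b.n_res:
        raise ValidationError(f"length mismatch: {a.n_res} vs {b.n_res}")
    return a.n_res


def sequence_to_names(sequence: str) -> list[str]:
    """Validate and split a one-letter sequence string."""
    seq = sequence.upper()
    for pos, letter in enumerate(seq):
        if letter not in AMINO_ACIDS and letter != UNKNOWN_AA:
            raise ValidationError(f"unknown amino-acid letter {letter!r} at position {pos}")
    return list(seq)
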