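"""Molecule parsing, identity keys and structure encodings.

Retention data is keyed by *compound*, not by stereoisomer: optical and
cis/trans isomers elute (to the accuracy relevant here) at the same retention
index, so the package collapses stereochemistry and isotope labels into a
single ``compound_key`` used for train/test hygiene throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the input."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"could not parse SMILES: {smiles!r}")


class EncodingError(ValueError):
    """Raised when a molecule cannot be encoded for the convolutional model."""


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule with canonical form and stereo-collapsed identity.

    ``compound_key`` is the canonical SMILES after removing stereo layers and
    isotope labels; it is identical for optical and cis/trans isomers and for
    isotopomers of the same constitution.
    """

    mol: Chem.Mol
    canonical_smiles: str
    compound_key: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Molecule({self.canonical_smiles!r})"


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Raises
    ------
    MoleculeParseError
        If RDKit cannot parse the string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(smiles)
    canonical = Chem.MolToSmiles(mol)
    return Molecule(mol=mol, canonical_smiles=canonical, compound_key=_compound_key(mol))


def _compound_key(mol: Chem.Mol) -> str:
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    for atom in flat.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(flat)


def is_n_alkane(molecule: Molecule) -> bool:
    """True iff the molecule is an unbranched acyclic saturated hydrocarbon."""
    mol = molecule.mol
    if mol.GetNumAtoms() == 0:
        return False
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            return False
        if atom.GetDegree() > 2:
            return False
    if mol.GetRingInfo().NumRings() > 0:
        return False
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            return False
    return True


# Character alphabet for the structure one-hot grid.  Covers organic-subset
# SMILES over the admission whitelist {C,H,O,N,S,P,F,Cl,Br,I,Si} plus ring
# closure digits, branches, bonds, charges and bracket atoms.
SMILES_ALPHABET: tuple[str, ...] = tuple(
    "#%()+-./0123456789=@BCFHINOPS[\\]cilnoprs"
)
_CHAR_INDEX = {ch: i for i, ch in enumerate(SMILES_ALPHABET)}

DEFAULT_L_MAX = 150


@dataclass(frozen=True)
class StructureTensor:
    """Character-level one-hot grid of a canonical SMILES.

    ``grid`` has shape ``(L_max, len(alphabet))``; occupied columns sum to 1
    and padding columns are all zero.
    """

    grid: np.ndarray
    length: int

    @property
    def l_max(self) -> int:
        return self.grid.shape[0]


def cnn_encode(molecule: Molecule, l_max: int = DEFAULT_L_MAX) -> StructureTensor:
    """One-hot encode the canonical SMILES for the convolutional model.

    Molecules whose canonical SMILES exceeds ``l_max`` characters are rejected
    (they must be filtered upstream by admission rules).
    """
    smiles = molecule.canonical_smiles
    if len(smiles) > l_max:
        raise EncodingError(
            f"SMILES length {len(smiles)} exceeds maximum {l_max}: {smiles!r}"
        )
    grid = np.zeros((l_max, len(SMILES_ALPHABET)), dtype=np.float32)
    for pos, ch in enumerate(smiles):
        try:
            grid[pos, _CHAR_INDEX[ch]] = 1.0
        except KeyError:
            raise EncodingError(f"character {ch!r} not in SMILES alphabet") from None
    return StructureTensor(grid=grid, length=len(smiles))


def cnn_decode(tensor: StructureTensor) -> str:
    """Inverse of :func:`cnn_encode` (used as a round-trip check)."""
    chars = []
    for col in tensor.grid:
        if col.sum() == 0:
            break
        chars.append(SMILES_ALPHABET[int(np.argmax(col))])
    return "".join(chars)
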