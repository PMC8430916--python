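"""Molecular descriptor and functional-group featurization.

The feature surface is a fixed 327-long vector per molecule: 243 general
molecular descriptors (a versioned manifest over RDKit's descriptor set plus
2D autocorrelation components) followed by 84 functional-group counters
(RDKit fragment SMARTS counts).  Per-descriptor affine scaling factors are a
frozen artifact shipped with the package — they are *not* refit per dataset,
so feature vectors are comparable across trainings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from rdkit.Chem import Descriptors, rdMolDescriptors

from .chem import Molecule

log = logging.getLogger(__name__)

N_GENERAL = 243
N_FRAGMENT = 84
N_TOTAL = N_GENERAL + N_FRAGMENT  # 327

_RDKIT_FUNCS = {name: fn for name, fn in Descriptors.descList if not name.startswith("fr_")}
_FRAGMENT_FUNCS = {name: fn for name, fn in Descriptors.descList if name.startswith("fr_")}


def _read_packaged_csv(name: str) -> pd.DataFrame:
    ref = resources.files("gcri.assets").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class DescriptorManifest:
    """Versioned name->provider map defining the descriptor vector layout."""

    general: tuple[tuple[str, str], ...]  # (name, provider)
    fragments: tuple[str, ...]
    version: int = 1

    def __post_init__(self):
        if len(self.general) != N_GENERAL:
            raise ValueError(f"manifest must list {N_GENERAL} general descriptors")
        if len(self.fragments) != N_FRAGMENT:
            raise ValueError(f"manifest must list {N_FRAGMENT} fragment counters")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.general) + self.fragments


def load_manifest() -> DescriptorManifest:
    gen = _read_packaged_csv("descriptor_manifest.csv")
    frag = _read_packaged_csv("fragment_counters.csv")
    return DescriptorManifest(
        general=tuple(zip(gen["name"], gen["provider"])),
        fragments=tuple(frag["name"]),
    )


def load_scaling() -> pd.DataFrame:
    """Frozen per-descriptor affine factors (columns: name, offset, scale)."""
    return _read_packaged_csv("descriptor_scaling.csv")


class Featurizer:
    """Computes raw and scaled descriptor vectors with per-compound caching.

    Scaling is ``(raw - offset) / scale`` with the shipped factors.  A
    descriptor that evaluates non-finite for a molecule is imputed with its
    offset (scaled value 0) and the event is logged.
    """

    def __init__(self, manifest: DescriptorManifest | None = None,
                 scaling: pd.DataFrame | None = None):
        self.manifest = manifest or load_manifest()
        scaling = scaling if scaling is not None else load_scaling()
        by_name = scaling.set_index("name")
        names = self.manifest.names
        self.offset = by_name.loc[list(names), "offset"].to_numpy(dtype=np.float64)
        self.scale = by_name.loc[list(names), "scale"].to_numpy(dtype=np.float64)
        if np.any(self.scale == 0) or not np.all(np.isfinite(self.scale)):
            raise ValueError("scaling factors must be finite and nonzero")
        self._cache: dict[str, np.ndarray] = {}

    def raw_vector(self, molecule: Molecule) -> np.ndarray:
        """Unscaled length-327 vector: 243 general descriptors + 84 counters."""
        mol = molecule.mol
        autocorr = None
        values = np.empty(N_TOTAL, dtype=np.float64)
        for i, (name, provider) in enumerate(self.manifest.general):
            if provider.startswith("autocorr2d:"):
                if autocorr is None:
                    autocorr = rdMolDescriptors.CalcAUTOCORR2D(mol)
                values[i] = autocorr[int(provider.split(":", 1)[1])]
            else:
                try:
                    values[i] = _RDKIT_FUNCS[name](mol)
                except Exception:
                    values[i] = np.nan
        values[N_GENERAL:] = self.functional_group_counts(molecule)
        return values

    def functional_group_counts(self, molecule: Molecule) -> np.ndarray:
        """The 84 functional-group counters (non-negative integers)."""
        out = np.empty(N_FRAGMENT, dtype=np.int64)
        for i, name in enumerate(self.manifest.fragments):
            out[i] = _FRAGMENT_FUNCS[name](molecule.mol)
        return out

    def vector(self, molecule: Molecule) -> np.ndarray:
        """Scaled length-327 descriptor vector (cached by compound key)."""
        key = molecule.compound_key
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        raw = self.raw_vector(molecule)
        bad = ~np.isfinite(raw)
        if bad.any():
            log.debug("imputed %d non-finite descriptors for %s",
                      int(bad.sum()), molecule.canonical_smiles)
            raw[bad] = self.offset[bad]
        scaled = ((raw - self.offset) / self.scale).astype(np.float32)
        self._cache[key] = scaled
        return scaled

    def matrix(self, molecules: list[Molecule]) -> np.ndarray:
        """Scaled vectors stacked to shape ``(n, 327)``."""
        return np.stack([self.vector(m) for m in molecules])


_DEFAULT: Featurizer | None = None


def default_featurizer() -> Featurizer:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Featurizer()
    return _DEFAULT


def descriptor_vector(molecule: Molecule, featurizer: Featurizer | None = None) -> np.ndarray:
    """Scaled length-327 descriptor vector for an admitted molecule."""
    return (featurizer or default_featurizer()).vector(molecule)


def functional_group_counts(molecule: Molecule,
                            featurizer: Featurizer | None = None) -> np.ndarray:
    """The 84 functional-group counters for a molecule."""
    return (featurizer or default_featurizer()).functional_group_counts(molecule)
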