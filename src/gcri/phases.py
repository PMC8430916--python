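"""Stationary-phase catalogs and the fixed-length phase encoding.

All neural models consume the same length-38 phase-encoding array so that
weights trained on non-polar data can initialize the polar models.  Non-polar
phases are one-hot encoded over 36 slots (closed catalog); polar phases over
the first 21 slots, with unrecognized polar names mapped to the catch-all
"Other polar" slot.  The remaining slots are fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

ENCODING_LENGTH = 38

NON_POLAR = "non-polar"
POLAR = "polar"
MID_POLAR = "mid-polar"
FAMILIES = (NON_POLAR, POLAR, MID_POLAR)

OTHER_POLAR = "Other polar"


class UnknownPhaseError(KeyError):
    """Raised for a phase name absent from a closed catalog."""


@dataclass(frozen=True)
class PhaseRegistry:
    """Ordered stationary-phase catalogs.

    The order of the name lists fixes both the one-hot slot of each phase and
    the layout of the predicted-RI feature block, so a registry is a versioned
    artifact that travels with trained models.
    """

    nonpolar_types: tuple[str, ...]
    polar_types: tuple[str, ...]
    version: int = 1
    encoding_length: int = ENCODING_LENGTH

    def __post_init__(self):
        if len(self.nonpolar_types) != 36:
            raise ValueError(f"expected 36 non-polar types, got {len(self.nonpolar_types)}")
        if len(self.polar_types) != 21:
            raise ValueError(f"expected 21 polar types, got {len(self.polar_types)}")
        if self.polar_types[-1] != OTHER_POLAR:
            raise ValueError(f"last polar type must be {OTHER_POLAR!r}")
        if len(set(self.nonpolar_types)) != 36 or len(set(self.polar_types)) != 21:
            raise ValueError("phase names must be unique within a registry")
        if self.encoding_length != ENCODING_LENGTH:
            raise ValueError(f"encoding length must be {ENCODING_LENGTH}")

    def types(self, family: str) -> tuple[str, ...]:
        if family == NON_POLAR:
            return self.nonpolar_types
        if family == POLAR:
            return self.polar_types
        raise ValueError(f"no direct catalog for family {family!r}")


@dataclass(frozen=True)
class SPEncoding:
    """A length-38 phase encoding with the index of the active slot."""

    vector: np.ndarray
    active_index: int
    family: str = field(default=NON_POLAR)


def sp_encode(phase_name: str, registry: PhaseRegistry, family: str) -> SPEncoding:
    """Encode a stationary phase as a fixed length-38 one-hot array.

    Polar names not present in the catalog fall back to the "Other polar"
    slot; the non-polar catalog is closed and unknown names raise
    :class:`UnknownPhaseError`.  Mid-polar phases have no direct encoding
    (they are served by the second-level model).
    """
    if family == NON_POLAR:
        try:
            idx = registry.nonpolar_types.index(phase_name)
        except ValueError:
            raise UnknownPhaseError(
                f"non-polar phase {phase_name!r} not in the closed catalog"
            ) from None
    elif family == POLAR:
        try:
            idx = registry.polar_types.index(phase_name)
        except ValueError:
            idx = registry.polar_types.index(OTHER_POLAR)
    else:
        raise ValueError(f"family {family!r} has no direct phase encoding")
    vec = np.zeros(ENCODING_LENGTH, dtype=np.float32)
    vec[idx] = 1.0
    return SPEncoding(vector=vec, active_index=idx, family=family)


def load_registry(path: str | Path) -> PhaseRegistry:
    """Load a phase registry from a YAML catalog file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PhaseRegistry(
        nonpolar_types=tuple(raw["nonpolar_types"]),
        polar_types=tuple(raw["polar_types"]),
        version=int(raw.get("version", 1)),
    )


_DEFAULT: PhaseRegistry | None = None


def default_registry() -> PhaseRegistry:
    """The registry shipped with the package (36 non-polar + 21 polar types)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("gcri.assets").joinpath("phase_registry.yaml")
        with resources.as_file(ref) as path:
            _DEFAULT = load_registry(path)
    return _DEFAULT
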