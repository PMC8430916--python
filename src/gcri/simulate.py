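"""Abraham-solvation-equation GC simulator with known ground truth.

Retention on a liquid stationary phase is modeled by the linear solvation
energy relationship

    log k = c + eE + sS + aA + bB + lL

with analyte parameters (E, S, A, B, L) derived from structure (counts of
donors, heteroatoms, aromatic rings, size) plus a small seeded jitter, and
phase parameters (c, e, s, a, b, l) per stationary phase.  Retention indices
are then produced with the Kovats bracketing formula against a simulated
n-alkane ladder on the same phase, so the near-linear link between log k and
RI emerges from the construction instead of being assumed.  The generator
emulates the shape of a large reference retention corpus — many phases,
several records per compound, phase-dependent polarity shifts, RI span of
roughly 300-4000 — at desk scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from rdkit.Chem import rdMolDescriptors

from .chem import Molecule, parse_molecule
from .data import RetentionRecord
from .phases import MID_POLAR, NON_POLAR, POLAR

# L of the n-alkane with n carbons is exactly linear in n, which makes the
# simulated ladder exactly linear in log k on every phase.
L_PER_CARBON = 0.52


class SimulatorConfigError(ValueError):
    """Raised for inconsistent simulator configuration (e.g. bad ladder)."""


@dataclass(frozen=True)
class AbrahamAnalyte:
    """An analyte with Abraham solute parameters and its structure."""

    molecule: Molecule
    E: float
    S: float
    A: float
    B: float
    L: float

    def __post_init__(self):
        if not self.L > 0:
            raise SimulatorConfigError("analyte L parameter must be positive")


@dataclass(frozen=True)
class AbrahamPhase:
    """A stationary phase with Abraham system constants and noise level."""

    name: str
    c: float
    e: float
    s: float
    a: float
    b: float
    l: float
    family: str = NON_POLAR
    ri_noise_sd: float = 10.0

    def __post_init__(self):
        if not self.l > 0:
            raise SimulatorConfigError("phase l parameter must be positive")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.c, self.e, self.s, self.a, self.b, self.l])


def log_k(analyte: AbrahamAnalyte, phase: AbrahamPhase) -> float:
    """The solvation-equation retention factor: c + eE + sS + aA + bB + lL."""
    return (phase.c + phase.e * analyte.E + phase.s * analyte.S
            + phase.a * analyte.A + phase.b * analyte.B + phase.l * analyte.L)


# ---------------------------------------------------------------------------
# Analyte library


_FAMILY_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("primary alcohol", "OC{chain}"),
    ("secondary alcohol", "CC(O){chain}"),
    ("diol", "OCC(O){chain}"),
    ("ester", "CC(=O)O{chain}"),
    ("ketone", "CC(=O){chain}"),
    ("aldehyde", "O=C{chain}"),
    ("ether", "CCOC{chain}"),
    ("alkylbenzene", "c1ccccc1{chain}"),
    ("phenol", "Oc1ccccc1{chain}"),
    ("pyridine", "c1ccncc1{chain}"),
    ("chloride", "ClC{chain}"),
    ("bromide", "BrC{chain}"),
    ("nitrile", "N#C{chain}"),
    ("amine", "NC{chain}"),
    ("thiol", "SC{chain}"),
    ("sulfide", "CSC{chain}"),
    ("branched alkane", "CC(C){chain}"),
)

_MAX_CHAIN = 18


def _analyte_rng(compound_key: str, seed: int) -> np.random.Generator:
    mix = (zlib.crc32(compound_key.encode()) ^ (seed * 2654435761)) & 0x7FFFFFFF
    return np.random.default_rng(mix)


def abraham_parameters(molecule: Molecule, seed: int) -> dict[str, float]:
    """Structure-linked Abraham parameters with a small seeded jitter.

    The map is intentionally simple (counts-based) so that desk-scale models
    can learn it: L grows with size, A with H-bond donors, B/S with
    heteroatoms and aromatic rings, E with polarizable atoms.  The jitter is
    deterministic given (structure, seed) and vanishes for parameters whose
    structural part is zero, so e.g. A = 0 exactly for donor-free analytes.
    """
    mol = molecule.mol
    heavy = mol.GetNumHeavyAtoms()
    donors = rdMolDescriptors.CalcNumHBD(mol)
    counts = {s: 0 for s in ("O", "N", "S", "F", "Cl", "Br", "I")}
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
    arom = rdMolDescriptors.CalcNumAromaticRings(mol)
    n_hal = counts["F"] + counts["Cl"] + counts["Br"] + counts["I"]

    rng = _analyte_rng(molecule.compound_key, seed)

    def jitter(base: float, sd: float) -> float:
        if base <= 0:
            return 0.0
        return base + float(np.clip(rng.normal(0.0, sd), -0.12, 0.12))

    L = 0.52 * heavy + 0.30 * arom + float(np.clip(rng.normal(0.0, 0.04), -0.12, 0.12))
    return {
        "E": jitter(0.18 * arom + 0.05 * counts["Cl"] + 0.12 * (counts["Br"] + counts["I"])
                    + 0.10 * counts["S"], 0.03),
        "S": jitter(0.22 * (counts["O"] + counts["N"]) + 0.28 * arom + 0.08 * n_hal, 0.04),
        "A": jitter(0.35 * donors, 0.03),
        "B": jitter(0.25 * counts["O"] + 0.22 * counts["N"] + 0.15 * counts["S"], 0.03),
        "L": max(L, 0.3),
    }


def generate_library(n: int, seed: int) -> list[AbrahamAnalyte]:
    """Generate n distinct analytes over enumerated compound families.

    n-Alkanes never appear in the library (they form the reference ladder).
    Deterministic: a fixed seed reproduces the library exactly.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    analytes: list[AbrahamAnalyte] = []
    fam_idx = 0
    while len(analytes) < n:
        name, template = _FAMILY_TEMPLATES[fam_idx % len(_FAMILY_TEMPLATES)]
        fam_idx += 1
        m = int(rng.integers(1, _MAX_CHAIN + 1))
        # occasional methyl branch for structural variety
        chain = "C" * m
        if m >= 4 and rng.random() < 0.3:
            cut = int(rng.integers(1, m - 1))
            chain = "C" * cut + "C(C)" + "C" * (m - cut - 1)
        smiles = template.format(chain=chain)
        molecule = parse_molecule(smiles)
        if molecule.compound_key in seen:
            continue
        seen.add(molecule.compound_key)
        params = abraham_parameters(molecule, seed)
        analytes.append(AbrahamAnalyte(molecule=molecule, **params))
    return analytes


# ---------------------------------------------------------------------------
# Phases and the alkane ladder


def default_phases() -> list[AbrahamPhase]:
    """Five non-polar and four polar phases named after catalog entries."""
    return [
        AbrahamPhase("DB-1", c=-0.20, e=0.05, s=0.02, a=0.00, b=0.00, l=1.00, family=NON_POLAR),
        AbrahamPhase("DB-5", c=-0.18, e=0.08, s=0.08, a=0.02, b=0.00, l=0.99, family=NON_POLAR),
        AbrahamPhase("Squalane", c=-0.22, e=0.12, s=0.00, a=0.00, b=0.00, l=1.02, family=NON_POLAR),
        AbrahamPhase("SE-54", c=-0.19, e=0.07, s=0.06, a=0.01, b=0.00, l=0.98, family=NON_POLAR),
        AbrahamPhase("OV-101", c=-0.21, e=0.05, s=0.03, a=0.00, b=0.00, l=1.00, family=NON_POLAR),
        AbrahamPhase("DB-WAX", c=-0.15, e=0.25, s=1.20, a=1.90, b=0.80, l=0.86, family=POLAR),
        AbrahamPhase("Carbowax 20M", c=-0.16, e=0.25, s=1.15, a=1.85, b=0.75, l=0.87, family=POLAR),
        AbrahamPhase("FFAP", c=-0.14, e=0.22, s=1.25, a=2.10, b=0.60, l=0.85, family=POLAR),
        AbrahamPhase("HP-Innowax", c=-0.15, e=0.24, s=1.18, a=1.90, b=0.78, l=0.86, family=POLAR),
    ]


def make_linear_phase(bases: Sequence[AbrahamPhase], weights: Sequence[float],
                      name: str, family: str = MID_POLAR,
                      ri_noise_sd: float = 10.0) -> AbrahamPhase:
    """A phase whose (c,e,s,a,b,l) vector is a weighted sum of base vectors.

    Because log k is linear in the phase vector, every analyte's log k on the
    new phase is exactly the same weighted sum of its base-phase log k values
    — ground truth for phase-combination recovery experiments.
    """
    if len(bases) == 0:
        raise ValueError("at least one base phase is required")
    if len(bases) > 5:
        raise ValueError("at most five base phases are supported")
    if len(weights) != len(bases):
        raise ValueError("one weight per base phase")
    vec = np.zeros(6)
    for w, p in zip(weights, bases):
        if not np.isfinite(w):
            raise ValueError("weights must be finite")
        vec += w * p.vector
    c, e, s, a, b, l = vec
    return AbrahamPhase(name=name, c=c, e=e, s=s, a=a, b=b, l=l,
                        family=family, ri_noise_sd=ri_noise_sd)


@dataclass(frozen=True)
class AlkaneLadder:
    """Simulated n-alkane reference series on one phase (strictly increasing)."""

    phase_name: str
    carbons: np.ndarray
    logk: np.ndarray

    def __post_init__(self):
        if len(self.carbons) != len(self.logk) or len(self.carbons) < 2:
            raise SimulatorConfigError("ladder needs >= 2 aligned points")
        if not np.all(np.diff(self.logk) > 0):
            raise SimulatorConfigError("ladder log k must be strictly increasing")


def make_ladder(phase: AbrahamPhase, n_min: int = 5, n_max: int = 40) -> AlkaneLadder:
    """Noiseless ladder: alkane Cn has (E,S,A,B)=0 and L = 0.52 n exactly."""
    carbons = np.arange(n_min, n_max + 1)
    logk = phase.c + phase.l * L_PER_CARBON * carbons
    return AlkaneLadder(phase_name=phase.name, carbons=carbons, logk=logk)


class KovatsRI(NamedTuple):
    ri: float
    extrapolated: bool


def kovats_ri(analyte: AbrahamAnalyte, phase: AbrahamPhase,
              ladder: AlkaneLadder) -> KovatsRI:
    """Kovats retention index by bracketing against the alkane ladder.

    RI = 100 [n + (log k_x - log k_n) / (log k_{n+1} - log k_n)] with n the
    bracketing alkane; outside the ladder the nearest pair extrapolates
    linearly and the result is flagged.
    """
    lk = log_k(analyte, phase)
    carbons, logk = ladder.carbons, ladder.logk
    extrapolated = bool(lk < logk[0] or lk > logk[-1])
    i = int(np.clip(np.searchsorted(logk, lk) - 1, 0, len(logk) - 2))
    frac = (lk - logk[i]) / (logk[i + 1] - logk[i])
    return KovatsRI(ri=100.0 * (carbons[i] + frac), extrapolated=extrapolated)


# ---------------------------------------------------------------------------
# Corpus assembly


def build_corpus(library: Sequence[AbrahamAnalyte], phases: Sequence[AbrahamPhase],
                 seed: int, replicates: int = 1, noise: bool = True,
                 n_min: int = 5, n_max: int = 40,
                 ) -> tuple[list[RetentionRecord], "pd.DataFrame"]:
    """Simulate a retention corpus: one or more records per (analyte, phase).

    Records carry RI = Kovats ground truth + Gaussian noise with the phase's
    ``ri_noise_sd`` (replicates draw independent noise).  Returns the records
    and a ground-truth table (compound_key, phase, true RI, extrapolation
    flag).  Bit-reproducible for a fixed (seed, configuration).
    """
    import pandas as pd

    if len(phases) == 0:
        raise ValueError("at least one phase is required")
    rng = np.random.default_rng(seed)
    records: list[RetentionRecord] = []
    truth_rows = []
    for phase in phases:
        ladder = make_ladder(phase, n_min=n_min, n_max=n_max)
        for analyte in library:
            ri_true, flagged = kovats_ri(analyte, phase, ladder)
            truth_rows.append({
                "compound_key": analyte.molecule.compound_key,
                "phase": phase.name, "family": phase.family,
                "ri_true": ri_true, "extrapolated": flagged,
            })
            for _ in range(replicates):
                ri = ri_true
                if noise and phase.ri_noise_sd > 0:
                    ri += float(rng.normal(0.0, phase.ri_noise_sd))
                records.append(RetentionRecord(
                    molecule=analyte.molecule, phase=phase.name,
                    family=phase.family, ri=ri, source="simulated",
                ))
    return records, pd.DataFrame(truth_rows)
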