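"""Retention records, admission filtering, compound-based splits and metrics.

Train/test hygiene is compound-based throughout: a compound (stereo- and
isotope-collapsed identity) contributes records to exactly one side of any
split, and excluding a test set removes *every* record of every test compound
from the training side, stereoisomers included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import Molecule, MoleculeParseError, is_n_alkane, parse_molecule
from .phases import FAMILIES

DEFAULT_ELEMENTS = frozenset({"C", "H", "O", "N", "S", "P", "F", "Cl", "Br", "I", "Si"})


@dataclass(frozen=True)
class RetentionRecord:
    """One (compound, stationary phase, retention value) observation."""

    molecule: Molecule
    phase: str
    family: str
    ri: float
    source: str = ""

    @property
    def compound_key(self) -> str:
        return self.molecule.compound_key

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown phase family {self.family!r}")
        if not self.ri > 0:
            raise ValueError(f"retention value must be positive, got {self.ri}")


def load_records(path: str | Path) -> tuple[list[RetentionRecord], list[tuple[str, str]]]:
    """Read a retention table (CSV/TSV, columns smiles,phase,family,ri[,source]).

    Returns admitted-parseable records plus a log of (smiles, reason) for rows
    whose structure could not be parsed.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    records, rejected = [], []
    for row in df.itertuples(index=False):
        try:
            mol = parse_molecule(row.smiles)
        except MoleculeParseError:
            rejected.append((row.smiles, "parse failure"))
            continue
        records.append(RetentionRecord(
            molecule=mol, phase=row.phase, family=row.family, ri=float(row.ri),
            source=str(getattr(row, "source", "") or ""),
        ))
    return records, rejected


def save_records(records: list[RetentionRecord], path: str | Path) -> None:
    pd.DataFrame({
        "smiles": [r.molecule.canonical_smiles for r in records],
        "phase": [r.phase for r in records],
        "family": [r.family for r in records],
        "ri": [r.ri for r in records],
        "source": [r.source for r in records],
    }).to_csv(path, index=False)


@dataclass(frozen=True)
class AdmissionConfig:
    """Structure admission rules: element whitelist, size cap, n-alkane rule."""

    elements: frozenset[str] = DEFAULT_ELEMENTS
    max_heavy_atoms: int = 100
    reject_n_alkanes: bool = True


def admit_molecule(molecule: Molecule, config: AdmissionConfig = AdmissionConfig()) -> str | None:
    """Return a rejection reason, or None if the molecule is admitted."""
    mol = molecule.mol
    if mol.GetNumHeavyAtoms() > config.max_heavy_atoms:
        return f"more than {config.max_heavy_atoms} heavy atoms"
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in config.elements:
            return f"element {atom.GetSymbol()} not in whitelist"
    if config.reject_n_alkanes and is_n_alkane(molecule):
        return "n-alkane"
    return None


def admit(records: list[RetentionRecord],
          config: AdmissionConfig = AdmissionConfig(),
          ) -> tuple[list[RetentionRecord], list[tuple[RetentionRecord, str]]]:
    """Filter records by the admission rules; rejections are logged, not fatal."""
    admitted, rejections = [], []
    for rec in records:
        reason = admit_molecule(rec.molecule, config)
        if reason is None:
            admitted.append(rec)
        else:
            rejections.append((rec, reason))
    return admitted, rejections


def exclude_compounds(train: list[RetentionRecord],
                      test: list[RetentionRecord]) -> list[RetentionRecord]:
    """Drop every training record whose compound occurs in the test set.

    Keys are stereo/isotope collapsed, so a training stereoisomer of a test
    compound is removed as well; exclusion is record-complete.
    """
    test_keys = {r.compound_key for r in test}
    return [r for r in train if r.compound_key not in test_keys]


def kfold(records: list[RetentionRecord], k: int, seed: int) -> list[list[RetentionRecord]]:
    """Partition records into k folds by compound key (records follow their compound)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    keys = sorted({r.compound_key for r in records})
    if len(keys) < k:
        raise ValueError(f"only {len(keys)} compounds for {k} folds")
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    assignment = {key: i % k for i, key in enumerate(keys)}
    folds: list[list[RetentionRecord]] = [[] for _ in range(k)]
    for rec in records:
        folds[assignment[rec.compound_key]].append(rec)
    return folds


def iter_train_test(folds: list[list[RetentionRecord]]):
    """Yield (train, test) pairs using each fold once as the test set."""
    for i, test in enumerate(folds):
        train = [r for j, f in enumerate(folds) if j != i for r in f]
        yield train, test


@dataclass(frozen=True)
class MetricsReport:
    """The accuracy suite used throughout: absolute, percentage and coverage errors.

    ``mae``/``mdae``/``rmse``/``coverage90`` share the unit of the targets
    (index units, or seconds for second-dimension retention); ``mpe``/``mdpe``
    are percentages of the reference value; ``r2`` is 1 - SSres/SStot.
    ``coverage90`` is the empirical 90th percentile of absolute deviations:
    90% of records deviate by less than this amount.
    """

    mae: float
    mdae: float
    rmse: float
    mpe: float
    mdpe: float
    r2: float
    coverage90: float
    n: int = 0
    units: str = "RI"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mae", "mdae", "rmse", "mpe", "mdpe", "r2", "coverage90", "n")}


def metrics(preds, refs, units: str = "RI") -> MetricsReport:
    """Compute the full accuracy report for paired predictions and references."""
    preds = np.asarray(preds, dtype=np.float64)
    refs = np.asarray(refs, dtype=np.float64)
    if preds.shape != refs.shape or preds.ndim != 1 or preds.size == 0:
        raise ValueError("preds and refs must be equal-length non-empty 1-D arrays")
    err = np.abs(preds - refs)
    sstot = float(np.sum((refs - refs.mean()) ** 2))
    if sstot == 0.0:
        warnings.warn("constant reference values: r2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((preds - refs) ** 2)) / sstot
    if np.any(refs <= 0):
        raise ValueError("percentage metrics require positive reference values")
    rel = err / refs * 100.0
    return MetricsReport(
        mae=float(err.mean()),
        mdae=float(np.median(err)),
        rmse=float(np.sqrt(np.mean((preds - refs) ** 2))),
        mpe=float(rel.mean()),
        mdpe=float(np.median(rel)),
        r2=r2,
        coverage90=float(np.quantile(err, 0.9)),
        n=preds.size,
        units=units,
    )


def records_dataframe(records: list[RetentionRecord]) -> pd.DataFrame:
    """Tabular view (smiles, compound_key, phase, family, ri, source)."""
    return pd.DataFrame({
        "smiles": [r.molecule.canonical_smiles for r in records],
        "compound_key": [r.compound_key for r in records],
        "phase": [r.phase for r in records],
        "family": [r.family for r in records],
        "ri": [r.ri for r in records],
        "source": [r.source for r in records],
    })
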