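"""Linear retention models: group contributions and phase combinations.

Two few-parameter model families complement the neural/SVR stack:

* a functional-group-contribution baseline — ordinary least squares of RI on
  the 84 functional-group counters plus an intercept, fit on the full data
  set (the model has too few parameters to overfit meaningfully);
* phase-combination models — RI on a data-poor phase expressed as an
  intercept-free linear combination of predicted RIs on at most five
  data-rich phases, built greedily: start from the single most correlated
  phase, then repeatedly add the phase giving the largest MAE gain,
  refitting all coefficients by least squares at each step, and stop when
  the gain drops below a threshold (a few index units).

The combination form is grounded in the solvation equation: if log k is
linear in five analyte parameters, log k (hence, near-linearly, RI) on any
liquid phase is a linear combination of log k on at most five others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class IncompleteInputError(KeyError):
    """Raised when a combination model is applied without all its inputs."""


@dataclass(frozen=True)
class GroupContributionModel:
    """Affine model over the 84 functional-group counters (RI units)."""

    intercept: float
    coefficients: np.ndarray

    def predict(self, counters: np.ndarray) -> np.ndarray:
        counters = np.atleast_2d(np.asarray(counters, dtype=np.float64))
        return counters @ self.coefficients + self.intercept


def fit_group_contributions(counters: np.ndarray, ri: np.ndarray) -> GroupContributionModel:
    """Least-squares fit of RI on functional-group counters (with intercept).

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning.
    """
    x = np.asarray(counters, dtype=np.float64)
    y = np.asarray(ri, dtype=np.float64)
    design = np.column_stack([np.ones(len(x)), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient counter design: minimum-norm solution",
                      stacklevel=2)
    return GroupContributionModel(intercept=float(coef[0]), coefficients=coef[1:])


@dataclass(frozen=True)
class LinearComboModel:
    """Intercept-free linear combination of per-phase RI values."""

    terms: tuple[tuple[str, float], ...]

    def __post_init__(self):
        if not 1 <= len(self.terms) <= 5:
            raise ValueError("a combination model has between 1 and 5 terms")
        if not all(np.isfinite(c) for _, c in self.terms):
            raise ValueError("coefficients must be finite")

    @property
    def phases(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.terms)


def apply_combo(model: LinearComboModel, ri_inputs: dict[str, float]) -> float:
    """Evaluate the combination: sum of coefficient x input RI (no intercept)."""
    try:
        return float(sum(coef * ri_inputs[phase] for phase, coef in model.terms))
    except KeyError as exc:
        raise IncompleteInputError(f"missing RI input for phase {exc.args[0]!r}") from None


def builtin_equations() -> dict[str, LinearComboModel]:
    """The fixed published combination equations for DB-1701 and DB-210."""
    return {
        "DB-1701": LinearComboModel(terms=(
            ("DB-624", 0.949),
            ("DB-WAX", 0.0769),
        )),
        "DB-210": LinearComboModel(terms=(
            ("Squalane", -3.3267),
            ("DB-1", -0.3007),
            ("DB-5", 3.0737),
            ("DB-624", 1.72),
            ("DB-WAX", -0.1071),
        )),
    }


def _ls_no_intercept(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    mae = float(np.mean(np.abs(x @ coef - y)))
    return coef, mae


def greedy_sp_combination(target_ri: np.ndarray, candidate_ri: pd.DataFrame,
                          gain_threshold: float = 5.0, max_terms: int = 5,
                          exclude: set[str] | None = None) -> LinearComboModel:
    """Build a phase-combination model greedily by MAE gain.

    ``candidate_ri`` holds one column of predicted RIs per candidate phase,
    row-aligned with ``target_ri``.  The first phase is the one most
    correlated (absolute Pearson correlation on centered values) with the
    target; subsequent phases are chosen to maximize the drop in MAE of the
    refit intercept-free least-squares model.  The process stops when the
    gain falls below ``gain_threshold`` (MAE, index units) or at
    ``max_terms`` terms.  Ties break toward the lowest column index.
    """
    if candidate_ri.shape[1] == 0:
        raise ValueError("no candidate phases")
    if max_terms > 5:
        raise ValueError("combination models use at most five phases")
    y = np.asarray(target_ri, dtype=np.float64)
    cols = [c for c in candidate_ri.columns if not exclude or c not in exclude]
    if not cols:
        raise ValueError("all candidate phases excluded")
    x_all = candidate_ri[cols].to_numpy(dtype=np.float64)

    yc = y - y.mean()
    best_first, best_corr = 0, -np.inf
    for j in range(x_all.shape[1]):
        xc = x_all[:, j] - x_all[:, j].mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        corr = abs(float(xc @ yc) / denom) if denom > 0 else 0.0
        if corr > best_corr + 1e-15:
            best_first, best_corr = j, corr
    selected = [best_first]
    coef, mae = _ls_no_intercept(x_all[:, selected], y)

    while len(selected) < max_terms:
        best_j, best_new = None, (None, np.inf)
        for j in range(x_all.shape[1]):
            if j in selected:
                continue
            cand_coef, cand_mae = _ls_no_intercept(x_all[:, selected + [j]], y)
            if cand_mae < best_new[1] - 1e-15:
                best_j, best_new = j, (cand_coef, cand_mae)
        if best_j is None or mae - best_new[1] < gain_threshold:
            break
        selected.append(best_j)
        coef, mae = best_new
    return LinearComboModel(terms=tuple((cols[j], float(c))
                                        for j, c in zip(selected, coef)))


def best_subset_combination(target_ri: np.ndarray, candidate_ri: pd.DataFrame,
                            max_terms: int = 5) -> tuple[LinearComboModel, float]:
    """Exhaustive best-subset least-squares oracle (small candidate sets only).

    Returns the intercept-free model with the lowest MAE over all candidate
    subsets of size <= max_terms, and that MAE.  Exponential in the number of
    candidates; intended as an independent check of the greedy builder.
    """
    from itertools import combinations

    y = np.asarray(target_ri, dtype=np.float64)
    cols = list(candidate_ri.columns)
    x_all = candidate_ri.to_numpy(dtype=np.float64)
    best = None
    for size in range(1, min(max_terms, len(cols)) + 1):
        for subset in combinations(range(len(cols)), size):
            coef, mae = _ls_no_intercept(x_all[:, list(subset)], y)
            if best is None or mae < best[1] - 1e-12:
                best = (tuple((cols[j], float(c)) for j, c in zip(subset, coef)), mae)
    return LinearComboModel(terms=best[0]), best[1]
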