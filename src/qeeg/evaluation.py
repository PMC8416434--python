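"""Feature survival, permutation significance and the combination sweep.

*Survival*: a feature "survives" if its elastic-net coefficient is
nonzero in more than ``threshold`` of the 10 cross-validation folds
(strictly greater; at the default threshold of 7 that means at least 8
of 10).

*Permutation test*: the group labels are randomly permuted and the full
10-fold cross-validated mean AUC recomputed - fold splitting redone and
the penalty re-tuned per permutation, so the null distribution reflects
the entire procedure. The p-value is the plain fraction of null AUCs at
or above the observed one (an add-one estimator is available by flag).

*Sweep*: all 21 parameter x band combinations are cross-validated and
the winner is the one with the highest mean AUC, ties broken toward
fewer features and then grid order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import QeegError
from .features import (
    FeatureCombination,
    FeatureMatrix,
    build_feature_matrix,
    enumerate_combination_grid,
)
from .models import EN, CVResult, ModelSpec, cross_validate, derive_seed

#: Default survival-rule threshold: nonzero in > 7 of 10 folds.
SURVIVAL_THRESHOLD = 7


# ---------------------------------------------------------------- survival


@dataclass
class SurvivalReport:
    """Per-feature stability of the elastic-net coefficients across folds."""

    table: pd.DataFrame  # index feature; nonzero_count, survived, sign_consistency, mean_coefficient
    threshold: int = SURVIVAL_THRESHOLD

    @property
    def survived(self) -> list[str]:
        return list(self.table.index[self.table["survived"]])


def extract_survival(cv: CVResult, threshold: int = SURVIVAL_THRESHOLD) -> SurvivalReport:
    """Apply the survival rule to the per-fold elastic-net coefficients.

    Counts exact zeros per feature across folds; a feature survives iff
    it is nonzero in strictly more than ``threshold`` folds.
    """
    if cv.method != EN or cv.coefficients is None:
        raise QeegError(f"survival extraction requires EN coefficients, got {cv.method}")
    coefs = cv.coefficients  # folds x features
    nonzero = coefs != 0.0
    counts = nonzero.sum(axis=0)
    signs = np.sign(coefs.to_numpy())
    sign_consistency, mean_coef = [], []
    for j, feat in enumerate(coefs.columns):
        s = signs[nonzero.iloc[:, j].to_numpy(), j]
        if s.size:
            pos = (s > 0).sum()
            sign_consistency.append(max(pos, s.size - pos) / s.size)
            mean_coef.append(float(coefs.iloc[:, j][nonzero.iloc[:, j]].mean()))
        else:
            sign_consistency.append(np.nan)
            mean_coef.append(0.0)
    table = pd.DataFrame(
        {
            "nonzero_count": counts.astype(int),
            "survived": counts > threshold,
            "sign_consistency": sign_consistency,
            "mean_coefficient": mean_coef,
        },
        index=coefs.columns,
    )
    return SurvivalReport(table, threshold)


# ---------------------------------------------------------------- permutation


@dataclass
class PermutationResult:
    """Observed AUC against the label-permutation null."""

    observed_auc: float  # percent
    null_aucs: np.ndarray  # percent
    n_perm: int
    add_one: bool = False
    low_resolution: bool = False

    @property
    def exceed_count(self) -> int:
        return int(np.sum(self.null_aucs >= self.observed_auc))

    @property
    def p_value(self) -> float:
        if self.add_one:
            return (self.exceed_count + 1) / (self.n_perm + 1)
        return self.exceed_count / self.n_perm

    @property
    def p_display(self) -> str:
        if not self.add_one and self.exceed_count == 0:
            return f"< {1 / self.n_perm:g}"
        return f"{self.p_value:g}"


def permutation_test(
    fm: FeatureMatrix,
    spec: ModelSpec,
    n_perm: int = 200,
    seed: int = 0,
    add_one: bool = False,
    observed: CVResult | None = None,
) -> PermutationResult:
    """Label-permutation null for the cross-validated mean AUC.

    Each permutation shuffles the labels, re-splits the folds and reruns
    the full (nested) cross-validation. Deterministic given ``seed``.
    """
    low = n_perm < 20
    if low:
        warnings.warn(f"n_perm={n_perm} < 20: low-resolution p-value", stacklevel=2)
    if observed is None:
        observed = cross_validate(fm, spec, seed=derive_seed(seed, "observed"))
    obs_auc = observed.mean_auc
    rng = np.random.default_rng(derive_seed(seed, "perm-labels"))
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(fm.y)
        fm_b = FeatureMatrix(fm.X, y_perm, combination=fm.combination)
        cv_b = cross_validate(fm_b, spec, seed=derive_seed(seed, "perm", b))
        null[b] = cv_b.mean_auc
    return PermutationResult(obs_auc, null, n_perm, add_one=add_one, low_resolution=low)


# ---------------------------------------------------------------- sweep


@dataclass
class SweepResult:
    """Per-combination cross-validation results and the selected winner."""

    table: pd.DataFrame
    best: FeatureCombination
    best_cv: CVResult
    results: dict[str, CVResult] = field(default_factory=dict)


def select_best(table: pd.DataFrame) -> int:
    """Winning row of a sweep table: max mean AUC, then fewer features,
    then grid order. Pure function of the (serializable) table."""
    t = table.reset_index(drop=True)
    ok = t["auc_mean"].notna()
    if not ok.any():
        raise QeegError("every combination failed; no best model")
    order = sorted(
        t.index[ok],
        key=lambda i: (-t.loc[i, "auc_mean"], t.loc[i, "n_features"], i),
    )
    return int(order[0])


def combination_sweep(
    records: pd.DataFrame,
    covs: pd.DataFrame,
    labels,
    spec: ModelSpec,
    adjust_iq: bool = False,
) -> SweepResult:
    """Cross-validate every combination of the 21-cell grid.

    Per-combination failures are recorded in their row (NaN metrics plus
    the error message) and the sweep continues.
    """
    grid = enumerate_combination_grid(adjust_iq)
    rows, results = [], {}
    best_cv = None
    for combo in grid:
        row = {
            "parameter": combo.parameter,
            "bands": "whole" if combo.is_whole else "+".join(combo.bands),
            "adjust_iq": combo.adjust_iq,
            "n_features": combo.n_columns,
        }
        try:
            fm = build_feature_matrix(records, covs, combo, labels)
            cv = cross_validate(fm, spec)
            row.update(cv.summary())
            row["error"] = ""
            results[combo.label()] = cv
        except QeegError as exc:
            row.update({k: np.nan for k in ("auc_mean", "auc_sd", "sens_mean", "sens_sd", "spec_mean", "spec_sd")})
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    best_idx = select_best(table)
    best = grid[best_idx]
    return SweepResult(table, best, results[best.label()], results)


def compare_methods(
    records: pd.DataFrame,
    covs: pd.DataFrame,
    labels,
    specs: dict[str, ModelSpec],
    adjust_iq: bool = False,
) -> pd.DataFrame:
    """Run the sweep per method; one best-combination row per method."""
    rows = []
    for name, spec in specs.items():
        sweep = combination_sweep(records, covs, labels, spec, adjust_iq)
        best_row = sweep.table.iloc[select_best(sweep.table)]
        rows.append(
            {
                "method": name,
                "best_combination": f"{best_row['parameter']}/{best_row['bands']}",
                **{
                    k: best_row[k]
                    for k in ("n_features", "auc_mean", "auc_sd", "sens_mean", "sens_sd", "spec_mean", "spec_sd")
                },
            }
        )
    return pd.DataFrame(rows)
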