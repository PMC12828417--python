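"""Per-variable significance tests and agreement with selection.

The headline diagnostic of the framework is the rank agreement between
classical univariate significance (Welch t-test for two classes,
one-way ANOVA for more) and the corrected selection frequency of each
variable, ``count(X_j) - count(X_j_perm)``.  Kendall's tau-b is used
because selection counts tie heavily; a strongly negative tau means
that statistically significant variables are also the ones the
selection keeps choosing — the state a safe augmentation level must
preserve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TabularDataset, ValidationError
from .selection import SelectionProfile


@dataclass
class AgreementResult:
    """Kendall agreement between p-values and corrected frequencies."""

    feature_names: list[str]
    pvalues: np.ndarray
    corrected_frequency: np.ndarray
    tau: float | None  # None when either vector is constant
    tau_p: float | None
    regime: str = "original"

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "tau": self.tau,
            "tau_p": self.tau_p,
            "features": self.feature_names,
            "pvalues": self.pvalues.tolist(),
            "corrected_frequency": self.corrected_frequency.tolist(),
        }


def agreement_table(results: list[AgreementResult]) -> pd.DataFrame:
    """One row per data regime with its Kendall tau and p-value;
    absent correlations appear as NA."""
    return pd.DataFrame(
        {
            "regime": [r.regime for r in results],
            "tau": [np.nan if r.tau is None else r.tau for r in results],
            "tau_p": [np.nan if r.tau_p is None else r.tau_p for r in results],
        }
    )


def per_variable_pvalues(
    data: TabularDataset, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate class-difference p-value for every feature column.

    Two classes use the two-sample t-test (Welch by default); more than
    two use one-way ANOVA.  No multiplicity correction is applied.
    Returns ``(pvalues, degenerate)`` where the mask flags variables
    with zero variance in every class (their p is set to 1).
    """
    data.validate()
    data.require_classes(2)
    classes = data.classes
    groups = [data.values[data.labels == c] for c in classes]
    J = data.n_features
    pvalues = np.empty(J)
    degenerate = np.zeros(J, dtype=bool)
    for j in range(J):
        cols = [g[:, j] for g in groups]
        if all(np.ptp(col) == 0 for col in cols):
            pvalues[j] = 1.0
            degenerate[j] = True
            continue
        if len(classes) == 2:
            p = stats.ttest_ind(cols[0], cols[1], equal_var=equal_var).pvalue
        else:
            p = stats.f_oneway(*cols).pvalue
        pvalues[j] = 1.0 if np.isnan(p) else float(p)
        degenerate[j] = bool(np.isnan(p))
    return pvalues, degenerate


def significance_selection_agreement(
    pvalues: np.ndarray,
    profile: SelectionProfile,
    counterpart_map: dict[str, str],
    feature_names: list[str] | None = None,
    regime: str = "original",
) -> AgreementResult:
    """Kendall tau-b between p-values and counterpart-corrected
    selection frequencies of the original variables.

    ``pvalues`` must be aligned with ``feature_names`` (default: the
    keys of ``counterpart_map`` in order).  When either vector is
    constant the correlation is undefined and reported as absent.
    """
    names = list(counterpart_map) if feature_names is None else list(feature_names)
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) != len(names):
        raise ValidationError("pvalues and variable set are misaligned")
    corrected = np.empty(len(names))
    for i, name in enumerate(names):
        if name not in counterpart_map:
            raise ValidationError(f"variable '{name}' has no engineered counterpart")
        perm = counterpart_map[name]
        if name not in profile.selection_count or perm not in profile.selection_count:
            raise ValidationError(f"profile is missing '{name}' or '{perm}'")
        corrected[i] = profile.selection_count[name] - profile.selection_count[perm]
    if np.ptp(pvalues) == 0 or np.ptp(corrected) == 0:
        tau, tau_p = None, None
    else:
        res = stats.kendalltau(pvalues, corrected)  # tau-b, tie-corrected
        tau, tau_p = float(res.statistic), float(res.pvalue)
        if np.isnan(tau):
            tau, tau_p = None, None
    return AgreementResult(
        feature_names=names,
        pvalues=pvalues,
        corrected_frequency=corrected,
        tau=tau,
        tau_p=tau_p,
        regime=regime,
    )
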