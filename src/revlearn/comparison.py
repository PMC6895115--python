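"""Nested model comparison: likelihood-ratio test, pseudo-r2, BIC, and
cohort-level model selection.

Conventions
-----------
* LRT statistic d = 2 * (logL_big - logL_small), chi-square distributed
  under the null with df = difference in free parameters; at df = 1 the
  p = 0.05 boundary is d = 3.842 (to the printed precision).
* pseudo-r2 is the chance-normalized log-likelihood,
  1 - logL / (m * ln 0.5): 0 at coin-flip performance, 1 at perfect
  prediction. A historical variant that plugs the raw chance
  probability 0.5^m into the normalization is available behind
  ``printed_form=True`` for audit; it is not on the 0-1 scale and is
  not used anywhere in the pipeline.
* BIC follows the larger-is-better convention logL - (k/2) * ln(m);
  multiply by -2 for the textbook -2 logL + k ln m scale
  (``bic(..., standard=True)``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import FitResult

__all__ = [
    "LRTResult",
    "ModelReport",
    "likelihood_ratio",
    "pseudo_r2",
    "bic",
    "select_model",
    "lrt_critical_d",
]

LN_HALF = math.log(0.5)


@dataclass(frozen=True)
class LRTResult:
    d_statistic: float
    df: int
    p_value: float
    significant: bool


def likelihood_ratio(fit_small: "FitResult", fit_big: "FitResult") -> LRTResult:
    """Likelihood-ratio test of the smaller model against the bigger.

    Grid-restricted fits of the sticky models can come out marginally
    below the nested smaller model when the neutral point (kappa = 0)
    is off-axis; a negative d is clamped to 0 with a warning, since
    nesting is a property of the continuous models.
    """
    if fit_big.n_free_params <= fit_small.n_free_params:
        raise ValueError("fit_big must have more free parameters than fit_small")
    if fit_big.n_trials != fit_small.n_trials:
        raise ValueError("fits must be of the same session")
    d = 2.0 * (fit_big.log_likelihood - fit_small.log_likelihood)
    if d < 0:
        warnings.warn(
            f"negative LRT statistic {d:.3g} clamped to 0 (grid-restricted fit)",
            stacklevel=2,
        )
        d = 0.0
    df = fit_big.n_free_params - fit_small.n_free_params
    p = float(stats.chi2.sf(d, df))
    return LRTResult(d, df, p, p < 0.05)


def lrt_critical_d(df: int = 1, alpha: float = 0.05, step: float = 0.001) -> float:
    """Smallest d on a ``step`` grid whose chi-square upper-tail
    probability is strictly below ``alpha``."""
    d = np.arange(0.0, 20.0 + step, step)
    below = stats.chi2.sf(d, df) < alpha
    return float(d[np.argmax(below)])


def pseudo_r2(log_likelihood: float, n_trials: int, printed_form: bool = False) -> float:
    """Chance-normalized fit measure: 1 - logL / (m ln 0.5)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if printed_form:
        chance = 0.5 ** n_trials
        return (log_likelihood - chance) / chance
    return 1.0 - log_likelihood / (n_trials * LN_HALF)


def bic(log_likelihood: float, n_free_params: int, n_trials: int, standard: bool = False) -> float:
    """BIC in the larger-is-better convention logL - (k/2) ln m."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    value = log_likelihood - 0.5 * n_free_params * math.log(n_trials)
    return -2.0 * value if standard else value


@dataclass(frozen=True)
class ModelReport:
    """Cohort-level comparison: per-model means and the selected model."""

    mean_pseudo_r2: pd.DataFrame  # index: subset, columns: model
    mean_bic: pd.DataFrame
    selected_model: str
    primary_subset: str
    criterion: str = "max mean BIC (logL - (k/2) ln m convention) on the primary subset"


def select_model(
    fits: pd.DataFrame,
    primary_subset: str | None = None,
    subset_col: str = "subset",
) -> ModelReport:
    """Cohort model selection from a long-format fits table.

    ``fits`` needs columns subject_id, model, pseudo_r2, bic and a
    subset label column (e.g. the group x timepoint cell). Every model
    must cover the same subjects within each subset. The winner is the
    model with the best mean BIC on the primary subset (default: the
    last subset in sorted order, so name the subset of interest
    explicitly in practice).
    """
    required = {"subject_id", "model", "pseudo_r2", "bic", subset_col}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns {sorted(missing)}")
    for subset, sub in fits.groupby(subset_col):
        per_model = sub.groupby("model")["subject_id"].apply(frozenset)
        if per_model.nunique() != 1:
            raise ValueError(f"subset {subset!r}: models fitted on different subject sets")
    mean_r2 = fits.pivot_table(index=subset_col, columns="model", values="pseudo_r2")
    mean_bic = fits.pivot_table(index=subset_col, columns="model", values="bic")
    if primary_subset is None:
        primary_subset = sorted(mean_bic.index)[-1]
    if primary_subset not in mean_bic.index:
        raise ValueError(f"primary subset {primary_subset!r} not present")
    selected = str(mean_bic.loc[primary_subset].idxmax())
    return ModelReport(mean_r2, mean_bic, selected, str(primary_subset))
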