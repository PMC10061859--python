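"""Histone-delta logistic model of tissue specificity.

For a focal tissue, each gene with both a promoter CGI and an assigned
enhancer contributes one row: the outcome is membership in that tissue's
tissue-specific set, and the predictors are the tissue-minus-ESC signal
differences of H3K4me1/H3K4me3/H3K27me3 at the promoter CGI body and
H3K4me1/H3K27ac at the nearest enhancer.  Predictors are standardized
(zero mean, unit variance; the scaling is recorded) so the forest-plot
odds ratios are comparable across marks.  The fit is plain
maximum-likelihood logistic regression (Newton/IRLS); perfect separation
is surfaced as an error rather than silently regularized.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDataError, SchemaError, SeparationError

logger = logging.getLogger(__name__)

PROMOTER_MARKS = ("H3K4me1", "H3K4me3", "H3K27me3")
ENHANCER_MARKS = ("H3K4me1", "H3K27ac")


def build_design(
    tissue: str,
    specific_sets: dict,
    promoter_signal: dict,
    enhancer_signal: dict,
    conditions: tuple = ("ESC", "tissue"),
    standardize: bool = True,
) -> tuple:
    """Assemble the per-gene design table for one focal tissue.

    Parameters
    ----------
    tissue
        Focal tissue; must be a key of ``specific_sets``.
    specific_sets
        ``{tissue: set(gene_id)}`` from tissue-specific selection.
    promoter_signal
        ``{(mark, condition): Series}`` of CGI-body mean signal keyed by
        gene_id, for the three promoter marks in both conditions.
    enhancer_signal
        ``{(mark, condition): Series}`` of nearest-enhancer mean signal
        keyed by gene_id (genes without an enhancer are simply absent).

    Returns
    -------
    (design, scaling): the design DataFrame (outcome + delta predictors,
    one row per gene with complete data) and the recorded per-column
    mean/sd used for standardization.
    """
    if tissue not in specific_sets:
        raise SchemaError(f"tissue {tissue!r} not in specific_sets")
    c1, c2 = conditions
    cols = {}
    for mark in PROMOTER_MARKS:
        cols[f"prom_{mark}"] = promoter_signal[(mark, c2)] - promoter_signal[(mark, c1)]
    for mark in ENHANCER_MARKS:
        cols[f"enh_{mark}"] = enhancer_signal[(mark, c2)] - enhancer_signal[(mark, c1)]
    design = pd.DataFrame(cols).dropna()
    n_prom = len(promoter_signal[(PROMOTER_MARKS[0], c1)])
    dropped = n_prom - len(design)
    if dropped:
        logger.info("%d gene(s) dropped for missing enhancer/promoter data", dropped)
    positives = specific_sets[tissue]
    design.insert(0, "outcome", design.index.isin(positives).astype(int))
    if design["outcome"].sum() == 0:
        raise DegenerateDataError(
            f"no tissue-specific genes of {tissue!r} have complete data; "
            "the model cannot be fit"
        )
    scaling = {}
    if standardize:
        for col in list(design.columns[1:]):
            mu, sd = design[col].mean(), design[col].std(ddof=0)
            if sd == 0:
                logger.warning("predictor %s has zero variance; dropped", col)
                design = design.drop(columns=col)
                continue
            design[col] = (design[col] - mu) / sd
            scaling[col] = {"mean": float(mu), "sd": float(sd)}
    return design, scaling


@dataclass
class LogisticFit:
    """Per-predictor coefficients, odds ratios and Wald intervals."""

    table: pd.DataFrame          # coef, se, odds_ratio, ci_low, ci_high, pvalue
    intercept: float
    converged: bool
    n_iter: int
    log_likelihood: float
    n: int
    scaling: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "predictors": self.table.to_dict(orient="index"),
        }


def fit_logistic(
    design: pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-8,
    scaling: dict | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of outcome ~ predictors.

    ``design`` is the output of :func:`build_design` (first column
    ``outcome``, remaining columns numeric predictors).  Wald 95% CIs are
    coefficient ± 1.96·SE, exponentiated to the odds-ratio scale.

    Raises :class:`SeparationError` when the likelihood does not converge
    or coefficients diverge — the hallmark of (quasi-)separation — naming
    the most suspect predictor.
    """
    if "outcome" not in design.columns:
        raise SchemaError("design must have an 'outcome' column")
    y = design["outcome"].to_numpy(dtype=float)
    X = design.drop(columns="outcome")
    if X.shape[1] == 0:
        raise SchemaError("design has no predictors")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise DegenerateDataError("outcome has no variation")
    zero_var = [c for c in X.columns if X[c].std(ddof=0) == 0]
    if zero_var:
        raise DegenerateDataError(f"zero-variance predictor(s): {zero_var}")
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=max_iter, tol=tol, disp=0)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        except Exception as exc:  # statsmodels PerfectSeparationError
            if "eparation" in type(exc).__name__ or "eparation" in str(exc):
                raise SeparationError(str(exc)) from exc
            raise
    params = res.params
    if not res.mle_retvals.get("converged", False) or np.abs(params[1:]).max() > 50:
        worst = X.columns[int(np.argmax(np.abs(params[1:])))]
        raise SeparationError(
            f"logistic fit did not converge; predictor {worst!r} appears to "
            "separate the outcome",
            predictor=str(worst),
        )
    se = res.bse
    z = 1.959963984540054  # Phi^-1(0.975)
    table = pd.DataFrame(
        {
            "coef": params[1:],
            "se": se[1:],
            "odds_ratio": np.exp(params[1:]),
            "ci_low": np.exp(params[1:] - z * se[1:]),
            "ci_high": np.exp(params[1:] + z * se[1:]),
            "pvalue": res.pvalues[1:],
        },
        index=X.columns,
    )
    return LogisticFit(
        table=table,
        intercept=float(params[0]),
        converged=bool(res.mle_retvals.get("converged", False)),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        log_likelihood=float(res.llf),
        n=len(y),
        scaling=scaling or {},
    )
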