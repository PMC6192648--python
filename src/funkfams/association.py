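"""Presence-covariate association via stratified logistic regression.

For each stratum (e.g. body site, or size fraction for marine samples) and
each eligible covariate, every family's presence/absence vector is modeled
as::

    presence ~ intercept + adjustment terms + covariate term(s)

Coefficients and standard errors come from the maximum-likelihood logistic
fit; each covariate term is tested with a Wald t-test (t = beta / SE,
two-sided, df = n_obs - n_parameters).  Within each (stratum, covariate)
pair, p-values are pooled across families and corrected with the
Benjamini-Hochberg step-up FDR procedure; a ``global`` pooling mode is also
available.

Eligibility: a covariate is testable in a stratum only if, after dropping
missing values, at least two of its levels have more than four observations
(count >= 5).  Numeric covariates apply the same rule to their distinct
values, are standardized (mean 0, sd 1) within the stratum before fitting,
and are therefore reported on the standardized scale.  Categorical
covariates use treatment coding against the most frequent level.

Perfect or quasi-separation (a covariate pattern that predicts the outcome
exactly, driving coefficients to infinity) is detected and flagged; such
fits are excluded from the FDR pool rather than shrunk, keeping the
estimator faithful to the plain maximum-likelihood model.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .family_screen import ConfigurationError

__all__ = [
    "PhenotypeEligibility",
    "LogisticFit",
    "AssociationResult",
    "phenotype_eligible",
    "fit_logistic",
    "wald_tests",
    "bh_fdr",
    "run_association",
    "results_frame",
]

#: Fitted probabilities this close to 0/1, with a large coefficient, flag separation.
_SEPARATION_PROB_TOL = 1e-10
_SEPARATION_COEF = 15.0


@dataclass(frozen=True)
class PhenotypeEligibility:
    covariate: str
    stratum: str
    level_counts: Mapping[object, int]
    eligible: bool


@dataclass(frozen=True)
class LogisticFit:
    coefficients: Mapping[str, float]
    std_errors: Mapping[str, float]
    converged: bool
    separation_flag: bool
    n_obs: int


@dataclass
class AssociationResult:
    family_id: str
    covariate: str
    stratum: str
    term: str
    coefficient: float
    std_error: float
    t_stat: float
    p_value: float
    q_value: float
    status: str  # OK | NOT_CONVERGED | SEPARATED | SKIPPED_INELIGIBLE


def phenotype_eligible(
    values: Sequence | pd.Series,
    covariate: str = "",
    stratum: str = "",
    min_levels: int = 2,
    min_obs_per_level: int = 5,
    numeric: bool | None = None,
) -> PhenotypeEligibility:
    """Decide whether a covariate has enough observed variation to test.

    Missing values are dropped first.  A categorical covariate is eligible
    iff at least ``min_levels`` of its levels each have
    ``min_obs_per_level`` or more observations.  A numeric covariate (where
    per-value counts are uninformative — every measurement may be unique)
    applies the same budget to the whole column: at least ``min_levels``
    distinct values and at least ``min_levels * min_obs_per_level`` total
    observations.  When ``numeric`` is None it is inferred from the dtype.
    """
    series = pd.Series(list(values))
    series = series[series.notna()]
    if numeric is None:
        numeric = pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series)
    counts = Counter(series.tolist())
    if numeric:
        eligible = (
            len(counts) >= min_levels
            and len(series) >= min_levels * min_obs_per_level
        )
    else:
        n_qualifying = sum(1 for n in counts.values() if n >= min_obs_per_level)
        eligible = n_qualifying >= min_levels
    return PhenotypeEligibility(
        covariate=covariate,
        stratum=stratum,
        level_counts=dict(counts),
        eligible=eligible,
    )


def _collinear_terms(design: np.ndarray, term_names: Sequence[str]) -> list[str]:
    """Name design columns implicated in rank deficiency (pivoted QR)."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [term_names[i] for i in sorted(piv[rank:])]


def fit_logistic(
    y: np.ndarray, design: np.ndarray, term_names: Sequence[str]
) -> LogisticFit:
    """Maximum-likelihood logistic regression with separation detection.

    Fits by Newton iterations (iteratively reweighted least squares) with
    coefficient-change tolerance 1e-8 and at most 100 iterations.  The
    design must include the intercept column and be full rank; ``y`` must
    contain both classes.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[0] != y.shape[0]:
        raise ValueError("design and response shapes disagree")
    if len(term_names) != design.shape[1]:
        raise ValueError("one term name per design column required")
    if y.shape[0] < design.shape[1]:
        raise ValueError("fewer observations than parameters")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("response must be binary 0/1")
    if classes.size < 2:
        raise ValueError("response is single-class; nothing to fit")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design; collinear term(s): {_collinear_terms(design, term_names)}"
        )

    separated = False
    converged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0, warn_convergence=False
            )
        params = np.asarray(result.params, dtype=float)
        bse = np.asarray(result.bse, dtype=float)
        converged = bool(result.mle_retvals.get("converged", False))
        fitted = result.predict()
        at_boundary = (fitted < _SEPARATION_PROB_TOL) | (fitted > 1 - _SEPARATION_PROB_TOL)
        if at_boundary.any() and np.abs(params).max() > _SEPARATION_COEF:
            separated = True
        if not np.isfinite(bse).all():
            separated = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
        params = np.full(design.shape[1], np.nan)
        bse = np.full(design.shape[1], np.nan)

    return LogisticFit(
        coefficients=dict(zip(term_names, params)),
        std_errors=dict(zip(term_names, bse)),
        converged=converged,
        separation_flag=separated,
        n_obs=int(y.shape[0]),
    )


def wald_tests(fit: LogisticFit) -> dict[str, tuple[float, float]]:
    """Per-term Wald t statistics and two-sided p-values.

    t = coefficient / SE with df = n_obs - n_parameters; requires a
    converged, non-separated fit.
    """
    if not fit.converged or fit.separation_flag:
        raise ValueError("wald_tests requires a converged, non-separated fit")
    df = fit.n_obs - len(fit.coefficients)
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    out: dict[str, tuple[float, float]] = {}
    for term, coef in fit.coefficients.items():
        se = fit.std_errors[term]
        if not np.isfinite(se) or se <= 0:
            raise ValueError(f"invalid standard error for term {term!r}")
        t = coef / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        out[term] = (float(t), p)
    return out


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------


def _encode_term(series: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Encode one metadata column as design columns.

    Numeric: one standardized column (constant columns contribute nothing).
    Categorical: treatment dummies against the most frequent level; a
    single-level factor contributes nothing.
    """
    if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
        x = series.to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            return np.empty((len(x), 0)), []
        return ((x - x.mean()) / sd)[:, None], [name]
    levels = series.astype(str)
    counts = levels.value_counts()
    # most frequent level is the reference; alphabetical tiebreak for determinism
    reference = sorted(counts.index[counts == counts.max()])[0]
    others = sorted(set(levels) - {reference})
    cols = [(levels == lvl).to_numpy(dtype=float)[:, None] for lvl in others]
    names = [f"{name}[{lvl} vs {reference}]" for lvl in others]
    if not cols:
        return np.empty((len(levels), 0)), []
    return np.hstack(cols), names


def _build_design(
    sub: pd.DataFrame, adjustment: Sequence[str], covariate: str
) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + adjustment + covariate design for one stratum.

    Returns (design, all term names, covariate term names).
    """
    blocks = [np.ones((len(sub), 1))]
    names = ["intercept"]
    for adj in adjustment:
        cols, col_names = _encode_term(sub[adj], adj)
        blocks.append(cols)
        names.extend(col_names)
    cov_cols, cov_names = _encode_term(sub[covariate], covariate)
    blocks.append(cov_cols)
    names.extend(cov_names)
    return np.hstack(blocks), names, cov_names


def _skipped(
    family_ids: Sequence[str], covariate: str, stratum: str
) -> list[AssociationResult]:
    return [
        AssociationResult(
            family_id=fid,
            covariate=covariate,
            stratum=stratum,
            term=covariate,
            coefficient=float("nan"),
            std_error=float("nan"),
            t_stat=float("nan"),
            p_value=float("nan"),
            q_value=float("nan"),
            status="SKIPPED_INELIGIBLE",
        )
        for fid in family_ids
    ]


def run_association(
    presence: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: Sequence[str],
    adjustment: Sequence[str] = (),
    stratum_var: str = "environment",
    min_levels: int = 2,
    min_obs_per_level: int = 5,
    fdr_pool: str = "per_stratum_covariate",
) -> list[AssociationResult]:
    """Test every family x covariate x stratum combination.

    ``presence`` is a family x sample boolean frame; ``samples`` is indexed
    by sample id and carries the covariate, adjustment and stratum columns.
    FDR correction is pooled across families within each (stratum,
    covariate) pair by default (``fdr_pool='global'`` pools everything);
    only status-OK tests enter a pool.
    """
    if fdr_pool not in ("per_stratum_covariate", "global"):
        raise ConfigurationError(f"unknown fdr_pool {fdr_pool!r}")
    for var in list(covariates) + list(adjustment) + [stratum_var]:
        if var not in samples.columns:
            raise ConfigurationError(f"variable {var!r} absent from sample metadata")

    family_ids = list(presence.index)
    results: list[AssociationResult] = []
    pools: dict[tuple[str, str], list[int]] = {}

    for stratum in sorted(samples[stratum_var].astype(str).unique()):
        in_stratum = samples.index[samples[stratum_var].astype(str) == stratum]
        for covariate in covariates:
            sub = samples.loc[in_stratum, list(dict.fromkeys([*adjustment, covariate]))]
            sub = sub.dropna()
            eligibility = phenotype_eligible(
                sub[covariate],
                covariate=covariate,
                stratum=stratum,
                min_levels=min_levels,
                min_obs_per_level=min_obs_per_level,
            )
            if not eligibility.eligible:
                results.extend(_skipped(family_ids, covariate, stratum))
                continue
            design, names, cov_names = _build_design(sub, adjustment, covariate)
            if not cov_names or len(sub) < design.shape[1] + 1:
                results.extend(_skipped(family_ids, covariate, stratum))
                continue

            for fid in family_ids:
                y = presence.loc[fid, sub.index].to_numpy(dtype=float)
                if np.unique(y).size < 2:
                    results.extend(_skipped([fid], covariate, stratum))
                    continue
                try:
                    fit = fit_logistic(y, design, names)
                except ValueError:
                    results.extend(_skipped([fid], covariate, stratum))
                    continue
                if fit.separation_flag or not fit.converged:
                    status = "SEPARATED" if fit.separation_flag else "NOT_CONVERGED"
                    for term in cov_names:
                        results.append(
                            AssociationResult(
                                family_id=fid,
                                covariate=covariate,
                                stratum=stratum,
                                term=term,
                                coefficient=float(fit.coefficients.get(term, np.nan)),
                                std_error=float(fit.std_errors.get(term, np.nan)),
                                t_stat=float("nan"),
                                p_value=float("nan"),
                                q_value=float("nan"),
                                status=status,
                            )
                        )
                    continue
                tests = wald_tests(fit)
                for term in cov_names:
                    t_stat, p_value = tests[term]
                    results.append(
                        AssociationResult(
                            family_id=fid,
                            covariate=covariate,
                            stratum=stratum,
                            term=term,
                            coefficient=float(fit.coefficients[term]),
                            std_error=float(fit.std_errors[term]),
                            t_stat=t_stat,
                            p_value=p_value,
                            q_value=float("nan"),
                            status="OK",
                        )
                    )
                    pools.setdefault((stratum, covariate), []).append(len(results) - 1)

    # BH correction within each pool over status-OK tests
    if fdr_pool == "global":
        merged: dict[tuple[str, str], list[int]] = {("*", "*"): []}
        for idx_list in pools.values():
            merged[("*", "*")].extend(idx_list)
        pools = merged
    for idx_list in pools.values():
        if not idx_list:
            continue
        qs = bh_fdr([results[i].p_value for i in idx_list])
        for i, q in zip(idx_list, qs):
            results[i].q_value = float(q)
    return results


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per family x term x stratum)."""
    return pd.DataFrame(
        [
            {
                "family_id": r.family_id,
                "covariate": r.covariate,
                "stratum": r.stratum,
                "term": r.term,
                "coefficient": r.coefficient,
                "std_error": r.std_error,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "status": r.status,
            }
            for r in results
        ]
    )
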