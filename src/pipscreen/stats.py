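"""Prevalence estimation and logistic-regression determinants.

Prevalence is reported on the percent scale with a Wald normal-approximation
95% confidence interval (Wilson available behind a flag), rounded half-up to
one decimal as in printed epidemiological tables. Odds ratios come from
maximum-likelihood logistic fits with Wald intervals on the log-odds scale;
"unadjusted" fits each covariate alone, "adjusted" fits all jointly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PrevalenceEstimate",
    "prevalence_ci",
    "round_half_up",
    "fit_logistic",
    "pip_count_table",
    "criterion_prevalence_table",
]

Z95 = 1.96


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion on the percent scale with its 95% CI, one decimal."""

    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.percent <= self.ci_high <= 100):
            raise ValueError(f"inconsistent prevalence estimate: {self}")


def prevalence_ci(
    numerator: int, denominator: int, method: str = "wald"
) -> PrevalenceEstimate:
    """Percentage prevalence with a 95% CI, rounded half-up to one decimal.

    Wald CI: ``p +/- 1.96 * sqrt(p(1-p)/N)`` on the percent scale, clamped to
    [0, 100]. ``method="wilson"`` substitutes the Wilson score interval.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    p = numerator / denominator
    if method == "wald":
        half = Z95 * np.sqrt(p * (1 - p) / denominator)
        low, high = p - half, p + half
    elif method == "wilson":
        low, high = proportion_confint(
            numerator, denominator, alpha=0.05, method="wilson"
        )
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return PrevalenceEstimate(
        numerator=numerator,
        denominator=denominator,
        percent=round_half_up(100 * p),
        ci_low=round_half_up(max(0.0, 100 * low)),
        ci_high=round_half_up(min(100.0, 100 * high)),
    )


def _design(
    df: pd.DataFrame, covariates: Mapping[str, Optional[Sequence[str]]]
) -> tuple[pd.DataFrame, list[tuple[str, str, bool]]]:
    """Build a dummy-coded design matrix with declared reference levels.

    ``covariates`` maps column name -> ordered level list (first = reference)
    or None for a 0/1 binary column. Returns (X with constant, term metadata
    as (covariate, level, is_reference) in output order).
    """
    cols = {}
    terms: list[tuple[str, str, bool]] = []
    for name, levels in covariates.items():
        if levels is None:
            cols[name] = df[name].astype(float)
            terms.append((name, name, False))
        else:
            observed = set(df[name].unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"{name}: undeclared levels {sorted(unknown)}")
            terms.append((name, levels[0], True))
            for lv in levels[1:]:
                cols[f"{name}[{lv}]"] = (df[name] == lv).astype(float)
                terms.append((name, lv, False))
    X = sm.add_constant(pd.DataFrame(cols, index=df.index), has_constant="add")
    return X, terms


def _fit(y: pd.Series, X: pd.DataFrame):
    model = sm.Logit(np.asarray(y, dtype=float), X)
    try:
        res = model.fit(disp=0, maxiter=100)
    except Exception as exc:  # pragma: no cover - statsmodels raises variously
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(
            "logistic fit did not converge after "
            f"{res.mle_retvals.get('iterations')} iterations; "
            "check for perfect separation or collinearity"
        )
    return res


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    covariates: Mapping[str, Optional[Sequence[str]]],
) -> pd.DataFrame:
    """Unadjusted and adjusted odds ratios for a binary outcome.

    Parameters
    ----------
    df
        Analysis table; ``outcome`` must be 0/1 or boolean.
    covariates
        Mapping column -> ordered levels (first level is the reference) or
        None for binary 0/1 columns. Unadjusted ORs fit each covariate
        alone; adjusted ORs fit all covariates jointly.

    Returns
    -------
    Tidy DataFrame with one row per term: covariate, level, reference,
    or_unadjusted, or_unadj_low, or_unadj_high, or_adjusted, or_adj_low,
    or_adj_high, p_adjusted. Reference rows carry OR 1 and NaN CIs.
    """
    y = df[outcome].astype(float)
    X_adj, terms = _design(df, covariates)
    res_adj = _fit(y, X_adj)

    unadj: dict[str, tuple[float, float, float]] = {}
    for name, levels in covariates.items():
        X_u, _ = _design(df, {name: levels})
        res_u = _fit(y, X_u)
        for col in X_u.columns:
            if col == "const":
                continue
            beta, se = res_u.params[col], res_u.bse[col]
            unadj[col] = (
                float(np.exp(beta)),
                float(np.exp(beta - Z95 * se)),
                float(np.exp(beta + Z95 * se)),
            )

    rows = []
    for name, level, is_ref in terms:
        if is_ref:
            rows.append(
                {
                    "covariate": name,
                    "level": level,
                    "reference": True,
                    "or_unadjusted": 1.0,
                    "or_unadj_low": np.nan,
                    "or_unadj_high": np.nan,
                    "or_adjusted": 1.0,
                    "or_adj_low": np.nan,
                    "or_adj_high": np.nan,
                    "p_adjusted": np.nan,
                }
            )
            continue
        col = name if covariates[name] is None else f"{name}[{level}]"
        beta, se = res_adj.params[col], res_adj.bse[col]
        ou, ol, oh = unadj[col]
        rows.append(
            {
                "covariate": name,
                "level": level,
                "reference": False,
                "or_unadjusted": ou,
                "or_unadj_low": ol,
                "or_unadj_high": oh,
                "or_adjusted": float(np.exp(beta)),
                "or_adj_low": float(np.exp(beta - Z95 * se)),
                "or_adj_high": float(np.exp(beta + Z95 * se)),
                "p_adjusted": float(res_adj.pvalues[col]),
            }
        )
    return pd.DataFrame(rows)


def pip_count_table(
    profiles: pd.DataFrame, ci_method: str = "wald"
) -> pd.DataFrame:
    """Summary prevalence table: overall, PIP-count categories and duplication.

    The denominator is the number of profile rows; category counts partition
    the any-PIP count by construction (asserted structurally).
    """
    denom = len(profiles)
    n_any = int(profiles["any_pip"].sum())
    n1 = int((profiles["n_pip"] == 1).sum())
    n2 = int((profiles["n_pip"] == 2).sum())
    n3 = int((profiles["n_pip"] >= 3).sum())
    assert n1 + n2 + n3 == n_any, "PIP count categories must partition any-PIP"
    n_dup = int(profiles["any_duplication"].sum()) if "any_duplication" in profiles else 0

    rows = []
    for label, n in [
        ("overall_pip", n_any),
        ("1_pip", n1),
        ("2_pip", n2),
        ("3plus_pip", n3),
        ("duplication", n_dup),
    ]:
        if denom > 0:
            est = prevalence_ci(n, denom, method=ci_method)
            rows.append(
                {
                    "row": label,
                    "n": n,
                    "denominator": denom,
                    "percent": est.percent,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        else:
            rows.append(
                {
                    "row": label,
                    "n": 0,
                    "denominator": 0,
                    "percent": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
    return pd.DataFrame(rows)


def criterion_prevalence_table(
    profiles: pd.DataFrame, criterion_ids: Sequence[str], ci_method: str = "wald"
) -> pd.DataFrame:
    """Per-criterion prevalence over the profile denominator."""
    denom = len(profiles)
    rows = []
    for cid in criterion_ids:
        n = int(profiles[cid].sum())
        if denom > 0:
            est = prevalence_ci(n, denom, method=ci_method)
            rows.append(
                {
                    "criterion_id": cid,
                    "n": n,
                    "denominator": denom,
                    "percent": est.percent,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        else:
            rows.append(
                {
                    "criterion_id": cid,
                    "n": 0,
                    "denominator": 0,
                    "percent": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
    return pd.DataFrame(rows)
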