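"""Linear-model ladder with small-sample AICc selection.

For each predictor/response pair, four ordinary-least-squares variants are
compared:

a. ``linear``                y ~ x
b. ``interaction``           y ~ x * UGS          (UGS main effect + slope per type)
c. ``quadratic``             y ~ xc + xc^2        (xc centered)
d. ``interaction_quadratic`` y ~ (xc + xc^2) * UGS

The variant with the smallest AICc wins (ties to the fewer-parameter
variant), and each predictor carries its winning term set into the
multivariate model. Quadratic terms always use the centered predictor and
its square, which leaves fitted values unchanged but tames collinearity.

AICc follows the Gaussian-likelihood convention with k counting every
regression coefficient plus the residual variance:

    AIC  = n ln(rss/n) + n (ln 2pi + 1) + 2k
    AICc = AIC + 2 k (k + 1) / (n - k - 1)
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import UGSType

__all__ = [
    "Variant",
    "ModelSpec",
    "ModelFit",
    "ols_fit",
    "aicc",
    "fit_univariate_ladder",
    "fit_multivariate",
]

log = logging.getLogger(__name__)

#: Treatment-coding reference level: the most frequent UGS type in the study.
UGS_REFERENCE = UGSType.HOME_GARDEN

_AICC_TIE_TOL = 1e-8


class Variant(str, enum.Enum):
    LINEAR = "linear"
    INTERACTION = "interaction"
    QUADRATIC = "quadratic"
    INTERACTION_QUADRATIC = "interaction_quadratic"


@dataclass(frozen=True)
class ModelSpec:
    response: str
    predictors: tuple[str, ...]
    variant: Variant | tuple[Variant, ...]


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    n: int
    k: int  # coefficients + 1 for the residual variance
    rss: float
    aicc: float
    r2: float
    p_overall: float
    params: dict[str, float]


def ols_fit(y: np.ndarray, design: pd.DataFrame) -> sm.regression.linear_model.RegressionResults:
    """OLS on an explicit design matrix (must include the constant column).

    Raises on rank deficiency, naming the collinear columns, rather than
    silently dropping them.
    """
    X = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy QR-style elimination
        bad = []
        cols: list[int] = []
        for j in range(X.shape[1]):
            trial = cols + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(design.columns[j])
            else:
                cols = trial
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear column(s): {bad}")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("more columns than observations")
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected AIC from the Gaussian profile likelihood."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    if rss <= 0:
        return -math.inf
    aic = n * math.log(rss / n) + n * (math.log(2 * math.pi) + 1) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _ugs_dummies(ugs: pd.Series) -> pd.DataFrame:
    """Treatment coding against the reference level."""
    levels = [u.value for u in UGSType if u != UGS_REFERENCE]
    out = pd.DataFrame(index=ugs.index)
    vals = ugs.astype(str)
    for lev in levels:
        if (vals == lev).any():
            out[f"ugs[{lev}]"] = (vals == lev).astype(float)
    return out


def _design(
    x: pd.Series, ugs: pd.Series | None, variant: Variant, name: str
) -> pd.DataFrame:
    xc = x - x.mean()
    cols: dict[str, np.ndarray] = {}
    if variant in (Variant.LINEAR, Variant.INTERACTION):
        cols[name] = x.to_numpy(dtype=float)
    else:
        cols[f"{name}_c"] = xc.to_numpy(dtype=float)
        cols[f"{name}_c2"] = (xc**2).to_numpy(dtype=float)
    df = pd.DataFrame(cols, index=x.index)
    if variant in (Variant.INTERACTION, Variant.INTERACTION_QUADRATIC):
        dummies = _ugs_dummies(ugs)
        for dcol in dummies.columns:
            df[dcol] = dummies[dcol]
        for xcol in list(cols):
            for dcol in dummies.columns:
                df[f"{xcol}:{dcol}"] = df[xcol] * dummies[dcol]
    return df


def _estimable(ugs: pd.Series) -> bool:
    """Interaction variants need every present UGS level at >= 2 sites."""
    counts = ugs.value_counts()
    return bool((counts >= 2).all())


def _fit_variant(
    y: pd.Series, x: pd.Series, ugs: pd.Series | None, variant: Variant, name: str, response: str
) -> ModelFit:
    design = _design(x, ugs, variant, name)
    design.insert(0, "const", 1.0)
    res = ols_fit(y.to_numpy(), design)
    n = int(res.nobs)
    k = design.shape[1] + 1
    rss = float(res.ssr)
    return ModelFit(
        spec=ModelSpec(response=response, predictors=(name,), variant=variant),
        n=n,
        k=k,
        rss=rss,
        aicc=aicc(rss, n, k),
        r2=float(res.rsquared),
        p_overall=float(res.f_pvalue),
        params=dict(zip(design.columns, res.params)),
    )


def _pick_winner(fits: list[ModelFit]) -> ModelFit:
    """Smallest AICc; near-ties (|delta| < 1e-8) resolve to fewer parameters."""
    best = min(fits, key=lambda f: (f.aicc, f.k))
    contenders = [f for f in fits if abs(f.aicc - best.aicc) < _AICC_TIE_TOL]
    return min(contenders, key=lambda f: f.k)


def fit_univariate_ladder(
    x: pd.Series,
    y: pd.Series,
    ugs: pd.Series,
    name: str = "x",
    response: str = "y",
) -> tuple[list[ModelFit], ModelFit]:
    """Fit the four variants for one predictor/response pair.

    Returns all estimable fits sorted by AICc, plus the winner. A variant
    whose interaction terms are inestimable (a UGS level observed at fewer
    than two sites) is excluded with a warning.
    """
    if len(y) < 10:
        raise ValueError("ladder needs at least 10 observations")
    fits: list[ModelFit] = []
    for variant in Variant:
        needs_ugs = variant in (Variant.INTERACTION, Variant.INTERACTION_QUADRATIC)
        if needs_ugs and not _estimable(ugs):
            log.warning(
                "variant %s for %s ~ %s excluded: a UGS level has fewer than 2 sites",
                variant.value,
                response,
                name,
            )
            continue
        try:
            fits.append(_fit_variant(y, x, ugs, variant, name, response))
        except (np.linalg.LinAlgError, ValueError) as exc:
            log.warning(
                "variant %s for %s ~ %s excluded: %s", variant.value, response, name, exc
            )
    if not fits:
        raise ValueError(f"no estimable variant for {response} ~ {name}")
    fits.sort(key=lambda f: (f.aicc, f.k))
    return fits, _pick_winner(fits)


def fit_multivariate(
    X: pd.DataFrame,
    y: pd.Series,
    term_plan: dict[str, Variant],
    ugs: pd.Series,
    response: str = "y",
) -> ModelFit:
    """Fit the combined model whose per-predictor terms come from the
    univariate winners.

    The UGS main effect enters once if any predictor's plan includes an
    interaction.
    """
    blocks = []
    any_interaction = any(
        v in (Variant.INTERACTION, Variant.INTERACTION_QUADRATIC) for v in term_plan.values()
    )
    dummies = _ugs_dummies(ugs) if any_interaction else None
    for name, variant in term_plan.items():
        block = _design(X[name], ugs, variant, name)
        if dummies is not None:
            block = block.drop(columns=[c for c in dummies.columns if c in block.columns])
        blocks.append(block)
    design = pd.concat(blocks, axis=1)
    if dummies is not None:
        design = pd.concat([dummies, design], axis=1)
    design.insert(0, "const", 1.0)
    res = ols_fit(y.to_numpy(), design)
    n = int(res.nobs)
    k = design.shape[1] + 1
    rss = float(res.ssr)
    return ModelFit(
        spec=ModelSpec(
            response=response,
            predictors=tuple(term_plan),
            variant=tuple(term_plan.values()),
        ),
        n=n,
        k=k,
        rss=rss,
        aicc=aicc(rss, n, k),
        r2=float(res.rsquared),
        p_overall=float(res.f_pvalue),
        params=dict(zip(design.columns, res.params)),
    )


def significance_stars(p: float) -> str:
    """Table footnote bands: * <0.05, ** <0.01, *** <0.001 (no correction)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
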