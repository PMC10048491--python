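"""Fixed-effect selection by Akaike information criterion differences.

For each trait the association model always carries the population
stratification clusters; the remaining candidate fixed effects (farm, sire,
birth year/season, calving year/season, age at first calving) are admitted
one at a time: an effect enters the model iff adding it to the
stratification-only null lowers the Gaussian OLS AIC by at least 10
(delta AIC <= -10). Effects are tested singly against the null, never
stepwise.

AIC here is the Gaussian OLS form ``n*ln(2*pi*RSS/n) + n + 2*(k+1)`` where
``k`` counts regression parameters and the +1 counts the residual variance.
Constant terms are kept (they cancel in differences); the RSS is floored at
1e-12 to guard exact fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OPTIONAL_EFFECTS = (
    "farm",
    "sire",
    "birth_year",
    "birth_season",
    "calving_year",
    "calving_season",
    "age_first_calving",
)
CONTINUOUS_EFFECTS = frozenset({"age_first_calving"})
RSS_FLOOR = 1e-12


@dataclass
class ModelSpec:
    """Per-trait model: mandatory stratification plus selected fixed effects."""

    trait: str
    included: tuple = ()
    delta_aic: dict = field(default_factory=dict)


class RankDeficientError(np.linalg.LinAlgError):
    pass


def _encode(values: np.ndarray, name: str, continuous: bool):
    if continuous:
        return values.reshape(-1, 1).astype(float), [name]
    levels, inverse = np.unique(values, return_inverse=True)
    # reference level = first; one-hot for the rest
    cols = np.zeros((len(values), len(levels) - 1))
    for j in range(1, len(levels)):
        cols[inverse == j, j - 1] = 1.0
    names = [f"{name}[{lv}]" for lv in levels[1:]]
    return cols, names


def build_design(
    covariates: pd.DataFrame,
    effects,
    add_intercept: bool = True,
    continuous=CONTINUOUS_EFFECTS,
) -> tuple[np.ndarray, list]:
    """Design matrix for the given effects with deterministic collinearity pruning.

    Categorical effects are dummy-coded against their first level; columns
    that are collinear with everything to their left are dropped with a
    warning (left-to-right scan).
    """
    blocks = []
    names: list = []
    if add_intercept:
        blocks.append(np.ones((len(covariates), 1)))
        names.append("intercept")
    for eff in effects:
        vals = covariates[eff].to_numpy()
        is_cont = eff in continuous or (
            np.issubdtype(vals.dtype, np.floating)
        )
        cols, cnames = _encode(vals, eff, is_cont)
        blocks.append(cols)
        names.extend(cnames)
    X = np.concatenate(blocks, axis=1) if blocks else np.empty((len(covariates), 0))

    # greedy left-to-right rank pruning
    kept: list[int] = []
    dropped: list[str] = []
    Q = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        x = X[:, j]
        resid = x - Q @ (Q.T @ x)
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(1.0, np.linalg.norm(x)):
            kept.append(j)
            Q = np.concatenate([Q, (resid / norm)[:, None]], axis=1)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropped collinear design columns: {dropped}")
    return X[:, kept], [names[j] for j in kept]


def aic(y, X) -> float:
    """Gaussian OLS AIC of ``y ~ X`` (X must already include any intercept)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise RankDeficientError(f"n={n} rows but k={k} parameters")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise RankDeficientError("design rank-deficient; prune collinear columns first")
    resid = y - X @ beta
    rss = max(float(resid @ resid), RSS_FLOOR)
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1)


def select_covariates(
    y,
    covariates: pd.DataFrame,
    candidates=OPTIONAL_EFFECTS,
    ps_column: str = "cluster",
    threshold: float = -10.0,
    trait: str = "",
) -> ModelSpec:
    """Single-extension delta-AIC selection against the stratification-only null.

    ``covariates`` must contain ``ps_column`` plus every candidate column;
    rows with any missing value among (y, ps, candidate) are dropped
    listwise per comparison. Candidates with a single level are skipped with
    a warning.
    """
    y = np.asarray(y, dtype=float)
    ps_effects = [ps_column] if covariates[ps_column].nunique() > 1 else []
    base_ok = np.isfinite(y) & covariates[ps_column].notna().to_numpy()

    delta: dict = {}
    included = []
    for eff in candidates:
        vals = covariates[eff]
        ok = base_ok & vals.notna().to_numpy()
        if vals[ok].nunique() < 2:
            warnings.warn(f"candidate {eff!r} has a single level; skipped")
            continue
        sub = covariates.loc[ok]
        X0, _ = build_design(sub, ps_effects)
        X1, _ = build_design(sub, ps_effects + [eff])
        d = aic(y[ok], X1) - aic(y[ok], X0)
        delta[eff] = d
        if d <= threshold:
            included.append(eff)
    spec = ModelSpec(trait=trait, included=tuple(included), delta_aic=delta)
    logger.info("model selection %s: included=%s", trait, spec.included)
    return spec


def selection_table(specs: dict) -> pd.DataFrame:
    """Long-format delta-AIC/inclusion table across traits (one row per test)."""
    rows = []
    for trait, spec in specs.items():
        for eff, d in spec.delta_aic.items():
            rows.append(
                {
                    "trait": trait,
                    "effect": eff,
                    "delta_aic": d,
                    "included": eff in spec.included,
                }
            )
    return pd.DataFrame(rows, columns=["trait", "effect", "delta_aic", "included"])
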