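"""Per-feature linear mixed-model screen for a material effect.

Each of the 36 feature columns is fit with::

    y_ij = beta0 + beta1 * I(material == water) + u_i + e_ij

with a participant random intercept ``u_i ~ N(0, sigma_u^2)`` and residual
``e_ij ~ N(0, sigma^2)``; the material effect is tested with a two-sided Wald
test (normal reference) on the REML estimate at ``alpha = 0.05``.  No
multiple-testing correction is applied: the screen reports raw per-feature
rejections.  Rows missing a feature value are dropped per feature, not
listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

KEY_COLUMNS = ("participant_id", "swallow_index", "material")


@dataclass
class MixedModelSpec:
    alpha: float = 0.05
    reference_material: str = "barium"
    treatment_material: str = "water"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class FeatureScreenStat:
    feature: str
    beta1_hat: float
    std_error: float
    p_value: float
    rejected: bool
    n_used: int
    converged: bool = True


@dataclass
class ScreenResult:
    per_feature: List[FeatureScreenStat]
    alpha: float
    n_dropped_missing: int = 0

    @property
    def n_total(self) -> int:
        return sum(1 for s in self.per_feature if s.converged)

    @property
    def n_rejected(self) -> int:
        return sum(1 for s in self.per_feature if s.converged and s.rejected)

    @property
    def rejected_features(self) -> List[str]:
        return [s.feature for s in self.per_feature if s.converged and s.rejected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": s.feature,
                    "beta1_hat": s.beta1_hat,
                    "std_error": s.std_error,
                    "p_value": s.p_value,
                    "rejected": s.rejected,
                    "n_used": s.n_used,
                    "converged": s.converged,
                }
                for s in self.per_feature
            ]
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_rejected": self.n_rejected,
            "n_total": self.n_total,
            "n_dropped_missing": self.n_dropped_missing,
            "rejected_features": self.rejected_features,
            "per_feature": self.to_frame().to_dict(orient="records"),
        }


def _profile_reml_fallback(
    y: np.ndarray, water: np.ndarray, groups: np.ndarray
) -> Optional[Tuple[float, float]]:
    """Profile-likelihood grid over the variance ratio as a convergence fallback.

    For each candidate ratio ``lam = sigma_u^2 / sigma^2`` the GLS estimate of
    (beta0, beta1) and its covariance are closed-form (Woodbury per
    participant block); the REML criterion is evaluated on a log-spaced grid
    and the best point returned as (beta1_hat, se).
    """
    X = np.column_stack([np.ones_like(water), water])
    uniq = np.unique(groups)
    blocks = [np.where(groups == g)[0] for g in uniq]
    best = None
    for lam in np.logspace(-6, 3, 60):
        XtVX = np.zeros((2, 2))
        XtVy = np.zeros(2)
        logdet = 0.0
        yty = 0.0
        for idx in blocks:
            m = len(idx)
            Xb, yb = X[idx], y[idx]
            w = lam / (1.0 + lam * m)
            XtVX += Xb.T @ Xb - w * np.outer(Xb.sum(0), Xb.sum(0))
            XtVy += Xb.T @ yb - w * Xb.sum(0) * yb.sum()
            yty += yb @ yb - w * yb.sum() ** 2
            logdet += np.log1p(lam * m)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            continue
        n = len(y)
        rss = yty - XtVy @ beta
        if rss <= 0:
            continue
        sigma2 = rss / (n - 2)
        sign, logdet_x = np.linalg.slogdet(XtVX)
        if sign <= 0:
            continue
        reml = -0.5 * ((n - 2) * np.log(sigma2) + logdet + logdet_x)
        if best is None or reml > best[0]:
            cov = sigma2 * np.linalg.inv(XtVX)
            best = (reml, float(beta[1]), float(np.sqrt(cov[1, 1])))
    if best is None:
        return None
    return best[1], best[2]


def fit_material_mixed_model(
    values: Sequence[float],
    material_labels: Sequence[str],
    participant_ids: Sequence[str],
    spec: Optional[MixedModelSpec] = None,
) -> Tuple[float, float, float]:
    """REML fit of the random-intercept material model for one feature.

    Returns ``(beta1_hat, std_error, p_value)`` where ``beta1`` is the
    water-minus-barium fixed effect and the p-value is a two-sided Wald test
    against a standard normal reference.
    """
    import statsmodels.api as sm

    spec = spec or MixedModelSpec()
    y = np.asarray(values, dtype=float)
    material = np.asarray(material_labels)
    groups = np.asarray(participant_ids)
    mask = np.isfinite(y)
    y, material, groups = y[mask], material[mask], groups[mask]
    present = set(material)
    if spec.treatment_material not in present or spec.reference_material not in present:
        raise ValueError(f"both materials required, found {sorted(present)}")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 participants")
    water = (material == spec.treatment_material).astype(float)
    exog = np.column_stack([np.ones_like(water), water])

    beta1 = se = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                model = sm.MixedLM(y, exog, groups=groups)
                fit = model.fit(reml=True, method=method)
                beta1 = float(fit.fe_params[1])
                se = float(fit.bse_fe[1])
                if np.isfinite(beta1) and np.isfinite(se) and se > 0:
                    break
            except Exception:
                continue
    if not (np.isfinite(beta1) and np.isfinite(se) and se > 0):
        fallback = _profile_reml_fallback(y, water, groups)
        if fallback is None:
            raise RuntimeError("mixed model did not converge")
        beta1, se = fallback
    z = beta1 / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta1, se, p


def run_feature_screen(
    table: pd.DataFrame,
    spec: Optional[MixedModelSpec] = None,
    feature_columns: Optional[List[str]] = None,
) -> ScreenResult:
    """Screen every feature column of a feature table.

    One mixed model per feature; a feature whose fit fails even through the
    profile fallback is reported unscreened (``converged=False``) and excluded
    from the totals.
    """
    spec = spec or MixedModelSpec()
    if table.empty:
        raise ValueError("empty feature table")
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c not in KEY_COLUMNS]
    stats_out: List[FeatureScreenStat] = []
    n_dropped = 0
    for col in feature_columns:
        y = table[col].to_numpy(dtype=float)
        n_missing = int((~np.isfinite(y)).sum())
        n_dropped += n_missing
        try:
            beta1, se, p = fit_material_mixed_model(
                y, table["material"].to_numpy(), table["participant_id"].to_numpy(), spec
            )
            stats_out.append(
                FeatureScreenStat(
                    feature=col,
                    beta1_hat=beta1,
                    std_error=se,
                    p_value=p,
                    rejected=bool(p < spec.alpha),
                    n_used=len(y) - n_missing,
                )
            )
        except RuntimeError:
            stats_out.append(
                FeatureScreenStat(
                    feature=col,
                    beta1_hat=np.nan,
                    std_error=np.nan,
                    p_value=np.nan,
                    rejected=False,
                    n_used=len(y) - n_missing,
                    converged=False,
                )
            )
    return ScreenResult(per_feature=stats_out, alpha=spec.alpha, n_dropped_missing=n_dropped)
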