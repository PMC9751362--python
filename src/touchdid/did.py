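"""Difference-in-differences and event-study estimators on the rolling panel.

Three specifications share the Gamma/inverse-link GLM of :mod:`.glm`:

overall
    ``1/Y = alpha (Treat x Post) + gamma Post + mu_g + const``
waves
    one interaction and one main effect per infection wave
    (February-June, July-November, December-January of year two/three)
event study
    a separate treatment-control contrast for every event-time month
    ``k = -6..11`` except the reference ``k = -1`` (January of year two),
    plus month-of-window main effects.  Pre-event coefficients (k < 0)
    diagnose the parallel-trends assumption.

The treatment group is absorbed into the intercept and ``mu_g`` is
estimated for the six control groups.  The common period main effects
(``Post``, wave, month-of-window) realise the double difference of the
design — the treated pre/post contrast net of the control-group contrast —
and with them the contrast cancels shared seasonality and long-term trend;
``time_effects=False`` drops them, leaving the within-treatment-group
contrast only.

Because the link is ``1/mu``, coefficient signs are reversed relative to
the response: every interaction is therefore also reported as an average
response-scale effect (absolute and relative), with confidence limits
mapped through the monotone link so that a response-scale interval
excludes zero exactly when the coefficient interval does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import SupportError
from .glm import GammaInverseGLM, GlmFit
from .panel import MONTHS_PER_GROUP, REFERENCE_K

REQUIRED_COLUMNS = ("group_id", "treat", "month_index", "post",
                    "first", "second", "third", "k", "y")


@dataclass
class DIDEstimate:
    """Tidy result of one DID fit: per-interaction coefficients, Wald
    inference and response-scale effects."""

    model: str
    effects: pd.DataFrame
    glm: GlmFit

    @property
    def significant(self) -> dict[str, bool]:
        return dict(zip(self.effects["term"], self.effects["significant"]))


def subset_dataset(panel: pd.DataFrame, attitude: str | None = None,
                   animacy: str | None = None) -> pd.DataFrame:
    """Select one attitude-by-animacy dataset from a combined panel."""
    out = panel
    if attitude is not None:
        out = out[out["attitude"] == attitude]
    if animacy is not None:
        out = out[out["animacy"] == animacy]
    return out.reset_index(drop=True)


def _check_single_dataset(panel: pd.DataFrame) -> None:
    for col in ("attitude", "animacy"):
        if col in panel.columns and panel[col].nunique() > 1:
            raise ValueError(
                f"panel mixes several {col} values; select one dataset first "
                "(see subset_dataset)"
            )


class _BasePanelGLM(BaseEstimator):
    """Shared fitting machinery for the DID and event-study estimators."""

    def __init__(self, time_effects: bool = True, zero_policy: str = "shift",
                 cluster_robust: bool = False, alpha: float = 0.05,
                 tol: float = 1e-8, max_iter: int = 100):
        self.time_effects = time_effects
        self.zero_policy = zero_policy
        self.cluster_robust = cluster_robust
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    # -- design ---------------------------------------------------------- #

    def _interaction_terms(self, panel: pd.DataFrame) -> dict[str, pd.Series]:
        raise NotImplementedError

    def _main_terms(self, panel: pd.DataFrame) -> dict[str, pd.Series]:
        raise NotImplementedError

    def _build_design(self, panel: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(index=panel.index)
        X["const"] = 1.0
        group_key = "start_year" if "start_year" in panel.columns else "group_id"
        control_levels = sorted(panel.loc[panel["treat"] == 0, group_key].unique())
        for lev in control_levels:
            X[f"mu_{lev}"] = ((panel[group_key] == lev) & (panel["treat"] == 0)).astype(float)
        if self.time_effects:
            for name, col in self._main_terms(panel).items():
                X[name] = col.astype(float)
        for name, col in self._interaction_terms(panel).items():
            X[name] = col.astype(float)
        return X

    # -- response -------------------------------------------------------- #

    def _prepare_y(self, panel: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        y = panel["y"].to_numpy(dtype=float)
        if (y < 0).any():
            raise SupportError("negative response values")
        zeros = y == 0
        if zeros.any():
            if self.zero_policy == "error":
                raise SupportError(f"{int(zeros.sum())} zero responses")
            if self.zero_policy == "drop":
                keep = ~zeros
                return panel.loc[keep].reset_index(drop=True), y[keep]
            if self.zero_policy != "shift":
                raise ValueError(f"unknown zero_policy {self.zero_policy!r}")
            shift = 0.5 * y[~zeros].min()
            warnings.warn(
                f"shifted {int(zeros.sum())} zero responses by {shift:.3g} "
                "(half the smallest positive value); Gamma support excludes 0",
                stacklevel=3,
            )
            y = np.where(zeros, shift, y)
        return panel, y

    def _fit_glm(self, panel: pd.DataFrame) -> tuple[pd.DataFrame, GammaInverseGLM]:
        _check_single_dataset(panel)
        missing = [c for c in REQUIRED_COLUMNS if c not in panel.columns]
        if missing:
            raise ValueError(f"panel lacks required columns: {missing}")
        panel, y = self._prepare_y(panel.reset_index(drop=True))
        X = self._build_design(panel)
        cluster = None
        if self.cluster_robust:
            cluster = (panel["group_id"].astype(str) + ":" + panel["month_index"].astype(str)).to_numpy()
        glm = GammaInverseGLM(fit_intercept=False, tol=self.tol,
                              max_iter=self.max_iter, cluster=cluster)
        glm.fit(X, y)
        return panel, glm

    # -- response-scale effects ------------------------------------------ #

    def _effect_row(self, glm: GammaInverseGLM, X: pd.DataFrame, term: str) -> dict:
        names = glm.param_names_
        j = names.index(term)
        beta = glm.params_[j]
        se = float(np.sqrt(glm.cov_.iloc[j, j]))
        z = beta / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        zcrit = stats.norm.ppf(1 - self.alpha / 2)
        lo, hi = beta - zcrit * se, beta + zcrit * se

        active = X[term].to_numpy() == 1.0
        eta1 = (X.to_numpy() @ glm.params_)[active]
        eta0 = eta1 - beta
        row = {
            "term": term, "coef": beta, "se": se, "z": z, "p_value": p,
            "ci_lo": lo, "ci_hi": hi, "significant": bool(p < self.alpha),
        }
        if (eta1 > 0).all() and (eta0 > 0).all():
            mu1, mu0 = 1.0 / eta1, 1.0 / eta0

            def _abs(b: float) -> float:
                return float(np.mean(1.0 / (eta0 + b) - mu0))

            def _rel(b: float) -> float:
                return float(np.mean(1.0 / (eta0 + b)) / np.mean(mu0) - 1.0)

            # the link is monotone decreasing, so CI endpoints swap
            row.update(
                effect_abs=float(np.mean(mu1 - mu0)),
                effect_abs_lo=_abs(hi), effect_abs_hi=_abs(lo),
                effect_rel=_rel(beta),
                effect_rel_lo=_rel(hi), effect_rel_hi=_rel(lo),
            )
        else:
            warnings.warn(
                f"linear predictor non-positive for term {term}; "
                "response-scale effect undefined", stacklevel=3,
            )
            row.update(effect_abs=np.nan, effect_abs_lo=np.nan, effect_abs_hi=np.nan,
                       effect_rel=np.nan, effect_rel_lo=np.nan, effect_rel_hi=np.nan)
        return row


class DIDEstimator(_BasePanelGLM):
    """Overall or wave-specific DID with Gamma/inverse GLM.

    Parameters
    ----------
    model : "overall" or "waves"
    time_effects : bool, default True
        Include the common period main effects (Post or wave dummies).
    zero_policy : "shift" | "drop" | "error", default "shift"
        Zero proportions are outside Gamma support; "shift" adds half the
        smallest positive response, with a warning.
    cluster_robust : bool, default False
        Cluster the covariance by group x month instead of model-based Wald.

    Attributes
    ----------
    estimate_ : DIDEstimate with the tidy effects table
    effects_ : the same table (DataFrame)
    glm_ : the underlying fitted GammaInverseGLM
    """

    def __init__(self, model: str = "overall", time_effects: bool = True,
                 zero_policy: str = "shift", cluster_robust: bool = False,
                 alpha: float = 0.05, tol: float = 1e-8, max_iter: int = 100):
        super().__init__(time_effects=time_effects, zero_policy=zero_policy,
                         cluster_robust=cluster_robust, alpha=alpha,
                         tol=tol, max_iter=max_iter)
        self.model = model

    def _main_terms(self, panel):
        if self.model == "overall":
            return {"post": panel["post"]}
        return {"first": panel["first"], "second": panel["second"],
                "third": panel["third"]}

    def _interaction_terms(self, panel):
        t = panel["treat"]
        if self.model == "overall":
            return {"treat_post": t * panel["post"]}
        if self.model == "waves":
            return {"treat_first": t * panel["first"],
                    "treat_second": t * panel["second"],
                    "treat_third": t * panel["third"]}
        raise ValueError(f"unknown model {self.model!r}")

    def fit(self, panel: pd.DataFrame, y=None):
        panel, glm = self._fit_glm(panel)
        X = self._build_design(panel)
        rows = [self._effect_row(glm, X, t) for t in self._interaction_terms(panel)]
        self.glm_ = glm
        self.effects_ = pd.DataFrame(rows)
        self.estimate_ = DIDEstimate(model=self.model, effects=self.effects_,
                                     glm=glm.glm_fit())
        return self

    def summary(self) -> pd.DataFrame:
        return self.effects_


class EventStudyEstimator(_BasePanelGLM):
    """Per-event-time treatment contrasts ``alpha_k`` (k = -6..11, k = -1
    omitted), with month-of-window main effects when ``time_effects``.

    Attributes
    ----------
    curve_ : DataFrame with one row per k in -6..11: coef (0 at the
        reference), se, ci_lo, ci_hi, significant.
    """

    REFERENCE_MONTH_INDEX = REFERENCE_K + 7  # January of year two

    def _main_terms(self, panel):
        return {
            f"month_{m}": (panel["month_index"] == m).astype(float)
            for m in range(1, MONTHS_PER_GROUP + 1)
            if m != self.REFERENCE_MONTH_INDEX
        }

    def _interaction_terms(self, panel):
        t = panel["treat"]
        return {
            f"k_{k}": t * (panel["k"] == k).astype(float)
            for k in range(-6, 12)
            if k != REFERENCE_K
        }

    def fit(self, panel: pd.DataFrame, y=None):
        panel, glm = self._fit_glm(panel)
        X = self._build_design(panel)
        rows = []
        for k in range(-6, 12):
            if k == REFERENCE_K:
                rows.append({"k": k, "term": f"k_{k}", "coef": 0.0, "se": 0.0,
                             "z": np.nan, "p_value": np.nan, "ci_lo": 0.0,
                             "ci_hi": 0.0, "significant": False,
                             "effect_abs": 0.0, "effect_abs_lo": 0.0,
                             "effect_abs_hi": 0.0, "effect_rel": 0.0,
                             "effect_rel_lo": 0.0, "effect_rel_hi": 0.0})
                continue
            row = self._effect_row(glm, X, f"k_{k}")
            rows.append({"k": k} | row)
        self.glm_ = glm
        self.curve_ = pd.DataFrame(rows)
        return self


# --------------------------------------------------------------------------- #
# functional wrappers
# --------------------------------------------------------------------------- #

def estimate_did_overall(panel: pd.DataFrame, **kwargs) -> DIDEstimate:
    return DIDEstimator(model="overall", **kwargs).fit(panel).estimate_


def estimate_did_waves(panel: pd.DataFrame, **kwargs) -> DIDEstimate:
    return DIDEstimator(model="waves", **kwargs).fit(panel).estimate_


def event_study(panel: pd.DataFrame, **kwargs) -> pd.DataFrame:
    return EventStudyEstimator(**kwargs).fit(panel).curve_
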