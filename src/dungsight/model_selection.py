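"""AICc ranking, Akaike weights, confidence sets and model averaging.

The candidate set follows a two-stage screen: every univariate density
model is fitted first, then multivariate models (with all two-way
interaction variants) are built from the best-ranked univariate predictors.
Relative support is summarized by Akaike weights
w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2); a 95% confidence set
collects top-ranked models until their cumulative weight reaches 0.95.
Coefficients are model-averaged with unconditional standard errors that
fold model-selection uncertainty into the sampling variance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integrated import FittedModel, ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["build_candidates", "delta_aicc", "akaike_weights", "confidence_set",
           "predictor_importance", "model_average", "ModelSet", "rank_models"]


def build_candidates(species: str, predictors, univariate_ranking=None,
                     top_m: int = 2, include_null: bool = True):
    """Enumerate candidate model specs from the two-stage rule.

    All univariate specs are always included.  If ``univariate_ranking`` (a
    list of predictor names ordered best-first, e.g. by univariate AICc) is
    given, the ``top_m`` leaders are combined into all two-predictor
    additive models and their interaction variants.  The global null
    (intercept + random effect only) closes the set.
    """
    predictors = list(predictors)
    if len(set(predictors)) != len(predictors):
        raise ValueError("duplicate predictor names")
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    if top_m > len(predictors):
        logger.warning("top_m=%d exceeds %d predictors; clamping",
                       top_m, len(predictors))
        top_m = len(predictors)
    specs = []
    if include_null:
        specs.append(ModelSpec(species=species, terms=()))
    for p in predictors:
        specs.append(ModelSpec(species=species, terms=(p,)))
    leaders = (univariate_ranking or predictors)[:top_m]
    for a, b in itertools.combinations(leaders, 2):
        specs.append(ModelSpec(species=species, terms=(a, b)))
        specs.append(ModelSpec(species=species, terms=(a, b),
                               interactions=((a, b),)))
    seen, out = set(), []
    for s in specs:
        if s.name not in seen:
            seen.add(s.name)
            out.append(s)
    return out


def delta_aicc(aicc_values) -> np.ndarray:
    """AICc differences Delta_i = AICc_i - min AICc."""
    a = np.asarray(aicc_values, float)
    if not np.all(np.isfinite(a)):
        raise ValueError("AICc values must be finite")
    return a - a.min()


def akaike_weights(delta) -> np.ndarray:
    """w_i = exp(-Delta_i/2), normalized over the candidate set."""
    d = np.asarray(delta, float)
    rel = np.exp(-0.5 * (d - d.min()))
    return rel / rel.sum()


def confidence_set(weights, level: float = 0.95) -> np.ndarray:
    """Membership flags for the smallest top-weight prefix reaching ``level``.

    ``weights`` must already be sorted descending; the model whose
    cumulative weight first reaches the level is included.
    """
    if not (0.0 < level <= 1.0):
        raise ValueError(f"level must be in (0, 1], got {level}")
    w = np.asarray(weights, float)
    if np.any(np.diff(w) > 1e-12):
        raise ValueError("weights must be sorted in descending order")
    cum = np.cumsum(w)
    flags = np.zeros(len(w), bool)
    # include models until the cumulative weight reaches the level
    cut = int(np.searchsorted(cum, level - 1e-12)) + 1
    flags[:min(cut, len(w))] = True
    return flags


@dataclass
class ModelSet:
    """A ranked candidate set with weights and confidence-set flags."""

    models: list                 # FittedModel, ranked
    table: pd.DataFrame          # model, k, loglik, AICc, delta, weight, cum, in set

    def confidence_models(self):
        flags = self.table["in_confidence_set"].to_numpy()
        return [m for m, f in zip(self.models, flags) if f]


def rank_models(fitted_models, level: float = 0.95) -> ModelSet:
    """Rank fitted models by AICc and attach weights and set membership.

    Ties in AICc are broken by ascending parameter count then model name,
    so the table is deterministic.
    """
    models = [m for m in fitted_models if m.converged and np.isfinite(m.aicc)]
    dropped = len(list(fitted_models)) - len(models)
    if dropped:
        logger.warning("dropping %d non-converged model(s) from ranking", dropped)
    if not models:
        raise ValueError("no converged models to rank")
    models = sorted(models, key=lambda m: (m.aicc, m.k, m.spec.name))
    a = np.array([m.aicc for m in models])
    d = delta_aicc(a)
    w = akaike_weights(d)
    flags = confidence_set(w, level)
    table = pd.DataFrame({
        "model": [m.spec.name for m in models],
        "k": [m.k for m in models],
        "loglik": [m.loglik for m in models],
        "aicc": a,
        "delta_aicc": d,
        "weight": w,
        "cum_weight": np.cumsum(w),
        "in_confidence_set": flags,
    })
    return ModelSet(models=models, table=table)


def _models_with(model_set: ModelSet, predictor: str):
    out = []
    for m, w in zip(model_set.models, model_set.table["weight"]):
        terms = set(m.spec.terms) | {t for ab in m.spec.interactions for t in ab}
        if predictor in terms:
            out.append((m, float(w)))
    return out


def predictor_importance(model_set: ModelSet) -> pd.Series:
    """Summed Akaike weight per predictor (main effect or interaction)."""
    preds = {}
    for m, w in zip(model_set.models, model_set.table["weight"]):
        terms = set(m.spec.terms) | {t for ab in m.spec.interactions for t in ab}
        for t in terms:
            preds[t] = preds.get(t, 0.0) + float(w)
    return pd.Series(preds).sort_values(ascending=False)


def model_average(model_set: ModelSet, predictor: str,
                  mode: str = "subset") -> dict:
    """Model-averaged coefficient for one predictor with unconditional SE.

    ``mode="subset"`` renormalizes weights over the models containing the
    predictor; ``mode="full"`` averages over the entire candidate set with
    absent models contributing a zero coefficient.  The unconditional SE is
    sqrt(sum w_i (se_i^2 + (beta_i - beta_bar)^2)) and the 95% CI is the
    usual normal interval around the average.
    """
    if mode not in ("subset", "full"):
        raise ValueError(f"mode must be 'subset' or 'full', got {mode!r}")
    containing = _models_with(model_set, predictor)
    if not containing:
        raise ValueError(f"predictor {predictor!r} absent from all models")

    entries = []  # (weight, beta, se)
    for m, w in containing:
        try:
            idx = m.data.colnames.index(predictor)
        except ValueError:
            # present only through an interaction; main effect absent
            continue
        se = m.se[idx] if m.se is not None else np.nan
        entries.append((w, float(m.beta[idx]), float(se)))
    if not entries:
        raise ValueError(
            f"predictor {predictor!r} has no main-effect coefficient to average")

    wts = np.array([e[0] for e in entries])
    betas = np.array([e[1] for e in entries])
    ses = np.array([e[2] for e in entries])
    if mode == "subset":
        wts = wts / wts.sum()
        beta_bar = float(np.sum(wts * betas))
        var = np.sum(wts * (np.nan_to_num(ses) ** 2 + (betas - beta_bar) ** 2))
    else:
        beta_bar = float(np.sum(wts * betas))  # absent models add w * 0
        var = np.sum(wts * (np.nan_to_num(ses) ** 2 + (betas - beta_bar) ** 2))
        w_out = 1.0 - wts.sum()
        var += w_out * beta_bar ** 2           # zero-coefficient models
    se_u = float(np.sqrt(var))
    return {"predictor": predictor, "mode": mode, "estimate": beta_bar,
            "se": se_u, "ci_lo": beta_bar - 1.96 * se_u,
            "ci_hi": beta_bar + 1.96 * se_u}
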