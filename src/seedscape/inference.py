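"""All-subsets AICc model selection and multimodel averaging.

Given a response and a small set of landscape predictors fixed at their
selected scales (the "global model"), every subset of the predictors plus
the intercept-only null model is fitted by Gaussian OLS and ranked by the
small-sample Akaike information criterion::

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1)

with k counting the intercept, the slopes and the residual variance. Akaike
weights ``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` are computed over
the full candidate set; models with delta AICc < 2 are flagged as best
supported. The 95% confidence set is the shortest ranking prefix whose
cumulative weight reaches 0.95 (the crossing model included). Within that
set (weights renormalized) coefficients are model-averaged over *all*
models — a term absent from a model contributes zero (full averaging) — with
the Burnham–Anderson unconditional standard error

    USE_j = sum_i w_i * sqrt( var(beta_ij) + (beta_ij - betabar_j)^2 )

and a term's relative importance is the summed weight of the models that
contain it. A term is flagged influential when betabar_j ± USE_j excludes
zero. Collinearity among the global model's terms is screened beforehand by
variance inflation factors (flagging threshold VIF >= 4).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import (
    AveragedEstimate,
    CandidateModel,
    ConfigError,
    GlobalModelSpec,
)

__all__ = [
    "vif_screen",
    "enumerate_models",
    "fit_and_rank",
    "confidence_set",
    "model_average",
    "run_inference",
    "InferenceReport",
]

VIF_THRESHOLD = 4.0
DELTA_SUPPORT = 2.0
CONFIDENCE_LEVEL = 0.95


def vif_screen(design: pd.DataFrame, threshold: float = VIF_THRESHOLD) -> pd.Series:
    """Variance inflation factor of each column of a design matrix.

    ``VIF_j = 1 / (1 - R²_j)`` from regressing column j on the others.
    Perfectly collinear columns yield ``inf`` (flagged, not raised). A
    single-column design trivially has VIF 1.
    """
    if design.shape[1] < 1:
        raise ConfigError("design matrix needs at least one column")
    if design.isna().any().any():
        raise ConfigError("design matrix contains missing values")
    vifs = {}
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        if np.allclose(X[:, j], X[0, j]):
            raise ConfigError(f"predictor {name!r} is constant")
        if len(cols) == 1:
            vifs[name] = 1.0
            continue
        others = sm.add_constant(np.delete(X, j, axis=1))
        fit = sm.OLS(X[:, j], others).fit()
        r2 = min(fit.rsquared, 1.0)
        vifs[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs, name="vif")


def enumerate_models(spec: GlobalModelSpec | Sequence[str]) -> list[CandidateModel]:
    """All subsets of the global model's terms, including the null model.

    Deterministic order: by subset size then lexicographically by term
    position in the global model.
    """
    terms = spec.term_names() if isinstance(spec, GlobalModelSpec) else tuple(spec)
    if len(terms) > 6:
        raise ConfigError("global models are limited to 6 terms")
    if len(set(terms)) != len(terms):
        raise ConfigError("duplicate terms in global model")
    out = []
    for size in range(len(terms) + 1):
        for combo in combinations(range(len(terms)), size):
            out.append(CandidateModel(terms=tuple(terms[i] for i in combo)))
    return out


def _fit_candidate(
    cand: CandidateModel, y: np.ndarray, data: pd.DataFrame
) -> CandidateModel | None:
    n = len(y)
    X = sm.add_constant(
        data.loc[:, list(cand.terms)].to_numpy(dtype=float), has_constant="add"
    )
    p = X.shape[1]
    k = p + 1  # + residual variance
    if n <= k + 1:
        return None  # AICc denominator would be non-positive
    fit = sm.OLS(y, X).fit()
    aicc = -2.0 * fit.llf + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)
    names = ("const",) + cand.terms
    return CandidateModel(
        terms=cand.terms,
        k=k,
        loglik=float(fit.llf),
        aicc=float(aicc),
        coef={nm: float(b) for nm, b in zip(names, fit.params)},
        se={nm: float(s) for nm, s in zip(names, fit.bse)},
    )


def fit_and_rank(
    candidates: Iterable[CandidateModel],
    response: Sequence[float] | pd.Series,
    data: pd.DataFrame,
) -> list[CandidateModel]:
    """Fit every candidate by Gaussian OLS and rank ascending by AICc.

    Candidates too large for the sample (n <= k + 1) are skipped. Deltas and
    Akaike weights are computed over the full fitted set; models with
    delta < 2 are flagged best-supported.
    """
    y = np.asarray(response, dtype=float)
    fitted = []
    for cand in candidates:
        res = _fit_candidate(cand, y, data)
        if res is not None:
            fitted.append(res)
    if not fitted:
        raise ConfigError("no candidate could be fitted")
    fitted.sort(key=lambda c: (c.aicc, len(c.terms), c.terms))
    best = fitted[0].aicc
    deltas = np.array([c.aicc - best for c in fitted])
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    for cand, d, wi in zip(fitted, deltas, w):
        cand.delta = float(d)
        cand.weight = float(wi)
        cand.best_supported = bool(d < DELTA_SUPPORT)
    return fitted


def confidence_set(
    ranked: Sequence[CandidateModel], level: float = CONFIDENCE_LEVEL
) -> list[CandidateModel]:
    """Shortest ranking prefix with cumulative Akaike weight >= level."""
    if not ranked:
        raise ConfigError("empty ranking")
    out = []
    cum = 0.0
    for cand in ranked:
        out.append(cand)
        cum += cand.weight
        if cum >= level - 1e-12:
            break
    return out


def model_average(conf_set: Sequence[CandidateModel]) -> list[AveragedEstimate]:
    """Full (zero-substitution) model-averaged estimates over a model set.

    Weights are renormalized within the set. Absent terms contribute 0 to
    the average and to the squared-deviation part of the USE.
    """
    if not conf_set:
        raise ConfigError("empty model set")
    w = np.array([c.weight for c in conf_set], dtype=float)
    if not np.all(np.isfinite(w)) or w.sum() <= 0:
        raise ConfigError("model weights must be computed before averaging")
    w = w / w.sum()
    terms: list[str] = []
    for c in conf_set:
        for t in c.terms:
            if t not in terms:
                terms.append(t)
    out = []
    for t in terms:
        betas = np.array([c.coef.get(t, 0.0) for c in conf_set])
        ses = np.array([c.se.get(t, 0.0) for c in conf_set])
        present = np.array([t in c.terms for c in conf_set])
        beta_bar = float(np.sum(w * betas))
        use = float(np.sum(w * np.sqrt(ses**2 + (betas - beta_bar) ** 2)))
        importance = float(np.sum(w[present]))
        influential = bool(
            (beta_bar - use > 0 and beta_bar + use > 0)
            or (beta_bar - use < 0 and beta_bar + use < 0)
        )
        out.append(
            AveragedEstimate(
                term=t,
                coefficient=beta_bar,
                use=use,
                importance=importance,
                influential=influential,
            )
        )
    return out


@dataclass
class InferenceReport:
    """Per-response outcome of the multimodel-inference stage."""

    response: str
    vif: pd.Series
    ranking: list[CandidateModel]
    confidence: list[CandidateModel]
    averaged: list[AveragedEstimate]
    aborted: str | None = None


def _term_column(
    metric_table: pd.DataFrame, metric: str, radius: float
) -> pd.Series:
    sub = metric_table[
        (metric_table["metric"] == metric)
        & (metric_table["radius_m"] == float(radius))
    ]
    if sub.empty:
        raise ConfigError(f"metric table lacks {metric} at {radius} m")
    return sub.set_index("patch_id")["value"]


def run_inference(
    global_specs: Iterable[GlobalModelSpec],
    diversity_table: pd.DataFrame,
    metric_table: pd.DataFrame,
    vif_threshold: float = VIF_THRESHOLD,
) -> list[InferenceReport]:
    """VIF screen -> all-subsets AICc ranking -> 95% set -> averaging.

    ``diversity_table`` must have one column per response name indexed by
    patch_id (or columns patch_id + response names). A response whose global
    model fails the VIF screen is aborted with a diagnostic rather than
    silently re-specified: dropping a term is the caller's decision.
    """
    div = diversity_table
    if "patch_id" in div.columns:
        div = div.set_index("patch_id")
    reports = []
    for spec in global_specs:
        if spec.response not in div.columns:
            raise ConfigError(f"unknown response {spec.response!r}")
        design = pd.DataFrame(
            {
                f"{m}_{int(r)}": _term_column(metric_table, m, r)
                for m, r in spec.terms
            }
        )
        joined = design.join(div[spec.response], how="inner").dropna()
        y = joined[spec.response]
        X = joined[list(design.columns)]
        vifs = vif_screen(X, threshold=vif_threshold) if X.shape[1] >= 2 else pd.Series(
            {c: 1.0 for c in X.columns}, name="vif"
        )
        if (vifs >= vif_threshold).any():
            bad = ", ".join(vifs[vifs >= vif_threshold].index)
            reports.append(
                InferenceReport(
                    response=spec.response,
                    vif=vifs,
                    ranking=[],
                    confidence=[],
                    averaged=[],
                    aborted=f"collinear terms (VIF >= {vif_threshold}): {bad}",
                )
            )
            continue
        ranked = fit_and_rank(enumerate_models(spec), y, X)
        conf = confidence_set(ranked)
        reports.append(
            InferenceReport(
                response=spec.response,
                vif=vifs,
                ranking=ranked,
                confidence=conf,
                averaged=model_average(conf),
            )
        )
    return reports
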