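"""Isolation-by-distance admixture regression and the time-trend model.

The spatial model regresses a per-individual admixture response — an
f4-style allele-sharing statistic or an estimated ancestry proportion —
on least-cost distances from the two source regions:

    y ~ a * dist_whg + b * dist_ag3 + c

fitted by ordinary least squares, with influence diagnostics (leverage,
studentized residuals, Cook's distance) and a reproducible
leverage-removal refit (Cook's D > 4/n by default) replacing visual
inspection of lm diagnostic plots. Observations from SNP-capture assays
and those whose response rests on too few sites (default 5000) are
excluded up front.

The time-trend model is the single-predictor analogue: admixture
proportion on calendar age (cal BP), where a negative coefficient on
cal BP means admixture increasing toward the present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_MIN_SITES = 5000
DEFAULT_COOKS_FACTOR = 4.0


@dataclass
class ClineModel:
    """An OLS fit with per-observation influence diagnostics."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    nobs: int
    diagnostics: pd.DataFrame  # leverage, studentized resid, cooks_d, flagged
    refit: "ClineModel | None" = None

    @property
    def flagged(self) -> list:
        return list(self.diagnostics.index[self.diagnostics["flagged"]])


def assemble_observations(fstat_table: pd.DataFrame,
                          distance_table: pd.DataFrame,
                          meta: pd.DataFrame, *,
                          min_sites: int = DEFAULT_MIN_SITES,
                          response_col: str = "response",
                          distance_choice: str = "min") -> pd.DataFrame:
    """Join responses, distances and metadata into the regression table.

    ``fstat_table`` needs columns (id, response, n_sites); the distance
    table (id, dist_whg, dist_ag3) — or per-choice columns recorded under
    ``distance_choice`` in {'min', 'median', 'total'}. Rows are annotated
    with an ``exclusion`` reason (capture assay, or n_sites below the
    threshold) rather than silently dropped.
    """
    for tab, name in ((fstat_table, "fstat"), (distance_table, "distance")):
        if tab["id"].duplicated().any():
            raise ValueError(f"duplicate join keys in {name} table")
    df = fstat_table.merge(distance_table, on="id", how="inner")
    df = df.merge(meta[["id", "assay"]], on="id", how="left")
    df["distance_choice"] = distance_choice
    reasons = np.full(len(df), "", dtype=object)
    reasons[df["assay"].eq("capture").to_numpy()] = "capture-assay"
    low = (df["n_sites"] < min_sites).to_numpy()
    reasons[low & (reasons == "")] = f"n_sites<{min_sites}"
    df["exclusion"] = reasons
    df["included"] = reasons == ""
    return df


def _fit(y: np.ndarray, X: pd.DataFrame, index,
         cooks_factor: float | None = None) -> ClineModel:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank "
                         f"deficient over columns {list(Xc.columns)}")
    if len(y) <= Xc.shape[1]:
        raise ValueError(
            f"need more than {Xc.shape[1]} observations for "
            f"{Xc.shape[1]} coefficients (no residual df)")
    res = sm.OLS(y, Xc).fit()
    infl = res.get_influence()
    diag = pd.DataFrame({
        "leverage": infl.hat_matrix_diag,
        "studentized_resid": infl.resid_studentized_external,
        "cooks_d": infl.cooks_distance[0],
    }, index=index)
    thresh = (cooks_factor if cooks_factor is not None
              else DEFAULT_COOKS_FACTOR) / len(y)
    diag["flagged"] = diag["cooks_d"] > thresh
    return ClineModel(res.params, res.bse, res.tvalues, res.pvalues,
                      float(res.rsquared), int(res.nobs), diag)


def fit_cline(observations: pd.DataFrame, *,
              response_col: str = "response",
              predictors: tuple[str, str] = ("dist_whg", "dist_ag3"),
              ) -> ClineModel:
    """OLS of the admixture response on the two source distances."""
    obs = observations.loc[observations.get("included", True) == True]  # noqa: E712
    if len(obs) < len(predictors) + 2:
        raise ValueError("need at least 4 included observations")
    return _fit(obs[response_col].to_numpy(), obs[list(predictors)],
                obs["id"] if "id" in obs else obs.index)


def leverage_refit(model: ClineModel, observations: pd.DataFrame, *,
                   response_col: str = "response",
                   predictors: tuple[str, str] = ("dist_whg", "dist_ag3"),
                   cooks_factor: float = DEFAULT_COOKS_FACTOR) -> ClineModel:
    """Refit without points whose Cook's distance exceeds ``factor``/n.

    Returns the original model with ``refit`` attached; with no flagged
    point the refit equals the original fit.
    """
    thresh = cooks_factor / model.nobs
    flagged = set(model.diagnostics.index[
        model.diagnostics["cooks_d"] > thresh])
    obs = observations.loc[observations.get("included", True) == True]  # noqa: E712
    key = obs["id"] if "id" in obs else obs.index
    keep = ~key.isin(flagged)
    if keep.sum() < len(predictors) + 2:
        raise ValueError("leverage removal leaves too few observations")
    sub = obs.loc[keep.to_numpy()]
    refit = _fit(sub[response_col].to_numpy(), sub[list(predictors)],
                 sub["id"] if "id" in sub else sub.index)
    return ClineModel(model.params, model.bse, model.tvalues, model.pvalues,
                      model.rsquared, model.nobs, model.diagnostics, refit)


def admixture_time_trend(alpha_table: pd.DataFrame, *,
                         alpha_col: str = "alpha",
                         age_col: str = "cal_bp_mid",
                         exclusions: list | None = None) -> ClineModel:
    """OLS of admixture proportion on cal BP midpoint.

    Cal BP counts backwards, so a *negative* coefficient on age means the
    proportion increases toward the present. ``exclusions`` (ids with
    extreme values, applied and reported) shrink n accordingly.
    """
    df = alpha_table.copy()
    if exclusions:
        df = df.loc[~df["id"].isin(set(exclusions))]
    if len(df) < 4:
        raise ValueError("need at least 4 observations after exclusions")
    model = _fit(df[alpha_col].to_numpy(), df[[age_col]],
                 df["id"] if "id" in df else df.index)
    model.diagnostics.attrs["n_excluded"] = \
        0 if not exclusions else len(alpha_table) - len(df)
    return model
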