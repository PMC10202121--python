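"""Regression correction of micronutrient biomarkers for inflammation.

The correction model: on the natural-log scale the biomarker is regressed
jointly on ln(AGP) and ln(CRP) (unweighted OLS, complete cases). Each
observation's excess inflammation is then measured as the reference-decile
truncated difference

    ln(marker)_diff = max(ln(marker) - ln(marker_ref), 0)

and the adjusted value is

    ln(MB_adj) = ln(MB_unadj) - beta_AGP * ln(AGP)_diff - beta_CRP * ln(CRP)_diff

exponentiated back to the original units. Observations at or below the
reference decile receive no correction, so a population free of
inflammation is returned unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import qc
from .registry import (
    AGP,
    CRP,
    BiomarkerRule,
    ReferenceValues,
    canonical_biomarker,
    canonical_group,
    external_reference,
    lookup_rule,
)

DEFAULT_MIN_FIT = 30


@dataclass
class AdjustmentModel:
    """Fitted log-log correction model for one biomarker.

    ``beta1`` is the slope on ln(AGP), ``beta2`` the slope on ln(CRP);
    each is present iff the corresponding marker is in ``markers_in_model``.
    Standard errors and 95% confidence bounds from the OLS fit are kept for
    diagnostics and coverage checks. Covariates (e.g. malaria status) enter
    the fit only; the correction itself subtracts only the inflammation
    terms.
    """

    biomarker: str
    markers_in_model: tuple
    intercept: float
    beta1: float | None = None
    beta2: float | None = None
    covariate_coefficients: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    conf_int: dict = field(default_factory=dict)
    n_used: int = 0

    def beta_for(self, marker: str) -> float | None:
        return self.beta1 if marker == AGP else self.beta2


@dataclass
class AdjustmentResult:
    """Per-row adjusted values plus model-level metadata.

    ``frame`` has columns ``mb_unadj``, ``mb_adj``, ``ln_agp_diff``,
    ``ln_crp_diff`` and ``adjusted_flag``. ``mb_adj`` is present iff every
    marker in the model is nonmissing for that row; rows whose truncated
    differences are all zero carry ``mb_adj == mb_unadj`` exactly.
    """

    biomarker: str
    frame: pd.DataFrame
    adjusted: bool
    model: AdjustmentModel | None = None
    refs: ReferenceValues | None = None
    reason: str = ""


def _as_clean_log(values, name: str) -> pd.Series:
    s = pd.to_numeric(pd.Series(values), errors="coerce")
    bad = s.notna() & (s <= 0)
    if bad.any():
        raise ValueError(
            f"{name} contains {int(bad.sum())} nonpositive value(s); the log "
            "transform is undefined — impute below-LoD/zero values first "
            "(see inflammadjust.qc.impute_below_lod)"
        )
    return np.log(s)


def fit_model(
    ln_mb: pd.Series,
    ln_agp: pd.Series | None = None,
    ln_crp: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    biomarker: str = "",
    min_n: int = DEFAULT_MIN_FIT,
) -> AdjustmentModel:
    """Unweighted OLS of ln(biomarker) jointly on ln(AGP) and ln(CRP).

    A single joint model containing every supplied marker (and covariates if
    given) is fitted on complete cases; the regression is unweighted even
    when the survey carries sampling weights.

    Raises on rank deficiency (e.g. a constant marker) or fewer than
    ``min_n`` complete cases.
    """
    if ln_agp is None and ln_crp is None:
        raise ValueError("at least one of ln_agp, ln_crp is required")
    data = {"ln_mb": pd.Series(ln_mb, dtype=float)}
    markers: list[str] = []
    if ln_agp is not None:
        data["ln_agp"] = pd.Series(ln_agp, dtype=float)
        markers.append(AGP)
    if ln_crp is not None:
        data["ln_crp"] = pd.Series(ln_crp, dtype=float)
        markers.append(CRP)
    df = pd.DataFrame(data)
    cov_names: list[str] = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).astype(float)
        cov_names = list(cov.columns)
        df = pd.concat([df, cov], axis=1)
    df = df.dropna()
    if len(df) < min_n:
        raise ValueError(f"only {len(df)} complete cases (< {min_n}); too few to fit")

    exog = sm.add_constant(df.drop(columns="ln_mb"))
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient (constant or collinear column)")
    res = sm.OLS(df["ln_mb"], exog).fit()

    ci = res.conf_int(alpha=0.05)
    model = AdjustmentModel(
        biomarker=biomarker,
        markers_in_model=tuple(markers),
        intercept=float(res.params["const"]),
        beta1=float(res.params["ln_agp"]) if AGP in markers else None,
        beta2=float(res.params["ln_crp"]) if CRP in markers else None,
        covariate_coefficients={c: float(res.params[c]) for c in cov_names},
        stderr={k: float(v) for k, v in res.bse.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
        n_used=int(res.nobs),
    )
    return model


def reference_difference(ln_value, ln_ref: float):
    """Reference-truncated log difference: ``max(ln_value - ln_ref, 0)``.

    Values at or below the reference decile yield 0 (no correction for that
    observation); missing log values propagate as missing. Accepts scalars
    or arrays.
    """
    if not np.isfinite(ln_ref):
        raise ValueError(f"ln_ref must be finite, got {ln_ref!r}")
    diff = np.maximum(np.asarray(ln_value, dtype=float) - ln_ref, 0.0)
    if np.ndim(ln_value) == 0 and not isinstance(ln_value, (pd.Series, np.ndarray)):
        return float(diff)
    if isinstance(ln_value, pd.Series):
        return pd.Series(diff, index=ln_value.index)
    return diff


def apply_adjustment(
    table: pd.DataFrame,
    model: AdjustmentModel,
    refs: ReferenceValues,
    biomarker_col: str | None = None,
    agp_col: str = "agp",
    crp_col: str = "crp",
) -> AdjustmentResult:
    """Apply the fitted correction to every row of a survey table.

    For each row the truncated log differences of the markers in the model
    are computed against ``refs`` and subtracted, weighted by the fitted
    slopes, from the log biomarker; the result is exponentiated back to the
    input units. Rows missing any marker in the model get a missing adjusted
    value rather than a partial correction.
    """
    biomarker_col = biomarker_col or model.biomarker
    if biomarker_col not in table.columns:
        raise KeyError(f"biomarker column {biomarker_col!r} not in table")
    mb = pd.to_numeric(table[biomarker_col], errors="coerce")
    ln_mb = _as_clean_log(mb, biomarker_col)

    marker_cols = {AGP: agp_col, CRP: crp_col}
    diffs: dict[str, pd.Series] = {}
    correction = pd.Series(0.0, index=table.index)
    for marker in model.markers_in_model:
        col = marker_cols[marker]
        ref = refs.ref_for(marker)
        if ref is None:
            raise ValueError(
                f"model uses {marker} but no {marker} reference value was supplied"
            )
        if col not in table.columns:
            raise KeyError(f"model uses {marker} but column {col!r} not in table")
        ln_marker = _as_clean_log(table[col], col)
        d = reference_difference(ln_marker, np.log(ref))
        diffs[marker] = d
        correction = correction + model.beta_for(marker) * d

    out = pd.DataFrame(index=table.index)
    out["mb_unadj"] = mb
    ln_adj = ln_mb - correction
    mb_adj = np.exp(ln_adj)
    # no-correction rows reproduce the input exactly, not just to round-off
    exact = correction == 0.0
    mb_adj[exact] = mb[exact]
    out["mb_adj"] = mb_adj
    out["ln_agp_diff"] = diffs.get(AGP, np.nan)
    out["ln_crp_diff"] = diffs.get(CRP, np.nan)
    out["adjusted_flag"] = correction.notna() & mb.notna()
    out.loc[~out["adjusted_flag"], "mb_adj"] = np.nan
    return AdjustmentResult(
        biomarker=model.biomarker or biomarker_col,
        frame=out,
        adjusted=True,
        model=model,
        refs=refs,
    )


def _unadjusted_result(table, biomarker_col, biomarker, reason) -> AdjustmentResult:
    mb = pd.to_numeric(table[biomarker_col], errors="coerce")
    frame = pd.DataFrame(
        {
            "mb_unadj": mb,
            "mb_adj": mb,
            "ln_agp_diff": np.nan,
            "ln_crp_diff": np.nan,
            "adjusted_flag": False,
        },
        index=table.index,
    )
    return AdjustmentResult(biomarker=biomarker, frame=frame, adjusted=False, reason=reason)


def adjust_biomarker(
    table: pd.DataFrame,
    biomarker_name: str,
    group: str,
    refs_override: ReferenceValues | None = None,
    covariates: Sequence[str] | None = None,
    biomarker_col: str | None = None,
    agp_col: str = "agp",
    crp_col: str = "crp",
    min_n: int = DEFAULT_MIN_FIT,
) -> AdjustmentResult:
    """End-to-end adjustment of one biomarker under the registry's policy.

    Looks up the rule for (biomarker, group); biomarkers whose rule uses no
    inflammation marker are returned unchanged and flagged unadjusted. For
    zinc in PSC the Spearman decision rule is evaluated first. Otherwise the
    joint log-log model is fitted on the markers the rule prescribes (among
    those present in the table — a single available marker is still used),
    truncated differences computed against the resolved reference deciles,
    and the correction applied.
    """
    biomarker = canonical_biomarker(biomarker_name)
    grp = canonical_group(group)
    biomarker_col = biomarker_col or biomarker
    rule = lookup_rule(biomarker, grp)

    if not rule.adjustable:
        return _unadjusted_result(
            table, biomarker_col, biomarker,
            f"no inflammation adjustment recommended for {biomarker} in {grp}",
        )

    available = {
        m: c
        for m, c in ((AGP, agp_col), (CRP, crp_col))
        if m in rule.markers_used and c in table.columns
    }
    if not available:
        raise ValueError(
            f"{biomarker} requires adjustment by {sorted(rule.markers_used)} "
            "but no inflammation marker column is present"
        )

    if rule.conditional and biomarker == "zinc":
        needed = qc.zinc_needs_adjustment(
            table[biomarker_col],
            table[agp_col] if AGP in available else None,
            table[crp_col] if CRP in available else None,
            group=grp,
        )
        if not needed:
            return _unadjusted_result(
                table, biomarker_col, biomarker,
                "zinc/inflammation Spearman screen not met; no adjustment",
            )

    if refs_override is not None:
        refs = refs_override
    else:
        refs = external_reference(grp)

    ln_mb = _as_clean_log(table[biomarker_col], biomarker_col)
    ln_agp = _as_clean_log(table[agp_col], agp_col) if AGP in available else None
    ln_crp = _as_clean_log(table[crp_col], crp_col) if CRP in available else None
    cov = table[list(covariates)] if covariates else None
    model = fit_model(ln_mb, ln_agp, ln_crp, covariates=cov, biomarker=biomarker, min_n=min_n)
    return apply_adjustment(
        table, model, refs, biomarker_col=biomarker_col, agp_col=agp_col, crp_col=crp_col
    )


def prevalence(
    values,
    cutoff: float,
    direction: str = "below",
    weights=None,
    with_se: bool = False,
):
    """Deficiency prevalence as a percentage.

    ``direction="below"`` counts values strictly below the cutoff (ferritin,
    retinol, RBP, zinc deficiency); ``"above"`` counts values strictly above
    it (elevated sTfR). The cutoff must be in the same units as the values.
    Optionally returns a binomial-approximation standard error; weights, if
    given, produce a weighted prevalence (default unweighted).
    """
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    s = pd.to_numeric(pd.Series(values), errors="coerce")
    mask = s.notna()
    if not mask.any():
        raise ValueError("all values missing; prevalence undefined")
    hits = (s < cutoff) if direction == "below" else (s > cutoff)
    if weights is None:
        n = int(mask.sum())
        p = hits[mask].mean()
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=s.index)[mask]
        n = int(mask.sum())
        p = float(np.average(hits[mask], weights=w))
    pct = 100.0 * float(p)
    if with_se:
        se = 100.0 * float(np.sqrt(p * (1.0 - p) / n))
        return pct, se
    return pct


@dataclass
class CovariateComparison:
    """Prevalence estimates with and without a binary covariate in the fit."""

    biomarker: str
    covariate: str
    prevalence_without: float
    prevalence_with: float
    model_without: AdjustmentModel | None
    model_with: AdjustmentModel | None

    @property
    def difference(self) -> float:
        return self.prevalence_with - self.prevalence_without


def compare_with_covariate(
    table: pd.DataFrame,
    biomarker_name: str,
    group: str,
    covariate_name: str,
    cutoff: float,
    direction: str = "below",
    refs_override: ReferenceValues | None = None,
    **kwargs,
) -> CovariateComparison:
    """Does adding a binary covariate (e.g. malaria status) to the
    correction model change the deficiency prevalence?

    The adjustment is run twice — with and without the covariate in the
    regression. The covariate alters the fitted inflammation slopes only;
    the correction still subtracts only the inflammation terms, so any
    difference in adjusted values flows through the coefficients.
    """
    cov = pd.to_numeric(table[covariate_name], errors="coerce").dropna()
    levels = set(cov.unique())
    if len(levels) < 2:
        raise ValueError(f"covariate {covariate_name!r} is constant; comparison undefined")
    if not levels <= {0, 1}:
        raise ValueError(f"covariate {covariate_name!r} must be binary 0/1, got {sorted(levels)}")

    without = adjust_biomarker(table, biomarker_name, group,
                               refs_override=refs_override, **kwargs)
    with_cov = adjust_biomarker(table, biomarker_name, group,
                                refs_override=refs_override,
                                covariates=[covariate_name], **kwargs)
    return CovariateComparison(
        biomarker=without.biomarker,
        covariate=covariate_name,
        prevalence_without=prevalence(without.frame["mb_adj"], cutoff, direction),
        prevalence_with=prevalence(with_cov.frame["mb_adj"], cutoff, direction),
        model_without=without.model,
        model_with=with_cov.model,
    )
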