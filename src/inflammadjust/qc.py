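"""Pre-adjustment data checks.

Before fitting the correction model a survey dataset is screened in three
steps: unit plausibility and univariate summaries; handling of values
censored at assay limits of detection (LoD) and comparison of the survey's
own lowest decile of each inflammation marker with the external reference
decile; and a check that the biomarker/inflammation relation has the
biologically expected direction. Adjustment should not proceed for a
biomarker whose relation is absent or reversed in the data at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .registry import AGP, CRP, BiomarkerRule, ReferenceValues, canonical_group, external_reference

#: Relative difference above which an internal decile replaces the external
#: reference decile.
REFERENCE_TOLERANCE = 0.20

#: Minimum complete pairs for any correlation/regression screen.
DEFAULT_MIN_PAIRS = 30

# Plausible medians if units are as required (AGP g/L, CRP mg/L); a median
# outside these ranges suggests the column is in different units.
_UNIT_RANGES = {AGP: (0.1, 5.0), CRP: (0.01, 200.0)}


class ReferenceChoice(NamedTuple):
    """Outcome of the internal-vs-external reference decile comparison for
    one inflammation marker."""

    value: float
    source: str  # "external" or "internal"
    relative_difference: float


@dataclass
class QcSummary:
    """Univariate summaries plus the per-marker reference decision.

    ``columns`` holds one row per summarised column with counts (n,
    n_missing, n_zero, n_below_lod), min, max and the lowest decile (10th
    percentile, linear interpolation between order statistics).
    """

    columns: pd.DataFrame
    reference_decisions: dict = field(default_factory=dict)
    unit_warnings: list = field(default_factory=list)


def check_units(agp: pd.Series | None = None, crp: pd.Series | None = None) -> list[str]:
    """Heuristic unit check: warn (never fail) when a marker's median falls
    outside the plausible range for the required units (AGP g/L, CRP mg/L)."""
    warnings = []
    for marker, values in ((AGP, agp), (CRP, crp)):
        if values is None:
            continue
        med = pd.Series(values).dropna().median()
        lo, hi = _UNIT_RANGES[marker]
        if np.isfinite(med) and not lo <= med <= hi:
            unit = "g/L" if marker == AGP else "mg/L"
            warnings.append(
                f"{marker} median {med:.3g} outside plausible range "
                f"[{lo}, {hi}] {unit}; check units"
            )
    return warnings


def _summarize_column(values: pd.Series, lod: float | None) -> dict:
    s = pd.to_numeric(pd.Series(values), errors="coerce")
    nonmissing = s.dropna()
    if nonmissing.empty:
        raise ValueError(f"column {values.name!r} has no nonmissing values")
    out = {
        "n": int(len(s)),
        "n_missing": int(s.isna().sum()),
        "n_zero": int((nonmissing == 0).sum()),
        "n_below_lod": int((nonmissing < lod).sum()) if lod is not None else np.nan,
        "min": float(nonmissing.min()),
        "max": float(nonmissing.max()),
        "lowest_decile": float(nonmissing.quantile(0.10)),
    }
    return out


def summarize(
    table: pd.DataFrame,
    lod_map: Mapping[str, float] | None = None,
    group: str | None = None,
    columns: list[str] | None = None,
    agp_col: str = "agp",
    crp_col: str = "crp",
) -> QcSummary:
    """Univariate summary statistics for biomarker and inflammation columns.

    Zeros and below-LoD values are counted but not modified. When ``group``
    is PSC or WRA and an inflammation column is present, the internal lowest
    decile is compared with the external reference decile and the resulting
    per-marker decision stored (see :func:`choose_reference`).

    Parameters
    ----------
    table : DataFrame
        Participant-level survey records.
    lod_map : mapping, optional
        Column name -> lower limit of detection.
    group : str, optional
        Population group; enables the reference-decile decision.
    columns : list of str, optional
        Columns to summarise (default: all numeric-convertible columns).
    """
    if table.empty:
        raise ValueError("empty table")
    lod_map = dict(lod_map or {})
    cols = columns if columns is not None else list(table.columns)
    rows = {}
    for col in cols:
        rows[col] = _summarize_column(table[col], lod_map.get(col))
    summary = pd.DataFrame.from_dict(rows, orient="index")

    decisions: dict[str, ReferenceChoice] = {}
    if group is not None and canonical_group(group) in ("PSC", "WRA"):
        ext = external_reference(group)
        for marker, col in ((AGP, agp_col), (CRP, crp_col)):
            if col in summary.index:
                decisions[marker] = choose_reference(
                    summary.loc[col, "lowest_decile"], ext.ref_for(marker)
                )

    warnings = check_units(
        table[agp_col] if agp_col in table.columns else None,
        table[crp_col] if crp_col in table.columns else None,
    )
    return QcSummary(columns=summary, reference_decisions=decisions, unit_warnings=warnings)


def impute_below_lod(
    values,
    lod: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    flags=None,
):
    """Random-number single imputation for values censored below a lower LoD.

    Each flagged value is replaced by one uniform draw strictly inside
    (0, lod); unflagged values pass through unchanged. By default a value is
    flagged when it is below the LoD — this covers censored values recorded
    as 0 as well as those recorded as a placeholder under the limit. Pass an
    explicit boolean ``flags`` mask to override (e.g. to also treat values
    recorded exactly at the LoD as censored).

    Reproducible for a fixed ``seed``; missing values stay missing.
    """
    if not lod > 0:
        raise ValueError(f"lod must be positive, got {lod!r}")
    s = pd.Series(values, dtype=float)
    if flags is None:
        flags = s.notna() & (s < lod)
    else:
        flags = pd.Series(np.asarray(flags, dtype=bool), index=s.index)
    n_flagged = int(flags.sum())
    if n_flagged:
        if rng is None:
            rng = np.random.default_rng(seed)
        draws = rng.uniform(0.0, lod, size=n_flagged)
        # keep the open-interval contract even at float boundaries
        draws = np.clip(draws, np.nextafter(0.0, lod), np.nextafter(lod, 0.0))
        s = s.copy()
        s[flags] = draws
    if isinstance(values, pd.Series):
        return s
    return s.to_numpy()


def choose_reference(internal_decile: float, external_ref: float) -> ReferenceChoice:
    """Decide between the external reference decile and the survey's own.

    The external value is kept when the internal lowest decile is within 20%
    of it (relative difference, external value as denominator); otherwise the
    internal decile is used. The decision is made per marker independently.
    """
    if not internal_decile > 0:
        raise ValueError(f"internal decile must be positive, got {internal_decile!r}")
    rel = abs(internal_decile - external_ref) / external_ref
    if rel <= REFERENCE_TOLERANCE:
        return ReferenceChoice(float(external_ref), "external", rel)
    return ReferenceChoice(float(internal_decile), "internal", rel)


def resolve_references(
    table: pd.DataFrame,
    group: str,
    agp_col: str | None = "agp",
    crp_col: str | None = "crp",
) -> ReferenceValues:
    """Apply :func:`choose_reference` to every inflammation column present
    and assemble the :class:`~inflammadjust.registry.ReferenceValues` to use
    for adjustment."""
    ext = external_reference(group)
    out = {"agp_ref": None, "crp_ref": None, "agp_source": "external", "crp_source": "external"}
    for marker, col, vkey, skey in (
        (AGP, agp_col, "agp_ref", "agp_source"),
        (CRP, crp_col, "crp_ref", "crp_source"),
    ):
        if col is None or col not in table.columns:
            continue
        decile = pd.to_numeric(table[col], errors="coerce").dropna().quantile(0.10)
        choice = choose_reference(decile, ext.ref_for(marker))
        out[vkey] = choice.value
        out[skey] = choice.source
    return ReferenceValues(group=ext.group, **out)


@dataclass
class MarkerScreen:
    """Bivariate screen of one biomarker against one inflammation marker."""

    marker: str
    n: int
    spearman_r: float
    spearman_p: float
    ols_slope_loglog: float

    @property
    def degenerate(self) -> bool:
        return not (np.isfinite(self.spearman_r) and np.isfinite(self.ols_slope_loglog))


@dataclass
class RelationScreen:
    """Direction screen across the markers a rule uses, with verdict."""

    biomarker: str
    markers: dict  # marker name -> MarkerScreen
    verdict: str  # "adjust" or "do_not_adjust"
    notes: list = field(default_factory=list)


def _spearman(x: np.ndarray, y: np.ndarray, method: str, seed: int | None):
    if method == "permutation":
        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic

        res = stats.permutation_test(
            (y,),
            statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=np.random.default_rng(seed),
        )
        return float(res.statistic), float(res.pvalue)
    import warnings

    with warnings.catch_warnings():
        # constant inputs are handled by the degenerate-screen path
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _pair_screen(
    mb: pd.Series, marker_values: pd.Series, marker: str, min_pairs: int,
    p_method: str, seed: int | None,
) -> MarkerScreen:
    df = pd.DataFrame({"mb": pd.to_numeric(mb, errors="coerce"),
                       "m": pd.to_numeric(marker_values, errors="coerce")}).dropna()
    n = len(df)
    if n < min_pairs:
        raise ValueError(
            f"only {n} complete {marker} pairs (< {min_pairs}); too few to screen"
        )
    x = df["m"].to_numpy()
    y = df["mb"].to_numpy()
    r, p = _spearman(x, y, p_method, seed)
    # log-log simple regression slope; requires strictly positive values
    if (x > 0).all() and (y > 0).all() and np.ptp(np.log(x)) > 0:
        slope = float(np.polyfit(np.log(x), np.log(y), 1)[0])
    else:
        slope = np.nan
    return MarkerScreen(marker=marker, n=n, spearman_r=r, spearman_p=p,
                        ols_slope_loglog=slope)


def screen_relation(
    mb_values,
    agp_values=None,
    crp_values=None,
    rule: BiomarkerRule | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    p_method: str = "approx",
    seed: int | None = None,
) -> RelationScreen:
    """Check that the biomarker/inflammation relation has the expected
    direction before adjusting.

    For each marker the rule uses (and for which data exist) a Spearman
    correlation and a log-log simple-regression slope are computed. The
    verdict is ``do_not_adjust`` only when the fitted slope contradicts the
    rule's expected sign (or is degenerate) for *every* available marker —
    iron biomarkers should relate positively to inflammation, vitamin A and
    zinc biomarkers negatively.
    """
    if rule is None:
        raise ValueError("a BiomarkerRule is required")
    available = {}
    if agp_values is not None and AGP in rule.markers_used:
        available[AGP] = agp_values
    if crp_values is not None and CRP in rule.markers_used:
        available[CRP] = crp_values
    if not available:
        raise ValueError(
            f"no data for any marker in {sorted(rule.markers_used)} "
            f"required by {rule.biomarker}"
        )
    mb = pd.Series(mb_values)
    screens: dict[str, MarkerScreen] = {}
    notes: list[str] = []
    any_consistent = False
    for marker, vals in available.items():
        sc = _pair_screen(mb, pd.Series(vals), marker, min_pairs, p_method, seed)
        screens[marker] = sc
        if sc.degenerate:
            notes.append(f"{marker}: degenerate relation (constant or nonpositive values)")
            continue
        if rule.expected_sign == "positive" and sc.ols_slope_loglog > 0:
            any_consistent = True
        elif rule.expected_sign == "negative" and sc.ols_slope_loglog < 0:
            any_consistent = True
        else:
            notes.append(
                f"{marker}: slope {sc.ols_slope_loglog:.3g} contradicts expected "
                f"{rule.expected_sign} relation"
            )
    verdict = "adjust" if any_consistent else "do_not_adjust"
    return RelationScreen(biomarker=rule.biomarker, markers=screens, verdict=verdict,
                          notes=notes)


def zinc_needs_adjustment(
    zinc_values,
    agp_values=None,
    crp_values=None,
    group: str = "PSC",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    p_method: str = "approx",
    seed: int | None = None,
    r_threshold: float = -0.1,
    p_threshold: float = 0.1,
) -> bool:
    """Decision rule for serum zinc.

    Zinc is adjusted only in preschool-age children, and only when the
    Spearman correlation between zinc and at least one available
    inflammation marker is negative (r < -0.1) and marginally significant
    (P < 0.1, two-sided). Returns False for any other group. Spearman is
    rank-based, so the result is invariant to monotone transforms of the
    inputs.
    """
    grp = canonical_group(group)
    if grp != "PSC":
        return False
    zinc = pd.Series(zinc_values)
    markers = [(AGP, agp_values), (CRP, crp_values)]
    markers = [(m, v) for m, v in markers if v is not None]
    if not markers:
        raise ValueError("zinc screening requires AGP and/or CRP data")
    for marker, vals in markers:
        sc = _pair_screen(zinc, pd.Series(vals), marker, min_pairs, p_method, seed)
        if np.isfinite(sc.spearman_r) and sc.spearman_r < r_threshold and sc.spearman_p < p_threshold:
            return True
    return False
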