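"""Adjustment policy registry.

Encodes which micronutrient biomarkers are corrected for inflammation, by
which acute-phase markers (AGP and/or CRP), in which population group, and
the external reference deciles against which excess inflammation is measured.

The policy is fixed knowledge distilled from the micronutrient-assessment
literature:

* ferritin, serum retinol and RBP are adjusted with **both** AGP and CRP
  in preschool-age children (PSC) and women of reproductive age (WRA);
* sTfR is adjusted with **AGP only**;
* serum zinc is adjusted (both markers) only in PSC, and only when a
  negative, marginally significant Spearman correlation with AGP or CRP is
  observed in the data at hand (see :func:`inflammadjust.qc.zinc_needs_adjustment`);
* serum folate, RBC folate and vitamin B-12 are never adjusted.

Ferritin and sTfR rise with inflammation (positive log-log relation);
retinol, RBP and zinc are depressed by it (negative relation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

AGP = "AGP"
CRP = "CRP"

#: Population groups with published external reference deciles, plus MANUAL
#: for any other group (user supplies reference values).
GROUPS = ("PSC", "WRA", "MANUAL")

#: Canonical biomarker identifiers known to the registry.
BIOMARKERS = (
    "ferritin",
    "stfr",
    "retinol",
    "rbp",
    "zinc",
    "serum_folate",
    "rbc_folate",
    "b12",
)

_SYNONYMS = {
    "ferritin": "ferritin",
    "serum_ferritin": "ferritin",
    "sf": "ferritin",
    "stfr": "stfr",
    "sftr": "stfr",
    "s_tfr": "stfr",
    "tfr": "stfr",
    "transferrin_receptor": "stfr",
    "soluble_transferrin_receptor": "stfr",
    "retinol": "retinol",
    "serum_retinol": "retinol",
    "sr": "retinol",
    "rbp": "rbp",
    "retinol_binding_protein": "rbp",
    "zinc": "zinc",
    "serum_zinc": "zinc",
    "zn": "zinc",
    "folate": "serum_folate",
    "serum_folate": "serum_folate",
    "rbc_folate": "rbc_folate",
    "red_blood_cell_folate": "rbc_folate",
    "b12": "b12",
    "b_12": "b12",
    "vitamin_b12": "b12",
    "vitamin_b_12": "b12",
    "cobalamin": "b12",
}

# External reference deciles: 10th percentile of the inflammation-marker
# distribution in a pooled multi-country reference population.
# AGP in g/L, CRP in mg/L.
EXTERNAL_REFERENCE = {
    "PSC": {AGP: 0.59, CRP: 0.10},
    "WRA": {AGP: 0.54, CRP: 0.16},
}


class UnknownBiomarkerError(KeyError):
    """Raised for a biomarker name the registry does not know."""


class UnknownGroupError(KeyError):
    """Raised for a population group the registry does not know."""


def canonical_biomarker(name: str) -> str:
    """Resolve a biomarker name (case-insensitive, common synonyms) to its
    canonical identifier.

    Raises
    ------
    UnknownBiomarkerError
        If the name cannot be resolved. Unknown names never default silently.
    """
    key = str(name).strip().lower().replace("-", "_").replace(" ", "_")
    try:
        return _SYNONYMS[key]
    except KeyError:
        raise UnknownBiomarkerError(
            f"unknown biomarker {name!r}; known: {', '.join(BIOMARKERS)}"
        ) from None


def canonical_group(group: str) -> str:
    key = str(group).strip().upper()
    if key not in GROUPS:
        raise UnknownGroupError(f"unknown population group {group!r}; known: {GROUPS}")
    return key


@dataclass(frozen=True)
class BiomarkerRule:
    """Per-biomarker adjustment policy for one population group.

    Attributes
    ----------
    biomarker : str
        Canonical biomarker identifier.
    group : str
        Population group the rule applies to.
    markers_used : frozenset of str
        Inflammation markers entering the correction model; empty means the
        biomarker is never adjusted in this group.
    conditional : bool
        True when adjustment additionally requires a data-driven check
        (zinc in PSC: the Spearman screen).
    expected_sign : str
        Expected sign of the log-log biomarker/inflammation relation:
        ``"positive"``, ``"negative"`` or ``"none"``.
    """

    biomarker: str
    group: str
    markers_used: frozenset = field(default_factory=frozenset)
    conditional: bool = False
    expected_sign: str = "none"

    @property
    def adjustable(self) -> bool:
        return bool(self.markers_used)


@dataclass(frozen=True)
class ReferenceValues:
    """Reference deciles used to truncate the inflammation correction.

    ``agp_ref`` is in g/L, ``crp_ref`` in mg/L; each may be ``None`` when that
    marker is not being used. ``agp_source``/``crp_source`` record whether the
    value is the published external decile, an internal decile from the survey
    itself, or user-supplied (MANUAL mode).
    """

    group: str
    agp_ref: float | None = None
    crp_ref: float | None = None
    agp_source: str = "external"
    crp_source: str = "external"

    def __post_init__(self):
        for name, val in (("agp_ref", self.agp_ref), ("crp_ref", self.crp_ref)):
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be positive, got {val!r}")

    def ref_for(self, marker: str) -> float | None:
        return self.agp_ref if marker == AGP else self.crp_ref

    def source_for(self, marker: str) -> str:
        return self.agp_source if marker == AGP else self.crp_source


_BOTH = frozenset({AGP, CRP})
_AGP_ONLY = frozenset({AGP})
_NONE = frozenset()

# sign conventions: acute-phase reactants (ferritin, sTfR) rise with
# inflammation; retinol/RBP/zinc fall.
_SIGNS = {
    "ferritin": "positive",
    "stfr": "positive",
    "retinol": "negative",
    "rbp": "negative",
    "zinc": "negative",
    "serum_folate": "none",
    "rbc_folate": "none",
    "b12": "none",
}


def _markers_for(biomarker: str, group: str) -> tuple[frozenset, bool]:
    if biomarker in ("serum_folate", "rbc_folate", "b12"):
        return _NONE, False
    if biomarker == "stfr":
        return _AGP_ONLY, False
    if biomarker == "zinc":
        # conditional rule established in PSC only; elsewhere no adjustment
        if group == "PSC":
            return _BOTH, True
        return _NONE, False
    # ferritin, retinol, rbp
    return _BOTH, False


def lookup_rule(biomarker_name: str, group: str) -> BiomarkerRule:
    """Return the adjustment rule for a biomarker in a population group.

    The lookup is total over known biomarkers x groups and pure; unknown
    names raise instead of defaulting. MANUAL (any other population group)
    follows the group-independent rules, with no zinc adjustment because the
    conditional zinc rule is established for PSC only.
    """
    biomarker = canonical_biomarker(biomarker_name)
    grp = canonical_group(group)
    markers, conditional = _markers_for(biomarker, grp)
    return BiomarkerRule(
        biomarker=biomarker,
        group=grp,
        markers_used=markers,
        conditional=conditional,
        expected_sign=_SIGNS[biomarker],
    )


def external_reference(group: str) -> ReferenceValues:
    """External reference deciles for PSC or WRA.

    MANUAL has no published constants; callers must build reference values
    with :func:`manual_reference` instead.
    """
    grp = canonical_group(group)
    if grp == "MANUAL":
        raise UnknownGroupError(
            "no external reference deciles exist for MANUAL; supply user values"
        )
    refs = EXTERNAL_REFERENCE[grp]
    return ReferenceValues(group=grp, agp_ref=refs[AGP], crp_ref=refs[CRP])


def manual_reference(agp_ref: float | None = None, crp_ref: float | None = None) -> ReferenceValues:
    """User-supplied reference deciles for a population group without
    published external values."""
    if agp_ref is None and crp_ref is None:
        raise ValueError("manual reference requires at least one of agp_ref, crp_ref")
    return ReferenceValues(
        group="MANUAL",
        agp_ref=agp_ref,
        crp_ref=crp_ref,
        agp_source="user",
        crp_source="user",
    )


def rules_table(groups: Iterable[str] = ("PSC", "WRA")) -> pd.DataFrame:
    """The full policy as a tidy table (one row per biomarker x group),
    including the external reference deciles, so documentation and tests
    share one source of truth with the code."""
    rows = []
    for group in groups:
        refs = EXTERNAL_REFERENCE.get(canonical_group(group), {})
        for biomarker in BIOMARKERS:
            rule = lookup_rule(biomarker, group)
            rows.append(
                {
                    "biomarker": biomarker,
                    "group": rule.group,
                    "uses_agp": AGP in rule.markers_used,
                    "uses_crp": CRP in rule.markers_used,
                    "conditional": rule.conditional,
                    "expected_sign": rule.expected_sign,
                    "external_agp_ref_g_per_l": refs.get(AGP),
                    "external_crp_ref_mg_per_l": refs.get(CRP),
                }
            )
    return pd.DataFrame(rows)


def export_rules(path: str | Path) -> Path:
    """Write the policy table to CSV."""
    path = Path(path)
    rules_table().to_csv(path, index=False)
    return path
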