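"""Leaf trait data model and the LMA = LVA x LD identity.

Leaf mass per area (LMA, g m-2) factors exactly into leaf volume per area
(LVA, mL m-2 -- numerically the leaf thickness in micrometres) and leaf
density (LD, g mL-1).  LVA in turn is the sum of the volumes per unit leaf
area (VA) of the anatomical tissues -- upper and lower epidermis, palisade
and spongy parenchyma, vascular plus sclerenchymatic tissue -- plus the
intercellular air spaces.  LD is the volumetric-fraction-weighted mean of
the tissue densities.  This module houses those identities, the grouped
tissue aggregation (epidermis, mesophyll, vascular+sclerenchyma, air
spaces), gravimetric soil-water-content derivation, and the trait-table
CSV interface used by the rest of the pipeline.

Units are fixed by convention throughout: VA and LVA in mL m-2 (equal to
micrometres of thickness), LMA in g m-2, LD in g mL-1, C and N
concentrations in mg g-1, soil water content in litres per square metre
of ground.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lmadecomp")

#: Default relative tolerance for agreement between a measured LVA and the
#: sum of the measured tissue VAs.  Thickness and tissue areas are measured
#: independently on sections, so exact equality cannot be assumed.
LVA_CONSISTENCY_RTOL = 0.05

#: Tissue groups used everywhere downstream, in display order.
TISSUE_GROUPS = ("epidermis", "mesophyll", "vascular_sclerenchyma", "air_spaces")

HABITS = ("deciduous", "evergreen")


class TraitDomainError(ValueError):
    """An input violates a domain constraint (negative volume, bad habit...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_TISSUE_FIELDS = (
    "upper_epidermis_va",
    "lower_epidermis_va",
    "palisade_va",
    "spongy_va",
    "vascular_sclerenchyma_va",
    "air_space_va",
)


@dataclass(frozen=True)
class TissueProfile:
    """Per-tissue volume per unit leaf area (mL m-2, equivalently um)."""

    upper_epidermis_va: float
    lower_epidermis_va: float
    palisade_va: float
    spongy_va: float
    vascular_sclerenchyma_va: float
    air_space_va: float

    def __post_init__(self) -> None:
        for name in _TISSUE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise TraitDomainError(
                    f"tissue volume per area {name!r} must be finite and >= 0, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _TISSUE_FIELDS], dtype=float)


@dataclass
class SpeciesTraitRecord:
    """Species-mean morphological, anatomical, chemical and site-water values.

    ``ld`` may be omitted, in which case it is derived as LMA / LVA on
    construction; a supplied LD always wins, with a consistency warning if
    it disagrees with the ratio.
    """

    species_id: str
    habit: str
    lma: float
    lva: float
    tissues: TissueProfile
    ld: float | None = None
    lcc: float | None = None
    lnc: float | None = None
    swc: float | None = None
    site: str | None = None
    ld_derived: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.habit not in HABITS:
            raise TraitDomainError(
                f"{self.species_id}: habit must be one of {HABITS}, got {self.habit!r}"
            )
        for name in ("lma", "lva"):
            v = getattr(self, name)
            if not (v > 0):
                raise TraitDomainError(f"{self.species_id}: {name} must be > 0, got {v!r}")
        if self.ld is None:
            self.ld = derive_ld(self.lma, self.lva)
            self.ld_derived = True
        else:
            if not (self.ld > 0):
                raise TraitDomainError(f"{self.species_id}: ld must be > 0, got {self.ld!r}")
            implied = self.lma / self.lva
            if abs(self.ld - implied) > 1e-6 * max(self.ld, implied):
                logger.warning(
                    "%s: supplied LD %.6g differs from LMA/LVA %.6g; keeping supplied value",
                    self.species_id, self.ld, implied,
                )

    def check_lva_consistency(self, rtol: float = LVA_CONSISTENCY_RTOL) -> bool:
        """True when measured LVA agrees with the tissue-VA sum within rtol."""
        total = lva_from_tissues(self.tissues)
        if total == 0:
            return False
        return abs(total - self.lva) <= rtol * self.lva


@dataclass(frozen=True)
class SoilSampleSet:
    """Fresh/dry soil masses (g) from one site, with the auger section area (cm2)."""

    samples: tuple[tuple[float, float], ...]
    auger_section_area: float = 5.0

    def __post_init__(self) -> None:
        if len(self.samples) == 0:
            raise TraitDomainError("soil sample set is empty")
        if not (self.auger_section_area > 0):
            raise TraitDomainError(
                f"auger section area must be > 0 cm2, got {self.auger_section_area!r}"
            )
        for i, (fresh, dry) in enumerate(self.samples):
            if dry < 0:
                raise TraitDomainError(f"sample {i}: dry mass {dry!r} g is negative")
            if fresh < dry:
                raise TraitDomainError(
                    f"sample {i}: fresh mass {fresh!r} g < dry mass {dry!r} g"
                )


# ---------------------------------------------------------------------------
# identities and aggregations
# ---------------------------------------------------------------------------


def derive_ld(lma: float, lva: float) -> float:
    """Leaf density (g mL-1) as the ratio of LMA (g m-2) to LVA (mL m-2)."""
    if not (lma > 0):
        raise TraitDomainError(f"lma must be > 0, got {lma!r}")
    if not (lva > 0):
        raise TraitDomainError(f"lva must be > 0, got {lva!r}")
    return lma / lva


def aggregate_tissues(profile: TissueProfile) -> dict[str, float]:
    """Collapse the six measured tissues into the four canonical groups.

    epidermis = upper + lower epidermis; mesophyll = palisade + spongy
    parenchyma; vascular+sclerenchyma and air spaces pass through.  The
    grouped total equals the raw six-tissue total exactly.
    """
    return {
        "epidermis": profile.upper_epidermis_va + profile.lower_epidermis_va,
        "mesophyll": profile.palisade_va + profile.spongy_va,
        "vascular_sclerenchyma": profile.vascular_sclerenchyma_va,
        "air_spaces": profile.air_space_va,
    }


def lva_from_tissues(profile: TissueProfile) -> float:
    """LVA (mL m-2) reconstructed as the sum of all tissue VAs plus air spaces."""
    return float(profile.as_array().sum())


def volume_fractions(profile: TissueProfile) -> dict[str, float]:
    """Percentage of total leaf volume occupied by each tissue group.

    Fractions are 100 * group VA / total VA and sum to 100 by construction.
    An all-zero profile has no defined fractions and is rejected.
    """
    total = lva_from_tissues(profile)
    if total <= 0:
        raise TraitDomainError("volume fractions undefined for an all-zero tissue profile")
    groups = aggregate_tissues(profile)
    return {name: 100.0 * va / total for name, va in groups.items()}


def soil_water_content(samples: SoilSampleSet) -> float:
    """Site soil water content (L m-2) by the gravimetric method.

    Each sample's water mass is fresh minus dry mass in grams (1 g of water
    occupies 1 mL); dividing by the auger cross-section (cm2) gives mL cm-2,
    and 1 mL cm-2 = 10 L m-2.  The site value is the mean over samples.
    """
    per_sample = [
        10.0 * (fresh - dry) / samples.auger_section_area
        for fresh, dry in samples.samples
    ]
    return float(np.mean(per_sample))


# ---------------------------------------------------------------------------
# trait-table CSV interface
# ---------------------------------------------------------------------------

#: Canonical trait CSV columns.  Unknown columns are preserved but ignored.
TRAIT_CSV_COLUMNS = (
    "species", "habit", "site",
    "lma_g_m2", "lva_ml_m2", "ld_g_ml", "lcc_mg_g", "lnc_mg_g",
    "ue_va", "le_va", "pal_va", "spo_va", "vs_va", "air_va",
    "swc_l_m2",
)

_REQUIRED_CSV = (
    "species", "habit", "lma_g_m2", "lva_ml_m2",
    "ue_va", "le_va", "pal_va", "spo_va", "vs_va", "air_va",
)


def read_trait_table(path) -> list[SpeciesTraitRecord]:
    """Read species-mean trait records from the canonical CSV schema."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_CSV if c not in df.columns]
    if missing:
        raise TraitDomainError(f"trait CSV missing required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        tissues = TissueProfile(
            upper_epidermis_va=row["ue_va"],
            lower_epidermis_va=row["le_va"],
            palisade_va=row["pal_va"],
            spongy_va=row["spo_va"],
            vascular_sclerenchyma_va=row["vs_va"],
            air_space_va=row["air_va"],
        )

        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else float(v)

        records.append(
            SpeciesTraitRecord(
                species_id=str(row["species"]),
                habit=str(row["habit"]).strip().lower(),
                lma=float(row["lma_g_m2"]),
                lva=float(row["lva_ml_m2"]),
                ld=_opt("ld_g_ml"),
                lcc=_opt("lcc_mg_g"),
                lnc=_opt("lnc_mg_g"),
                swc=_opt("swc_l_m2"),
                site=str(row["site"]) if "site" in df.columns and not pd.isna(row.get("site")) else None,
                tissues=tissues,
            )
        )
    return records


def write_trait_table(records: Sequence[SpeciesTraitRecord], path) -> None:
    """Write records back to the canonical CSV schema (lossless round-trip)."""
    frame = records_to_frame(records)[list(TRAIT_CSV_COLUMNS)]
    frame.to_csv(path, index=False)


def records_to_frame(records: Sequence[SpeciesTraitRecord]) -> pd.DataFrame:
    """Tidy per-species DataFrame with raw, grouped and fractional traits.

    Columns: the canonical CSV schema plus derived ``epidermis_va``,
    ``mesophyll_va``, ``vascular_sclerenchyma_va``, ``air_spaces_va`` and
    the four ``*_frac`` percentages -- the working table for all the
    regression, partitioning and network stages.
    """
    rows = []
    for r in records:
        groups = aggregate_tissues(r.tissues)
        fracs = volume_fractions(r.tissues)
        rows.append({
            "species": r.species_id,
            "habit": r.habit,
            "site": r.site,
            "lma_g_m2": r.lma,
            "lva_ml_m2": r.lva,
            "ld_g_ml": r.ld,
            "lcc_mg_g": r.lcc,
            "lnc_mg_g": r.lnc,
            "ue_va": r.tissues.upper_epidermis_va,
            "le_va": r.tissues.lower_epidermis_va,
            "pal_va": r.tissues.palisade_va,
            "spo_va": r.tissues.spongy_va,
            "vs_va": r.tissues.vascular_sclerenchyma_va,
            "air_va": r.tissues.air_space_va,
            "swc_l_m2": r.swc,
            "epidermis_va": groups["epidermis"],
            "mesophyll_va": groups["mesophyll"],
            "vascular_sclerenchyma_va": groups["vascular_sclerenchyma"],
            "air_spaces_va": groups["air_spaces"],
            "epidermis_frac": fracs["epidermis"],
            "mesophyll_frac": fracs["mesophyll"],
            "vascular_sclerenchyma_frac": fracs["vascular_sclerenchyma"],
            "air_spaces_frac": fracs["air_spaces"],
        })
    return pd.DataFrame(rows)


def read_soil_table(path) -> dict[str, float]:
    """Per-site SWC (L m-2) from a soil CSV (site, sample, fresh_g, dry_g, auger_cm2)."""
    df = pd.read_csv(path)
    required = {"site", "fresh_g", "dry_g"}
    if not required.issubset(df.columns):
        raise TraitDomainError(f"soil CSV must have columns {sorted(required)}")
    out = {}
    for site, grp in df.groupby("site", sort=True):
        area = float(grp["auger_cm2"].iloc[0]) if "auger_cm2" in grp.columns else 5.0
        sample_set = SoilSampleSet(
            samples=tuple(zip(grp["fresh_g"].astype(float), grp["dry_g"].astype(float))),
            auger_section_area=area,
        )
        out[str(site)] = soil_water_content(sample_set)
    return out
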