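"""Realm and biome-realm assignment of species, and per-realm analyses.

A species belongs to a realm (or biome-realm) only when strictly more than
half of its range cells fall inside that unit; otherwise it is unassigned
and excluded from realm-level analyses. Biome-realms with fewer than five
low-risk or five high-risk species are discarded. Per-realm analyses rerun
the threshold sweep and the classifier on the realm's species only, and
record for each unit the threshold at which the high-risk group's mean
change in above-threshold extent peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .range_overlap import RangeMask
from .risk_model import ModelReport, ModelSettings, threshold_selection
from .risk_transitions import HIGH_RISK, LOW_RISK
from .sweep_stats import GroupSweep, group_sweep

logger = logging.getLogger(__name__)

REALM_CODES = ("AA", "AT", "IM", "NA", "NT", "PA")
MIN_SPECIES_PER_CLASS = 5

__all__ = [
    "RealmAssignment",
    "assign_realm",
    "filter_biome_realms",
    "per_realm_analysis",
    "peak_change_threshold",
    "REALM_CODES",
]


@dataclass(frozen=True)
class RealmAssignment:
    species_id: str
    realm: str | None
    biome_realm: str | None
    realm_fraction: float
    biome_realm_fraction: float


def _majority_unit(codes: np.ndarray) -> tuple[object, float]:
    """Unit holding a strict majority of cells, or (None, best fraction)."""
    units, counts = np.unique(codes, return_counts=True)
    best = counts.argmax()
    frac = counts[best] / codes.size
    if frac > 0.5:
        return units[best], float(frac)
    return None, float(frac)


def assign_realm(
    mask: RangeMask,
    realm_raster: np.ndarray,
    biome_raster: np.ndarray | None = None,
    legend: dict[int, str] | None = None,
) -> RealmAssignment:
    """Assign a species to the realm (and biome-realm) holding > 50% of its range.

    ``realm_raster`` holds integer realm codes on the species' grid;
    ``legend`` maps codes to realm names. The biome-realm is the
    (realm, biome) pair; its id is ``"<realm>:<biome>"``.
    """
    realm_raster = np.asarray(realm_raster)
    mask.grid.validate_array(realm_raster, "realm raster")
    codes = realm_raster[mask.mask]
    realm_code, realm_frac = _majority_unit(codes)
    realm = None
    if realm_code is not None:
        realm = legend[int(realm_code)] if legend else str(realm_code)

    biome_realm = None
    br_frac = 0.0
    if biome_raster is not None:
        biome_raster = np.asarray(biome_raster)
        mask.grid.validate_array(biome_raster, "biome raster")
        pairs = codes.astype(np.int64) * 10_000 + biome_raster[mask.mask]
        pair_code, br_frac = _majority_unit(pairs)
        if pair_code is not None:
            r_code, b_code = divmod(int(pair_code), 10_000)
            r_name = legend[r_code] if legend else str(r_code)
            biome_realm = f"{r_name}:{b_code}"
    return RealmAssignment(
        species_id=mask.species_id,
        realm=realm,
        biome_realm=biome_realm,
        realm_fraction=realm_frac,
        biome_realm_fraction=br_frac,
    )


def filter_biome_realms(
    assignments: list[RealmAssignment],
    labels: pd.DataFrame,
    min_per_class: int = MIN_SPECIES_PER_CLASS,
) -> dict[str, list[str]]:
    """Biome-realms with at least five species of each risk class.

    Returns ``{biome_realm: [species_id, ...]}`` for retained units.
    """
    by_species = labels.set_index("species_id")["risk_class"]
    units: dict[str, list[str]] = {}
    for a in assignments:
        if a.biome_realm is not None:
            units.setdefault(a.biome_realm, []).append(a.species_id)
    retained = {}
    for unit, species in units.items():
        classes = by_species.loc[species]
        n_low = int((classes == LOW_RISK).sum())
        n_high = int((classes == HIGH_RISK).sum())
        if n_low >= min_per_class and n_high >= min_per_class:
            retained[unit] = species
    return retained


def peak_change_threshold(sweep: GroupSweep, group: str = HIGH_RISK) -> int:
    """Threshold where the group's mean delta-extent is largest (ties: lowest t)."""
    col = f"mean_delta_{group}"
    vals = sweep.table[col].to_numpy(dtype=float)
    return int(sweep.table["t"].to_numpy()[int(np.argmax(vals))])


def per_realm_analysis(
    realm: str,
    assignments: list[RealmAssignment],
    overlaps: pd.DataFrame,
    labels: pd.DataFrame,
    covariates: pd.DataFrame,
    t_grid,
    settings: ModelSettings,
) -> tuple[GroupSweep, int, pd.DataFrame, dict[int, ModelReport]] | None:
    """Sweep + threshold selection restricted to one realm's species.

    Returns ``(sweep, best_t, performance_curve, reports)`` or ``None``
    (with a log entry) when the realm lacks enough species of either class.
    """
    species = [a.species_id for a in assignments if a.realm == realm]
    sub_labels = labels[labels["species_id"].isin(species)]
    n_low = int((sub_labels["risk_class"] == LOW_RISK).sum())
    n_high = int((sub_labels["risk_class"] == HIGH_RISK).sum())
    if min(n_low, n_high) < settings.n_folds:
        logger.warning(
            "realm %s skipped: %d low-risk / %d high-risk species "
            "(need >= %d per class)",
            realm,
            n_low,
            n_high,
            settings.n_folds,
        )
        return None
    sub_overlaps = overlaps[overlaps["species_id"].isin(species)]
    sub_cov = covariates[covariates["species_id"].isin(species)]
    sweep = group_sweep(sub_overlaps, sub_labels)
    best_t, curve, reports = threshold_selection(
        sub_overlaps, sub_cov, sub_labels, t_grid, settings
    )
    return sweep, best_t, curve, reports
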