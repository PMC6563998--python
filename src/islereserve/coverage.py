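"""Protected-area gap-analysis statistics.

Per-species protected proportions, loss of in-reserve climate space between
two periods, species-richness overlays, the future-period exclusion filter
for species with no projected suitable climate space, and per-group
mean +/- sd summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .raster import BinaryGrid, Grid, require_aligned

__all__ = [
    "proportion_in_pa",
    "loss_within_pa",
    "richness_map",
    "filter_extinct",
    "group_summary",
]

log = logging.getLogger(__name__)


def proportion_in_pa(species: BinaryGrid, pa: BinaryGrid) -> float:
    """Fraction of a species' suitable cells that fall inside the protected
    areas: |presence âˆ© PA| / |presence|.

    Undefined (raises) for a species with no suitable cells; callers apply
    :func:`filter_extinct` first.
    """
    require_aligned(species, pa)
    presence = species.presence
    n = int(presence.sum())
    if n == 0:
        raise ValueError("species has no suitable cells; proportion undefined")
    return float((presence & pa.presence).sum() / n)


def loss_within_pa(species_t1: BinaryGrid, species_t2: BinaryGrid, pa: BinaryGrid) -> float:
    """Signed loss of a species' suitable climate space inside the PAs
    between two periods: (|t1 ∩ PA| - |t2 ∩ PA|) / |PA|.

    Positive values are losses (range contraction inside the reserves);
    gains come out negative and are reported as such.
    """
    require_aligned(species_t1, species_t2, pa)
    pa_cells = pa.presence
    n_pa = int(pa_cells.sum())
    if n_pa == 0:
        raise ValueError("protected area is empty")
    n1 = int((species_t1.presence & pa_cells).sum())
    n2 = int((species_t2.presence & pa_cells).sum())
    return (n1 - n2) / n_pa


def richness_map(layers) -> Grid:
    """Cumulative number of species per cell across aligned presence layers."""
    layers = list(layers)
    if not layers:
        raise ValueError("richness_map needs at least one layer")
    require_aligned(*layers)
    counts = np.zeros(layers[0].values.shape)
    for layer in layers:
        counts += layer.presence
    ref = layers[0]
    return Grid(
        values=counts,
        nodata_mask=ref.nodata_mask.copy(),
        cellsize=ref.cellsize,
        origin=ref.origin,
        nodata_value=ref.nodata_value,
    )


def filter_extinct(layers_by_period: dict) -> list:
    """Species retained for future-period analyses.

    ``layers_by_period`` maps species_id -> (baseline grid, future grid).
    Species whose future layer has no suitable cells are excluded from
    future-period analyses (they stay in baseline analyses); each exclusion
    is logged.
    """
    retained = []
    for sid, (_t1, t2) in layers_by_period.items():
        if t2.n_ones == 0:
            log.warning("species %s has no projected future climate space; excluded", sid)
        else:
            retained.append(sid)
    if not retained:
        log.warning("no species retain future climate space; future analysis set is empty")
    return retained


def group_summary(values: dict, groups: dict) -> pd.DataFrame:
    """Per-group mean and sample sd of per-species statistics, in percent.

    ``values`` maps species_id -> statistic (a proportion); ``groups`` maps
    species_id -> group label. Singleton groups get sd = 0 by convention
    (with a warning); groups with no values are skipped with a warning.
    """
    rows = []
    by_group: dict[str, list[float]] = {}
    for sid, v in values.items():
        by_group.setdefault(groups[sid], []).append(float(v))
    for group in sorted(by_group):
        vals = np.asarray(by_group[group])
        if vals.size == 0:  # pragma: no cover - empty groups never land here
            log.warning("group %s has no species; skipped", group)
            continue
        if vals.size == 1:
            log.warning("group %s has a single species; sd reported as 0", group)
            sd = 0.0
        else:
            sd = float(vals.std(ddof=1))
        rows.append(
            {
                "group": group,
                "n_species": int(vals.size),
                "mean_pct": float(vals.mean()) * 100.0,
                "sd_pct": sd * 100.0,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_species", "mean_pct", "sd_pct"])
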