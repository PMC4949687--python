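"""Overlap of task-activation masks with topological-map masks.

The headline statistic is the percentage of thresholded reading-activation
surface area that lies inside a thresholded sensory-motor map mask,
computed with vertex-wise areas (one third of adjacent face areas), so
regional sums reproduce enclosed triangle areas exactly.  The denominator
is always the reading-activation area; a symmetric Dice coefficient is
reported as a secondary column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import region_area


@dataclass
class RegionPartition:
    """Named disjoint vertex regions (e.g. frontal / temporal / occipital).

    ``treat_as_map`` lists extra vertex patches counted as belonging to
    the map even if the map mask misses them — e.g. the foveal patch,
    where central fixation suppresses the periodic signal although the
    cortex there is retinotopic.
    """

    regions: dict = field(default_factory=dict)  # name -> set of vertex indices
    treat_as_map: list = field(default_factory=list)  # list of vertex-index sets

    def __post_init__(self) -> None:
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if set(self.regions[a]) & set(self.regions[b]):
                    raise ValueError(f"regions {a!r} and {b!r} overlap")

    def augmented_map(self, map_mask) -> set:
        out = set(map_mask)
        for patch in self.treat_as_map:
            out |= set(patch)
        return out


def _row(reading: set, map_mask: set, areas: np.ndarray) -> dict:
    read_area = region_area(areas, reading)
    inter = reading & map_mask
    over_area = region_area(areas, inter)
    map_area = region_area(areas, map_mask)
    if read_area > 0:
        pct = 100.0 * over_area / read_area
    else:
        pct = np.nan  # undefined, not zero
    denom = read_area + map_area
    dice = 2.0 * over_area / denom if denom > 0 else np.nan
    return {
        "reading_area_mm2": read_area,
        "overlap_area_mm2": over_area,
        "percent_overlap": pct,
        "dice": dice,
    }


def overlap_percentage(
    reading_mask,
    map_mask,
    areas: np.ndarray,
    partition: RegionPartition | None = None,
) -> pd.DataFrame:
    """Overlap report: overall row plus one row per named region.

    Regional rows restrict the reading mask to the region before
    intersecting with the (treat-as-map augmented) map mask.  Percentages
    are exact floats; round only when formatting.
    """
    reading = set(np.asarray(list(reading_mask), dtype=int).tolist())
    partition = partition or RegionPartition()
    mmask = partition.augmented_map(map_mask)
    rows = {"Overall": _row(reading, mmask, areas)}
    for name, region in partition.regions.items():
        rows[name] = _row(reading & set(region), mmask, areas)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df


def multimap_report(
    reading_mask,
    map_masks: dict,
    areas: np.ndarray,
    partition: RegionPartition | None = None,
) -> pd.DataFrame:
    """Per-map overlap rows plus a union row over all map masks.

    The union row answers the headline question — what fraction of the
    reading activation lies within *any* topological map — and is always
    at least as large as every per-map row.
    """
    if not map_masks:
        raise ValueError("need at least one map mask")
    frames = []
    for name, mask in map_masks.items():
        df = overlap_percentage(reading_mask, mask, areas, partition)
        df.insert(0, "map", name)
        frames.append(df)
    union: set = set()
    for mask in map_masks.values():
        union |= set(mask)
    df = overlap_percentage(reading_mask, union, areas, partition)
    df.insert(0, "map", "union")
    frames.append(df)
    out = pd.concat(frames)
    return out.reset_index().set_index(["map", "region"])
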