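"""Functional atlas registry and component matching.

The reference atlas merges four published local parcellations — parietal
cortex (10 components: 5 SPL + 5 IPL), temporoparietal junction (2),
ventral frontal cortex (12) and dorsal frontal cortex (10) — into a
single registry of 34 cortical areas.  Decomposition spatial maps are
assigned to atlas areas by spatial correlation: each area selects the
map whose z-scored values correlate best with the area's z-scored
binary mask over in-brain voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtlasComponent",
    "AtlasRegistry",
    "ComponentAssignment",
    "DEFAULT_ATLAS_TABLE",
    "default_metadata",
    "build_registry",
    "match_components",
]

SUB_ATLASES = ("parietal", "TPJ", "ventral_frontal", "dorsal_frontal")

#: The 34 components of the merged functional atlas:
#: (id, sub_atlas, component code, anatomical area).
DEFAULT_ATLAS_TABLE: tuple[tuple[int, str, str, str], ...] = (
    (1, "parietal", "SPLA", "Ventral intraparietal area (BA 7)"),
    (2, "parietal", "SPLB", "BA 5"),
    (3, "parietal", "SPLC", "Antero-medial intraparietal sulcus"),
    (4, "parietal", "SPLD", "BA 7"),
    (5, "parietal", "SPLE", "Posterior intraparietal sulcus"),
    (6, "parietal", "IPLA", "Parietal operculum"),
    (7, "parietal", "IPLB", "Anterior supramarginal gyrus"),
    (8, "parietal", "IPLC", "Posterior supramarginal gyrus"),
    (9, "parietal", "IPLD", "Anterior angular gyrus"),
    (10, "parietal", "IPLE", "Posterior angular gyrus"),
    (11, "TPJ", "TPJa", "Areas 39, 40, 22"),
    (12, "TPJ", "TPJp", "Areas 39, 40, and 22"),
    (13, "ventral_frontal", "6v", "BA 6"),
    (14, "ventral_frontal", "6r", "BA 6"),
    (15, "ventral_frontal", "IFJ", "Inferior frontal junction (BA 6, 9, 44)"),
    (16, "ventral_frontal", "44d", "BA 44, dorsal"),
    (17, "ventral_frontal", "44v", "BA 44, ventral"),
    (18, "ventral_frontal", "45A", "BA 45"),
    (19, "ventral_frontal", "45", "BA 45"),
    (20, "ventral_frontal", "47", "BA 47"),
    (21, "ventral_frontal", "IFS", "Inferior frontal sulcus (BA 9)"),
    (22, "ventral_frontal", "46", "BA 46"),
    (23, "ventral_frontal", "FPl", "Lateral frontopolar region (BA 10)"),
    (24, "ventral_frontal", "FPm", "Medial frontopolar region (BA 10)"),
    (25, "dorsal_frontal", "Cluster1", "Supplemental motor area (BA 6)"),
    (26, "dorsal_frontal", "Cluster2", "Pre-supplemental motor area (BA 6)"),
    (27, "dorsal_frontal", "Cluster3", "BA 9"),
    (28, "dorsal_frontal", "Cluster4", "BA 10"),
    (29, "dorsal_frontal", "Cluster5", "BA 9, 46"),
    (30, "dorsal_frontal", "Cluster6", "BA 9, 46"),
    (31, "dorsal_frontal", "Cluster7", "BA 46"),
    (32, "dorsal_frontal", "Cluster8", "BA 8"),
    (33, "dorsal_frontal", "Cluster9", "Anterior, dorsal premotor area (BA 6)"),
    (34, "dorsal_frontal", "Cluster10", "BA 8"),
)


def default_metadata() -> pd.DataFrame:
    """The merged atlas metadata as a table (id, sub_atlas, component, anatomical_area)."""
    return pd.DataFrame(
        DEFAULT_ATLAS_TABLE, columns=["id", "sub_atlas", "component", "anatomical_area"]
    )


@dataclass(frozen=True)
class AtlasComponent:
    id: int
    name: str
    sub_atlas: str
    anatomical_label: str
    mask: np.ndarray  # flat voxel indices

    def __post_init__(self) -> None:
        if self.mask.size == 0:
            raise ValueError(f"atlas component {self.id} ({self.name}) has an empty mask")
        if self.sub_atlas not in SUB_ATLASES:
            raise ValueError(f"unknown sub-atlas {self.sub_atlas!r}")


class AtlasRegistry:
    """The named atlas components together with their label volume."""

    def __init__(self, components: list[AtlasComponent], label_volume: np.ndarray):
        ids = [c.id for c in components]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atlas component ids")
        names = [c.name for c in components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate atlas component names")
        self.components = sorted(components, key=lambda c: c.id)
        self.label_volume = label_volume

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, area_id: int) -> AtlasComponent:
        for c in self.components:
            if c.id == area_id:
                return c
        raise KeyError(area_id)

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.components]

    def sub_atlas(self, name: str) -> list[AtlasComponent]:
        return [c for c in self.components if c.sub_atlas == name]

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.id, c.sub_atlas, c.name, c.anatomical_label) for c in self.components],
            columns=["id", "sub_atlas", "component", "anatomical_area"],
        )


@dataclass
class ComponentAssignment:
    """Per atlas area: index of the best-matching spatial map and its correlation."""

    area_ids: list[int]
    map_index: dict[int, int]
    correlation: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "area_id": self.area_ids,
                "map_index": [self.map_index[a] for a in self.area_ids],
                "correlation": [self.correlation[a] for a in self.area_ids],
            }
        )


def build_registry(
    label_volume: np.ndarray, metadata_table: pd.DataFrame | None = None
) -> AtlasRegistry:
    """Assemble an :class:`AtlasRegistry` from a label volume and metadata.

    ``label_volume`` holds integers 0 (background) and the component ids;
    every id in the metadata must be present in the volume.  With no
    metadata the 34-area default table is used.
    """
    if metadata_table is None:
        metadata_table = default_metadata()
    required = {"id", "sub_atlas", "component", "anatomical_area"}
    missing_cols = required - set(metadata_table.columns)
    if missing_cols:
        raise ValueError(f"metadata missing columns {sorted(missing_cols)}")
    flat = np.asarray(label_volume).ravel()
    components = []
    for row in metadata_table.itertuples(index=False):
        mask = np.nonzero(flat == int(row.id))[0]
        if mask.size == 0:
            raise ValueError(
                f"label volume has no voxels for atlas id {row.id} ({row.component})"
            )
        components.append(
            AtlasComponent(
                id=int(row.id),
                name=str(row.component),
                sub_atlas=str(row.sub_atlas),
                anatomical_label=str(row.anatomical_area),
                mask=mask,
            )
        )
    return AtlasRegistry(components, np.asarray(label_volume))


def _zscore(v: np.ndarray) -> np.ndarray | None:
    sd = v.std()
    if sd == 0:
        return None
    return (v - v.mean()) / sd


def match_components(
    spatial_maps: np.ndarray,
    registry: AtlasRegistry,
    brain_mask: np.ndarray | None = None,
) -> ComponentAssignment:
    """Assign each atlas area the spatial map it correlates best with.

    ``spatial_maps`` is (n_maps, n_voxels) on the registry's grid.  For
    every area the Pearson correlation between the z-scored binary area
    mask and each z-scored map is computed over in-brain voxels (default:
    all voxels); the argmax map wins, ties broken by lowest map index.
    The same map may serve several areas.  Zero-variance maps are
    excluded with a warning; correlations keep their sign.
    """
    maps = np.atleast_2d(np.asarray(spatial_maps, dtype=float))
    if maps.shape[0] == 0:
        raise ValueError("need at least one spatial map")
    n_vox = registry.label_volume.size
    if maps.shape[1] != n_vox:
        raise ValueError(
            f"maps have {maps.shape[1]} voxels but atlas grid has {n_vox}"
        )
    if brain_mask is None:
        in_brain = np.ones(n_vox, dtype=bool)
    else:
        in_brain = np.asarray(brain_mask).ravel().astype(bool)
    z_maps: dict[int, np.ndarray] = {}
    for m in range(maps.shape[0]):
        z = _zscore(maps[m, in_brain])
        if z is None:
            warnings.warn(
                f"spatial map {m} has zero variance over in-brain voxels; excluded",
                stacklevel=2,
            )
            continue
        z_maps[m] = z
    if not z_maps:
        raise ValueError("all spatial maps have zero variance; nothing to match")
    n = int(in_brain.sum())
    area_ids, map_index, correlation = [], {}, {}
    for comp in registry.components:
        mask_vec = np.zeros(n_vox)
        mask_vec[comp.mask] = 1.0
        z_mask = _zscore(mask_vec[in_brain])
        if z_mask is None:
            raise ValueError(f"atlas area {comp.id} mask constant over in-brain voxels")
        best_m, best_r = None, -np.inf
        for m in sorted(z_maps):
            r = float(z_mask @ z_maps[m]) / n
            if r > best_r + 1e-15:
                best_m, best_r = m, r
        area_ids.append(comp.id)
        map_index[comp.id] = best_m
        correlation[comp.id] = best_r
    return ComponentAssignment(area_ids, map_index, correlation)
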