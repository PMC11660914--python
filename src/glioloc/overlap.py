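"""Lesion-atlas overlap quantification and group frequency maps.

Three overlap measures are produced per subject:

* lobar involvement — a lobe counts as involved when the lesion covers
  at least ``min_voxels`` (default 250) of it;
* tissue-compartment overlap — voxels, mL and fraction-of-lesion for
  cortex, white matter and deep grey nuclei (fractions need not sum to
  1: lesion voxels may fall outside all three);
* within-tissue network ratios — per functional network, the lesion
  voxels inside that network divided by the lesion voxels inside the
  union of all networks of the same tissue; defined ratios sum to 1.

Undefined quantities (empty lesion, lesion missing every network) are
reported as NaN, never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from glioloc.imaging import (
    ImageGrid,
    LabelAtlas,
    LesionMask,
    _require_same_grid,
    write_image,
)

logger = logging.getLogger(__name__)

COMPARTMENT_CLASSES = ("cortex", "white_matter", "deep_grey")


@dataclass(frozen=True)
class OverlapEntry:
    region_name: str
    tissue_class: str
    overlap_voxels: int
    overlap_ml: float
    fraction_of_lesion: float  # NaN when the lesion is empty
    within_tissue_ratio: float  # NaN when undefined / not applicable


@dataclass
class OverlapProfile:
    subject_id: str
    entries: list[OverlapEntry] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries]).assign(subject_id=self.subject_id)

    def get(self, region_name: str) -> OverlapEntry:
        for e in self.entries:
            if e.region_name == region_name:
                return e
        raise KeyError(region_name)


@dataclass
class FrequencyMap:
    """Voxel-wise count of subjects whose lesion covers each voxel."""

    grid: ImageGrid
    counts: np.ndarray
    group_label: str = "all"
    display_threshold: int = 2

    @property
    def display_counts(self) -> np.ndarray:
        """Counts with voxels below the display threshold zeroed."""
        out = self.counts.copy()
        out[out < self.display_threshold] = 0
        return out

    def write(self, out_dir: str | Path, prefix: str | None = None) -> None:
        prefix = prefix or f"frequency_{self.group_label}"
        out_dir = Path(out_dir)
        write_image(out_dir / f"{prefix}_raw.nii.gz", self.counts.astype(np.int16), self.grid)
        write_image(
            out_dir / f"{prefix}_thr{self.display_threshold}.nii.gz",
            self.display_counts.astype(np.int16),
            self.grid,
        )


def _overlap_counts(mask: LesionMask, atlas: LabelAtlas) -> dict[int, int]:
    """Voxel intersection count per atlas label (labels are exclusive)."""
    _require_same_grid(mask.grid, atlas.grid, "mask and atlas")
    inside = atlas.labels[mask.bool()]
    if inside.size == 0:
        return {int(l): 0 for l in atlas.label_ids}
    counts = np.bincount(inside, minlength=int(atlas.labels.max()) + 1)
    return {int(l): int(counts[l]) if l < len(counts) else 0 for l in atlas.label_ids}


def lobar_involvement(
    mask: LesionMask, lobes: LabelAtlas, min_voxels: int = 250
) -> set[str]:
    """Lobes whose labels the lesion overlaps by at least ``min_voxels`` voxels.

    The threshold is inclusive: an overlap of exactly ``min_voxels``
    counts as involvement.
    """
    if not (lobes.table["tissue_class"] == "lobe").all():
        raise ValueError("lobar_involvement expects an atlas with tissue_class 'lobe'")
    counts = _overlap_counts(mask, lobes)
    names = dict(zip(lobes.table["label_id"], lobes.table["region_name"]))
    return {names[l] for l, c in counts.items() if c >= min_voxels}


def compartment_overlap(mask: LesionMask, tissue: LabelAtlas) -> OverlapProfile:
    """Overlap with cortex / white matter / deep grey nuclei.

    ``fraction_of_lesion`` is overlap voxels over lesion voxels and is
    NaN for an empty lesion. Classes may each comprise several labels
    (e.g. individual deep nuclei); counts aggregate over the class.
    """
    present = set(tissue.table["tissue_class"])
    missing = set(COMPARTMENT_CLASSES) - present
    if missing:
        raise ValueError(f"tissue atlas lacks classes: {sorted(missing)}")
    counts = _overlap_counts(mask, tissue)
    vv = mask.grid.voxel_volume
    n_lesion = mask.n_voxels
    profile = OverlapProfile(subject_id=mask.subject_id)
    for cls in COMPARTMENT_CLASSES:
        ids = tissue.table.loc[tissue.table["tissue_class"] == cls, "label_id"]
        vox = int(sum(counts[int(l)] for l in ids))
        frac = vox / n_lesion if n_lesion > 0 else float("nan")
        profile.entries.append(
            OverlapEntry(
                region_name=cls,
                tissue_class=cls,
                overlap_voxels=vox,
                overlap_ml=vox * vv / 1000.0,
                fraction_of_lesion=frac,
                within_tissue_ratio=float("nan"),
            )
        )
    return profile


def network_overlap_ratio(mask: LesionMask, networks: LabelAtlas) -> OverlapProfile:
    """Within-tissue overlap ratio for each functional network.

    ratio(n) = lesion voxels in network n / lesion voxels in the union
    of all networks of the atlas. Ratios sum to 1 when the denominator
    is positive; all are NaN when the lesion misses every network.
    """
    classes = set(networks.table["tissue_class"])
    if not classes <= {"gm_network", "wm_network"} or len(classes) != 1:
        raise ValueError("network atlas must have a single network tissue_class")
    cls = classes.pop()
    counts = _overlap_counts(mask, networks)
    denom = sum(counts.values())
    vv = mask.grid.voxel_volume
    n_lesion = mask.n_voxels
    profile = OverlapProfile(subject_id=mask.subject_id)
    if denom == 0:
        logger.info(
            "subject %s: lesion outside all %s parcels; ratios undefined",
            mask.subject_id,
            cls,
        )
    for _, row in networks.table.iterrows():
        vox = counts[int(row["label_id"])]
        ratio = vox / denom if denom > 0 else float("nan")
        frac = vox / n_lesion if n_lesion > 0 else float("nan")
        profile.entries.append(
            OverlapEntry(
                region_name=str(row["region_name"]),
                tissue_class=cls,
                overlap_voxels=vox,
                overlap_ml=vox * vv / 1000.0,
                fraction_of_lesion=frac,
                within_tissue_ratio=ratio,
            )
        )
    return profile


def frequency_map(
    masks: Sequence[LesionMask],
    display_threshold: int = 2,
    group_label: str = "all",
) -> FrequencyMap:
    """Voxel-wise sum of a group's binary masks.

    The raw count map is retained; the displayed map zeroes voxels
    covered by fewer than ``display_threshold`` subjects.
    """
    if len(masks) == 0:
        raise ValueError("frequency_map requires at least one mask")
    grid = masks[0].grid
    counts = np.zeros(grid.dims, dtype=np.int32)
    for m in masks:
        _require_same_grid(grid, m.grid, "frequency-map masks")
        counts += m.values
    return FrequencyMap(
        grid=grid, counts=counts, group_label=group_label, display_threshold=display_threshold
    )


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------


def overlap_table(
    masks: Sequence[LesionMask],
    atlas: LabelAtlas,
    measure: str = "fraction",
) -> pd.DataFrame:
    """Subjects x regions table of one overlap measure for one atlas family.

    ``measure`` is one of ``voxels``, ``ml``, ``fraction``
    (fraction-of-lesion) or ``ratio`` (within-tissue network ratio;
    network atlases only).
    """
    rows = {}
    classes = set(atlas.table["tissue_class"])
    for m in masks:
        if measure == "ratio":
            prof = network_overlap_ratio(m, atlas)
            rows[m.subject_id] = {e.region_name: e.within_tissue_ratio for e in prof.entries}
        else:
            counts = _overlap_counts(m, atlas)
            names = dict(zip(atlas.table["label_id"], atlas.table["region_name"]))
            vv = m.grid.voxel_volume
            n = m.n_voxels
            rows[m.subject_id] = {
                names[l]: (
                    c
                    if measure == "voxels"
                    else c * vv / 1000.0
                    if measure == "ml"
                    else (c / n if n else float("nan"))
                )
                for l, c in counts.items()
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def compartment_table(masks: Sequence[LesionMask], tissue: LabelAtlas) -> pd.DataFrame:
    """Subjects x {cortex, white_matter, deep_grey} x {voxels, ml, fraction}."""
    rows = []
    for m in masks:
        prof = compartment_overlap(m, tissue)
        row: dict[str, float] = {"subject_id": m.subject_id}
        for e in prof.entries:
            row[f"{e.region_name}_voxels"] = e.overlap_voxels
            row[f"{e.region_name}_ml"] = e.overlap_ml
            row[f"{e.region_name}_fraction"] = e.fraction_of_lesion
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
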