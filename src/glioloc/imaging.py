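"""NIfTI lesion-mask and atlas IO on a shared template grid.

Everything downstream counts voxels, so the module is strict about
grids: masks and atlases must live on one grid (dims + affine within
tolerance) and mismatches raise instead of silently resampling. An
explicit nearest-neighbour resampler is available for the rare case
where resampling is genuinely wanted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: absolute tolerance (mm) for element-wise affine agreement
GRID_ATOL = 1e-4

COMPARTMENTS = ("core", "oedema", "global")
TISSUE_CLASSES = (
    "lobe",
    "cortex",
    "white_matter",
    "deep_grey",
    "gm_network",
    "wm_network",
)


class GridMismatchError(ValueError):
    """Raised when two images do not share a template grid."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel grid: dimensions plus a voxel-to-world affine (mm)."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) <= 0.0:
            raise ValueError("affine upper-left 3x3 block is singular")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "ImageGrid", atol: float = GRID_ATOL) -> bool:
        return check_same_grid(self, other, atol=atol)


def check_same_grid(a: ImageGrid, b: ImageGrid, atol: float = GRID_ATOL) -> bool:
    """True iff dims are equal and affines agree element-wise within ``atol`` mm."""
    return a.dims == b.dims and bool(np.allclose(a.affine, b.affine, rtol=0.0, atol=atol))


def _require_same_grid(a: ImageGrid, b: ImageGrid, what: str = "images") -> None:
    if not check_same_grid(a, b):
        raise GridMismatchError(
            f"{what} are on different grids: dims {a.dims} vs {b.dims}; "
            "resample explicitly with resample_nearest() if this is intended"
        )


@dataclass
class LesionMask:
    """A subject's binary lesion occupancy for one tumour compartment.

    ``compartment`` is one of ``core`` (enhancing + non-enhancing tumour
    and necrosis), ``oedema``, or ``global`` (their union).
    """

    grid: ImageGrid
    values: np.ndarray
    compartment: str = "core"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != self.grid.dims:
            raise ValueError(f"values shape {v.shape} != grid dims {self.grid.dims}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("lesion mask values must be binary (0/1)")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"compartment must be one of {COMPARTMENTS}")
        self.values = v.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        return mask_volume_ml(self)

    def bool(self) -> np.ndarray:
        return self.values.astype(bool)


def union_mask(core: LesionMask, oedema: LesionMask, subject_id: str | None = None) -> LesionMask:
    """Global compartment: voxel-wise union of core and oedema."""
    _require_same_grid(core.grid, oedema.grid, "core and oedema masks")
    return LesionMask(
        grid=core.grid,
        values=(core.bool() | oedema.bool()).astype(np.uint8),
        compartment="global",
        subject_id=subject_id if subject_id is not None else core.subject_id,
    )


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation plus its label table.

    The table maps ``label_id`` to ``region_name`` and ``tissue_class``
    (one of ``lobe``, ``cortex``, ``white_matter``, ``deep_grey``,
    ``gm_network``, ``wm_network``). Label 0 is background.
    """

    grid: ImageGrid
    labels: np.ndarray
    table: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.dims:
            raise ValueError(f"labels shape {lab.shape} != grid dims {self.grid.dims}")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("atlas labels must be integers")
            lab = np.round(lab).astype(np.int32)
        self.labels = lab.astype(np.int32)
        t = pd.DataFrame(self.table, columns=["label_id", "region_name", "tissue_class"])
        t["label_id"] = t["label_id"].astype(int)
        if t["label_id"].duplicated().any():
            raise ValueError("duplicate label_id in atlas table")
        bad = set(t["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown tissue_class values: {sorted(bad)}")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(t["label_id"])
        if missing:
            raise ValueError(f"labels present in volume but absent from table: {sorted(missing)}")
        self.table = t.reset_index(drop=True)

    @property
    def label_ids(self) -> np.ndarray:
        return self.table["label_id"].to_numpy()

    def region_names(self) -> list[str]:
        return list(self.table["region_name"])

    def mask_of(self, region_name: str) -> np.ndarray:
        row = self.table[self.table["region_name"] == region_name]
        if row.empty:
            raise KeyError(f"region {region_name!r} not in atlas table")
        return self.labels == int(row["label_id"].iloc[0])


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def _load_volume(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    grid = ImageGrid(dims=tuple(data.shape), affine=np.asarray(img.affine))
    return data, grid


def read_mask(
    path: str | Path,
    grid_ref: ImageGrid | None = None,
    compartment: str = "core",
    subject_id: str = "",
    threshold: float = 0.5,
) -> LesionMask:
    """Read a lesion mask, binarizing at ``threshold`` (value > 0.5 -> 1).

    If ``grid_ref`` is given the file's grid must match it within
    tolerance; mismatches raise :class:`GridMismatchError` rather than
    resampling.
    """
    data, grid = _load_volume(path)
    if grid_ref is not None:
        _require_same_grid(grid, grid_ref, f"mask {path} and reference grid")
    values = (data > threshold).astype(np.uint8)
    return LesionMask(grid=grid, values=values, compartment=compartment, subject_id=subject_id)


def write_image(path: str | Path, values: np.ndarray, grid: ImageGrid) -> None:
    """Write a 3D array as NIfTI on ``grid``."""
    values = np.asarray(values)
    if values.shape != grid.dims:
        raise ValueError(f"values shape {values.shape} != grid dims {grid.dims}")
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = nib.Nifti1Image(values, np.asarray(grid.affine))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_atlas(
    nifti_path: str | Path,
    table_path: str | Path,
    grid_ref: ImageGrid | None = None,
    name: str = "",
) -> LabelAtlas:
    """Read a label volume and its TSV table (label_id, region_name, tissue_class)."""
    data, grid = _load_volume(nifti_path)
    if grid_ref is not None:
        _require_same_grid(grid, grid_ref, f"atlas {nifti_path} and reference grid")
    table = pd.read_csv(table_path, sep="\t")
    return LabelAtlas(grid=grid, labels=data, table=table, name=name or Path(nifti_path).stem)


def write_atlas(nifti_path: str | Path, table_path: str | Path, atlas: LabelAtlas) -> None:
    write_image(nifti_path, atlas.labels.astype(np.int16), atlas.grid)
    Path(table_path).parent.mkdir(parents=True, exist_ok=True)
    atlas.table.to_csv(table_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def mask_volume_ml(mask: LesionMask) -> float:
    """Lesion volume in mL: lesioned voxel count x voxel volume / 1000."""
    return mask.n_voxels * mask.grid.voxel_volume / 1000.0


def lr_axis(grid: ImageGrid) -> int:
    """Voxel axis most aligned with the world left-right (x) direction."""
    return int(np.argmax(np.abs(grid.affine[0, :3])))


def _midline_world_x(grid: ImageGrid, axis: int) -> float:
    centre = np.array([(d - 1) / 2.0 for d in grid.dims])
    return float(grid.voxel_to_world(centre)[0, 0])


def flip_lateral(mask: LesionMask, mode: str = "mirror") -> LesionMask:
    """Reflect a lesion about the mid-sagittal voxel plane.

    Modes
    -----
    ``mirror``
        Unconditional reflection (an involution).
    ``unify_left`` / ``unify_right``
        Reflect only when the lesion's centre of mass lies in the
        opposite hemisphere, so that all lesions end up on one side.
        A centre of mass exactly on the midline is treated as already
        unified (logged).
    """
    if mode not in ("mirror", "unify_left", "unify_right"):
        raise ValueError(f"unknown flip mode {mode!r}")
    axis = lr_axis(mask.grid)
    if mode == "mirror":
        return LesionMask(
            grid=mask.grid,
            values=np.flip(mask.values, axis=axis).copy(),
            compartment=mask.compartment,
            subject_id=mask.subject_id,
        )
    if mask.n_voxels == 0:
        return mask
    com = np.array(ndimage.center_of_mass(mask.values))
    x_com = float(mask.grid.voxel_to_world(com)[0, 0])
    x_mid = _midline_world_x(mask.grid, axis)
    if x_com == x_mid:
        logger.info(
            "subject %s: lesion centre of mass on the midline; treated as already unified",
            mask.subject_id,
        )
        return mask
    on_right = x_com > x_mid
    want_right = mode == "unify_right"
    if on_right == want_right:
        return mask
    return flip_lateral(mask, "mirror")


def hemisphere_of(mask: LesionMask) -> str:
    """``left`` or ``right`` by the lesion centre of mass in world x (ties -> left)."""
    if mask.n_voxels == 0:
        raise ValueError("empty lesion has no hemisphere")
    axis = lr_axis(mask.grid)
    com = np.array(ndimage.center_of_mass(mask.values))
    x_com = float(mask.grid.voxel_to_world(com)[0, 0])
    return "right" if x_com > _midline_world_x(mask.grid, axis) else "left"


def grid_is_lr_symmetric(grid: ImageGrid, brain: np.ndarray) -> bool:
    """Self-check for unify modes: the brain mask must equal its mirror."""
    axis = lr_axis(grid)
    return bool(np.array_equal(brain, np.flip(brain, axis=axis)))


def resample_nearest(values: np.ndarray, src: ImageGrid, dst: ImageGrid) -> np.ndarray:
    """Opt-in nearest-neighbour resampling of ``values`` from ``src`` onto ``dst``.

    Changes voxel counts; never applied implicitly.
    """
    # dst voxel -> world -> src voxel
    m = np.linalg.inv(src.affine) @ dst.affine
    out = ndimage.affine_transform(
        np.asarray(values, dtype=float),
        m[:3, :3],
        offset=m[:3, 3],
        output_shape=dst.dims,
        order=0,
        mode="constant",
        cval=0.0,
    )
    if np.issubdtype(np.asarray(values).dtype, np.integer) or np.asarray(values).dtype == bool:
        return np.round(out).astype(np.asarray(values).dtype)
    return out
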