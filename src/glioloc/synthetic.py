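"""Synthetic template, atlases, lesions and cohort manifests.

The generator emulates the study conditions of a 93-subject
glioblastoma cohort: 42 methylated subjects (41 with a quantified
methylation percentage, mean 33.9 +/- 18.3%), core volumes
43.2 +/- 29.3 mL, oedema 54.8 +/- 43.4 mL, and a planted positive
population correlation (+0.36) between the methylation percentage and
the fraction of the core overlapping cortex. The anticorrelation with
deep grey matter involvement is not planted independently; it arises
from the compositional cortex/deep trade-off of lesion placement and
is verified rather than imposed.

Geometry: a mirror-symmetric ellipsoidal "brain" on an isotropic grid
(field of view fixed at 128 mm, so voxel size scales with the grid
dimension; 64^3 -> 2 mm). An outer ribbon is cortex, the interior
white matter, two paired central blobs deep grey. Lobes are five
angular sectors; grey-matter networks partition cortex + deep grey
into 7 parcels and white-matter networks partition white matter into
4. Lesions are grown by stochastic 6-connected region growing from a
seed voxel whose tissue placement is biased per subject.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from glioloc.imaging import (
    ImageGrid,
    LabelAtlas,
    LesionMask,
    grid_is_lr_symmetric,
    hemisphere_of,
    union_mask,
    write_atlas,
    write_image,
)
from glioloc.overlap import compartment_overlap
from glioloc.stats import classify_methylation

logger = logging.getLogger(__name__)

FOV_MM = 128.0  # fixed field of view; voxel size = FOV / dims

LOBE_NAMES = ("frontal", "parietal", "temporal", "occipital", "insular")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from a global seed."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class SyntheticCohortSpec:
    """Study conditions for the synthetic cohort (defaults = the emulated cohort)."""

    n_subjects: int = 93
    n_methylated: int = 42
    n_quantified: int = 41
    methylation_mean: float = 33.9
    methylation_sd: float = 18.3
    methylation_floor: float = 8.0
    core_volume_mean: float = 43.2
    core_volume_sd: float = 29.3
    oedema_volume_mean: float = 54.8
    oedema_volume_sd: float = 43.4
    planted_r_cortex: float = 0.36
    planted_r_deep: float = -0.35
    age_mean: float = 62.3
    age_sd: float = 11.3
    n_male: int = 66
    grid_dims: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_methylated <= self.n_subjects):
            raise ValueError("n_methylated must be <= n_subjects")
        if not (self.n_quantified <= self.n_methylated):
            raise ValueError("n_quantified must be <= n_methylated")
        for name in ("methylation_sd", "core_volume_sd", "oedema_volume_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("planted_r_cortex", "planted_r_deep"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")


def fixtures_spec(seed: int = 0) -> SyntheticCohortSpec:
    """A 5-subject micro-cohort on a small grid, for unit tests and smoke runs."""
    return SyntheticCohortSpec(
        n_subjects=5,
        n_methylated=3,
        n_quantified=3,
        n_male=3,
        grid_dims=(24, 24, 24),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Template and atlases
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTemplate:
    grid: ImageGrid
    brain: np.ndarray  # bool
    lobes: LabelAtlas
    tissue: LabelAtlas
    gmn: LabelAtlas
    wmn: LabelAtlas

    @property
    def atlases(self) -> dict[str, LabelAtlas]:
        return {"lobes": self.lobes, "tissue": self.tissue, "gmn": self.gmn, "wmn": self.wmn}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        write_image(out / "brain_mask.nii.gz", self.brain.astype(np.uint8), self.grid)
        for name, atlas in self.atlases.items():
            write_atlas(out / f"atlas_{name}.nii.gz", out / f"atlas_{name}.tsv", atlas)


def _make_grid(dims: tuple[int, int, int]) -> ImageGrid:
    dims = tuple(int(d) for d in dims)
    vs = FOV_MM / dims[0]
    affine = np.diag([vs, vs, vs, 1.0])
    # centre the grid so the mid-voxel plane is world x = 0 (RAS, x = left-right)
    affine[:3, 3] = [-vs * (d - 1) / 2.0 for d in dims]
    return ImageGrid(dims=dims, affine=affine)


def generate_template(
    dims: tuple[int, int, int] | int = (64, 64, 64), seed: int = 0
) -> SyntheticTemplate:
    """Build a mirror-symmetric brain with lobar, tissue and network atlases.

    All parcellations are functions of |x| and the (y, z) angle only,
    so every atlas equals its own mirror image label-for-label and the
    unify flip modes pass their symmetry self-check by construction.
    """
    if isinstance(dims, int):
        dims = (dims, dims, dims)
    if min(dims) < 16:
        raise ValueError("grid dims must be >= 16 per axis to fit all compartments")
    grid = _make_grid(dims)
    d0, d1, d2 = dims
    idx = np.indices(dims, dtype=float)
    # normalized coordinates in [-1, 1] (0 at the mid-voxel plane)
    u = [(idx[a] - (dims[a] - 1) / 2.0) / (dims[a] / 2.0) for a in range(3)]
    semi = (0.82, 0.92, 0.78)
    r2 = (u[0] / semi[0]) ** 2 + (u[1] / semi[1]) ** 2 + (u[2] / semi[2]) ** 2
    brain = r2 <= 1.0

    # cortex = outer ribbon of the brain (2 voxels at 64^3, scaled with dims)
    thickness = max(2, round(dims[0] / 32))
    edt = ndimage.distance_transform_edt(brain)
    cortex = brain & (edt <= thickness)

    # deep grey = two blobs paired across the midline
    deep_r = 0.18
    deep_c2 = (np.abs(u[0]) - 0.30) ** 2 + u[1] ** 2 + u[2] ** 2
    deep = brain & ~cortex & (deep_c2 <= deep_r**2)
    white = brain & ~cortex & ~deep

    if not (cortex.any() and deep.any() and white.any()):
        raise ValueError(f"dims {dims} too small to contain all tissue compartments")

    theta = np.arctan2(u[2], u[1])  # independent of x -> mirror-symmetric

    def sectors(region: np.ndarray, n: int, offset: float = 0.0) -> np.ndarray:
        bins = np.floor((theta + math.pi + offset) / (2 * math.pi) * n).astype(int) % n
        out = np.zeros(dims, dtype=np.int32)
        out[region] = bins[region] + 1
        return out

    lobes = LabelAtlas(
        grid=grid,
        labels=sectors(brain, 5),
        table=pd.DataFrame(
            {"label_id": range(1, 6), "region_name": LOBE_NAMES, "tissue_class": "lobe"}
        ),
        name="lobes",
    )

    tissue_labels = np.zeros(dims, dtype=np.int32)
    tissue_labels[cortex] = 1
    tissue_labels[white] = 2
    tissue_labels[deep] = 3
    tissue = LabelAtlas(
        grid=grid,
        labels=tissue_labels,
        table=pd.DataFrame(
            {
                "label_id": [1, 2, 3],
                "region_name": ["cortex", "white_matter", "deep_grey"],
                "tissue_class": ["cortex", "white_matter", "deep_grey"],
            }
        ),
        name="tissue",
    )

    # grey-matter networks: 5 cortical sectors + 2 deep parcels (ant/post)
    gmn_labels = sectors(cortex, 5, offset=math.pi / 5)
    gmn_labels[deep & (u[1] > 0)] = 6
    gmn_labels[deep & (u[1] <= 0)] = 7
    gmn = LabelAtlas(
        grid=grid,
        labels=gmn_labels,
        table=pd.DataFrame(
            {
                "label_id": range(1, 8),
                "region_name": [f"gmn_{i}" for i in range(1, 6)] + ["deep_anterior", "deep_posterior"],
                "tissue_class": "gm_network",
            }
        ),
        name="gmn",
    )

    wmn = LabelAtlas(
        grid=grid,
        labels=sectors(white, 4, offset=math.pi / 7),
        table=pd.DataFrame(
            {
                "label_id": range(1, 5),
                "region_name": [f"wmn_{i}" for i in range(1, 5)],
                "tissue_class": "wm_network",
            }
        ),
        name="wmn",
    )

    template = SyntheticTemplate(grid=grid, brain=brain, lobes=lobes, tissue=tissue, gmn=gmn, wmn=wmn)
    if not grid_is_lr_symmetric(grid, brain):
        raise AssertionError("template failed the left-right symmetry self-check")
    return template


# ---------------------------------------------------------------------------
# Lesion growing
# ---------------------------------------------------------------------------

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_OFFSETS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64
)


def _grow_region(
    allowed: np.ndarray,
    start: np.ndarray,
    target: int,
    rng: np.random.Generator,
    frontier_keep: float = 0.65,
) -> np.ndarray:
    """Stochastic 6-connected growth of ``start`` inside ``allowed`` to ``target`` voxels.

    A persistent frontier pool holds every allowed voxel adjacent to
    the region; each iteration accepts a random subset (probability
    ``frontier_keep``) and enqueues the neighbours of the accepted
    voxels. The final batch is subsampled exactly, so the achieved
    count equals ``target`` unless growth is trapped by the allowed
    region. 6-connectivity of the result is guaranteed by
    construction.
    """
    shape = allowed.shape
    region = start.copy()
    count = int(region.sum())
    if count >= target:
        return region
    candidate = np.zeros(shape, dtype=bool)
    region_flat = region.reshape(-1)
    allowed_flat = allowed.reshape(-1)
    cand_flat = candidate.reshape(-1)
    dims = np.array(shape)

    def _new_neighbours(coords: np.ndarray) -> np.ndarray:
        nb = (coords[:, None, :] + _OFFSETS6[None, :, :]).reshape(-1, 3)
        ok = np.all((nb >= 0) & (nb < dims), axis=1)
        nb = nb[ok]
        flat = np.ravel_multi_index((nb[:, 0], nb[:, 1], nb[:, 2]), shape)
        flat = flat[allowed_flat[flat] & ~region_flat[flat] & ~cand_flat[flat]]
        flat = np.unique(flat)
        cand_flat[flat] = True
        return np.column_stack(np.unravel_index(flat, shape))

    pool = _new_neighbours(np.argwhere(region))
    while count < target and len(pool):
        keep = rng.random(len(pool)) < frontier_keep
        if not keep.any():
            keep[rng.integers(len(pool))] = True
        sel = pool[keep]
        rest = pool[~keep]
        if count + len(sel) > target:
            sel = sel[rng.choice(len(sel), size=target - count, replace=False)]
        flat = np.ravel_multi_index((sel[:, 0], sel[:, 1], sel[:, 2]), shape)
        region_flat[flat] = True
        count += len(sel)
        if count >= target:
            break
        pool = np.concatenate([rest, _new_neighbours(sel)])
    return region


def _seed_pools(template: "SyntheticTemplate") -> tuple[np.ndarray, np.ndarray]:
    """Cortex-adjacent and deep-adjacent seed-voxel pools (cached on the template)."""
    cached = getattr(template, "_seed_pool_cache", None)
    if cached is None:
        tissue = template.tissue.labels
        cortex_idx = np.argwhere(tissue == 1)
        deep_like = ndimage.binary_dilation(tissue == 3, _STRUCT6, iterations=2) & template.brain
        deep_idx = np.argwhere(deep_like)
        cached = (cortex_idx, deep_idx)
        object.__setattr__(template, "_seed_pool_cache", cached)
    return cached


def _crop_box(shape: tuple[int, ...], centre: np.ndarray, half: int) -> tuple[slice, ...]:
    return tuple(
        slice(max(0, int(c) - half), min(s, int(c) + half + 1)) for c, s in zip(centre, shape)
    )


def generate_lesion(
    template: SyntheticTemplate,
    rng: np.random.Generator,
    target_core_ml: float,
    target_oedema_ml: float,
    cortex_bias: float = 0.7,
    subject_id: str = "",
    max_retries: int = 6,
) -> tuple[LesionMask, LesionMask]:
    """Grow a core and a surrounding disjoint oedema shell.

    The seed voxel is sampled from cortex-adjacent tissue with
    probability ``cortex_bias`` and from deep-adjacent tissue
    otherwise; both regions stay inside the brain mask. Growth that
    gets trapped before reaching 90% of the core target is retried
    from a fresh seed voxel (bounded retries).
    """
    grid = template.grid
    vv = grid.voxel_volume
    core_target = max(8, int(round(target_core_ml * 1000.0 / vv)))
    oedema_target = max(8, int(round(target_oedema_ml * 1000.0 / vv)))
    brain_n = int(template.brain.sum())
    if core_target + oedema_target > 0.9 * brain_n:
        raise ValueError("target lesion volume not achievable within the brain mask")

    cortex_idx, deep_idx = _seed_pools(template)

    half = int(np.ceil((3.0 * (core_target + oedema_target) / (4.0 * math.pi)) ** (1.0 / 3.0) * 2.0)) + 3

    for attempt in range(max_retries):
        pool = cortex_idx if rng.random() < cortex_bias else deep_idx
        seed_vox = pool[rng.integers(len(pool))]
        box = _crop_box(grid.dims, seed_vox, half)
        allowed = template.brain[box]
        start = np.zeros_like(allowed)
        start[tuple(seed_vox - np.array([s.start for s in box]))] = True
        core_local = _grow_region(allowed, start, core_target, rng)
        achieved = int(core_local.sum())
        if achieved >= 0.9 * core_target:
            global_local = _grow_region(allowed, core_local, achieved + oedema_target, rng)
            core = np.zeros(grid.dims, dtype=np.uint8)
            core[box] = core_local.astype(np.uint8)
            glob = np.zeros(grid.dims, dtype=np.uint8)
            glob[box] = global_local.astype(np.uint8)
            oedema = (glob.astype(bool) & ~core.astype(bool)).astype(np.uint8)
            return (
                LesionMask(grid=grid, values=core, compartment="core", subject_id=subject_id),
                LesionMask(grid=grid, values=oedema, compartment="oedema", subject_id=subject_id),
            )
        logger.debug("lesion growth trapped (attempt %d, %d/%d voxels); retrying", attempt, achieved, core_target)
    raise RuntimeError(
        f"lesion growth trapped after {max_retries} retries (target {core_target} voxels)"
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    template: SyntheticTemplate
    manifest: pd.DataFrame
    core_masks: dict[str, LesionMask]
    oedema_masks: dict[str, LesionMask]
    achieved_r_cortex: float

    def write(self, out_dir: str | Path) -> Path:
        """Write the NIfTI + TSV layout the pipeline consumes; returns the manifest path."""
        out = Path(out_dir)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        self.template.write(out / "template")
        manifest = self.manifest.copy()
        core_paths, oedema_paths = [], []
        for sid in manifest["subject_id"]:
            cp = out / "masks" / f"{sid}_core.nii.gz"
            op = out / "masks" / f"{sid}_oedema.nii.gz"
            write_image(cp, self.core_masks[sid].values, self.template.grid)
            write_image(op, self.oedema_masks[sid].values, self.template.grid)
            core_paths.append(str(cp.relative_to(out)))
            oedema_paths.append(str(op.relative_to(out)))
        manifest["core_path"] = core_paths
        manifest["oedema_path"] = oedema_paths
        manifest_path = out / "manifest.tsv"
        manifest.to_csv(manifest_path, sep="\t", index=False)
        return manifest_path


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, lower: float = 0.5
) -> np.ndarray:
    a = (lower - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: SyntheticCohortSpec | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort: template, lesions and manifest.

    Methylation percentages for the quantified methylated subset are a
    linear function of each subject's realized cortical overlap
    fraction plus Gaussian noise calibrated by
    sd_noise = sd_signal * sqrt(1/r^2 - 1), so the population
    correlation equals ``planted_r_cortex`` before clipping to
    [methylation_floor, 100]. Post-clip attenuation is measured and
    logged, not corrected. Unmethylated subjects receive percentages
    below the floor; the status column always derives from the >=8%
    rule. Bit-reproducible for a fixed spec (seed included).
    """
    spec = spec or SyntheticCohortSpec()
    template = generate_template(spec.grid_dims, seed=derive_seed(spec.seed, "template"))
    rng = np.random.default_rng(derive_seed(spec.seed, "cohort"))

    n = spec.n_subjects
    subject_ids = [f"sub-{i+1:03d}" for i in range(n)]
    core_targets = _truncated_normal(rng, spec.core_volume_mean, spec.core_volume_sd, n)
    oedema_targets = _truncated_normal(rng, spec.oedema_volume_mean, spec.oedema_volume_sd, n)
    # per-subject placement bias: spread across the cortex-deep axis
    cortex_biases = rng.beta(1.4, 0.9, size=n)

    lesion_seeds = rng.integers(0, 2**31 - 1, size=n)
    core_masks: dict[str, LesionMask] = {}
    oedema_masks: dict[str, LesionMask] = {}
    rows = []
    for i, sid in enumerate(subject_ids):
        sub_rng = np.random.default_rng(int(lesion_seeds[i]))
        core, oedema = generate_lesion(
            template,
            sub_rng,
            target_core_ml=float(core_targets[i]),
            target_oedema_ml=float(oedema_targets[i]),
            cortex_bias=float(cortex_biases[i]),
            subject_id=sid,
        )
        core_masks[sid] = core
        oedema_masks[sid] = oedema
        prof = compartment_overlap(core, template.tissue)
        rows.append(
            {
                "subject_id": sid,
                "core_volume_ml": core.volume_ml,
                "oedema_volume_ml": oedema.volume_ml,
                "global_volume_ml": union_mask(core, oedema).volume_ml,
                "hemisphere": hemisphere_of(core),
                "cortex_fraction": prof.get("cortex").fraction_of_lesion,
                "white_matter_fraction": prof.get("white_matter").fraction_of_lesion,
                "deep_grey_fraction": prof.get("deep_grey").fraction_of_lesion,
            }
        )
    manifest = pd.DataFrame(rows)

    # demographics
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 18.0, 95.0)
    manifest["age"] = np.round(age, 1)
    sex = np.array(["M"] * spec.n_male + ["F"] * (n - spec.n_male))
    manifest["sex"] = rng.permutation(sex)

    # molecular assignment: methylated subset chosen at random
    meth_idx = rng.choice(n, size=spec.n_methylated, replace=False)
    quant_idx = rng.choice(meth_idx, size=spec.n_quantified, replace=False)
    pct = np.full(n, np.nan)

    r = spec.planted_r_cortex
    c = manifest.loc[quant_idx, "cortex_fraction"].to_numpy(float)
    z = (c - c.mean()) / c.std()
    eps = rng.standard_normal(spec.n_quantified)
    raw = spec.methylation_mean + spec.methylation_sd * (r * z + math.sqrt(1.0 - r**2) * eps)
    clipped = np.clip(raw, spec.methylation_floor, 100.0)
    achieved = float(np.corrcoef(clipped, c)[0, 1])
    if abs(achieved - r) > 0.3:
        logger.warning(
            "planted cortical correlation infeasible after clipping: target %.2f, achieved %.2f",
            r,
            achieved,
        )
    else:
        logger.info("planted cortical correlation %.2f; achieved after clipping %.3f", r, achieved)
    pct[quant_idx] = np.round(clipped, 1)

    unmeth_idx = np.setdiff1d(np.arange(n), meth_idx)
    pct[unmeth_idx] = np.round(rng.uniform(0.0, spec.methylation_floor - 0.1, size=len(unmeth_idx)), 1)

    status = np.empty(n, dtype=object)
    for i in range(n):
        if np.isnan(pct[i]):
            # the methylated subject without a quantified percentage
            status[i] = "methylated" if i in meth_idx else "unmethylated"
        else:
            status[i] = classify_methylation(float(pct[i]))
    manifest["methylation_pct"] = pct
    manifest["methylation_status"] = status

    cols = [
        "subject_id",
        "age",
        "sex",
        "methylation_pct",
        "methylation_status",
        "hemisphere",
        "core_volume_ml",
        "oedema_volume_ml",
        "global_volume_ml",
        "cortex_fraction",
        "white_matter_fraction",
        "deep_grey_fraction",
    ]
    manifest = manifest[cols]
    return SyntheticCohort(
        spec=spec,
        template=template,
        manifest=manifest,
        core_masks=core_masks,
        oedema_masks=oedema_masks,
        achieved_r_cortex=achieved,
    )


def generate_null_cohort(spec: SyntheticCohortSpec | None = None, seed: int | None = None) -> SyntheticCohort:
    """A cohort with no location-methylation association by construction.

    Identical lesion set to :func:`generate_cohort` with the same spec;
    the molecular columns are then permuted across subjects with a
    derived seed, severing any link to lesion topology.
    """
    spec = spec or SyntheticCohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    cohort = generate_cohort(spec)
    perm_rng = np.random.default_rng(derive_seed(spec.seed, "null-permutation"))
    perm = perm_rng.permutation(len(cohort.manifest))
    mol = cohort.manifest[["methylation_pct", "methylation_status"]].to_numpy()[perm]
    manifest = cohort.manifest.copy()
    manifest[["methylation_pct", "methylation_status"]] = mol
    manifest["methylation_pct"] = manifest["methylation_pct"].astype(float)
    return replace(cohort, manifest=manifest)
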