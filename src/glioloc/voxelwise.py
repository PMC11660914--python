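"""Mass-univariate voxel-wise lesion mapping with permutation FWE.

Each voxel inside the analysis mask (voxels lesioned in at least
``min_overlap`` subjects) gets an OLS fit of its binary lesion
indicator on [intercept, predictor, nuisance...]; the t statistic of
the predictor contrast forms the observed map. Family-wise error is
controlled by the permutation max-statistic method: the null
distribution of the maximum |t| over the mask is built from label
permutations (plain predictor permutation without nuisance, the
Freedman–Lane residual-permutation scheme with nuisance), and

    p_fwe(v) = (1 + #{perm max >= |t_obs(v)|}) / (n_perm + 1).

When the permutation space is small enough it is enumerated exhaustively
and the p-values are exact. Uncorrected p-values come from the same
permutations voxel-by-voxel.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from glioloc.imaging import ImageGrid, LesionMask, _require_same_grid, flip_lateral, write_image

logger = logging.getLogger(__name__)


@dataclass
class VoxelwiseDesign:
    """A voxel-wise GLM: tested predictor plus optional nuisance columns."""

    predictor: np.ndarray
    nuisance: np.ndarray | None = None
    tails: str = "two"
    name: str = "voxelwise"

    def __post_init__(self) -> None:
        p = np.asarray(self.predictor, dtype=float).ravel()
        if p.std() == 0:
            raise ValueError("predictor is constant across subjects")
        self.predictor = p
        if self.nuisance is not None:
            z = np.asarray(self.nuisance, dtype=float)
            if z.ndim == 1:
                z = z[:, None]
            if z.shape[0] != p.size:
                raise ValueError("nuisance rows must match predictor length")
            self.nuisance = z
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")

    @property
    def n(self) -> int:
        return int(self.predictor.size)

    def matrix(self) -> np.ndarray:
        """Design matrix [intercept, predictor, nuisance...]; checks rank."""
        cols = [np.ones(self.n), self.predictor]
        if self.nuisance is not None:
            cols.extend(self.nuisance.T)
        x = np.column_stack(cols)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("rank-deficient design (nuisance collinear with predictor/intercept)")
        return x

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.predictor, (0.0, 1.0)).all())


@dataclass
class VoxelwiseResult:
    """Observed t-map with permutation p-maps, defined inside the analysis mask."""

    name: str
    grid: ImageGrid
    t_map: np.ndarray
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    analysis_mask: np.ndarray
    n_permutations: int
    seed: int
    tails: str
    df: float
    n: int
    exact: bool = False

    def n_significant(self, alpha: float = 0.05) -> int:
        """Voxels surviving FWE correction at ``alpha``."""
        inside = self.p_fwe[self.analysis_mask]
        return int(np.sum(inside <= alpha))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        write_image(out / f"{self.name}_tstat.nii.gz", np.nan_to_num(self.t_map).astype(np.float32), self.grid)
        write_image(out / f"{self.name}_p_unc.nii.gz", np.nan_to_num(self.p_uncorrected, nan=1.0).astype(np.float32), self.grid)
        write_image(out / f"{self.name}_p_fwe.nii.gz", np.nan_to_num(self.p_fwe, nan=1.0).astype(np.float32), self.grid)
        write_image(out / f"{self.name}_mask.nii.gz", self.analysis_mask.astype(np.uint8), self.grid)

    def log_row(self, alpha: float = 0.05) -> dict:
        return {
            "analysis": self.name,
            "n": self.n,
            "n_perm": self.n_permutations,
            "seed": self.seed,
            "tails": self.tails,
            "exact": self.exact,
            "n_voxels": int(self.analysis_mask.sum()),
            f"n_significant_fwe_{alpha}": self.n_significant(alpha),
        }


# ---------------------------------------------------------------------------
# Lesion matrix
# ---------------------------------------------------------------------------


def build_lesion_matrix(
    masks: Sequence[LesionMask], min_overlap: int = 2
) -> tuple[np.ndarray, np.ndarray, ImageGrid]:
    """Stack masks into a subjects x voxels matrix over the analysis mask.

    The analysis mask keeps voxels lesioned in at least ``min_overlap``
    subjects (only the lower bound is applied).
    """
    if len(masks) < 2:
        raise ValueError("need at least two masks")
    grid = masks[0].grid
    for m in masks[1:]:
        _require_same_grid(grid, m.grid, "lesion-matrix masks")
    stack = np.stack([m.values for m in masks])  # n x dims
    counts = stack.sum(axis=0)
    analysis_mask = counts >= min_overlap
    if not analysis_mask.any():
        raise ValueError(f"empty analysis mask at min_overlap={min_overlap}")
    y = stack[:, analysis_mask].astype(np.float64)
    return y, analysis_mask, grid


# ---------------------------------------------------------------------------
# GLM t-statistics
# ---------------------------------------------------------------------------


def _t_from_design(y: np.ndarray, x: np.ndarray, c_idx: int = 1) -> np.ndarray:
    """t of design column ``c_idx`` at every voxel, OLS, df = n - p."""
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    xty = x.T @ y  # p x V
    beta = xtx_inv @ xty
    rss = np.einsum("nv,nv->v", y, y) - np.einsum("pv,pv->v", xty, beta)
    rss = np.maximum(rss, 0.0)
    var = rss / (n - p) * xtx_inv[c_idx, c_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[c_idx] / np.sqrt(var)
    # zero residual variance: effect either absent (t=0) or perfectly
    # determined (+/-inf); keep the sign so max-|t| comparisons behave
    zero = var == 0.0
    if zero.any():
        b = beta[c_idx][zero]
        t[zero] = np.where(b == 0.0, 0.0, np.sign(b) * np.inf)
    return t


def glm_t_map(lesions: np.ndarray, design: VoxelwiseDesign) -> tuple[np.ndarray, float]:
    """Observed per-voxel t-map for a lesion matrix; returns (t, df).

    With a binary group predictor and no nuisance this reduces exactly
    to the pooled-variance two-sample t on the lesion indicator; with a
    continuous predictor it equals the Pearson-r t transform.
    """
    y = np.asarray(lesions, dtype=float)
    x = design.matrix()
    if y.shape[0] != x.shape[0]:
        raise ValueError("lesion matrix rows must match design rows")
    if y.shape[0] <= x.shape[1] + 1:
        raise ValueError("need n subjects > design columns + 1")
    return _t_from_design(y, x), float(y.shape[0] - x.shape[1])


# ---------------------------------------------------------------------------
# Permutation inference
# ---------------------------------------------------------------------------


def _enumerate_orders(design: VoxelwiseDesign, n_perm: int) -> list[np.ndarray] | None:
    """All distinct label orders when the space is <= n_perm, else None."""
    n = design.n
    if design.nuisance is None and design.is_binary:
        n1 = int(design.predictor.sum())
        total = math.comb(n, n1)
        if total <= n_perm:
            base = np.zeros(n)
            orders = []
            for ones in itertools.combinations(range(n), n1):
                v = base.copy()
                v[list(ones)] = 1.0
                orders.append(v)
            return orders
        return None
    if math.factorial(n) <= n_perm:
        return [np.array(p) for p in itertools.permutations(range(n))]
    return None


def permutation_fwe(
    lesions: np.ndarray,
    design: VoxelwiseDesign,
    n_perm: int = 1000,
    seed: int = 0,
    freedman_lane: bool = True,
) -> dict:
    """Max-statistic permutation inference on a lesion matrix.

    Returns a dict with ``t`` (observed), ``p_unc``, ``p_fwe``, ``df``,
    ``n_perm`` and ``exact``. Without nuisance the predictor labels are
    permuted; with nuisance the Freedman–Lane scheme permutes the
    reduced-model residuals (plain predictor permutation available with
    ``freedman_lane=False``). Exhaustive enumeration replaces random
    sampling whenever the permutation space is no larger than
    ``n_perm`` (p-values then exact).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(lesions, dtype=float)
    x = design.matrix()
    n = design.n
    t_obs, df = glm_t_map(y, design)
    two = design.tails == "two"
    score_obs = np.abs(t_obs) if two else t_obs

    rng = np.random.default_rng(seed)
    use_fl = design.nuisance is not None and freedman_lane
    if use_fl:
        z = np.column_stack([np.ones(n), design.nuisance])
        hz = z @ np.linalg.pinv(z)
        fitted = hz @ y
        resid = y - fitted

    def _t_for(perm: np.ndarray | None, labels: np.ndarray | None) -> np.ndarray:
        if labels is not None:  # enumerated binary relabeling, no nuisance
            xp = x.copy()
            xp[:, 1] = labels
            return _t_from_design(y, xp)
        if use_fl:
            y_star = fitted + resid[perm]
            return _t_from_design(y_star, x)
        xp = x.copy()
        xp[:, 1] = design.predictor[perm]
        return _t_from_design(y, xp)

    enumerated = _enumerate_orders(design, n_perm)
    exceed_unc = np.zeros(y.shape[1])
    exceed_max = np.zeros(y.shape[1])
    if enumerated is not None:
        total = len(enumerated)
        logger.info("permutation space (%d) <= n_perm (%d): exact enumeration", total, n_perm)
        binary_case = design.nuisance is None and design.is_binary
        for item in enumerated:
            t_p = _t_for(None, item) if binary_case else _t_for(item.astype(int), None)
            score = np.abs(t_p) if two else t_p
            exceed_unc += score >= score_obs
            exceed_max += np.max(score) >= score_obs
        p_unc = exceed_unc / total
        p_fwe = exceed_max / total
        n_used, exact = total, True
    else:
        for _ in range(n_perm):
            perm = rng.permutation(n)
            t_p = _t_for(perm, None)
            score = np.abs(t_p) if two else t_p
            exceed_unc += score >= score_obs
            exceed_max += np.max(score) >= score_obs
        p_unc = (1.0 + exceed_unc) / (n_perm + 1.0)
        p_fwe = (1.0 + exceed_max) / (n_perm + 1.0)
        n_used, exact = n_perm, False
    return {
        "t": t_obs,
        "p_unc": p_unc,
        "p_fwe": p_fwe,
        "df": df,
        "n_perm": n_used,
        "exact": exact,
    }


def voxelwise_analysis(
    masks: Sequence[LesionMask],
    design: VoxelwiseDesign,
    min_overlap: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
    freedman_lane: bool = True,
) -> VoxelwiseResult:
    """End-to-end voxel-wise run: lesion matrix -> GLM -> permutation FWE maps."""
    y, analysis_mask, grid = build_lesion_matrix(masks, min_overlap=min_overlap)
    res = permutation_fwe(y, design, n_perm=n_perm, seed=seed, freedman_lane=freedman_lane)

    def to_map(values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(grid.dims, fill, dtype=np.float64)
        out[analysis_mask] = values
        return out

    return VoxelwiseResult(
        name=design.name,
        grid=grid,
        t_map=to_map(res["t"]),
        p_uncorrected=to_map(res["p_unc"]),
        p_fwe=to_map(res["p_fwe"]),
        analysis_mask=analysis_mask,
        n_permutations=res["n_perm"],
        seed=seed,
        tails=design.tails,
        df=res["df"],
        n=design.n,
        exact=res["exact"],
    )


# ---------------------------------------------------------------------------
# The full suite of analyses
# ---------------------------------------------------------------------------


def run_voxelwise_suite(
    manifest: pd.DataFrame,
    core_masks: dict[str, LesionMask],
    n_perm: int = 1000,
    seed: int = 0,
    min_overlap: int = 2,
    flip_mode: str = "unify_left",
    include_flipped: bool = True,
    include_volume_corrected: bool = True,
) -> list[VoxelwiseResult]:
    """Run the standard voxel-wise analyses on a cohort.

    (a) methylated vs unmethylated group contrast; (b) continuous
    methylation percentage over the quantified methylated subset;
    (c) high vs low methylation by median split of that subset — each
    optionally repeated with core volume as a nuisance covariate and
    with lesions flipped to one hemisphere.
    """
    analyses: list[tuple[str, pd.DataFrame, np.ndarray]] = []
    known = manifest[manifest["methylation_status"].isin(["methylated", "unmethylated"])]
    analyses.append(
        ("status_group", known, (known["methylation_status"] == "methylated").to_numpy(float))
    )
    quant = manifest[
        (manifest["methylation_status"] == "methylated") & manifest["methylation_pct"].notna()
    ]
    if len(quant) >= 4:
        analyses.append(("methylation_pct", quant, quant["methylation_pct"].to_numpy(float)))
        cutoff = float(np.median(quant["methylation_pct"]))
        analyses.append(
            ("median_split", quant, (quant["methylation_pct"] > cutoff).to_numpy(float))
        )

    variants: list[tuple[str, bool]] = [("", False)]
    if include_volume_corrected:
        variants.append(("_volcorr", True))

    flip_variants: list[tuple[str, bool]] = [("", False)]
    if include_flipped:
        flip_variants.append(("_flipped", True))

    results: list[VoxelwiseResult] = []
    run_idx = 0
    for flip_suffix, do_flip in flip_variants:
        for base_name, sub, predictor in analyses:
            masks = [core_masks[sid] for sid in sub["subject_id"]]
            if do_flip:
                masks = [flip_lateral(m, flip_mode) for m in masks]
            for var_suffix, with_vol in variants:
                if np.asarray(predictor).std() == 0:
                    logger.warning("skipping %s%s%s: constant predictor", base_name, var_suffix, flip_suffix)
                    continue
                n_cols = 3 if with_vol else 2
                if len(sub) <= n_cols + 1:
                    logger.warning(
                        "skipping %s%s%s: only %d subjects for a %d-column design",
                        base_name, var_suffix, flip_suffix, len(sub), n_cols,
                    )
                    continue
                nuis = sub["core_volume_ml"].to_numpy(float) if with_vol else None
                design = VoxelwiseDesign(
                    predictor=predictor,
                    nuisance=nuis,
                    name=f"{base_name}{var_suffix}{flip_suffix}",
                )
                results.append(
                    voxelwise_analysis(
                        masks,
                        design,
                        min_overlap=min_overlap,
                        n_perm=n_perm,
                        seed=seed + run_idx,
                    )
                )
                run_idx += 1
    return results
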