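"""Config-driven orchestration of the full lesion-location analysis.

Stages, in order: overlap profiling -> lobar/side/volume group tests ->
network repeated-measures ANOVAs -> compartment correlations (plain and
partial) -> frequency maps -> voxel-wise suite. Outputs are a tidy
results TSV (one test per row), per-atlas overlap TSVs, NIfTI maps and
a JSON run log recording every seed, threshold and family size, which
suffices to re-execute the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from glioloc.imaging import (
    ImageGrid,
    LabelAtlas,
    LesionMask,
    check_same_grid,
    read_atlas,
    read_mask,
    union_mask,
)
from glioloc.overlap import (
    compartment_table,
    frequency_map,
    lobar_involvement,
    overlap_table,
)
from glioloc.stats import (
    StatResult,
    bonferroni,
    classify_methylation,
    involvement_percentages,
    median_split,
    chi_square_2x2,
    partial_r,
    pearson_r,
    rm_anova_wilks,
    two_sample_t,
)
from glioloc.synthetic import derive_seed
from glioloc.voxelwise import run_voxelwise_suite

logger = logging.getLogger(__name__)

#: Bonferroni family sizes per analysis block (overridable in the config)
DEFAULT_FAMILIES = {
    "volume_by_status": 3,
    "lobe_by_status": 5,
    "four_category_volume": 6,
    "volume_by_median_split": 3,
    "pct_vs_volume": 3,
    "pct_vs_compartment": 3,
    "partial_pct_vs_compartment": 3,
}

ATLAS_NAMES = ("lobes", "tissue", "gmn", "wmn")


@dataclass
class PipelineConfig:
    manifest: str
    atlases: dict[str, str]  # name -> NIfTI path; label table = same stem + .tsv
    out_dir: str = "glioloc_out"
    methylation_cutoff: float = 8.0
    lobar_min_voxels: int = 250
    frequency_display_threshold: int = 2
    voxelwise_min_overlap: int = 2
    n_permutations: int = 1000
    flip_mode: str = "unify_left"
    alpha: float = 0.05
    bonferroni_families: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("lobar_min_voxels", "frequency_display_threshold", "voxelwise_min_overlap", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        raw["manifest"] = str((base / raw["manifest"]).resolve())
        raw["atlases"] = {k: str((base / v).resolve()) for k, v in raw["atlases"].items()}
        if "out_dir" in raw:
            raw["out_dir"] = str((base / raw["out_dir"]).resolve())
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _table_path(nifti_path: str | Path) -> Path:
    p = Path(nifti_path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return p.with_name(stem + ".tsv")


@dataclass
class LoadedInputs:
    manifest: pd.DataFrame
    core_masks: dict[str, LesionMask]
    oedema_masks: dict[str, LesionMask]
    atlases: dict[str, LabelAtlas]
    grid: ImageGrid


def load_inputs(config: PipelineConfig) -> LoadedInputs:
    atlases = {
        name: read_atlas(path, _table_path(path), name=name)
        for name, path in config.atlases.items()
    }
    grid = next(iter(atlases.values())).grid
    manifest = pd.read_csv(config.manifest, sep="\t")
    base = Path(config.manifest).parent
    core_masks, oedema_masks = {}, {}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        core_masks[sid] = read_mask(base / row["core_path"], grid_ref=grid, compartment="core", subject_id=sid)
        if "oedema_path" in manifest.columns and pd.notna(row.get("oedema_path")):
            oedema_masks[sid] = read_mask(
                base / row["oedema_path"], grid_ref=grid, compartment="oedema", subject_id=sid
            )
    manifest["subject_id"] = manifest["subject_id"].astype(str)
    return LoadedInputs(manifest=manifest, core_masks=core_masks, oedema_masks=oedema_masks, atlases=atlases, grid=grid)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("subject_id", "methylation_status", "core_path")


def validate_inputs(config: PipelineConfig) -> list[dict[str, str]]:
    """Machine-readable pre-flight checks; violations are data, not exceptions."""
    violations: list[dict[str, str]] = []

    def flag(check: str, where: str, message: str) -> None:
        violations.append({"check": check, "where": where, "message": message})

    atlases: dict[str, LabelAtlas] = {}
    for name, path in config.atlases.items():
        try:
            atlases[name] = read_atlas(path, _table_path(path), name=name)
        except Exception as exc:  # noqa: BLE001 - collected as a violation
            flag("atlas_readable", name, str(exc))
    grids = [a.grid for a in atlases.values()]
    for name, a in atlases.items():
        if grids and not check_same_grid(a.grid, grids[0]):
            flag("atlas_grid", name, "atlas grid differs from the first atlas")

    try:
        manifest = pd.read_csv(config.manifest, sep="\t")
    except Exception as exc:  # noqa: BLE001
        flag("manifest_readable", str(config.manifest), str(exc))
        return violations
    for col in REQUIRED_COLUMNS:
        if col not in manifest.columns:
            flag("manifest_schema", col, "required column missing")
    if violations and any(v["check"] == "manifest_schema" for v in violations):
        return violations

    base = Path(config.manifest).parent
    ref_grid = grids[0] if grids else None
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        pct = row.get("methylation_pct")
        status = row.get("methylation_status")
        if pd.notna(pct):
            try:
                expected = classify_methylation(float(pct), config.methylation_cutoff)
            except ValueError as exc:
                flag("methylation_range", sid, str(exc))
            else:
                if status != expected:
                    flag(
                        "status_consistency",
                        sid,
                        f"pct {pct} implies {expected!r} but status is {status!r}",
                    )
        for col in ("core_path", "oedema_path"):
            if col in manifest.columns and pd.notna(row.get(col)):
                p = base / row[col]
                if not p.exists():
                    flag("mask_exists", sid, f"{p} not found")
                elif ref_grid is not None:
                    try:
                        read_mask(p, grid_ref=ref_grid)
                    except Exception as exc:  # noqa: BLE001
                        flag("mask_grid", sid, str(exc))
    return violations


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _rows(results: list[StatResult]) -> list[dict]:
    return [r.as_row() for r in results]


def _with_family(result: StatResult, family: str, families: dict[str, int]) -> StatResult:
    m = families.get(family)
    if m:
        corrected, _ = bonferroni([result.p_value], family_size=m)
        result.p_corrected = float(corrected[0])
        result.family_size = m
    result.test_name = f"{family}:{result.test_name}"
    return result


def stage_overlap(inputs: LoadedInputs, config: PipelineConfig, out: Path) -> dict[str, pd.DataFrame]:
    masks = [inputs.core_masks[s] for s in inputs.manifest["subject_id"]]
    tables = {
        "lobes": overlap_table(masks, inputs.atlases["lobes"], measure="voxels"),
        "tissue": compartment_table(masks, inputs.atlases["tissue"]),
        "gmn": overlap_table(masks, inputs.atlases["gmn"], measure="ratio"),
        "wmn": overlap_table(masks, inputs.atlases["wmn"], measure="ratio"),
    }
    for name, df in tables.items():
        df.to_csv(out / f"overlap_{name}.tsv", sep="\t")
    return tables


def stage_stats(
    inputs: LoadedInputs,
    config: PipelineConfig,
    tables: dict[str, pd.DataFrame],
    out: Path,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    manifest = inputs.manifest.set_index("subject_id")
    families = config.bonferroni_families
    results: list[StatResult] = []
    extra: dict[str, Any] = {}

    is_meth = manifest["methylation_status"] == "methylated"
    volumes = {}
    for comp in ("core", "oedema", "global"):
        col = f"{comp}_volume_ml"
        if col not in manifest.columns and comp == "global" and inputs.oedema_masks:
            manifest[col] = [
                union_mask(inputs.core_masks[s], inputs.oedema_masks[s]).volume_ml
                for s in manifest.index
            ]
        if col in manifest.columns:
            volumes[comp] = manifest[col].astype(float)

    # cohort summary
    summary = {
        "n_subjects": len(manifest),
        "n_methylated": int(is_meth.sum()),
        "methylation_pct_mean": float(manifest.loc[is_meth, "methylation_pct"].mean()),
        "methylation_pct_sd": float(manifest.loc[is_meth, "methylation_pct"].std()),
        "methylation_pct_median": float(manifest.loc[is_meth, "methylation_pct"].median()),
    }
    for comp, v in volumes.items():
        summary[f"{comp}_volume_mean_ml"] = float(v.mean())
        summary[f"{comp}_volume_sd_ml"] = float(v.std())
    extra["cohort_summary"] = summary

    # lobar involvement counts/percentages (inclusive >= threshold rule)
    lobe_table = tables["lobes"]
    involved = lobe_table >= config.lobar_min_voxels
    counts = involved.sum(axis=0).to_dict()
    extra["lobar_involvement_counts"] = {k: int(v) for k, v in counts.items()}
    extra["lobar_involvement_pct"] = involvement_percentages(
        extra["lobar_involvement_counts"], len(manifest)
    )

    # volume t-tests by status
    for comp, v in volumes.items():
        res = two_sample_t(v[is_meth], v[~is_meth])
        res.test_name = f"{comp}_volume_by_status"
        results.append(_with_family(res, "volume_by_status", families))

    # hemisphere x status chi-square
    if "hemisphere" in manifest.columns:
        tab = pd.crosstab(is_meth, manifest["hemisphere"] == "right").to_numpy()
        if tab.shape == (2, 2) and (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
            res = chi_square_2x2(tab)
            res.test_name = "hemisphere_by_status"
            results.append(res)

    # per-lobe involvement x status chi-square
    for lobe in involved.columns:
        inv = involved[lobe].reindex(manifest.index)
        tab = pd.crosstab(is_meth, inv).reindex(
            index=[False, True], columns=[False, True], fill_value=0
        ).to_numpy()
        try:
            res = chi_square_2x2(tab)
        except ValueError:
            continue
        res.test_name = f"{lobe}_involvement_by_status"
        results.append(_with_family(res, "lobe_by_status", families))

    # four categories (status x side): pairwise global-volume t-tests
    if "hemisphere" in manifest.columns and "global" in volumes:
        cats = {}
        for st in (True, False):
            for side in ("left", "right"):
                sel = (is_meth == st) & (manifest["hemisphere"] == side)
                label = f"{'meth' if st else 'unmeth'}_{side}"
                cats[label] = volumes["global"][sel]
        labels = list(cats)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                a, b = cats[labels[i]], cats[labels[j]]
                if len(a) >= 2 and len(b) >= 2:
                    res = two_sample_t(a, b)
                    res.test_name = f"global_volume_{labels[i]}_vs_{labels[j]}"
                    results.append(_with_family(res, "four_category_volume", families))

    # quantified methylated subset
    quant = manifest[is_meth & manifest["methylation_pct"].notna()]
    pct = quant["methylation_pct"].astype(float)
    extra["n_quantified"] = int(len(quant))

    if len(quant) >= 4:
        # median split: volume differences between highly and lowly methylated
        high, low, cutoff = median_split(pct.to_numpy())
        extra["median_split_cutoff"] = cutoff
        hi_sel = pct > cutoff
        for comp, v in volumes.items():
            a, b = v[quant.index][hi_sel], v[quant.index][~hi_sel]
            if len(a) >= 2 and len(b) >= 2:
                res = two_sample_t(a, b)
                res.test_name = f"{comp}_volume_by_median_split"
                results.append(_with_family(res, "volume_by_median_split", families))

        # correlations with volumes
        for comp, v in volumes.items():
            res = pearson_r(pct, v[quant.index])
            res.test_name = f"pct_vs_{comp}_volume"
            results.append(_with_family(res, "pct_vs_volume", families))

        # correlations with compartment fractions, plain and partial
        tissue_tab = tables["tissue"]
        core_vol = volumes["core"][quant.index]
        for comp in ("cortex", "white_matter", "deep_grey"):
            frac = tissue_tab[f"{comp}_fraction"].reindex(quant.index).astype(float)
            res = pearson_r(pct, frac)
            res.test_name = f"pct_vs_{comp}_fraction"
            results.append(_with_family(res, "pct_vs_compartment", families))
            res = partial_r(pct, frac, core_vol)
            res.test_name = f"pct_vs_{comp}_fraction_partial_core_volume"
            results.append(_with_family(res, "partial_pct_vs_compartment", families))

    # repeated-measures MANOVA over network ratio profiles
    for fam in ("gmn", "wmn"):
        ratios = tables[fam].reindex(manifest.index)
        complete = ratios.dropna()
        dropped = len(ratios) - len(complete)
        if dropped:
            logger.info("%s rm-ANOVA: dropped %d subject(s) with undefined ratios", fam, dropped)
        extra[f"{fam}_rm_anova_dropped"] = dropped
        between = is_meth.reindex(complete.index).astype(float).to_numpy()
        try:
            rm = rm_anova_wilks(complete.to_numpy(float), between=between)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("%s rm-ANOVA failed: %s", fam, exc)
            continue
        rm.condition.test_name = f"{fam}_{rm.condition.test_name}"
        results.append(rm.condition)
        if rm.interaction is not None:
            rm.interaction.test_name = f"{fam}_{rm.interaction.test_name}"
            results.append(rm.interaction)

    frame = pd.DataFrame(_rows(results))
    frame.to_csv(out / "results.tsv", sep="\t", index=False)
    with open(out / "cohort_summary.json", "w") as fh:
        json.dump(extra, fh, indent=2, default=float)
    return frame, extra


def stage_frequency(inputs: LoadedInputs, config: PipelineConfig, out: Path) -> None:
    manifest = inputs.manifest
    groups = {
        "all": manifest["subject_id"],
        "methylated": manifest.loc[manifest["methylation_status"] == "methylated", "subject_id"],
        "unmethylated": manifest.loc[manifest["methylation_status"] == "unmethylated", "subject_id"],
    }
    for label, sids in groups.items():
        if len(sids) == 0:
            continue
        fm = frequency_map(
            [inputs.core_masks[s] for s in sids],
            display_threshold=config.frequency_display_threshold,
            group_label=label,
        )
        fm.write(out)


def stage_voxelwise(inputs: LoadedInputs, config: PipelineConfig, out: Path) -> pd.DataFrame:
    results = run_voxelwise_suite(
        inputs.manifest,
        inputs.core_masks,
        n_perm=config.n_permutations,
        seed=derive_seed(config.seed, "voxelwise"),
        min_overlap=config.voxelwise_min_overlap,
        flip_mode=config.flip_mode,
    )
    rows = []
    for res in results:
        res.write(out / "voxelwise")
        rows.append(res.log_row(config.alpha))
    log = pd.DataFrame(rows)
    log.to_csv(out / "voxelwise_runlog.tsv", sep="\t", index=False)
    return log


def run_full_analysis(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage; returns a report bundle of tables and paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"out_dir": str(out)}
    stage = "load"
    try:
        inputs = load_inputs(config)
        stage = "overlap"
        tables = stage_overlap(inputs, config, out)
        report["overlap_tables"] = tables
        stage = "stats"
        results, extra = stage_stats(inputs, config, tables, out)
        report["results"] = results
        report["summary"] = extra
        stage = "frequency"
        stage_frequency(inputs, config, out)
        stage = "voxelwise"
        report["voxelwise_log"] = stage_voxelwise(inputs, config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    run_log = {
        "config": asdict(config),
        "derived_seeds": {s: derive_seed(config.seed, s) for s in ("template", "cohort", "voxelwise")},
        "families": config.bonferroni_families,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    report["run_log"] = run_log
    return report
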