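"""File I/O, pipeline configuration and the end-to-end pipeline runner.

Volumes travel as NIfTI-1 (.nii.gz) with the voxel size encoded in the
affine, phenotype and result tables as TSV, configuration as YAML and
manifests / cluster nulls as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import backrecon, decomposition, fnc, sdr, symptoms
from .synthetic import (
    CohortDataset,
    SubjectScan,
    make_ground_truth,
    phenotype_table,
    simulate_cohort,
)

log = logging.getLogger("restica")

PHENOTYPE_COLUMNS = [
    "subject_id", "group", "age", "gender", "iq", "pcl_total",
    "pssi_reexperiencing", "pssi_avoidance", "pssi_arousal", "bdi",
]


class ValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline knobs with their defaults.

    Thresholds mirror the analysis constants: voxel-wise p = 0.001 for the
    contrasts, cluster-level alpha = 0.05 with an additional Bonferroni
    factor over the analyzed networks, 0.15 Hz fifth-order low-pass for the
    FNC time courses.
    """

    output_dir: str = "restica-out"
    seed: int = 0
    # synthetic cohort
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_networks: int = 6
    n_timepoints: int = 150
    n_per_group: tuple[int, int, int] = (12, 8, 8)
    # decomposition
    model_order: int | None = None
    subject_pca_dim: int = 30
    icasso_runs: int = 5
    # SDR stage
    mask_alpha: float = 0.05
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    n_networks_bonferroni: int | None = None
    mc_iterations: int = 1000
    connectivity: int = 26
    # FNC stage
    filter_order: int = 5
    filter_cutoff_hz: float = 0.15
    # symptom stage
    kurtosis_threshold: float = -1.0

    def validate(self) -> None:
        for name in ("mask_alpha", "voxel_p", "cluster_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.model_order is not None and self.subject_pca_dim < self.model_order:
            raise ValidationError("subject_pca_dim must be >= model_order")
        if self.connectivity not in (6, 18, 26):
            raise ValidationError("connectivity must be 6, 18 or 26")
        if self.filter_cutoff_hz <= 0:
            raise ValidationError("filter_cutoff_hz must be > 0")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded): re-running with
        any altered threshold changes it, moving the output directory does
        not."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "n_per_group"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write subjects as NIfTI-1, phenotype as TSV, ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(cohort.subjects[0].voxel_size_mm)
    for s in cohort.subjects:
        nib.save(nib.Nifti1Image(s.data.astype(np.float32), aff), out / f"{s.subject_id}.nii.gz")
    nib.save(
        nib.Nifti1Image(cohort.brain_mask.astype(np.uint8), aff), out / "brain_mask.nii.gz"
    )
    pheno = phenotype_table(cohort)
    pheno["tr_s"] = cohort.subjects[0].tr_s
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    if cohort.ground_truth is not None:
        (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    return out


def read_cohort(
    image_paths: list[str | Path], mask_path: str | Path, phenotype_path: str | Path
) -> CohortDataset:
    """Load a cohort from per-subject NIfTI files, a mask and a phenotype TSV."""
    pheno = pd.read_csv(phenotype_path, sep="\t")
    missing_cols = set(PHENOTYPE_COLUMNS) - set(pheno.columns)
    if missing_cols:
        raise ValidationError(f"phenotype table missing columns: {sorted(missing_cols)}")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    ref_affine = mask_img.affine
    voxel = float(np.abs(ref_affine[0, 0]))
    tr = float(pheno["tr_s"].iloc[0]) if "tr_s" in pheno.columns else 3.0
    by_id = {row.subject_id: row for row in pheno.itertuples()}
    subjects = []
    bad_grid = []
    for p in image_paths:
        p = Path(p)
        sid = p.name.replace(".nii.gz", "").replace(".nii", "")
        if sid not in by_id:
            raise ValidationError(f"subject {sid!r} missing from phenotype table")
        img = nib.load(str(p))
        if img.shape[:3] != mask.shape or not np.allclose(img.affine, ref_affine, atol=1e-4):
            bad_grid.append(str(p))
            continue
        row = by_id[sid]
        data = np.asarray(img.dataobj, dtype=float)
        scan = SubjectScan(
            subject_id=sid, data=data, brain_mask=mask, tr_s=tr, voxel_size_mm=voxel,
            group=row.group, age=row.age, gender=int(row.gender), iq=row.iq,
            pcl_total=_opt(row.pcl_total), pssi_reexperiencing=_opt(row.pssi_reexperiencing),
            pssi_avoidance=_opt(row.pssi_avoidance), pssi_arousal=_opt(row.pssi_arousal),
            bdi=_opt(row.bdi),
        )
        inside = data[mask]
        if not np.isfinite(inside).all():
            n_bad = int((~np.isfinite(inside)).sum())
            raise ValidationError(f"{sid}: {n_bad} non-finite voxels inside mask")
        subjects.append(scan)
    if bad_grid:
        raise ValidationError(f"grid/affine mismatch for: {bad_grid}")
    return CohortDataset(subjects=subjects, ground_truth=None, seed=-1)


def _opt(v):
    try:
        f = float(v)
        return None if np.isnan(f) else f
    except (TypeError, ValueError):
        return None


# --------------------------------------------------------- stage I/O


def write_decomposition(decomp, out_dir: str | Path, voxel_size_mm: float) -> Path:
    """Group maps as one 4-D NIfTI plus per-component 3-D files, with the
    stability/flag table as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size_mm)
    nib.save(
        nib.Nifti1Image(np.moveaxis(decomp.group_maps, 0, -1).astype(np.float32), aff),
        out / "group_maps.nii.gz",
    )
    for i, m in enumerate(decomp.group_maps):
        nib.save(nib.Nifti1Image(m.astype(np.float32), aff), out / f"group_map_{i:02d}.nii.gz")
    nib.save(nib.Nifti1Image(decomp.brain_mask.astype(np.uint8), aff), out / "brain_mask.nii.gz")
    pd.DataFrame(
        {
            "component": range(decomp.model_order),
            "stability_iq": decomp.stability_iq,
            "explained_variance": decomp.explained_variance,
            "artifact": [f for f, _ in decomp.artifact_flags],
            "artifact_reasons": [";".join(r) for _, r in decomp.artifact_flags],
        }
    ).to_csv(out / "components.tsv", sep="\t", index=False)
    return out


def read_decomposition(dir_path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load (group_maps, brain_mask, component table) written by
    :func:`write_decomposition`."""
    d = Path(dir_path)
    maps = np.moveaxis(np.asarray(nib.load(str(d / "group_maps.nii.gz")).dataobj, float), -1, 0)
    mask = np.asarray(nib.load(str(d / "brain_mask.nii.gz")).dataobj) > 0
    table = pd.read_csv(d / "components.tsv", sep="\t")
    return maps, mask, table


def write_subject_networks(networks: list, out_dir: str | Path, voxel_size_mm: float) -> Path:
    """Per-subject maps (4-D NIfTI), time courses (TSV) and a JSON sidecar
    with the method tag."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_size_mm)
    for sn in networks:
        nib.save(
            nib.Nifti1Image(np.moveaxis(sn.maps, 0, -1).astype(np.float32), aff),
            out / f"{sn.subject_id}_maps.nii.gz",
        )
        pd.DataFrame(sn.timecourses).to_csv(
            out / f"{sn.subject_id}_timecourses.tsv", sep="\t", index=False, header=False
        )
        (out / f"{sn.subject_id}_networks.json").write_text(
            json.dumps(
                {
                    "subject_id": sn.subject_id,
                    "method": sn.method,
                    "reference_corr": list(map(float, sn.reference_corr)),
                    "fallback": sn.fallback,
                }
            )
        )
    return out


def read_subject_networks(dir_path: str | Path, brain_mask: np.ndarray) -> list:
    from .backrecon import SubjectNetworks

    d = Path(dir_path)
    out = []
    for sidecar in sorted(d.glob("*_networks.json")):
        meta = json.loads(sidecar.read_text())
        sid = meta["subject_id"]
        maps = np.moveaxis(
            np.asarray(nib.load(str(d / f"{sid}_maps.nii.gz")).dataobj, float), -1, 0
        )
        tcs = pd.read_csv(d / f"{sid}_timecourses.tsv", sep="\t", header=None).to_numpy()
        out.append(
            SubjectNetworks(
                subject_id=sid, maps=maps, timecourses=tcs,
                reference_corr=np.asarray(meta["reference_corr"]),
                method=meta["method"], brain_mask=brain_mask,
                fallback=list(meta["fallback"]),
            )
        )
    return out


def write_sdr_records(records: list, out_dir: str | Path, config_hash: str = "") -> Path:
    """SDR table as TSV plus a JSON file carrying the voxel sets."""
    from .sdr import sdr_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = sdr_table(records)
    if config_hash:
        table["config_hash"] = config_hash
    table.to_csv(out / "sdr_table.tsv", sep="\t", index=False)
    (out / "sdr_records.json").write_text(
        json.dumps(
            [
                {
                    "sdr_id": r.sdr_id, "component": r.component, "pattern": r.pattern,
                    "size_mm3": r.size_mm3, "peak_t": r.peak_t, "peak_mm": list(r.peak_mm),
                    "survives_bonferroni": bool(r.survives_bonferroni),
                    "voxels": r.voxels.tolist(),
                }
                for r in records
            ]
        )
    )
    return out


def read_sdr_records(dir_path: str | Path) -> list:
    from .sdr import SDRecord

    raw = json.loads((Path(dir_path) / "sdr_records.json").read_text())
    return [
        SDRecord(
            sdr_id=r["sdr_id"], component=r["component"], pattern=r["pattern"],
            voxels=np.asarray(r["voxels"], dtype=int), size_mm3=r["size_mm3"],
            peak_t=r["peak_t"], peak_mm=tuple(r["peak_mm"]),
            survives_bonferroni=r["survives_bonferroni"],
        )
        for r in raw
    ]


def run_pipeline(config: PipelineConfig, cohort: CohortDataset | None = None) -> Path:
    """Execute decompose -> backrecon -> sdr -> fnc -> correlate.

    With no cohort given, a synthetic one is simulated from the config.
    Writes maps, tables and a manifest into ``config.output_dir`` and
    returns that directory.  A stage failure is re-raised with the stage
    name after partial outputs are persisted.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if cohort is None:
            gt = make_ground_truth(
                grid_shape=config.grid_shape, n_networks=config.n_networks,
                n_timepoints=config.n_timepoints, seed=config.seed,
            )
            cohort = simulate_cohort(gt, config.n_per_group, seed=config.seed)
        log.info("cohort: %d subjects", len(cohort.subjects))
        pheno = phenotype_table(cohort)
        pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
        voxel = cohort.subjects[0].voxel_size_mm
        aff = _affine(voxel)

        stage = "decompose"
        decomp = decomposition.decompose_cohort(
            cohort, model_order=config.model_order,
            subject_pca_dim=config.subject_pca_dim,
            n_icasso_runs=config.icasso_runs, seed=config.seed,
        )
        write_decomposition(decomp, out, voxel)

        stage = "backrecon"
        keep = decomp.nonartifact_indices
        refs = decomp.group_maps[keep]
        networks = backrecon.backreconstruct_cohort(cohort, refs, method="guided")
        write_subject_networks(networks, out / "subject_networks", voxel)

        stage = "sdr"
        groups = [s.group for s in cohort.subjects]
        records, masks, nulls = sdr.detect_sdrs(
            networks, groups, cohort.brain_mask, voxel,
            mask_alpha=config.mask_alpha, voxel_p=config.voxel_p,
            cluster_alpha=config.cluster_alpha,
            n_networks_bonferroni=config.n_networks_bonferroni,
            n_iter=config.mc_iterations, connectivity=config.connectivity,
            seed=config.seed, affine=aff,
        )
        write_sdr_records(records, out, config.config_hash())
        (out / "cluster_nulls.json").write_text(
            json.dumps({key: n.to_dict() for key, n in nulls.items()})
        )

        stage = "fnc"
        comps_with_sdr = sorted({r.component for r in records})
        pairs = [
            (i, j) for idx, i in enumerate(comps_with_sdr) for j in comps_with_sdr[idx + 1:]
        ]
        if not pairs:
            pairs = None
        z_by_group, fnc_results = fnc.fnc_for_cohort(
            networks, groups, cohort.subjects[0].tr_s, pairs_to_test=pairs,
            cutoff_hz=config.filter_cutoff_hz, order=config.filter_order,
        )
        fnc_df = pd.DataFrame(
            [
                {
                    "pair": f"{r.pair[0]}-{r.pair[1]}", "F": r.f_stat,
                    "df1": r.df[0], "df2": r.df[1], "p": r.p_uncorrected,
                    "p_bonferroni": r.p_bonferroni,
                    **{f"posthoc_{k}": v for k, v in r.posthoc.items()},
                }
                for r in fnc_results
            ]
        )
        fnc_df["config_hash"] = config.config_hash()
        fnc_df.to_csv(out / "fnc_tests.tsv", sep="\t", index=False)

        stage = "correlate"
        corr_rows = []
        if records:
            corrs = symptoms.correlate_sdrs_with_symptoms(
                networks, groups, records, pheno,
                kurtosis_threshold=config.kurtosis_threshold,
            )
            corr_rows = [dataclasses.asdict(c) for c in corrs]
        corr_df = pd.DataFrame(corr_rows)
        corr_df["config_hash"] = config.config_hash()
        corr_df.to_csv(out / "symptom_correlations.tsv", sep="\t", index=False)

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": dataclasses.asdict(config),
            "n_subjects": len(cohort.subjects),
            "n_sdrs": len(records),
            "stages": ["simulate", "decompose", "backrecon", "sdr", "fnc", "correlate"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
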