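"""End-to-end orchestration: simulate -> preprocess -> GFC -> group stats ->
clinical stats -> classification, with file-based stage interfaces.

Volumes travel as NIfTI-1 (.nii / .nii.gz), motion as 6-column whitespace
text (translations mm, rotations radians), tables as TSV with a header row
and ``NA`` for missing, configuration as YAML, and each run writes a JSON
manifest recording the exact parameters, per-stage outputs with SHA-256
checksums, and per-subject QC outcomes.  All randomness flows from the
single configured seed through named substreams, so deterministic stages
reproduce identical checksums on rerun.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import clinical as _clinical
from . import group_stats as _gs
from . import synthetic as _syn
from .gfc import GFCMap, extract_cluster_mean_z, gfc_map, make_gm_mask
from .preprocess import Bold4D, MotionTrace, compute_fd, motion_qc, preprocess_bold

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    pass


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# NIfTI and table I/O
# ---------------------------------------------------------------------------

def save_volume(data: np.ndarray, affine: np.ndarray, path, tr: float | None = None) -> None:
    """Write a 3D/4D array as NIfTI-1; for 4D data the TR is stored in the
    time-axis zoom (pixdim[4], seconds)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    if tr is not None:
        hdr = img.header
        zooms = hdr.get_zooms()
        hdr.set_zooms(zooms[:3] + (float(tr),))
        hdr.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - rewrap as a format error
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return data, np.asarray(img.affine, dtype=np.float64)


def save_bold(bold: Bold4D, path) -> None:
    save_volume(bold.data, bold.affine, path, tr=bold.tr)


def load_bold(path) -> Bold4D:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 4:
        raise FormatError(
            f"{path}: expected a 4D BOLD image, got {img.ndim}D (header field dim)"
        )
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise FormatError(f"{path}: time-axis zoom (header field pixdim[4]) must be > 0")
    return Bold4D(np.asarray(img.get_fdata(), dtype=np.float64), img.affine, tr)


def save_motion(motion: MotionTrace, path) -> None:
    np.savetxt(str(path), motion.params, fmt="%.10g")


def load_motion(path) -> MotionTrace:
    params = np.loadtxt(str(path))
    return MotionTrace(np.atleast_2d(params))


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of a pipeline run; every default is a named, overridable key."""

    output_dir: str = "gfcpipe_out"
    input_dir: str | None = None          # existing cohort; None -> simulate
    seed: int = 0
    # cohort simulation
    n_per_group: tuple[int, int, int] = (35, 17, 28)
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_volumes: int = 250
    tr: float = 2.0
    noise_sd: float = 1.0
    effect_regions: tuple = ()            # (region_id, group, delta) triples
    motion_spikes: dict = field(default_factory=dict)
    # preprocessing
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.08)
    filter_type: str = "ideal"
    use_wm_regressor: bool = True
    use_csf_regressor: bool = True
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    # GFC
    mask_threshold: float = 0.2
    chunk_size: int = 2048
    # group statistics
    q: float = 0.05
    connectivity: int = 26
    min_extent: int = 1
    posthoc_mask_by_ancova: bool = False
    covariates: tuple[str, ...] = ("age", "gender", "education_years", "mean_fd")
    # clinical correlations
    correlation_variables: tuple[str, ...] = (
        "hrsd17", "anx_som", "weight_loss", "cognitive", "retardation", "sleep")
    correlation_subsets: tuple[str, ...] = ("patients", "S1", "S0")
    # classification
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: str | float = "auto"
    svm_standardize: bool = True
    max_subset_size: int = 3

    def cohort_config(self) -> _syn.CohortConfig:
        regions = tuple(
            _syn.EffectRegion(int(r[0]), str(r[1]), float(r[2]))
            for r in self.effect_regions
        )
        return _syn.CohortConfig(
            n_per_group=tuple(self.n_per_group),
            grid_shape=tuple(self.grid_shape),
            tr=self.tr,
            n_volumes=self.n_volumes,
            effect_regions=regions,
            noise_sd=self.noise_sd,
            motion_spikes={int(k): v for k, v in self.motion_spikes.items()},
            seed=self.seed,
        )

    def svm_config(self) -> _classify.SVMConfig:
        return _classify.SVMConfig(
            kernel=self.svm_kernel, C=self.svm_C,
            gamma=self.svm_gamma, standardize=self.svm_standardize,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect_regions"] = [list(r) for r in self.effect_regions]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_per_group", "grid_shape", "band", "covariates",
                    "correlation_variables", "correlation_subsets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "effect_regions" in raw and raw["effect_regions"] is not None:
            raw["effect_regions"] = tuple(tuple(r) for r in raw["effect_regions"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

class RunManifest:
    def __init__(self, config: RunConfig):
        self.data = {
            "software": {"name": "gfcpipe", "version": __version__},
            "config": config.to_dict(),
            "started": datetime.datetime.now().isoformat(timespec="seconds"),
            "stages": {},
        }

    def record(self, stage: str, params: dict, outputs: list, extra: dict | None = None) -> None:
        self.data["stages"][stage] = {
            "params": params,
            "outputs": {str(p): sha256_file(p) for p in outputs},
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        }
        if extra:
            self.data["stages"][stage].update(extra)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, default=str)


def _subject_ids(table: pd.DataFrame) -> list[str]:
    return list(table["id"].astype(str))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig, manifest: RunManifest | None = None) -> Path:
    """Generate the synthetic cohort and write it in standard formats."""
    out = Path(cfg.output_dir) / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    bundle = _syn.generate_cohort(cfg.cohort_config())
    files = []
    for sid, img, mot in zip(_subject_ids(bundle.subjects), bundle.images, bundle.motion):
        p_img = out / f"{sid}_bold.nii.gz"
        p_rp = out / f"{sid}_rp.txt"
        save_bold(img, p_img)
        save_motion(mot, p_rp)
        files += [p_img, p_rp]
    aff = bundle.config.affine
    for name, vol in (("gm_prob", bundle.gm_prob),
                      ("wm_mask", bundle.wm_mask.astype(np.float32)),
                      ("csf_mask", bundle.csf_mask.astype(np.float32))):
        p = out / f"{name}.nii.gz"
        save_volume(vol, aff, p)
        files.append(p)
    p_tsv = out / "participants.tsv"
    write_tsv(bundle.subjects, p_tsv)
    p_truth = out / "truth.json"
    p_truth.write_text(_syn.truth_to_json(bundle.truth))
    files += [p_tsv, p_truth]
    if manifest:
        manifest.record("simulate", {"seed": cfg.seed,
                                     "n_per_group": list(cfg.n_per_group),
                                     "grid_shape": list(cfg.grid_shape),
                                     "n_volumes": cfg.n_volumes,
                                     "noise_sd": cfg.noise_sd,
                                     "effect_regions": [list(r) for r in cfg.effect_regions]},
                        files, {"cohort_hash": bundle.content_hash()})
    return out


def _cohort_dir(cfg: RunConfig) -> Path:
    if cfg.input_dir is not None:
        return Path(cfg.input_dir)
    return Path(cfg.output_dir) / "cohort"


def stage_preprocess(cfg: RunConfig, manifest: RunManifest | None = None) -> Path:
    """Discard, detrend, band-pass and nuisance-regress every subject; QC."""
    cohort = _cohort_dir(cfg)
    out = Path(cfg.output_dir) / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    table = read_tsv(cohort / "participants.tsv")
    wm = csf = None
    if cfg.use_wm_regressor and (cohort / "wm_mask.nii.gz").exists():
        wm = load_volume(cohort / "wm_mask.nii.gz")[0] > 0.5
    if cfg.use_csf_regressor and (cohort / "csf_mask.nii.gz").exists():
        csf = load_volume(cohort / "csf_mask.nii.gz")[0] > 0.5
    files, qc_rows = [], []
    for sid in _subject_ids(table):
        bold = load_bold(cohort / f"{sid}_bold.nii.gz")
        motion = load_motion(cohort / f"{sid}_rp.txt")
        clean, trimmed = preprocess_bold(
            bold, motion, n_discard=cfg.n_discard,
            low_hz=cfg.band[0], high_hz=cfg.band[1], filter_type=cfg.filter_type,
            wm_mask=wm, csf_mask=csf,
        )
        qc = motion_qc(trimmed, cfg.trans_limit_mm, cfg.rot_limit_deg)
        _, mean_fd = compute_fd(trimmed)
        qc_rows.append({
            "id": sid,
            "max_trans": qc.max_translation_mm,
            "max_rot_deg": qc.max_rotation_deg,
            "mean_fd": mean_fd,
            "pass": qc.passed,
        })
        p = out / f"{sid}_preproc.nii.gz"
        save_bold(clean, p)
        files.append(p)
    qc_df = pd.DataFrame(qc_rows)
    p_qc = out / "qc_report.tsv"
    write_tsv(qc_df, p_qc)
    files.append(p_qc)
    if manifest:
        manifest.record(
            "preprocess",
            {"n_discard": cfg.n_discard, "band": list(cfg.band),
             "filter_type": cfg.filter_type, "order": "discard,detrend,bandpass,nuisance",
             "nuisance": "friston24" + ("+wm" if wm is not None else "")
             + ("+csf" if csf is not None else "") + ",global_signal_not_removed",
             "trans_limit_mm": cfg.trans_limit_mm, "rot_limit_deg": cfg.rot_limit_deg},
            files,
            {"qc_excluded": [r["id"] for r in qc_rows if not r["pass"]]},
        )
    return out


def stage_gfc(cfg: RunConfig, manifest: RunManifest | None = None) -> Path:
    """Per-subject GFC maps inside the gray-matter mask."""
    cohort = _cohort_dir(cfg)
    pre = Path(cfg.output_dir) / "preproc"
    out = Path(cfg.output_dir) / "gfc"
    out.mkdir(parents=True, exist_ok=True)
    table = read_tsv(cohort / "participants.tsv")
    prob, aff = load_volume(cohort / "gm_prob.nii.gz")
    mask = make_gm_mask(prob, aff, cfg.mask_threshold)
    files, rows = [], []
    for sid in _subject_ids(table):
        bold = load_bold(pre / f"{sid}_preproc.nii.gz")
        gmap = gfc_map(bold, mask, chunk_size=cfg.chunk_size, subject_id=sid)
        p = out / f"{sid}_gfc.nii.gz"
        save_volume(gmap.values, gmap.affine, p)
        files.append(p)
        inside = gmap.values[mask.mask]
        rows.append({
            "id": sid,
            "mask_voxels": mask.n_voxels,
            "undefined_voxels": gmap.n_undefined,
            "map_mean": float(np.nanmean(inside)),
            "map_sd": float(np.nanstd(inside)),
        })
    p_sum = out / "gfc_summary.tsv"
    write_tsv(pd.DataFrame(rows), p_sum)
    files.append(p_sum)
    if manifest:
        manifest.record("gfc", {"mask_threshold": cfg.mask_threshold,
                                "chunk_size": cfg.chunk_size,
                                "fisher_z": "before averaging, self excluded, signed r"},
                        files)
    return out


def _load_gfc_maps(cfg: RunConfig, ids) -> list[GFCMap]:
    gdir = Path(cfg.output_dir) / "gfc"
    maps = []
    for sid in ids:
        vals, aff = load_volume(gdir / f"{sid}_gfc.nii.gz")
        maps.append(GFCMap(vals, aff, sid))
    return maps


def _included_table(cfg: RunConfig) -> pd.DataFrame:
    """Participants that passed motion QC, with mean FD merged in."""
    cohort = _cohort_dir(cfg)
    table = read_tsv(cohort / "participants.tsv")
    qc = read_tsv(Path(cfg.output_dir) / "preproc" / "qc_report.tsv")
    merged = table.merge(qc[["id", "mean_fd", "pass"]], on="id")
    return merged[merged["pass"].astype(bool)].reset_index(drop=True)


def stage_group_stats(cfg: RunConfig, manifest: RunManifest | None = None) -> Path:
    """ANCOVA + FDR + clusters, post hoc contrasts, and region features."""
    cohort = _cohort_dir(cfg)
    out = Path(cfg.output_dir) / "stats"
    out.mkdir(parents=True, exist_ok=True)
    table = _included_table(cfg)
    ids = _subject_ids(table)
    maps = _load_gfc_maps(cfg, ids)
    prob, aff = load_volume(cohort / "gm_prob.nii.gz")
    gm = make_gm_mask(prob, aff, cfg.mask_threshold)
    mask3d = _gs.analysis_mask(maps, gm.mask)
    files = []

    design = _gs.build_design(table, covariates=cfg.covariates)
    fmap = _gs.fit_voxel_ancova(maps, design, mask3d)
    _gs.apply_fdr(fmap, cfg.q)
    f_clusters = _gs.label_clusters(fmap, cfg.connectivity, cfg.min_extent)
    for name, vol in (("ancova_F", fmap.volume("stat")), ("ancova_p", fmap.volume("p"))):
        p = out / f"{name}.nii.gz"
        save_volume(vol, aff, p)
        files.append(p)
    p_fc = out / "ancova_clusters.tsv"
    write_tsv(_gs.cluster_table(f_clusters), p_fc)
    files.append(p_fc)

    ancova_surviving = None
    if cfg.posthoc_mask_by_ancova:
        ancova_surviving = np.zeros(mask3d.shape, bool)
        ancova_surviving[mask3d] = fmap.fdr_mask

    pairs = [("S1", "S0"), ("S1", "HC"), ("S0", "HC")]
    region_cols: dict[str, np.ndarray] = {}
    cluster_counts = {}
    for ga, gb in pairs:
        sel = table["group"].isin([ga, gb]).to_numpy()
        sub_table = table[sel].reset_index(drop=True)
        sub_maps = [m for m, s in zip(maps, sel) if s]
        pair_mask = mask3d if ancova_surviving is None else (mask3d & ancova_surviving)
        if not pair_mask.any():
            cluster_counts[f"{ga}_vs_{gb}"] = 0
            continue
        sub_design = _gs.build_design(sub_table, covariates=cfg.covariates,
                                      reference_group=gb)
        tmap = _gs.posthoc_t(sub_maps, sub_design, pair_mask)
        _gs.apply_fdr(tmap, cfg.q)
        clusters = _gs.label_clusters(tmap, cfg.connectivity, cfg.min_extent)
        tag = f"{ga}_vs_{gb}"
        for name, vol in ((f"posthoc_{tag}_t", tmap.volume("stat")),
                          (f"posthoc_{tag}_p", tmap.volume("p"))):
            p = out / f"{name}.nii.gz"
            save_volume(vol, aff, p)
            files.append(p)
        p_ct = out / f"posthoc_{tag}_clusters.tsv"
        write_tsv(_gs.cluster_table(clusters), p_ct)
        files.append(p_ct)
        cluster_counts[tag] = len(clusters)
        for i, cl in enumerate(clusters):
            region_cols[f"{tag}_c{i + 1}"] = cl.voxels

    # Region features: per-subject mean GFC z inside each reported cluster;
    # falls back to the planted truth regions when no cluster survived,
    # so downstream stages remain exercisable on null-ish cohorts.
    if not region_cols and (cohort / "truth.json").exists():
        truth = json.loads((cohort / "truth.json").read_text())
        for rid, info in truth.items():
            region_cols[f"truth_{rid}"] = np.asarray(info["voxels"], dtype=int)
    feat_rows = []
    for sid, m in zip(ids, maps):
        row = {"id": sid}
        for name, vox in region_cols.items():
            row[name] = extract_cluster_mean_z(m, vox)
        feat_rows.append(row)
    feats = pd.DataFrame(feat_rows)
    p_feat = out / "region_features.tsv"
    write_tsv(feats, p_feat)
    files.append(p_feat)
    if manifest:
        manifest.record("group_stats",
                        {"q": cfg.q, "connectivity": cfg.connectivity,
                         "min_extent": cfg.min_extent,
                         "covariates": list(cfg.covariates),
                         "posthoc_mask_by_ancova": cfg.posthoc_mask_by_ancova},
                        files,
                        {"n_included": len(ids),
                         "ancova_clusters": len(f_clusters),
                         "posthoc_clusters": cluster_counts,
                         "region_features": list(region_cols)})
    return out


def stage_clinical_stats(cfg: RunConfig, manifest: RunManifest | None = None) -> Path:
    """Cohort-description statistics and BH-corrected clinical correlations."""
    out = Path(cfg.output_dir) / "clinical"
    out.mkdir(parents=True, exist_ok=True)
    table = _included_table(cfg)
    rows = []
    for var in ("age", "education_years", "hrsd17", "anx_som", "weight_loss",
                "cognitive", "retardation", "sleep"):
        vals = table[var].to_numpy(float)
        labels = table["group"].to_numpy()
        try:
            f, p, df = _clinical.oneway_anova(vals, labels)
            rows.append({"variable": var, "test": "anova", "statistic": f,
                         "p": p, "df1": df[0], "df2": df[1]})
        except _clinical.ClinicalStatsError:
            continue
    counts = pd.crosstab(table["group"], table["gender"])
    if counts.shape[1] == 2 and (counts.to_numpy().sum(axis=1) > 0).all():
        chi2, p, df = _clinical.chisq_independence(counts.to_numpy())
        rows.append({"variable": "gender", "test": "chi_square",
                     "statistic": chi2, "p": p, "df1": df, "df2": np.nan})
    dur = table[table["group"].isin(["S1", "S0"])]
    x = dur.loc[dur["group"] == "S1", "illness_duration_months"].dropna().to_numpy(float)
    y = dur.loc[dur["group"] == "S0", "illness_duration_months"].dropna().to_numpy(float)
    if x.size >= 2 and y.size >= 2:
        t, p, df = _clinical.two_sample_t(x, y)
        rows.append({"variable": "illness_duration_months", "test": "two_sample_t",
                     "statistic": t, "p": p, "df1": df, "df2": np.nan})
    p_stats = out / "group_stats.tsv"
    write_tsv(pd.DataFrame(rows), p_stats)
    files = [p_stats]

    feats = read_tsv(Path(cfg.output_dir) / "stats" / "region_features.tsv")
    merged = table.merge(feats, on="id").set_index("id")
    region_names = [c for c in feats.columns if c != "id"]
    all_results = []
    subsets = {
        "patients": merged["group"].isin(["S1", "S0"]),
        "S1": merged["group"] == "S1",
        "S0": merged["group"] == "S0",
    }
    for name in cfg.correlation_subsets:
        sel = subsets[name]
        sub = merged[sel]
        if len(sub) < 4 or not region_names:
            continue
        res = _clinical.pearson_with_bh(
            sub[region_names], sub[list(cfg.correlation_variables)],
            subset=name, q=cfg.q,
        )
        all_results.extend(res)
    p_corr = out / "correlations.tsv"
    write_tsv(_clinical.correlation_table(all_results), p_corr)
    files.append(p_corr)
    if manifest:
        manifest.record("clinical_stats",
                        {"bh_q": cfg.q,
                         "family": "all region x variable pairs per subject subset",
                         "subsets": list(cfg.correlation_subsets)},
                        files)
    return out


def stage_classify(cfg: RunConfig, manifest: RunManifest | None = None) -> Path:
    """LOOCV SVM comparisons: S1 vs S0 and S1 vs HC, with subset search."""
    out = Path(cfg.output_dir) / "classify"
    out.mkdir(parents=True, exist_ok=True)
    table = _included_table(cfg)
    feats = read_tsv(Path(cfg.output_dir) / "stats" / "region_features.tsv")
    merged = table.merge(feats, on="id")
    region_names = [c for c in feats.columns if c != "id"]
    files = []
    summary = {}
    for ga, gb in (("S1", "S0"), ("S1", "HC")):
        tag = f"{ga}_vs_{gb}"
        # features discovered in this pair's contrast, else all available
        cols = [c for c in region_names if c.startswith(tag)] or region_names
        sub = merged[merged["group"].isin([ga, gb])]
        if not cols or (sub["group"] == ga).sum() < 3 or (sub["group"] == gb).sum() < 3:
            summary[tag] = "skipped (insufficient subjects or features)"
            continue
        results = _classify.feature_subset_search(
            sub[cols], sub["group"].to_numpy(), positive_label=ga,
            max_subset_size=cfg.max_subset_size, config=cfg.svm_config(),
        )
        rows = [{
            "features": "+".join(r.features),
            "tp": r.counts.tp, "fn": r.counts.fn,
            "tn": r.counts.tn, "fp": r.counts.fp,
            "accuracy": r.metrics.accuracy,
            "sensitivity": r.metrics.sensitivity,
            "specificity": r.metrics.specificity,
        } for r in results]
        p_rep = out / f"{tag}_report.tsv"
        write_tsv(pd.DataFrame(rows), p_rep)
        files.append(p_rep)
        best = results[0]
        _, preds = _classify.loocv_svm(sub[list(best.features)],
                                       sub["group"].to_numpy(), ga,
                                       cfg.svm_config())
        p_pred = out / f"{tag}_predictions.tsv"
        write_tsv(pd.DataFrame({"id": sub["id"], "group": sub["group"],
                                "predicted": preds}), p_pred)
        files.append(p_pred)
        summary[tag] = {"best_features": list(best.features),
                        "accuracy": best.metrics.accuracy,
                        "sensitivity": best.metrics.sensitivity,
                        "specificity": best.metrics.specificity}
    if manifest:
        manifest.record("classify",
                        {"kernel": cfg.svm_kernel, "C": cfg.svm_C,
                         "gamma": str(cfg.svm_gamma),
                         "standardize": cfg.svm_standardize,
                         "max_subset_size": cfg.max_subset_size},
                        files, {"comparisons": summary})
    return out


def analyze_bundle(
    bundle: _syn.CohortBundle,
    cfg: RunConfig | None = None,
) -> dict:
    """In-memory analysis of a generated cohort (no file I/O).

    Runs preprocessing, GFC mapping, the group ANCOVA with FDR and the
    three post hoc contrasts on a :class:`~gfcpipe.synthetic.CohortBundle`,
    returning the intermediate objects.  Convenience path for validation
    studies and simulations; the file-based stages produce the same numbers.
    """
    cfg = cfg or RunConfig()
    table = bundle.subjects.copy()
    maps = []
    mean_fds = []
    keep = []
    mask = make_gm_mask(bundle.gm_prob, bundle.config.affine, cfg.mask_threshold)
    for i, (bold, motion) in enumerate(zip(bundle.images, bundle.motion)):
        clean, trimmed = preprocess_bold(
            bold, motion, n_discard=cfg.n_discard,
            low_hz=cfg.band[0], high_hz=cfg.band[1], filter_type=cfg.filter_type,
            wm_mask=bundle.wm_mask, csf_mask=bundle.csf_mask,
        )
        qc = motion_qc(trimmed, cfg.trans_limit_mm, cfg.rot_limit_deg)
        _, mean_fd = compute_fd(trimmed)
        if not qc.passed:
            continue
        keep.append(i)
        mean_fds.append(mean_fd)
        maps.append(gfc_map(clean, mask, chunk_size=cfg.chunk_size,
                            subject_id=table["id"].iloc[i]))
    table = table.iloc[keep].reset_index(drop=True)
    table["mean_fd"] = mean_fds
    mask3d = _gs.analysis_mask(maps, mask.mask)
    design = _gs.build_design(table, covariates=cfg.covariates)
    fmap = _gs.apply_fdr(_gs.fit_voxel_ancova(maps, design, mask3d), cfg.q)
    f_clusters = _gs.label_clusters(fmap, cfg.connectivity, cfg.min_extent)
    posthoc = {}
    for ga, gb in (("S1", "S0"), ("S1", "HC"), ("S0", "HC")):
        sel = table["group"].isin([ga, gb]).to_numpy()
        sub_design = _gs.build_design(table[sel].reset_index(drop=True),
                                      covariates=cfg.covariates, reference_group=gb)
        tmap = _gs.apply_fdr(
            _gs.posthoc_t([m for m, s in zip(maps, sel) if s], sub_design, mask3d),
            cfg.q)
        posthoc[f"{ga}_vs_{gb}"] = {
            "stat_map": tmap,
            "clusters": _gs.label_clusters(tmap, cfg.connectivity, cfg.min_extent),
        }
    return {"table": table, "maps": maps, "mask": mask, "mask3d": mask3d,
            "ancova": fmap, "ancova_clusters": f_clusters, "posthoc": posthoc}


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Run every stage in order and write the manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg)
    if cfg.input_dir is None:
        stage_simulate(cfg, manifest)
    stage_preprocess(cfg, manifest)
    stage_gfc(cfg, manifest)
    stage_group_stats(cfg, manifest)
    stage_clinical_stats(cfg, manifest)
    stage_classify(cfg, manifest)
    manifest.data["finished"] = datetime.datetime.now().isoformat(timespec="seconds")
    manifest.save(outdir / "manifest.json")
    return manifest
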