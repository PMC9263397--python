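"""Synthetic three-group resting-state cohort with known planted effects.

Generates everything the downstream pipeline consumes — 4D BOLD images,
rigid-body motion traces, a tissue-probability template, and a clinical
table — for a cohort of two patient groups and healthy controls
(default 35 / 17 / 28 subjects, TR = 2 s, 250 volumes), so that every
analysis stage can be validated against ground truth.

BOLD model
----------
Each voxel's series is a loading-weighted sum of band-limited (0.01-0.08 Hz)
Gaussian latent signals plus white noise:

    y_v(t) = loading(v) * s(t) + noise_sd * eps_v(t)

The baseline loading equals the gray-matter probability at the voxel, so
gray-matter voxels share a common latent signal and exhibit positive global
connectivity, while background voxels are essentially noise.  Inside a
planted effect region the loading is scaled by (1 + delta) for subjects of
the designated group, raising (delta > 0) or lowering (delta < 0) that
region's mean connectivity with the rest of the mask.

Clinical scores are drawn from truncated normals with the configured
per-group moments, rounded to integers and clipped to each scale's valid
range; healthy controls' weight-loss factor is fixed at zero.  All
randomness flows from a single integer seed through named substreams, so a
fixed (config, seed) pair reproduces the cohort bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .preprocess import Bold4D, MotionTrace
from .preprocess import _ideal_bandpass


class ConfigurationError(ValueError):
    pass


class DegenerateSignalError(ValueError):
    pass


GROUPS = ("S1", "S0", "HC")

#: per-variable (per-group mean, per-group SD) and valid integer range.
#: S1 = patients with GI symptoms, S0 = patients without, HC = controls.
DEFAULT_CLINICAL_MOMENTS: dict[str, dict] = {
    "age": {"S1": (30.86, 6.84), "S0": (30.29, 8.05), "HC": (30.14, 5.00),
            "range": (18, 55)},
    "education_years": {"S1": (14.51, 3.28), "S0": (12.94, 3.46), "HC": (14.61, 2.69),
                        "range": (0, 25)},
    "illness_duration_months": {"S1": (6.23, 4.63), "S0": (6.94, 3.98), "HC": None,
                                "range": (1, 240)},
    "hrsd17": {"S1": (22.69, 3.41), "S0": (20.18, 2.67), "HC": (0.89, 0.88),
               "range": (0, 52)},
    "anx_som": {"S1": (7.31, 1.92), "S0": (6.41, 1.66), "HC": (0.39, 0.57),
                "range": (0, 18)},
    "weight_loss": {"S1": (0.80, 0.83), "S0": (0.06, 0.24), "HC": (0.0, 0.0),
                    "range": (0, 2)},
    "cognitive": {"S1": (3.71, 1.78), "S0": (3.41, 1.50), "HC": (0.0, 0.0),
                  "range": (0, 12)},
    "retardation": {"S1": (6.40, 1.42), "S0": (6.76, 1.56), "HC": (0.18, 0.39),
                    "range": (0, 14)},
    "sleep": {"S1": (4.46, 1.42), "S0": (3.53, 1.28), "HC": (0.32, 0.55),
              "range": (0, 6)},
}

#: probability of male gender per group (13/35, 6/17, 14/28)
DEFAULT_P_MALE = {"S1": 13 / 35, "S0": 6 / 17, "HC": 14 / 28}

#: anchor positions of plantable effect regions, as fractions of the grid
#: half-extent relative to the grid center; all lie inside the gray-matter
#: shell of the synthetic template.
REGION_ANCHORS = (
    (-0.45, 0.35, 0.20),
    (0.45, 0.35, 0.20),
    (0.00, -0.55, 0.10),
    (0.00, 0.55, -0.25),
    (-0.40, -0.35, -0.30),
    (0.40, -0.35, -0.30),
    (0.00, 0.00, 0.60),
    (0.00, 0.00, -0.60),
)


def subsidiary_rng(seed: int, *keys) -> np.random.Generator:
    """Named substream of the global seed (stage-name-keyed SeedSequence)."""
    entropy = [int(seed)] + [zlib.crc32(str(k).encode("utf8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class EffectRegion:
    """A planted connectivity effect: region `region_id` has its loading
    scaled by (1 + delta) for subjects of `group`."""

    region_id: int
    group: str
    delta: float


@dataclass
class CohortConfig:
    n_per_group: tuple[int, int, int] = (35, 17, 28)
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    tr: float = 2.0
    n_volumes: int = 250
    affine: np.ndarray | None = None
    effect_regions: tuple[EffectRegion, ...] = ()
    noise_sd: float = 1.0
    latent_band: tuple[float, float] = (0.01, 0.08)
    clinical_moments: dict = field(default_factory=lambda: DEFAULT_CLINICAL_MOMENTS)
    p_male: dict = field(default_factory=lambda: dict(DEFAULT_P_MALE))
    motion_step_trans_mm: float = 0.04
    motion_step_rot_rad: float = 0.0004
    motion_spikes: dict = field(default_factory=dict)  # subject index -> [(frame, mm)]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 1 for n in self.n_per_group):
            raise ConfigurationError("n_per_group must be three positive integers")
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise ConfigurationError("grid_shape axes must each be >= 8")
        if self.n_volumes < 20:
            raise ConfigurationError("n_volumes must be >= 20")
        if not self.tr > 0:
            raise ConfigurationError("TR must be positive")
        for er in self.effect_regions:
            if not np.isfinite(er.delta) or er.delta <= -1:
                raise ConfigurationError(
                    f"effect delta must be finite and > -1, got {er.delta}"
                )
            if er.group not in GROUPS:
                raise ConfigurationError(f"unknown effect group {er.group!r}")
            if not 0 <= er.region_id < len(REGION_ANCHORS):
                raise ConfigurationError(
                    f"region_id must be in [0, {len(REGION_ANCHORS)})"
                )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.affine is None:
            # 3 mm isotropic voxels, grid centered on the world origin
            shape = np.asarray(self.grid_shape)
            aff = np.diag([3.0, 3.0, 3.0, 1.0])
            aff[:3, 3] = -3.0 * (shape - 1) / 2
            self.affine = aff
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed, affine=self.affine.copy())


@dataclass
class CohortBundle:
    subjects: pd.DataFrame
    images: list[Bold4D]
    motion: list[MotionTrace]
    gm_prob: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    truth: dict[int, dict]
    config: CohortConfig

    def content_hash(self) -> str:
        """SHA-256 over all arrays and the clinical table (determinism check)."""
        h = hashlib.sha256()
        for img in self.images:
            h.update(np.ascontiguousarray(img.data).tobytes())
        for m in self.motion:
            h.update(np.ascontiguousarray(m.params).tobytes())
        h.update(np.ascontiguousarray(self.gm_prob).tobytes())
        h.update(self.subjects.to_csv(sep="\t", index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Tissue template and designated regions
# ---------------------------------------------------------------------------

def _normalized_radius(grid_shape) -> np.ndarray:
    shape = np.asarray(grid_shape)
    center = (shape - 1) / 2
    half = shape / 2
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return np.sqrt(sum(((g - c) / h) ** 2 for g, c, h in zip(grids, center, half)))


def generate_tissue_template(grid_shape) -> np.ndarray:
    """Gray-matter probability volume: a smooth ellipsoidal shell.

    Probabilities are high on a shell (mimicking cortical gray matter),
    fall to near zero both in the deep core (the white-matter/ventricle
    territory used for nuisance compartments) and outside the head, and the
    p > 0.2 mask is connected and covers >= 30% of the grid.  Deterministic
    (no randomness).
    """
    if len(grid_shape) != 3 or any(s < 8 for s in grid_shape):
        raise ConfigurationError("grid_shape axes must each be >= 8")
    rho = _normalized_radius(grid_shape)
    outer = 1.0 / (1.0 + np.exp((rho - 0.85) / 0.06))
    inner = 1.0 / (1.0 + np.exp((0.30 - rho) / 0.04))
    return np.clip(outer * inner, 0.0, 1.0)


def compartment_masks(grid_shape) -> tuple[np.ndarray, np.ndarray]:
    """Designated white-matter and CSF compartments in the deep core.

    These voxels sit where the gray-matter probability is below the 0.2
    masking threshold; their mean series serve as nuisance regressors.  No
    tissue segmentation is performed.
    """
    rho = _normalized_radius(grid_shape)
    core = rho < 0.22
    x = np.arange(grid_shape[0])[:, None, None]
    left = np.broadcast_to(x < grid_shape[0] / 2, grid_shape)
    wm = core & left
    csf = core & ~left
    if not wm.any() or not csf.any():
        raise ConfigurationError("grid too small for nuisance compartments")
    return wm, csf


def region_voxels(region_id: int, grid_shape, gm_mask: np.ndarray) -> np.ndarray:
    """Voxel indices (m x 3) of a plantable region: a 3x3x3 cube at the
    region's anchor, intersected with the gray-matter mask."""
    if not 0 <= region_id < len(REGION_ANCHORS):
        raise ConfigurationError(f"region_id must be in [0, {len(REGION_ANCHORS)})")
    shape = np.asarray(grid_shape)
    center = (shape - 1) / 2 + np.asarray(REGION_ANCHORS[region_id]) * shape / 2
    center = np.round(center).astype(int)
    lo = np.maximum(center - 1, 0)
    hi = np.minimum(center + 1, shape - 1)
    sub = np.zeros(tuple(shape), dtype=bool)
    sub[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = True
    sub &= gm_mask
    idx = np.argwhere(sub)
    if idx.size == 0:
        raise ConfigurationError(
            f"region {region_id} does not intersect the gray-matter mask"
        )
    return idx


# ---------------------------------------------------------------------------
# Per-subject generators
# ---------------------------------------------------------------------------

def _band_limited_latent(n_volumes: int, tr: float, band, rng) -> np.ndarray:
    s = rng.standard_normal(n_volumes)
    s = _ideal_bandpass(s[None, :], tr, band[0], band[1])[0]
    sd = s.std()
    if sd == 0:
        raise DegenerateSignalError("latent signal has zero variance")
    return s / sd


def generate_bold(
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    gm_prob: np.ndarray | None = None,
    truth: dict[int, dict] | None = None,
) -> Bold4D:
    """One subject's 4D BOLD series under the latent-loading model."""
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    if gm_prob is None:
        gm_prob = generate_tissue_template(config.grid_shape)
    loading = gm_prob.astype(np.float64).copy()
    if truth is None:
        gm_mask = gm_prob > 0.2
        truth = {
            er.region_id: {
                "voxels": region_voxels(er.region_id, config.grid_shape, gm_mask),
                "group": er.group,
                "delta": er.delta,
            }
            for er in config.effect_regions
        }
    for info in truth.values():
        if info["group"] == group:
            idx = np.asarray(info["voxels"])
            loading[idx[:, 0], idx[:, 1], idx[:, 2]] *= 1.0 + info["delta"]
    if config.noise_sd == 0 and not np.any(loading):
        raise DegenerateSignalError("zero noise with all-zero loadings")
    latent = _band_limited_latent(config.n_volumes, config.tr, config.latent_band, rng)
    data = loading[..., None] * latent[None, None, None, :]
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal(data.shape)
    return Bold4D(data, config.affine, config.tr)


def generate_motion(
    config: CohortConfig,
    rng: np.random.Generator,
    spikes=(),
) -> MotionTrace:
    """Random-walk T x 6 motion trace (translations mm, rotations rad).

    `spikes` is a list of (frame, magnitude_mm) transient jumps added to the
    x-translation at single frames, used to exercise motion QC.
    """
    t = config.n_volumes
    steps = np.hstack([
        rng.normal(0.0, config.motion_step_trans_mm, (t, 3)),
        rng.normal(0.0, config.motion_step_rot_rad, (t, 3)),
    ])
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    for frame, mm in spikes:
        params[int(frame), 0] += mm
    return MotionTrace(params)


def _truncnorm_int(mean: float, sd: float, lo: float, hi: float, rng) -> int:
    if sd == 0:
        return int(round(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draw = _stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return int(np.clip(round(float(draw)), lo, hi))


def generate_clinical_scores(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> dict:
    """One subject's demographic and clinical record.

    Scores are truncated-normal draws at the configured per-group moments,
    integer-rounded and clipped to each scale's range; variables configured
    with a zero SD (e.g. controls' weight-loss factor) are exactly their
    mean.  Gender is Bernoulli (1 = male).
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group {group!r}")
    record: dict = {"group": group}
    for var, spec in config.clinical_moments.items():
        moments = spec[group]
        if moments is None:
            record[var] = np.nan
            continue
        lo, hi = spec["range"]
        record[var] = _truncnorm_int(moments[0], moments[1], lo, hi, rng)
    record["gender"] = int(rng.random() < config.p_male[group])
    return record


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate the full cohort: clinical table, motion, images, template, truth."""
    gm_prob = generate_tissue_template(config.grid_shape)
    wm_mask, csf_mask = compartment_masks(config.grid_shape)
    gm_mask = gm_prob > 0.2
    truth = {
        er.region_id: {
            "voxels": region_voxels(er.region_id, config.grid_shape, gm_mask),
            "group": er.group,
            "delta": er.delta,
        }
        for er in config.effect_regions
    }
    groups = [g for g, n in zip(GROUPS, config.n_per_group) for _ in range(n)]
    rows = []
    images: list[Bold4D] = []
    motions: list[MotionTrace] = []
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        rec = generate_clinical_scores(group, config, subsidiary_rng(config.seed, "clinical", i))
        rec["id"] = sid
        rows.append(rec)
        spikes = config.motion_spikes.get(i, ())
        motions.append(generate_motion(config, subsidiary_rng(config.seed, "motion", i), spikes))
        images.append(
            generate_bold(group, config, subsidiary_rng(config.seed, "bold", i),
                          gm_prob=gm_prob, truth=truth)
        )
    cols = ["id", "group", "age", "gender", "education_years",
            "illness_duration_months", "hrsd17", "anx_som", "weight_loss",
            "cognitive", "retardation", "sleep"]
    subjects = pd.DataFrame(rows)[cols]
    return CohortBundle(subjects, images, motions, gm_prob, wm_mask, csf_mask,
                        truth, config)


def truth_to_json(truth: dict[int, dict]) -> str:
    """Serializable form of the planted-effect ground truth."""
    payload = {
        str(rid): {
            "voxels": np.asarray(info["voxels"]).tolist(),
            "group": info["group"],
            "delta": info["delta"],
        }
        for rid, info in truth.items()
    }
    return json.dumps(payload, indent=1)
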