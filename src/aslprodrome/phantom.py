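"""Digital perfusion phantom: synthetic subjects and cohorts.

The phantom replaces access-restricted clinical scans with a forward model
that the rest of the pipeline can be validated against.  A subject is a
nested-ellipsoid "head" (CSF ventricle core, WM shell, GM outer shell) with
smooth partial-volume transitions, a ground-truth CBF map, and a simulated
pulsed-ASL time series built by inverting the one-compartment quantification
equation exactly — so with zero noise the pipeline must recover the truth to
machine precision.  On top of the clean signal the simulator adds thermal
noise, slow scanner drift, rigid head motion, and sporadically corrupted
volumes of the two kinds seen in practice (decorrelated-noise volumes from
labeling instability, and global intensity jumps from hardware instability).

Cohort simulation generates the subject-level covariate/biomarker table with
group-graded perfusion and hippocampal effects, emulating a continuum from
cognitively normal aging through early/late mild cognitive impairment to
mild dementia.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import QuantParams, scaling_volume
from .rigid import apply_rigid
from .types import AslSeries, CONTROL, LABEL, M0, TissueMaps, default_affine

GROUPS = ("CN", "EMCI", "LMCI", "AD")


@dataclass
class PhantomSpec:
    """Geometry, timing, and noise model of one synthetic acquisition.

    The default grid mirrors the 2D EPI readout this pipeline targets:
    64 x 64 in-plane matrix, 24 slices of 4 mm with a 25 % inter-slice gap
    (5 mm slice pitch in the affine), TR 3400 ms, bolus/inversion times
    TI1/TI2 = 700/1900 ms, and 105 volumes: one M0 calibration image then
    52 label/control pairs.

    Noise defaults are assumptions, not reproductions of any scanner:
    ``noise_sd`` is thermal noise in signal units on an M0 scale of 1000,
    chosen so that a clean difference map correlates with the mean of the
    others at roughly 0.4 over gray matter — the regime in which the
    correlation-based cleaning of real series operates; ``drift_amplitude``
    is a slow gain-like drift weighted by proton density.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size: tuple[float, float, float] = (3.4, 3.4, 5.0)
    n_volumes: int = 105
    tr_ms: float = 3400.0
    ti1_ms: float = 700.0
    ti2_ms: float = 1900.0
    gm_cbf_true: float = 60.0
    wm_cbf_true: float = 20.0
    m0_scale: float = 1000.0
    noise_sd: float = 0.6
    drift_amplitude: float = 2.0
    drift_period_s: float = 300.0
    motion_schedule: np.ndarray | None = None  # (n_volumes, 6)
    outlier_schedule: tuple[tuple[int, str], ...] = ()  # (volume index, kind)
    corruption_sd: float = 10.0  # 'noise' corruption, signal units
    corruption_offset: float = 30.0  # 'offset' corruption, signal units
    first_volume: str = LABEL  # tag of volume 1; subtraction is always control-label
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 3 or self.n_volumes % 2 == 0:
            raise ValueError(
                "n_volumes must be odd (one M0 plus complete label/control pairs)"
            )
        for name in ("tr_ms", "ti1_ms", "ti2_ms", "m0_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.first_volume not in (LABEL, CONTROL):
            raise ValueError("first_volume must be 'label' or 'control'")
        for idx, kind in self.outlier_schedule:
            if not 1 <= idx < self.n_volumes:
                raise ValueError("outlier volume indices must lie in [1, n_volumes)")
            if kind not in ("noise", "offset"):
                raise ValueError(f"unknown corruption kind {kind!r}")
        if self.motion_schedule is not None:
            ms = np.asarray(self.motion_schedule, dtype=np.float64)
            if ms.shape != (self.n_volumes, 6):
                raise ValueError("motion_schedule must be (n_volumes, 6)")
            self.motion_schedule = ms

    @property
    def n_pairs(self) -> int:
        return (self.n_volumes - 1) // 2

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size)

    def quant_params(self) -> QuantParams:
        return QuantParams(ti1_ms=self.ti1_ms, ti2_ms=self.ti2_ms)

    def volume_labels(self) -> list[str]:
        first, second = (
            (LABEL, CONTROL) if self.first_volume == LABEL else (CONTROL, LABEL)
        )
        tags = [M0]
        for _ in range(self.n_pairs):
            tags.extend([first, second])
        return tags


@dataclass
class GroundTruth:
    """Everything the simulator knows and the pipeline must estimate."""

    cbf_map: np.ndarray  # ml/100 g/min per voxel
    tissue: TissueMaps
    outlier_indices: frozenset[int]
    motion: np.ndarray  # (n_volumes, 6) applied rigid parameters

    def __post_init__(self) -> None:
        if self.cbf_map.min() < 0:
            raise ValueError("ground-truth CBF must be nonnegative")


# ---------------------------------------------------------------------------
# Tissue / anatomy


def _ellipsoid_radius(spec: PhantomSpec) -> np.ndarray:
    """Normalized elliptical radius of each voxel center (0 at center)."""
    shape = spec.grid_shape
    vox = np.asarray(spec.voxel_size, dtype=np.float64)
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    # elliptical head: narrower left-right than anterior-posterior, which
    # also breaks in-plane rotational symmetry so axial rotation is
    # identifiable by registration
    half_extent = (np.asarray(shape) * vox) / 2.0
    semi = np.array([0.76, 0.88, 0.85]) * half_extent
    r2 = sum(((c - mu) * v / a) ** 2 for c, mu, v, a in zip(coords, center, vox, semi))
    return np.sqrt(r2)


# shell boundaries on the normalized radius and sigmoid transition width
# (width ~2 mm physically: partial-volume rims exist but shell cores are pure)
_R_CSF, _R_WM, _R_BRAIN, _EDGE_W = 0.28, 0.60, 0.92, 0.028


def make_tissue_phantom(spec: PhantomSpec) -> tuple[TissueMaps, np.ndarray]:
    """Build the concentric-shell tissue probabilities and true CBF map.

    CSF occupies the core ("ventricles"), WM the middle shell, GM the outer
    shell; sigmoidal transitions create genuine partial-volume voxels.  The
    probabilities sum to <= 1 (background outside the head).  True perfusion
    is the tissue mixture ``gm_cbf_true * P_GM + wm_cbf_true * P_WM``.
    """
    r = _ellipsoid_radius(spec)

    def interior(boundary: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((r - boundary) / _EDGE_W))

    f_csf = interior(_R_CSF)
    f_inner = interior(_R_WM)
    f_brain = interior(_R_BRAIN)
    csf = f_csf
    wm = np.clip(f_inner - f_csf, 0.0, 1.0)
    gm = np.clip(f_brain - f_inner, 0.0, 1.0)
    tissue = TissueMaps(gm=gm, wm=wm, csf=csf, affine=spec.affine)
    for name in ("gm", "wm", "csf"):
        if not (getattr(tissue, name) > 0.5).any():
            raise ValueError(
                f"grid too small: no voxel reaches P_{name} > 0.5 "
                f"for shape {spec.grid_shape}"
            )
    cbf = spec.gm_cbf_true * gm + spec.wm_cbf_true * wm
    return tissue, cbf


def m0_map(spec: PhantomSpec, tissue: TissueMaps) -> np.ndarray:
    """Proton-density (M0) image: tissue-weighted equilibrium signal."""
    return spec.m0_scale * (
        0.85 * tissue.gm + 0.70 * tissue.wm + 1.00 * tissue.csf
    )


def make_ground_truth(spec: PhantomSpec) -> GroundTruth:
    tissue, cbf = make_tissue_phantom(spec)
    motion = (
        spec.motion_schedule
        if spec.motion_schedule is not None
        else np.zeros((spec.n_volumes, 6))
    )
    return GroundTruth(
        cbf_map=cbf,
        tissue=tissue,
        outlier_indices=frozenset(i for i, _ in spec.outlier_schedule),
        motion=motion,
    )


# ---------------------------------------------------------------------------
# Forward signal model


def simulate_subject_series(
    spec: PhantomSpec,
    truth: GroundTruth | None = None,
    params: QuantParams | None = None,
) -> AslSeries:
    """Simulate the 4D pulsed-ASL acquisition for one subject.

    Volume 0 is the M0 image; subsequent volumes alternate label/control
    (order set by ``spec.first_volume``).  The clean control-minus-label
    difference equals the exact inverse of the quantification equation
    applied to the true CBF map; noise, drift, motion, and scheduled
    corrupted volumes are layered on top.  Fully deterministic given
    ``spec.seed``.
    """
    truth = truth if truth is not None else make_ground_truth(spec)
    if truth.tissue.shape != tuple(spec.grid_shape):
        raise ValueError("ground-truth grid does not match spec grid")
    params = params or spec.quant_params()
    rng = np.random.default_rng(spec.seed)

    m0 = m0_map(spec, truth.tissue)
    dm = truth.cbf_map * scaling_volume(m0, params)  # exact inverse of quantify
    labels = spec.volume_labels()

    shape = tuple(spec.grid_shape) + (spec.n_volumes,)
    data = np.empty(shape, dtype=np.float64)
    head = m0 / spec.m0_scale  # proton-density weighting for drift
    drift_phase = rng.uniform(0, 2 * np.pi)
    outlier_kind = dict(spec.outlier_schedule)

    for t in range(spec.n_volumes):
        tag = labels[t]
        vol = m0.copy()
        if tag == LABEL:
            vol -= dm
        if t > 0 and spec.drift_amplitude > 0:
            t_sec = t * spec.tr_ms / 1000.0
            g = np.sin(2 * np.pi * t_sec / spec.drift_period_s + drift_phase)
            vol = vol + spec.drift_amplitude * g * head
        kind = outlier_kind.get(t)
        if kind == "noise":
            # labeling instability: the perfusion signal is replaced by
            # spatially decorrelated noise on top of the static tissue signal
            vol = m0 + rng.normal(0.0, spec.corruption_sd, size=m0.shape)
        elif kind == "offset":
            vol = vol + spec.corruption_offset
        if spec.noise_sd > 0 and kind != "noise":
            vol = vol + rng.normal(0.0, spec.noise_sd, size=m0.shape)
        if truth.motion is not None and not np.allclose(truth.motion[t], 0):
            vol = apply_rigid(vol, truth.motion[t], np.asarray(spec.voxel_size))
        data[..., t] = vol

    return AslSeries(
        data=data, affine=spec.affine, volume_labels=labels, tr_ms=spec.tr_ms
    )


# ---------------------------------------------------------------------------
# Phantom-space regions of interest


def phantom_roi_specs(spec: PhantomSpec):
    """Meta-ROI and control-ROI definitions in phantom mm coordinates.

    The composite meta-ROI places spheres in the phantom's GM shell at the
    positions its real-data counterpart samples: one posterior-midline
    (precuneus-like) sphere, bilateral parietal spheres, and bilateral
    temporal spheres.  The control ROI is a single occipital (visual-cortex
    analogue) sphere, spatially disjoint from the meta spheres.  Centers are
    derived from the grid geometry, never hard-coded voxel indices.
    """
    from .pvc import RoiSpec  # local import to avoid a module cycle

    shape = np.asarray(spec.grid_shape, dtype=np.float64)
    vox = np.asarray(spec.voxel_size, dtype=np.float64)
    center_mm = (shape - 1.0) / 2.0 * vox
    semi = np.array([0.76, 0.88, 0.85]) * (shape * vox) / 2.0
    rho = 0.5 * (_R_WM + _R_BRAIN)  # mid-GM shell

    def at(direction) -> tuple[float, float, float]:
        d = np.asarray(direction, dtype=np.float64)
        d = d / np.linalg.norm(d)
        return tuple(center_mm + rho * semi * d)

    r_meta = 0.13 * float(np.min(shape * vox))  # scales with field of view
    r_ctrl = 0.09 * float(np.min(shape * vox))
    meta = RoiSpec(
        name="meta",
        role="meta",
        spheres=[
            (at([0.0, -0.90, 0.44]), r_meta),  # precuneus-like
            (at([0.80, -0.30, 0.52]), r_meta),  # right parietal
            (at([-0.80, -0.30, 0.52]), r_meta),  # left parietal
            (at([0.90, -0.20, -0.39]), r_meta),  # right temporal
            (at([-0.90, -0.20, -0.39]), r_meta),  # left temporal
        ],
    )
    control = RoiSpec(
        name="control",
        role="control",
        spheres=[(at([0.0, -0.93, -0.37]), r_ctrl)],
    )
    return [meta, control]


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CdrModel:
    """Linear generative model for the dementia-severity score (CDR sum of
    boxes): baseline + group offset + coefficients on the true biomarkers
    plus Gaussian noise, clipped at 0.

    With all offsets and noise zero the score is exactly linear in
    (CBF, hippocampal volume), which pins down the sign conventions:
    lower perfusion and smaller hippocampus mean higher (worse) severity.
    """

    intercept: float = 7.65
    b_cbf: float = -0.05  # per ml/100 g/min
    b_hippo: float = -0.0015  # per mm^3 of mean hippocampal volume
    noise_sd: float = 1.0
    group_offsets: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.0, "EMCI": 1.0, "LMCI": 1.6, "AD": 3.6}
    )


@dataclass
class CohortSpec:
    """Statistical structure of the simulated cohort.

    Group sizes default to the usable-sample sizes of a four-group aging
    continuum (44/31/30/15).  Mean meta-ROI perfusion declines across the
    continuum while the control-region perfusion carries no group effect;
    hippocampal volume shows marked atrophy only at the dementia stage.
    Demographics (age, education, sex ratio) and psychometrics (MMSE,
    delayed logical-memory recall) use group means/SDs typical of such
    cohorts.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CN": 44, "EMCI": 31, "LMCI": 30, "AD": 15}
    )
    group_cbf_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 48.0, "EMCI": 46.0, "LMCI": 43.4, "AD": 39.3}
    )
    group_cbf_sds: dict[str, float] = field(
        default_factory=lambda: {g: 8.0 for g in GROUPS}
    )
    control_cbf_mean: float = 50.0
    control_cbf_sd: float = 8.0
    group_hippo_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 3500.0, "EMCI": 3640.0, "LMCI": 3396.0, "AD": 2980.0}
    )
    group_hippo_sds: dict[str, float] = field(
        default_factory=lambda: {g: 400.0 for g in GROUPS}
    )
    icv_mean: float = 1.5e6  # mm^3, split ~ GM 40% / WM 35% / CSF 25%
    icv_sd: float = 1.5e5
    age_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 73.0, "EMCI": 68.7, "LMCI": 72.3, "AD": 75.6}
    )
    age_sds: dict[str, float] = field(
        default_factory=lambda: {"CN": 7.0, "EMCI": 7.2, "LMCI": 7.4, "AD": 8.8}
    )
    education_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 16.3, "EMCI": 16.6, "LMCI": 16.6, "AD": 15.7}
    )
    education_sds: dict[str, float] = field(
        default_factory=lambda: {"CN": 2.5, "EMCI": 2.8, "LMCI": 2.9, "AD": 2.8}
    )
    female_fraction: dict[str, float] = field(
        default_factory=lambda: {"CN": 26 / 44, "EMCI": 14 / 31, "LMCI": 14 / 30, "AD": 4 / 15}
    )
    mmse_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 29.0, "EMCI": 28.6, "LMCI": 27.7, "AD": 22.4}
    )
    mmse_sds: dict[str, float] = field(
        default_factory=lambda: {"CN": 1.3, "EMCI": 1.4, "LMCI": 2.0, "AD": 1.6}
    )
    wms_lm_means: dict[str, float] = field(
        default_factory=lambda: {"CN": 13.5, "EMCI": 9.0, "LMCI": 4.2, "AD": 1.3}
    )
    wms_lm_sds: dict[str, float] = field(
        default_factory=lambda: {"CN": 3.2, "EMCI": 1.7, "LMCI": 2.8, "AD": 2.2}
    )
    cbf_measurement_sd: float = 2.0  # ml/100 g/min added to the "measured" ROI mean
    cdr_model: CdrModel = field(default_factory=CdrModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"n_per_group[{g!r}] must be >= 2")
        for d in (self.group_cbf_sds, self.group_hippo_sds, self.age_sds):
            if any(s <= 0 for s in d.values()):
                raise ValueError("all SDs must be positive")


def simulate_cohort(cspec: CohortSpec) -> pd.DataFrame:
    """Generate the per-subject cohort table.

    One row per subject: group, demographics, psychometrics, true and
    measured meta-ROI CBF, control-ROI CBF, hippocampal volumes, intracranial
    volume, the normalized hippocampal ratio, severity scores, and a QC flag
    (all-pass here; the image pipeline overwrites it where image data are
    simulated).
    """
    rng = np.random.default_rng(cspec.seed)
    rows = []
    sid = 0
    for g in GROUPS:
        n = cspec.n_per_group.get(g, 0)
        for _ in range(n):
            sid += 1
            age = rng.normal(cspec.age_means[g], cspec.age_sds[g])
            edu = rng.normal(cspec.education_means[g], cspec.education_sds[g])
            sex = "F" if rng.uniform() < cspec.female_fraction[g] else "M"
            cbf_true = rng.normal(cspec.group_cbf_means[g], cspec.group_cbf_sds[g])
            ctrl_cbf = rng.normal(cspec.control_cbf_mean, cspec.control_cbf_sd)
            hippo_mean = rng.normal(cspec.group_hippo_means[g], cspec.group_hippo_sds[g])
            asym = rng.normal(0.0, 60.0)
            left, right = hippo_mean + asym, hippo_mean - asym
            icv = max(rng.normal(cspec.icv_mean, cspec.icv_sd), 8e5)
            gm_vol, wm_vol, csf_vol = 0.40 * icv, 0.35 * icv, 0.25 * icv
            cdr = cspec.cdr_model
            cdr_sb = (
                cdr.intercept
                + cdr.group_offsets.get(g, 0.0)
                + cdr.b_cbf * cbf_true
                + cdr.b_hippo * hippo_mean
                + (rng.normal(0.0, cdr.noise_sd) if cdr.noise_sd > 0 else 0.0)
            )
            rows.append(
                {
                    "subject_id": f"sub-{sid:04d}",
                    "group": g,
                    "age": age,
                    "sex": sex,
                    "education": edu,
                    "mmse": float(np.clip(rng.normal(cspec.mmse_means[g], cspec.mmse_sds[g]), 0, 30)),
                    "cdr_sb": max(cdr_sb, 0.0) if cdr.noise_sd > 0 else cdr_sb,
                    "wms_lm_delayed": float(
                        np.clip(rng.normal(cspec.wms_lm_means[g], cspec.wms_lm_sds[g]), 0, 25)
                    ),
                    "meta_roi_cbf_true": cbf_true,
                    "meta_roi_cbf": cbf_true + rng.normal(0.0, cspec.cbf_measurement_sd),
                    "control_roi_cbf": ctrl_cbf + rng.normal(0.0, cspec.cbf_measurement_sd),
                    "hippo_left_mm3": left,
                    "hippo_right_mm3": right,
                    "gm_mm3": gm_vol,
                    "wm_mm3": wm_vol,
                    "csf_mm3": csf_vol,
                    "icv_mm3": icv,
                    "hippo_norm": ((left + right) / 2.0) / icv,
                    "qc_pass": True,
                }
            )
    df = pd.DataFrame(rows)
    df["group"] = pd.Categorical(df["group"], categories=list(GROUPS))
    return df
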