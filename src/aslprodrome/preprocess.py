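"""Denoising chain for the raw ASL series.

Fixed stage order: rigid motion correction -> isotropic Gaussian smoothing ->
zero-phase temporal high-pass filtering -> temporal nuisance regression.
Every stage preserves the grid; masks only steer estimation.

Two choices deserve a note.  First, the high-pass filter removes the
per-voxel temporal mean, which would invalidate M0-relative quantification,
so the mean is re-added after filtering.  Second, the label/control
alternation *is* the perfusion signal and lives at the Nyquist frequency —
exactly where the global/WM/CSF regressors also carry it — so nuisance
regression includes a protected +/-1 alternation covariate whose fitted
component is retained; without it, global-signal regression would delete the
perfusion effect.
"""

from __future__ import annotations

import warnings

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, signal

from .types import AslSeries, CONTROL, LABEL, NuisanceSet, TissueMaps

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Motion correction


def _to_sitk(arr: np.ndarray, voxel_size: np.ndarray) -> "sitk.Image":
    # numpy (x, y, z) -> sitk array layout (z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T, dtype=np.float64))
    img.SetSpacing(tuple(float(v) for v in voxel_size))
    return img


def _register_rigid(
    ref_img: "sitk.Image",
    vol_img: "sitk.Image",
    mask_img: "sitk.Image | None",
    init_params: tuple | None,
) -> "sitk.Euler3DTransform":
    """Rigid registration to the reference by mean-squares intensity
    difference over the mask: multi-resolution regular-step gradient
    descent, trilinear interpolation."""
    tx = sitk.Euler3DTransform()
    center = ref_img.TransformContinuousIndexToPhysicalPoint(
        [(s - 1) / 2.0 for s in ref_img.GetSize()]
    )
    tx.SetCenter(center)
    if init_params is not None:
        tx.SetParameters(init_params)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    if mask_img is not None:
        reg.SetMetricFixedMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.5,
        minStep=1e-5,
        numberOfIterations=200,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 0.5])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(tx, inPlace=True)
    reg.Execute(ref_img, vol_img)
    return tx


def motion_correct(
    series: AslSeries,
    mask: np.ndarray | None = None,
) -> tuple[AslSeries, np.ndarray]:
    """Rigidly align every volume to the M0 reference.

    Each volume's 6 rigid parameters (3 translations mm, 3 rotations deg,
    about the volume center) are estimated by minimizing the mean squared
    intensity difference to the M0 volume over the brain mask.  Every
    volume starts from the identity transform — head motion in resting ASL
    is small, and an identity start leaves genuinely still volumes with an
    exactly zero estimate instead of inheriting the previous volume's
    residual.  Returns the realigned series and the estimated motion, one
    row per volume (row 0, the reference, is zero; all-zero volumes are
    flagged with a warning and left untouched with zero parameters).
    """
    if series.n_volumes < 3:
        raise ValueError("motion correction requires at least 3 volumes")
    ref = series.m0
    if mask is None:
        mask = make_brain_mask(ref)
    vox = series.voxel_size
    ref_img = _to_sitk(ref, vox)
    mask_img = sitk.Cast(_to_sitk(mask.astype(np.uint8), vox), sitk.sitkUInt8)
    out = series.data.copy()
    motion = np.zeros((series.n_volumes, 6))

    for t in range(1, series.n_volumes):
        vol = series.data[..., t]
        if not np.any(vol):
            warnings.warn(f"volume {t} is all zero; skipping motion estimation")
            continue
        vol_img = _to_sitk(vol, vox)
        tx = _register_rigid(ref_img, vol_img, mask_img, None)
        p = tx.GetParameters()  # (angleX, angleY, angleZ, tx, ty, tz)
        motion[t] = [p[3], p[4], p[5], *np.rad2deg(p[:3])]
        # an effectively identity transform: keep the acquired values
        # instead of blurring them through interpolation
        if max(abs(v) for v in p[3:]) < 0.01 and max(abs(v) for v in p[:3]) < np.deg2rad(0.01):
            continue
        resampled = sitk.Resample(
            vol_img, ref_img, tx, sitk.sitkLinear, 0.0, sitk.sitkFloat64
        )
        out[..., t] = sitk.GetArrayFromImage(resampled).T
    return series.copy_with(out), motion


# ---------------------------------------------------------------------------
# Spatial smoothing


def smooth_volume(
    vol: np.ndarray, fwhm_mm: float, voxel_size: np.ndarray
) -> np.ndarray:
    """Isotropic Gaussian smoothing of one 3D volume.

    sigma = FWHM / (2 sqrt(2 ln 2)) in mm, converted per axis to voxel
    units.  The boundary is zero-padded (mode='constant'), so intensity is
    conserved for compactly supported signals but edge voxels of extended
    signals darken slightly.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size, dtype=np.float64)
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)


def smooth_gaussian(
    series: AslSeries, fwhm_mm: float = 4.0, include_m0: bool = False
) -> AslSeries:
    """Per-volume 3D Gaussian smoothing of the series.

    The M0 calibration volume is left unsmoothed by default so that
    quantification divides by the acquired (not blurred) calibration image.
    """
    out = series.data.copy()
    start = 0 if include_m0 else 1
    for t in range(start, series.n_volumes):
        out[..., t] = smooth_volume(series.data[..., t], fwhm_mm, series.voxel_size)
    return series.copy_with(out)


# ---------------------------------------------------------------------------
# Temporal filtering


def butterworth_sos(
    cutoff_hz: float, fs_hz: float, order: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    if cutoff_hz >= fs_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    return signal.butter(order, cutoff_hz, btype="highpass", fs=fs_hz)


def highpass_timeseries(
    arr: np.ndarray, fs_hz: float, cutoff_hz: float = 0.01, order: int = 2
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth high-pass along the last
    axis, with the pre-filter mean re-added afterwards.

    Edge transients are handled with Gustafsson's method, which (unlike
    pad-and-reflect) leaves a Nyquist-frequency alternation — the perfusion
    signal — untouched even on short series.
    """
    if arr.shape[-1] < 8:
        raise ValueError("temporal filtering requires at least 8 time points")
    b, a = butterworth_sos(cutoff_hz, fs_hz, order)
    mean = arr.mean(axis=-1, keepdims=True)
    filtered = signal.filtfilt(b, a, arr - mean, axis=-1, method="gust")
    return filtered + mean


def highpass_butterworth(
    series: AslSeries, cutoff_hz: float = 0.01, order: int = 2
) -> AslSeries:
    """Per-voxel temporal high-pass of the label/control frames (the M0
    frame is a separate calibration image and is not filtered)."""
    fs = 1000.0 / series.tr_ms
    out = series.data.copy()
    out[..., 1:] = highpass_timeseries(series.data[..., 1:], fs, cutoff_hz, order)
    return series.copy_with(out)


# ---------------------------------------------------------------------------
# Masking and nuisance extraction


def make_brain_mask(
    m0: np.ndarray, threshold_frac: float = 0.3
) -> np.ndarray:
    """Threshold mask: voxels above ``threshold_frac`` of the robust maximum
    (98th percentile), keeping only the largest connected component.

    Percentile thresholding makes the mask invariant to global intensity
    rescaling.
    """
    if np.any(m0 < 0):
        m0 = np.clip(m0, 0, None)
    robust_max = np.percentile(m0, 98)
    mask = m0 > threshold_frac * robust_max
    if not mask.any():
        raise ValueError("brain mask is empty")
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (1 + int(np.argmax(sizes)))
    return mask


def extract_nuisance_timecourses(
    series: AslSeries,
    tissue: TissueMaps,
    mask: np.ndarray,
    motion: np.ndarray | None = None,
    wm_threshold: float = 0.9,
    csf_threshold: float = 0.9,
) -> NuisanceSet:
    """Mean global / WM / CSF signal per non-M0 volume.

    The global timecourse averages over the brain mask; the WM and CSF
    timecourses average over high-probability segments (P > 0.9 by default).
    ``motion`` rows for the non-M0 volumes are carried along if provided.
    """
    if tissue.shape != series.data.shape[:3]:
        raise ValueError("tissue maps must share the series grid")
    wm_seg = tissue.wm > wm_threshold
    csf_seg = tissue.csf > csf_threshold
    for name, seg in (("mask", mask), ("wm", wm_seg), ("csf", csf_seg)):
        if not seg.any():
            raise ValueError(f"empty {name} segment after thresholding")
    frames = series.data[..., 1:]
    glob = frames[mask].mean(axis=0)
    wm_tc = frames[wm_seg].mean(axis=0)
    csf_tc = frames[csf_seg].mean(axis=0)
    if motion is None:
        motion_tc = np.zeros((len(glob), 6))
    else:
        motion_tc = np.asarray(motion, dtype=np.float64)
        if motion_tc.shape[0] == series.n_volumes:
            motion_tc = motion_tc[1:]
    return NuisanceSet(motion=motion_tc, global_signal=glob, wm=wm_tc, csf=csf_tc)


# ---------------------------------------------------------------------------
# Nuisance regression


def alternation_vector(series: AslSeries) -> np.ndarray:
    """+1 for control frames, -1 for label frames (non-M0 volumes)."""
    return np.array(
        [1.0 if tag == CONTROL else -1.0 for tag in series.volume_labels[1:]]
    )


def regress_nuisance(
    series: AslSeries,
    nuisance: NuisanceSet,
    protect_alternation: bool = True,
) -> AslSeries:
    """Voxelwise OLS removal of the nuisance regressors.

    The design holds [intercept, (protected +/-1 alternation), 9 nuisance
    regressors]; only the fitted nuisance components are subtracted, so the
    mean signal level and the perfusion alternation survive.  Each nuisance
    regressor is first orthogonalized against the protected columns — the
    global/WM/CSF timecourses themselves carry the perfusion alternation,
    and without the projection any near-collinearity would let the nuisance
    fit absorb (and delete) an arbitrary share of the perfusion signal.
    Nuisance columns that vanish after orthogonalization (exactly collinear
    or constant, e.g. zero motion traces) are dropped with a warning.
    """
    if nuisance.n_timepoints != series.n_volumes - 1:
        raise ValueError("nuisance length must equal the number of non-M0 volumes")
    t = nuisance.n_timepoints
    protected = [np.ones(t)]
    if protect_alternation:
        protected.append(alternation_vector(series))
    P = np.column_stack(protected)
    raw = nuisance.as_matrix()
    scale = np.abs(raw).max() if np.abs(raw).max() > 0 else 1.0

    # orthogonalize nuisance columns against the protected subspace
    coef, *_ = np.linalg.lstsq(P, raw, rcond=None)
    orth = raw - P @ coef
    norms = np.linalg.norm(orth, axis=0)
    kept_nuis = [j for j in range(9) if norms[j] > 1e-10 * max(scale, 1.0)]
    if len(kept_nuis) < 9:
        dropped = sorted(set(range(9)) - set(kept_nuis))
        warnings.warn(f"dropped collinear/constant nuisance regressors at columns {dropped}")
    N = orth[:, kept_nuis]

    X = np.column_stack([P, N]) if N.size else P
    frames = series.data[..., 1:]
    Y = frames.reshape(-1, t).T  # (t, nvox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted_nuisance = N @ beta[P.shape[1]:] if N.size else 0.0
    cleaned = (Y - fitted_nuisance).T.reshape(frames.shape)
    out = series.data.copy()
    out[..., 1:] = cleaned
    return series.copy_with(out)


# ---------------------------------------------------------------------------
# Full chain


def preprocess_series(
    series: AslSeries,
    tissue: TissueMaps,
    fwhm_mm: float = 4.0,
    cutoff_hz: float = 0.01,
    do_motion_correct: bool = True,
    protect_alternation: bool = True,
) -> tuple[AslSeries, np.ndarray, np.ndarray]:
    """Run the fixed denoising chain; returns (series, motion, brain mask)."""
    mask = make_brain_mask(series.m0)
    if do_motion_correct:
        series, motion = motion_correct(series, mask=mask)
    else:
        motion = np.zeros((series.n_volumes, 6))
    series = smooth_gaussian(series, fwhm_mm=fwhm_mm)
    series = highpass_butterworth(series, cutoff_hz=cutoff_hz)
    nuisance = extract_nuisance_timecourses(series, tissue, mask, motion=motion)
    series = regress_nuisance(series, nuisance, protect_alternation=protect_alternation)
    return series, motion, mask
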