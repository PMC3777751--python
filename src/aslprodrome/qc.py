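"""Quality control of the CBF time series.

Two layers, mirroring how unsuppressed pulsed-ASL data are cleaned in
practice:

* an **initial screen** flags pairs with excessive framewise displacement or
  a whole-brain mean CBF far outside the series distribution (catching
  global intensity jumps, which leave the spatial pattern — and hence any
  correlation-based statistic — untouched);
* an **adaptive correlation screen** computes, for each CBF map, the Pearson
  correlation over gray-matter voxels with the mean of the remaining kept
  maps (leave-one-out), and removes maps whose correlation falls below an
  absolute floor (default 0.15) or outside mean +/- 2 SD of the map
  correlations.  The screen iterates until no new outlier appears.

By default the +/- 2 SD band is computed over the correlations of *all*
maps of the current pass — including already-removed ones, whose near-zero
correlations keep the band wide.  This is what makes the iteration stable:
restricting the band to surviving maps re-standardizes a clean sample every
pass and trims ~5 % of good maps per iteration in a runaway cascade
(verifiable by simulation).  The all-maps band typically converges in one
removal pass.  ``band_scope='kept'`` selects the alternative reading.

The surviving maps are averaged into the final CBF image, and subject-level
flags mark inadequate brain coverage and extensive non-physiological
negative gray-matter CBF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .types import AslSeries, CbfSeries


@dataclass
class QcReport:
    """Audit record of the cleaning of one subject's CBF series."""

    initial_outliers: list[int]
    adaptive_outliers: list[list[int]]  # removed indices, per iteration
    cc_per_map: list[float]  # final-pass correlations, one per map
    n_iterations: int
    n_removed_total: int
    coverage_ok: bool | None = None
    negativity_ok: bool | None = None
    params: dict = field(default_factory=dict)

    def removed_indices(self) -> list[int]:
        out = list(self.initial_outliers)
        for it in self.adaptive_outliers:
            out.extend(it)
        return sorted(out)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# Initial screen


def framewise_displacement(motion: np.ndarray, rot_radius_mm: float = 50.0) -> np.ndarray:
    """FD per volume: sum of absolute translation increments (mm) plus
    rotation increments (rad) scaled by a 50 mm head radius."""
    motion = np.asarray(motion, dtype=np.float64)
    d = np.diff(motion, axis=0, prepend=motion[:1])
    trans = np.abs(d[:, :3]).sum(axis=1)
    rot = np.abs(np.deg2rad(d[:, 3:6])).sum(axis=1)
    return trans + rot_radius_mm * rot


def initial_outliers(
    motion: np.ndarray,
    wholebrain_cbf: np.ndarray,
    fd_threshold_mm: float = 1.5,
    k_sd: float = 2.5,
) -> list[int]:
    """Flag CBF maps by motion or whole-brain mean deviation.

    ``motion`` may be per non-M0 volume (2n x 6; pooled per pair by the
    maximum FD of its two volumes) or already per pair (n x 6).
    ``wholebrain_cbf`` is the mean CBF inside the brain mask, one value per
    map; maps outside mean +/- k_sd * SD are flagged.
    """
    wb = np.asarray(wholebrain_cbf, dtype=np.float64)
    n = wb.size
    if n < 4:
        raise ValueError("initial screening requires at least 4 CBF maps")
    motion = np.asarray(motion, dtype=np.float64)
    fd = framewise_displacement(motion)
    if motion.shape[0] == 2 * n:
        fd_pair = np.maximum(fd[0::2], fd[1::2])
    elif motion.shape[0] == n:
        fd_pair = fd
    else:
        raise ValueError("motion must have n_maps or 2*n_maps rows")
    mu, sd = wb.mean(), wb.std(ddof=1)
    flagged = set(np.flatnonzero(fd_pair > fd_threshold_mm).tolist())
    if sd > 0:
        flagged |= set(np.flatnonzero(np.abs(wb - mu) > k_sd * sd).tolist())
    return sorted(flagged)


# ---------------------------------------------------------------------------
# Adaptive correlation screen


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a - a.mean(), b - b.mean()) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def leave_one_out_cc(
    gm_values: np.ndarray, kept: np.ndarray, include_self: bool = False
) -> np.ndarray:
    """Correlation of each map's GM voxels with the mean of the kept maps.

    ``gm_values`` is (n_gm_voxels, n_maps).  For a kept map the reference
    mean excludes the map itself unless ``include_self``; removed maps are
    correlated against the mean of all kept maps.
    """
    n = gm_values.shape[1]
    kept_idx = np.flatnonzero(kept)
    nk = kept_idx.size
    total = gm_values[:, kept_idx].sum(axis=1)
    cc = np.empty(n)
    for i in range(n):
        if kept[i] and not include_self:
            if nk < 2:
                raise ValueError("leave-one-out mean needs at least 2 kept maps")
            ref = (total - gm_values[:, i]) / (nk - 1)
        else:
            ref = total / nk
        cc[i] = _safe_corr(gm_values[:, i], ref)
    return cc


def adaptive_clean(
    cbf: CbfSeries,
    gm_mask: np.ndarray,
    cc_floor: float = 0.15,
    k_sd: float = 2.0,
    band_scope: str = "all",
    include_self: bool = False,
    initial_removed: list[int] | None = None,
) -> QcReport:
    """Iterative correlation-based outlier removal; updates ``cbf.kept``.

    Per pass: leave-one-out GM correlations for every map; kept maps with
    CC below ``cc_floor`` or outside mean +/- ``k_sd`` SD of the band
    correlations become new outliers and are removed; repeat until stable.
    Maps screened out beforehand (``initial_removed``) never contribute to
    the leave-one-out means.
    """
    if band_scope not in ("all", "kept"):
        raise ValueError("band_scope must be 'all' or 'kept'")
    if not np.asarray(gm_mask, dtype=bool).any():
        raise ValueError("gray-matter mask is empty")
    kept = cbf.kept.copy()
    initial_removed = list(initial_removed or [])
    kept[initial_removed] = False
    if kept.sum() == 0:
        raise ValueError("no usable CBF time points")
    if kept.sum() < 4:
        raise ValueError("adaptive cleaning requires at least 4 kept maps")

    gm_values = cbf.maps[np.asarray(gm_mask, dtype=bool)]  # (n_gm, n_maps)
    iterations: list[list[int]] = []
    cc = np.zeros(cbf.n_maps)
    while True:
        cc = leave_one_out_cc(gm_values, kept, include_self=include_self)
        band = cc if band_scope == "all" else cc[kept]
        mu = band.mean()
        sd = band.std(ddof=1) if band.size > 1 else 0.0
        new = [
            int(i)
            for i in np.flatnonzero(kept)
            if cc[i] < cc_floor or (sd > 0 and abs(cc[i] - mu) > k_sd * sd)
        ]
        if not new:
            if not iterations:
                iterations.append([])
            break
        iterations.append(new)
        kept[new] = False
        if kept.sum() == 0:
            raise ValueError("no usable CBF time points")
        if kept.sum() < 2:
            break

    cbf.kept[:] = kept
    adaptive = [it for it in iterations if it] or []
    report = QcReport(
        initial_outliers=sorted(initial_removed),
        adaptive_outliers=adaptive,
        cc_per_map=[float(c) for c in cc],
        n_iterations=max(len(iterations), 1),
        n_removed_total=len(initial_removed) + sum(len(it) for it in adaptive),
        params={
            "cc_floor": cc_floor,
            "k_sd": k_sd,
            "band_scope": band_scope,
            "include_self": include_self,
        },
    )
    return report


def finalize_cbf(cbf: CbfSeries) -> np.ndarray:
    """Voxelwise mean over the kept maps — the subject's final CBF image."""
    if cbf.kept.sum() == 0:
        raise ValueError("no kept CBF maps to average")
    return cbf.maps[..., cbf.kept].mean(axis=3)


# ---------------------------------------------------------------------------
# Subject-level QC


def subject_qc(
    series: AslSeries,
    final_map: np.ndarray,
    gm_mask: np.ndarray,
    brain_mask: np.ndarray,
    coverage_frac: float = 0.9,
    negativity_frac: float = 0.1,
    signal_floor_frac: float = 0.05,
) -> tuple[bool, bool]:
    """Subject-level pass/fail flags.

    ``coverage_ok``: at least ``coverage_frac`` of brain-mask voxels carry
    signal (above ``signal_floor_frac`` of the volume's robust maximum) in
    every volume — acquisitions that miss part of the brain fail; the floor
    keeps smoothing spill-over into truly unacquired slices from counting
    as coverage.  ``negativity_ok``: at most ``negativity_frac`` of
    gray-matter voxels have negative final CBF (extensive non-physiological
    negative values indicate labeling or hardware instability).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    absdata = np.abs(series.data)
    floors = signal_floor_frac * np.percentile(
        absdata.reshape(-1, series.n_volumes), 98, axis=0
    )
    always_nonzero = (absdata > floors).all(axis=3)
    coverage = always_nonzero[brain_mask].mean() if brain_mask.any() else 0.0
    coverage_ok = bool(coverage >= coverage_frac)
    if gm_mask.any():
        neg_frac = (final_map[gm_mask] < 0).mean()
    else:
        neg_frac = 1.0
    negativity_ok = bool(neg_frac <= negativity_frac)
    return coverage_ok, negativity_ok


def run_qc(
    cbf: CbfSeries,
    gm_mask: np.ndarray,
    brain_mask: np.ndarray,
    motion: np.ndarray | None = None,
    series: AslSeries | None = None,
    fd_threshold_mm: float = 1.5,
    initial_k_sd: float = 2.5,
    cc_floor: float = 0.15,
    k_sd: float = 2.0,
    band_scope: str = "all",
    coverage_mask: np.ndarray | None = None,
) -> tuple[QcReport, np.ndarray]:
    """Full QC chain: initial screen, adaptive cleaning, final averaging,
    and (if the raw series is supplied) subject-level flags.

    ``coverage_mask`` is the reference extent the acquisition should cover
    (e.g. the anatomical brain from the tissue maps); it defaults to the
    signal-derived ``brain_mask``, but note that a mask derived from a
    truncated acquisition cannot reveal the truncation.
    Returns the report and the final mean CBF map.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    wb = cbf.maps[brain_mask].mean(axis=0)
    if motion is None:
        motion_tc = np.zeros((cbf.n_maps, 6))
    else:
        motion_tc = np.asarray(motion, dtype=np.float64)
        if motion_tc.shape[0] == cbf.n_maps * 2 + 1:
            motion_tc = motion_tc[1:]  # drop the M0 row
    init = initial_outliers(motion_tc, wb, fd_threshold_mm=fd_threshold_mm, k_sd=initial_k_sd)
    report = adaptive_clean(
        cbf, gm_mask, cc_floor=cc_floor, k_sd=k_sd, band_scope=band_scope,
        initial_removed=init,
    )
    final_map = finalize_cbf(cbf)
    if series is not None:
        report.coverage_ok, report.negativity_ok = subject_qc(
            series,
            final_map,
            gm_mask,
            brain_mask if coverage_mask is None else coverage_mask,
        )
    return report, final_map
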