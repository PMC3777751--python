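"""Pairwise subtraction and one-compartment pulsed-ASL CBF quantification.

The acquisition is a PICORE/Q2TIPS pulsed sequence: a saturation scheme caps
the labeled bolus at duration TI1, and imaging starts at inversion time TI2.
Under the one-compartment (general kinetic, well-mixed) model the
control-minus-label difference signal relates to perfusion as

    CBF = 6000 * lambda * dM
          / (2 * alpha * M0 * (TI1/1000) * exp(-TI2_slice / T1_blood))

in ml/100 g/min, where ``lambda`` is the blood-brain water partition
coefficient (ml/g), ``alpha`` the labeling efficiency, and TI2_slice the
effective inversion time of each slice (TI2 plus the per-slice acquisition
increment for the sequential 2D readout).  The factor 6000 converts
ml/g/s to ml/100 g/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AslSeries, CbfSeries, CONTROL, LABEL


@dataclass(frozen=True)
class QuantParams:
    """Constants of the one-compartment quantification.

    Defaults follow common 3T practice: T1 of arterial blood 1664 ms,
    labeling efficiency 0.95 for pulsed labeling, partition coefficient
    0.9 ml/g, and a 45 ms per-slice acquisition increment for the sequential
    ascending EPI readout.  All are overridable; nothing downstream assumes
    the defaults.
    """

    ti1_ms: float = 700.0
    ti2_ms: float = 1900.0
    t1_blood_ms: float = 1664.0
    labeling_efficiency: float = 0.95
    partition_coefficient: float = 0.9
    slice_time_ms: float = 45.0

    def __post_init__(self) -> None:
        for name in ("ti1_ms", "ti2_ms", "t1_blood_ms", "partition_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must lie in (0, 1]")
        if self.slice_time_ms < 0:
            raise ValueError("slice_time_ms must be nonnegative")
        if self.ti2_ms <= self.ti1_ms:
            raise ValueError("ti2_ms must exceed ti1_ms")


def scaling_volume(
    m0: np.ndarray, params: QuantParams, slice_axis: int = 2
) -> np.ndarray:
    """Per-voxel factor mapping CBF (ml/100 g/min) to difference signal dM.

    dM = CBF * scaling_volume(...)  — the exact inverse used both by the
    quantifier and by the digital-phantom forward model, so the two stay
    consistent under any parameter set.
    """
    n_slices = m0.shape[slice_axis]
    slice_idx = np.arange(n_slices, dtype=np.float64)
    shape = [1, 1, 1]
    shape[slice_axis] = n_slices
    ti2_slice = params.ti2_ms + slice_idx.reshape(shape) * params.slice_time_ms
    decay = np.exp(-ti2_slice / params.t1_blood_ms)
    return (
        2.0
        * params.labeling_efficiency
        * m0
        * (params.ti1_ms / 1000.0)
        * decay
        / (6000.0 * params.partition_coefficient)
    )


def pairwise_subtract(series: AslSeries) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Adjacent control-minus-label subtraction.

    Returns one dM map per (label, control) pair, as a 4D stack, plus the
    source volume indices of each pair.  Simple pairwise subtraction only —
    no surround or sinc-interpolated schemes.
    """
    n_tagged = series.n_volumes - 1
    if n_tagged % 2 != 0:
        raise ValueError(
            f"series has {n_tagged} label/control volumes; an even count is required"
        )
    pairs = series.pair_indices
    dm = np.empty(series.data.shape[:3] + (len(pairs),), dtype=np.float64)
    for k, (lab, ctl) in enumerate(pairs):
        dm[..., k] = series.data[..., ctl] - series.data[..., lab]
    return dm, pairs


def quantify_cbf(
    dm: np.ndarray,
    m0: np.ndarray,
    params: QuantParams,
    affine: np.ndarray | None = None,
    pair_index: list[tuple[int, int]] | None = None,
    slice_axis: int = 2,
    m0_floor_frac: float = 0.1,
) -> CbfSeries:
    """Convert a dM stack to CBF maps (ml/100 g/min).

    Voxels whose M0 falls below ``m0_floor_frac`` of the robust maximum
    (98th percentile) carry no usable calibration signal; they are set to 0
    and flagged in ``m0_valid``.  Negative CBF values elsewhere are retained
    — screening them is the quality-control stage's job.
    """
    dm = np.asarray(dm, dtype=np.float64)
    m0 = np.asarray(m0, dtype=np.float64)
    if dm.shape[:3] != m0.shape:
        raise ValueError("dM stack and M0 volume must share a grid")
    scale = scaling_volume(m0, params, slice_axis=slice_axis)
    robust_max = np.percentile(m0, 98)
    valid = m0 > m0_floor_frac * robust_max
    maps = np.where(valid[..., None], dm / np.where(valid, scale, 1.0)[..., None], 0.0)
    n = dm.shape[3]
    if pair_index is None:
        pair_index = [(1 + 2 * k, 2 + 2 * k) for k in range(n)]
    if affine is None:
        affine = np.eye(4)
    return CbfSeries(
        maps=maps,
        pair_index=list(pair_index),
        kept=np.ones(n, dtype=bool),
        affine=affine,
        m0_valid=valid,
    )


def quantify_series(
    series: AslSeries,
    params: QuantParams | None = None,
    m0_floor_frac: float = 0.1,
) -> CbfSeries:
    """Convenience chain: pairwise subtraction then quantification, taking
    the M0 calibration image directly from volume 0 (unsmoothed)."""
    params = params or QuantParams()
    dm, pairs = pairwise_subtract(series)
    return quantify_cbf(
        dm,
        series.m0,
        params,
        affine=series.affine,
        pair_index=pairs,
        m0_floor_frac=m0_floor_frac,
    )
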