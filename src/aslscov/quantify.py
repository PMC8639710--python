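"""CBF quantification from single-PLD pCASL difference data.

Implements the single-compartment quantification recipe: average the
control-label difference repeats, calibrate the M0 image into an
arterial-blood magnetisation map (T1 saturation correction and division by
the blood-brain partition coefficient), and invert the fully-delivered
branch of the kinetic model voxel-wise.  Partial-volume correction uses the
classic local linear-regression method: within a small kernel around each
voxel, measured CBF is regressed on the grey- and white-matter partial
volume fractions to recover pure-tissue perfusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetic import AcquisitionParams

__all__ = [
    "CBFMap",
    "average_repeats",
    "calibrate_m0",
    "quantify_cbf",
    "pvc_regress",
]


@dataclass
class CBFMap:
    """A calibrated perfusion map in ml/100g/min with its validity mask."""

    values: np.ndarray
    mask: np.ndarray
    pvc_flag: bool

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share one grid")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("CBF values must be finite on the valid mask")


def average_repeats(diff_volumes: np.ndarray) -> np.ndarray:
    """Voxel-wise arithmetic mean over the repeat axis (axis 0)."""
    diff_volumes = np.asarray(diff_volumes, dtype=float)
    if diff_volumes.ndim != 4 or diff_volumes.shape[0] < 1:
        raise ValueError("expected a non-empty (repeats, x, y, z) array")
    return diff_volumes.mean(axis=0)


def calibrate_m0(m0_volume: np.ndarray, params: AcquisitionParams) -> np.ndarray:
    """Arterial-blood magnetisation from the M0 scan.

    ``m0b = m0 / (1 - exp(-tr_m0 / t1_tissue)) / lambda_bbp`` — an
    incomplete-saturation correction for the finite TR of the calibration
    scan followed by the partition-coefficient scaling from tissue to blood
    signal.
    """
    if params.tr_m0 <= 0 or params.t1_tissue <= 0:
        raise ValueError("tr_m0 and t1_tissue must be positive")
    sat = 1.0 - np.exp(-params.tr_m0 / params.t1_tissue)
    return np.asarray(m0_volume, dtype=float) / sat / params.lambda_bbp


def quantify_cbf(
    mean_diff: np.ndarray,
    m0b_map: np.ndarray,
    params: AcquisitionParams,
    mask_threshold: float = 0.05,
) -> CBFMap:
    """Single-compartment CBF quantification of the mean difference image.

    Inverts the fully-delivered (att <= pld) branch of the kinetic model::

        f = 6000 * dM * exp(pld/T1b) / (2 alpha T1b m0b (1 - exp(-tau/T1b)))

    Voxels whose m0b falls below ``mask_threshold`` times the robust (99th
    percentile) maximum are excluded from the validity mask to avoid
    division blow-ups outside the head.
    """
    mean_diff = np.asarray(mean_diff, dtype=float)
    m0b = np.asarray(m0b_map, dtype=float)
    if mean_diff.shape != m0b.shape:
        raise ValueError("difference and m0b maps must share one grid")
    robust_max = np.percentile(m0b, 99)
    if robust_max <= 0:
        raise ValueError("m0b map is non-positive everywhere")
    mask = m0b > mask_threshold * robust_max

    denom = (
        2.0
        * params.alpha
        * params.t1_blood
        * m0b
        * (1.0 - np.exp(-params.tau / params.t1_blood))
    )
    values = np.zeros_like(mean_diff)
    np.divide(
        6000.0 * mean_diff * np.exp(params.pld / params.t1_blood),
        denom,
        out=values,
        where=mask,
    )
    return CBFMap(values=values, mask=mask, pvc_flag=False)


def _kernel_offsets(radius_inplane: int, radius_throughplane: int):
    r, rz = radius_inplane, radius_throughplane
    return [
        (dx, dy, dz)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        for dz in range(-rz, rz + 1)
    ]


def pvc_regress(
    cbf_map: CBFMap,
    pv_gm: np.ndarray,
    pv_wm: np.ndarray,
    radius_inplane: int = 2,
    radius_throughplane: int = 1,
    min_pv: float = 0.01,
    cond_limit: float = 1e6,
) -> tuple[CBFMap, CBFMap]:
    """Local linear-regression partial-volume correction.

    For each voxel, solve the least-squares system ``cbf ~ pv_gm * f_gm +
    pv_wm * f_wm`` over the kernel neighbourhood (within-mask voxels whose
    total tissue fraction exceeds ``min_pv``), yielding pure grey- and
    white-matter perfusion maps.  Voxels whose local design is rank
    deficient (fewer than two usable neighbours, or collinear pv columns as
    judged by the condition number) are masked out rather than extrapolated.
    The input map must be an uncorrected (non-PVC) map and is not modified.
    """
    if cbf_map.pvc_flag:
        raise ValueError("pvc_regress expects a non-PVC input map")
    grid = cbf_map.values.shape
    if pv_gm.shape != grid or pv_wm.shape != grid:
        raise ValueError("pv maps must be on the CBF grid")
    if radius_inplane < 1 and radius_throughplane < 1:
        raise ValueError("kernel must extend at least one voxel")
    if (2 * radius_inplane + 1) > min(grid[:2]) or (2 * radius_throughplane + 1) > grid[2]:
        raise ValueError("kernel larger than grid")

    offsets = _kernel_offsets(radius_inplane, radius_throughplane)
    usable = cbf_map.mask & ((pv_gm + pv_wm) > min_pv)

    # accumulate the 2x2 normal equations with shifted-array sums
    s_gg = np.zeros(grid)
    s_gw = np.zeros(grid)
    s_ww = np.zeros(grid)
    s_gy = np.zeros(grid)
    s_wy = np.zeros(grid)
    count = np.zeros(grid)
    g = np.where(usable, pv_gm, 0.0)
    w = np.where(usable, pv_wm, 0.0)
    y = np.where(usable, cbf_map.values, 0.0)

    def shifted(a, off):
        out = np.zeros_like(a)
        src = [slice(max(-o, 0), a.shape[i] - max(o, 0)) for i, o in enumerate(off)]
        dst = [slice(max(o, 0), a.shape[i] - max(-o, 0)) for i, o in enumerate(off)]
        out[tuple(dst)] = a[tuple(src)]
        return out

    for off in offsets:
        gs, ws, ys = shifted(g, off), shifted(w, off), shifted(y, off)
        s_gg += gs * gs
        s_gw += gs * ws
        s_ww += ws * ws
        s_gy += gs * ys
        s_wy += ws * ys
        count += shifted(usable.astype(float), off)

    det = s_gg * s_ww - s_gw**2
    trace = s_gg + s_ww
    # smallest eigenvalue of the 2x2 Gram matrix; rank-2 check via condition
    disc = np.sqrt(np.maximum(trace**2 - 4 * det, 0.0))
    lam_min = (trace - disc) / 2.0
    lam_max = (trace + disc) / 2.0
    full_rank = (count >= 2) & (lam_min > 0) & (lam_max < cond_limit * lam_min)

    f_gm = np.zeros(grid)
    f_wm = np.zeros(grid)
    np.divide(s_ww * s_gy - s_gw * s_wy, det, out=f_gm, where=full_rank)
    np.divide(s_gg * s_wy - s_gw * s_gy, det, out=f_wm, where=full_rank)

    out_mask = usable & full_rank
    return (
        CBFMap(values=f_gm, mask=out_mask, pvc_flag=True),
        CBFMap(values=f_wm, mask=out_mask, pvc_flag=True),
    )
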