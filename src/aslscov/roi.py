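"""ROI masks and per-subject perfusion metrics.

The headline metric is the spatial coefficient of variation (sCoV) of an
uncorrected CBF map within a region of interest::

    sCoV = sd(CBF in ROI) / mean(CBF in ROI) * 100 %

which acts as a surrogate for arterial transit time: when the
post-labelling delay is shorter than the transit time, label lingers in
proximal vessels (bright) while distal tissue is under-supplied (dark),
inflating the spatial spread of the map.  sCoV is always computed from the
*non*-PVC map, because partial-volume correction smooths away exactly the
heterogeneity of interest; mean CBF is reported from both map types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import ROI_CODES, collapse_group
from .quantify import CBFMap

__all__ = [
    "ROISet",
    "SubjectRecord",
    "binarise_mask",
    "spatial_cov",
    "roi_mean",
    "roi_set_from_labels",
    "extract_subject_metrics",
    "records_to_frame",
]

#: order in which ROI metrics are reported
ROI_NAMES = (
    "gm",
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "pcc",
    "precuneus",
    "hippocampus",
    "angular",
)


@dataclass
class ROISet:
    """Named boolean masks on one grid: total GM, four lobes, four parcels."""

    masks: dict

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one grid")
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI {name!r} is empty")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self):
        return tuple(self.masks)


@dataclass
class SubjectRecord:
    """One subject's covariates and derived per-ROI perfusion metrics."""

    id: str
    group: str  # five-level severity label
    age: float
    sex: str
    site: str
    scov: dict = field(default_factory=dict)  # ROI -> percent
    mean_cbf: dict = field(default_factory=dict)  # ROI -> ml/100g/min (non-PVC)
    mean_cbf_pvc: dict = field(default_factory=dict)  # ROI -> ml/100g/min (PVC GM)

    @property
    def group_collapsed(self) -> str:
        return collapse_group(self.group)


def binarise_mask(pv_map: np.ndarray, threshold: float = 0.25) -> np.ndarray:
    """Binarise a partial-volume map at a fractional threshold (inclusive).

    The boundary convention is ``pv >= threshold``: a voxel exactly at the
    threshold is included.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    pv_map = np.asarray(pv_map, dtype=float)
    if np.any(pv_map < 0) or np.any(pv_map > 1):
        raise ValueError("partial-volume values must lie in [0, 1]")
    return pv_map >= threshold


def spatial_cov(values: np.ndarray, mask: np.ndarray) -> float:
    """Spatial coefficient of variation over a mask, in percent.

    Sample (n-1) standard deviation divided by the mean, times 100.
    Raises if the mask holds fewer than two voxels or the mean is zero.
    """
    vals = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size < 2:
        raise ValueError("sCoV needs at least two voxels in the ROI")
    mu = vals.mean()
    if mu == 0:
        raise ValueError("sCoV undefined for zero-mean ROI")
    return float(vals.std(ddof=1) / mu * 100.0)


def roi_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of a map over a non-empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(np.asarray(values, dtype=float)[mask].mean())


def roi_set_from_labels(
    roi_labels: np.ndarray,
    pv_gm: np.ndarray,
    gm_threshold: float = 0.25,
    lobe_gm_only: bool = True,
) -> ROISet:
    """Build the standard ROI set from a phantom label map.

    Total GM is the binarised (>= ``gm_threshold``) grey-matter fraction.
    Lobe masks include the small parcels they contain (PCC, precuneus and
    angular gyrus count as parietal; hippocampus as temporal) and are, by
    default, intersected with the GM mask.
    """
    gm = binarise_mask(pv_gm, gm_threshold)
    c = ROI_CODES
    lobes = {
        "frontal": np.isin(roi_labels, [c["frontal"]]),
        "parietal": np.isin(
            roi_labels, [c["parietal"], c["pcc"], c["precuneus"], c["angular"]]
        ),
        "temporal": np.isin(roi_labels, [c["temporal"], c["hippocampus"]]),
        "occipital": np.isin(roi_labels, [c["occipital"]]),
    }
    parcels = {
        name: roi_labels == c[name]
        for name in ("pcc", "precuneus", "hippocampus", "angular")
    }
    masks = {"gm": gm}
    for name, m in {**lobes, **parcels}.items():
        masks[name] = (m & gm) if lobe_gm_only else m
    return ROISet(masks=masks)


def extract_subject_metrics(
    cbf_nonpvc: CBFMap,
    cbf_pvc_gm: CBFMap | None,
    roiset: ROISet,
    meta: dict,
) -> SubjectRecord:
    """Fill a SubjectRecord with per-ROI sCoV and mean CBF.

    sCoV comes exclusively from the non-PVC map (enforced through
    ``pvc_flag``); mean CBF is reported from both the non-PVC and, when
    provided, the PVC grey-matter map.  ROI masks are intersected with each
    map's validity mask.
    """
    if cbf_nonpvc.pvc_flag:
        raise ValueError("sCoV must be computed from a non-PVC map")
    if cbf_pvc_gm is not None and not cbf_pvc_gm.pvc_flag:
        raise ValueError("cbf_pvc_gm must be a PVC map")
    grid = cbf_nonpvc.values.shape
    if any(roiset[name].shape != grid for name in roiset.names()):
        raise ValueError("ROI masks and CBF map must share one grid")
    if cbf_pvc_gm is not None and cbf_pvc_gm.values.shape != grid:
        raise ValueError("PVC map and non-PVC map must share one grid")

    rec = SubjectRecord(
        id=str(meta["id"]),
        group=str(meta["group"]),
        age=float(meta["age"]),
        sex=str(meta["sex"]),
        site=str(meta["site"]),
    )
    for name in roiset.names():
        m = roiset[name] & cbf_nonpvc.mask
        if not m.any():
            raise ValueError(f"ROI {name!r} empty after masking")
        rec.scov[name] = spatial_cov(cbf_nonpvc.values, m)
        rec.mean_cbf[name] = roi_mean(cbf_nonpvc.values, m)
        if cbf_pvc_gm is not None:
            mp = roiset[name] & cbf_pvc_gm.mask
            if mp.any():
                rec.mean_cbf_pvc[name] = roi_mean(cbf_pvc_gm.values, mp)
            else:
                rec.mean_cbf_pvc[name] = float("nan")
    return rec


def records_to_frame(records) -> pd.DataFrame:
    """Flatten SubjectRecords into a tidy table (one row per subject)."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "group": r.group,
            "group4": r.group_collapsed,
            "age": r.age,
            "sex": r.sex,
            "site": r.site,
        }
        for name, v in r.scov.items():
            row[f"scov_{name}"] = v
        for name, v in r.mean_cbf.items():
            row[f"cbf_{name}"] = v
        for name, v in r.mean_cbf_pvc.items():
            row[f"cbf_pvc_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
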