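"""Digital brain phantoms and synthetic cognitive-decline cohorts.

The phantom is a stylised three-shell "brain" (CSF rim, grey-matter ribbon,
white-matter core) on a small 3-D grid.  Anatomical realism is not the goal:
the generator exists to give the downstream pipeline data with the
*statistical* structure a multi-site cognitive-decline perfusion study
assumes — group-dependent arterial-transit-time (ATT) prolongation, regional
grey-matter hypoperfusion, age/sex/site covariate effects and a posterior
vascular territory in which transit delays bite first.

Groups follow the five-level severity coding ``control < scd < amci < mmci
< ad`` (subjective cognitive decline; amnestic single-domain and
multi-domain mild cognitive impairment; probable Alzheimer's dementia),
with a helper to collapse the two MCI subtypes into a single ``mci`` level
for four-group analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUP_LEVELS",
    "GROUP_LEVELS_COLLAPSED",
    "ROI_CODES",
    "Phantom",
    "CohortConfig",
    "collapse_group",
    "sample_covariates",
    "build_phantom",
    "simulate_cohort",
    "simulate_metric_records",
]

GROUP_LEVELS = ("control", "scd", "amci", "mmci", "ad")
GROUP_LEVELS_COLLAPSED = ("control", "scd", "mci", "ad")

#: integer codes of the ROI label map; small parcels override lobe codes
ROI_CODES = {
    "frontal": 1,
    "parietal": 2,
    "temporal": 3,
    "occipital": 4,
    "pcc": 5,
    "precuneus": 6,
    "hippocampus": 7,
    "angular": 8,
}

#: ROI names that carry group CBF effects (small AD-sensitive parcels)
PARCEL_NAMES = ("pcc", "precuneus", "hippocampus", "angular")


def collapse_group(group: str) -> str:
    """Collapse the two MCI subtypes into a single ``mci`` level."""
    if group not in GROUP_LEVELS:
        raise ValueError(f"unknown group level {group!r}")
    return "mci" if group in ("amci", "mmci") else group


@dataclass
class Phantom:
    """Per-subject ground truth: tissue fractions, perfusion and transit times.

    All maps share one grid.  ``cbf_gm``/``cbf_wm`` are the pure-tissue
    perfusion values (ml/100g/min); ``cbf_true`` is the partial-volume
    weighted voxel CBF ``pv_gm*cbf_gm + pv_wm*cbf_wm`` that a non-PVC
    quantification should recover.  ``att_true`` is the tissue arterial
    transit time in seconds; ``att_arterial`` the (earlier) arrival time in
    the macrovascular compartment; ``abv`` the arterial blood-volume
    fraction.
    """

    pv_gm: np.ndarray
    pv_wm: np.ndarray
    pv_csf: np.ndarray
    cbf_gm: np.ndarray
    cbf_wm: np.ndarray
    cbf_true: np.ndarray
    att_true: np.ndarray
    arterial_mask: np.ndarray
    abv: np.ndarray
    att_arterial: np.ndarray
    m0_tissue: np.ndarray
    roi_labels: np.ndarray
    voxel_size_mm: tuple = (3.0, 3.0, 4.0)
    subject_id: str = "sub-000"

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    @property
    def tissue_mask(self) -> np.ndarray:
        return (self.pv_gm + self.pv_wm) > 0

    def validate(self) -> None:
        eps = 1e-9
        for name in ("pv_gm", "pv_wm", "pv_csf"):
            pv = getattr(self, name)
            if np.any(pv < -eps) or np.any(pv > 1 + eps):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(self.pv_gm + self.pv_wm + self.pv_csf > 1 + 1e-6):
            raise ValueError("partial volumes exceed 1")
        if np.any(self.cbf_true < 0):
            raise ValueError("cbf_true must be non-negative")
        if np.any(self.att_true[self.tissue_mask] <= 0):
            raise ValueError("att_true must be positive on tissue")
        if np.any((self.abv < 0) | (self.abv > 1)):
            raise ValueError("abv outside [0, 1]")


def _default_group_sizes() -> dict:
    # 122-participant cohort: 20 controls, 44 SCD, 45 MCI (split between
    # subtypes is a configurable choice), 13 AD.
    return {"control": 20, "scd": 44, "amci": 23, "mmci": 22, "ad": 13}


def _default_att_offsets() -> dict:
    return {"control": 0.0, "scd": 0.10, "amci": 0.25, "mmci": 0.35, "ad": 0.50}


def _default_cbf_effects() -> dict:
    # regional hypoperfusion (ml/100g/min) in AD-sensitive parcels
    return {
        "control": {},
        "scd": {r: -2.0 for r in PARCEL_NAMES},
        "amci": {r: -5.0 for r in PARCEL_NAMES},
        "mmci": {r: -7.0 for r in PARCEL_NAMES},
        "ad": {r: -10.0 for r in PARCEL_NAMES},
    }


def _default_age_dist() -> dict:
    return {
        "control": (67.4, 8.3),
        "scd": (69.0, 7.7),
        "amci": (71.1, 7.1),
        "mmci": (71.1, 7.1),
        "ad": (74.9, 6.2),
    }


def _default_sex_p_female() -> dict:
    return {"control": 0.80, "scd": 0.59, "amci": 0.51, "mmci": 0.51, "ad": 0.23}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate a 122-participant, three-site cognitive-decline cohort:
    group sizes 20/44/45(=23+22)/13, per-group age means rising from 67.4 to
    74.9 years, a strongly female control group, and site sampling
    proportions 91:16:15.  ATT effects are additive in seconds; CBF effects
    additive in ml/100g/min.
    """

    group_sizes: dict = field(default_factory=_default_group_sizes)
    att_base: float = 1.2
    att_group_offsets: dict = field(default_factory=_default_att_offsets)
    att_posterior: float = 0.2
    att_age_slope: float = 0.005  # s per year
    age_ref: float = 70.0
    cbf_gm_base: float = 60.0
    cbf_wm_base: float = 20.0
    cbf_group_effects: dict = field(default_factory=_default_cbf_effects)
    age_dist: dict = field(default_factory=_default_age_dist)
    sex_p_female: dict = field(default_factory=_default_sex_p_female)
    site_names: tuple = ("site_a", "site_b", "site_c")
    site_probs: tuple = (91 / 122, 16 / 122, 15 / 122)
    site_att_offsets: dict = field(
        default_factory=lambda: {"site_a": 0.0, "site_b": 0.05, "site_c": -0.05}
    )
    site_cbf_offsets: dict = field(
        default_factory=lambda: {"site_a": 0.0, "site_b": -3.0, "site_c": 3.0}
    )
    grid: tuple = (32, 32, 24)
    voxel_size_mm: tuple = (3.0, 3.0, 4.0)
    m0_scale: float = 1000.0
    csf_m0_factor: float = 1.3
    abv_vessel: float = 0.5
    abv_background: float = 0.0
    noise_sd: float = 1.0
    seed: int = 1234

    def validate(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        for g in self.group_sizes:
            if g not in GROUP_LEVELS:
                raise ValueError(f"unknown group level {g!r}")
        p = np.asarray(self.site_probs, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("site probabilities must be in [0,1] and sum to 1")
        if len(self.site_probs) != len(self.site_names):
            raise ValueError("site_probs and site_names lengths differ")
        if min(self.grid) < 16:
            raise ValueError("grid must be at least 16 voxels per axis")
        for g, p_f in self.sex_p_female.items():
            if not (0.0 <= p_f <= 1.0):
                raise ValueError(f"sex proportion for {g!r} outside [0,1]")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _normalised_coords(grid, voxel_size_mm):
    """Voxel-centre coordinates scaled so the brain ellipsoid has radius 1."""
    axes = []
    for n, dv in zip(grid, voxel_size_mm):
        c = (np.arange(n) - (n - 1) / 2.0) * dv
        semi = 0.95 * (n * dv) / 2.0
        axes.append(c / semi)
    return np.meshgrid(*axes, indexing="ij")


def _shell_fractions(rho, ramp):
    """Partition-of-unity tissue fractions along the radial profile."""

    def inside(c):
        return np.clip((c + ramp / 2.0 - rho) / ramp, 0.0, 1.0)

    in_wm = inside(0.72)
    in_gm = inside(0.92)
    in_brain = inside(1.0)
    return in_gm - in_wm, in_wm, in_brain - in_gm  # gm, wm, csf


def _label_rois(xh, yh, zh, pv_gm):
    """Integer ROI label map; small parcels override lobe codes."""
    labels = np.zeros(pv_gm.shape, dtype=np.int16)
    gm = pv_gm > 0.01
    frontal = gm & (yh >= 0.2)
    occipital = gm & (yh <= -0.45)
    mid = gm & ~frontal & ~occipital
    parietal = mid & (zh >= 0.0)
    temporal = mid & (zh < 0.0)
    labels[frontal] = ROI_CODES["frontal"]
    labels[parietal] = ROI_CODES["parietal"]
    labels[temporal] = ROI_CODES["temporal"]
    labels[occipital] = ROI_CODES["occipital"]

    ax = np.abs(xh)
    pcc = gm & (ax <= 0.35) & (yh >= -0.75) & (yh <= -0.3) & (zh >= 0.1) & (zh <= 0.55)
    prec = gm & (ax <= 0.35) & (yh >= -0.8) & (yh <= -0.3) & (zh > 0.55) & (zh <= 1.0)
    hipp = gm & (ax >= 0.25) & (ax <= 0.85) & (yh >= -0.3) & (yh <= 0.15) & (zh >= -0.95) & (zh <= -0.4)
    ang = gm & (ax >= 0.4) & (ax <= 1.0) & (yh >= -0.65) & (yh <= -0.2) & (zh >= 0.1) & (zh <= 0.65)
    labels[pcc] = ROI_CODES["pcc"]
    labels[prec] = ROI_CODES["precuneus"]
    labels[hipp] = ROI_CODES["hippocampus"]
    labels[ang] = ROI_CODES["angular"]
    return labels


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def sample_covariates(group: str, config: CohortConfig, rng: np.random.Generator):
    """Draw (age, sex, site) for one subject from the configured distributions."""
    if group not in config.age_dist or group not in config.sex_p_female:
        raise KeyError(f"group {group!r} missing from covariate configuration")
    mean, sd = config.age_dist[group]
    age = float(rng.normal(mean, sd))
    sex = "f" if rng.random() < config.sex_p_female[group] else "m"
    site = str(rng.choice(config.site_names, p=np.asarray(config.site_probs)))
    return age, sex, site


def build_phantom(
    config: CohortConfig,
    group: str,
    covariates,
    seed: int,
    subject_id: str = "sub-000",
) -> Phantom:
    """Build one subject's ground-truth phantom.

    The mean tissue ATT is ``att_base + group offset + site offset +
    att_age_slope*(age - age_ref)``, with the posterior territory
    (posterior third of the brain) receiving an extra ``att_posterior``
    seconds.  Regional CBF effects configured for the subject's group are
    added to the pure grey-matter perfusion inside the named parcels.
    Deterministic given ``seed``.
    """
    config.validate()
    if group not in GROUP_LEVELS:
        raise ValueError(f"unknown group level {group!r}")
    if min(config.grid) < 16:
        raise ValueError("grid must be at least 16 voxels per axis")
    age, sex, site = covariates

    xh, yh, zh = _normalised_coords(config.grid, config.voxel_size_mm)
    rho = np.sqrt(xh**2 + yh**2 + zh**2)
    ramp = float(np.mean([dv / (0.95 * n * dv / 2.0)
                          for n, dv in zip(config.grid, config.voxel_size_mm)]))
    pv_gm, pv_wm, pv_csf = _shell_fractions(rho, ramp)
    labels = _label_rois(xh, yh, zh, pv_gm)
    tissue = (pv_gm + pv_wm) > 0

    att = np.full(config.grid, config.att_base, dtype=float)
    att += config.att_group_offsets.get(group, 0.0)
    att += config.site_att_offsets.get(site, 0.0)
    att += config.att_age_slope * (age - config.age_ref)
    att[yh <= -0.2] += config.att_posterior
    att = np.clip(att, 0.05, None)

    cbf_gm = np.full(config.grid, config.cbf_gm_base, dtype=float)
    cbf_gm += config.site_cbf_offsets.get(site, 0.0)
    for roi, delta in config.cbf_group_effects.get(group, {}).items():
        cbf_gm[labels == ROI_CODES[roi]] += delta
    cbf_gm = np.clip(cbf_gm, 0.0, None)
    cbf_wm = np.full(config.grid, config.cbf_wm_base, dtype=float)
    cbf_true = pv_gm * cbf_gm + pv_wm * cbf_wm

    # a few posterior vessel tracks feeding the occipital/temporal cortex;
    # kept below the 25% GM threshold so vascular signal brightens the map
    # without entering GM-masked tissue statistics
    arterial = (
        (np.abs(xh) < 0.12) & (yh < -0.35) & (np.abs(zh) < 0.35)
        & (rho < 1.0) & (pv_gm < 0.2)
    )
    abv = np.where(arterial, config.abv_vessel, config.abv_background)
    abv = np.where(rho < 1.0, abv, 0.0)
    att_arterial = np.clip(att - 0.5, 0.05, None)

    m0 = config.m0_scale * (pv_gm + pv_wm + config.csf_m0_factor * pv_csf)

    ph = Phantom(
        pv_gm=pv_gm,
        pv_wm=pv_wm,
        pv_csf=pv_csf,
        cbf_gm=cbf_gm,
        cbf_wm=cbf_wm,
        cbf_true=cbf_true,
        att_true=att,
        arterial_mask=arterial,
        abv=abv,
        att_arterial=att_arterial,
        m0_tissue=m0,
        roi_labels=labels,
        voxel_size_mm=tuple(config.voxel_size_mm),
        subject_id=subject_id,
    )
    ph.validate()
    return ph


def simulate_cohort(config: CohortConfig):
    """Generate one phantom per configured subject.

    Returns a list of ``(Phantom, meta)`` pairs where ``meta`` is a dict with
    ``id, group, age, sex, site, seed``.  All randomness derives from
    ``config.seed`` through per-subject spawned streams, so the same config
    reproduces the cohort bit for bit.
    """
    config.validate()
    total = sum(config.group_sizes.values())
    if total == 0:
        raise ValueError("cohort has zero subjects")

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(total)
    out = []
    idx = 0
    for group in GROUP_LEVELS:
        for _ in range(config.group_sizes.get(group, 0)):
            child = children[idx]
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(child)
            cov = sample_covariates(group, config, rng)
            sid = f"sub-{idx:03d}"
            ph = build_phantom(config, group, cov, seed=sub_seed, subject_id=sid)
            meta = {
                "id": sid,
                "group": group,
                "age": cov[0],
                "sex": cov[1],
                "site": cov[2],
                "seed": sub_seed,
            }
            out.append((ph, meta))
            idx += 1
    return out


def simulate_metric_records(
    group_sizes: dict,
    group_means: dict,
    sd: float,
    seed: int,
    age_effect: float = 0.0,
    sex_effect: float = 0.0,
    site_effects: dict | None = None,
    site_probs: tuple = (91 / 122, 16 / 122, 15 / 122),
    site_names: tuple = ("site_a", "site_b", "site_c"),
) -> pd.DataFrame:
    """Simulate per-subject metric values directly at the records level.

    A fast generator for statistical experiments on the group-comparison
    machinery (no imaging involved): ``value = group mean + age_effect*(age
    - 70) + sex_effect*(sex == f) + site effect + N(0, sd)``.  Ages are
    N(70, 7.5), sex is balanced.  Returns a cohort table with columns
    ``id, group, age, sex, site, value``.
    """
    if set(group_sizes) != set(group_means):
        raise ValueError("group_sizes and group_means must share keys")
    rng = np.random.default_rng(seed)
    site_effects = site_effects or {}
    rows = []
    i = 0
    for group, n in group_sizes.items():
        for _ in range(n):
            age = rng.normal(70.0, 7.5)
            sex = "f" if rng.random() < 0.5 else "m"
            site = str(rng.choice(site_names, p=np.asarray(site_probs)))
            value = (
                group_means[group]
                + age_effect * (age - 70.0)
                + sex_effect * (sex == "f")
                + site_effects.get(site, 0.0)
                + rng.normal(0.0, sd)
            )
            rows.append(
                {"id": f"sub-{i:03d}", "group": group, "age": age,
                 "sex": sex, "site": site, "value": value}
            )
            i += 1
    return pd.DataFrame(rows)
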