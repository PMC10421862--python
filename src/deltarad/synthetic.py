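"""Synthetic paired pre/post CT phantom cohorts with coupled survival.

Each patient gets two phantoms (pre- and post-treatment): an ellipsoidal
liver lesion over noisy liver-parenchyma background, with a smoothed
Gaussian random field inside the lesion whose amplitude is the patient's
planted texture heterogeneity.  The post-minus-pre change in that amplitude
is the planted delta-heterogeneity; overall survival is drawn from an
exponential model whose log-hazard is ``effect`` times the standardized
delta, and the RECIST-style response label flips to non-responder when the
delta exceeds a threshold (rising heterogeneity after therapy marks
non-response).  An optional peri-hepatic fat band with HU in [-100, -10]
sits against the lesion so rim fat exclusion is exercised.

Everything is reproducible bit-for-bit from (config, seed): recorded HU are
integers and all draws run through numpy SeedSequence streams keyed by the
config seed, patient index and timepoint.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CTVolume, SegmentationMask, CLINICAL_COLUMNS

TIMEPOINTS = ("pre", "post")


@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Defaults emulate contrast-enhanced abdominal CT of liver metastases:
    liver background ~N(60, 10) HU, lesions 6-12 mm radius at a distinct
    mean HU, texture correlation length 2 mm, planted heterogeneity
    amplitude 5-15 HU pre-treatment with a N(0, 5) HU post-pre change, and
    exponential survival with ~20-month baseline median.
    """

    n_patients: int = 32
    shape: tuple = (64, 64, 24)
    spacing: tuple = (1.0, 1.0, 3.0)
    lesion_radius_mm: tuple = (6.0, 12.0)
    liver_hu_mean: float = 60.0
    liver_hu_sd: float = 10.0
    lesion_hu_mean: float = 90.0
    fat_band: bool = True
    fat_hu: tuple = (-100.0, -10.0)
    texture_corr_mm: float = 2.0
    texture_amp_range: tuple = (5.0, 15.0)
    texture_delta_sd: float = 5.0
    effect: float = 1.0            # beta on standardized delta-heterogeneity log-hazard
    baseline_hazard: float = np.log(2) / 20.0   # per month; median ~20 months
    censoring_rate: float = 0.2
    horizon_months: float = 48.0
    responder_rule: float = 0.0    # non-responder iff delta-heterogeneity > this
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("shape", "spacing", "lesion_radius_mm", "fat_hu", "texture_amp_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PatientTruth:
    """Planted ground truth for one synthetic patient."""

    patient_id: str
    amp_pre: float
    amp_post: float
    delta_heterogeneity: float       # standardized (amp_post - amp_pre) / delta_sd
    radius_pre_mm: tuple
    radius_post_mm: tuple
    event_time: float                # latent, uncensored
    os_months: float
    event: int
    response: str
    age: float
    race: str


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list                   # of dicts with keys pre/post volume+mask
    truth: list                      # of PatientTruth

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for t, pat in zip(self.truth, self.patients):
            vol_ml = (
                pat["pre_mask"].voxels.sum()
                * np.prod(self.config.spacing) / 1000.0
            )
            rows.append({
                "patient_id": t.patient_id,
                "os_months": t.os_months,
                "event": t.event,
                "response": t.response,
                "age": t.age,
                "race": t.race,
                "baseline_tumor_volume_ml": vol_ml,
            })
        return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)

    def write(self, out_dir, ext: str = ".nii") -> pd.DataFrame:
        """Write volumes/masks as NIfTI plus clinical and manifest CSVs.

        The manifest stores file names relative to ``out_dir`` so that a
        cohort written twice (anywhere) is byte-identical.
        """
        import os
        from . import io as vio

        os.makedirs(out_dir, exist_ok=True)
        manifest = []
        for pat in self.patients:
            pid = pat["patient_id"]
            entry = {"patient_id": pid}
            for tp in TIMEPOINTS:
                vname = f"{pid}_{tp}{ext}"
                mname = f"{pid}_{tp}_mask{ext}"
                vio.write_volume(pat[f"{tp}_volume"], os.path.join(out_dir, vname))
                vio.write_mask(pat[f"{tp}_mask"], os.path.join(out_dir, mname))
                entry[f"{tp}_volume"] = vname
                entry[f"{tp}_mask"] = mname
            manifest.append(entry)
        mdf = pd.DataFrame(manifest)
        mdf.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        vio.write_clinical_table(
            self.clinical_frame(), os.path.join(out_dir, "clinical.csv")
        )
        self.config.to_json(os.path.join(out_dir, "cohort_config.json"))
        return mdf


def _patient_stream(config: CohortConfig, patient_index: int, stream: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(patient_index), int(stream)])
    )


def plant_covariates(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-patient planted texture parameters (deterministic in seed)."""
    rows = []
    lo, hi = config.texture_amp_range
    for i in range(config.n_patients):
        rng = _patient_stream(config, i, 0)
        amp_pre = rng.uniform(lo, hi)
        raw_delta = rng.normal(0.0, config.texture_delta_sd)
        amp_post = max(amp_pre + raw_delta, 0.5)
        delta = (amp_post - amp_pre) / config.texture_delta_sd
        rows.append({
            "patient_index": i,
            "amp_pre": amp_pre,
            "amp_post": amp_post,
            "delta_heterogeneity": delta,
        })
    return pd.DataFrame(rows)


def _lesion_radii(config: CohortConfig, patient_index: int, timepoint: str):
    rng = _patient_stream(config, patient_index, 1 + TIMEPOINTS.index(timepoint))
    lo, hi = config.lesion_radius_mm
    # mildly anisotropic ellipsoid; z radius kept <= in-plane radius
    r_xy = rng.uniform(lo, hi)
    return (r_xy, r_xy * rng.uniform(0.8, 1.0), min(r_xy, hi) * rng.uniform(0.6, 0.9))


def generate_phantom(config: CohortConfig, patient_index: int, timepoint: str,
                     seed: int = None):
    """Build one phantom volume and its exact lesion mask.

    Returns (CTVolume, SegmentationMask).  The lesion is an axis-aligned
    ellipsoid centred in the volume; its interior HU is the lesion mean plus
    a smoothed Gaussian random field standardized to the patient's planted
    amplitude for this timepoint (amplitude 0 gives an exactly constant
    interior).  HU are rounded to integers for cross-platform determinism.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
    shape = tuple(config.shape)
    spacing = np.asarray(config.spacing, dtype=float)
    radii = np.asarray(_lesion_radii(config, patient_index, timepoint))

    half_extent_mm = (np.asarray(shape) - 1) / 2.0 * spacing
    if np.any(radii + 12.0 > half_extent_mm):
        raise ValueError(
            f"lesion too large for volume: radii {tuple(radii)} mm need a 12 mm "
            f"rim margin inside half-extents {tuple(half_extent_mm)} mm"
        )

    planted = plant_covariates(config).iloc[patient_index]
    amplitude = planted["amp_pre"] if timepoint == "pre" else planted["amp_post"]

    rng = _patient_stream(config, patient_index, 10 + TIMEPOINTS.index(timepoint))
    vol = rng.normal(config.liver_hu_mean, config.liver_hu_sd, size=shape)

    center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = sum(((g - c) * s / r) ** 2
             for g, c, s, r in zip(grids, center, spacing, radii))
    lesion = d2 <= 1.0

    # smoothed random field: white noise * gaussian(correlation length)
    sigma_vox = config.texture_corr_mm / spacing
    noise = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    inside = fieldv[lesion]
    sd = inside.std()
    if sd > 0 and amplitude > 0:
        texture = (fieldv - inside.mean()) / sd * amplitude
    else:
        texture = np.zeros(shape)
    vol[lesion] = config.lesion_hu_mean + texture[lesion]

    if config.fat_band:
        # fat slab against the +x face of the lesion, inside rim reach
        xs = np.where(lesion.any(axis=(1, 2)))[0]
        x0 = xs.max() + 1
        width = max(1, int(round(4.0 / spacing[0])))  # ~4 mm thick
        x1 = min(x0 + width, shape[0])
        if x1 > x0:
            lo, hi = config.fat_hu
            band = rng.uniform(lo, hi, size=(x1 - x0,) + shape[1:])
            sub = vol[x0:x1]
            sub[~lesion[x0:x1]] = band[~lesion[x0:x1]]
            vol[x0:x1] = sub

    vol = np.rint(vol)
    pid = f"P{patient_index:03d}"
    volume = CTVolume(vol, tuple(spacing), id=f"{pid}_{timepoint}",
                      timepoint=timepoint)
    mask = SegmentationMask(lesion, tuple(spacing), grid=volume.id, label="tumor")
    return volume, mask


def generate_clinical_truth(config: CohortConfig) -> pd.DataFrame:
    """Planted covariates plus survival/response draws, without the images.

    Uses the same per-patient RNG streams as :func:`generate_cohort`, so the
    clinical columns agree with a full image cohort built from the same
    config; baseline tumor volume is the analytic ellipsoid volume rather
    than the voxelized one.  Useful for many-replicate statistical checks
    of the survival generator.
    """
    planted = plant_covariates(config)
    rows = []
    races = np.array(["white", "black", "other"])
    for i in range(config.n_patients):
        delta = planted.loc[i, "delta_heterogeneity"]
        rng = _patient_stream(config, i, 20)
        rate = config.baseline_hazard * np.exp(config.effect * delta)
        t_event = rng.exponential(1.0 / rate)
        censored = rng.uniform() < config.censoring_rate
        os_months = rng.uniform(0, t_event) if censored else t_event
        r = np.asarray(_lesion_radii(config, i, "pre"))
        rows.append({
            "patient_id": f"P{i:03d}",
            "os_months": max(os_months, 1e-3),
            "event": int(not censored),
            "response": ("non-responder" if delta > config.responder_rule
                         else "responder"),
            "age": float(np.clip(rng.normal(60, 10), 30, 90)),
            "race": str(rng.choice(races, p=[0.7, 0.2, 0.1])),
            "baseline_tumor_volume_ml": 4.0 / 3.0 * np.pi * np.prod(r) / 1000.0,
            "delta_heterogeneity": float(delta),
            "event_time": float(t_event),
        })
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full paired cohort with survival coupled to planted deltas.

    Survival: T ~ Exp(rate = baseline_hazard * exp(effect * delta)), where
    delta is the standardized planted delta-heterogeneity.  A fraction
    ``censoring_rate`` of patients (Bernoulli draws) is censored at a
    uniform time below T.  Response is non-responder iff delta exceeds
    ``responder_rule``.
    """
    planted = plant_covariates(config)
    clin = generate_clinical_truth(config)
    patients, truth = [], []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        pat = {"patient_id": pid}
        for tp in TIMEPOINTS:
            v, m = generate_phantom(config, i, tp)
            pat[f"{tp}_volume"] = v
            pat[f"{tp}_mask"] = m
        row = clin.iloc[i]
        patients.append(pat)
        truth.append(PatientTruth(
            patient_id=pid,
            amp_pre=float(planted.loc[i, "amp_pre"]),
            amp_post=float(planted.loc[i, "amp_post"]),
            delta_heterogeneity=float(row["delta_heterogeneity"]),
            radius_pre_mm=tuple(_lesion_radii(config, i, "pre")),
            radius_post_mm=tuple(_lesion_radii(config, i, "post")),
            event_time=float(row["event_time"]),
            os_months=float(row["os_months"]),
            event=int(row["event"]),
            response=str(row["response"]),
            age=float(row["age"]),
            race=str(row["race"]),
        ))
    return SyntheticCohort(config=config, patients=patients, truth=truth)
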