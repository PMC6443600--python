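"""Synthetic tumor phantoms and survival cohorts.

No imaging or clinical data accompany the analysis this package implements,
so every downstream stage is exercised on simulated inputs with the same
statistical structure the analysis assumes:

* tumor "phantoms" are Gaussian-random-field textures inside an ellipsoidal
  mask, so that texture heterogeneity is a controllable ground truth;
* time to progression (TTP) follows a Weibull proportional-hazards model
  whose log-hazard is driven by a latent texture risk and an AST
  (aspartate aminotransferase) risk flag;
* overall survival (OS) is TTP plus an independent exponential
  post-progression survival, administratively censored to a target rate.

The default configuration emulates a 96-patient first-line chemotherapy
cohort plus a 14-patient EGFR-TKI validation arm of advanced lung squamous
cell carcinoma, with RECIST response marginals PR/SD/PD ~ 27/56/13.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TextureParams",
    "TumorPhantom",
    "SurvivalRecord",
    "SyntheticPatient",
    "CohortConfig",
    "generate_tumor_phantom",
    "simulate_endpoints",
    "generate_cohort",
    "cohort_to_dataframe",
    "write_cohort",
    "spawn_seeds",
]

#: the 24 pre-therapy clinical / blood variables carried per patient
CLINICAL_VARIABLES = [
    "gender", "age", "ecog", "number_smoke", "smoke_status",
    "history_lung_cancer", "family_history",
    "wbc", "ne", "ly", "mono", "eo", "hb", "plt", "alt", "tbil", "alb",
    "ast", "fg", "tp", "cea",
    "t_stage", "n_stage", "m_stage",
]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan one master seed out into ``n`` independent stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class TextureParams:
    """Generating parameters of one texture class.

    correlation_length
        Length scale (in voxels) of the squared-exponential covariance of
        the Gaussian random field; larger values give smoother, coarser
        texture.
    contrast
        Multiplier on the field amplitude; the stand-in for intra-tumor
        heterogeneity that the hazard model can latch onto.
    mean_intensity
        Additive offset, in HU-like units.
    noise_sd
        Marginal standard deviation of the field before the contrast
        multiplier.
    """

    correlation_length: float = 3.0
    contrast: float = 1.0
    mean_intensity: float = 40.0
    noise_sd: float = 15.0

    def __post_init__(self):
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TumorPhantom:
    volume: np.ndarray
    mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    params: TextureParams | None = None

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")


@dataclass(frozen=True)
class SurvivalRecord:
    time: float            # months
    event: int             # 1 = observed, 0 = censored
    endpoint: str = "TTP"  # "TTP" | "OS"

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


@dataclass
class SyntheticPatient:
    id: str
    arm: str                       # "chemo" | "tki"
    clinical: dict
    ttp: SurvivalRecord
    os: SurvivalRecord
    response: str | None           # PR | SD | PD, chemo arm only
    phantom: TumorPhantom | None = None
    latent_risk: float = 0.0       # ground-truth texture risk (z-scale)
    ast_risk: int = 0              # ground-truth AST risk flag


@dataclass
class CohortConfig:
    """Stated world of the simulated cohorts.

    Defaults mirror the emulated study: 96 chemotherapy + 14 EGFR-TKI
    patients; signature log-hazard ln(2.45) and AST log-hazard ln(3.66)
    (the multivariable hazard-ratio magnitudes of the emulated analysis);
    exponential baseline with median ``scale * ln 2`` = 3.6 months, the
    cohort-wide median TTP; ~20% OS censoring (19/96); TTP events all
    observed unless ``censor_ttp`` is set.
    """

    n_chemo: int = 96
    n_tki: int = 14
    texture_classes: list[TextureParams] = field(default_factory=lambda: [
        TextureParams(correlation_length=3.0, contrast=1.0),
        TextureParams(correlation_length=1.5, contrast=2.0),
    ])
    hazard_coefs: dict = field(default_factory=lambda: {
        "beta_signature": float(np.log(2.45)),
        "beta_ast": float(np.log(3.66)),
    })
    baseline: dict = field(default_factory=lambda: {"shape": 1.0, "scale": 5.2})
    censor_rate_os: float = 19 / 96
    censor_ttp: bool = False
    post_progression_mean: float = 7.9   # months; OS - TTP gap
    ast_risk_prevalence: float = 0.25
    latent_jitter_sd: float = 0.5        # within-texture-class risk spread
    confound_demographics: bool = False  # optional robustness switch
    image_shape: tuple[int, int, int] = (24, 24, 24)
    with_images: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_chemo < 2:
            raise ValueError("n_chemo must be >= 2")
        if not 0 <= self.censor_rate_os < 1:
            raise ValueError("censor_rate_os must be in [0, 1)")
        if self.baseline["shape"] <= 0 or self.baseline["scale"] <= 0:
            raise ValueError("baseline shape and scale must be > 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        d = json.loads(text)
        d["texture_classes"] = [TextureParams(**t) for t in d["texture_classes"]]
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# phantoms

def generate_tumor_phantom(
    params: TextureParams,
    shape: tuple[int, int, int] = (24, 24, 24),
    seed: int = 0,
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> TumorPhantom:
    """Gaussian-random-field texture inside an ellipsoidal mask.

    White noise is convolved with a Gaussian kernel of sigma =
    ``correlation_length / sqrt(2)``, which yields a squared-exponential
    autocovariance with the requested length scale; the field is then
    rescaled to marginal sd ``noise_sd``, multiplied by ``contrast`` and
    shifted by ``mean_intensity``.  Bit-identical for a fixed seed.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError("shape must have >= 8 voxels per axis")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sigma = params.correlation_length / np.sqrt(2.0)
    fieldv = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = fieldv.std()
    if sd > 0 and params.noise_sd > 0:
        fieldv = fieldv / sd * params.noise_sd * params.contrast
    else:
        fieldv = np.zeros(shape)
    volume = fieldv + params.mean_intensity

    # ellipsoid inscribed with semi-axes at 40% of each extent
    grids = np.indices(shape).astype(float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.4 * s for s in shape]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask = d2 <= 1.0
    return TumorPhantom(volume=volume, mask=mask,
                        voxel_spacing=voxel_spacing, params=params)


# ---------------------------------------------------------------------------
# survival endpoints

def simulate_endpoints(
    linpred: np.ndarray,
    baseline: dict,
    censor_rate_os: float,
    seed: int = 0,
    post_progression_mean: float = 7.9,
    censor_ttp: bool = False,
) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """Draw (TTP, OS) records under a Weibull proportional-hazards model.

    TTP_i = scale * (-log U / exp(linpred_i)) ** (1/shape); OS_i = TTP_i +
    an independent exponential post-progression survival.  OS is
    administratively censored at the empirical (1 - censor_rate_os)
    quantile of the drawn OS times, which achieves approximately the
    requested censoring rate.
    """
    linpred = np.asarray(linpred, dtype=float)
    if not np.all(np.isfinite(linpred)):
        raise ValueError("linear predictors must be finite")
    if censor_rate_os >= 1 or censor_rate_os < 0:
        raise ValueError("censor_rate_os must be in [0, 1)")
    shape, scale = float(baseline["shape"]), float(baseline["scale"])
    rng = np.random.default_rng(seed)
    n = linpred.size
    u = rng.uniform(size=n)
    ttp = scale * (-np.log(u) / np.exp(linpred)) ** (1.0 / shape)
    ttp = np.maximum(ttp, 1e-6)
    post = rng.exponential(post_progression_mean, size=n)
    os_t = ttp + post

    if censor_rate_os > 0:
        horizon = float(np.quantile(os_t, 1.0 - censor_rate_os))
    else:
        horizon = np.inf
    os_event = (os_t <= horizon).astype(int)
    os_obs = np.minimum(os_t, horizon)
    if censor_ttp:
        ttp_event = (ttp <= horizon).astype(int)
        ttp_obs = np.minimum(ttp, horizon)
    else:
        ttp_event = np.ones(n, dtype=int)
        ttp_obs = ttp

    ttp_records = [SurvivalRecord(float(t), int(e), "TTP")
                   for t, e in zip(ttp_obs, ttp_event)]
    os_records = [SurvivalRecord(float(t), int(e), "OS")
                  for t, e in zip(os_obs, os_event)]
    return ttp_records, os_records


# ---------------------------------------------------------------------------
# clinical tables

def _draw_clinical(rng: np.random.Generator, n: int, ast_flag: np.ndarray) -> pd.DataFrame:
    """Clinical/blood table with margins roughly matching the emulated
    chemotherapy cohort (86/96 aged <65, 82/96 male, 78/96 smokers, ...).

    AST values are generated conditionally on the ground-truth risk flag
    (normal range vs elevated); all other variables are independent of
    hazard by default.
    """
    df = pd.DataFrame(index=range(n))
    df["gender"] = np.where(rng.uniform(size=n) < 82 / 96, "male", "female")
    df["age"] = np.clip(rng.normal(57, 7, size=n), 30, 84).round(0)
    df["ecog"] = np.where(rng.uniform(size=n) < 40 / 96, rng.integers(0, 2, size=n), 2)
    smoker = rng.uniform(size=n) < 78 / 96
    df["smoke_status"] = np.where(smoker, "yes", "no")
    # pack-history in cigarettes; cohort median near the 9600 registry cut-off
    df["number_smoke"] = np.where(
        smoker, rng.lognormal(np.log(9600), 0.9, size=n), 0.0).round(0)
    df["history_lung_cancer"] = np.where(rng.uniform(size=n) < 0.15, "yes", "no")
    df["family_history"] = np.where(rng.uniform(size=n) < 11 / 96, "yes", "no")

    df["wbc"] = np.clip(rng.normal(7.5, 2.2, size=n), 2.0, 25.0)       # 1e9/L
    df["ne"] = np.clip(rng.normal(4.8, 1.7, size=n), 1.0, 20.0)
    df["ly"] = np.clip(rng.normal(1.6, 0.55, size=n), 0.2, 5.0)
    df["mono"] = np.clip(rng.normal(0.45, 0.18, size=n), 0.05, 2.0)
    df["eo"] = np.clip(rng.normal(0.18, 0.14, size=n), 0.0, 1.5)
    df["hb"] = np.clip(rng.normal(126, 16, size=n), 60, 190)           # g/L
    df["plt"] = np.clip(rng.normal(260, 85, size=n), 40, 700)          # 1e9/L
    df["alt"] = np.clip(rng.lognormal(np.log(22), 0.5, size=n), 4, 300)  # U/L
    df["tbil"] = np.clip(rng.lognormal(np.log(11), 0.4, size=n), 2, 60)  # umol/L
    df["alb"] = np.clip(rng.normal(40, 4.5, size=n), 20, 55)           # g/L
    # AST conditional on the risk flag: elevated >40 U/L iff at risk
    ast_normal = np.clip(rng.normal(24, 7, size=n), 8, 40)
    ast_high = 40 + rng.lognormal(np.log(18), 0.6, size=n)
    df["ast"] = np.where(ast_flag == 1, ast_high, ast_normal)
    df["fg"] = np.clip(rng.normal(3.4, 0.8, size=n), 1.5, 8.0)         # g/L
    df["tp"] = np.clip(rng.normal(68, 6, size=n), 45, 90)              # g/L
    df["cea"] = np.clip(rng.lognormal(np.log(3.2), 0.8, size=n), 0.2, 200)  # ng/mL

    stage_iv = rng.uniform(size=n) < 41 / 96
    df["t_stage"] = rng.integers(1, 5, size=n)
    df["n_stage"] = rng.integers(0, 4, size=n)
    df["m_stage"] = stage_iv.astype(int)
    # C-reactive protein (mg/L) for the Glasgow score; ~15% missing records
    crp = np.clip(rng.lognormal(np.log(6), 1.0, size=n), 0.2, 200)
    crp[rng.uniform(size=n) < 0.15] = np.nan
    df["crp"] = crp
    return df


def _assign_response(rng: np.random.Generator, latent: np.ndarray,
                     noise_sd: float = 0.8) -> np.ndarray:
    """RECIST response by rank-thresholding a noisy copy of the latent risk
    so marginal proportions are PR/SD/PD = 27/56/13 out of 96 (CR absent)."""
    n = latent.size
    noisy = latent + rng.normal(0, noise_sd, size=n)
    order = np.argsort(noisy)
    n_pr = int(round(n * 27 / 96))
    n_pd = int(round(n * 13 / 96))
    resp = np.full(n, "SD", dtype=object)
    resp[order[:n_pr]] = "PR"
    if n_pd > 0:
        resp[order[-n_pd:]] = "PD"
    return resp


# ---------------------------------------------------------------------------
# cohorts

def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Simulate the full two-arm cohort.

    Each chemotherapy patient draws a texture class; the latent texture
    risk is the z-scored class contrast plus within-class jitter.  The TTP
    log-hazard is ``beta_signature * latent + beta_ast * ast_flag``
    (centred).  TKI-arm patients are generated at the hazard of the
    low-risk end of the chemotherapy cohort (low texture class, normal
    AST), emulating a validation arm whose efficacy matches the low-risk
    stratum.  Reproducible bit-for-bit from ``config.seed``.
    """
    if not config.texture_classes:
        raise ValueError("texture_classes must be non-empty")
    (s_class, s_clin, s_surv, s_resp, s_img, s_tki) = spawn_seeds(config.seed, 6)
    rng_class = np.random.default_rng(s_class)
    rng_clin = np.random.default_rng(s_clin)
    rng_resp = np.random.default_rng(s_resp)
    rng_tki = np.random.default_rng(s_tki)

    n, m = config.n_chemo, config.n_tki
    classes = config.texture_classes
    contrasts = np.array([c.contrast for c in classes], dtype=float)
    mu_c, sd_c = contrasts.mean(), contrasts.std() if len(classes) > 1 else 1.0
    sd_c = sd_c if sd_c > 0 else 1.0

    cls_idx = rng_class.integers(0, len(classes), size=n)
    latent = (contrasts[cls_idx] - mu_c) / sd_c
    latent = latent + rng_class.normal(0, config.latent_jitter_sd, size=n)
    ast_flag = (rng_clin.uniform(size=n) < config.ast_risk_prevalence).astype(int)

    beta_s = float(config.hazard_coefs["beta_signature"])
    beta_a = float(config.hazard_coefs["beta_ast"])
    linpred = beta_s * latent + beta_a * ast_flag

    clinical = _draw_clinical(rng_clin, n, ast_flag)
    if config.confound_demographics:
        # optional robustness switch: tie age into the hazard
        age_z = (clinical["age"] - clinical["age"].mean()) / clinical["age"].std()
        linpred = linpred + 0.3 * age_z.to_numpy()
    center = linpred.mean()
    linpred = linpred - center

    ttp_rec, os_rec = simulate_endpoints(
        linpred, config.baseline, config.censor_rate_os, seed=s_surv,
        post_progression_mean=config.post_progression_mean,
        censor_ttp=config.censor_ttp)
    response = _assign_response(rng_resp, latent)

    # TKI arm: hazard of the low-risk corner of the chemo cohort (low
    # texture class, normal AST), on the same centred scale
    low_latent = (contrasts.min() - mu_c) / sd_c
    lin_tki = np.full(m, beta_s * low_latent) - center
    ast_tki = np.zeros(m, dtype=int)
    clin_tki = _draw_clinical(rng_tki, m, ast_tki) if m else None
    if m:
        ttp_tki, os_tki = simulate_endpoints(
            lin_tki, config.baseline, config.censor_rate_os,
            seed=(s_surv + 1) % (2**31 - 1),
            post_progression_mean=config.post_progression_mean,
            censor_ttp=config.censor_ttp)

    img_seeds = spawn_seeds(s_img, n + m)
    patients: list[SyntheticPatient] = []
    for i in range(n):
        phantom = None
        if config.with_images:
            phantom = generate_tumor_phantom(
                classes[cls_idx[i]], config.image_shape, seed=img_seeds[i])
        patients.append(SyntheticPatient(
            id=f"chemo-{i:03d}", arm="chemo",
            clinical=clinical.iloc[i].to_dict(),
            ttp=ttp_rec[i], os=os_rec[i], response=str(response[i]),
            phantom=phantom, latent_risk=float(latent[i]),
            ast_risk=int(ast_flag[i])))
    for j in range(m):
        phantom = None
        if config.with_images:
            phantom = generate_tumor_phantom(
                classes[int(np.argmin(contrasts))], config.image_shape,
                seed=img_seeds[n + j])
        patients.append(SyntheticPatient(
            id=f"tki-{j:03d}", arm="tki",
            clinical=clin_tki.iloc[j].to_dict(),
            ttp=ttp_tki[j], os=os_tki[j], response=None,
            phantom=phantom, latent_risk=float(low_latent), ast_risk=0))
    return patients


def cohort_to_dataframe(patients: list[SyntheticPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {"id": p.id, "arm": p.arm}
        row.update(p.clinical)
        row.update({
            "ttp_months": p.ttp.time, "ttp_event": p.ttp.event,
            "os_months": p.os.time, "os_event": p.os.event,
            "response": p.response if p.response is not None else "",
            "latent_risk": p.latent_risk, "ast_risk": p.ast_risk,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(patients: list[SyntheticPatient], config: CohortConfig,
                 outdir: str | Path) -> Path:
    """Write NIfTI volumes/masks, ``cohort.csv`` and a ``config.json`` echo."""
    import nibabel as nib

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for p in patients:
        if p.phantom is None:
            continue
        aff = np.diag(list(p.phantom.voxel_spacing) + [1.0])
        nib.save(nib.Nifti1Image(p.phantom.volume.astype(np.float32), aff),
                 outdir / "images" / f"{p.id}.nii")
        nib.save(nib.Nifti1Image(p.phantom.mask.astype(np.uint8), aff),
                 outdir / "masks" / f"{p.id}.nii")
    df = cohort_to_dataframe(patients)
    df.to_csv(outdir / "cohort.csv", index=False, float_format="%.6g")
    (outdir / "config.json").write_text(config.to_json())
    return outdir / "cohort.csv"
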