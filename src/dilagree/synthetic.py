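"""Synthetic multiparametric prostate MRI cohort with known ground truth.

The observational study this package supports cannot be reproduced without
its images and observers, so every pipeline stage is instead verified on a
synthetic cohort whose generating parameters are known:

* lesions are voxelized random ellipsoids with volumes drawn from a
  lognormal distribution centred near 2 mL, matching reported dominant
  intraprostatic lesion volumes;
* per-sequence contours are smooth random boundary perturbations of the base
  lesion, whose RMS displacement (mm) controls the expected Dice overlap;
* parametric map pairs are coupled through a Gaussian copula whose Pearson
  parameter ``r = 2·sin(π·ρ_s/6)`` yields a prescribed Spearman ρ_s inside
  the Boolean sum volume;
* the ADC map is not copied from the truth but produced the way scanners
  produce it: monoexponential diffusion signals at b = 50/400/800 s/mm² with
  additive Gaussian noise, refitted voxel-wise by log-linear least squares;
* a configurable fraction of patients receives an uninformative Ktrans map
  (lesion voxels redrawn from the background distribution), mirroring cases
  where Ktrans cannot distinguish tumour from normal prostate.

Native grids emulate the study acquisition (T2W 0.5×0.5×3.0 mm, ADC
2.0×2.0×3.0 mm, Ktrans 1.5×1.5×3.0 mm); functional maps are synthesised on
their native grids and rigidly resampled to the T2W reference with linear
interpolation, exactly as the analysis pipeline expects.  Latent copula
fields are spatially smoothed so that this resampling round-trip perturbs
ranks only marginally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cohort import PatientMeta
from .grids import (
    BinaryMask,
    ImageGeometry,
    ScalarVolume,
    read_nifti,
    resample_to_reference,
    write_nifti,
)
from .voxelwise import boolean_sum_volume

__all__ = [
    "GenerationError",
    "SyntheticConfig",
    "SyntheticCase",
    "default_marginals",
    "generate_base_lesion",
    "perturb_lesion",
    "simulate_dwi_and_fit_adc",
    "ADCFitResult",
    "generate_correlated_pair",
    "make_ktrans_unusable",
    "generate_cohort",
    "write_cohort",
    "load_cohort_case",
    "calibrate_perturbation",
]


class GenerationError(RuntimeError):
    """A synthetic case could not be generated under the given config."""


SEQUENCES = ("T2W", "ADC", "KTRANS")

#: Zone prevalences reported for dominant lesions (AFS/CZ/PZ/TZ); the raw
#: study percentages sum to 98.6% (unlabeled remainder), so they are
#: renormalised here to a proper probability vector.
_RAW_ZONE_W = {"AFS": 0.352, "CZ": 0.056, "PZ": 0.324, "TZ": 0.254}
DEFAULT_ZONE_WEIGHTS = {k: v / sum(_RAW_ZONE_W.values()) for k, v in _RAW_ZONE_W.items()}
DEFAULT_GRADE_WEIGHTS = {"1": 0.303, "2": 0.394, "3": 0.172, "4+5": 0.131}


def default_marginals() -> dict[str, dict[str, stats.rv_continuous]]:
    """Lesion and background intensity distributions per modality.

    ADC in mm²/s (lesion ≈ 990×10⁻⁶, background higher), Ktrans in min⁻¹
    (lesion exponential with mean 4, hypovascular background), T2W in
    arbitrary units with a hypointense lesion.
    """

    def tnorm(mean, sd):
        return stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)

    return {
        "T2W": {"lesion": tnorm(300.0, 60.0), "background": tnorm(450.0, 80.0)},
        "ADC": {"lesion": tnorm(990e-6, 150e-6), "background": tnorm(1500e-6, 200e-6)},
        "KTRANS": {
            "lesion": stats.expon(scale=4.0),
            "background": stats.expon(scale=1.0),
        },
    }


@dataclass
class SyntheticConfig:
    """Stated world of the synthetic cohort.

    Defaults reproduce the study's acquisition geometry and cohort structure:
    90 patients, lesion volumes lognormal with mean 2.14 mL and SD 2.1 mL,
    zone and grade-group prevalences as reported, 19/90 patients with an
    uninformative Ktrans map, b-values 50/400/800 s/mm², and Spearman
    targets of 0.20 (T2-ADC) and 0.13 (T2-Ktrans) matching the cohort means
    the voxel-wise analysis reports.
    """

    n_patients: int = 90
    seed: int = 0
    #: physical field of view (mm); shared by all modalities
    fov_mm: tuple[float, float, float] = (48.0, 48.0, 42.0)
    spacings_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "T2W": (0.5, 0.5, 3.0),
            "ADC": (2.0, 2.0, 3.0),
            "KTRANS": (1.5, 1.5, 3.0),
        }
    )
    volume_mean_ml: float = 2.14
    volume_sd_ml: float = 2.1
    volume_min_ml: float = 0.25
    volume_max_ml: float = 8.0
    #: RMS boundary displacement per sequence contour (mm)
    perturb_scale_mm: dict[str, float] = field(
        default_factory=lambda: {"T2W": 0.75, "ADC": 1.25, "KTRANS": 2.25}
    )
    #: correlation length of boundary perturbation fields (mm)
    perturb_smooth_mm: float = 4.0
    #: second observer redraws contours with this much extra displacement
    observer2_scale_mm: float = 2.5
    two_observers: bool = False
    target_rho: dict[str, float] = field(
        default_factory=lambda: {"T2-ADC": 0.20, "T2-Ktrans": 0.13, "ADC-Ktrans": 0.15}
    )
    #: correlation length of latent copula fields (mm); at least the coarsest
    #: native spacing, so resampling does not scramble ranks
    field_smooth_mm: float = 3.0
    zone_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_WEIGHTS)
    )
    grade_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_WEIGHTS)
    )
    ktrans_unusable_fraction: float = 19.0 / 90.0
    b_values: tuple[float, ...] = (50.0, 400.0, 800.0)
    dwi_s0: float = 1000.0
    #: additive Gaussian noise SD on diffusion signals (same units as s0)
    dwi_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, w in (("zone", self.zone_weights), ("grade", self.grade_weights)):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} weights must sum to 1, got {sum(w.values())}")
        if any(s < 0 for s in self.perturb_scale_mm.values()):
            raise ValueError("perturbation scales must be >= 0")
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("need >= 2 strictly increasing b-values")
        for rho in self.target_rho.values():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"target Spearman must be in [-1, 1], got {rho}")

    def geometry(self, modality: str) -> ImageGeometry:
        """Native grid for a modality, centred on the shared field of view."""
        sp = self.spacings_mm[modality]
        shape = tuple(max(1, round(self.fov_mm[d] / sp[d])) for d in range(3))
        return ImageGeometry(shape=shape, spacing=sp, origin=(0.0, 0.0, 0.0))

    @property
    def reference(self) -> ImageGeometry:
        return self.geometry("T2W")

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, dict):
                out[k] = {str(kk): vv for kk, vv in v.items()}
            elif isinstance(v, tuple):
                out[k] = list(v)
            else:
                out[k] = v
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SyntheticCase:
    """One generated patient: delivered data plus retained ground truth."""

    meta: PatientMeta
    #: delivered maps on the reference (T2W) grid, keyed by modality
    volumes: dict[str, ScalarVolume]
    #: contours per observer then per sequence, on the reference grid
    masks: dict[str, dict[str, BinaryMask]]
    base_mask: BinaryMask
    true_adc: ScalarVolume
    target_rho: dict[str, float]
    perturb_scale_mm: dict[str, float]


# ---------------------------------------------------------------------------
# lesion geometry


def _signed_distance_mm(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Negative inside the mask, positive outside, approximately 0 on the
    boundary; Euclidean, in mm."""
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    return d_out - d_in


def _smooth_unit_field(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    smooth_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian random field with (approximately) unit pointwise variance.

    White noise filtered with an isotropic-in-mm Gaussian kernel, rescaled by
    the exact kernel L2 norm so the marginal stays standard normal.
    """
    noise = rng.standard_normal(shape)
    if smooth_mm <= 0:
        return noise
    sigma_vox = [smooth_mm / s for s in spacing]
    sm = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    norm = 1.0
    for sv in sigma_vox:
        radius = int(4 * sv + 0.5)
        imp = np.zeros(2 * radius + 1)
        imp[radius] = 1.0
        w = ndimage.gaussian_filter1d(imp, sv)
        norm *= float(np.sum(w**2))
    return sm / np.sqrt(norm)


def generate_base_lesion(
    geometry: ImageGeometry,
    volume_ml: float,
    rng: np.random.Generator,
    semi_axes_mm: tuple[float, float, float] | None = None,
    center_jitter_mm: float = 2.0,
    axis_ratio_range: tuple[float, float] = (0.75, 1.3),
) -> BinaryMask:
    """Voxelize a random ellipsoidal lesion of a prescribed volume.

    Semi-axes are drawn with mild random anisotropy and rescaled so the
    analytic ellipsoid volume ``4/3·π·abc`` equals ``volume_ml``; passing
    ``semi_axes_mm`` pins them instead (``volume_ml`` then ignored).  The
    lesion center sits near the grid center with a small jitter and the
    ellipsoid must fit entirely inside the grid.
    """
    if semi_axes_mm is None:
        target_mm3 = volume_ml * 1000.0
        ratios = rng.uniform(*axis_ratio_range, size=3)
        base = (target_mm3 * 3.0 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
        semi = base * ratios
    else:
        semi = np.asarray(semi_axes_mm, dtype=float)
    extent = np.asarray(geometry.spacing) * np.asarray(geometry.shape)
    center = (
        np.asarray(geometry.origin)
        + extent / 2.0
        + rng.uniform(-center_jitter_mm, center_jitter_mm, size=3)
    )
    if np.any(semi >= extent / 2.0 - 1e-9):
        raise GenerationError(
            f"lesion semi-axes {semi} mm do not fit the {extent} mm grid"
        )
    pts = geometry.voxel_center_grid()
    r2 = np.sum(((pts - center) / semi) ** 2, axis=-1)
    voxels = r2 <= 1.0
    if not voxels.any():
        raise GenerationError("requested lesion volume rasterises to zero voxels")
    return BinaryMask(geometry=geometry, voxels=voxels, label="base")


def perturb_lesion(
    base: BinaryMask,
    scale_mm: float,
    rng: np.random.Generator,
    smooth_mm: float = 4.0,
    label: str = "",
) -> BinaryMask:
    """Displace the lesion boundary by a smooth random field of RMS ``scale_mm``.

    The mask is re-thresholded as ``signed_distance <= g`` where ``g`` is a
    Gaussian random field with pointwise SD ``scale_mm`` and correlation
    length ``smooth_mm`` — a smooth inward/outward boundary shift.  Scale 0
    returns the base mask exactly.
    """
    if scale_mm < 0:
        raise ValueError("perturbation scale must be >= 0")
    if scale_mm == 0:
        return BinaryMask(geometry=base.geometry, voxels=base.voxels.copy(), label=label)
    sdf = _signed_distance_mm(base.voxels, base.geometry.spacing)
    g = scale_mm * _smooth_unit_field(
        base.geometry.shape, base.geometry.spacing, smooth_mm, rng
    )
    voxels = sdf <= g
    if not voxels.any():
        raise GenerationError("boundary perturbation emptied the mask")
    return BinaryMask(geometry=base.geometry, voxels=voxels, label=label)


# ---------------------------------------------------------------------------
# diffusion simulation and ADC refit


@dataclass
class ADCFitResult:
    """Voxel-wise log-linear ADC fit of simulated diffusion signals."""

    volume: ScalarVolume
    #: voxels where the fit was clipped at 0 or had <2 usable signals
    flagged: np.ndarray


def simulate_dwi_and_fit_adc(
    true_adc: ScalarVolume,
    b_values: Sequence[float],
    s0: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> ADCFitResult:
    """Simulate monoexponential DWI and refit the ADC map.

    Per voxel the signal at each b-value is ``s0·exp(−b·ADC)`` plus additive
    Gaussian noise; the ADC estimate is the negative slope of the ordinary
    least-squares line through ``(b, log S)``.  Non-positive noisy signals
    are excluded from that voxel's fit (flagged; 0 reported if fewer than two
    usable signals remain) and negative slopes are clipped to 0 and flagged.
    """
    b = np.asarray(b_values, dtype=float)
    if b.size < 2:
        raise ValueError("need at least two b-values")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    adc = true_adc.values
    if np.any(adc < 0):
        raise ValueError("true ADC must be non-negative")
    signals = s0 * np.exp(-b[:, None, None, None] * adc[None])
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    valid = signals > 0
    logs = np.where(valid, np.log(np.where(valid, signals, 1.0)), 0.0)
    nv = valid.sum(axis=0).astype(float)
    bb = b[:, None, None, None]
    sum_b = np.where(valid, bb, 0.0).sum(axis=0)
    sum_b2 = np.where(valid, bb**2, 0.0).sum(axis=0)
    sum_y = logs.sum(axis=0)
    sum_by = (np.where(valid, bb, 0.0) * logs).sum(axis=0)
    denom = nv * sum_b2 - sum_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (nv * sum_by - sum_b * sum_y) / denom
    fitted = -slope
    too_few = nv < 2
    fitted = np.where(too_few, 0.0, fitted)
    clipped = fitted < 0
    fitted = np.where(clipped, 0.0, fitted)
    flagged = too_few | clipped | ~valid.all(axis=0)
    vol = ScalarVolume(
        geometry=true_adc.geometry, values=fitted, modality="ADC", units=true_adc.units
    )
    return ADCFitResult(volume=vol, flagged=flagged)


# ---------------------------------------------------------------------------
# copula-coupled parametric maps


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter that yields Spearman ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _copula_corr_matrix(targets: dict[str, float]) -> np.ndarray:
    """3×3 latent correlation matrix for (T2W, ADC, KTRANS) targets."""
    r = np.eye(3)
    idx = {"T2W": 0, "ADC": 1, "KTRANS": 2}
    for pair, (a, b) in {
        "T2-ADC": ("T2W", "ADC"),
        "T2-Ktrans": ("T2W", "KTRANS"),
        "ADC-Ktrans": ("ADC", "KTRANS"),
    }.items():
        rr = spearman_to_pearson(targets.get(pair, 0.0))
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rr
    w, v = np.linalg.eigh(r)
    if w.min() < 1e-10:  # nudge to the nearest usable PSD matrix
        w = np.clip(w, 1e-10, None)
        r = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
    return r


def _correlated_latents(
    geometry: ImageGeometry,
    corr: np.ndarray,
    smooth_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """k smoothed standard-normal fields with pointwise correlation ``corr``.

    Smoothing every component with the same kernel preserves the pointwise
    cross-correlation, so the copula parameter survives the smoothing.
    """
    k = corr.shape[0]
    white = np.stack(
        [_smooth_unit_field(geometry.shape, geometry.spacing, smooth_mm, rng)
         for _ in range(k)]
    )
    chol = np.linalg.cholesky(corr)
    return np.einsum("ij,j...->i...", chol, white)


def generate_correlated_pair(
    bsv: BinaryMask,
    target_rho_s: float,
    marginal_a,
    marginal_b,
    rng: np.random.Generator,
    background_a=None,
    background_b=None,
    smooth_mm: float = 0.0,
) -> tuple[ScalarVolume, ScalarVolume]:
    """Two maps whose in-BSV values have Spearman correlation ``target_rho_s``.

    Inside the BSV the pair follows a Gaussian copula with Pearson parameter
    ``2·sin(π·ρ_s/6)`` transformed to the given marginals; outside, values
    are drawn independently from the background marginals (defaulting to the
    lesion marginals).
    """
    if not -1.0 <= target_rho_s <= 1.0:
        raise ValueError(f"target Spearman must be in [-1, 1], got {target_rho_s}")
    r = spearman_to_pearson(target_rho_s)
    corr = np.array([[1.0, r], [r, 1.0]])
    z = _correlated_latents(bsv.geometry, corr, smooth_mm, rng)
    u = stats.norm.cdf(z)
    background_a = background_a if background_a is not None else marginal_a
    background_b = background_b if background_b is not None else marginal_b
    z_bg = np.stack(
        [_smooth_unit_field(bsv.geometry.shape, bsv.geometry.spacing, smooth_mm, rng)
         for _ in range(2)]
    )
    u_bg = stats.norm.cdf(z_bg)
    vals_a = np.where(bsv.voxels, marginal_a.ppf(u[0]), background_a.ppf(u_bg[0]))
    vals_b = np.where(bsv.voxels, marginal_b.ppf(u[1]), background_b.ppf(u_bg[1]))
    va = ScalarVolume(geometry=bsv.geometry, values=vals_a)
    vb = ScalarVolume(geometry=bsv.geometry, values=vals_b)
    return va, vb


def make_ktrans_unusable(
    vol: ScalarVolume,
    bsv: BinaryMask,
    background,
    rng: np.random.Generator,
) -> ScalarVolume:
    """Redraw in-BSV values from the background distribution.

    After this transformation lesion and background voxels are statistically
    indistinguishable, so any downstream voxel-wise correlation involving the
    map is expected to be ≈ 0; callers mark the case ``ktrans_usable=False``.
    """
    vals = vol.values.copy()
    n = int(bsv.voxels.sum())
    vals[bsv.voxels] = background.rvs(size=n, random_state=rng)
    return ScalarVolume(
        geometry=vol.geometry, values=vals, modality=vol.modality, units=vol.units
    )


# ---------------------------------------------------------------------------
# cohort assembly


_PAIR_MODS = {"T2-ADC": ("T2W", "ADC"), "T2-Ktrans": ("T2W", "KTRANS"),
              "ADC-Ktrans": ("ADC", "KTRANS")}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _generate_case(
    config: SyntheticConfig, patient_id: str, rng: np.random.Generator,
    marginals: dict, ktrans_usable: bool,
) -> SyntheticCase:
    ref = config.reference
    zone = rng.choice(list(config.zone_weights), p=list(config.zone_weights.values()))
    grade = rng.choice(list(config.grade_weights), p=list(config.grade_weights.values()))
    mu, sigma = _lognormal_params(config.volume_mean_ml, config.volume_sd_ml)
    volume_ml = float(np.clip(rng.lognormal(mu, sigma),
                              config.volume_min_ml, config.volume_max_ml))

    base = generate_base_lesion(ref, volume_ml, rng)

    def draw_contour(scale: float, label: str) -> BinaryMask:
        # an observer redraws rather than submits an empty contour
        for _ in range(20):
            try:
                return perturb_lesion(base, scale, rng,
                                      smooth_mm=config.perturb_smooth_mm,
                                      label=label)
            except GenerationError:
                continue
        raise GenerationError(
            f"could not draw a non-empty contour for {patient_id} ({label})"
        )

    masks: dict[str, dict[str, BinaryMask]] = {"obs1": {}}
    for seq in SEQUENCES:
        masks["obs1"][seq] = draw_contour(config.perturb_scale_mm[seq],
                                          f"{seq}:obs1")
    if config.two_observers:
        masks["obs2"] = {}
        for seq in SEQUENCES:
            masks["obs2"][seq] = draw_contour(config.observer2_scale_mm,
                                              f"{seq}:obs2")

    bsv = boolean_sum_volume(list(masks["obs1"].values()))
    # The coupled "tumour signal" region extends one coarse native voxel
    # beyond the union contour, so that linear resampling of the functional
    # maps never mixes independent background values into BSV-edge voxels.
    margin_vox = [
        int(np.ceil(max(sp[d] for sp in config.spacings_mm.values())
                    / ref.spacing[d]))
        for d in range(3)
    ]
    struct = np.ones([2 * m + 1 for m in margin_vox], dtype=bool)
    coupled = BinaryMask(
        geometry=ref,
        voxels=ndimage.binary_dilation(bsv.voxels, structure=struct),
        label="coupled-region",
    )
    corr = _copula_corr_matrix(config.target_rho)
    z = _correlated_latents(ref, corr, config.field_smooth_mm, rng)
    u = stats.norm.cdf(z)
    z_bg = np.stack(
        [_smooth_unit_field(ref.shape, ref.spacing, config.field_smooth_mm, rng)
         for _ in range(3)]
    )
    u_bg = stats.norm.cdf(z_bg)
    fields: dict[str, np.ndarray] = {}
    for i, seq in enumerate(SEQUENCES):
        lesion = marginals[seq]["lesion"].ppf(u[i])
        background = marginals[seq]["background"].ppf(u_bg[i])
        fields[seq] = np.where(coupled.voxels, lesion, background)

    units = {"T2W": "a.u.", "ADC": "mm^2/s", "KTRANS": "1/min"}
    true_adc = ScalarVolume(geometry=ref, values=fields["ADC"], modality="ADC",
                            units=units["ADC"])

    volumes: dict[str, ScalarVolume] = {
        "T2W": ScalarVolume(geometry=ref, values=fields["T2W"], modality="T2W",
                            units=units["T2W"])
    }
    # ADC: resample truth to the native DWI grid, simulate + refit, resample back
    adc_native_geom = config.geometry("ADC")
    adc_native_true = resample_to_reference(true_adc, adc_native_geom)
    fit = simulate_dwi_and_fit_adc(
        adc_native_true, config.b_values, config.dwi_s0, config.dwi_noise_sd, rng
    )
    volumes["ADC"] = resample_to_reference(fit.volume, ref)

    kt_ref = ScalarVolume(geometry=ref, values=fields["KTRANS"], modality="KTRANS",
                          units=units["KTRANS"])
    if not ktrans_usable:
        kt_ref = make_ktrans_unusable(
            kt_ref, coupled, marginals["KTRANS"]["background"], rng
        )
    kt_native = resample_to_reference(kt_ref, config.geometry("KTRANS"))
    volumes["KTRANS"] = resample_to_reference(kt_native, ref)

    meta = PatientMeta(
        patient_id=patient_id, zone=str(zone), grade_group=str(grade),
        observer_id="obs1", ktrans_usable=ktrans_usable,
    )
    return SyntheticCase(
        meta=meta, volumes=volumes, masks=masks, base_mask=base,
        true_adc=true_adc, target_rho=dict(config.target_rho),
        perturb_scale_mm=dict(config.perturb_scale_mm),
    )


def generate_cohort(config: SyntheticConfig) -> list[SyntheticCase]:
    """Generate the full cohort; deterministic for a fixed config and seed.

    Exactly ``round(ktrans_unusable_fraction · n_patients)`` patients receive
    an uninformative Ktrans map (assigned at random but with a fixed count),
    so a fraction of 19/90 over 90 patients flags exactly 19 cases.
    """
    marginals = default_marginals()
    ss = np.random.SeedSequence(config.seed)
    assign_child, *children = ss.spawn(config.n_patients + 1)
    n_unusable = int(round(config.ktrans_unusable_fraction * config.n_patients))
    assign_rng = np.random.default_rng(assign_child)
    unusable_idx = set(
        assign_rng.choice(config.n_patients, size=n_unusable, replace=False).tolist()
    )
    cases = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        patient_id = f"P{i + 1:03d}"
        cases.append(
            _generate_case(config, patient_id, rng, marginals,
                           ktrans_usable=i not in unusable_idx)
        )
    return cases


# ---------------------------------------------------------------------------
# on-disk cohort layout


def write_cohort(cases: list[SyntheticCase], outdir: str | Path,
                 config: SyntheticConfig | None = None) -> None:
    """Write a cohort as per-patient NIfTI files plus metadata/manifest CSVs.

    Layout: ``<outdir>/<patient_id>/{t2w,adc,ktrans}.nii`` and
    ``mask_<seq>_<obs>.nii``; ``metadata.csv`` and ``ground_truth.csv`` at
    the top level; ``manifest.json`` records seed and config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows, truth_rows = [], []
    for case in cases:
        pdir = outdir / case.meta.patient_id
        pdir.mkdir(exist_ok=True)
        for mod, vol in case.volumes.items():
            write_nifti(vol, pdir / f"{mod.lower()}.nii")
        for obs, seq_masks in case.masks.items():
            for seq, mask in seq_masks.items():
                write_nifti(mask, pdir / f"mask_{seq.lower()}_{obs}.nii")
        write_nifti(case.base_mask, pdir / "mask_base.nii")
        m = case.meta
        meta_rows.append(
            {"patient_id": m.patient_id, "zone": m.zone,
             "grade_group": m.grade_group, "observer_id": m.observer_id,
             "ktrans_usable": m.ktrans_usable}
        )
        truth_rows.append(
            {"patient_id": m.patient_id,
             "base_volume_ml": case.base_mask.volume_ml(),
             **{f"rho_{p}": v for p, v in case.target_rho.items()},
             **{f"scale_{s}": v for s, v in case.perturb_scale_mm.items()}}
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    if config is not None:
        manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                    "n_patients": config.n_patients, "config": config.to_jsonable()}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_cohort_case(cohort_dir: str | Path, patient_id: str,
                     observers: Sequence[str] = ("obs1",)) -> SyntheticCase | None:
    """Load one patient's delivered volumes and masks from a cohort directory."""
    pdir = Path(cohort_dir) / patient_id
    if not pdir.is_dir():
        return None
    meta_df = pd.read_csv(Path(cohort_dir) / "metadata.csv")
    row = meta_df[meta_df["patient_id"] == patient_id]
    if len(row) != 1:
        raise ValueError(f"metadata row missing for {patient_id}")
    row = row.iloc[0]
    meta = PatientMeta(
        patient_id=str(row["patient_id"]), zone=str(row["zone"]),
        grade_group=str(row["grade_group"]), observer_id=str(row["observer_id"]),
        ktrans_usable=bool(row["ktrans_usable"]),
    )
    volumes = {}
    for mod in SEQUENCES:
        vol = read_nifti(pdir / f"{mod.lower()}.nii", kind="volume")
        vol.modality = mod
        volumes[mod] = vol
    masks: dict[str, dict[str, BinaryMask]] = {}
    for obs in observers:
        masks[obs] = {}
        for seq in SEQUENCES:
            path = pdir / f"mask_{seq.lower()}_{obs}.nii"
            if path.exists():
                masks[obs][seq] = read_nifti(path, kind="mask")
    base = read_nifti(pdir / "mask_base.nii", kind="mask")
    return SyntheticCase(
        meta=meta, volumes=volumes, masks=masks, base_mask=base,
        true_adc=volumes["ADC"], target_rho={}, perturb_scale_mm={},
    )


def calibrate_perturbation(
    scales_mm: Sequence[float],
    n_reps: int = 25,
    seed: int = 0,
    volume_ml: float = 2.14,
    geometry: ImageGeometry | None = None,
    smooth_mm: float = 4.0,
) -> pd.DataFrame:
    """Monte-Carlo map from boundary-perturbation scale to expected Dice.

    For each scale, ``n_reps`` independent perturbations of fresh base
    lesions are compared against their base mask; the table reports the mean
    and SD of Dice per scale.  Seeded and reproducible.
    """
    from .metrics import dice as _dice

    if geometry is None:
        geometry = SyntheticConfig().reference
    rng = np.random.default_rng(seed)
    rows = []
    for scale in scales_mm:
        vals = []
        for _ in range(n_reps):
            base = generate_base_lesion(geometry, volume_ml, rng)
            pert = perturb_lesion(base, scale, rng, smooth_mm=smooth_mm)
            vals.append(_dice(base, pert))
        vals = np.asarray(vals)
        rows.append({"scale_mm": scale, "dice_mean": vals.mean(),
                     "dice_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                     "n": n_reps})
    return pd.DataFrame(rows)
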