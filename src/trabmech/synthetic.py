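"""Synthetic trabecular phantoms and simulated multi-resolution scans.

The generator emulates the study design this package targets: a cadaveric
trabecular-bone cube imaged once at fine (micro-CT-like, ~20 µm) resolution
— the gold standard — and re-imaged by clinical-resolution scanners
(CBCT / HR-pQCT analogs, 75–82 µm) that blur the structure, add noise and
report uncalibrated intensities.

Ground truth is a thresholded anisotropic Gaussian-correlated random field:
smoothed white noise produces plate/rod mixtures whose volume fraction is set
exactly by the threshold and whose trabecular thickness scales with the
smoothing correlation length.  A scan of a truth volume assigns bone/water
intensities, applies a Gaussian PSF, block-averages down to the clinical
voxel size (detector integration), then adds noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume, GrayVolume

__all__ = [
    "PhantomSpec",
    "ImagingSpec",
    "Specimen",
    "generate_ground_truth",
    "simulate_scan",
    "make_specimen_set",
    "DEFAULT_MODALITIES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one ground-truth trabecular cube.

    ``thickness_scale_mm`` is the Gaussian correlation length of the random
    field; mean trabecular thickness of the thresholded structure grows with
    it (roughly 2x at BV/TV ~ 0.1, see the histomorphometry tests).
    ``anisotropy`` >= 1 stretches the correlation length along axis 3, making
    the structure — and its apparent stiffness — stiffest along that axis.
    """

    side_mm: float = 8.0
    fine_voxel_mm: float = 0.02
    target_bvtv: float = 0.15
    thickness_scale_mm: float = 0.12
    anisotropy: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        n = self.side_mm / self.fine_voxel_mm
        if abs(n - round(n)) > 1e-8 or round(n) < 32:
            raise ValueError(
                "side_mm/fine_voxel_mm must be an integer grid dimension >= 32"
            )
        if not 0.02 < self.target_bvtv < 0.8:
            raise ValueError("target_bvtv must lie in (0.02, 0.8)")
        if self.anisotropy < 1:
            raise ValueError("anisotropy must be >= 1")

    @property
    def grid_n(self) -> int:
        return int(round(self.side_mm / self.fine_voxel_mm))


@dataclass(frozen=True)
class ImagingSpec:
    """Parameters of one simulated scanner.

    Intensities are arbitrary device units (clinical CBCT does not provide
    calibrated CT values); defaults give a contrast-to-noise ratio ~8, inside
    the 6–10.4 range the emulated devices produce.
    """

    out_voxel_mm: float = 0.08
    psf_fwhm_mm: float = 0.16
    noise_sd: float = 125.0
    bone_intensity: float = 1000.0
    background_intensity: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.out_voxel_mm <= 0:
            raise ValueError("out_voxel_mm must be > 0")


#: Scanner analogs mirroring the emulated study: a fine micro-CT-like scan
#: (high CNR, voxel = ground-truth voxel) and clinical-resolution rescans.
#: Voxel sizes follow the emulated devices (80/82/75 um).
DEFAULT_MODALITIES: dict[str, ImagingSpec] = {
    "micro": ImagingSpec(out_voxel_mm=0.02, psf_fwhm_mm=0.03, noise_sd=60.0),
    "cbct_a": ImagingSpec(out_voxel_mm=0.08, psf_fwhm_mm=0.16, noise_sd=100.0),
    "hrpqct": ImagingSpec(out_voxel_mm=0.082, psf_fwhm_mm=0.18, noise_sd=125.0),
    "cbct_n": ImagingSpec(out_voxel_mm=0.075, psf_fwhm_mm=0.20, noise_sd=160.0),
}


def generate_ground_truth(spec: PhantomSpec) -> BinaryVolume:
    """Threshold an anisotropic Gaussian-correlated random field.

    The threshold is the intensity quantile that yields exactly the target
    bone fraction, so ``|BV/TV - target_bvtv|`` is bounded by one voxel's
    worth of probability mass.  Deterministic for a fixed ``rng_seed``.
    """
    n = spec.grid_n
    rng = np.random.default_rng(spec.rng_seed)
    noise = rng.standard_normal((n, n, n))
    sigma_vox = spec.thickness_scale_mm / spec.fine_voxel_mm
    sigma = (sigma_vox, sigma_vox, sigma_vox * spec.anisotropy)
    if min(sigma) < 0.5:
        raise ValueError(
            "thickness_scale_mm below half a voxel: structure unresolvable "
            f"(sigma={min(sigma):.2f} voxels); refine fine_voxel_mm"
        )
    fld = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    thr = np.quantile(fld, 1.0 - spec.target_bvtv)
    mask = fld > thr
    achieved = mask.mean()
    if abs(achieved - spec.target_bvtv) > 0.005:
        raise RuntimeError(
            f"could not reach target BV/TV {spec.target_bvtv}: got {achieved:.4f} "
            "(degenerate field, e.g. too-smooth threshold plateau)"
        )
    return BinaryVolume(mask, spec.fine_voxel_mm)


def simulate_scan(truth: BinaryVolume, imaging: ImagingSpec) -> GrayVolume:
    """Image a ground-truth mask: intensity map -> PSF blur -> block-average
    resample -> additive Gaussian noise.

    The output voxel size is the nearest integer multiple of the truth voxel
    (detector binning); it must be >= the truth voxel.
    """
    if imaging.out_voxel_mm < truth.voxel_mm - 1e-9:
        raise ValueError("out_voxel_mm must be >= the ground-truth voxel size")
    factor = max(1, int(round(imaging.out_voxel_mm / truth.voxel_mm)))
    out_voxel = factor * truth.voxel_mm

    img = np.where(
        truth.data, imaging.bone_intensity, imaging.background_intensity
    ).astype(np.float64)
    if imaging.psf_fwhm_mm > 0:
        sigma_vox = imaging.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sigma_vox /= truth.voxel_mm
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    if factor > 1:
        n = (np.array(img.shape) // factor) * factor
        img = img[: n[0], : n[1], : n[2]]
        sh = (
            n[0] // factor, factor,
            n[1] // factor, factor,
            n[2] // factor, factor,
        )
        img = img.reshape(sh).mean(axis=(1, 3, 5))
    if imaging.noise_sd > 0:
        rng = np.random.default_rng(imaging.rng_seed)
        img = img + rng.normal(0.0, imaging.noise_sd, size=img.shape)
    return GrayVolume(img, out_voxel)


@dataclass
class Specimen:
    """One synthetic specimen: ground truth plus its simulated scans."""

    specimen_id: str
    seed: int
    phantom: PhantomSpec
    truth: BinaryVolume
    scans: dict[str, GrayVolume] = field(default_factory=dict)


def make_specimen_set(
    n: int,
    base_seed: int,
    phantom: PhantomSpec = PhantomSpec(),
    modalities: dict[str, ImagingSpec] | None = None,
    bvtv_range: tuple[float, float] = (0.05, 0.45),
) -> list[Specimen]:
    """Generate ``n`` specimens spanning a BV/TV design grid with one fine
    and several degraded scans each.

    One master seed spawns independent per-specimen and per-scan streams, so
    the set is reproducible and scans of different modalities see independent
    noise.  Target BV/TV increases strictly across the set, covering the
    range observed across the emulated study's specimens.
    """
    if n < 3:
        raise ValueError("need at least 3 specimens")
    modalities = dict(modalities or DEFAULT_MODALITIES)
    lo, hi = bvtv_range
    targets = np.linspace(lo, hi, n)
    master = np.random.SeedSequence(base_seed)
    children = master.spawn(n)
    specimens = []
    for i, (target, child) in enumerate(zip(targets, children)):
        # one stream per specimen; scan seeds drawn from it
        seeds = child.generate_state(1 + len(modalities)) % (2**31)
        spec = replace(
            phantom, target_bvtv=float(target), rng_seed=int(seeds[0])
        )
        truth = generate_ground_truth(spec)
        scans = {}
        for j, (name, imspec) in enumerate(modalities.items()):
            scans[name] = simulate_scan(
                truth, replace(imspec, rng_seed=int(seeds[1 + j]))
            )
        specimens.append(
            Specimen(
                specimen_id=f"S{i + 1:02d}",
                seed=int(seeds[0]),
                phantom=spec,
                truth=truth,
                scans=scans,
            )
        )
    return specimens
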