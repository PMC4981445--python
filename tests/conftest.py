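import numpy as np
import pytest
from scipy import ndimage

import trabmech as tm


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 6-connected component of a boolean array."""
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


@pytest.fixture(scope="session")
def connected_phantom() -> tm.BinaryVolume:
    """A 64-cube trabecular truth reduced to one connected component."""
    spec = tm.PhantomSpec(
        side_mm=3.2,
        fine_voxel_mm=0.05,
        target_bvtv=0.3,
        thickness_scale_mm=0.2,
        rng_seed=5,
    )
    truth = tm.generate_ground_truth(spec)
    return tm.BinaryVolume(largest_component(truth.data), truth.voxel_mm)


@pytest.fixture(scope="session")
def noisefree_scan(connected_phantom) -> tm.GrayVolume:
    """Two-intensity (0 / 1000) noise-free image of the connected phantom."""
    return tm.simulate_scan(
        connected_phantom,
        tm.ImagingSpec(out_voxel_mm=0.05, psf_fwhm_mm=0.0, noise_sd=0.0),
    )


@pytest.fixture(scope="session")
def noisy_scan(connected_phantom) -> tm.GrayVolume:
    """Same phantom at CNR ~ 8 (blur + additive noise)."""
    return tm.simulate_scan(
        connected_phantom,
        tm.ImagingSpec(out_voxel_mm=0.05, psf_fwhm_mm=0.07, noise_sd=125.0, rng_seed=6),
    )


@pytest.fixture(scope="session")
def porous_masks_8() -> list[tm.BinaryVolume]:
    """Small connected porous masks for FE oracle comparisons."""
    rng = np.random.default_rng(42)
    out = []
    while len(out) < 3:
        raw = ndimage.gaussian_filter(rng.standard_normal((8, 8, 8)), 1.2)
        mask = largest_component(raw > np.quantile(raw, 0.55))
        if mask.sum() >= 80:
            out.append(tm.BinaryVolume(mask, 0.1))
    return out
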