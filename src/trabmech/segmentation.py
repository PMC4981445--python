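"""Bone/background segmentation.

Two routes, matching how the emulated study treated its modalities:

* **ARG** (automated region growing) for clinical-resolution scans whose
  intensities are not calibrated.  Seeds are taken from the high-intensity
  tail of the histogram and eroded to interior voxels; the *strictest*
  homogeneity threshold is the intensity spread (SD) of the seeds
  themselves, the *most permissive* is 1.6x that, and 50 thresholds are
  swept linearly between them.  Growth is seeded region growing: the
  frontier voxel closest to the running region mean is admitted next, for
  as long as the region SD stays below the homogeneity threshold.  The
  iteration minimising an assessment function — within-region
  inhomogeneity (penalising over-segmentation) against mean boundary
  gradient (penalising boundaries that sit off the true bone/water
  interface) — is returned.

* A global histogram threshold (Otsu, maximum between-class variance) for
  fine micro-CT-like data with calibrated, high-contrast intensities.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .volume import BinaryVolume, GrayVolume

__all__ = [
    "ARGConfig",
    "ARGResult",
    "SeedSelectionError",
    "select_seeds",
    "strictest_threshold",
    "region_grow",
    "assessment",
    "arg_segment",
    "otsu_segment",
    "cnr",
]

log = logging.getLogger(__name__)

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
_SMOOTH_SIGMA = 1.0  # voxels; noise suppression for seeds and assessment


class SeedSelectionError(RuntimeError):
    pass


@dataclass(frozen=True)
class ARGConfig:
    """ARG tuning knobs.

    ``permissive_factor`` scales the strictest threshold to the top of the
    schedule; ``assessment_weights`` = (inhomogeneity, boundary-gradient).
    """

    n_iterations: int = 50
    permissive_factor: float = 1.6
    seed_percentile: float | None = None
    assessment_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")
        if self.permissive_factor <= 1:
            raise ValueError("permissive_factor must be > 1")
        if self.seed_percentile is not None and not 0 < self.seed_percentile < 100:
            raise ValueError("seed_percentile must be in (0, 100)")


@dataclass
class ARGResult:
    selected_mask: BinaryVolume
    selected_iteration: int
    thresholds: list[float]
    assessment_values: list[float]
    masks_nested: bool = True
    masks: list[BinaryVolume] = field(default_factory=list, repr=False)


def _seed_tail(vol: GrayVolume, config: ARGConfig) -> np.ndarray:
    """Histogram-derived seed region before erosion to interior voxels."""
    data = np.asarray(vol.data, dtype=float)
    if np.ptp(data) == 0:
        raise SeedSelectionError("constant volume: no intensity tail to seed from")
    smooth = ndimage.gaussian_filter(data, _SMOOTH_SIGMA)
    if config.seed_percentile is None:
        try:
            thr = float(threshold_multiotsu(smooth, classes=3)[-1])
        except ValueError:  # too few distinct values for a 3-class split
            thr = float(threshold_otsu(smooth))
    else:
        thr = np.percentile(smooth, config.seed_percentile)
    tail = smooth > thr
    if not tail.any():  # heavily discrete histogram: fall back to >=
        tail = smooth >= thr
    return tail


def select_seeds(vol: GrayVolume, config: ARGConfig = ARGConfig()) -> BinaryVolume:
    """Seeds from the upper intensity tail, eroded to interior voxels.

    The cutoff is derived from the attenuation-value distribution of the
    whole volume: by default the upper threshold of a three-class
    between-class-variance split (multi-Otsu) of a lightly smoothed copy,
    which isolates the bone tail whether the histogram is bimodal
    (high bone fraction) or background-dominated (sparse trabeculae).  The
    seed set then spans the upper mode, and its *raw*-intensity spread
    reflects both noise and partial-volume blur — the scale the homogeneity
    schedule must sweep.  A fixed upper ``seed_percentile`` can override
    the histogram split.  Smoothing keeps seed blobs spatially coherent
    rather than isolated noise spikes.  Raises
    :class:`SeedSelectionError` if the volume is constant or the erosion
    empties the seed set (advice: lower ``seed_percentile``).
    """
    tail = _seed_tail(vol, config)
    seeds = ndimage.binary_erosion(tail, structure=_FACE_STRUCT)
    if not seeds.any():
        raise SeedSelectionError(
            "seed set empty after erosion to interior voxels; "
            f"lower seed_percentile (currently {config.seed_percentile})"
        )
    return BinaryVolume(seeds, vol.voxel_mm)


def strictest_threshold(vol: GrayVolume, seeds: BinaryVolume) -> float:
    """Homogeneity of the original seeds: the SD of seed-voxel intensities.

    A zero spread (noise-free or single-voxel seeds) is floored to a small
    epsilon so the threshold schedule stays well defined.
    """
    vals = np.asarray(vol.data, dtype=float)[seeds.data]
    if vals.size == 0:
        raise ValueError("empty seed set")
    spread = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if spread == 0.0:
        eps = 1e-6 * max(1.0, abs(float(vals.mean())))
        log.info("zero seed spread floored to epsilon %.3g", eps)
        return eps
    return spread


def _grow_ordered(
    data: np.ndarray, seeds: np.ndarray, cap: float
) -> tuple[list[int], np.ndarray]:
    """Greedy seeded region growing under a homogeneity cap.

    Admits, one at a time, the 6-connected frontier voxel whose intensity is
    closest to the running region mean, while that deviation stays
    <= ``cap``.  Returns the admission order (flat indices) and the
    deviation recorded at each admission.  Because the greedy order does not
    depend on the cap, the result for a smaller cap is a prefix of the
    result for a larger one — growth is monotone in the threshold by
    construction.
    """
    shape = data.shape
    flat = data.ravel()
    strides = (shape[1] * shape[2], shape[2], 1)
    inregion = seeds.ravel().copy()
    queued = inregion.copy()
    n = int(inregion.sum())
    s = float(flat[inregion].sum())

    def neighbors(idx: int):
        i, r = divmod(idx, strides[0])
        j, k = divmod(r, shape[2])
        if i > 0:
            yield idx - strides[0]
        if i < shape[0] - 1:
            yield idx + strides[0]
        if j > 0:
            yield idx - strides[1]
        if j < shape[1] - 1:
            yield idx + strides[1]
        if k > 0:
            yield idx - 1
        if k < shape[2] - 1:
            yield idx + 1

    mean = s / n
    heap: list[tuple[float, int]] = []
    seed_idx = np.flatnonzero(inregion)
    for idx in seed_idx:
        for nb in neighbors(int(idx)):
            if not queued[nb]:
                queued[nb] = True
                heapq.heappush(heap, (abs(flat[nb] - mean), nb))
    order: list[int] = []
    devs: list[float] = []
    while heap:
        p, idx = heapq.heappop(heap)
        v = float(flat[idx])
        p_now = abs(v - mean)
        if heap and p_now > heap[0][0] + 1e-12:
            heapq.heappush(heap, (p_now, idx))
            continue
        if p_now > cap:
            break
        n += 1
        s += v
        mean = s / n
        inregion[idx] = True
        order.append(idx)
        devs.append(p_now)
        for nb in neighbors(idx):
            if not queued[nb]:
                queued[nb] = True
                heapq.heappush(heap, (abs(flat[nb] - mean), nb))
    return order, np.asarray(devs)


def region_grow(
    vol: GrayVolume, seeds: BinaryVolume, threshold: float
) -> BinaryVolume:
    """Face-connected seeded growth under a homogeneity cap.

    The region repeatedly admits the frontier voxel whose intensity is
    closest to the running region mean, while that deviation stays within
    ``threshold``; passes repeat until no frontier voxel qualifies under
    the final region mean, so the result is a fixed point — growing it
    again with the same threshold adds nothing.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not seeds.data.any():
        raise ValueError("empty seed set")
    data = np.asarray(vol.data, dtype=float)
    mask = seeds.data.copy()
    while True:
        order, _ = _grow_ordered(data, mask, threshold)
        if not order:
            break
        mask = mask.copy()
        mask.ravel()[np.asarray(order, dtype=np.int64)] = True
    return BinaryVolume(mask, vol.voxel_mm)


class _AssessmentContext:
    """Volume-level quantities shared by all assessment evaluations.

    The volume's own attenuation histogram is split into three classes
    (background / partial volume / bone) by a three-class
    between-class-variance threshold on a noise-suppressed copy; the score
    measures the region's disagreement with that split.
    """

    def __init__(self, vol: GrayVolume):
        data = np.asarray(vol.data, dtype=float)
        self.smooth = ndimage.gaussian_filter(data, _SMOOTH_SIGMA)
        try:
            t1, t2 = threshold_multiotsu(self.smooth, classes=3)
        except ValueError:
            t1 = t2 = float(threshold_otsu(self.smooth))
        self.bone_class = self.smooth >= t2
        self.background_class = self.smooth < t1
        self.n_bone = max(int(self.bone_class.sum()), 1)

    def score(self, mask: np.ndarray, weights: tuple[float, float]) -> float:
        if not mask.any() or mask.all():
            return float("inf")
        w_leak, w_miss = weights
        leak = (self.background_class & mask).sum() / mask.sum()
        miss = (self.bone_class & ~mask).sum() / self.n_bone
        return float(w_leak * leak + w_miss * miss)


def assessment(
    vol: GrayVolume,
    mask: BinaryVolume,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Segmentation quality score; lower is better.

    The volume's histogram is split into background / partial-volume / bone
    classes (three-class between-class-variance split of a noise-suppressed
    copy).  The score is ``w_leak * leak + w_miss * miss`` where ``leak`` is
    the fraction of the region made of background-class voxels (penalizing
    over-segmentation into water) and ``miss`` is the fraction of
    bone-class voxels left outside the region (penalizing
    under-segmentation).  Partial-volume voxels are free to join the
    region, mirroring how segmentation at clinical resolution counts the
    blurred halo of thin trabeculae as bone.  Empty or full masks score
    +inf.
    """
    return _AssessmentContext(vol).score(mask.data, weights)


def arg_segment(vol: GrayVolume, config: ARGConfig = ARGConfig()) -> ARGResult:
    """Full ARG sweep: seeds -> 50-threshold schedule -> assessment argmin.

    Thresholds are linearly spaced from the strictest (seed homogeneity SD)
    to ``permissive_factor`` times it, both endpoints included.  Because
    greedy growth is monotone in the threshold, the 50 masks are computed as
    prefixes of a single growth to the most permissive cap, and are nested
    by construction.  Ties in the assessment argmin resolve to the
    strictest (lowest) iteration.
    """
    seeds = select_seeds(vol, config)
    # the strictest threshold measures the homogeneity of the original
    # (uneroded) seed region; erosion to interior voxels is a robustness
    # step for the growth itself
    tail = _seed_tail(vol, config)
    t0 = strictest_threshold(vol, BinaryVolume(tail, vol.voxel_mm))
    thresholds = np.linspace(t0, config.permissive_factor * t0, config.n_iterations)
    data = np.asarray(vol.data, dtype=float)
    order, devs = _grow_ordered(data, seeds.data, float(thresholds[-1]))
    order = np.asarray(order, dtype=np.int64)
    # first index where the deviation trace exceeds each threshold
    lengths = np.searchsorted(
        np.maximum.accumulate(devs) if len(devs) else np.empty(0),
        thresholds,
        side="right",
    )
    ctx = _AssessmentContext(vol)
    masks: list[BinaryVolume] = []
    scores: list[float] = []
    mask = seeds.data.copy()
    prev_len = 0
    for L in lengths:
        L = int(L)
        mask.ravel()[order[prev_len:L]] = True
        prev_len = L
        m = mask.copy()
        masks.append(BinaryVolume(m, vol.voxel_mm))
        scores.append(ctx.score(m, config.assessment_weights))
    best = int(np.argmin(scores))  # argmin takes the first (strictest) on ties
    return ARGResult(
        selected_mask=masks[best],
        selected_iteration=best,
        thresholds=[float(t) for t in thresholds],
        assessment_values=scores,
        masks_nested=True,
        masks=masks,
    )


def otsu_segment(vol: GrayVolume) -> BinaryVolume:
    """Global threshold maximising between-class variance; upper class = bone."""
    data = np.asarray(vol.data)
    if np.ptp(data) == 0:
        raise ValueError("constant volume cannot be thresholded")
    thr = threshold_otsu(data)
    return BinaryVolume(data > thr, vol.voxel_mm)


def cnr(
    vol: GrayVolume, bone_roi: BinaryVolume, background_roi: BinaryVolume
) -> float:
    """Contrast-to-noise ratio: |mean(bone) - mean(bg)| / sd(bg)."""
    b = bone_roi.data
    g = background_roi.data
    if not b.any() or not g.any():
        raise ValueError("both ROIs must be non-empty")
    if (b & g).any():
        raise ValueError("ROIs must be disjoint")
    data = np.asarray(vol.data, dtype=float)
    contrast = abs(data[b].mean() - data[g].mean())
    noise = data[g].std(ddof=1)
    if noise == 0:
        if contrast == 0:
            return 0.0
        warnings.warn("zero background SD: CNR is infinite", stacklevel=2)
        return float("inf")
    return float(contrast / noise)
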