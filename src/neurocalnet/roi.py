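"""Semi-automated somatic ROI extraction from fluorescence movies.

The workflow mirrors the field's manual-plus-correlation approach: build a
correlation image in which pixels belonging to one soma light up (their
time courses co-fluctuate), place a seed per cell (manually, or with
:func:`propose_seeds`), grow each ROI by adding 8-connected neighbors whose
trace correlates with the running ROI mean trace, then average pixels
within each mask — optionally subtracting a surrounding-annulus background
— to obtain one trace per neuron.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, maximum_filter

from neurocalnet.calcium import TraceMatrix

__all__ = [
    "FluorescenceMovie",
    "RoiSet",
    "correlation_image",
    "grow_rois",
    "extract_traces",
    "propose_seeds",
]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FluorescenceMovie:
    """A T x H x W fluorescence stack with frame-rate metadata."""

    data: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie must be 3-D (T, H, W)")
        if self.data.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite movie values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class RoiSet:
    """Labelled pixel masks over one field of view.

    ``masks`` is a list of boolean H x W arrays; 0-based (row, col)
    coordinates throughout.
    """

    masks: list[np.ndarray]
    frame_shape: tuple[int, int]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        checked = []
        for m in self.masks:
            m = np.asarray(m, dtype=bool)
            if m.shape != tuple(self.frame_shape):
                raise ValueError("mask shape mismatch")
            if not m.any():
                raise ValueError("empty ROI mask")
            checked.append(m)
        self.masks = checked
        if self.labels is None:
            self.labels = [f"roi{i:03d}" for i in range(len(self.masks))]

    def __len__(self) -> int:
        return len(self.masks)

    def union(self) -> np.ndarray:
        out = np.zeros(self.frame_shape, dtype=bool)
        for m in self.masks:
            out |= m
        return out

    def label_image(self) -> np.ndarray:
        """0 = background, i+1 = ROI i (later ROIs win overlaps)."""
        img = np.zeros(self.frame_shape, dtype=np.int32)
        for i, m in enumerate(self.masks):
            img[m] = i + 1
        return img


def correlation_image(movie: FluorescenceMovie) -> np.ndarray:
    """Mean temporal Pearson correlation of each pixel with its 8-neighborhood.

    Border pixels average over their available neighbors.  Pixels with a
    constant time course have undefined correlation and contribute 0 by
    convention.  Because each pixel trace is z-scored first, the map is
    invariant to per-pixel affine intensity rescaling.
    """
    if movie.n_frames < 10:
        raise ValueError("need at least 10 frames for a correlation image")
    x = movie.data
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    T, H, W = x.shape
    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for dr, dc in _NEIGHBORS8:
        r0, r1 = max(0, dr), min(H, H + dr)
        c0, c1 = max(0, dc), min(W, W + dc)
        a = z[:, r0:r1, c0:c1]
        b = z[:, r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        acc[r0:r1, c0:c1] += np.einsum("tij,tij->ij", a, b) / T
        cnt[r0:r1, c0:c1] += 1
    return acc / cnt


def propose_seeds(
    corr_img: np.ndarray,
    n_seeds: int = 25,
    min_distance: int = 5,
    min_value: float = 0.2,
) -> list[tuple[int, int]]:
    """Suggest seed pixels at local maxima of the correlation image.

    A convenience replacing the manual cell-outlining step; returns up to
    ``n_seeds`` (row, col) coordinates of the strongest local maxima at
    least ``min_distance`` pixels apart, with map value above ``min_value``.
    """
    size = 2 * min_distance + 1
    is_max = corr_img == maximum_filter(corr_img, size=size, mode="nearest")
    rr, cc = np.nonzero(is_max & (corr_img > min_value))
    order = np.argsort(corr_img[rr, cc])[::-1]
    picked: list[tuple[int, int]] = []
    for k in order:
        r, c = int(rr[k]), int(cc[k])
        if all(max(abs(r - pr), abs(c - pc)) >= min_distance for pr, pc in picked):
            picked.append((r, c))
        if len(picked) == n_seeds:
            break
    return picked


def _grow_one(
    z: np.ndarray,
    seed: tuple[int, int],
    corr_threshold: float,
    max_area: int,
) -> np.ndarray:
    """Grow one ROI from a seed on z-scored pixel traces (T, H, W).

    Breadth-first with neighbors enqueued in row-major order; each
    frontier pixel is tested once against the current ROI mean trace.
    """
    T, H, W = z.shape
    mask = np.zeros((H, W), dtype=bool)
    mask[seed] = True
    total = z[:, seed[0], seed[1]].copy()  # running sum of member z-traces
    n_px = 1
    seen = {seed}
    queue: deque[tuple[int, int]] = deque()

    def push_neighbors(r: int, c: int) -> None:
        for dr, dc in _NEIGHBORS8:  # row-major offsets
            p = (r + dr, c + dc)
            if 0 <= p[0] < H and 0 <= p[1] < W and p not in seen:
                seen.add(p)
                queue.append(p)

    push_neighbors(*seed)
    while queue and n_px < max_area:
        p = queue.popleft()
        trace = z[:, p[0], p[1]]
        mean_trace = total / n_px
        msd = mean_trace.std()
        psd = trace.std()
        if msd == 0 or psd == 0:
            continue
        r_val = float(np.dot(mean_trace - mean_trace.mean(), trace) / (T * msd * psd))
        if r_val > corr_threshold:
            mask[p] = True
            total += trace
            n_px += 1
            push_neighbors(*p)
    return mask


def grow_rois(
    movie: FluorescenceMovie,
    seeds: list[tuple[int, int]],
    corr_threshold: float = 0.3,
    max_area: int = 400,
    merge_jaccard: float = 0.5,
) -> RoiSet:
    """Seeded region growing on trace correlation.

    From each seed, 8-connected neighbors whose z-scored trace correlates
    with the current ROI mean trace above ``corr_threshold`` are added
    (row-major visit order, capped at ``max_area`` pixels).  Grown masks
    with Jaccard overlap above ``merge_jaccard`` are merged; residual
    overlapping pixels go to the seed with the higher correlation-image
    value (ties broken row-major by seed), so the result is independent of
    the order of the seed list.
    """
    H, W = movie.frame_shape
    for r, c in seeds:
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"seed {(r, c)} outside frame")
        if not np.all(np.isfinite(movie.data[:, r, c])):
            raise ValueError(f"seed {(r, c)} on non-finite pixel")
    x = movie.data
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    z = np.zeros_like(x)
    ok = sd > 0
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]

    order = sorted(range(len(seeds)), key=lambda i: tuple(seeds[i]))
    masks = {i: _grow_one(z, tuple(seeds[i]), corr_threshold, max_area) for i in order}

    # merge near-duplicate masks (two seeds landing in one cell)
    groups = [[i] for i in order]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ma = np.any([masks[i] for i in groups[a]], axis=0)
                mb = np.any([masks[i] for i in groups[b]], axis=0)
                inter = np.logical_and(ma, mb).sum()
                union = np.logical_or(ma, mb).sum()
                if union and inter / union > merge_jaccard:
                    groups[a] = groups[a] + groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    merged = [np.any([masks[i] for i in g], axis=0) for g in groups]
    rep_seed = [min(tuple(seeds[i]) for i in g) for g in groups]

    # resolve residual overlaps by correlation-image value at the seed
    cimg = correlation_image(movie)
    overlap = np.sum(merged, axis=0) > 1
    if overlap.any():
        strength = [cimg[s] for s in rep_seed]
        claim_order = sorted(
            range(len(merged)), key=lambda i: (-strength[i], rep_seed[i])
        )
        taken = np.zeros((H, W), dtype=bool)
        resolved = [None] * len(merged)
        for i in claim_order:
            m = merged[i] & ~(overlap & taken)
            resolved[i] = m
            taken |= merged[i]
        merged = resolved

    keep = [(s, m) for s, m in zip(rep_seed, merged) if m.any()]
    keep.sort(key=lambda sm: sm[0])
    return RoiSet(masks=[m for _, m in keep], frame_shape=(H, W))


def extract_traces(
    movie: FluorescenceMovie,
    rois: RoiSet,
    background: str | None = "annulus",
    annulus_gap: int = 2,
    annulus_width: int = 3,
) -> TraceMatrix:
    """Average pixels within each ROI per frame, with optional background
    subtraction from a surrounding annulus.

    The annulus is a dilation ring (``annulus_gap`` to
    ``annulus_gap + annulus_width`` pixels out) excluding every ROI pixel;
    its per-frame mean is subtracted from the ROI trace, cancelling
    spatially uniform drift.  If exclusion empties the annulus, the global
    non-ROI median frame value is used instead (with a warning).
    """
    if len(rois) == 0:
        return TraceMatrix(
            values=np.zeros((0, movie.n_frames)),
            frame_rate=movie.frame_rate,
            labels=[],
        )
    x = movie.data
    T = movie.n_frames
    all_rois = rois.union()
    out = np.empty((len(rois), T))
    for i, m in enumerate(rois.masks):
        trace = x[:, m].mean(axis=1)
        if background == "annulus":
            outer = binary_dilation(m, iterations=annulus_gap + annulus_width)
            inner = binary_dilation(m, iterations=annulus_gap)
            ring = outer & ~inner & ~all_rois
            if ring.any():
                bg = x[:, ring].mean(axis=1)
            else:
                warnings.warn(
                    f"empty background annulus for ROI {i}; "
                    "using global non-ROI median",
                    stacklevel=2,
                )
                bg = np.median(x[:, ~all_rois], axis=1)
            trace = trace - bg
        elif background is not None:
            raise ValueError("background must be 'annulus' or None")
        out[i] = trace
    return TraceMatrix(values=out, frame_rate=movie.frame_rate, labels=list(rois.labels))
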