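"""Independent brute-force oracles for the imaging operations.

Everything here is written the slow, obvious way — explicit loops, BFS
flood fill, direct separable convolution — deliberately avoiding the
labelled-array and filter routines the implementation uses, so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int, int]]]:
    """26-connected components of a binary mask via BFS."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    components = []
    for start in map(tuple, np.argwhere(mask)):
        if visited[start]:
            continue
        comp = set()
        queue = deque([start])
        visited[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in NEIGHBORS_26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)):
                    if mask[w] and not visited[w]:
                        visited[w] = True
                        queue.append(w)
        components.append(comp)
    return components


def delineate_oracle(
    values: np.ndarray,
    threshold: float,
    voxel_volume_ml: float,
    exclusion: np.ndarray | None = None,
    prior: np.ndarray | None = None,
    min_component_ml: float = 0.1,
) -> np.ndarray:
    """Voxel-by-voxel reimplementation of the isocontour delineation."""
    above = values > threshold
    if exclusion is not None:
        above &= ~np.asarray(exclusion, dtype=bool)
    keep = np.zeros_like(above)
    for comp in flood_fill_components(above):
        if prior is not None:
            selected = any(prior[v] for v in comp)
        else:
            selected = len(comp) * voxel_volume_ml >= min_component_ml
        if selected:
            for v in comp:
                keep[v] = True
    return keep


def jaccard_oracle(a: np.ndarray, b: np.ndarray) -> float:
    inter = union = 0
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    for idx in np.ndindex(a.shape):
        if a[idx] and b[idx]:
            inter += 1
        if a[idx] or b[idx]:
            union += 1
    return inter / union


def gaussian_smooth_oracle(
    arr: np.ndarray, sigma_vox: list[float], truncate: float = 4.0
) -> np.ndarray:
    """Zero-padded separable Gaussian, kernel radius matching the standard
    truncated discrete Gaussian (radius = int(truncate * sigma + 0.5))."""
    out = np.asarray(arr, dtype=float)
    for axis, sigma in enumerate(sigma_vox):
        radius = int(truncate * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-0.5 * (x / sigma) ** 2)
        kernel /= kernel.sum()
        out = np.moveaxis(out, axis, -1)
        padded = np.pad(out, [(0, 0)] * (out.ndim - 1) + [(radius, radius)])
        smoothed = np.zeros_like(out)
        for i, k in enumerate(kernel):
            smoothed += k * padded[..., i : i + out.shape[-1]]
        out = np.moveaxis(smoothed, -1, axis)
    return out


def shape_components_oracle(
    mask_ref: np.ndarray,
    mask_test: np.ndarray,
    spacing,
    fwhm_mm: float = 5.0,
    level: float = 0.5,
) -> dict[str, list[float]]:
    """Signed smoothed-difference components; volumes (mL) per direction."""
    diff = np.asarray(mask_test, dtype=float) - np.asarray(mask_ref, dtype=float)
    sigma_vox = [fwhm_mm * 0.42466090014400953 / s for s in spacing]
    smoothed = gaussian_smooth_oracle(diff, sigma_vox)
    vox_ml = float(np.prod(spacing)) / 1000.0
    out = {}
    for direction, exceed in (
        ("expansion", smoothed > level),
        ("erosion", smoothed < -level),
    ):
        comps = flood_fill_components(exceed)
        out[direction] = sorted(len(c) * vox_ml for c in comps)
    return out


def sd_repeated_oracle(d_values, subject_ids) -> float:
    """Variance-components SD recomputed straight from the formulas."""
    d = np.asarray(d_values, dtype=float)
    subjects = sorted(set(subject_ids))
    groups = [d[[s == subj for s in subject_ids]] for subj in subjects]
    k = len(groups)
    n = d.size
    if n == k:
        return float(np.std(d, ddof=1))
    ms_w = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
    ms_b = sum(len(g) * (g.mean() - d.mean()) ** 2 for g in groups) / (k - 1)
    m0 = (n - sum(len(g) ** 2 for g in groups) / n) / (k - 1)
    sigma_b2 = max(0.0, (ms_b - ms_w) / m0)
    return float(np.sqrt(sigma_b2 + ms_w))
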