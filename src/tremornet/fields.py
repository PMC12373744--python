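"""Random-field utilities on the atlas graph.

Smoothing, smoothness (FWHM) estimation and connected-component labeling.
All functions accept fields as ``(k, n_vertices)`` stacks so callers can
process many maps (e.g. Monte-Carlo null fields) in one shot.  A grid atlas
takes the separable-Gaussian fast path; any other graph falls back to
iterated neighbor-diffusion whose kernel converges to the same Gaussian.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, sparse

from .core import SurfaceAtlas
from .errors import DegenerateDataError

# FWHM = sqrt(8 ln 2) * sigma for a Gaussian kernel
_FWHM_PER_SIGMA = math.sqrt(8.0 * math.log(2.0))


def sigma_from_fwhm(fwhm: float) -> float:
    return fwhm / _FWHM_PER_SIGMA


def smooth_fields(fields: np.ndarray, atlas: SurfaceAtlas, fwhm: float) -> np.ndarray:
    """Smooth each row of ``fields`` to kernel width ``fwhm`` (vertex units)."""
    fields = np.atleast_2d(np.asarray(fields, dtype=float))
    if fwhm <= 1.0:  # below the vertex spacing: nothing to do
        return fields.copy()
    sigma = sigma_from_fwhm(fwhm)
    if atlas.grid_shape is not None:
        h, w = atlas.grid_shape
        arr = fields.reshape(fields.shape[0], h, w)
        # periodic boundary keeps the field stationary (uniform variance)
        out = ndimage.gaussian_filter(arr, sigma=(0.0, sigma, sigma), mode="wrap")
        return out.reshape(fields.shape[0], -1)
    return _diffuse(fields, atlas, sigma)


def _diffuse(fields: np.ndarray, atlas: SurfaceAtlas, sigma: float) -> np.ndarray:
    # one step of x <- (1-lam) x + lam * mean(neighbors) adds lam/2 variance
    # per axis of an equivalent lattice walk, so t = ceil(2 sigma^2 / lam)
    lam = 0.5
    t = max(1, int(math.ceil(2.0 * sigma * sigma / lam)))
    adj = atlas.adjacency().astype(float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    walk = sparse.diags(1.0 / deg) @ adj
    out = fields.copy()
    for _ in range(t):
        out = (1.0 - lam) * out + lam * (walk @ out.T).T
    return out


def smoothing_gain(atlas: SurfaceAtlas, fwhm: float) -> float:
    """Std-dev of unit white noise after smoothing (impulse-response norm)."""
    impulse = np.zeros((1, atlas.n_vertices))
    if atlas.grid_shape is not None:
        h, w = atlas.grid_shape
        center = (h // 2) * w + (w // 2)
    else:
        center = atlas.n_vertices // 2
    impulse[0, center] = 1.0
    kernel = smooth_fields(impulse, atlas, fwhm)
    return float(np.sqrt(np.sum(kernel**2)))


def estimate_fwhm(fields: np.ndarray, atlas: SurfaceAtlas) -> float:
    """Smoothness (FWHM, vertex units) from nearest-neighbor differences.

    Uses the classic relation for a Gaussian autocorrelation function:
    rho(1) = 1 - var(diff) / (2 var), FWHM = sqrt(-2 ln 2 / ln rho(1)).
    The estimate is floored at one vertex spacing (white noise resolves to
    the sampling grid, not to zero width).
    """
    fields = np.atleast_2d(np.asarray(fields, dtype=float))
    fields = fields - fields.mean(axis=1, keepdims=True)
    var = float(np.mean(fields**2))
    if var <= 0:
        raise DegenerateDataError("all fields are constant; smoothness undefined")
    i, j = atlas.edges[:, 0], atlas.edges[:, 1]
    vardiff = float(np.mean((fields[:, i] - fields[:, j]) ** 2))
    rho = 1.0 - vardiff / (2.0 * var)
    if rho <= 0.25:  # at/below the white-noise floor
        return 1.0
    return max(1.0, math.sqrt(-2.0 * math.log(2.0) / math.log(rho)))


def label_components(mask: np.ndarray, atlas: SurfaceAtlas) -> tuple[np.ndarray, int]:
    """Connected components of ``mask`` under atlas adjacency.

    Returns ``(labels, n)`` with labels 1..n on masked vertices, 0 elsewhere
    (the ndimage.label convention).
    """
    mask = np.asarray(mask, dtype=bool)
    if atlas.grid_shape is not None:
        lab, n = ndimage.label(mask.reshape(atlas.grid_shape))
        return lab.ravel(), int(n)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.zeros(mask.size, dtype=np.int32), 0
    sub = atlas.adjacency()[idx][:, idx]
    n, labels = sparse.csgraph.connected_components(sub, directed=False)
    out = np.zeros(mask.size, dtype=np.int32)
    out[idx] = labels + 1
    return out, int(n)


def max_component_size(mask: np.ndarray, atlas: SurfaceAtlas) -> int:
    labels, n = label_components(mask, atlas)
    if n == 0:
        return 0
    return int(np.bincount(labels[labels > 0]).max())
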