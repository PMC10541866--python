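"""Isotropic 3D gray-level co-occurrence matrices (GLCMs).

The co-occurrence matrix is pooled over all directions at a fixed voxel
distance: for each in-ROI reference voxel, its neighbours are the voxels on
the cubic (Chebyshev) shell at exactly that distance — the hollow surface of
a cube of half-width ``d``, with ``24 d**2 + 2`` offsets. Ordered gray-level
pairs are accumulated over the full negation-closed shell, so the matrix is
symmetric by construction. At the ROI border only voxels inside the ROI (and
inside the image grid) count; there is no padding.

Intensities are quantized to ``G`` uniform bins over the in-ROI min–max range
before counting. A constant ROI maps to level 0 everywhere and yields the
degenerate single-cell matrix p(0,0)=1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volumes import IntensityVolume, ROIMask


@dataclass
class QuantizedVolume:
    """Gray levels in [0, G-1] inside the mask; undefined (-1) outside."""

    data: np.ndarray  # int array, -1 outside mask
    G: int
    mask: np.ndarray


@dataclass
class GLCMatrix:
    """G x G symmetric normalized co-occurrence matrix at distance d."""

    p: np.ndarray
    d: int
    G: int
    raw_count: int
    label_id: int | None = None

    @property
    def degenerate(self) -> bool:
        return self.raw_count == 0

    def to_tsv(self, path: str | Path) -> None:
        header = f"# label={self.label_id} d={self.d} G={self.G} raw_count={self.raw_count}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.p, delimiter="\t", fmt="%.12g")


def quantize(volume: IntensityVolume, mask: ROIMask, G: int = 32) -> QuantizedVolume:
    """Uniformly bin in-mask intensities into G levels over their min-max range.

    The in-mask maximum maps to level G-1; a constant ROI maps entirely to
    level 0.
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = volume.data[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(volume.data.shape, -1, dtype=np.int32)
    if hi == lo:
        out[m] = 0
    else:
        levels = np.floor((vals - lo) / (hi - lo) * G).astype(np.int32)
        np.clip(levels, 0, G - 1, out=levels)  # the max value lands in bin G
        out[m] = levels
    return QuantizedVolume(data=out, G=int(G), mask=m)


def shell_offsets(d: int) -> np.ndarray:
    """Integer offsets (dx, dy, dz) with Chebyshev norm exactly d.

    Returns an (n, 3) array with n = (2d+1)^3 - (2d-1)^3 = 24 d^2 + 2,
    closed under negation.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    rng = np.arange(-d, d + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    cheb = np.abs(offs).max(axis=1)
    return offs[cheb == d]


def _half_shell(d: int) -> np.ndarray:
    """One offset per +/- pair (lexicographically positive representative)."""
    offs = shell_offsets(d)
    key = offs[:, 0] * 1000000 + offs[:, 1] * 1000 + offs[:, 2]
    return offs[key > 0]


def compute_glcm(
    q: QuantizedVolume, mask: ROIMask, d: int, label_id: int | None = None
) -> GLCMatrix:
    """Accumulate ordered gray-level pairs over the Chebyshev shell at distance d.

    Counts every (level(v), level(v+o)) with both v and v+o in-mask and
    in-grid, over all shell offsets o; normalizes by the total pair count.
    A ROI with no valid pairs yields the all-zero matrix flagged degenerate.
    """
    if d < 1:
        raise ValueError("distance must be >= 1")
    m = mask.data
    if q.data.shape != m.shape:
        raise ValueError("quantized volume and mask grids differ")
    G = q.G
    levels = q.data
    counts = np.zeros((G, G), dtype=np.int64)
    shape = m.shape
    # half shell + transpose: the shell is negation-closed, so each unordered
    # pair contributes one count in each direction
    for off in _half_shell(d):
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        valid = m[src] & m[dst]
        if not valid.any():
            continue
        a = levels[src][valid]
        b = levels[dst][valid]
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T
    raw = int(counts.sum())
    p = counts / raw if raw > 0 else counts.astype(np.float64)
    return GLCMatrix(p=p, d=int(d), G=G, raw_count=raw, label_id=label_id)


def compute_glcm_bruteforce(
    q: QuantizedVolume, mask: ROIMask, d: int
) -> GLCMatrix:
    """Naive triple-loop reference implementation (for oracle tests)."""
    m = mask.data
    G = q.G
    levels = q.data
    counts = np.zeros((G, G), dtype=np.int64)
    nx, ny, nz = m.shape
    offs = shell_offsets(d)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not m[x, y, z]:
                    continue
                for ox, oy, oz in offs:
                    u, v, w = x + ox, y + oy, z + oz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and m[u, v, w]:
                        counts[levels[x, y, z], levels[u, v, w]] += 1
    raw = int(counts.sum())
    p = counts / raw if raw > 0 else counts.astype(np.float64)
    return GLCMatrix(p=p, d=int(d), G=G, raw_count=raw)


def sparsity(m: GLCMatrix) -> float:
    """Fraction of zero entries among the G x G matrix entries."""
    return float(np.count_nonzero(m.p == 0) / m.p.size)
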