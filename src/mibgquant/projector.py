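"""Parallel-beam projector/backprojector pair for emission tomography.

The projector models an idealized parallel-hole collimator rotating in the
transaxial (y, x) plane: a view at angle ``theta`` is obtained by rotating
every transaxial slice by ``-theta`` about the slice center with bilinear
interpolation and summing along the x axis.  Each view is therefore a
(n_slices, n_bins) array indexed by (axial position, transverse bin).

No attenuation, scatter, or depth-dependent response is modeled.

The per-view operation is assembled once as a sparse matrix acting on
flattened slices, so the backprojector is the exact adjoint of the forward
projector — a property the multiplicative EM update relies on.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["ParallelProjector"]


def _rotation_matrix(n: int, theta_rad: float) -> sparse.csr_array:
    """Sparse bilinear in-plane rotation of an (n, n) slice about its center.

    Rows index output pixels (flattened), columns input pixels.  Output
    pixels whose source falls outside the grid get empty rows, so mass near
    the corners is clipped; phantoms are expected to live inside the
    inscribed circle, where rotation conserves counts to interpolation
    accuracy.
    """
    c = (n - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # inverse mapping: source coordinate of each output pixel
    cos_t, sin_t = np.cos(theta_rad), np.sin(theta_rad)
    ys = c + cos_t * (yy - c) - sin_t * (xx - c)
    xs = c + sin_t * (yy - c) + cos_t * (xx - c)

    y0 = np.floor(ys).astype(np.int64)
    x0 = np.floor(xs).astype(np.int64)
    fy = ys - y0
    fx = xs - x0

    rows, cols, vals = [], [], []
    out_idx = (yy * n + xx).ravel()
    for dy, dx, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yi = (y0 + dy).ravel()
        xi = (x0 + dx).ravel()
        wi = w.ravel()
        ok = (yi >= 0) & (yi < n) & (xi >= 0) & (xi < n) & (wi > 0)
        rows.append(out_idx[ok])
        cols.append(yi[ok] * n + xi[ok])
        vals.append(wi[ok])

    mat = sparse.coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n),
    )
    return mat.tocsr()


class ParallelProjector:
    """Matched parallel-beam forward/backprojector on an (nz, n, n) grid.

    Parameters
    ----------
    n : int
        In-plane grid size (slices are n x n; each view has n transverse bins).
    angles_deg : array-like
        View angles in degrees, strictly increasing over [0, 360).
    """

    _cache: dict[tuple, "ParallelProjector"] = {}

    def __init__(self, n: int, angles_deg) -> None:
        self.n = int(n)
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        summer = sparse.csr_array(
            (np.ones(n * n), (np.repeat(np.arange(n), n), np.arange(n * n))),
            shape=(n, n * n),
        )
        # view matrix: (n bins, n*n pixels) = sum over x of the rotated slice
        self._view_mats = [
            summer @ _rotation_matrix(n, -np.deg2rad(a)) for a in self.angles_deg
        ]
        self._view_mats_T = [m.T.tocsr() for m in self._view_mats]
        self._stacked: dict[tuple, tuple] = {}

    def _stacked_ops(self, idx: tuple):
        """Vertically stacked view matrices for a fixed view subset."""
        if idx not in self._stacked:
            m = sparse.vstack([self._view_mats[v] for v in idx]).tocsr()
            self._stacked[idx] = (m, m.T.tocsr())
        return self._stacked[idx]

    @classmethod
    def cached(cls, n: int, angles_deg) -> "ParallelProjector":
        key = (int(n), tuple(np.round(np.asarray(angles_deg, float), 9)))
        if key not in cls._cache:
            cls._cache[key] = cls(n, angles_deg)
        return cls._cache[key]

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    def forward(self, volume: np.ndarray, view_idx=None) -> np.ndarray:
        """Project a (nz, n, n) volume into (n_views, nz, n) line integrals."""
        vol = np.asarray(volume, dtype=float)
        nz = vol.shape[0]
        flat = vol.reshape(nz, -1)
        idx = tuple(range(self.n_views)) if view_idx is None else tuple(view_idx)
        m, _ = self._stacked_ops(idx)
        # (n_views*n, n*n) @ (n*n, nz) -> (n_views*n bins, nz)
        out = (m @ flat.T).T.reshape(nz, len(idx), self.n)
        return np.ascontiguousarray(np.moveaxis(out, 1, 0))

    def back(self, views: np.ndarray, view_idx=None) -> np.ndarray:
        """Adjoint of :meth:`forward`; views is (n_views_used, nz, n)."""
        views = np.asarray(views, dtype=float)
        nz = views.shape[1]
        idx = tuple(range(self.n_views)) if view_idx is None else tuple(view_idx)
        _, mt = self._stacked_ops(idx)
        stacked = np.moveaxis(views, 0, 1).reshape(nz, len(idx) * self.n)
        flat = (mt @ stacked.T).T
        return flat.reshape(nz, self.n, self.n)
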