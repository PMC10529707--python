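"""Uniform staggered (MAC) Cartesian grids.

Velocity component ``d`` lives on faces normal to axis ``d`` (one extra entry
along that axis, boundary faces included); pressure and scalars live at cell
centers.  The box boundary is free-slip: normal velocity is zero on the
boundary faces and tangential components satisfy a zero normal derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CartesianGrid"]


@dataclass(frozen=True)
class CartesianGrid:
    """Uniform Cartesian grid with equal spacing in all directions."""

    n: tuple            # cells per axis
    h: float            # spacing, cm
    origin: tuple       # coordinate of the lower box corner, cm

    @property
    def dim(self) -> int:
        return len(self.n)

    @property
    def extent(self) -> tuple:
        return tuple(nd * self.h for nd in self.n)

    def face_shape(self, d: int) -> tuple:
        return tuple(nd + (1 if e == d else 0) for e, nd in enumerate(self.n))

    def zero_velocity(self) -> list:
        return [np.zeros(self.face_shape(d)) for d in range(self.dim)]

    def zero_cells(self) -> np.ndarray:
        return np.zeros(self.n)

    def cell_axes(self) -> list:
        return [self.origin[d] + (np.arange(self.n[d]) + 0.5) * self.h
                for d in range(self.dim)]

    def cell_centers(self) -> np.ndarray:
        """(N, dim) array of all cell-center coordinates (C order)."""
        mesh = np.meshgrid(*self.cell_axes(), indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def face_coord(self, d: int, points: np.ndarray) -> np.ndarray:
        """Fractional grid coordinates of physical points in the index space
        of the component-d face array."""
        g = (points - np.asarray(self.origin)) / self.h
        g = g.copy()
        for e in range(self.dim):
            if e != d:
                g[:, e] -= 0.5
        return g

    def divergence(self, u: list) -> np.ndarray:
        div = np.zeros(self.n)
        for d in range(self.dim):
            hi = [slice(None)] * self.dim
            lo = [slice(None)] * self.dim
            hi[d] = slice(1, None)
            lo[d] = slice(0, -1)
            div += (u[d][tuple(hi)] - u[d][tuple(lo)]) / self.h
        return div

    def cell_velocity(self, u: list) -> np.ndarray:
        """Cell-centered velocity vectors, shape n + (dim,)."""
        out = np.empty(self.n + (self.dim,))
        for d in range(self.dim):
            hi = [slice(None)] * self.dim
            lo = [slice(None)] * self.dim
            hi[d] = slice(1, None)
            lo[d] = slice(0, -1)
            out[..., d] = 0.5 * (u[d][tuple(hi)] + u[d][tuple(lo)])
        return out

    def max_cfl(self, u: list, dt: float) -> float:
        vmax = max(float(np.max(np.abs(ud))) for ud in u)
        return vmax * dt / self.h
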