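"""Rule-based myocardial fiber architecture.

Per-element orthonormal fiber/sheet/sheet-normal triads from the transmural
helix rule: the fiber lies in the local circumferential-longitudinal plane at
a helix angle varying linearly with wall depth from -60 deg at the
endocardium to +60 deg at the epicardium.  The sheet direction is purely
transmural (a zero sheet angle; with the sheet and fiber-sheet moduli null in
the passive set this choice does not affect stress and is the simplest safe
one).  The unloaded sarcomere length rises linearly from 1.78 um at the
endocardium to 1.91 um at the epicardium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VolumetricMesh, GeometryError

__all__ = ["FiberField", "assign_fiber_field", "assign_sarcomere_reference",
           "LR_ENDO", "LR_EPI"]

LR_ENDO = 1.78   # um, unloaded sarcomere length at the endocardium
LR_EPI = 1.91    # um, at the epicardium


@dataclass
class FiberField:
    """Per-element reference fiber (f0), sheet (s0), sheet-normal (n0), lr (um)."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray
    lr: np.ndarray

    def check_orthonormal(self, tol: float = 1e-10) -> None:
        for v in (self.f0, self.s0, self.n0):
            if np.abs(np.linalg.norm(v, axis=1) - 1.0).max() > tol:
                raise ValueError("fiber triad vectors are not unit length")
        for u, v in ((self.f0, self.s0), (self.f0, self.n0), (self.s0, self.n0)):
            if np.abs(np.einsum("ei,ei->e", u, v)).max() > tol:
                raise ValueError("fiber triad is not orthogonal")


def _element_transmural(mesh: VolumetricMesh) -> np.ndarray:
    if mesh.transmural_coord is None:
        raise GeometryError("mesh is missing the transmural coordinate field")
    return mesh.transmural_coord[mesh.elements].mean(axis=1)


def _element_transmural_gradient(mesh: VolumetricMesh) -> np.ndarray:
    """P1 gradient of the transmural field over the corner tetrahedra."""
    w = mesh.transmural_coord
    c = mesh.elements[:, :4]
    x = mesh.nodes[c]
    M = x[:, 1:] - x[:, :1]              # (E, 3, 3) rows x_i - x_0
    dv = w[c[:, 1:]] - w[c[:, :1]]
    return np.linalg.solve(M, dv[..., None])[..., 0]


def assign_fiber_field(mesh: VolumetricMesh, endo_angle: float = -60.0,
                       epi_angle: float = 60.0) -> FiberField:
    """Helix-rule fiber triads, linear in the transmural coordinate.

    The local basis is circumferential (about the long axis), longitudinal
    (completing the wall-tangent plane) and transmural (from the gradient of
    the wall-depth field).  Elements with a degenerate circumferential
    direction at the apex pole copy the triad of the nearest well-defined
    element, so emitted vectors are always unit length.
    """
    w_e = _element_transmural(mesh)
    grad = _element_transmural_gradient(mesh)
    cen = mesh.element_centroids()

    e_t = grad.copy()
    nrm = np.linalg.norm(e_t, axis=1)
    bad_t = nrm < 1e-8
    e_t[~bad_t] /= nrm[~bad_t, None]

    c_raw = np.stack([-cen[:, 1], cen[:, 0], np.zeros(len(cen))], axis=1)
    cnorm = np.linalg.norm(c_raw, axis=1)
    scale = np.linalg.norm(mesh.nodes[:, :2], axis=1).max()
    bad_c = cnorm < 1e-3 * scale
    ok = ~(bad_t | bad_c)
    c_hat = np.zeros_like(c_raw)
    c_hat[ok] = c_raw[ok] / cnorm[ok, None]
    # project out the transmural component, renormalize
    c_hat[ok] -= np.einsum("ei,ei->e", c_hat[ok], e_t[ok])[:, None] * e_t[ok]
    cn = np.linalg.norm(c_hat[ok], axis=1)
    ok_idx = np.flatnonzero(ok)
    degenerate = ok_idx[cn < 1e-6]
    c_hat[ok_idx] /= np.maximum(cn, 1e-12)[:, None]
    ok[degenerate] = False

    l_hat = np.cross(e_t, c_hat)

    alpha = np.deg2rad(endo_angle + (epi_angle - endo_angle) * w_e)
    f0 = np.cos(alpha)[:, None] * c_hat + np.sin(alpha)[:, None] * l_hat
    s0 = e_t
    n0 = np.cross(f0, s0)

    if np.any(~ok):
        tree = cKDTree(cen[ok])
        _, nearest = tree.query(cen[~ok])
        src = np.flatnonzero(ok)[nearest]
        f0[~ok], s0[~ok], n0[~ok] = f0[src], s0[src], n0[src]

    # exact renormalization against accumulated round-off
    f0 /= np.linalg.norm(f0, axis=1)[:, None]
    s0 -= np.einsum("ei,ei->e", s0, f0)[:, None] * f0
    s0 /= np.linalg.norm(s0, axis=1)[:, None]
    n0 = np.cross(f0, s0)

    field = FiberField(f0=f0, s0=s0, n0=n0,
                       lr=assign_sarcomere_reference(mesh))
    field.check_orthonormal()
    return field


def assign_sarcomere_reference(mesh: VolumetricMesh) -> np.ndarray:
    """Unloaded sarcomere length per element: lr = 1.78 + 0.13 w (um)."""
    w_e = _element_transmural(mesh)
    return LR_ENDO + (LR_EPI - LR_ENDO) * w_e
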