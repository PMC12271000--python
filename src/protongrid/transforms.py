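"""Homogeneous 4x4 placement transforms.

Two rigid placements are used when commissioning the collimator inside a
treatment planning system:

* the *beam transform*, which carries an object from the nominal beam frame
  (gantry 0, couch 0) to an arbitrary gantry/couch orientation plus an
  isocenter translation, and
* the *cylinder transform*, which places a divergence-matched optimization
  cylinder by tilting it by the per-axis divergence angles and translating it
  to its aperture.

Angles are degrees externally and converted to radians only here, at the
single boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransformMatrix", "BeamGeometry", "beam_transform", "cylinder_transform"]


@dataclass
class TransformMatrix:
    """Homogeneous 4x4 placement operator.

    The last row is pinned to (0, 0, 0, 1).  For a rigid placement the
    upper-left 3x3 block must be a proper rotation (orthonormal, det = +1).
    """

    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (4, 4):
            raise ValueError("transform must be 4x4")
        if not np.allclose(self.m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")

    @property
    def rotation(self) -> np.ndarray:
        return self.m[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.m[:3, 3]

    def is_rigid(self, tol: float = 1e-9) -> bool:
        """True when the rotation block is orthonormal with det +1."""
        r = self.rotation
        return (np.allclose(r @ r.T, np.eye(3), atol=tol)
                and abs(np.linalg.det(r) - 1.0) < tol)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of points (or a single 3-vector)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "TransformMatrix") -> "TransformMatrix":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return TransformMatrix(self.m @ other.m)

    def inverse(self) -> "TransformMatrix":
        inv = np.eye(4)
        r = self.rotation
        inv[:3, :3] = r.T
        inv[:3, 3] = -r.T @ self.translation
        return TransformMatrix(inv)


@dataclass
class BeamGeometry:
    """Gantry/couch orientation, isocenter translation, and snout extension.

    Angles are in degrees (interpreted modulo 360); ``isocenter_translation``
    is the (Bx, By, Bz) column of the placement matrix in mm; snout_extension
    is the distance (mm) of the accessory mount plane from isocenter along
    the beam axis.
    """

    gantry_angle: float = 0.0
    couch_angle: float = 0.0
    isocenter_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    snout_extension: float = 235.0

    def __post_init__(self):
        self.isocenter_translation = np.asarray(self.isocenter_translation, dtype=float)
        if self.isocenter_translation.shape != (3,):
            raise ValueError("isocenter_translation must be a 3-vector")


def beam_transform(geom: BeamGeometry) -> TransformMatrix:
    """Rigid placement for a beam at gantry angle θg and couch angle θc.

    The rotation block is::

        [ cosθg·cosθc   −sinθg·cosθc   sinθc ]
        [ sinθg          cosθg         0     ]
        [ −cosθg·sinθc   sinθg·sinθc   cosθc ]

    with the translation column equal to the isocenter translation.  The
    result is always a proper rigid transform.
    """
    tg = np.deg2rad(geom.gantry_angle % 360.0)
    tc = np.deg2rad(geom.couch_angle % 360.0)
    cg, sg = np.cos(tg), np.sin(tg)
    cc, sc = np.cos(tc), np.sin(tc)
    m = np.eye(4)
    m[:3, :3] = [[cg * cc, -sg * cc, sc],
                 [sg, cg, 0.0],
                 [-cg * sc, sg * sc, cc]]
    m[:3, 3] = geom.isocenter_translation
    return TransformMatrix(m)


def cylinder_transform(tilt_x: float, tilt_y: float,
                       translation: np.ndarray) -> TransformMatrix:
    """Rigid placement of a divergence-matched optimization cylinder.

    The cylinder is tilted by the per-axis divergence angles and moved to its
    aperture: rotation R_x(θy) · R_z(θx) followed by the translation
    (Cx, Cy, Cz).  This is the proper-rotation composition consistent with
    the stated per-axis divergences (a literal transcription of the commonly
    printed matrix has one inconsistent sign in its (2,1) element and is not
    orthonormal; a rigid placement requires the form used here).

    Parameters
    ----------
    tilt_x, tilt_y : float
        Divergence tilts in degrees.
    translation : (3,) float
        (Cx, Cy, Cz) in mm.
    """
    ax = np.deg2rad(tilt_x)
    ay = np.deg2rad(tilt_y)
    rz = np.array([[np.cos(ax), -np.sin(ax), 0.0],
                   [np.sin(ax), np.cos(ax), 0.0],
                   [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0],
                   [0.0, np.cos(ay), -np.sin(ay)],
                   [0.0, np.sin(ay), np.cos(ay)]])
    m = np.eye(4)
    m[:3, :3] = rx @ rz
    m[:3, 3] = np.asarray(translation, dtype=float)
    return TransformMatrix(m)
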