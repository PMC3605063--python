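"""Angle arithmetic on the ring.

Positions live on the midline of an annular arena and are represented as
angles in [0, 2*pi).  Increasing angle is anti-clockwise (ACW); "clockwise"
(CW) therefore means decreasing angle.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles into [0, 2*pi).  Idempotent.

    Guards the float edge case where ``x % (2*pi)`` of a tiny negative number
    rounds up to exactly 2*pi.
    """
    w = np.asarray(theta, dtype=float) % TWO_PI
    return np.where(w == TWO_PI, 0.0, w)


def wrap_signed(delta):
    """Wrap angular differences into (-pi, pi]."""
    d = (np.asarray(delta, dtype=float) + np.pi) % TWO_PI - np.pi
    return np.where(d == -np.pi, np.pi, d)


def angular_separation(theta_a, theta_b):
    """Unsigned ring distance between two angles, in [0, pi].

    Symmetric in its arguments: min(|d|, 2*pi - |d|) of the raw difference.
    Computed without an intermediate shift so that exact separations (zone
    boundaries) are preserved.
    """
    d = np.abs(np.asarray(theta_b, dtype=float) - np.asarray(theta_a, dtype=float)) % TWO_PI
    return np.minimum(d, TWO_PI - d)


def signed_ahead(focal_theta, focal_orientation, other_theta):
    """Distance of ``other`` ahead of the focal along its heading, in [0, 2*pi).

    ``focal_orientation`` is +1 for ACW travel, -1 for CW.  A value of 0 means
    the other individual sits exactly at the focal position.
    """
    return (np.asarray(focal_orientation, dtype=float)
            * (np.asarray(other_theta, dtype=float) - np.asarray(focal_theta, dtype=float))) % TWO_PI
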