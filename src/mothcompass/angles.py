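"""Compass-angle conventions and elementary circular arithmetic.

All angles in this package are **compass degrees**: 0° = geographical north,
increasing clockwise (N -> E -> S -> W), reduced modulo 360.  This matches the
heading convention of the flight-simulator encoder and the sky-rotation angle
of the electrophysiology rig (0°/360° = heading north, 90° = east).

Internally, trigonometry represents a compass angle ``a`` by the unit vector
``(cos a, sin a)`` *in the compass frame* (first component points north,
second east).  ``atan2(sin_part, cos_part)`` then returns the compass angle
directly.  This is the single compass<->math conversion used everywhere; the
mathematical (counter-clockwise-from-east) angle is ``90 - a`` if ever needed
for plotting.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap360",
    "wrap180",
    "compass_to_math",
    "math_to_compass",
    "to_unit_vectors",
    "vector_to_compass",
    "circ_diff",
    "directed_turn",
]


def wrap360(a):
    """Reduce angle(s) in degrees to [0, 360)."""
    return np.asarray(a, dtype=float) % 360.0


def wrap180(a):
    """Reduce angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


def compass_to_math(a):
    """Compass degrees (0=N, CW) -> mathematical degrees (0=E, CCW)."""
    return wrap360(90.0 - np.asarray(a, dtype=float))


def math_to_compass(a):
    """Mathematical degrees (0=E, CCW) -> compass degrees (0=N, CW)."""
    return wrap360(90.0 - np.asarray(a, dtype=float))


def to_unit_vectors(a_deg):
    """Compass degrees -> (north_component, east_component) unit vectors."""
    rad = np.deg2rad(np.asarray(a_deg, dtype=float))
    return np.cos(rad), np.sin(rad)


def vector_to_compass(north, east):
    """Inverse of :func:`to_unit_vectors`; returns compass degrees in [0, 360)."""
    return wrap360(np.rad2deg(np.arctan2(east, north)))


def circ_diff(a, b):
    """Signed shortest-arc difference ``a - b`` in (-180, 180] degrees.

    Positive = ``a`` lies clockwise of ``b``.  Antisymmetric except at
    exactly 180°, where +180 is returned for both orders.
    """
    return wrap180(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def directed_turn(frm, to, sense="cw"):
    """Magnitude in [0, 360) of the turn from ``frm`` to ``to`` in a fixed sense.

    ``sense='cw'`` measures the clockwise (compass-increasing) arc,
    ``sense='ccw'`` the anticlockwise arc.  A moth reorienting from a mean
    heading of 168° to 355° has turned 187° clockwise (but only 173° along the
    shortest arc); from 341° to 167° is a 174° anticlockwise turn.  Use
    :func:`circ_diff` when the shortest arc is wanted instead.
    """
    if sense == "cw":
        return float(wrap360(np.asarray(to, dtype=float) - np.asarray(frm, dtype=float)))
    if sense == "ccw":
        return float(wrap360(np.asarray(frm, dtype=float) - np.asarray(to, dtype=float)))
    raise ValueError(f"sense must be 'cw' or 'ccw', got {sense!r}")
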