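"""Centralized unit conventions and conversions.

Internal computations use SI with angles in radians; interfaces that mirror
the platform's conventions use degrees (perturbation amplitudes, platform
angles) and centimetres (CoP displacements).  All conversions go through
this module so the convention lives in one place.

Sign conventions
----------------
==============  ==========================================================
Quantity        Positive direction
==============  ==========================================================
DP angle        dorsiflexion (toes up)
IE angle        eversion (sole outward)
DP torque       plantarflexion-resisting: a dorsiflexing perturbation
                produces a positive differential torque
IE torque       inversion-resisting, mirror of the above
CoP AP          anterior (toward the toes)
CoP ML          global frame: toward the subject's right; per plate: toward
                the plate's IE-positive side
==============  ==========================================================
"""

import numpy as np

#: standard gravity (m/s^2), used for bodyweight <-> load conversions
G = 9.80665


def deg2rad(x):
    return np.deg2rad(x)


def rad2deg(x):
    return np.rad2deg(x)


def cm2m(x):
    return np.asarray(x) / 100.0


def m2cm(x):
    return np.asarray(x) * 100.0


def kg2n(mass_kg):
    """Weight (N) of a mass (kg)."""
    return np.asarray(mass_kg) * G
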