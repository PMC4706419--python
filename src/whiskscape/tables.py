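"""Published parameter tables for the rat macrovibrissal array.

All angles are in degrees, lengths in mm.  Azimuth convention throughout the
package: 0° points caudal, 180° rostral, measured in the horizontal plane of
the head.  Rows run A (dorsal) to E (ventral); column 0 is the Greek column
(alpha..delta, the caudal-most whiskers of rows A-D), columns 1-6 run rostral.
"""

from __future__ import annotations

ROWS = ("A", "B", "C", "D", "E")
GREEK = 0  # column index of the Greek whiskers

GREEK_NAMES = {"A": "alpha", "B": "beta", "C": "gamma", "D": "delta"}

#: whisker arc lengths, mm, keyed by (row, column)
LENGTHS_MM = {
    ("A", 0): 46.40, ("A", 1): 38.47, ("A", 2): 30.55, ("A", 3): 22.61, ("A", 4): 14.68,
    ("B", 0): 48.62, ("B", 1): 40.69, ("B", 2): 32.76, ("B", 3): 24.83, ("B", 4): 16.90,
    ("B", 5): 8.97,
    ("C", 0): 50.85, ("C", 1): 42.92, ("C", 2): 34.98, ("C", 3): 27.05, ("C", 4): 19.12,
    ("C", 5): 11.19, ("C", 6): 3.26,
    ("D", 0): 53.07, ("D", 1): 45.14, ("D", 2): 37.21, ("D", 3): 29.28, ("D", 4): 21.35,
    ("D", 5): 13.41, ("D", 6): 5.48,
    ("E", 1): 47.36, ("E", 2): 39.43, ("E", 3): 31.50, ("E", 4): 23.57, ("E", 5): 15.64,
    ("E", 6): 7.70,
}

#: the 31 valid (row, column) cells of one mystacial pad, in canonical order
VALID_CELLS = tuple(sorted(LENGTHS_MM, key=lambda rc: (rc[0], rc[1])))

#: per-row whisking kinematics: elevation phi = phi_intercept + phi_slope * dtheta,
#: roll zeta = zeta_rest + zeta_slope * dtheta.  Bounds are the published error
#: bounds used by the sensitivity analysis.
KINEMATIC_ROWS = {
    #        phi0    +/-    slope   zslope  +/-
    "A": dict(phi_intercept=56.0, phi_bound=5.3, phi_slope=0.12,
              zeta_slope=-0.76, zeta_bound=0.08),
    "B": dict(phi_intercept=25.0, phi_bound=9.4, phi_slope=0.30,
              zeta_slope=-0.25, zeta_bound=0.18),
    "C": dict(phi_intercept=-4.2, phi_bound=6.3, phi_slope=0.30,
              zeta_slope=0.22, zeta_bound=0.22),
    "D": dict(phi_intercept=-27.2, phi_bound=7.7, phi_slope=0.14,
              zeta_slope=0.43, zeta_bound=0.11),
    "E": dict(phi_intercept=-44.0, phi_bound=7.6, phi_slope=0.02,
              zeta_slope=0.73, zeta_bound=0.14),
}

#: (theta_full_retraction, theta_rest, theta_full_protraction) per whisker, deg
REST_ANGLES = {
    ("A", 0): (22.9, 67.9, 167.9),
    ("B", 0): (23.5, 52.5, 152.5),
    ("C", 0): (18.0, 48.0, 148.0),
    ("D", 0): (37.4, 53.4, 153.4),
    ("A", 1): (16.0, 73.0, 168.0),
    ("B", 1): (18.8, 61.8, 156.8),
    ("C", 1): (24.8, 57.8, 152.8),
    ("D", 1): (39.4, 62.4, 157.4),
    ("E", 1): (48.0, 68.0, 163.0),
    ("A", 2): (9.7, 78.7, 168.7),
    ("B", 2): (19.4, 71.4, 161.4),
    ("C", 2): (20.4, 69.4, 159.4),
    ("D", 2): (25.7, 71.7, 161.7),
    ("E", 2): (29.3, 75.3, 165.3),
    ("A", 3): (5.6, 84.6, 169.6),
    ("B", 3): (23.1, 81.1, 166.1),
    ("C", 3): (20.2, 80.2, 165.2),
    ("D", 3): (17.2, 81.2, 166.2),
    ("E", 3): (26.9, 82.9, 167.9),
    ("A", 4): (0.6, 90.6, 170.6),
    ("B", 4): (17.8, 90.8, 170.8),
    ("C", 4): (25.8, 90.8, 170.8),
    ("D", 4): (17.8, 90.8, 170.8),
    ("E", 4): (26.6, 90.6, 170.6),
    ("B", 5): (21.4, 100.4, 175.4),
    ("C", 5): (29.4, 101.4, 176.4),
    ("D", 5): (18.2, 100.2, 175.2),
    ("E", 5): (26.3, 98.3, 173.3),
    ("C", 6): (31.9, 111.9, 181.9),
    ("D", 6): (25.5, 109.5, 179.5),
    ("E", 6): (33.7, 105.7, 175.7),
}

#: large-protraction amplitudes per column (deg from rest): the rostral-most
#: column protracts 70 deg, each more caudal column 5 deg further, Greek 100.
PER_COLUMN_AMPLITUDE = {0: 100.0, 1: 95.0, 2: 90.0, 3: 85.0, 4: 80.0, 5: 75.0, 6: 70.0}

#: basepoint translation over an extreme protraction, mm:
#: (rostral, lateral-outward, dorsal) components.
_TRANS_ROSTRAL = {0: 3.17, 1: 2.87, 2: 2.57, 3: 2.29, 4: 2.03, 5: 1.79, 6: 1.56}
_TRANS_DORSAL = {"A": 2.57, "B": 1.29, "C": 0.0, "D": -1.29, "E": -2.57}

BASEPOINT_TRANSLATIONS = {
    (row, col): (_TRANS_ROSTRAL[col], _TRANS_ROSTRAL[col], _TRANS_DORSAL[row])
    for (row, col) in VALID_CELLS
}


def whisker_name(row: str, col: int) -> str:
    """Conventional name of a whisker cell, e.g. 'C2' or 'gamma'."""
    if col == GREEK:
        return GREEK_NAMES[row]
    return f"{row}{col}"
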