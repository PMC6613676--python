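"""Dower lead-field matrices linking the 12-lead ECG and the vectorcardiogram.

The vectorcardiogram (VCG) axes follow the convention x -> body front,
y -> left side, z with the foot pointing along -z.  Both matrices operate on
the eight independent leads in the fixed order V1..V6, I, II; the remaining
limb leads are linear combinations (Einthoven/Goldberger) and carry no extra
information.

``FORWARD_DOWER`` (8x3) projects a dipole (x, y, z) onto the eight leads
(Dower's image-surface coefficients).  ``INVERSE_DOWER`` (3x8) is the
published Edenbrandt-Pahlm least-squares inverse; it agrees with the
Moore-Penrose pseudoinverse of ``FORWARD_DOWER`` to the printed rounding
(dipole recovery error < 0.1%).
"""

from __future__ import annotations

import numpy as np

#: Order of the independent leads expected by both matrices.
INDEPENDENT_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6", "I", "II")

#: All 12 conventional lead names.
ALL_LEADS: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Forward Dower matrix, shape (8, 3): leads = FORWARD_DOWER @ (x, y, z).
FORWARD_DOWER = np.array([
    [-0.515, 0.157, -0.917],   # V1
    [0.044, 0.164, -1.387],    # V2
    [0.882, 0.098, -1.277],    # V3
    [1.213, 0.127, -0.601],    # V4
    [1.125, 0.127, -0.086],    # V5
    [0.831, 0.076, 0.230],     # V6
    [0.632, -0.235, 0.059],    # I
    [0.235, 1.066, -0.132],    # II
])

#: Inverse Dower matrix (Edenbrandt & Pahlm), shape (3, 8):
#: (x, y, z) = INVERSE_DOWER @ (V1..V6, I, II).
INVERSE_DOWER = np.array([
    [-0.172, -0.074, 0.122, 0.231, 0.239, 0.194, 0.156, -0.010],
    [0.057, -0.019, -0.106, -0.022, 0.041, 0.048, -0.227, 0.887],
    [-0.229, -0.310, -0.246, -0.063, 0.055, 0.108, 0.022, 0.102],
])


def derived_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> dict[str, np.ndarray]:
    """Synthesize III, aVR, aVL, aVF from leads I and II.

    Uses the Einthoven identity III = II - I and the Goldberger
    augmented-lead definitions.
    """
    return {
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }
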