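"""Exact utility formulas for the wet-lab assay readouts.

Pure functions, no I/O; they do not enter the variant pipeline.
"""

from __future__ import annotations

import warnings

__all__ = [
    "tumor_volume",
    "fold_change_ddct",
    "wound_healing_pct",
    "growth_rate_pct",
    "average_optical_density",
]


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Xenograft tumor volume V = 0.5 * L * W^2 (mm^3).

    W is the smaller caliper diameter by convention; reversed inputs are
    swapped with a warning.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("tumor dimensions must be non-negative")
    if width_mm > length_mm:
        warnings.warn("width > length; swapping (W is the smaller diameter)")
        length_mm, width_mm = width_mm, length_mm
    return 0.5 * length_mm * width_mm**2


def fold_change_ddct(
    ct_target_a: float, ct_ref_a: float, ct_target_b: float, ct_ref_b: float
) -> float:
    """Relative expression of condition A vs B by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference) per condition; the fold change is
    2 ** -(dCt_A - dCt_B).
    """
    ddct = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return 2.0 ** (-ddct)


def wound_healing_pct(area_initial: float, area_t: float) -> float:
    """Scratch closure: (initial - current area) / initial * 100%."""
    if area_initial <= 0:
        raise ValueError("initial area must be positive")
    if area_t < 0:
        raise ValueError("area must be non-negative")
    return (area_initial - area_t) / area_initial * 100.0


def growth_rate_pct(od_control: float, od_experimental: float) -> float:
    """Growth inhibition: (control OD - experimental OD) / control OD * 100%."""
    if od_control <= 0:
        raise ValueError("control OD must be positive")
    return (od_control - od_experimental) / od_control * 100.0


def average_optical_density(iod: float, area: float) -> float:
    """AOD = IOD / Area (immunohistochemistry staining intensity)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return iod / area
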