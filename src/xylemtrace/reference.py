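"""Published summary statistics of the original study, used as inputs.

These are the printed per-segment means and model-fit statistics of the
Arabidopsis inflorescence-stem study the pipeline reconstructs.  They serve
two purposes: the in-study arithmetic (percent count reductions, ratio and
R-squared differences) is recomputed from them at run time, and the
synthetic-data defaults are anchored to them.  All derived quantities below
are computed, never stored.
"""

from __future__ import annotations

from .stats import percent_reduction

#: per-segment mean conductive-vessel counts (n = 22 segments)
COUNTS = {
    "px_bf": 61.0, "px_ef": 43.0,
    "mx_bf": 40.0, "mx_ef": 23.0,
    "total_bf": 102.0, "total_ef": 66.0,
}

#: pooled vessel-level mean inner diameters, um (n = 301 paired vessels)
MEAN_DIAMETER_UM = {"bf": 9.43, "ef": 9.66}

#: mean per-segment 100 * K_h / K_ht, percent (n = 22)
KH_KHT_RATIO_PERCENT = {"bf": 20.12, "ef": 33.00}

#: K_h ~ K_ht ordinary-least-squares coefficient of determination
REGRESSION_R2 = {"bf": 0.6706, "ef": 0.8118}

#: coefficient of variation of the per-segment K_h/K_ht ratio
RATIO_CV = {"bf": 0.87, "ef": 0.69}

#: pooled theoretical conductivity, m^4 MPa^-1 s^-1 (n = 22)
KHT = {"bf": 1.18e-10, "ef": 6.14e-11}


def derived_comparisons() -> dict:
    """Recompute the study's headline comparison arithmetic from the inputs."""
    return {
        "px_reduction_percent": percent_reduction(COUNTS["px_bf"], COUNTS["px_ef"]),
        "mx_reduction_percent": percent_reduction(COUNTS["mx_bf"], COUNTS["mx_ef"]),
        "total_reduction_percent": percent_reduction(COUNTS["total_bf"],
                                                     COUNTS["total_ef"]),
        "diameter_shift_um": MEAN_DIAMETER_UM["ef"] - MEAN_DIAMETER_UM["bf"],
        "ratio_difference_percent": (KH_KHT_RATIO_PERCENT["ef"]
                                     - KH_KHT_RATIO_PERCENT["bf"]),
        "r2_difference": REGRESSION_R2["ef"] - REGRESSION_R2["bf"],
        "cv_difference": RATIO_CV["bf"] - RATIO_CV["ef"],
    }
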