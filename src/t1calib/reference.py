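"""Packaged reference correction functions and cohort summary statistics.

These are the published site-specific second-degree MOLLI-based (MC2, static
900 ms RRI) correction equations for three 3-T scanner installations
(institutions "A", "B", "C") from a multi-institution healthy-subject T1
harmonization study, together with that study's per-institution cohort
summaries. They serve as realistic defaults: the reference equations anchor
the synthetic scanner biases, and the summaries let pooled statistics be
reconstructed from per-institution (n, mean, SD) triples.
"""
from __future__ import annotations

from .models import CorrectionFunction

__all__ = [
    "REFERENCE_CORRECTIONS",
    "REFERENCE_COHORT_SUMMARY",
    "REFERENCE_INSTITUTIONS",
]

REFERENCE_INSTITUTIONS = ("A", "B", "C")


def _mc2(institution_id, contrast_state, b, c, d, r2):
    return CorrectionFunction(
        method="MC",
        degree=2,
        rri_mode="static",
        rri_used=900.0,
        coeff_a=0.0,
        coeff_b=b,
        coeff_c=c,
        coeff_d=d,
        r_squared=r2,
        institution_id=institution_id,
        contrast_state=contrast_state,
    )


#: Published MC2-static correction equations, keyed by
#: (institution_id, contrast_state).
REFERENCE_CORRECTIONS = {
    ("A", "native"): _mc2("A", "native", -0.0001376, 1.307912, -85.43315, 0.9982),
    ("B", "native"): _mc2("B", "native", -0.0001273, 1.288508, -83.56056, 0.9984),
    ("C", "native"): _mc2("C", "native", -0.0001360, 1.278690, -78.19730, 0.9984),
    ("A", "post_contrast"): _mc2(
        "A", "post_contrast", -0.0000965, 1.354858, -109.29932, 0.9964
    ),
    ("B", "post_contrast"): _mc2(
        "B", "post_contrast", -0.000072, 1.309827, -97.524167, 0.9967
    ),
    ("C", "post_contrast"): _mc2(
        "C", "post_contrast", -0.000103, 1.337582, -104.943758, 0.9969
    ),
}

#: Published per-institution cohort summaries: (n, mean, SD).
#: Native T1 in ms, ECV in percent; "global" = mean over the 16 AHA
#: segments, "mid_septum" = mean over the mid-septal segments.
REFERENCE_COHORT_SUMMARY = {
    "native_t1_ms": {
        "global": {
            "before": {"A": (28, 1198.7, 32.1), "B": (15, 1217.7, 39.9), "C": (26, 1232.7, 31.1)},
            "after": {"A": (28, 1284.5, 31.5), "B": (15, 1296.5, 39.1), "C": (26, 1291.3, 29.3)},
        },
        "mid_septum": {
            "before": {"A": (28, 1210.7, 35.0), "B": (15, 1227.1, 34.8), "C": (26, 1244.2, 31.5)},
            "after": {"A": (28, 1296.2, 34.2), "B": (15, 1305.6, 33.9), "C": (26, 1302.1, 29.7)},
        },
    },
    "ecv_percent": {
        "global": {
            "before": {"A": (28, 26.6, 1.8), "B": (15, 27.5, 3.6), "C": (26, 27.4, 2.5)},
            "after": {"A": (28, 24.4, 2.2), "B": (15, 25.9, 3.7), "C": (26, 25.4, 2.6)},
        },
        "mid_septum": {
            "before": {"A": (28, 26.7, 1.9), "B": (15, 27.4, 3.1), "C": (26, 27.8, 2.5)},
            "after": {"A": (28, 24.2, 1.9), "B": (15, 25.6, 3.1), "C": (26, 25.8, 2.7)},
        },
    },
}
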