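"""Published two-site cataract coding comparison, bundled as example data.

A published case study of two Kaiser Permanente health systems (KPWA and
KPNW) reported, for the cataract clinical group (phecode 366), the number
of endorsements of each non-rare ICD-10 code at each site together with a
smoothed, person-time-adjusted frequency ratio:

    ratio = ((f_KPWA + 10) / PT_KPWA) / ((f_KPNW + 10) / PT_KPNW)

The sites' person-time totals were not printed, but because the same
person-time ratio ``c = PT_KPNW / PT_KPWA`` multiplies every row, it can be
recovered from the printed columns themselves:  for each row,
``printed_ratio / ((f_A + 10) / (f_B + 10))`` estimates ``c``, and the
median across rows is robust to the two-decimal rounding of the printed
ratios.  :func:`calibrated_ratio` recomputes any row's ratio from the raw
frequencies this way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import smoothed_frequency_ratio

#: Cataract-group code frequencies at the two sites and the published
#: smoothed frequency ratio (site A = KPWA, site B = KPNW).
CATARACT_TABLE = pd.DataFrame(
    [
        ("E08.36", 23, 0, 3.10),
        ("E10.36", 92, 117, 0.75),
        ("E11.36", 3065, 2996, 0.96),
        ("H26.40", 561, 1144, 0.46),
        ("H26.411", 11, 1, 1.79),
        ("H26.491", 3044, 771, 3.67),
        ("H26.492", 3129, 741, 3.93),
        ("H26.493", 3952, 636, 5.76),
        ("H26.499", 70, 0, 7.51),
        ("H26.8", 526, 1323, 0.38),
        ("H26.9", 16704, 15786, 0.99),
        ("H59.021", 47, 14, 2.23),
        ("H59.022", 78, 10, 4.13),
        ("H59.029", 1, 72, 0.13),
        ("Z96.1", 35888, 44526, 0.76),
        ("Z98.41", 3950, 199, 17.79),
        ("Z98.42", 3723, 195, 17.10),
        ("Z98.49", 622, 112, 4.87),
    ],
    columns=["code", "f_A", "f_B", "published_ratio"],
).set_index("code")

KAPPA = 10  # smoothing count used by the published ratio


def person_time_ratio(exclude: str | None = None) -> float:
    """Median estimate of c = PT_B / PT_A from the published rows.

    ``exclude`` drops one code from the calibration so that recomputing that
    code's ratio does not use its own printed value.
    """
    tab = CATARACT_TABLE
    if exclude is not None:
        tab = tab.drop(index=exclude)
    smoothed = (tab["f_A"] + KAPPA) / (tab["f_B"] + KAPPA)
    return float(np.median(tab["published_ratio"] / smoothed))


def calibrated_ratio(code: str) -> float:
    """Recompute one row's smoothed person-time-adjusted frequency ratio
    from the raw frequencies, calibrating person-time from the other rows.

    With c = PT_B / PT_A, the ratio equals c * (f_A + 10) / (f_B + 10);
    we evaluate it through :func:`~codeharmony.detect.smoothed_frequency_ratio`
    with PT_A = 1 / c and PT_B = 1.
    """
    c = person_time_ratio(exclude=code)
    row = CATARACT_TABLE.loc[code]
    result = smoothed_frequency_ratio(
        int(row["f_A"]), int(row["f_B"]), pt_a=1.0 / c, pt_b=1.0, kappa=KAPPA
    )
    return result.ratio
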