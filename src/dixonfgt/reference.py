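"""Published cohort-level reference values for the five Dixon datasets.

These are the printed per-dataset summaries (mean +/- sample SD over 20
breasts in 10 volunteers) from the study this package reimplements;
they serve as inputs to internal-consistency checks and as context in
reports. Per-breast values were published only as a supplementary
document and are not redistributed here; :mod:`dixonfgt.stats` accepts
any CSV in the same per-breast layout.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["TABLE1", "REPEATABILITY", "table1_frame"]

#: Cohort mean and SD by dataset: FGT volume [cm^3], total breast volume
#: [cm^3], %FGT, and the applied signal-intensity correction factor.
TABLE1: dict[str, dict[str, tuple[float, float]]] = {
    "hr-gre-pd":   {"fgt_cm3": (143.7, 63.5),  "total_cm3": (492.6, 299.2),
                    "pct_fgt": (36.3, 16.5),   "c": (1.21, 0.16)},
    "hr-gre-pd-r": {"fgt_cm3": (135.2, 56.2),  "total_cm3": (482.6, 296.2),
                    "pct_fgt": (35.4, 16.2),   "c": (1.07, 0.18)},
    "hr-gre-t1":   {"fgt_cm3": (157.6, 69.5),  "total_cm3": (492.6, 299.2),
                    "pct_fgt": (39.2, 16.3),   "c": (3.27, 0.38)},
    "lr-gre-pd":   {"fgt_cm3": (134.2, 57.8),  "total_cm3": (484.2, 298.6),
                    "pct_fgt": (35.2, 16.5),   "c": (1.14, 0.22)},
    "lr-gre-t1":   {"fgt_cm3": (153.7, 68.8),  "total_cm3": (484.2, 298.6),
                    "pct_fgt": (39.1, 16.1),   "c": (3.36, 0.68)},
    "lr-se-t1":    {"fgt_cm3": (207.3, 109.4), "total_cm3": (484.2, 298.6),
                    "pct_fgt": (47.8, 11.6),   "c": (2.91, 0.63)},
}

#: Published test-retest repeatability between the repeat PD-weighted
#: datasets: coefficient of repeatability and coefficient of variation.
REPEATABILITY: dict[str, dict[str, float]] = {
    "fgt_cm3":   {"cor": 29.4, "cov_pct": 7.6},
    "total_cm3": {"cor": 64.1, "cov_pct": 4.7},
    "pct_fgt":   {"cor": 4.3,  "cov_pct": 4.3},
}


def table1_frame() -> pd.DataFrame:
    """The reference summaries as a tidy DataFrame
    (dataset, measure, mean, sd)."""
    rows = [
        {"dataset": ds, "measure": m, "mean": mu, "sd": sd}
        for ds, measures in TABLE1.items()
        for m, (mu, sd) in measures.items()
    ]
    return pd.DataFrame(rows)
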