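"""Published summary figures of the reference survey analysis.

The Active Survey of Health and Welfare 2000 (Japan) is not publicly
deposited; only summary figures are published.  The per-age-group sample
sizes below are inputs for sample-accounting checks — they let the
grouping pipeline be exercised at the study's exact group sizes without
the raw data.
"""

from __future__ import annotations

__all__ = ["GROUP_SAMPLE_SIZES", "SCALE_MAX_LIKERT_20", "N_NEGATIVE_ITEMS"]

#: Analyzed respondents per age group in the published analysis.
GROUP_SAMPLE_SIZES = {
    "12-19": 2457,
    "20-29": 3748,
    "30-39": 3761,
    "40-49": 3629,
    "50-59": 3569,
    "60-69": 2253,
    "70-79": 1161,
    "80-89": 412,
}

#: Maximum attainable 20-item Likert total (20 items x max score 3).
SCALE_MAX_LIKERT_20 = 60

#: Number of CES-D items that follow the exponential category model.
N_NEGATIVE_ITEMS = 16
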