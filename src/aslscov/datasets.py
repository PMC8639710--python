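"""Built-in reference inputs.

Demographic summary statistics of a published 122-participant, three-site
cognitive-decline perfusion cohort (controls, subjective cognitive decline,
mild cognitive impairment, probable Alzheimer's dementia).  Only the
printed group summaries are stored — means, standard deviations, group
sizes and percentages — so the package's summary-statistics machinery can
re-derive the cohort's test statistics from them.
"""

from __future__ import annotations

from .cohort_stats import GroupSummary, counts_from_percent

__all__ = ["reference_cohort_table"]

GROUPS = ("control", "scd", "mci", "ad")
GROUP_NS = (20, 44, 45, 13)


def reference_cohort_table() -> dict:
    """Group summaries of the reference cognitive-decline cohort.

    Returns a dict with:

    - ``ace3``: GroupSummary of the ACE-III global cognition score (0-100),
    - ``age``: GroupSummary of age in years,
    - ``sex_female_counts``: per-group female counts (from printed
      percentages 80/59/51/23),
    - ``vascular_risk_counts``: per-group counts with aggregated vascular
      risk score >= 2 (from printed percentages 30/36/31/46),
    - ``group_ns``: the group sizes (20, 44, 45, 13).
    """
    ace3 = GroupSummary(
        groups=GROUPS,
        means=(94.6, 91.7, 85.2, 79.2),
        sds=(3.8, 4.9, 7.1, 6.2),
        ns=GROUP_NS,
    )
    age = GroupSummary(
        groups=GROUPS,
        means=(67.4, 69.0, 71.1, 74.9),
        sds=(8.3, 7.7, 7.1, 6.2),
        ns=GROUP_NS,
    )
    return {
        "ace3": ace3,
        "age": age,
        "sex_female_counts": counts_from_percent((80, 59, 51, 23), GROUP_NS),
        "vascular_risk_counts": counts_from_percent((30, 36, 31, 46), GROUP_NS),
        "group_ns": GROUP_NS,
    }
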