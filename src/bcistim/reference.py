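"""Published group-level summary statistics of the reference study.

The raw recordings behind these numbers are not publicly available; the
printed per-group mean (min ~ max) offline BCI accuracies are kept here as a
small reference dataset so pre/post contrasts of the published cohort can be
recomputed.
"""

from __future__ import annotations

__all__ = ["GROUP_ACCURACY", "published_delta"]

#: (arm, group) -> printed mean / range accuracies (%) and group size.
GROUP_ACCURACY = {
    ("sham", "low"): {
        "pre": 53.75, "pre_range": (43.75, 60.0),
        "post": 53.99, "post_range": (43.75, 61.25),
        "n": 6,
    },
    ("sham", "high"): {
        "pre": 71.88, "pre_range": (63.75, 95.0),
        "post": 62.71, "post_range": (47.5, 85.0),
        "n": 6,
    },
    ("vibrotactile", "low"): {
        "pre": 52.5, "pre_range": (47.5, 60.0),
        "post": 61.63, "post_range": (46.25, 76.25),
        "n": 10,
    },
    ("vibrotactile", "high"): {
        "pre": 74.17, "pre_range": (65.0, 78.75),
        "post": 63.75, "post_range": (50.0, 75.0),
        "n": 3,
    },
    ("tdcs", "low"): {
        "pre": 51.12, "pre_range": (46.15, 56.25),
        "post": 56.25, "post_range": (45.0, 67.5),
        "n": 10,
    },
    ("tdcs", "high"): {
        "pre": 75.11, "pre_range": (66.25, 88.75),
        "post": 63.44, "post_range": (48.75, 77.5),
        "n": 4,
    },
}


def published_delta(arm: str, group: str) -> float:
    """Post minus pre mean accuracy (percentage points) at the printed
    2-decimal precision."""
    rec = GROUP_ACCURACY[(arm, group)]
    return round(rec["post"] - rec["pre"], 2)
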