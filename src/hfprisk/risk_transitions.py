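"""Red List category histories: filtering, transition classes, tabulation.

Categories are the ordered set LC < NT < VU < EN < CR < EW < EX, plus the
unranked DD (data deficient) and NE (not evaluated). A species' pair of
categories at the two assessment dates is classified two ways:

* risk class — "low-risk" for species that stayed LC or moved to a lower
  category; "high-risk" for species that kept a threatened/near-threatened
  category or moved to a higher one;
* uplist class — "uplisted" iff the category rank increased, else
  "not-uplisted".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RANKED_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX")
UNRANKED_CATEGORIES = ("DD", "NE")
ALL_CATEGORIES = RANKED_CATEGORIES + UNRANKED_CATEGORIES
RANK = {c: i for i, c in enumerate(RANKED_CATEGORIES)}

LOW_RISK = "low-risk"
HIGH_RISK = "high-risk"
UPLISTED = "uplisted"
NOT_UPLISTED = "not-uplisted"

__all__ = [
    "CategoryHistory",
    "TransitionLabel",
    "filter_species",
    "classify_transition",
    "classify_uplisting",
    "tabulate_transitions",
    "label_catalogue",
    "RANKED_CATEGORIES",
    "RANK",
    "LOW_RISK",
    "HIGH_RISK",
    "UPLISTED",
    "NOT_UPLISTED",
]


@dataclass(frozen=True)
class CategoryHistory:
    species_id: str
    cat_start: str
    cat_end: str

    def __post_init__(self) -> None:
        for cat in (self.cat_start, self.cat_end):
            if cat not in ALL_CATEGORIES:
                raise ValueError(f"unknown Red List category {cat!r}")


@dataclass(frozen=True)
class TransitionLabel:
    species_id: str
    risk_class: str
    uplist_class: str


def filter_species(
    catalogue: list[CategoryHistory],
    exclude_ew_start: bool = True,
) -> tuple[list[CategoryHistory], pd.DataFrame]:
    """Drop species that cannot be analysed; log each exclusion with a reason.

    Excluded: species not evaluated or data deficient at either date, and
    species already extinct (EX — and EW when ``exclude_ew_start`` is set)
    at the start of the period.
    """
    retained: list[CategoryHistory] = []
    log: list[dict[str, str]] = []
    extinct_start = {"EX", "EW"} if exclude_ew_start else {"EX"}
    for rec in catalogue:
        if rec.cat_start == "NE" or rec.cat_end == "NE":
            log.append({"species_id": rec.species_id, "reason": "not evaluated"})
        elif rec.cat_start == "DD" or rec.cat_end == "DD":
            log.append({"species_id": rec.species_id, "reason": "data deficient"})
        elif rec.cat_start in extinct_start:
            log.append({"species_id": rec.species_id, "reason": "extinct at start"})
        else:
            retained.append(rec)
    return retained, pd.DataFrame(log, columns=["species_id", "reason"])


def _require_ranked(cat: str) -> int:
    if cat not in RANK:
        raise ValueError(f"category {cat!r} has no rank")
    return RANK[cat]


def classify_transition(cat_start: str, cat_end: str) -> str:
    """Two-class risk transition for a ranked category pair.

    Low-risk: LC retained, or any downlisting. High-risk: a threatened or
    near-threatened category retained, or any uplisting. Exhaustive and
    mutually exclusive over ranked pairs.
    """
    r0, r1 = _require_ranked(cat_start), _require_ranked(cat_end)
    if r1 < r0 or (r0 == r1 == RANK["LC"]):
        return LOW_RISK
    return HIGH_RISK


def classify_uplisting(cat_start: str, cat_end: str) -> str:
    r0, r1 = _require_ranked(cat_start), _require_ranked(cat_end)
    return UPLISTED if r1 > r0 else NOT_UPLISTED


def label_catalogue(catalogue: list[CategoryHistory]) -> list[TransitionLabel]:
    return [
        TransitionLabel(
            species_id=rec.species_id,
            risk_class=classify_transition(rec.cat_start, rec.cat_end),
            uplist_class=classify_uplisting(rec.cat_start, rec.cat_end),
        )
        for rec in catalogue
    ]


def tabulate_transitions(
    labels: list[TransitionLabel],
    histories: list[CategoryHistory],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Category-by-category count matrix plus headline shares (percent).

    Shares (one decimal, percentages of the analysis set): low-risk,
    high-risk, uplisted, downlisted, and threatened/near-threatened species
    that retained their category.
    """
    if not labels:
        raise ValueError("empty label set")
    if len(labels) != len(histories):
        raise ValueError("labels and histories differ in length")
    n = len(labels)
    cats = list(RANKED_CATEGORIES)
    matrix = pd.DataFrame(0, index=cats, columns=cats, dtype=np.int64)
    matrix.index.name = "initial"
    matrix.columns.name = "final"
    n_up = n_down = n_threat_ret = 0
    for rec in histories:
        matrix.loc[rec.cat_start, rec.cat_end] += 1
        r0, r1 = RANK[rec.cat_start], RANK[rec.cat_end]
        n_up += r1 > r0
        n_down += r1 < r0
        n_threat_ret += r0 == r1 and RANK["NT"] <= r0 <= RANK["CR"]
    n_high = sum(lab.risk_class == HIGH_RISK for lab in labels)
    pct = lambda k: round(100.0 * k / n, 1)
    shares = {
        "n": n,
        "low_risk_pct": pct(n - n_high),
        "high_risk_pct": pct(n_high),
        "uplisted_pct": pct(n_up),
        "downlisted_pct": pct(n_down),
        "threatened_retained_pct": pct(n_threat_ret),
    }
    return matrix, shares
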