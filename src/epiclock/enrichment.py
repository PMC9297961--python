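"""Region and CpG-island enrichment of top CpGs via Fisher's exact test.

For each annotation category (genic region class relative to the closest
TSS, or island status) and each direction of methylation change (hyper /
hypo), a 2x2 table is built against the full annotated array background:

                      selected (direction)   background, not selected
    in category               a                        b
    not in category           c                        d

The two-sided Fisher exact p-value is the standard exact definition: the
sum of probabilities, under the hypergeometric distribution with the
observed margins, of every table at most as probable as the observed one.
The sample odds ratio a*d/(b*c) uses the Haldane 0.5 continuity correction
when a cell is zero (flagged).  Significance stars follow the usual figure
convention: * p<.05, ** p<1e-2, *** p<1e-3, **** p<1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .data import CpGAnnotation, ISLAND_STATUSES, REGION_CLASSES
from .ewas import TopCpGSet

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))

_FIELD_CATEGORIES = {
    "region_class": REGION_CLASSES,
    "island_status": ISLAND_STATUSES,
}


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


@dataclass
class EnrichmentRow:
    category: str
    direction: str
    a: int                     # in category, selected
    b: int                     # in category, background not selected
    c: int                     # not in category, selected
    d: int                     # not in category, background not selected
    odds_ratio: float
    p: float
    stars: str
    haldane_corrected: bool


def _fisher_row(category: str, direction: str, a: int, b: int, c: int, d: int) -> EnrichmentRow:
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return EnrichmentRow(category=category, direction=direction,
                         a=a, b=b, c=c, d=d, odds_ratio=float(orr),
                         p=float(p), stars=significance_stars(p),
                         haldane_corrected=corrected)


def region_enrichment(
    selected: TopCpGSet,
    annotation: CpGAnnotation,
    annotation_field: str = "region_class",
) -> list[EnrichmentRow]:
    """Per category x direction Fisher tests of the selected CpGs against
    the annotated array background.

    Every selected CpG must be annotated; the background is all annotated
    CpGs on the array.
    """
    if annotation_field not in _FIELD_CATEGORIES:
        raise ValueError(f"unknown annotation field {annotation_field!r}")
    ann = annotation.frame
    missing = [c for c in selected.all_ids if c not in ann.index]
    if missing:
        raise ValueError(f"selected CpG(s) missing annotation: {missing[:10]}")
    background = set(ann.index)
    rows: list[EnrichmentRow] = []
    for direction, ids in (("hyper", selected.hyper), ("hypo", selected.hypo)):
        sel = set(ids)
        rest = background - sel
        for category in _FIELD_CATEGORIES[annotation_field]:
            in_cat = set(ann.index[ann[annotation_field] == category])
            a = len(sel & in_cat)
            b = len(rest & in_cat)
            c = len(sel - in_cat)
            d = len(rest - in_cat)
            rows.append(_fisher_row(category, direction, a, b, c, d))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "category": r.category, "direction": r.direction,
        "a_selected_in": r.a, "b_background_in": r.b,
        "c_selected_out": r.c, "d_background_out": r.d,
        "odds_ratio": r.odds_ratio, "p": r.p, "stars": r.stars,
        "haldane_corrected": r.haldane_corrected,
    } for r in rows])
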