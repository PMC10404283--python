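"""Published reference summaries used for arithmetic cross-checks.

A three-region survey of water beetles in dystrophic lakes of northern
Poland (Kashubian, Masurian and Suwalki Lakelands; 207 samples, 4533
individuals) published regional abundance totals broken down by
ecological and functional group. Those printed group totals are enough to
recompute the group shares the survey reports, which makes them a handy
fixed input for exercising the aggregation arithmetic without the raw
per-sample data. Only printed totals are stored here — nothing is
derived or fitted.
"""

from __future__ import annotations

import pandas as pd

from .community import group_share
from .io import SurveyTable, build_biomass_matrix

REGIONS = ("Kashubian", "Masurian", "Suwalki")

#: per-region sample counts of the reference survey
REGION_SAMPLES = {"Kashubian": 71, "Masurian": 66, "Suwalki": 70}

#: published total abundance per region and its published grand total
REGION_ABUNDANCE = {"Kashubian": 695, "Masurian": 1937, "Suwalki": 1901}
TOTAL_ABUNDANCE = 4533

#: published per-region abundance of each ecological group
ECOLOGICAL_GROUP_ABUNDANCE = {
    "eurytope": {"Kashubian": 396, "Masurian": 1084, "Suwalki": 986},
    "tyrphophile": {"Kashubian": 252, "Masurian": 807, "Suwalki": 796},
    "argilophile": {"Kashubian": 8, "Masurian": 22, "Suwalki": 110},
    "potamophile": {"Kashubian": 39, "Masurian": 24, "Suwalki": 9},
}

#: published per-region abundance of each functional group
FUNCTIONAL_GROUP_ABUNDANCE = {
    "shredder": {"Kashubian": 314, "Masurian": 717, "Suwalki": 784},
    "grazer_scraper": {"Kashubian": 1, "Masurian": 18, "Suwalki": 17},
    "predator": {"Kashubian": 379, "Masurian": 1193, "Suwalki": 1097},
    "polyphage": {"Kashubian": 1, "Masurian": 9, "Suwalki": 3},
}

#: published shares (%) recomputable from the totals above
PUBLISHED_SHARES = {
    "eurytope_overall_pct": 54.4,
    "argilophile_overall_pct": 3.1,
    "tyrphophile_suwalki_pct": 41.9,
    "potamophile_kashubian_pct": 5.6,
}


def reference_group_survey() -> tuple[SurveyTable, pd.DataFrame]:
    """The published group totals reshaped as a tiny survey table.

    One pseudo-species per ecological group (its regional abundance total
    as the count of a single 'sample' per region), with matching species
    metadata — enough to push the printed numbers through the real
    pivot/aggregation code path.
    """
    records = []
    for group, per_region in ECOLOGICAL_GROUP_ABUNDANCE.items():
        for region, n in per_region.items():
            if n > 0:
                records.append(
                    {
                        "sample_id": region,
                        "species_id": f"{group}_pool",
                        "count": n,
                        "biomass": float(n),
                    }
                )
    survey = SurveyTable(pd.DataFrame(records))
    meta = pd.DataFrame(
        {
            "species_id": [f"{g}_pool" for g in ECOLOGICAL_GROUP_ABUNDANCE],
            "ecological_group": list(ECOLOGICAL_GROUP_ABUNDANCE),
            "functional_group": ["predator"] * len(ECOLOGICAL_GROUP_ABUNDANCE),
        }
    )
    return survey, meta


def recomputed_shares() -> dict:
    """Recompute the published group shares from the printed group totals.

    Routed through the package's pivot + aggregation + share arithmetic;
    returns percentages rounded to one decimal, the printed precision.
    """
    from .community import group_aggregate

    survey, meta = reference_group_survey()
    matrix = build_biomass_matrix(survey, value_kind="abundance")
    agg = group_aggregate(matrix, meta.set_index("species_id", drop=False), "ecological")
    total = float(agg["N"].sum())
    eurytope = group_share(float(agg.at["eurytope", "N"]), total)
    argilophile = group_share(float(agg.at["argilophile", "N"]), total)

    suwalki_total = sum(g["Suwalki"] for g in ECOLOGICAL_GROUP_ABUNDANCE.values())
    kashubian_total = sum(g["Kashubian"] for g in ECOLOGICAL_GROUP_ABUNDANCE.values())
    tyrph_suwalki = group_share(
        ECOLOGICAL_GROUP_ABUNDANCE["tyrphophile"]["Suwalki"], suwalki_total
    )
    potamo_kashubian = group_share(
        ECOLOGICAL_GROUP_ABUNDANCE["potamophile"]["Kashubian"], kashubian_total
    )
    return {
        "regional_total": total,
        "eurytope_overall_pct": round(eurytope, 1),
        "argilophile_overall_pct": round(argilophile, 1),
        "tyrphophile_suwalki_pct": round(tyrph_suwalki, 1),
        "potamophile_kashubian_pct": round(potamo_kashubian, 1),
    }
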