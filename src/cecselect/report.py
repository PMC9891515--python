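"""Paper-style tabular reports: per-site top contaminants and the compact
letter-pair site-difference table."""

from __future__ import annotations

import pandas as pd

from .datamodel import SiteAggregate
from .screen import ScreenResult, letter_pairs


def top_ten_table(agg: SiteAggregate, n: int = 10) -> pd.DataFrame:
    """Per site: the n highest aggregated maxima among detected analytes.

    Sorted by concentration descending, ties broken lexicographically by
    analyte name; columns site, contaminant, class, concentration,
    n_observations.  Sites with fewer than n detected analytes contribute
    fewer rows.
    """
    rows = []
    for site in agg.sites:
        conc = agg.max_concentration.loc[site]
        detected = conc[conc > 0]
        ordered = sorted(detected.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
        for analyte, value in ordered:
            rows.append({
                "site": site,
                "contaminant": analyte,
                "class": agg.analyte_class.get(analyte),
                "concentration": float(value),
                "n_observations": int(agg.n_observations.loc[site, analyte]),
            })
    return pd.DataFrame(rows, columns=["site", "contaminant", "class",
                                       "concentration", "n_observations"])


def site_difference_table(result: ScreenResult) -> pd.DataFrame:
    """Letter-pair rendering of significant site differences, one row per
    selected metabolite, one letter column per site."""
    rows = []
    for name in result.selected:
        letters = letter_pairs(result, name)
        row = {"metabolite": name,
               "F": float(result.table.loc[name, "F"]),
               "p": float(result.table.loc[name, "p"])}
        row.update({site: letters[site] for site in result.site_order})
        rows.append(row)
    cols = ["metabolite", "F", "p", *result.site_order]
    return pd.DataFrame(rows, columns=cols)
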