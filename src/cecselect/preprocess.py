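"""Raw panels/matrices -> analysis-ready X and Y blocks.

Pipeline order is fixed: censor -> aggregate (max over events, below-limit
records contribute zero) -> drop analytes never detected anywhere; and on
the metabolite side: median-normalize (block-wise when run-day blocks are
recorded) -> impute.  Each step reports what it changed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (ContaminantPanel, MetaboliteMatrix, ResponseBlock,
                        SiteAggregate, TEMPERATURE_RESPONSE)
from .errors import ValidationError


def aggregate_max_by_site(panel: ContaminantPanel) -> SiteAggregate:
    """Per (site, analyte): maximum concentration over sampling events.

    Below-detection-limit records contribute zero, so an analyte censored at
    every event of a site aggregates to exactly 0 ("not detected" there).
    Temperature aggregates to the per-site maximum reading.
    """
    df = panel.records
    sites = sorted(df["site"].unique())
    analytes = sorted(df["analyte"].unique())
    contrib = df["concentration"].fillna(0.0)
    work = df.assign(_value=contrib)
    gb = work.groupby(["site", "analyte"], sort=True)
    max_c = gb["_value"].max().unstack(fill_value=0.0).reindex(
        index=sites, columns=analytes, fill_value=0.0)
    n_obs = gb.size().unstack(fill_value=0).reindex(
        index=sites, columns=analytes, fill_value=0).astype(int)

    temps = {}
    for s in sites:
        readings = panel.site_temperature.get(s, [])
        if len(readings) == 0:
            raise ValidationError(f"site {s!r} has no temperature readings")
        temps[s] = float(max(readings))
    return SiteAggregate(
        max_concentration=max_c,
        n_observations=n_obs,
        max_temperature=pd.Series(temps, name=TEMPERATURE_RESPONSE).reindex(sites),
        analyte_class=panel.analyte_classes().reindex(analytes),
    )


@dataclass
class DetectionFilterResult:
    aggregate: SiteAggregate
    retained: list[str]
    dropped: list[str]


def drop_undetected(agg: SiteAggregate) -> DetectionFilterResult:
    """Remove analytes whose aggregated maximum is zero at every site."""
    max_c = agg.max_concentration
    detected_mask = (max_c > 0).any(axis=0)
    retained = [a for a in agg.analytes if detected_mask[a]]
    dropped = [a for a in agg.analytes if not detected_mask[a]]
    out = SiteAggregate(
        max_concentration=max_c[retained],
        n_observations=agg.n_observations[retained],
        max_temperature=agg.max_temperature,
        analyte_class=agg.analyte_class.reindex(retained),
    )
    return DetectionFilterResult(aggregate=out, retained=retained, dropped=dropped)


def median_normalize(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Scale each metabolite so its (block-wise, if blocks are recorded)
    non-missing median equals 1.

    Block-wise scaling removes multiplicative run-day intensity effects; the
    pooled per-metabolite median still lands on 1 because each block's does.
    Double normalization is refused.
    """
    if matrix.normalized:
        raise ValidationError("matrix is already median-normalized")
    values = matrix.values.copy()
    arr = values.to_numpy(float)
    all_missing = np.all(np.isnan(arr), axis=0)
    if all_missing.any():
        name = values.columns[np.argmax(all_missing)]
        raise ValidationError(f"metabolite {name!r} has no non-missing values")

    if matrix.block_of is not None:
        for block in matrix.block_of.unique():
            rows = (matrix.block_of == block).to_numpy()
            med = np.nanmedian(arr[rows], axis=0)
            if np.any(~np.isfinite(med)) or np.any(med <= 0):
                bad = values.columns[int(np.argmax(~(med > 0)))]
                raise ValidationError(
                    f"metabolite {bad!r} has non-positive median in block {block!r}")
            arr[rows] = arr[rows] / med
    else:
        med = np.nanmedian(arr, axis=0)
        if np.any(med <= 0):
            bad = values.columns[int(np.argmax(~(med > 0)))]
            raise ValidationError(f"metabolite {bad!r} has non-positive median")
        arr = arr / med
    values.iloc[:, :] = arr
    return MetaboliteMatrix(values=values, site_of=matrix.site_of.copy(),
                            normalized=True,
                            block_of=None if matrix.block_of is None
                            else matrix.block_of.copy())


@dataclass
class ImputationResult:
    matrix: MetaboliteMatrix
    n_imputed: int


def impute_missing(
    matrix: MetaboliteMatrix, strategy: str = "minimum"
) -> ImputationResult:
    """Fill missing cells per metabolite: ``minimum`` (observed column
    minimum, the default), ``half-minimum``, or ``fail-on-missing``."""
    if strategy not in ("minimum", "half-minimum", "fail-on-missing"):
        raise ValidationError(f"unknown imputation strategy {strategy!r}")
    values = matrix.values.copy()
    arr = values.to_numpy(float)
    n_missing = int(np.isnan(arr).sum())
    if strategy == "fail-on-missing":
        if n_missing:
            raise ValidationError(f"{n_missing} missing cell(s) present")
        return ImputationResult(matrix=matrix.copy(), n_imputed=0)
    if n_missing:
        col_min = np.nanmin(arr, axis=0)
        fill = col_min if strategy == "minimum" else col_min / 2.0
        idx = np.where(np.isnan(arr))
        arr[idx] = fill[idx[1]]
        values.iloc[:, :] = arr
    out = MetaboliteMatrix(values=values, site_of=matrix.site_of.copy(),
                           normalized=matrix.normalized,
                           block_of=None if matrix.block_of is None
                           else matrix.block_of.copy())
    return ImputationResult(matrix=out, n_imputed=n_missing)


def build_response_block(
    agg: SiteAggregate, matrix: MetaboliteMatrix
) -> ResponseBlock:
    """Per-sample Y rows: the sample's site aggregate (analyte maxima, then
    max temperature as the last column).  Rows are site-constant."""
    unknown = set(matrix.site_of.unique()) - set(agg.sites)
    if unknown:
        raise ValidationError(f"sample site(s) not in aggregate: {sorted(unknown)}")
    all_zero = [a for a in agg.analytes
                if not (agg.max_concentration[a] > 0).any()]
    if all_zero:
        raise ValidationError(
            f"all-zero response column(s) (run drop_undetected first): {all_zero[:5]}")
    wide = agg.max_concentration.copy()
    wide[TEMPERATURE_RESPONSE] = agg.max_temperature
    rows = wide.loc[matrix.site_of.to_numpy()]
    rows.index = matrix.values.index
    provenance = {a: {"max_over_events": True, "site_count": len(agg.sites)}
                  for a in agg.analytes}
    provenance[TEMPERATURE_RESPONSE] = {"max_over_events": True,
                                        "site_count": len(agg.sites)}
    return ResponseBlock(values=rows, site_of=matrix.site_of.copy(),
                         provenance=provenance)
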