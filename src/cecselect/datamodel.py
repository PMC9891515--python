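"""Core data containers for the caged-biomonitoring analysis.

The study design the containers describe: sentinel animals are deployed in
cages at several river sites; water samples taken at repeated sampling events
are assayed against a large target panel of contaminants of emerging concern
(hormones, pesticides, pharmaceuticals and personal care products), each with
a detection limit; hemolymph metabolite abundances are measured once per
animal.  Contaminant data are long-format event records; metabolite data are
a wide sample x metabolite matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CONTAMINANT_CLASSES = ("hormone", "pesticide", "ppcp")

#: Name of the water-temperature column appended to the response block.
TEMPERATURE_RESPONSE = "temperature"

#: Columns of the long-format contaminant record table.
PANEL_COLUMNS = ("site", "event", "analyte", "contaminant_class",
                 "concentration", "censored", "detection_limit")


@dataclass
class ContaminantPanel:
    """Per-event contaminant measurements plus per-site temperature readings.

    ``records`` columns (one row per site x event x analyte):

    site, event, analyte : str
    contaminant_class    : str, one of :data:`CONTAMINANT_CLASSES`
    concentration        : float (ppm-like units, carried opaquely); NaN when
                           the record is censored (below detection limit)
    censored             : bool, True iff the value fell below the limit
    detection_limit      : float > 0

    A record is *either* a numeric concentration *or* censored, never both.
    """

    records: pd.DataFrame
    site_temperature: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"panel records missing columns: {sorted(missing)}")
        dup = df.duplicated(subset=["site", "event", "analyte"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValidationError(
                "duplicate (site, event, analyte) triple: "
                f"({row['site']}, {row['event']}, {row['analyte']})"
            )
        cens = df["censored"].astype(bool)
        conc = df["concentration"]
        if (cens & conc.notna()).any():
            raise ValidationError("censored record carries a numeric concentration")
        if (~cens & conc.isna()).any():
            raise ValidationError("uncensored record lacks a concentration")
        if (conc.dropna() < 0).any():
            bad = df.loc[conc < 0].iloc[0]
            raise ValidationError(f"negative concentration for analyte {bad['analyte']!r}")
        if (df["detection_limit"] <= 0).any():
            raise ValidationError("detection limits must be strictly positive")
        bad_cls = set(df["contaminant_class"]) - set(CONTAMINANT_CLASSES)
        if bad_cls:
            raise ValidationError(f"unknown contaminant class(es): {sorted(bad_cls)}")
        record_sites = set(df["site"])
        orphan = set(self.site_temperature) - record_sites
        if orphan:
            raise ValidationError(
                f"temperature readings for sites absent from records: {sorted(orphan)}"
            )

    @property
    def sites(self) -> list[str]:
        return sorted(self.records["site"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self.records["analyte"].unique())

    @property
    def n_censored(self) -> int:
        return int(self.records["censored"].sum())

    def analyte_classes(self) -> pd.Series:
        """Map analyte -> contaminant class (pass-through metadata)."""
        return (self.records.drop_duplicates("analyte")
                .set_index("analyte")["contaminant_class"])

    def equals(self, other: "ContaminantPanel") -> bool:
        a = self.records.reset_index(drop=True)
        b = other.records.reset_index(drop=True)
        return a.equals(b) and self.site_temperature == other.site_temperature


@dataclass
class MetaboliteMatrix:
    """Sample x metabolite abundance grid with per-sample site labels.

    ``values`` is indexed by sample id, one column per metabolite; NaN marks
    a missing cell (never silently zero).  ``normalized`` records whether
    per-metabolite median scaling (median := 1) has been applied.
    ``block_of`` optionally assigns each sample to a run-day block.
    """

    values: pd.DataFrame
    site_of: pd.Series
    normalized: bool = False
    block_of: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if not self.values.index.equals(self.site_of.index):
            raise ValidationError("site labels do not align with sample ids")
        if self.block_of is not None and not self.values.index.equals(self.block_of.index):
            raise ValidationError("block labels do not align with sample ids")
        if self.normalized:
            med = np.nanmedian(self.values.to_numpy(float), axis=0)
            if np.nanmax(np.abs(med - 1.0)) > 1e-12:
                raise ValidationError("matrix flagged normalized but medians deviate from 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sites(self) -> list[str]:
        return sorted(self.site_of.unique())

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def copy(self, **updates) -> "MetaboliteMatrix":
        kw = dict(
            values=self.values.copy(),
            site_of=self.site_of.copy(),
            normalized=self.normalized,
            block_of=None if self.block_of is None else self.block_of.copy(),
        )
        kw.update(updates)
        return MetaboliteMatrix(**kw)


@dataclass
class SiteAggregate:
    """Per-site maxima of contaminant concentrations and water temperature.

    Censored records contribute zero, so an analyte never seen above its
    detection limit at a site has ``max_concentration == 0`` there.
    ``n_observations`` counts sampling events with a record (censored or not).
    """

    max_concentration: pd.DataFrame   # sites x analytes
    n_observations: pd.DataFrame      # sites x analytes, int
    max_temperature: pd.Series        # site -> degrees C
    analyte_class: pd.Series          # analyte -> class label

    def __post_init__(self) -> None:
        if (self.max_concentration.to_numpy() < 0).any():
            raise ValidationError("aggregated maxima must be non-negative")
        if not self.max_concentration.columns.equals(self.n_observations.columns):
            raise ValidationError("aggregate grids disagree on analytes")
        if not self.max_concentration.index.equals(self.n_observations.index):
            raise ValidationError("aggregate grids disagree on sites")

    @property
    def sites(self) -> list[str]:
        return list(self.max_concentration.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.max_concentration.columns)


@dataclass
class ResponseBlock:
    """Analysis-ready Y block: per-sample rows of site-level response values.

    Columns are the retained analytes followed by ``temperature``; every
    sample's row equals its site's aggregated row, so rows are site-constant
    by construction.  ``force_keep`` marks responses never eligible for
    elimination during model selection (temperature by default).
    """

    values: pd.DataFrame              # samples x responses
    site_of: pd.Series
    provenance: dict = field(default_factory=dict)
    force_keep: tuple[str, ...] = (TEMPERATURE_RESPONSE,)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.site_of.index):
            raise ValidationError("response rows do not align with sample ids")
        arr = self.values.to_numpy(float)
        for site in self.site_of.unique():
            rows = arr[(self.site_of == site).to_numpy()]
            if rows.shape[0] and not np.allclose(rows, rows[0], rtol=0, atol=0):
                raise ValidationError(f"response rows are not site-constant at {site!r}")

    @property
    def response_names(self) -> list[str]:
        return list(self.values.columns)
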