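"""Delimited-text and JSON input/output for the study data model.

On-disk conventions: comma-separated UTF-8 with "." decimals (tab accepted
via ``sep``); below-detection-limit concentrations are stored as the token
``ND`` next to an explicit ``detection_limit`` column.  Parsers never coerce
missing cells or censored values to zero — that substitution happens only in
preprocessing, where it is auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ContaminantPanel, MetaboliteMatrix
from .errors import SchemaError, ValidationError

ND_TOKEN = "ND"
_PANEL_FILE_COLUMNS = ["site", "event", "analyte", "class",
                       "concentration", "detection_limit"]


def read_contaminant_table(
    path: str | Path,
    *,
    sep: str = ",",
    nd_token: str = ND_TOKEN,
    censor_below_limit: bool = False,
    temperature_path: str | Path | None = None,
) -> ContaminantPanel:
    """Read a long-format contaminant measurement table.

    ``censor_below_limit`` additionally flags numeric concentrations strictly
    below their detection limit as censored (for files that store raw lab
    values without the sentinel token).  Malformed rows are reported with
    their file line numbers (header is line 1).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(_PANEL_FILE_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")

    problems: list[str] = []
    conc = np.full(len(raw), np.nan)
    cens = np.zeros(len(raw), dtype=bool)
    lod = np.full(len(raw), np.nan)
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2
        tok = getattr(row, "concentration").strip()
        try:
            lod[i] = float(getattr(row, "detection_limit"))
        except ValueError:
            problems.append(f"line {line}: unreadable detection_limit {getattr(row, 'detection_limit')!r}")
            continue
        if tok == nd_token:
            cens[i] = True
        else:
            try:
                conc[i] = float(tok)
            except ValueError:
                problems.append(f"line {line}: unreadable concentration {tok!r}")
                continue
            if conc[i] < 0:
                problems.append(f"line {line}: negative concentration for {row.analyte!r}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    if censor_below_limit:
        below = ~cens & (conc < lod)
        cens |= below
        conc[below] = np.nan

    records = pd.DataFrame({
        "site": raw["site"],
        "event": raw["event"],
        "analyte": raw["analyte"],
        "contaminant_class": raw["class"],
        "concentration": conc,
        "censored": cens,
        "detection_limit": lod,
    })
    site_temperature: dict[str, list[float]] = {}
    if temperature_path is not None:
        # dtype=str + float(): exact round-trip (pandas' fast float path
        # can be one ulp off)
        tdf = pd.read_csv(temperature_path, sep=sep, dtype=str)
        if not {"site", "temperature"} <= set(tdf.columns):
            raise SchemaError(f"{temperature_path}: needs columns site, temperature")
        for site, grp in tdf.groupby("site", sort=True):
            site_temperature[str(site)] = [float(v) for v in grp["temperature"]]
    return ContaminantPanel(records=records, site_temperature=site_temperature)


def write_contaminant_table(
    panel: ContaminantPanel,
    path: str | Path,
    *,
    sep: str = ",",
    nd_token: str = ND_TOKEN,
    temperature_path: str | Path | None = None,
) -> None:
    df = panel.records.copy()
    conc = df["concentration"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    conc[df["censored"]] = nd_token
    out = pd.DataFrame({
        "site": df["site"], "event": df["event"], "analyte": df["analyte"],
        "class": df["contaminant_class"], "concentration": conc,
        "detection_limit": df["detection_limit"].map(lambda v: repr(float(v))),
    })
    out.to_csv(path, sep=sep, index=False)
    if temperature_path is not None:
        rows = [(site, repr(float(t)))
                for site in sorted(panel.site_temperature)
                for t in panel.site_temperature[site]]
        pd.DataFrame(rows, columns=["site", "temperature"]).to_csv(
            temperature_path, sep=sep, index=False)


def read_metabolite_matrix(path: str | Path, *, sep: str = ",") -> MetaboliteMatrix:
    """Read a wide sample x metabolite table.

    Layout: first column sample id, second column site label, an optional
    ``block`` column (run-day batch), then one numeric column per metabolite.
    Empty cells are preserved as missing (NaN), never zero.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    if len(cols) < 3:
        raise SchemaError(f"{path}: need sample id, site and >=1 metabolite column")
    sample_col, site_col = cols[0], cols[1]
    rest = cols[2:]
    block = None
    if rest and rest[0] == "block":
        block = pd.Series(raw["block"].to_numpy(), index=raw[sample_col], name="block")
        rest = rest[1:]
    ids = raw[sample_col]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample id {dup!r}")

    values = np.full((len(raw), len(rest)), np.nan)
    for j, name in enumerate(rest):
        for i, tok in enumerate(raw[name]):
            tok = tok.strip()
            if tok == "":
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ValidationError(
                    f"{path}: line {i + 2}: non-numeric cell {tok!r} in column {name!r}"
                ) from None
    vdf = pd.DataFrame(values, index=pd.Index(ids, name=sample_col), columns=rest)
    site_of = pd.Series(raw[site_col].to_numpy(), index=vdf.index, name="site")
    return MetaboliteMatrix(values=vdf, site_of=site_of, normalized=False, block_of=block)


def write_metabolite_matrix(
    matrix: MetaboliteMatrix, path: str | Path, *, sep: str = ","
) -> None:
    body = matrix.values.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out = pd.DataFrame(index=matrix.values.index)
    out["site"] = matrix.site_of
    if matrix.block_of is not None:
        out["block"] = matrix.block_of
    out = pd.concat([out, body], axis=1)
    out.index.name = matrix.values.index.name or "sample_id"
    out.to_csv(path, sep=sep, index=True)


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyJSONEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
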