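"""Measurement-table CSV schema, series construction, and report output.

No isotope raw data were archived by the underlying study, so the CSV
schema defined here is this package's own exchange contract: one row
per replicate measurement, comma-separated, UTF-8, "." decimal, header
required, empty cell = missing.  Columns::

    series_id, compound, cultivation_acceptor, vial_id, replicate,
    f, delta13C_permil, delta37Cl_permil, sd13C_permil, sd37Cl_permil

Unknown columns are preserved on read but ignored by the analysis.
Reports serialize deterministically (sorted keys, fixed float display:
enrichment factors and Lambda to 1 decimal, AKIE to 3 decimals, with
full precision retained under separate keys), so regenerating with the
same inputs and seed is byte-identical.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    DeltaValue,
    ExperimentSeries,
    InvalidInputError,
    IsotopeMeasurement,
)

__all__ = [
    "SCHEMA_COLUMNS",
    "SchemaError",
    "MeasurementTable",
    "AnalysisReport",
    "read_measurements",
    "write_measurements",
    "table_to_series",
    "series_to_table",
    "analyze_series",
    "write_report",
    "report_to_json",
    "report_to_tsv",
]

SCHEMA_COLUMNS = (
    "series_id",
    "compound",
    "cultivation_acceptor",
    "vial_id",
    "replicate",
    "f",
    "delta13C_permil",
    "delta37Cl_permil",
    "sd13C_permil",
    "sd37Cl_permil",
)

_NUMERIC = ("f", "delta13C_permil", "delta37Cl_permil", "sd13C_permil", "sd37Cl_permil")

#: Written as a comment line ahead of the header so files self-identify.
SCHEMA_VERSION_COMMENT = "# dualcsia measurement table v1"


class SchemaError(ValueError):
    """Header-level violation of the measurement-table schema."""


@dataclass
class MeasurementTable:
    """Typed measurement rows plus row-level parse errors."""

    data: pd.DataFrame
    row_errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def series_ids(self) -> list[str]:
        return sorted(self.data["series_id"].unique())


def read_measurements(path: str | Path) -> MeasurementTable:
    """Read a measurement CSV, validating the schema.

    Header problems (missing required column) abort with
    :class:`SchemaError`; malformed numeric cells are collected per row
    with their file line numbers and the offending rows dropped.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, dtype=str, comment="#", skip_blank_lines=True, keep_default_na=False
    )
    missing = [c for c in SCHEMA_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    # map frame index -> 1-based file line, accounting for comment lines
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    data_lines = [
        i + 1
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    body_lines = data_lines[1:]  # first non-comment line is the header

    row_errors: list[str] = []
    keep_rows = []
    for pos, (_, row) in enumerate(raw.iterrows()):
        line_no = body_lines[pos] if pos < len(body_lines) else -1
        parsed = dict(row)
        ok = True
        for col in _NUMERIC:
            cell = row[col].strip()
            if cell == "":
                parsed[col] = None
                continue
            try:
                parsed[col] = float(cell)
            except ValueError:
                row_errors.append(
                    f"line {line_no}: column {col!r}: cannot parse {cell!r} as a number"
                )
                ok = False
        if ok and parsed["f"] is not None and not 0.0 < parsed["f"] < 1.5:
            row_errors.append(
                f"line {line_no}: f = {parsed['f']} outside the plausible range (0, 1.5)"
            )
            ok = False
        try:
            parsed["replicate"] = int(row["replicate"]) if row["replicate"].strip() else 1
        except ValueError:
            row_errors.append(
                f"line {line_no}: column 'replicate': cannot parse "
                f"{row['replicate']!r} as an integer"
            )
            ok = False
        if ok:
            keep_rows.append(parsed)
    frame = pd.DataFrame(keep_rows, columns=list(raw.columns))
    return MeasurementTable(data=frame, row_errors=row_errors)


def series_to_table(series: ExperimentSeries) -> pd.DataFrame:
    """Flatten a series to the schema frame, f = 1 reference rows included.

    The starting composition travels as a reference row at f = 1.0
    (vial_id "ref", replicate 0) so the file is self-contained.
    """
    df = series.to_dataframe()
    ref_rows = []
    if series.delta0_c is not None or series.delta0_cl is not None:
        ref_rows.append(
            {
                "series_id": series.series_id,
                "compound": series.compound,
                "cultivation_acceptor": series.cultivation_acceptor,
                "vial_id": "ref",
                "replicate": 0,
                "f": 1.0,
                "delta13C_permil": series.delta0_c,
                "delta37Cl_permil": series.delta0_cl,
                "sd13C_permil": None,
                "sd37Cl_permil": None,
            }
        )
    if ref_rows:
        df = pd.DataFrame(ref_rows + df.to_dict("records"))
    return df[list(SCHEMA_COLUMNS)]


def write_measurements(series: ExperimentSeries, path: str | Path) -> None:
    """Write a series as a schema CSV with the version comment line."""
    df = series_to_table(series)
    buf = _io.StringIO()
    buf.write(SCHEMA_VERSION_COMMENT + "\n")
    df.to_csv(buf, index=False, float_format="%.10g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def table_to_series(
    table: MeasurementTable | pd.DataFrame,
    series_id: str | None = None,
    delta0_c: float | None = None,
    delta0_cl: float | None = None,
) -> ExperimentSeries:
    """Assemble one :class:`ExperimentSeries` from a measurement table.

    With several series in the table, ``series_id`` selects one.
    Reference rows at f = 1 supply the starting composition unless
    explicit ``delta0`` values are given.
    """
    df = table.data if isinstance(table, MeasurementTable) else table
    if df.empty:
        raise InvalidInputError("measurement table is empty")
    ids = sorted(df["series_id"].unique())
    if series_id is None:
        if len(ids) > 1:
            raise InvalidInputError(
                f"table holds {len(ids)} series ({', '.join(map(str, ids))}); "
                "pass series_id to select one"
            )
        series_id = ids[0]
    sub = df[df["series_id"] == series_id]
    if sub.empty:
        raise InvalidInputError(f"no rows for series {series_id!r}; have {ids}")
    compound = sub["compound"].iloc[0]
    acceptor = sub["cultivation_acceptor"].iloc[0]
    measurements = []
    for _, row in sub.iterrows():
        dc = row["delta13C_permil"]
        dcl = row["delta37Cl_permil"]
        measurements.append(
            IsotopeMeasurement(
                vial_id=str(row["vial_id"]),
                compound=compound,
                cultivation_acceptor=acceptor,
                f=float(row["f"]),
                delta_c=None if pd.isna(dc) or dc is None else DeltaValue(float(dc), "C"),
                delta_cl=None
                if pd.isna(dcl) or dcl is None
                else DeltaValue(float(dcl), "Cl"),
                sd_c=None if pd.isna(row["sd13C_permil"]) else float(row["sd13C_permil"]),
                sd_cl=None
                if pd.isna(row["sd37Cl_permil"])
                else float(row["sd37Cl_permil"]),
                replicate=int(row["replicate"]),
            )
        )
    return ExperimentSeries(
        series_id=str(series_id),
        compound=compound,
        cultivation_acceptor=acceptor,
        measurements=measurements,
        delta0_c=delta0_c,
        delta0_cl=delta0_cl,
    )


# ---------------------------------------------------------------------------
# Analysis report
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Full per-series analysis: fits, AKIEs, pattern, scenario verdicts."""

    payload: dict

    def to_json(self) -> str:
        return report_to_json(self)

    def to_tsv(self) -> str:
        return report_to_tsv(self)


def _slope_block(res, name: str, units: str) -> dict:
    lo, hi = res.ci95
    return {
        "name": name,
        "units": units,
        "value": res.slope,
        "value_display": round(res.slope, 1),
        "stderr": res.stderr,
        "ci95_low": lo,
        "ci95_high": hi,
        "r_squared": res.r_squared,
        "n_points": res.n_points,
        "intercept": res.intercept,
    }


def _akie_block(akie_result) -> dict:
    block = {
        "units": "dimensionless",
        "value": akie_result.akie,
        "value_display": akie_result.akie_display,
        "epsilon_in_permil": akie_result.epsilon_in,
        "n": akie_result.params.n,
        "x": akie_result.params.x,
        "z": akie_result.params.z,
        "provenance": akie_result.params.provenance,
        "streitwieser_limit": akie_result.streitwieser_limit,
        "exceeds_limit": akie_result.exceeds_limit,
        "mechanism_plausible": akie_result.mechanism_plausible,
    }
    if akie_result.ci95 is not None:
        block["ci95_low"], block["ci95_high"] = akie_result.ci95
    return block


def analyze_series(
    series: ExperimentSeries,
    alpha: float = 0.05,
    lambda_boundary: float | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full pipeline on one series and assemble the report.

    Fits the Rayleigh enrichment factor per available element, the
    dual-element slope when both elements are present, computes AKIEs
    under every registered mechanism parameterization for the compound,
    evaluates Streitwieser plausibility, and labels the dual-element
    pattern.
    """
    from .akie import (
        DEFAULT_LAMBDA_BOUNDARY,
        classify_dual_pattern,
        compute_akie,
        evaluate_mechanism_scenarios,
        registry_lookup,
        RegistryLookupError,
    )
    from .rayleigh import DualElementModel, RayleighModel

    boundary = DEFAULT_LAMBDA_BOUNDARY if lambda_boundary is None else lambda_boundary
    payload: dict = {
        "software": "dualcsia",
        "version": __version__,
        "series_id": series.series_id,
        "compound": series.compound,
        "cultivation_acceptor": series.cultivation_acceptor,
        "config": {
            "alpha": alpha,
            "lambda_boundary": boundary,
            "lambda_boundary_note": "operational configuration, not theory",
            "seed": seed,
        },
    }
    fits: dict[str, object] = {}
    for element, key in (("C", "epsilon_c"), ("Cl", "epsilon_cl")):
        if any(m.delta(element) is not None for m in series.measurements):
            res = RayleighModel(series, element).fit(alpha=alpha)
            fits[element] = res
            payload[key] = _slope_block(res, f"epsilon_{element}", "permil")
    if len(series.paired_points()) >= 3:
        lam_res = DualElementModel(series).fit(alpha=alpha)
        payload["lambda"] = _slope_block(lam_res, "lambda", "dimensionless")
        pattern = classify_dual_pattern(lam_res, boundary=boundary)
        payload["pattern"] = {
            "label": pattern.label,
            "boundary": pattern.boundary,
            "units": "dimensionless",
        }
    akie_payload: dict = {}
    mechanisms = ("concerted", "stepwise") if series.compound == "1,2-DCA" else ("one_step",)
    for mechanism in mechanisms:
        for element in ("C", "Cl"):
            if element not in fits:
                continue
            try:
                params = registry_lookup(series.compound, element, mechanism)
            except RegistryLookupError:
                continue
            res = fits[element]
            akie_payload[f"{mechanism}_{element.lower()}"] = _akie_block(
                compute_akie(res.epsilon, params, ci95=res.ci95)
            )
    payload["akie"] = akie_payload
    if series.compound == "1,2-DCA" and "C" in fits and "Cl" in fits:
        report = evaluate_mechanism_scenarios(
            fits["C"].epsilon, fits["Cl"].epsilon, series.compound
        )
        payload["mechanism_scenarios"] = {
            s.mechanism: {"plausible": s.plausible} for s in report.scenarios
        }
        payload["surviving_mechanisms"] = list(report.surviving)
    return AnalysisReport(payload=payload)


def _round_floats(obj, ndigits: int = 12):
    """Cut float noise below reproducibility-relevant precision."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report_to_json(report: AnalysisReport) -> str:
    return json.dumps(_round_floats(report.payload), sort_keys=True, indent=2) + "\n"


def report_to_tsv(report: AnalysisReport) -> str:
    """One summary row per series, mirroring published-table columns."""
    p = report.payload
    cols = ["series_id", "compound", "cultivation_acceptor"]
    vals = [p["series_id"], p["compound"], p["cultivation_acceptor"]]
    for key, label in (("epsilon_c", "eps_C_permil"), ("epsilon_cl", "eps_Cl_permil")):
        block = p.get(key)
        cols += [label, f"{label}_ci95_halfwidth", f"{label}_R2"]
        if block:
            hw = (block["ci95_high"] - block["ci95_low"]) / 2.0
            vals += [f"{block['value']:.1f}", f"{hw:.1f}", f"{block['r_squared']:.2f}"]
        else:
            vals += ["n.d.", "n.d.", "n.d."]
    for key, value in sorted(p.get("akie", {}).items()):
        cols.append(f"akie_{key}")
        vals.append(f"{value['value']:.3f}")
    block = p.get("lambda")
    cols += ["lambda", "lambda_R2", "pattern"]
    if block:
        vals += [
            f"{block['value']:.1f}",
            f"{block['r_squared']:.2f}",
            p.get("pattern", {}).get("label", ""),
        ]
    else:
        vals += ["n.d.", "n.d.", ""]
    return "\t".join(cols) + "\n" + "\t".join(map(str, vals)) + "\n"


def write_report(report: AnalysisReport, path: str | Path, format: str = "json") -> None:
    """Serialize a report deterministically as JSON or TSV."""
    if format == "json":
        text = report_to_json(report)
    elif format == "tsv":
        text = report_to_tsv(report)
    else:
        raise InvalidInputError(f"unknown report format {format!r}; use json or tsv")
    Path(path).write_text(text, encoding="utf-8")
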