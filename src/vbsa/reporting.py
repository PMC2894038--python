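"""Report serialization (JSON) and publication-style table rendering (CSV)."""

from __future__ import annotations

import json

import numpy as np

from .errors import ConfigError
from .variance import SensitivityReport, VarianceDecomposition, classify

SCHEMA_VERSION = 1


def report_to_dict(report, extra=None):
    dec = report.decomposition
    doc = {
        "schema_version": SCHEMA_VERSION,
        "method": report.method,
        "labels": list(report.labels),
        "sesi": report.sesi.tolist(),
        "jesi": report.jesi.tolist(),
        "classification": list(report.classification),
        "theta": report.theta,
        "budget": report.budget,
    }
    if dec is not None:
        doc.update(
            V=dec.V,
            Vj=dec.Vj.tolist(),
            Vjj=dec.Vjj.tolist(),
            clamp={
                "Vj": np.asarray(dec.meta.get("clamped_Vj", [])).tolist(),
                "n": int(dec.meta.get("n_clamped", 0)),
            },
            vtot_estimate=dec.meta.get("Vtot_estimate"),
        )
    if extra:
        doc.update(extra)
    return doc


def report_to_json(report, extra=None):
    return json.dumps(report_to_dict(report, extra), indent=1)


def report_from_dict(doc):
    """Rebuild a SensitivityReport (losslessly for all index-level fields)."""
    dec = None
    if "Vj" in doc:
        dec = VarianceDecomposition(
            Vj=np.asarray(doc["Vj"], dtype=float),
            Vjj=np.asarray(doc["Vjj"], dtype=float),
            V=float(doc["V"]),
            method=doc["method"],
            budget=int(doc["budget"]),
            meta={"Vtot_estimate": doc.get("vtot_estimate")},
        )
    report = SensitivityReport(
        sesi=np.asarray(doc["sesi"], dtype=float),
        jesi=np.asarray(doc["jesi"], dtype=float),
        labels=list(doc["labels"]),
        method=doc["method"],
        budget=int(doc["budget"]),
        theta=float(doc.get("theta", 0.10)),
        classification=list(doc.get("classification", [])),
        decomposition=dec,
    )
    return report


def report_from_json(text):
    return report_from_dict(json.loads(text))


def truncate_pct(fraction):
    """Percentage truncated toward zero to an integer, as printed in the
    result tables (values are nonnegative after clamping)."""
    return int(100.0 * fraction)


def render_table(reports, style="paper", display_floor=0.05, reference=None,
                 theta=0.10):
    """Side-by-side SESI/JESI table across methods, one row per factor.

    Percentages are truncated to integers; rows are kept only when the
    reference method (default: 'mc' if present, else the first report)
    shows a truncated SESI or JESI of at least the display floor (5%).
    Factors whose reference SESI or JESI clears the decision threshold are
    flagged with '*' in the influence column.  The display floor and the
    classification threshold are independent knobs.
    """
    if style != "paper":
        raise ConfigError(f"unknown table style {style!r}")
    reports = [report_from_dict(r) if isinstance(r, dict) else r for r in reports]
    if not reports:
        raise ConfigError("no reports to render")
    labels = reports[0].labels
    for r in reports[1:]:
        if r.labels != labels:
            raise ConfigError("reports have mismatched factor labels")
    methods = [r.method for r in reports]
    if reference is None:
        reference = "mc" if "mc" in methods else methods[0]
    if reference not in methods:
        raise ConfigError(f"reference method {reference!r} not among reports")
    ref = reports[methods.index(reference)]
    ref = classify(ref, theta)

    floor_pct = int(round(100 * display_floor))
    header = (
        ["factor"]
        + [f"sesi_{m}" for m in methods]
        + [f"jesi_{m}" for m in methods]
        + [f"class_{reference}", "influential"]
    )
    lines = [",".join(header)]
    for i, label in enumerate(labels):
        s_ref = truncate_pct(ref.sesi[i])
        e_ref = truncate_pct(ref.jesi[i])
        if s_ref < floor_pct and e_ref < floor_pct:
            continue
        row = [str(label)]
        row += [str(truncate_pct(r.sesi[i])) for r in reports]
        row += [str(truncate_pct(r.jesi[i])) for r in reports]
        cls = ref.classification[i]
        row += [cls, "*" if cls != "noninfluential" else ""]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"
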