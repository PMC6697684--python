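"""Tabular species reports: karyotype-parameter row and marker listing."""

from __future__ import annotations

import json

import pandas as pd

from .asymmetry import KaryotypeIndices
from .karyotype import Karyotype
from .markers import CytoMarker, band_amount_percent, marker_code

__all__ = ["species_report", "write_report", "read_report"]


def species_report(
    karyotype: Karyotype,
    indices: KaryotypeIndices,
    markers: list[CytoMarker] | None = None,
) -> dict:
    """Assemble the per-species report bundle.

    Returns a JSON-serializable dict with a ``parameters`` row (karyotype
    formula, TCL ± SD, relative-length range, CI ± SD, asymmetry indices,
    Stebbins category) and a ``markers`` listing (position codes and band
    amounts per marker class).
    """
    markers = markers or []
    params = {
        "species": karyotype.species_label,
        "KF": karyotype.formula,
        "two_n": karyotype.two_n,
        "TCL": round(indices.tcl, 4),
        "TCL_sd": round(indices.tcl_sd, 4),
        "RRL_min": round(indices.rrl_min, 4),
        "RRL_max": round(indices.rrl_max, 4),
        "CI_mean": round(indices.ci_mean, 4),
        "CI_sd": round(indices.ci_sd, 4),
        "A1": round(indices.a1, 4),
        "A2": round(indices.a2, 4),
        "AsK": round(indices.as_k, 4),
        "AI": round(indices.ai, 4),
        "stebbins": indices.stebbins,
    }
    amounts = band_amount_percent(markers, karyotype) if markers else {}
    marker_rows = [
        {
            "marker_class": m.marker_class,
            "code": marker_code(m, karyotype),
            "pair_id": m.pair_id,
            "arm": m.arm,
            "position_class": m.position_class,
            "homologs_present": m.homologs_present,
        }
        for m in markers
    ]
    return {
        "parameters": params,
        "band_amount_percent": {k: round(v, 4) for k, v in amounts.items()},
        "markers": marker_rows,
    }


def write_report(report: dict, json_path=None, csv_path=None) -> None:
    """Write the report as JSON and/or a parameters CSV (one species row)."""
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
    if csv_path is not None:
        pd.DataFrame([report["parameters"]]).to_csv(csv_path, index=False)


def read_report(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
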