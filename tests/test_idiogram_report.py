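"""SVG idiogram geometry, species reports and the command-line interface."""

import json
import xml.etree.ElementTree as ET

import pytest
from click.testing import CliRunner

from cytophylo import (
    CytoMarker,
    IdiogramStyle,
    aggregate_pairs,
    karyotype_indices,
    length_ratio,
    render_idiogram,
    species_report,
)
from cytophylo.cli import main as cli_main
from cytophylo.report import read_report, write_report
from conftest import make_karyotype

SVG = "{http://www.w3.org/2000/svg}"


def parse(svg_str):
    return ET.fromstring(svg_str.split("\n", 1)[1])


def test_single_pair_idiogram_has_one_glyph_and_label():
    k = make_karyotype([(1.0, 2.0)])
    root = parse(render_idiogram(k))
    glyphs = [g for g in root.iter(f"{SVG}g") if g.get("class") == "pair"]
    labels = [t for t in root.iter(f"{SVG}text") if t.get("class") == "ar-label"]
    assert len(glyphs) == 1 and len(labels) == 1
    assert labels[0].text == "2.00"


def test_idiogram_heights_proportional_to_relative_length(zero_noise_karyotype):
    root = parse(render_idiogram(zero_noise_karyotype))
    glyphs = {g.get("id"): g for g in root.iter(f"{SVG}g") if g.get("class") == "pair"}
    assert len(glyphs) == 19
    heights = {}
    for gid, g in glyphs.items():
        arms = [r for r in g.iter(f"{SVG}rect") if r.get("class") == "arm"]
        assert len(arms) == 2
        heights[gid] = sum(float(r.get("height")) for r in arms)
    ratio = max(heights.values()) / min(heights.values())
    assert ratio == pytest.approx(length_ratio(zero_noise_karyotype), rel=1e-3)


def test_rdna_band_centre_at_di_fraction_of_long_arm():
    style = IdiogramStyle()
    k = make_karyotype([(4.7, 4.7), (2.0, 2.0)])
    d = 0.2553 * 4.7
    m = CytoMarker("rDNA_45S", 1, "L", "PROX", band_len=0.3, d=d)
    root = parse(render_idiogram(k, [m], style))
    pair1 = [g for g in root.iter(f"{SVG}g") if g.get("id") == "pair-1"][0]
    arms = [r for r in pair1.iter(f"{SVG}rect") if r.get("class") == "arm"]
    band = [r for r in pair1.iter(f"{SVG}rect") if "rDNA_45S" in r.get("class", "")][0]
    long_rect = max(arms, key=lambda r: float(r.get("y")))
    long_top, long_h = float(long_rect.get("y")), float(long_rect.get("height"))
    centre = float(band.get("y")) + float(band.get("height")) / 2
    assert (centre - long_top) / long_h == pytest.approx(0.2553, abs=1e-3)
    assert band.get("data-fraction") == "0.2553"


def test_heteromorphic_marker_drawn_on_one_chromatid():
    style = IdiogramStyle()
    k = make_karyotype([(2.0, 3.0)])
    both = CytoMarker("DAPI_band", 1, "S", "CEN", band_len=0.2)
    one = CytoMarker("DAPI_band", 1, "L", "PROX", band_len=0.2,
                     homologs_present="one")
    root = parse(render_idiogram(k, [both, one], style))
    widths = sorted(
        float(r.get("width"))
        for r in root.iter(f"{SVG}rect")
        if "marker" in r.get("class", "")
    )
    assert widths[0] == pytest.approx(style.chromatid_width)
    assert widths[1] == pytest.approx(2 * style.chromatid_width + style.chromatid_gap)


def test_satellite_glyph_rendered_distal_to_constriction(zero_noise_karyotype):
    root = parse(render_idiogram(zero_noise_karyotype))
    sats = [r for r in root.iter(f"{SVG}rect") if r.get("class") == "satellite"]
    assert len(sats) == 1


def test_idiogram_marker_unknown_pair_rejected():
    k = make_karyotype([(1.0, 1.0)])
    with pytest.raises(ValueError, match="pair 7"):
        render_idiogram(k, [CytoMarker("CPD_band", 7, "L", "INT")])


def test_idiogram_is_deterministic(zero_noise_karyotype):
    assert render_idiogram(zero_noise_karyotype) == render_idiogram(
        zero_noise_karyotype
    )


def test_species_report_contents(zero_noise_karyotype, bundle):
    idx = karyotype_indices(zero_noise_karyotype)
    rep = species_report(zero_noise_karyotype, idx, bundle.markers)
    assert rep["parameters"]["KF"] == "2n=2x=38=34m(2SAT)+4sm"
    assert rep["parameters"]["stebbins"] == "2B"
    assert rep["band_amount_percent"]["CPD_band"] > 0
    codes = [m["code"] for m in rep["markers"]]
    assert any(code.startswith("1L-PROX (") for code in codes)
    # empty marker set: no crash, empty listing
    rep0 = species_report(zero_noise_karyotype, idx, [])
    assert rep0["markers"] == [] and rep0["band_amount_percent"] == {}


def test_report_round_trip(tmp_path, zero_noise_karyotype):
    idx = karyotype_indices(zero_noise_karyotype)
    rep = species_report(zero_noise_karyotype, idx, [])
    write_report(rep, json_path=tmp_path / "r.json", csv_path=tmp_path / "r.csv")
    back = read_report(tmp_path / "r.json")
    assert back == json.loads(json.dumps(rep))
    assert back["parameters"]["A1"] == round(idx.a1, 4)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cli_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    runner = CliRunner()
    res = runner.invoke(cli_main, ["simulate", "--out-dir", str(out)])
    assert res.exit_code == 0, res.output
    return out


def test_cli_karyotype_writes_json(cli_dataset, tmp_path):
    runner = CliRunner()
    out = tmp_path / "karyo.json"
    res = runner.invoke(
        cli_main,
        ["karyotype", "--in", str(cli_dataset / "measurements.csv"),
         "--out", str(out)],
    )
    assert res.exit_code == 0
    payload = json.loads(out.read_text())
    assert payload["two_n"] == 38
    assert payload["formula"].startswith("2n=2x=38=")


def test_cli_nj_is_deterministic(cli_dataset, tmp_path):
    runner = CliRunner()
    args = ["nj", "--in", str(cli_dataset / "alignment.fasta"),
            "--bootstrap", "25", "--seed", "42"]
    o1, o2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
    r1 = runner.invoke(cli_main, args + ["--out", str(o1)])
    r2 = runner.invoke(cli_main, args + ["--out", str(o2)])
    assert r1.exit_code == 0 and r2.exit_code == 0
    assert o1.read_bytes() == o2.read_bytes()


def test_cli_pipeline_formula_matches_preset(cli_dataset, tmp_path):
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        ["report", "--measurements", str(cli_dataset / "measurements.csv"),
         "--markers", str(cli_dataset / "markers.csv"),
         "--out-dir", str(tmp_path / "rep")],
    )
    assert res.exit_code == 0
    assert "2n=2x=38=34m(2SAT)+4sm" in res.output
    assert (tmp_path / "rep" / "idiogram.svg").exists()
    assert (tmp_path / "rep" / "parameters.csv").exists()


def test_cli_unknown_subcommand_exits_2():
    res = CliRunner().invoke(cli_main, ["frobnicate"])
    assert res.exit_code == 2


def test_cli_validation_error_exits_2(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("cell_id,pair_id,homolog,short_arm_um,long_arm_um,"
                   "satellite_um,satellite_arm\nc1,1,1,1.0,2.0,0,none\n")
    res = CliRunner().invoke(
        cli_main, ["karyotype", "--in", str(bad), "--out", str(tmp_path / "o.json")]
    )
    assert res.exit_code == 2
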