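import json
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sperc.core import ValidationError, VolatilityBand, default_bands
from sperc.volatility import (
    EvaporationParams,
    band_conservatism_report,
    evaporation_rate,
    f_air_continuous,
)

# hand/spreadsheet oracle values: exp(12.2 + 0.933 * ln(vp))
ER_ORACLE = {
    1.0: 198789.15114295442,       # exp(12.2)
    0.01: 2706.404327554953,
    1e-4: 36.846197803525286,
}


@pytest.mark.parametrize("vp, expected", sorted(ER_ORACLE.items()))
def test_evaporation_rate_against_closed_form(vp, expected):
    assert evaporation_rate(vp) == pytest.approx(expected, rel=1e-12)


def test_evaporation_rate_strictly_increasing():
    grid = np.logspace(-8, 5, 500)
    er = evaporation_rate(grid)
    assert np.all(np.diff(er) > 0)


@pytest.mark.parametrize("vp", [0.0, -2.0, math.inf, math.nan])
def test_evaporation_rate_domain_errors(vp):
    with pytest.raises(ValidationError):
        evaporation_rate(vp)


def test_f_air_continuous_at_volatility_cutoff():
    """24 h of constant evaporation at 0.01 Pa releases ~65% of a 1 kg/ha
    dose, the basis of the transition-band underestimate discussion."""
    expected = 24 * math.exp(12.2 + 0.933 * math.log(0.01)) / 1e5
    got = f_air_continuous(0.01)
    assert got == pytest.approx(expected, rel=1e-9)
    assert got == pytest.approx(0.65, abs=0.01)


def test_f_air_continuous_caps_at_one():
    assert f_air_continuous(1.0) == 1.0
    assert f_air_continuous(1.0, cap=False) == pytest.approx(47.7, rel=0.01)


def test_f_air_inverse_proportional_to_application_rate():
    lo = f_air_continuous(1e-4, EvaporationParams(application_rate_kg_ha=1.0), cap=False)
    hi = f_air_continuous(1e-4, EvaporationParams(application_rate_kg_ha=2.0), cap=False)
    assert hi == pytest.approx(lo / 2, rel=1e-12)


def test_closed_form_equals_numeric_integration():
    """The 24-h released mass equals the trapezoid integral of the constant
    evaporation rate over the window (independent numeric oracle)."""
    params = EvaporationParams()
    for vp in (1e-6, 1e-3, 5e-3):
        er = evaporation_rate(vp, params)
        t = np.linspace(0.0, params.duration_h, 777)
        mass_ug_m2 = np.trapezoid(np.full_like(t, er), t)
        oracle = mass_ug_m2 / (1e5 * params.application_rate_kg_ha)
        assert f_air_continuous(vp, params, cap=False) == pytest.approx(
            oracle, rel=1e-12
        )


@given(
    st.floats(min_value=-8, max_value=5),
    st.floats(min_value=0.0, max_value=3.0),
)
def test_f_air_continuous_non_decreasing(lo_exp, span):
    a = 10.0 ** lo_exp
    b = 10.0 ** (lo_exp + span)
    assert f_air_continuous(b) >= f_air_continuous(a)


def test_conservatism_report_matches_banded_picture(v4_bands):
    """Band values sit above the calculated curve everywhere except a narrow
    range just below 0.01 Pa, where the banded 0.5 is ~20% short."""
    report = band_conservatism_report(v4_bands)
    bad = report.non_conservative_bands
    assert [b.label for b in bad] == ["0.001 to <0.01"]
    b = bad[0]
    # monotone curve: the deficit peaks at the band's upper edge
    assert b.vp_at_max_deficit == pytest.approx(0.01, rel=1e-6)
    assert b.max_deficit == pytest.approx(0.15, abs=0.01)
    assert 0.15 <= b.max_relative_deficit <= 0.25


def test_conservatism_zero_when_bands_are_saturated():
    bands = [
        VolatilityBand(0.0, 1e-2, "low", 1.0),
        VolatilityBand(1e-2, math.inf, "high", 1.0),
    ]
    report = band_conservatism_report(bands)
    assert all(b.max_deficit == 0.0 for b in report.bands)


def test_conservatism_report_errors():
    with pytest.raises(ValidationError):
        band_conservatism_report([])
    with pytest.raises(ValidationError):
        band_conservatism_report(default_bands(), grid_points_per_decade=5)


def test_report_serialization(v4_bands):
    report = band_conservatism_report(v4_bands, grid_points_per_decade=20)
    payload = json.loads(report.to_json())
    assert {b["label"] for b in payload["bands"]} == {b.label for b in v4_bands}
    table = report.curve_table().strip().splitlines()
    assert table[0] == "vp_pa\tf_air_calc"
    vp, f = map(float, table[1].split("\t"))
    assert f == pytest.approx(f_air_continuous(vp), rel=1e-6)


def test_params_validation():
    with pytest.raises(ValidationError):
        EvaporationParams(slope=-0.1)
    with pytest.raises(ValidationError):
        EvaporationParams(duration_h=0)
    with pytest.raises(ValidationError):
        EvaporationParams(application_rate_kg_ha=0)
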