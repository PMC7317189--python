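import json

import numpy as np
import pytest

from sperc.core import ApplicationMethod, ValidationError, classify_volatility
from sperc.engine import (
    ReleaseFactorSet,
    builtin_version_table,
    get_release_factors,
    list_sperc,
    load_version_table,
    mass_balance_check,
)

SPRAY = ApplicationMethod.SPRAY
GRANULAR = ApplicationMethod.GRANULAR

# the full version-4 table: (method, probe vp, f_air, f_soil, f_sw, f_waste)
V4_ROWS = [
    (SPRAY, 3e-6, 0.01, 1.0, 0.002, 0.0),
    (SPRAY, 3e-5, 0.1, 1.0, 0.002, 0.0),
    (SPRAY, 5e-4, 0.2, 1.0, 0.002, 0.0),
    (SPRAY, 5e-3, 0.5, 1.0, 0.002, 0.0),
    (SPRAY, 0.05, 1.0, 0.0, 0.002, 0.0),
    (GRANULAR, 5e-3, 0.0, 1.0, 0.0, 0.0001),
    (GRANULAR, 0.05, 0.0, 1.0, 0.0, 0.0001),
]


@pytest.mark.parametrize("method, vp, f_air, f_soil, f_sw, f_waste", V4_ROWS)
def test_v4_table_fidelity(method, vp, f_air, f_soil, f_sw, f_waste):
    rfs = get_release_factors(method, vp, version=4)
    assert (rfs.f_air, rfs.f_soil, rfs.f_surface_water, rfs.f_waste) == (
        f_air,
        f_soil,
        f_sw,
        f_waste,
    )
    assert rfs.sperc_id == ("8d.2.v4" if method is SPRAY else "8d.1.v4")


def test_spray_f_air_matches_band_lookup():
    """Engine air factors agree with the volatility banding for every vp."""
    for vp in np.logspace(-8, 4, 400):
        rfs = get_release_factors(SPRAY, float(vp), version=4)
        assert rfs.f_air == classify_volatility(float(vp)).f_air_spray


def test_v4_constant_columns():
    for vp in np.logspace(-7, 2, 50):
        assert get_release_factors(SPRAY, float(vp)).f_surface_water == 0.002
        g = get_release_factors(GRANULAR, float(vp))
        assert g.f_air == 0.0 and g.f_surface_water == 0.0


def test_erc8d_defaults_as_version_zero():
    for method in (SPRAY, GRANULAR):
        rfs = get_release_factors(method, 1.0, version=0)
        assert (rfs.f_air, rfs.f_soil, rfs.f_surface_water) == (1.0, 1.0, 0.2)


def test_unknown_version_lists_available():
    with pytest.raises(ValidationError, match="0, 4"):
        get_release_factors(SPRAY, 1.0, version=3)


def test_volatile_granular_flagged_not_rejected():
    rfs = get_release_factors(GRANULAR, 0.05)
    assert any("volatile-granular" in f for f in rfs.flags)
    assert get_release_factors(GRANULAR, 1e-4).flags == ()
    assert get_release_factors(SPRAY, 0.05).flags == ()


def test_invalid_vp_rejected():
    with pytest.raises(ValidationError):
        get_release_factors(SPRAY, -1.0)
    with pytest.raises(ValidationError):
        get_release_factors(SPRAY, 0.0)


def _rfs(f_air, f_soil, f_sw, f_waste):
    return ReleaseFactorSet(f_air, f_soil, f_sw, f_waste, "test", "band")


def test_mass_balance_decoupled_flags_but_passes():
    rfs = get_release_factors(SPRAY, 5e-3)  # sum 0.5 + 1 + 0.002 = 1.502
    report = mass_balance_check(rfs, "decoupled")
    assert report.factor_sum == pytest.approx(1.502)
    assert not report.violation
    assert any("intentional conservatism" in f for f in report.flags)


def test_mass_balance_coupled_violations():
    assert mass_balance_check(_rfs(0.5, 1.0, 0.002, 0.0), "coupled").violation
    # granular volatile row: 0 + 1 + 0 + 0.0001 exceeds 1 in coupled mode
    assert mass_balance_check(_rfs(0.0, 1.0, 0.0, 0.0001), "coupled").violation
    # floating-point-only excess is tolerated
    assert not mass_balance_check(_rfs(0.5, 0.5, 0.0, 0.0), "coupled").violation


def test_mass_balance_all_zero_passes_both_modes():
    zero = _rfs(0.0, 0.0, 0.0, 0.0)
    assert not mass_balance_check(zero, "coupled").violation
    assert not mass_balance_check(zero, "decoupled").violation
    assert mass_balance_check(zero, "decoupled").flags == ()


def test_list_sperc_row_counts():
    assert len(list_sperc(4)) == 7  # 5 spray bands + 2 granular rows
    rows0 = list_sperc(0)
    assert len(rows0) == 1
    assert rows0[0][2].as_dict()["f_surface_water"] == 0.2


def test_table_json_round_trip(v4_table):
    clone = load_version_table(json.loads(v4_table.to_json()))
    assert clone.version == v4_table.version
    assert clone.mass_balance_mode == v4_table.mass_balance_mode
    for method in v4_table.rows:
        got = [(b.label, r) for b, r in clone.rows[method]]
        want = [(b.label, r) for b, r in v4_table.rows[method]]
        assert got == want


def test_coupled_config_validated_at_load(synthetic_v2_table_dict):
    table = load_version_table(synthetic_v2_table_dict)
    rfs = get_release_factors(SPRAY, 5e-3, version=2, table=table)
    assert rfs.f_surface_water == 0.0
    assert rfs.sperc_id == "8d.2.v2"
    # injecting a coupled row with sum > 1 must fail at load
    bad = json.loads(json.dumps(synthetic_v2_table_dict))
    bad["rows"][0]["f_soil"] = 1.0
    with pytest.raises(ValidationError, match="coupled"):
        load_version_table(bad)


def test_synthetic_v3_coupled_semantics(synthetic_v3_table_dict):
    table = load_version_table(synthetic_v3_table_dict)
    for band, rfs in table.rows[SPRAY]:
        assert rfs.f_surface_water == 0.002
        assert rfs.factor_sum <= 1.0 + 1e-9


def test_version_mismatch_rejected(v4_table):
    with pytest.raises(ValidationError, match="version"):
        get_release_factors(SPRAY, 1.0, version=2, table=v4_table)
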