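import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def v4_bands():
    from sperc.core import default_bands

    return default_bands()


@pytest.fixture(scope="session")
def v4_table():
    from sperc.engine import builtin_version_table

    return builtin_version_table(4)


@pytest.fixture
def synthetic_v2_table_dict():
    """Synthetic stand-in for the unpublished version-2 table: surface water
    zero everywhere, factors coupled."""
    rows = []
    for lower, upper, label, f_air in [
        (0.0, 1e-5, "<0.00001", 0.01),
        (1e-5, 1e-4, "0.00001 to <0.0001", 0.1),
        (1e-4, 1e-3, "0.0001 to <0.001", 0.2),
        (1e-3, 1e-2, "0.001 to <0.01", 0.5),
        (1e-2, "inf", ">=0.01", 1.0),
    ]:
        rows.append(
            {
                "method": "spray",
                "lower_pa": lower,
                "upper_pa": upper,
                "band_label": label,
                "f_air": f_air,
                "f_soil": round(1.0 - f_air, 10),
                "f_surface_water": 0.0,
                "f_waste": 0.0,
                "sperc_id": "8d.2.v2",
            }
        )
    rows.append(
        {
            "method": "granular",
            "lower_pa": 0.0,
            "upper_pa": "inf",
            "band_label": "all",
            "f_air": 0.0,
            "f_soil": 1.0,
            "f_surface_water": 0.0,
            "f_waste": 0.0,
            "sperc_id": "8d.1.v2",
        }
    )
    return {"version": 2, "mass_balance_mode": "coupled", "rows": rows}


@pytest.fixture
def synthetic_v3_table_dict(synthetic_v2_table_dict):
    """Synthetic stand-in for version 3: non-zero surface water with air
    reduced to keep the coupled sum at or below 1."""
    raw = {"version": 3, "mass_balance_mode": "coupled", "rows": []}
    for r in synthetic_v2_table_dict["rows"]:
        r = dict(r)
        r["sperc_id"] = r["sperc_id"].replace("v2", "v3")
        if r["method"] == "spray":
            r["f_surface_water"] = 0.002
            r["f_air"] = round(max(r["f_air"] - 0.002, 0.0), 10)
        raw["rows"].append(r)
    return raw


@pytest.fixture
def small_inventory_csv(tmp_path):
    path = tmp_path / "inv.csv"
    path.write_text(
        "id,name,vapor_pressure_pa,physical_state,is_inorganic,is_polymer,"
        "use_tonnage_t_per_y\n"
        "S1,solvent A,2.3E-4,liquid,false,false,120\n"
        "S2,filler B,,solid,true,false,40\n"
        "S3,thickener C,1e-6,solid,false,true,10\n"
        "S4,surfactant D,0.05,liquid,false,false,5\n"
        "S5,no-data E,,solid,false,false,\n"
        "S6,bad F,not-a-number,solid,false,false,\n"
        "S7,implausible G,1e12,solid,false,false,2\n"
    )
    return path
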