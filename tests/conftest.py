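import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hipcea.engine import SimulationConfig
from hipcea.life_tables import LifeTable, Sex
from hipcea.synthetic import default_life_table, packaged_parameters

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return packaged_parameters()


@pytest.fixture(scope="session")
def female_table():
    return default_life_table(Sex.FEMALE)


@pytest.fixture(scope="session")
def male_table():
    return default_life_table(Sex.MALE)


@pytest.fixture
def base_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def zero_mortality_table():
    return LifeTable(sex=Sex.FEMALE, min_age=0, q=np.zeros(121))


@pytest.fixture(scope="session")
def no_event_overrides():
    """Overrides that switch off every implant event for all strategies."""
    out = {}
    for a in (65, 70, 75, 80, 85):
        out[f"p_dis_sb_{a}"] = 0.0
        out[f"p_rev_dis_sb_{a}"] = 0.0
        out[f"p_rev_nondis_sb_{a}"] = 0.0
    return out


@pytest.fixture(scope="session")
def identical_strategy_overrides():
    """Overrides that make the three strategies clinically and economically
    identical (unit relative risks, shared utilities and costs)."""
    return {
        "rr_dis_dm_vs_sb": 1.0, "rr_dis_dm_vs_bha": 1.0,
        "rr_rev_dis_bha_vs_dm": 1.0, "rr_rev_nondis_bha_vs_dm": 1.0,
        "rr_rev_dis_dm_vs_sb": 1.0, "rr_rev_nondis_dm_vs_sb": 1.0,
        "u_well_bha": 0.87, "u_well_sb": 0.87, "u_well_dm": 0.87,
        "c_implant_bha": 714000.0, "c_implant_sb": 714000.0, "c_implant_dm": 714000.0,
        "fee_bha": 376900.0, "fee_sb": 376900.0, "fee_dm": 376900.0,
        "c_initial_bha": 2191285.0, "c_initial_sb": 2191285.0, "c_initial_dm": 2191285.0,
    }


def icer_se(a, b):
    """Delta-method standard error of the ICER of a vs b, ignoring the
    (typically variance-reducing) cost-effect covariance."""
    d_cost = a.mean_cost - b.mean_cost
    d_qaly = a.mean_qaly - b.mean_qaly
    var_dc = a.se_cost**2 + b.se_cost**2
    var_de = a.se_qaly**2 + b.se_qaly**2
    ratio = d_cost / d_qaly
    return np.sqrt(var_dc + ratio**2 * var_de) / abs(d_qaly)


@pytest.fixture(scope="session")
def icer_se_fn():
    return icer_se
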