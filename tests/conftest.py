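import pytest

from persoref import BVProfile, HSPEstimate, case_table


@pytest.fixture(scope="session")
def case_rows():
    return case_table.load_case()


@pytest.fixture(scope="session")
def case_by_name(case_rows):
    return {r.profile.measurand_name: r for r in case_rows}


@pytest.fixture
def generic_profile():
    return BVProfile("analyte", "U/L", cv_i=10.0, cv_g=20.0, cv_a=2.0,
                     pop_ri_lower=1.0, pop_ri_upper=9.0, display_decimals=2)


@pytest.fixture
def generic_hsp():
    return HSPEstimate(mean=5.0, sd=0.5, n=3)
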