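import numpy as np
import pytest

from censuswalk import HospitalSimConfig, calibrate, simulate_hospital

#: master seeds for the study-scale reference ensembles; every test that needs
#: a calibration band shares these so the (slow-ish) Monte Carlo runs once.
WHITE_SEED = 11
BROWNIAN_SEED = 12
STUDY_N = 1329
STUDY_M = 100


@pytest.fixture(scope="session")
def white_ensemble():
    return calibrate("white", STUDY_N, m=STUDY_M, seed=WHITE_SEED)


@pytest.fixture(scope="session")
def brownian_ensemble():
    return calibrate("brownian", STUDY_N, m=STUDY_M, seed=BROWNIAN_SEED)


@pytest.fixture(scope="session")
def clean_panel():
    """One artifact-free simulated command panel at the study scale."""
    return simulate_hospital(HospitalSimConfig(), seed=7).series


@pytest.fixture()
def panel_csv(tmp_path, clean_panel):
    from censuswalk import write_panel_csv

    path = tmp_path / "panel.csv"
    write_panel_csv(clean_panel, path)
    return path


def make_panel(adm, dis, inp, beds=192, dates=None):
    from censuswalk import PanelSeries

    return PanelSeries(adm=np.asarray(adm, float), dis=np.asarray(dis, float),
                       inp=np.asarray(inp, float), beds=beds, dates=dates)
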