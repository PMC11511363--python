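import pytest

from bilicomp.optical import (
    OpticalParams,
    calibration_panel_spec,
    default_params,
    simulate_panel,
    default_panel_spec,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def noiseless_params():
    return default_params().with_(noise_rel_sd=0.0)


@pytest.fixture(scope="session")
def additive_params():
    """Noiseless additive-interference parameters: exact linear dR law."""
    return default_params().with_(
        noise_rel_sd=0.0, interference_mode="additive", additive_gamma=0.5
    )


@pytest.fixture(scope="session")
def noiseless_panel(noiseless_params):
    return simulate_panel(default_panel_spec(), noiseless_params, seed=0)


@pytest.fixture(scope="session")
def noisy_panel(params):
    return simulate_panel(default_panel_spec(), params, seed=42)


@pytest.fixture(scope="session")
def noisy_calibration(params):
    return simulate_panel(calibration_panel_spec(), params, seed=42)


@pytest.fixture(scope="session")
def additive_panel(additive_params):
    """Additive-mode oracle panel with a truly non-hemolyzed reference group.

    At 0.0 g/dL the additive hemoglobin offset vanishes, so the reference
    group lies exactly on the exponential calibration law and the whole
    pipeline (calibrate → deltas → linear fit → correct → invert) is exact.
    """
    from bilicomp.optical import PanelSpec, PANEL_BILIRUBIN_MGDL

    spec = PanelSpec(PANEL_BILIRUBIN_MGDL, (0.0, 0.29, 0.50, 0.75, 0.99), 5)
    return simulate_panel(spec, additive_params, seed=0)
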