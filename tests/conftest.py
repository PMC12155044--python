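import numpy as np
import pandas as pd
import pytest

from serorate import (NoiseParams, ObservationModel, SeroresponseDraw,
                      SimulationConfig, SRParamEnsemble, default_ensemble,
                      default_noise)


@pytest.fixture
def toy_draw():
    """Single kinetics draw with round numbers (peak 100x baseline, quadratic
    decay shape)."""
    return SeroresponseDraw("HlyE_IgG", y0=1.0, y1=100.0, t1=10.0,
                            alpha=0.01, r=2.0)


@pytest.fixture
def toy_ensemble(toy_draw):
    df = pd.DataFrame([{
        "antigen_iso": toy_draw.antigen_iso, "y0": toy_draw.y0,
        "y1": toy_draw.y1, "t1": toy_draw.t1, "alpha": toy_draw.alpha,
        "r": toy_draw.r}])
    return SRParamEnsemble(df)


@pytest.fixture
def toy_noise():
    return NoiseParams("HlyE_IgG", nu=1.0, eps=0.2, y_low=0.1, y_high=5000.0)


@pytest.fixture
def toy_model(toy_ensemble, toy_noise):
    return ObservationModel.from_inputs(toy_ensemble, {"HlyE_IgG": toy_noise},
                                        "HlyE_IgG")


@pytest.fixture(scope="session")
def igg_ensemble():
    """Default-condition 20-draw ensemble for the IgG biomarker."""
    return default_ensemble(K=20, seed=0, antigen_isos=["HlyE_IgG"])


@pytest.fixture(scope="session")
def igg_noise():
    return {"HlyE_IgG": default_noise()["HlyE_IgG"]}


@pytest.fixture(scope="session")
def igg_survey(igg_ensemble, igg_noise):
    """One simulated survey under the default study conditions (λ=0.2/PY)."""
    from serorate import simulate_survey
    cfg = SimulationConfig(lambda_true=0.2, n_subjects=1000,
                           ensemble=igg_ensemble, noise=igg_noise, seed=11)
    pop, truth = simulate_survey(cfg)
    return cfg, pop, truth


def write_csv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p
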