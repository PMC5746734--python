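import numpy as np
import pandas as pd
import pytest

from hilicomp import EffectSpec, study_design

PHASES = ["BEH_amide", "amide", "zwitterionic", "diol"]


@pytest.fixture(scope="session")
def design48() -> pd.DataFrame:
    return study_design()


def effect_spec(phase=None, ph=None, ionic=None, baseline=2.0,
                residual_sd=0.0, offset_spread=0.0, interactions=None) -> EffectSpec:
    """Effect spec with zero defaults for unspecified factors."""
    return EffectSpec(
        baseline=baseline,
        offsets={
            "phase": phase or {p: 0.0 for p in PHASES},
            "pH": ph or {"acid": 0.0, "mod_acid": 0.0, "neutral": 0.0},
            "ionic_strength": ionic or {"low": 0.0, "high": 0.0},
        },
        interactions=interactions or {},
        residual_sd=residual_sd,
        offset_spread=offset_spread,
    )


@pytest.fixture
def strong_phase_spec() -> EffectSpec:
    """Phase offsets of 5 and 2.5 residual standard deviations (sigma=0.1)."""
    return effect_spec(phase={"BEH_amide": 0.5, "amide": -0.5,
                              "zwitterionic": 0.25, "diol": -0.25},
                       residual_sd=0.1)


@pytest.fixture
def met_names() -> list[str]:
    return [f"m{i + 1:02d}" for i in range(54)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
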