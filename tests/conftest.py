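import numpy as np
import pandas as pd
import pytest

import regenscan
from regenscan.config import GeneratorConfig

#: configuration used for coefficient-recovery simulations: clean separation
#: between intact and partially regenerated limbs (so the detector is exact),
#: homoskedastic Gaussian organ noise, and only the regenerated-mass effect
#: injected.
RECOVERY_KWARGS = dict(
    n_crabs=736,
    cw_range=(18.0, 32.0),
    limb_noise_sd=0.02,
    p_loss_sd=0.0,
    molt_stage_range=(0.98, 1.02),
    regen_fraction_range=(0.1, 0.6),
    organ_allometry=((6e-5, 2.8), (9e-5, 2.8), (3e-5, 2.7), (6e-4, 2.9)),
    organ_noise_sd=0.08,
    organ_noise_model="gaussian",
    season_amplitude=0.0,
    tradeoff_coeffs=(
        (0.0, 0.0, -0.05311),
        (0.0, 0.0, -0.07376),
        (0.0, 0.0, -0.005),
        (0.0, 0.0, -1.24),
    ),
)

#: noiseless configuration under which residual-threshold detection must
#: recover the truth flags exactly (fractions up to 0.9 regenerated)
NOISELESS_KWARGS = dict(
    n_crabs=400,
    cw_range=(22.0, 32.0),
    p_loss=0.12,
    p_loss_sd=0.0,
    p_bud_given_loss=0.2,
    p_partial_given_loss=0.5,
    regen_fraction_range=(0.1, 0.9),
    limb_noise_sd=0.0,
    molt_stage_range=(1.0, 1.0),
)


def recovery_config(seed: int, **overrides) -> GeneratorConfig:
    kwargs = dict(RECOVERY_KWARGS)
    kwargs.update(overrides)
    return GeneratorConfig(seed=seed, **kwargs)


def noiseless_config(seed: int, **overrides) -> GeneratorConfig:
    kwargs = dict(NOISELESS_KWARGS)
    kwargs.update(overrides)
    return GeneratorConfig(seed=seed, **kwargs)


def flags_long(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-crab flag table -> long (crab_id, limb, flag) frame."""
    fl = flags.copy()
    fl.columns = [int(c[-2:]) for c in fl.columns]
    long = fl.stack().rename("flag").reset_index()
    long.columns = ["crab_id", "limb", "flag"]
    return long


def detection_confusion(crabs, truth, flags):
    """(sensitivity, specificity, exact) of regeneration flags vs truth."""
    merged = truth.limb_truth.merge(flags_long(flags), on=["crab_id", "limb"])
    partial = merged[merged.true_status == "partial"]
    intact = merged[merged.true_status == "intact"]
    sens = float(partial.flag.mean()) if len(partial) else np.nan
    spec = 1.0 - float(intact.flag.mean()) if len(intact) else np.nan
    exact = bool((merged.flag == (merged.true_status == "partial")).all())
    return sens, spec, exact


@pytest.fixture(scope="session")
def default_pop():
    cfg = GeneratorConfig(n_crabs=250, seed=11)
    crabs, truth = regenscan.generate_population(cfg)
    return cfg, crabs, truth


@pytest.fixture(scope="session")
def default_fits(default_pop):
    _, crabs, _ = default_pop
    return regenscan.allometry.fit_all_limbs(crabs)


@pytest.fixture(scope="session")
def default_assessment(default_pop, default_fits):
    _, crabs, _ = default_pop
    return regenscan.assess_population(crabs, default_fits)
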