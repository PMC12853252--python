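"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from oculoscene import stats
from oculoscene.config import RunConfig
from oculoscene.pipeline import preprocess_block
from oculoscene.scenes import build_session
from oculoscene.synth import SynthParams, draw_traits, simulate_block, simulate_participant


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_params():
    return SynthParams()


@pytest.fixture(scope="session")
def one_block():
    """One simulated 10-trial block plus its preprocessed signals."""
    params = SynthParams()
    rng = np.random.default_rng(7)
    traits = draw_traits(params, rng)
    design = build_session(3, n_blocks=1)
    trials = [t for t in design.trials if t.block == 1][:10]
    block = simulate_block(1, trials, traits, params, rng)
    prep = preprocess_block(block, RunConfig())
    return block, prep


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants x 1 block, fully preprocessed (for group-level tests)."""
    cfg = RunConfig(n_participants=6, n_blocks=1)
    out = []
    for ss in np.random.SeedSequence(21).spawn(6):
        rng = np.random.default_rng(ss)
        design = build_session(int(rng.integers(2 ** 31)), n_blocks=1)
        blocks, traits, responses = simulate_participant(design, cfg.synth, rng)
        table = pd.concat([b.trial_table for b in blocks], ignore_index=True)
        scored = stats.score_trial_presses(table, responses)
        preps = [preprocess_block(b, cfg) for b in blocks]
        out.append(dict(blocks=blocks, preps=preps, scored=scored, traits=traits))
    return cfg, out


@pytest.fixture(scope="session")
def recovery_cohort():
    """Twelve participants x 2 blocks: the scaled parameter-recovery dataset."""
    cfg = RunConfig(n_participants=12, n_blocks=2)
    out = []
    for ss in np.random.SeedSequence(1234).spawn(12):
        rng = np.random.default_rng(ss)
        design = build_session(int(rng.integers(2 ** 31)), n_blocks=2)
        blocks, traits, responses = simulate_participant(design, cfg.synth, rng)
        table = pd.concat([b.trial_table for b in blocks], ignore_index=True)
        scored = stats.score_trial_presses(table, responses)
        preps = [preprocess_block(b, cfg) for b in blocks]
        out.append(dict(preps=preps, scored=scored, traits=traits))
    return cfg, out
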