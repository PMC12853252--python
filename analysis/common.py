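"""Shared helpers for the numbered analysis drivers.

All drivers work on the same simulated cohort (12 participants x 2 blocks,
the desk-scale preset) so their results refer to one dataset.  The cohort is
cached under scratch/cache/ after the first simulation; delete the cache to
re-simulate.
"""

from __future__ import annotations

import pickle
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

COHORT_SEED = 1234
N_PARTICIPANTS = 12
N_BLOCKS = 2


def load_cohort(seed: int = COHORT_SEED, n_participants: int = N_PARTICIPANTS,
                n_blocks: int = N_BLOCKS, cache: bool = True):
    """Simulate (or load) the analysis cohort.

    Returns ``(cfg, cohort)`` where each cohort entry holds the preprocessed
    blocks (``preps``), scored behavior (``scored``), raw responses, and the
    generator traits.
    """
    from oculoscene import stats
    from oculoscene.config import RunConfig
    from oculoscene.pipeline import preprocess_block
    from oculoscene.scenes import build_session
    from oculoscene.synth import simulate_participant

    cache_path = (ROOT / "scratch" / "cache"
                  / f"cohort_{seed}_{n_participants}x{n_blocks}.pkl")
    cfg = RunConfig(n_participants=n_participants, n_blocks=n_blocks, seed=seed)
    if cache and cache_path.exists():
        with open(cache_path, "rb") as fh:
            return cfg, pickle.load(fh)

    cohort = []
    for pi, ss in enumerate(np.random.SeedSequence(seed).spawn(n_participants)):
        rng = np.random.default_rng(ss)
        design = build_session(int(rng.integers(2 ** 31)), n_blocks=n_blocks)
        blocks, traits, responses = simulate_participant(design, cfg.synth, rng)
        table = pd.concat([b.trial_table for b in blocks], ignore_index=True)
        scored = stats.score_trial_presses(table, responses)
        preps = [preprocess_block(b, cfg) for b in blocks]
        cohort.append(dict(participant=f"P{pi:02d}", preps=preps, scored=scored,
                           responses=responses, traits=traits))
        print(f"  simulated {cohort[-1]['participant']}", file=sys.stderr)
    if cache:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        with open(cache_path, "wb") as fh:
            pickle.dump(cohort, fh)
    return cfg, cohort


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
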