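"""Stimulus and session design: the tone-cloud scenes and their composition.

Builds one full session and reports the design facts that everything
downstream relies on: the ERB-spaced carrier pool, the per-block condition
counts, decoy proportion, and change-time scheduling.  Writes the trial
table and the frequency pool under results/design/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir

from oculoscene.scenes import (build_scene, build_session, erb_number,
                               make_frequency_pool)


def main():
    out = outdir("design")

    pool = make_frequency_pool()
    cams = erb_number(pool)
    pd.DataFrame(dict(carrier_hz=pool, erb_number_cam=cams)).to_csv(
        out / "frequency_pool.tsv", sep="\t", index=False)
    print(f"carrier pool: {np.round(pool, 1).tolist()} Hz")
    print(f"ERB-rate spacing: {np.diff(cams)[0]:.3f} cam (constant)")

    design = build_session(0)
    table = design.trial_table()
    table.to_csv(out / "trial_table.tsv", sep="\t", index=False)
    main_counts = table[~table.is_decoy].condition.value_counts()
    print(f"\nsession: {len(table)} trials in {design.n_blocks} blocks "
          f"({len(table) // design.n_blocks} per block)")
    print(f"decoy trials: {int(table.is_decoy.sum())} "
          f"({100 * table.is_decoy.mean():.0f}%)")
    print(f"analyzable trials per main condition: "
          f"{main_counts.min()}-{main_counts.max()}")

    rng = np.random.default_rng(0)
    cd_times = [build_scene("CD", "REG", rng).change_time_s for _ in range(200)]
    print(f"\nCA change time: exactly 6.000 s by construction")
    print(f"CD-REG change times: {np.mean(cd_times):.3f} +- "
          f"{np.std(cd_times):.3f} s (scheduled at the expected onset of the "
          f"first missing tone, always ~6 s)")


if __name__ == "__main__":
    main()
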