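"""Cine-angiography branch counting across experimental groups.

Generates ten seeded contrast-arrival sequences per group from the
bundled branching profiles, runs subtraction, median filtering and
automated generation counting, and compares group means per branching
generation.  The hyperoxia profile encodes losses of ~18% (generation
2) and ~21% (generation 3); IL-1Ra largely restores them.
"""

from pathlib import Path

import pandas as pd

from bpdph import experiments
from bpdph.profiles import angiogram_trees

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    tables = {
        g: experiments.angiography_generation_counts(g)
        for g in angiogram_trees()["conditions"]
    }
    pd.concat(tables.values()).to_csv(OUT / "angio_generation_counts.csv", index=False)
    air = tables["air_vehicle"]
    for g, df in tables.items():
        exact = (
            (df[["gen1", "gen2", "gen3"]].to_numpy() == df[["true1", "true2", "true3"]].to_numpy())
            .all(axis=1)
            .mean()
        )
        print(
            f"  {g:<22s} mean counts g1-g3: "
            f"{df['gen1'].mean():.1f} / {df['gen2'].mean():.1f} / {df['gen3'].mean():.1f}"
            f"   (exact recovery in {exact:.0%} of seeds)"
        )
    hyp = tables["hyperoxia_vehicle"]
    r2 = 100 * (1 - hyp["gen2"].mean() / air["gen2"].mean())
    r3 = 100 * (1 - hyp["gen3"].mean() / air["gen3"].mean())
    print(f"  hyperoxia vs air: generation 2 -{r2:.0f}%, generation 3 -{r3:.0f}%")


if __name__ == "__main__":
    main()
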