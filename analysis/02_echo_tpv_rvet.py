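"""Doppler-derived pulmonary vascular resistance surrogate per group.

Builds the deterministic velocity envelope of each bundled timing
profile, detects the ejection window, and computes TPV/RVET — the
index that falls when pulmonary vascular resistance rises.  Expected:
0.32 (air vehicle), 0.27 (hyperoxia vehicle), 0.31 (hyperoxia IL-1Ra).
"""

from pathlib import Path

import pandas as pd

from bpdph import experiments
from bpdph.profiles import doppler_profiles

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for group in doppler_profiles()["profiles"]:
        ratio = experiments.echo_group_ratio(group)
        rows.append({"group": group, "tpv_rvet": ratio})
        print(f"  {group:<22s} TPV/RVET = {ratio:.3f}")
    pd.DataFrame(rows).to_csv(OUT / "echo_tpv_rvet.csv", index=False)
    print("Hyperoxia lowers the ratio (higher resistance); IL-1Ra restores it.")


if __name__ == "__main__":
    main()
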