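"""Synthetic qPCR CT tables around configured group means."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..molquant import ExpressionTable

__all__ = ["generate_ct_table"]


def generate_ct_table(
    group_means: dict[str, dict[str, float]],
    noise_sd: float = 0.25,
    n_per_group: int = 8,
    seed: int = 0,
    *,
    housekeeping: str = "Actb",
) -> ExpressionTable:
    """Draw per-sample CT values as group mean + N(0, noise_sd) cycles.

    ``group_means`` maps group label -> {gene -> mean CT}; the
    housekeeping gene must be present in every group.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for g, means in group_means.items():
        if housekeeping not in means:
            raise ValueError(f"housekeeping gene {housekeeping!r} missing from group {g!r}")
    rng = np.random.default_rng(seed)

    rows = []
    for group, means in group_means.items():
        for i in range(n_per_group):
            row = {"sample": f"{group}_{i + 1}", "group": group}
            for gene, mu in means.items():
                row[gene] = mu + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(row)
    df = pd.DataFrame(rows).set_index("sample")
    return ExpressionTable(ct=df.drop(columns="group"), groups=df["group"], housekeeping=housekeeping)
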