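#!/usr/bin/env python
"""Exact statistics on counted-cell and colony-loss experiments.

Simulates cell-count tables like a mitotic-arrest scoring experiment (five
SPI strains vs a control, 141-560 cells per condition), tests each strain
against the control with Fisher's exact test, attaches 95% Clopper-Pearson
intervals, and estimates plasmid/chromosome loss frequencies from pooled
replicate platings.  Writes results/counts/*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from spiscreen.counts import (
    binomial_ci,
    fisher_exact,
    loss_frequency,
    pool_counts,
    sectored_colonies,
)
from spiscreen.io import write_table
from spiscreen.synthetic import generate_counts

OUT = Path(__file__).resolve().parent.parent / "results" / "counts"
SEED = 20160611


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- mitotic-arrest scoring: five SPI strains vs control -------------
    labels = ["control"] + [f"spi-{i}" for i in range(1, 6)]
    n_cells = [560, 141, 220, 310, 450, 260]
    true_p = [0.05, 0.45, 0.40, 0.30, 0.25, 0.15]
    counts = generate_counts(n_cells, true_p, seed=SEED, labels=labels)

    ctrl = counts.iloc[0]
    rows = []
    for _, row in counts.iloc[1:].iterrows():
        p = fisher_exact(
            [[int(row["positive"]), int(row["negative"])],
             [int(ctrl["positive"]), int(ctrl["negative"])]]
        )
        est = binomial_ci(int(row["positive"]), int(row["total"]))
        rows.append(
            {
                "condition": row["condition"],
                "positive": row["positive"],
                "total": row["total"],
                "proportion": round(est.proportion, 4),
                "ci_low": round(est.ci_low, 4),
                "ci_high": round(est.ci_high, 4),
                "fisher_p_vs_control": p,
            }
        )
    arrest = pd.DataFrame(rows)
    write_table(arrest, OUT / "mitotic_arrest.tsv")
    print(arrest.to_string(index=False))

    # --- plasmid loss: 8 replicates of ~1000 cells ------------------------
    rng = np.random.default_rng(SEED)
    true_loss = 0.12
    reps = []
    for _ in range(8):
        plated = rng.integers(500, 1001)
        kept = rng.binomial(plated, 1.0 - true_loss)
        reps.append((plated - kept, plated))  # (lost, permissive total)
    lost, total = pool_counts(reps)
    est = binomial_ci(lost, total)
    per_rep = [loss_frequency(n - k, n) for k, n in reps]
    write_table(
        pd.DataFrame({"replicate": range(1, 9), "loss_frequency": np.round(per_rep, 4)}),
        OUT / "plasmid_loss_replicates.tsv",
    )
    print(
        f"plasmid loss: pooled {lost}/{total} = {est.proportion:.3f} "
        f"[{est.ci_low:.3f}, {est.ci_high:.3f}] (true {true_loss})"
    )

    # --- chromosome loss: red-sectored colonies ---------------------------
    sect = sectored_colonies(int(rng.binomial(1000, 0.02)), 1000)
    print(
        f"chromosome loss: {sect.successes}/1000 sectored = {sect.proportion:.3f} "
        f"[{sect.ci_low:.3f}, {sect.ci_high:.3f}]"
    )


if __name__ == "__main__":
    main()
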