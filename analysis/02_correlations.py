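#!/usr/bin/env python
"""Per-cell-line correlation maps between markers and environment features.

Reads the simulated marker table (run 01_simulate.py first), computes the
(16 markers + 5 environment features) Pearson correlation matrix for each
cell line, and exports CSVs plus a heatmap per line.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from mpsprofiler import correlation_matrix, read_marker_table
from mpsprofiler.data_model_io import CELL_LINES, ENV_FEATURE_NAMES

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_marker_table(ROOT / "synthetic" / "markers.csv")
    out = ROOT / "correlations"
    out.mkdir(parents=True, exist_ok=True)
    for line in CELL_LINES:
        m = correlation_matrix(table, line)
        m.to_csv(out / f"correlation_{line}.csv")
        fig, ax = plt.subplots(figsize=(8, 7))
        im = ax.imshow(m.values, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(m.labels)), m.labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(m.labels)), m.labels, fontsize=6)
        fig.colorbar(im, shrink=0.8)
        fig.tight_layout()
        fig.savefig(out / f"correlation_{line}.png", dpi=150)
        plt.close(fig)

        # report the strongest marker-environment couplings
        n_markers = len(table.marker_names)
        env_block = m.values[:n_markers, n_markers:]
        flat = [
            (abs(env_block[i, j]), table.marker_names[i], ENV_FEATURE_NAMES[j],
             env_block[i, j])
            for i in range(n_markers)
            for j in range(env_block.shape[1])
            if np.isfinite(env_block[i, j])
        ]
        flat.sort(reverse=True)
        print(f"{line}: strongest marker-environment correlations")
        for _, marker, feat, r in flat[:4]:
            print(f"  {marker:20s} vs {feat:12s} r = {r:+.2f}")


if __name__ == "__main__":
    main()
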