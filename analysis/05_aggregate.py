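#!/usr/bin/env python
"""Cross-condition feature-importance aggregation.

Sums each marker's mutual-information score over all 12 condition levels
and ranks the panel, exporting the combined table and a bar chart.  On
the planted design the mesenchymal/CD44-family markers should lead and
proliferation/ALDH+% should trail.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from mpsprofiler import aggregate_importance, read_marker_table, run_all_conditions
from mpsprofiler.profiling_pipeline import derive_seed

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    table = read_marker_table(ROOT / "synthetic" / "markers.csv")
    out = ROOT / "aggregate"
    out.mkdir(parents=True, exist_ok=True)
    profiles = run_all_conditions(table, seed=derive_seed(SEED, "conditions"))
    agg = aggregate_importance(profiles)
    frame = agg.to_frame()
    frame.to_csv(out / "aggregate_importance.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.barh(frame["marker"][::-1], frame["combined_score"][::-1])
    ax.set_xlabel("combined MI score (nats, summed over 12 levels)")
    fig.tight_layout()
    fig.savefig(out / "aggregate_importance.png", dpi=150)
    plt.close(fig)

    print("combined feature importance (top 5):")
    for _, row in frame.head(5).iterrows():
        print(f"  {row['marker']:20s} {row['combined_score']:.2f} "
              f"(retained at {row['times_retained']}/12 levels)")
    print("lowest-scoring (bottom 3):")
    for _, row in frame.tail(3).iterrows():
        print(f"  {row['marker']:20s} {row['combined_score']:.2f}")


if __name__ == "__main__":
    main()
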