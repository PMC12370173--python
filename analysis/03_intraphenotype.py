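#!/usr/bin/env python
"""How many environment-driven behaviors exist within each cell line?

Clusters each cell line's records (all 12 microenvironments pooled,
z-scored markers) with k-means for k = 2..6 and selects k by the
least-drop silhouette rule, then cross-tabulates the chosen bipartition
against the stress conditions (pH 6.5 / dynamic perfusion).
"""

import json
from pathlib import Path

from mpsprofiler import intraphenotype_behaviors, read_marker_table
from mpsprofiler.data_model_io import CELL_LINES
from mpsprofiler.profiling_pipeline import derive_seed

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    table = read_marker_table(ROOT / "synthetic" / "markers.csv")
    out = ROOT / "intraphenotype"
    out.mkdir(parents=True, exist_ok=True)
    doc = {}
    for line in CELL_LINES:
        res = intraphenotype_behaviors(
            table, line, k_max=6, seed=derive_seed(SEED, "intraphenotype")
        )
        doc[line] = {
            "k_star": res.k_star,
            "silhouette_by_k": {str(k): round(v, 4) for k, v in res.scores.items()},
            "low_confidence": res.low_confidence,
        }
        res.assignments_frame.to_csv(out / f"clusters_{line}.csv", index=False)
        print(f"{line}: k* = {res.k_star}  "
              f"silhouettes {doc[line]['silhouette_by_k']}")
        frame = res.assignments_frame
        stress = (frame["pH"] == 6.5) | (frame["perfusion"] == "dynamic")
        tab = frame.groupby([stress.rename("stress"), "cluster"]).size()
        print("  cluster membership vs stress condition:")
        print("  " + tab.to_string().replace("\n", "\n  "))
    (out / "intraphenotype.json").write_text(json.dumps(doc, indent=1))


if __name__ == "__main__":
    main()
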