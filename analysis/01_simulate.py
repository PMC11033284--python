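"""Generate the synthetic storage study and summarize its structure.

Emulates the study design: five pesticides observed daily for 30 days under
25/30/35/40 degC at 65 % RH and 65/70/75/80 % RH at 25 degC (the shared
25 degC / 65 % condition counts once per sweep arm), 1200 records in all.
Writes the residue table and a per-series summary under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ricestore.io import write_residue_table
from ricestore.synthetic import StudyDesign, generate_study_dataset

OUT = Path("results")
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    design = StudyDesign()
    data = generate_study_dataset(design, seed=SEED)
    write_residue_table(data, OUT / "residues.csv")

    rows = []
    for s in data:
        drop_week1 = 1 - s.conc[7] / s.conc[0]
        rows.append((s.pesticide, s.condition.temperature_C,
                     s.condition.rh_pct, s.conc[0], s.conc[-1], drop_week1))
    df = pd.DataFrame(rows, columns=["pesticide", "temperature_C", "rh_pct",
                                     "c0_mgkg", "c30_mgkg",
                                     "frac_lost_week1"])
    df.to_csv(OUT / "series_summary.csv", index=False)

    n = sum(len(s) for s in data)
    print(f"generated {n} records across {len(data)} condition series")
    wk1 = df.groupby("pesticide")["frac_lost_week1"].mean().sort_values()
    print("mean fraction degraded in week 1 (slowest first):")
    for pest, frac in wk1.items():
        print(f"  {pest:22s} {frac:5.1%}")
    print("-> the slow degrader keeps most of its residue past day 7, the "
          "others flatten after the first week")


if __name__ == "__main__":
    main()
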