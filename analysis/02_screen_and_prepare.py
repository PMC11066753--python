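"""Screen the cohort by the inclusion rules and prepare each included series.

Applies the two preregistered-style rules (>= 130 days of data, < 30%
missingness on every variable), then selects the longest phase free of >7-day
item-wise gaps, Kalman-imputes the remaining short gaps and z-standardizes.
Prepared series go to results/prepared/, the screening table to results/.
"""

from pathlib import Path

import pandas as pd

from tvvarnet import (
    kalman_impute,
    load_diary_csv,
    screen_inclusion,
    select_longest_segment,
    z_standardize,
)
from tvvarnet.pipeline import write_dataset_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
PREP = ROOT / "prepared"
PREP.mkdir(parents=True, exist_ok=True)

rows = []
for csv in sorted((ROOT / "cohort").glob("*.csv")):
    if csv.name == "cohort_manifest.csv":
        continue
    ds = load_diary_csv(csv, "date", participant_id=csv.stem)
    rep = screen_inclusion(ds)
    row = {
        "participant": csv.stem,
        "n_days": rep.n_days,
        "worst_missing_pct": round(100 * rep.missing_frac_per_var.max(), 2),
        "included": rep.included,
        "reasons": ";".join(rep.reasons),
    }
    if rep.included:
        seg = select_longest_segment(ds)
        prepared, scaling = z_standardize(kalman_impute(seg))
        write_dataset_csv(prepared, PREP / f"{csv.stem}.csv")
        row["segment_days"] = seg.T
    rows.append(row)
    status = "included" if rep.included else f"EXCLUDED ({row['reasons']})"
    print(f"{csv.stem}: {rep.n_days} days, worst missing {row['worst_missing_pct']}% -> {status}")

table = pd.DataFrame(rows)
table.to_csv(ROOT / "screening.csv", index=False)
print(f"\n{int(table.included.sum())}/{len(table)} participants included; table at results/screening.csv")
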