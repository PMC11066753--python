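"""Block-bootstrap stability of the fitted time-varying coefficients.

For each fitted participant, refit the tv-VAR on block-resampled lag pairs
and summarize 90% bands per edge per estimation point. Wide bands relative to
the point estimates flag edges whose presence should not be over-interpreted.
Also reports the 3 most time-varying edges of each participant's model.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tvvarnet import bootstrap_tvvar, edge_variability_ranking, load_diary_csv
from tvvarnet.tvvar import KernelSpec, LocalVarFit, TvVarModel

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"

N_BOOT = 30


def load_model(path):
    obj = json.loads(path.read_text())
    fits = [
        LocalVarFit(
            np.array(f["intercepts"]), np.array(f["B"]),
            np.array(f["residual_sd"]), np.array(f["lambda_used"]), f["flags"],
        )
        for f in obj["fits"]
    ]
    kernel = KernelSpec(obj["bandwidth"], obj["n_estimation_points"])
    return TvVarModel(kernel, fits, obj["T"], obj["var_names"])


rows = []
for fit_dir in sorted((ROOT / "fits").iterdir()):
    model = load_model(fit_dir / "model.json")
    ds = load_diary_csv(ROOT / "prepared" / f"{fit_dir.name}.csv", "date")
    ds.standardized = True
    ens = bootstrap_tvvar(
        ds, model.kernel.bandwidth, n_points=model.n_points, n_boot=N_BOOT, seed=SEED
    )
    ens.to_frame().to_csv(fit_dir / "bootstrap_samples.csv", index=False)
    top = edge_variability_ranking(model, top_k=3)
    top.to_csv(fit_dir / "top_varying_edges.csv", index=False)
    coefs = model.coef_array()
    nonzero = coefs != 0
    med_width = float(np.median(ens.band_width()[nonzero])) if nonzero.any() else 0.0
    med_est = float(np.median(np.abs(coefs[nonzero]))) if nonzero.any() else 0.0
    rows.append(
        {
            "participant": fit_dir.name,
            "n_boot": N_BOOT,
            "block_length": ens.block_length,
            "median_band_width_nonzero": round(med_width, 3),
            "median_abs_nonzero_estimate": round(med_est, 3),
        }
    )
    print(
        f"{fit_dir.name}: median 90% band width {med_width:.3f} vs median |estimate| "
        f"{med_est:.3f}; top edge {top.predictor[0]} -> {top.response[0]} "
        f"(SD {top.variability[0]:.3f})"
    )

pd.DataFrame(rows).to_csv(ROOT / "bootstrap_summary.csv", index=False)
print("\nsummary at results/bootstrap_summary.csv")
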