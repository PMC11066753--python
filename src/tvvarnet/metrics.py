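"""Model-quality metrics, data-quality diagnostics and network export.

Predictability is reported per variable *at each estimation point*: residuals
of the kernel-mixed predictions are aggregated with that point's kernel
weights, giving a local R^2 and RMSE whose trajectories show where in the
series the model explains anything. R^2 may be negative for bad local fits
and is reported as-is. Networks are exported as directed weighted edge lists
with display weights scaled to a fixed maximum so figures are comparable
across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DiaryDataset
from .tvvar import TvVarModel, _pair_times, _raw_kernel, predict_all_days

__all__ = [
    "PredictionMetrics",
    "prediction_errors",
    "detect_floor_ceiling",
    "edge_variability_ranking",
    "export_networks",
    "to_networkx",
]


@dataclass
class PredictionMetrics:
    """Per-estimation-point, per-variable R^2 and RMSE with overall means."""

    r2: np.ndarray  # (n_points, p)
    rmse: np.ndarray
    mean_r2: float
    mean_rmse: float
    var_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        n_points, p = self.r2.shape
        rows = []
        for k in range(n_points):
            for j in range(p):
                rows.append(
                    {
                        "estimation_point": k + 1,
                        "variable": self.var_names[j],
                        "r2": self.r2[k, j],
                        "rmse": self.rmse[k, j],
                    }
                )
        return pd.DataFrame(rows)


def prediction_errors(model: TvVarModel, ds: DiaryDataset) -> PredictionMetrics:
    """Kernel-weighted local R^2 and RMSE of the fitted model on its data.

    R^2 at estimation point e = 1 - wMSE/wVar, with both moments taken under
    that point's kernel weights; RMSE = sqrt(wMSE), on the standardized scale.
    The participant-level summaries are plain arithmetic means over the
    (estimation point, variable) grid.
    """
    if ds.p != model.p or ds.T != model.T:
        raise ValueError("dataset dimensions do not match model")
    Y = ds.values[1:]
    pred = predict_all_days(model, ds)
    times = _pair_times(ds.T)
    n_points = model.n_points
    r2 = np.empty((n_points, model.p))
    rmse = np.empty((n_points, model.p))
    sq_err = (Y - pred) ** 2
    for k, t_e in enumerate(model.kernel.estimation_grid):
        w = _raw_kernel(times, t_e, model.kernel.bandwidth)
        S = w.sum()
        wmse = (w[:, None] * sq_err).sum(axis=0) / S
        ybar = (w[:, None] * Y).sum(axis=0) / S
        wvar = (w[:, None] * (Y - ybar) ** 2).sum(axis=0) / S
        r2[k] = 1.0 - wmse / wvar
        rmse[k] = np.sqrt(wmse)
    return PredictionMetrics(
        r2=r2,
        rmse=rmse,
        mean_r2=float(r2.mean()),
        mean_rmse=float(rmse.mean()),
        var_names=list(model.var_names),
    )


def detect_floor_ceiling(
    ds: DiaryDataset,
    scale_bounds: dict[str, tuple[float, float]] | tuple[float, float],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Flag variables piled up at a bounded scale's extremes (raw scale).

    A variable is flagged iff the fraction of its *observed* entries sitting
    exactly at the scale minimum, or the fraction at the maximum, strictly
    exceeds ``threshold`` (a fraction of exactly 0.5 is not flagged). Such
    pileup violates the continuous-Gaussian working assumptions, so flagged
    participants' networks should not be interpreted.
    """
    rows = []
    for j, name in enumerate(ds.var_names):
        lo, hi = scale_bounds[name] if isinstance(scale_bounds, dict) else scale_bounds
        obs = ds.values[ds.mask[:, j], j]
        frac_floor = float(np.mean(obs == lo)) if obs.size else 0.0
        frac_ceiling = float(np.mean(obs == hi)) if obs.size else 0.0
        worst = max(frac_floor, frac_ceiling)
        rows.append(
            {
                "variable": name,
                "frac_floor": frac_floor,
                "frac_ceiling": frac_ceiling,
                "offending_fraction": worst,
                "flagged": worst > threshold,
            }
        )
    return pd.DataFrame(rows)


def edge_variability_ranking(model: TvVarModel, top_k: int = 3) -> pd.DataFrame:
    """Rank edges by the SD of their coefficient across estimation points.

    The most time-varying edges are the interesting ones to plot; returns the
    ``top_k`` with (response, predictor, variability). Ties resolve by edge
    name order so the ranking is stable.
    """
    coefs = model.coef_array()  # (n_points, p, p)
    sd = coefs.std(axis=0)
    sd[sd < 1e-12] = 0.0  # keep constant trajectories exactly tied
    rows = []
    for i in range(model.p):
        for j in range(model.p):
            rows.append(
                {
                    "response": model.var_names[i],
                    "predictor": model.var_names[j],
                    "variability": float(sd[i, j]),
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["variability", "response", "predictor"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df.head(top_k)


def export_networks(
    model: TvVarModel,
    points: tuple[int, ...] = (2, 10, 19),
    max_edge: float = 0.5,
) -> pd.DataFrame:
    """Directed weighted edge lists at selected (1-based) estimation points.

    Display weight = clamp(|coef| / max_edge, 0, 1) with the sign kept as an
    attribute; zero coefficients yield no edge. The day equivalent of each
    estimation point is included so networks can be placed in calendar time.
    """
    for pt in points:
        if not 1 <= pt <= model.n_points:
            raise ValueError(f"estimation point {pt} outside grid 1..{model.n_points}")
    days = model.grid_days()
    rows = []
    for pt in points:
        B = model.fits[pt - 1].B
        for i in range(model.p):
            for j in range(model.p):
                c = B[i, j]
                if c == 0.0:
                    continue
                rows.append(
                    {
                        "estimation_point": pt,
                        "day": int(days[pt - 1]),
                        "from": model.var_names[j],
                        "to": model.var_names[i],
                        "weight": float(c),
                        "display_weight": float(min(abs(c) / max_edge, 1.0)),
                        "sign": "negative" if c < 0 else "positive",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "estimation_point", "day", "from", "to",
            "weight", "display_weight", "sign",
        ],
    )


def to_networkx(model: TvVarModel, point: int, max_edge: float = 0.5):
    """Directed graph of the network at one (1-based) estimation point.

    Nodes are variables; edges carry the raw coefficient plus the display
    weight and sign, so the graph can be written to any text graph format
    (GML, GraphML) for external layout tools.
    """
    import networkx as nx

    G = nx.DiGraph(estimation_point=point, day=int(model.grid_days()[point - 1]))
    G.add_nodes_from(model.var_names)
    for _, row in export_networks(model, points=(point,), max_edge=max_edge).iterrows():
        G.add_edge(
            row["from"], row["to"],
            weight=float(row["weight"]),
            display_weight=float(row["display_weight"]),
            sign=row["sign"],
        )
    return G
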