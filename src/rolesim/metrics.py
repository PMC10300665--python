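"""Segregation index and replicate summaries.

The segregation index of an occupancy table is twice the occupancy-weighted
mean absolute deviation of each role's type share from 50:50,

    S = 2 * sum_r (n0_r + n1_r) |n0_r/(n0_r + n1_r) - 1/2| / sum_r (n0_r + n1_r),

summed over occupied roles; 0 means every role is evenly split, 1 means every
role is performed by a single type.  Empty roles carry no weight; an entirely
empty table has no defined index and is returned as ``None``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def segregation_index(occupancy) -> float | None:
    """Segregation index of a (roles x 2) occupancy count table."""
    occ = np.asarray(occupancy, dtype=float)
    if occ.ndim != 2 or occ.shape[1] != 2:
        raise ValueError("occupancy must be a (n_roles, 2) table")
    if np.any(occ < 0):
        raise ValueError("occupancy counts must be >= 0")
    total = occ.sum(axis=1)
    grand = total.sum()
    if grand == 0:
        return None
    occupied = total > 0
    share0 = occ[occupied, 0] / total[occupied]
    return float(2.0 * np.sum(total[occupied] * np.abs(share0 - 0.5)) / grand)


def summarize_runs(results) -> dict:
    """Summarise replicate runs: mean trajectory and final-value distribution.

    ``results`` is a sequence of :class:`~rolesim.simulation.SimulationResult`
    (or of plain segregation series).  Returns the per-timestep mean series
    and mean/sd/quantiles of the final-timestep values.
    """
    series = [np.asarray(getattr(r, "segregation", r), dtype=float)
              for r in results]
    if not series:
        raise ValueError("need at least one run")
    lengths = {s.shape[0] for s in series}
    if len(lengths) != 1:
        raise ValueError("runs have unequal lengths")
    stacked = np.vstack(series)
    finals = stacked[:, -1] if stacked.shape[1] else np.array([])
    q = (np.percentile(finals, [2.5, 25, 50, 75, 97.5]) if finals.size
         else np.full(5, np.nan))
    return {
        "mean_series": stacked.mean(axis=0),
        "final_values": finals,
        "final_mean": float(finals.mean()) if finals.size else float("nan"),
        "final_sd": float(finals.std(ddof=1)) if finals.size > 1 else 0.0,
        "final_quantiles": dict(zip(("q2.5", "q25", "q50", "q75", "q97.5"),
                                    (float(v) for v in q))),
    }


def tidy_frame(results, model: int, priors: str, theta: float,
               first_replicate: int = 0) -> pd.DataFrame:
    """Long-format table: model, priors, theta, replicate, timestep, segregation."""
    rows = []
    for rep, r in enumerate(results, start=first_replicate):
        series = np.asarray(getattr(r, "segregation", r), dtype=float)
        rows.append(pd.DataFrame({
            "model": model,
            "priors": priors,
            "theta": theta,
            "replicate": rep,
            "timestep": np.arange(series.shape[0]),
            "segregation": series,
        }))
    return pd.concat(rows, ignore_index=True)
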