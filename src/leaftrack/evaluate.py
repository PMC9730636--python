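"""Scoring of predicted leaf ranks against ground truth.

Accuracy is the percentage of non-artefact segmented leaves whose
predicted rank matches the ground-truth rank, split by the leaf's
ligulated/growing status at its own observation date; the mean absolute
error (MAE) of the rank is computed among wrong predictions only.
Standard regression metrics (bias, RMSE, MAPE, R^2) cover continuous
traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LIGULATED, TrackedPlant
from .synthetic import SimulatedTruth

__all__ = ["TrackingScore", "rank_accuracy", "regression_metrics"]


@dataclass
class TrackingScore:
    accuracy_ligulated: float
    accuracy_growing: float
    mae_wrong_ligulated: float  # nan when no wrong assigned prediction
    mae_wrong_growing: float
    n_ligulated: int
    n_growing: int
    n_wrong_ligulated: int = 0
    n_wrong_growing: int = 0


def rank_accuracy(predicted: TrackedPlant, truth: SimulatedTruth) -> TrackingScore:
    """Score predicted ranks observation-by-observation.

    Artefact-flagged observations are excluded.  An unassigned non-artefact
    leaf counts as wrong but enters no MAE (it has no rank error).  Raises
    when an observation lacks a ground-truth label.
    """
    stats = {
        LIGULATED: {"n": 0, "correct": 0, "errors": [], "wrong": 0},
        "growing": {"n": 0, "correct": 0, "errors": [], "wrong": 0},
    }
    for snap in predicted.snapshots:
        if snap.discarded:
            continue
        for lf in snap.leaves:
            if lf.uid not in truth.truth_ranks:
                raise ValueError(f"unmatched observation: {lf.uid}")
            true_rank = truth.truth_ranks[lf.uid]
            if true_rank == "artefact":
                continue
            group = stats[LIGULATED if lf.status == LIGULATED else "growing"]
            group["n"] += 1
            if lf.rank == true_rank:
                group["correct"] += 1
            else:
                group["wrong"] += 1
                if lf.rank is not None:
                    group["errors"].append(abs(lf.rank - int(true_rank)))
    if stats[LIGULATED]["n"] == 0 and stats["growing"]["n"] == 0:
        raise ValueError("degenerate input: no scorable observation")

    def acc(g):
        return 100.0 * g["correct"] / g["n"] if g["n"] else float("nan")

    def mae(g):
        return float(np.mean(g["errors"])) if g["errors"] else float("nan")

    return TrackingScore(
        accuracy_ligulated=acc(stats[LIGULATED]),
        accuracy_growing=acc(stats["growing"]),
        mae_wrong_ligulated=mae(stats[LIGULATED]),
        mae_wrong_growing=mae(stats["growing"]),
        n_ligulated=stats[LIGULATED]["n"],
        n_growing=stats["growing"]["n"],
        n_wrong_ligulated=stats[LIGULATED]["wrong"],
        n_wrong_growing=stats["growing"]["wrong"],
    )


def regression_metrics(pred, obs) -> dict[str, float]:
    """Bias, RMSE, MAPE (%) and R^2 between paired series."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need >= 2 paired values")
    resid = pred - obs
    out = {
        "bias": float(resid.mean()),
        "rmse": float(np.sqrt((resid**2).mean())),
    }
    if np.any(obs == 0):
        import warnings

        warnings.warn("zero observations: MAPE omitted", stacklevel=2)
    else:
        out["mape"] = float(np.mean(np.abs(resid) / np.abs(obs)) * 100.0)
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("degenerate input: constant observations, R^2 undefined")
    out["r2"] = 1.0 - float((resid**2).sum()) / ss_tot
    return out
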