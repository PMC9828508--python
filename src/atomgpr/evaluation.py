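"""Model-quality reporting: S-curves, learning curves, true-vs-predicted
tables and Kabsch superposition of trajectories.

An S-curve is the cumulative distribution of per-configuration total
prediction errors (error on the x axis, percentile on the y axis); the
further left and steeper, the better the model.  "No-cancellation" sums
absolute atomic errors, the pessimistic bound; "cancellation" takes the
magnitude of the signed sum, which is what a simulation consuming total
energies actually feels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .alf import ALFDefinition, featurize
from .gpr import GPRModel, predict_many
from .molio import Trajectory

__all__ = [
    "SCurve",
    "total_prediction_error",
    "s_curve",
    "kabsch_superpose",
    "superpose_trajectory",
    "true_vs_predicted",
    "learning_curve",
]


def total_prediction_error(atomic_pe: np.ndarray,
                           mode: str = "no_cancellation") -> float:
    """Collapse signed per-atom errors into one configuration error.

    ``no_cancellation``: sum of absolute atomic errors.
    ``cancellation``: absolute value of the signed sum (atomic errors may
    offset each other, as they do physically when totals are consumed).
    """
    atomic_pe = np.asarray(atomic_pe, float)
    if atomic_pe.size == 0:
        raise ValueError("need at least one atomic error")
    if mode == "no_cancellation":
        return float(np.sum(np.abs(atomic_pe)))
    if mode == "cancellation":
        return float(abs(np.sum(atomic_pe)))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SCurve:
    sorted_errors: np.ndarray
    percentiles: np.ndarray
    mode: str = "no_cancellation"

    def percentile_below(self, threshold: float) -> float:
        """Percent of configurations with error below ``threshold``."""
        return 100.0 * float(np.mean(self.sorted_errors < threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"error": self.sorted_errors,
                             "percentile": self.percentiles})


def s_curve(per_config_errors: np.ndarray,
            mode: str = "no_cancellation") -> SCurve:
    """Sort configuration errors ascending; the k-th of m errors sits at
    percentile 100*k/m."""
    e = np.sort(np.asarray(per_config_errors, float))
    if e.size == 0:
        raise ValueError("need at least one configuration error")
    pct = 100.0 * np.arange(1, e.size + 1) / e.size
    return SCurve(sorted_errors=e, percentiles=pct, mode=mode)


def kabsch_superpose(A: np.ndarray, B: np.ndarray,
                     subset: list[int] | None = None
                     ) -> tuple[np.ndarray, float]:
    """Optimal proper rotation of B onto A and the all-atom RMSD.

    Centroids are taken over ``subset`` (all atoms when None); the
    rotation minimizing the subset RMSD is found by the Kabsch algorithm
    (determinant +1 enforced, never a reflection), then applied to every
    atom to report the full RMSD.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError("coordinate arrays must share a shape")
    idx = list(range(len(A))) if subset is None else list(subset)
    if len(idx) < 3:
        raise ValueError("need at least 3 subset atoms")
    a = A[idx] - A[idx].mean(axis=0)
    b = B[idx] - B[idx].mean(axis=0)
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise ValueError("subset atoms are collinear or coincident")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    moved = (B - B[idx].mean(axis=0)) @ R.T + A[idx].mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((A - moved) ** 2, axis=1))))
    return R, rmsd


def heavy_atom_subset(elements: list[str]) -> list[int]:
    """Default Kabsch subset: all non-hydrogen atoms (falls back to all
    atoms when fewer than three are heavy)."""
    heavy = [i for i, e in enumerate(elements) if e != "H"]
    return heavy if len(heavy) >= 3 else list(range(len(elements)))


def superpose_trajectory(trajectory: Trajectory,
                         subset: list[int] | None = None) -> Trajectory:
    """Superpose every frame onto the first (mist-plot preprocessing)."""
    if subset is None:
        subset = heavy_atom_subset(trajectory.elements)
    ref = trajectory[0].coordinates
    out = []
    for cfg in trajectory:
        R, _ = kabsch_superpose(ref, cfg.coordinates, subset)
        moved = ((cfg.coordinates - cfg.coordinates[subset].mean(axis=0))
                 @ R.T + ref[subset].mean(axis=0))
        new = type(cfg)(elements=list(cfg.elements), coordinates=moved,
                        frame_id=cfg.frame_id)
        out.append(new)
    return Trajectory(configurations=out,
                      source_tag=trajectory.source_tag + " superposed")


def true_vs_predicted(models: dict[int, GPRModel], trajectory: Trajectory,
                      frame_ids: list[int], oracle,
                      alf: ALFDefinition) -> pd.DataFrame:
    """Per-frame table of true and predicted atomic and total energies.

    ``predicted_total`` is the sum of the per-atom predictions; frames for
    which the oracle cannot supply a truth are skipped.
    """
    atoms = sorted(models)
    rows = []
    for f in frame_ids:
        cfg = trajectory[f]
        row = {"frame_id": f}
        try:
            truths = {a: oracle.atomic_energy(f, a) for a in atoms}
        except Exception:  # oracle failure: skip the row
            continue
        preds = {}
        for a in atoms:
            x = featurize(cfg, alf, a).values
            mu, _ = predict_many(models[a], x[None], with_variance=False)
            preds[a] = float(mu[0])
            row[f"true_atom_{a}"] = truths[a]
            row[f"pred_atom_{a}"] = preds[a]
        row["true_total"] = float(sum(truths.values()))
        row["predicted_total"] = float(sum(preds.values()))
        rows.append(row)
    return pd.DataFrame(rows)


def learning_curve(history: pd.DataFrame) -> pd.DataFrame:
    """Mean/max validation error against training-set size, per atom group."""
    cols = ["atoms", "iteration", "ntrain", "val_rmse", "val_max"]
    return history[cols].copy()
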