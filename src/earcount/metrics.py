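"""Count-evaluation metrics: MAE, RMSE, nRMSE and accuracy rate.

For predictions h_i and true counts y_i over m images:

* ``MAE  = (1/m) Σ |h_i − y_i|``
* ``RMSE = sqrt((1/m) Σ (h_i − y_i)²)``
* ``nRMSE = 100 · RMSE / (y_max − y_min)`` (percent; undefined — reported
  as NaN — when all true counts coincide)
* ``Acc_rate = 100 · mean(1 − |h_i − y_i| / y_i)`` (percent; images with
  y_i = 0 are excluded from the mean and flagged)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EvalReport", "evaluate", "plot_predictions"]


@dataclass
class EvalReport:
    mae: float
    rmse: float
    nrmse_percent: float
    acc_rate_percent: float
    n_images: int
    n_zero_truth: int = 0
    per_image: list[tuple[str, float, float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "nrmse_percent": None if math.isnan(self.nrmse_percent) else self.nrmse_percent,
            "acc_rate_percent": self.acc_rate_percent,
            "n_images": self.n_images,
            "n_zero_truth": self.n_zero_truth,
            "per_image": [
                {"image_id": i, "predicted": h, "true": y, "abs_error": e}
                for i, h, y, e in self.per_image
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(
    predictions, truths, image_ids: list[str] | None = None
) -> EvalReport:
    """Score predicted against true counts.

    Raises on a length mismatch or empty input; a degenerate true-count
    range makes nRMSE NaN rather than failing the whole report.
    """
    h = np.asarray(predictions, dtype=float)
    y = np.asarray(truths, dtype=float)
    if h.shape != y.shape or h.ndim != 1:
        raise ValueError(f"prediction/truth shape mismatch: {h.shape} vs {y.shape}")
    if h.size == 0:
        raise ValueError("cannot evaluate empty count lists")
    if (y < 0).any():
        raise ValueError("true counts must be non-negative")
    ids = image_ids if image_ids is not None else [str(i) for i in range(h.size)]

    err = h - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    y_range = float(y.max() - y.min())
    nrmse = 100.0 * rmse / y_range if y_range > 0 else float("nan")
    nonzero = y > 0
    if nonzero.any():
        acc = float(100.0 * np.mean(1.0 - np.abs(err[nonzero]) / y[nonzero]))
    else:
        acc = float("nan")
    return EvalReport(
        mae=mae,
        rmse=rmse,
        nrmse_percent=nrmse,
        acc_rate_percent=acc,
        n_images=int(h.size),
        n_zero_truth=int((~nonzero).sum()),
        per_image=[
            (ids[i], float(h[i]), float(y[i]), float(abs(err[i])))
            for i in range(h.size)
        ],
    )


def plot_predictions(report: EvalReport, path: str | Path | None = None):
    """Predicted-vs-true count scatter with the identity line (convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = [p for _, p, _, _ in report.per_image]
    y = [t for _, _, t, _ in report.per_image]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y, h, s=18, alpha=0.7)
    lim = [0, max(max(h, default=1), max(y, default=1)) * 1.1]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("true count")
    ax.set_ylabel("predicted count")
    ax.set_title(f"MAE {report.mae:.2f}, RMSE {report.rmse:.2f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
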