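"""Per-event total correlation error σᵀ.

The three accuracies — channel alignment σᴬ, FM→EM correlation σᶜ and event
localization σᴱ — arise from independent measurements, so they combine as a
root sum of squares: σᵀ = sqrt(σᴬ² + σᶜ² + σᴱ²).  σᵀ is the radius of the
uncertainty circle around the predicted EM position of an event of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .align import ChannelShift
from .localization import LocalizedSpot
from .transform import ConformalTransform


def total_error(sigma_a_nm: float, sigma_c_nm: float, sigma_e_nm: float) -> float:
    """Root-sum-square of the three independent error components (nm).

    Full precision is kept; rounding happens only at presentation.
    """
    comps = np.array([sigma_a_nm, sigma_c_nm, sigma_e_nm], dtype=float)
    if not np.all(np.isfinite(comps)):
        raise ValueError("error components must be finite")
    if np.any(comps < 0):
        raise ValueError("error components must be >= 0")
    return float(np.sqrt(np.sum(comps**2)))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Presentation rounding: half-up to the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ErrorBudget:
    """The σᴬ/σᶜ/σᴱ/σᵀ quadruple for one event of interest, with provenance."""

    event_id: str
    sigma_a_nm: float
    sigma_c_nm: float
    sigma_e_nm: float
    sigma_t_nm: float = field(init=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sigma_t_nm = total_error(self.sigma_a_nm, self.sigma_c_nm, self.sigma_e_nm)

    def to_dict(self) -> dict:
        return {
            "event_id": self.event_id,
            "sigma_a_nm": self.sigma_a_nm,
            "sigma_c_nm": self.sigma_c_nm,
            "sigma_e_nm": self.sigma_e_nm,
            "sigma_t_nm": self.sigma_t_nm,
            "provenance": self.provenance,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def budget_report(event_id: str,
                  shift: ChannelShift | None,
                  transform: ConformalTransform | None,
                  spot: LocalizedSpot | None) -> ErrorBudget:
    """Assemble an ErrorBudget from the three pipeline stages.

    ``shift`` must be the alignment between the event's channel (green for a
    labelled virus) and the fiducial reference channel (blue); ``transform``
    carries the leave-one-out σᶜ; ``spot`` is the localized event supplying
    σᴱ.  A missing stage raises an error naming it.
    """
    missing = []
    if shift is None:
        missing.append("channel alignment (sigma_a)")
    if transform is None or transform.sigma_c_nm is None:
        missing.append("FM->EM correlation (sigma_c)")
    if spot is None or not spot.converged:
        missing.append("event localization (sigma_e)")
    if missing:
        raise ValueError(f"cannot assemble error budget for {event_id}; "
                         f"missing stage(s): {', '.join(missing)}")
    return ErrorBudget(
        event_id=event_id,
        sigma_a_nm=shift.sigma_a_nm,
        sigma_c_nm=transform.sigma_c_nm,
        sigma_e_nm=spot.sigma_e_nm,
        provenance={
            "shift": shift.to_dict(),
            "transform": {k: v for k, v in transform.to_dict().items()
                          if k != "loo_displacements_nm"},
            "spot": {"x_nm": spot.x_nm, "y_nm": spot.y_nm,
                     "stderr_x_nm": spot.stderr_x_nm,
                     "stderr_y_nm": spot.stderr_y_nm},
        },
    )


def overlay_figure(em_image, predicted_xy_nm, sigma_t_nm, path) -> None:
    """EM image with the uncertainty circle of radius σᵀ at the predicted position."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    px = em_image.pixel_size_nm
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(em_image.pixels, cmap="gray", origin="upper")
    x_px, y_px = np.asarray(predicted_xy_nm, dtype=float) / px
    circ = plt.Circle((x_px, y_px), sigma_t_nm / px, fill=False,
                      edgecolor="red", linestyle="--", linewidth=1.5)
    ax.add_patch(circ)
    ax.plot([x_px], [y_px], "r+", markersize=8)
    ax.set_title(f"predicted position, sigma_T = {round_half_up(sigma_t_nm):g} nm")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
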