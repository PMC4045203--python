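"""Multi-channel alignment from TetraSpeck fiducials.

TetraSpeck microspheres fluoresce in all three channels, so a bead found in
red, green and blue within a small coincidence radius identifies itself as
an alignment fiducial (single-colour FluoSpheres and labelled viruses fail
the triple test).  The inter-channel shift is modelled as a global
translation — the vitrified specimen is a rigid body and a single optical
detection path rules out rotations — estimated as the mean of per-fiducial
displacements; their standard deviation is the alignment accuracy σᴬ.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import ChannelImage, PointRecord
from .localization import LocalizedSpot

logger = logging.getLogger(__name__)

FM_CHANNELS = ("red", "green", "blue")
REFERENCE_CHANNEL = "blue"  # FluoSpheres (blue) carry the FM->EM correlation

DEFAULT_COINCIDENCE_RADIUS_NM = 500.0
DEFAULT_MIN_SEPARATION_NM = 500.0
DEFAULT_OUTLIER_K = 3.0


@dataclass
class FiducialMatch:
    """One TetraSpeck matched across the red, green and blue channels."""

    id: str
    red: LocalizedSpot
    green: LocalizedSpot
    blue: LocalizedSpot

    def displacement(self, moving: str, reference: str = REFERENCE_CHANNEL) -> np.ndarray:
        """(dx, dy) in nm of the moving-channel position relative to the reference."""
        return self.spot(moving).xy - self.spot(reference).xy

    def spot(self, channel: str) -> LocalizedSpot:
        if channel not in FM_CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        return getattr(self, channel)


@dataclass
class ChannelShift:
    """Global displacement of one channel relative to a reference.

    ``sigma_a_x_nm``/``sigma_a_y_nm`` are per-axis sample standard deviations
    of the per-fiducial displacements; the scalar σᴬ is their mean.
    """

    moving_channel: str
    reference_channel: str
    dx_nm: float
    dy_nm: float
    sigma_a_x_nm: float
    sigma_a_y_nm: float
    n_used: int
    n_outliers_removed: int = 0
    low_confidence: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.n_used < 3:
            self.low_confidence = True

    @property
    def sigma_a_nm(self) -> float:
        return 0.5 * (self.sigma_a_x_nm + self.sigma_a_y_nm)

    @property
    def dxy(self) -> np.ndarray:
        return np.array([self.dx_nm, self.dy_nm], dtype=float)

    def to_dict(self) -> dict:
        return {
            "moving": self.moving_channel,
            "reference": self.reference_channel,
            "dx_nm": self.dx_nm,
            "dy_nm": self.dy_nm,
            "sigma_a_x_nm": self.sigma_a_x_nm,
            "sigma_a_y_nm": self.sigma_a_y_nm,
            "sigma_a_nm": self.sigma_a_nm,
            "n_used": self.n_used,
            "n_outliers_removed": self.n_outliers_removed,
            "low_confidence": self.low_confidence,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelShift":
        return cls(
            moving_channel=d["moving"], reference_channel=d["reference"],
            dx_nm=d["dx_nm"], dy_nm=d["dy_nm"],
            sigma_a_x_nm=d["sigma_a_x_nm"], sigma_a_y_nm=d["sigma_a_y_nm"],
            n_used=d["n_used"], n_outliers_removed=d.get("n_outliers_removed", 0),
        )

    @classmethod
    def load(cls, path) -> "ChannelShift":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rough_align(picks: dict[str, tuple[float, float]],
                reference: str = REFERENCE_CHANNEL) -> dict[str, np.ndarray]:
    """Coarse per-channel offsets from one manually picked bead per channel.

    ``picks`` maps each channel to the picked (x, y) in nm of the same
    physical bead.  The returned offset, added to a channel's coordinates,
    brings the picked bead into coincidence with the reference pick, after
    which automated matching with the standard 500 nm radius applies.
    """
    missing = [ch for ch in FM_CHANNELS if ch not in picks]
    if missing:
        raise ValueError(f"rough-alignment pick missing for channel(s): {missing}")
    ref = np.asarray(picks[reference], dtype=float)
    return {ch: ref - np.asarray(picks[ch], dtype=float) for ch in FM_CHANNELS}


def match_triple(
    spots_red: list[LocalizedSpot],
    spots_green: list[LocalizedSpot],
    spots_blue: list[LocalizedSpot],
    coincidence_radius_nm: float = DEFAULT_COINCIDENCE_RADIUS_NM,
    min_separation_nm: float = DEFAULT_MIN_SEPARATION_NM,
    rough_offsets_nm: dict[str, np.ndarray] | None = None,
) -> list[FiducialMatch]:
    """Associate spots visible in all three channels into TetraSpeck matches.

    Greedy nearest-neighbour association is seeded from the blue channel in
    decreasing intensity order; a triple is accepted only when red and green
    partners both lie within ``coincidence_radius_nm`` of the blue spot
    (after optional rough offsets).  Accepted matches whose blue positions
    lie closer than ``min_separation_nm`` are removed pairwise — crowded
    beads corrupt the shift statistics.
    """
    offs = {ch: np.zeros(2) for ch in FM_CHANNELS}
    if rough_offsets_nm:
        for ch, v in rough_offsets_nm.items():
            offs[ch] = np.asarray(v, dtype=float)

    def corrected(spots, ch):
        return [s.xy + offs[ch] for s in spots]

    red_xy = corrected(spots_red, "red")
    green_xy = corrected(spots_green, "green")
    blue_order = sorted(range(len(spots_blue)),
                        key=lambda i: spots_blue[i].amplitude, reverse=True)
    used_red: set[int] = set()
    used_green: set[int] = set()
    accepted: list[FiducialMatch] = []
    for k, bi in enumerate(blue_order):
        bxy = spots_blue[bi].xy + offs["blue"]
        ri = _nearest(bxy, red_xy, coincidence_radius_nm, used_red)
        gi = _nearest(bxy, green_xy, coincidence_radius_nm, used_green)
        if ri is None or gi is None:
            continue
        used_red.add(ri)
        used_green.add(gi)
        accepted.append(FiducialMatch(
            id=f"ts{len(accepted):03d}",
            red=spots_red[ri], green=spots_green[gi], blue=spots_blue[bi],
        ))
    # proximity filter on blue positions: both members of a close pair go
    drop: set[int] = set()
    for i in range(len(accepted)):
        for j in range(i + 1, len(accepted)):
            d = np.linalg.norm(accepted[i].blue.xy - accepted[j].blue.xy)
            if d < min_separation_nm:
                drop.update((i, j))
    kept = [m for i, m in enumerate(accepted) if i not in drop]
    if drop:
        logger.info("proximity filter removed %d crowded match(es)", len(drop))
    kept.sort(key=lambda m: m.blue.amplitude, reverse=True)
    return kept


def _nearest(xy, candidates, radius, used):
    best, best_d = None, radius
    for i, c in enumerate(candidates):
        if i in used:
            continue
        d = np.linalg.norm(c - xy)
        if d <= best_d:
            best, best_d = i, d
    return best


def estimate_shift(
    matches: list[FiducialMatch],
    moving: str,
    reference: str = REFERENCE_CHANNEL,
    outlier_k: float = DEFAULT_OUTLIER_K,
) -> ChannelShift:
    """Mean displacement of ``moving`` vs ``reference`` with σᴬ and outlier pass.

    The outlier pass is jackknifed: each fiducial's displacement is compared
    with the mean of the *other* fiducials, and dropped when it deviates by
    more than ``outlier_k`` of their per-axis standard deviation on either
    axis.  (Comparing against statistics that include the candidate would
    let a single gross outlier inflate the SD enough to mask itself at the
    small n typical here.)  One pass only; statistics are then recomputed on
    the kept set.
    """
    if len(matches) < 2:
        raise ValueError("need at least 2 fiducial matches to estimate a shift")
    disp = np.array([m.displacement(moving, reference) for m in matches])

    def stats(d):
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1) if len(d) > 1 else np.zeros(2)
        return mean, sd

    keep = np.ones(len(disp), dtype=bool)
    if len(disp) >= 3:
        for i in range(len(disp)):
            rest = np.delete(disp, i, axis=0)
            mean_r, sd_r = stats(rest)
            if np.any(np.abs(disp[i] - mean_r) > outlier_k * np.maximum(sd_r, 1e-12)):
                keep[i] = False
    n_out = int((~keep).sum())
    if keep.sum() < 2:  # degenerate: refuse to drop below 2 fiducials
        keep = np.ones(len(disp), dtype=bool)
        n_out = 0
    mean, sd = stats(disp[keep])
    shift = ChannelShift(
        moving_channel=moving, reference_channel=reference,
        dx_nm=float(mean[0]), dy_nm=float(mean[1]),
        sigma_a_x_nm=float(sd[0]), sigma_a_y_nm=float(sd[1]),
        n_used=int(keep.sum()), n_outliers_removed=n_out,
    )
    if shift.low_confidence:
        logger.warning("shift %s->%s from only %d fiducial(s): low confidence",
                       moving, reference, shift.n_used)
    return shift


def apply_shift(obj, shift: ChannelShift):
    """Translate points or an image so the moving channel lands on the reference.

    Point coordinates (PointRecord list, LocalizedSpot list, or an (n, 2)
    array in nm) are translated by (-dx, -dy).  Images are resampled with
    bilinear interpolation by the same translation — for visualization only;
    all quantitative work downstream uses point coordinates.
    """
    d = shift.dxy
    if isinstance(obj, ChannelImage):
        shift_px = -d[::-1] / obj.pixel_size_nm  # (dy, dx) in px, negated
        moved = ndimage.shift(obj.pixels, shift=shift_px, order=1, mode="nearest")
        return ChannelImage(pixels=moved, channel_label=obj.channel_label,
                            pixel_size_nm=obj.pixel_size_nm)
    if isinstance(obj, np.ndarray):
        return obj - d
    out = []
    for p in obj:
        if isinstance(p, PointRecord):
            out.append(PointRecord(id=p.id, frame=p.frame, channel=p.channel,
                                   x_nm=p.x_nm - d[0], y_nm=p.y_nm - d[1],
                                   extra=dict(p.extra)))
        elif isinstance(p, LocalizedSpot):
            q = LocalizedSpot(**{**p.__dict__})
            q.x_nm = p.x_nm - d[0]
            q.y_nm = p.y_nm - d[1]
            out.append(q)
        else:
            raise TypeError(f"cannot shift object of type {type(p)}")
    return out
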