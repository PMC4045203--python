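"""FM→EM coordinate transformation from FluoSphere control points.

The map between the aligned fluorescence frame and the EM projection image
is a linear conformal (similarity) transform — uniform scale, rotation and
translation, with reflection available behind an explicit flag — fitted in
closed form by the Procrustes/Umeyama construction.  Its accuracy σᶜ is
estimated by leave-one-out: each fiducial in turn is excluded from the fit,
its EM position predicted from the rest, and the mean of the prediction
displacements taken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ChannelImage
from .localization import sigma_from_fwhm

DEFAULT_HIGHPASS_CUTOFF_PX = 70.0


@dataclass
class ControlPointPair:
    """A FluoSphere's position in both frames: FM (aligned blue) and EM, in nm."""

    id: str
    fm: np.ndarray
    em: np.ndarray

    def __post_init__(self) -> None:
        self.fm = np.asarray(self.fm, dtype=float)
        self.em = np.asarray(self.em, dtype=float)
        if not (np.all(np.isfinite(self.fm)) and np.all(np.isfinite(self.em))):
            raise ValueError(f"control point {self.id}: non-finite coordinates")


@dataclass
class ConformalTransform:
    """2D similarity map em = s·R(θ)·fm + t (optionally with a reflection)."""

    scale: float
    rotation_rad: float
    translation_nm: np.ndarray
    reflection: bool = False
    sigma_c_nm: float | None = None
    loo_displacements_nm: np.ndarray | None = None
    n_fiducials: int = 0
    residuals_nm: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        self.translation_nm = np.asarray(self.translation_nm, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part (scaled rotation, times a flip if reflected)."""
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        if self.reflection:
            rot = rot @ np.diag([1.0, -1.0])
        return self.scale * rot

    def apply(self, fm_points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(fm_points, dtype=float))
        out = pts @ self.matrix.T + self.translation_nm
        return out[0] if np.asarray(fm_points).ndim == 1 else out

    def inverse(self) -> "ConformalTransform":
        inv_m = np.linalg.inv(self.matrix)
        inv_t = -inv_m @ self.translation_nm
        ang = np.arctan2(inv_m[1, 0], inv_m[0, 0]) if not self.reflection else \
            np.arctan2(inv_m[1, 0], inv_m[0, 0])
        return ConformalTransform(
            scale=1.0 / self.scale,
            rotation_rad=float(ang),
            translation_nm=inv_t,
            reflection=self.reflection,
        )

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation_rad": self.rotation_rad,
            "tx_nm": float(self.translation_nm[0]),
            "ty_nm": float(self.translation_nm[1]),
            "reflection": self.reflection,
            "sigma_c_nm": self.sigma_c_nm,
            "n_fiducials": self.n_fiducials,
            "loo_displacements_nm": (
                None if self.loo_displacements_nm is None
                else [float(v) for v in self.loo_displacements_nm]
            ),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ConformalTransform":
        loo = d.get("loo_displacements_nm")
        return cls(
            scale=d["scale"], rotation_rad=d["rotation_rad"],
            translation_nm=np.array([d["tx_nm"], d["ty_nm"]]),
            reflection=d.get("reflection", False),
            sigma_c_nm=d.get("sigma_c_nm"),
            loo_displacements_nm=None if loo is None else np.asarray(loo, float),
            n_fiducials=d.get("n_fiducials", 0),
        )

    @classmethod
    def load(cls, path) -> "ConformalTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def highpass_filter(image: ChannelImage,
                    cutoff_px: float = DEFAULT_HIGHPASS_CUTOFF_PX) -> ChannelImage:
    """Remove smooth background by subtracting a Gaussian-blurred copy.

    The smooth cut-off is parameterized as the FWHM of the blur kernel, so
    ``cutoff_px=70`` suppresses structure broader than ~70 pixels while an
    isolated point source keeps its sub-pixel centroid.
    """
    from scipy import ndimage

    if not cutoff_px > 0:
        raise ValueError("cutoff_px must be > 0")
    sigma = sigma_from_fwhm(cutoff_px)
    filtered = image.pixels - ndimage.gaussian_filter(image.pixels, sigma=sigma)
    return ChannelImage(pixels=filtered - 0.0, channel_label=image.channel_label,
                        pixel_size_nm=image.pixel_size_nm)


def _umeyama(src: np.ndarray, dst: np.ndarray, allow_reflection: bool):
    """Closed-form least-squares similarity fit src -> dst (Procrustes/Umeyama)."""
    n = len(src)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    var_s = (sc**2).sum() / n
    if var_s == 0:
        raise ValueError("degenerate control points: all FM positions identical")
    cov = dc.T @ sc / n
    u, s_vals, vt = np.linalg.svd(cov)
    # collinearity check on the source spread
    sv_src = np.linalg.svd(sc, compute_uv=False)
    if n >= 3 and sv_src[-1] < 1e-9 * sv_src[0]:
        warnings.warn("control points are nearly collinear; transform is weakly "
                      "constrained perpendicular to the line", stacklevel=2)
    d = np.ones(2)
    if np.linalg.det(u @ vt) < 0:
        if allow_reflection:
            pass  # keep the improper map: it is the better fit
        else:
            d[-1] = -1.0
    rot = u @ np.diag(d) @ vt
    scale = float((s_vals * d).sum() / var_s)
    if scale <= 0:
        raise ValueError("degenerate geometry: non-positive fitted scale")
    t = mu_d - scale * rot @ mu_s
    return scale, rot, t


def fit_conformal(pairs: list[ControlPointPair],
                  allow_reflection: bool = False,
                  compute_loo: bool = True) -> ConformalTransform:
    """Least-squares similarity transform through FluoSphere control points.

    Needs at least 2 pairs; with ≥ 3 pairs the leave-one-out accuracy σᶜ is
    attached unless ``compute_loo=False``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 control point pairs")
    ids = [p.id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("control point ids must be unique")
    src = np.array([p.fm for p in pairs])
    dst = np.array([p.em for p in pairs])
    scale, rot, t = _umeyama(src, dst, allow_reflection)
    reflection = bool(np.linalg.det(rot) < 0)
    if reflection:
        rot_proper = rot @ np.diag([1.0, -1.0])
    else:
        rot_proper = rot
    theta = float(np.arctan2(rot_proper[1, 0], rot_proper[0, 0]))
    tf = ConformalTransform(
        scale=scale, rotation_rad=theta, translation_nm=t,
        reflection=reflection, n_fiducials=len(pairs),
    )
    tf.residuals_nm = np.linalg.norm(tf.apply(src) - dst, axis=1)
    if compute_loo and len(pairs) >= 3:
        sigma_c, disps = loo_accuracy(pairs, allow_reflection=allow_reflection)
        tf.sigma_c_nm = sigma_c
        tf.loo_displacements_nm = disps
    return tf


def loo_accuracy(pairs: list[ControlPointPair],
                 allow_reflection: bool = False) -> tuple[float, np.ndarray]:
    """Leave-one-out correlation accuracy σᶜ.

    Each fiducial in turn is held out, the transform fitted on the rest and
    the held-out EM position predicted; σᶜ is the arithmetic mean of the n
    Euclidean prediction displacements (in nm).
    """
    if len(pairs) < 3:
        raise ValueError("leave-one-out needs at least 3 control point pairs")
    disps = np.empty(len(pairs))
    for i, held_out in enumerate(pairs):
        rest = pairs[:i] + pairs[i + 1:]
        tf = fit_conformal(rest, allow_reflection=allow_reflection, compute_loo=False)
        predicted = tf.apply(held_out.fm)
        disps[i] = np.linalg.norm(predicted - held_out.em)
    return float(disps.mean()), disps


def predict_position(transform: ConformalTransform, fm_point) -> np.ndarray:
    """EM position of an FM point (nm) under the fitted transform."""
    return transform.apply(np.asarray(fm_point, dtype=float))


def pairs_from_points(fm_points, em_points) -> list[ControlPointPair]:
    """Build control point pairs by matching ids across an fm and an em table."""
    fm_by_id = {p.id: p for p in fm_points if p.frame == "fm"}
    em_by_id = {p.id: p for p in em_points if p.frame == "em"}
    unmatched = sorted(set(fm_by_id) ^ set(em_by_id))
    if unmatched:
        raise ValueError(f"control point ids without a partner: {unmatched}")
    return [ControlPointPair(id=i, fm=fm_by_id[i].xy, em=em_by_id[i].xy)
            for i in sorted(fm_by_id)]
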