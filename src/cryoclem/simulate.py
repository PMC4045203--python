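"""Synthetic cryoCLEM scenes with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
field of point emitters of three species — TetraSpecks (200 nm beads,
fluorescent in red/green/blue), FluoSpheres (100 nm, blue only) and dim
green "virus" events — rendered as pixel-integrated Gaussian PSFs on a
linear background with Poisson photon noise.  Non-reference channels carry
a global shift (stage drift) plus small per-bead jitter (residual local
error), and the EM side is produced by a known similarity transform plus
positional jitter.  Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import erf

from .io import ChannelImage, PointRecord
from .localization import sigma_from_fwhm
from .transform import ConformalTransform

SPECIES_CHANNELS = {
    "tetraspeck": ("red", "green", "blue"),
    "fluosphere": ("blue",),
    "event": ("green",),
}
#: species visible (electron-dense) in the EM projection image
EM_VISIBLE_SPECIES = ("tetraspeck", "fluosphere")

FM_CHANNELS = ("red", "green", "blue")


@dataclass
class SceneSpec:
    """Parameters of one synthetic field of view.

    Defaults follow the imaging conditions of a 63x cryo-fluorescence setup:
    103 nm pixels, PSF FWHM 450 nm (green/blue) and 560 nm (red), 5–15
    beads of each fiducial species per field.
    """

    field_size_px: int = 256
    pixel_size_nm: float = 103.0
    n_tetraspeck: int = 10
    n_fluosphere: int = 10
    n_event: int = 3
    # total detected photons per emitter and channel
    brightness: dict = field(default_factory=lambda: {
        "tetraspeck": {"red": 40000.0, "green": 40000.0, "blue": 40000.0},
        "fluosphere": {"blue": 60000.0},
        "event": {"green": 1500.0},
    })
    psf_fwhm_nm: dict = field(default_factory=lambda: {
        "red": 560.0, "green": 450.0, "blue": 450.0,
    })
    # global stage-drift shift of each channel relative to blue, in nm
    channel_shifts_nm: dict = field(default_factory=lambda: {
        "red": (0.0, 0.0), "green": (0.0, 0.0),
    })
    # per-bead residual jitter (SD, nm) of non-reference channels vs blue
    channel_jitter_sd_nm: float = 15.0
    # background plane in photons: offset, slope_x, slope_y (per px)
    background: tuple = (200.0, 0.1, -0.05)
    poisson_noise: bool = True
    read_noise_sd: float = 0.0
    min_separation_nm: float = 1200.0
    border_margin_px: int = 12
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SceneSpec":
        d = json.loads(Path(path).read_text())
        d["channel_shifts_nm"] = {k: tuple(v) for k, v in d["channel_shifts_nm"].items()}
        d["background"] = tuple(d["background"])
        return cls(**d)


@dataclass
class Emitter:
    id: str
    species: str
    base_xy_nm: np.ndarray                 # true position in the blue/FM frame
    channel_xy_nm: dict                    # channel -> rendered position (nm)


@dataclass
class GroundTruth:
    """Everything the generator knows: true positions, shifts and EM transform."""

    emitters: list
    channel_shifts_nm: dict
    pixel_size_nm: float
    em_transform: dict | None = None       # scale, rotation_rad, tx_nm, ty_nm
    em_jitter_sd_nm: float | None = None

    def positions(self, species: str, channel: str = "blue") -> np.ndarray:
        """(n, 2) array of true positions of one species in one channel frame."""
        rows = [e.channel_xy_nm[channel] for e in self.emitters
                if e.species == species and channel in e.channel_xy_nm]
        return np.array(rows).reshape(-1, 2)

    def of_species(self, species: str) -> list:
        return [e for e in self.emitters if e.species == species]

    def to_json(self, path) -> None:
        d = {
            "channel_shifts_nm": {k: list(v) for k, v in self.channel_shifts_nm.items()},
            "pixel_size_nm": self.pixel_size_nm,
            "em_transform": self.em_transform,
            "em_jitter_sd_nm": self.em_jitter_sd_nm,
            "emitters": [
                {"id": e.id, "species": e.species,
                 "base_xy_nm": list(e.base_xy_nm),
                 "channel_xy_nm": {c: list(v) for c, v in e.channel_xy_nm.items()}}
                for e in self.emitters
            ],
        }
        Path(path).write_text(json.dumps(d, indent=2))


def _place_emitters(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Uniform placement with a minimum pairwise separation (rejection sampling)."""
    n_total = spec.n_tetraspeck + spec.n_fluosphere + spec.n_event
    lo = spec.border_margin_px * spec.pixel_size_nm
    hi = (spec.field_size_px - 1 - spec.border_margin_px) * spec.pixel_size_nm
    placed: list[np.ndarray] = []
    attempts = 0
    max_attempts = 2000 * max(n_total, 1)
    while len(placed) < n_total:
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_total} emitters with min separation "
                f"{spec.min_separation_nm} nm in a {spec.field_size_px} px field"
            )
        attempts += 1
        cand = rng.uniform(lo, hi, size=2)
        if all(np.linalg.norm(cand - p) >= spec.min_separation_nm for p in placed):
            placed.append(cand)
    return np.array(placed).reshape(n_total, 2)


def _render_channel(spec: SceneSpec, channel: str,
                    emitters: list[Emitter], rng: np.random.Generator) -> ChannelImage:
    n = spec.field_size_px
    px = spec.pixel_size_nm
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    b0, b1, b2 = spec.background
    expected = b0 + b1 * xx + b2 * yy
    expected = np.clip(expected, 0, None)
    sigma_px = sigma_from_fwhm(spec.psf_fwhm_nm[channel]) / px
    xs = np.arange(n, dtype=float)
    for e in emitters:
        if channel not in e.channel_xy_nm:
            continue
        photons = spec.brightness[e.species][channel]
        x0, y0 = np.asarray(e.channel_xy_nm[channel]) / px
        # pixel-integrated Gaussian: product of erf differences per axis
        fx = 0.5 * (erf((xs - x0 + 0.5) / (np.sqrt(2) * sigma_px))
                    - erf((xs - x0 - 0.5) / (np.sqrt(2) * sigma_px)))
        fy = 0.5 * (erf((xs - y0 + 0.5) / (np.sqrt(2) * sigma_px))
                    - erf((xs - y0 - 0.5) / (np.sqrt(2) * sigma_px)))
        expected += photons * np.outer(fy, fx)
    if spec.poisson_noise:
        img = rng.poisson(expected).astype(float)
    else:
        img = expected.copy()
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0.0, spec.read_noise_sd, size=img.shape)
    return ChannelImage(pixels=np.clip(img, 0, None), channel_label=channel,
                        pixel_size_nm=px)


def generate_scene(spec: SceneSpec) -> tuple[GroundTruth, dict[str, ChannelImage]]:
    """Render the three FM channel images and return them with ground truth."""
    rng = np.random.default_rng(spec.seed)
    base = _place_emitters(spec, rng)
    species_seq = (["tetraspeck"] * spec.n_tetraspeck
                   + ["fluosphere"] * spec.n_fluosphere
                   + ["event"] * spec.n_event)
    shifts = {"blue": np.zeros(2)}
    for ch in ("red", "green"):
        shifts[ch] = np.asarray(spec.channel_shifts_nm.get(ch, (0.0, 0.0)), float)
    counters = {"tetraspeck": 0, "fluosphere": 0, "event": 0}
    emitters: list[Emitter] = []
    for sp, xy in zip(species_seq, base):
        eid = f"{sp[:2]}{counters[sp]:03d}"
        counters[sp] += 1
        channel_xy = {}
        for ch in SPECIES_CHANNELS[sp]:
            pos = xy + shifts[ch]
            if ch != "blue" and spec.channel_jitter_sd_nm > 0:
                pos = pos + rng.normal(0.0, spec.channel_jitter_sd_nm, size=2)
            channel_xy[ch] = np.asarray(pos, float)
        emitters.append(Emitter(id=eid, species=sp, base_xy_nm=np.asarray(xy, float),
                                channel_xy_nm=channel_xy))
    images = {ch: _render_channel(spec, ch, emitters, rng) for ch in FM_CHANNELS}
    truth = GroundTruth(emitters=emitters,
                        channel_shifts_nm={ch: tuple(v) for ch, v in shifts.items()
                                           if ch != "blue"},
                        pixel_size_nm=spec.pixel_size_nm)
    return truth, images


def generate_em_side(truth: GroundTruth,
                     transform: ConformalTransform,
                     jitter_sd_nm: float,
                     em_pixel_size_nm: float,
                     seed: int = 0,
                     render: bool = False):
    """EM-frame coordinates of the electron-dense beads under a known transform.

    ``em_i = T(fm_i) + N(0, jitter_sd^2 I)``.  Only TetraSpecks and
    FluoSpheres receive EM records; the green virus-like events have no
    EM-visible truth marker, mirroring the real correlation problem.
    Optionally renders a simple EM image with dark disks at the bead
    positions.
    """
    rng = np.random.default_rng(seed)
    records: list[PointRecord] = []
    for e in truth.emitters:
        if e.species not in EM_VISIBLE_SPECIES:
            continue
        em_xy = transform.apply(e.base_xy_nm)
        if jitter_sd_nm > 0:
            em_xy = em_xy + rng.normal(0.0, jitter_sd_nm, size=2)
        records.append(PointRecord(id=e.id, frame="em", channel="em",
                                   x_nm=float(em_xy[0]), y_nm=float(em_xy[1]),
                                   extra={"species": e.species}))
    truth.em_transform = {k: v for k, v in transform.to_dict().items()
                          if k in ("scale", "rotation_rad", "tx_nm", "ty_nm", "reflection")}
    truth.em_jitter_sd_nm = jitter_sd_nm
    if not render:
        return records
    image = _render_em_image(records, em_pixel_size_nm)
    return records, image


def _render_em_image(records: list[PointRecord], em_pixel_size_nm: float,
                     pad_px: int = 64) -> ChannelImage:
    pts = np.array([[r.x_nm, r.y_nm] for r in records]).reshape(-1, 2)
    lo = pts.min(axis=0) - pad_px * em_pixel_size_nm
    hi = pts.max(axis=0) + pad_px * em_pixel_size_nm
    n_x = max(int(np.ceil((hi[0] - lo[0]) / em_pixel_size_nm)), 16)
    n_y = max(int(np.ceil((hi[1] - lo[1]) / em_pixel_size_nm)), 16)
    yy, xx = np.mgrid[0:n_y, 0:n_x].astype(float)
    img = np.full((n_y, n_x), 1000.0)
    radii = {"tetraspeck": 100.0, "fluosphere": 50.0}  # bead radii in nm
    for r in records:
        cx = (r.x_nm - lo[0]) / em_pixel_size_nm
        cy = (r.y_nm - lo[1]) / em_pixel_size_nm
        rad_px = radii.get(str(r.extra.get("species")), 50.0) / em_pixel_size_nm
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad_px**2
        img[mask] = 200.0  # beads are electron dense: dark
    return ChannelImage(pixels=img, channel_label="em", pixel_size_nm=em_pixel_size_nm)


def preset_scene(name: str, seed: int = 0) -> SceneSpec:
    """Named standard scenes used throughout the tests and the CLI.

    - ``fig2-large-shift``: stage drift at the extreme observed scale —
      red shifted (3098, 787) nm and green (449, 148) nm vs blue.
    - ``table3-case1-like``: a cellular field with a dim green virus event
      and moderate drift.
    - ``loo-calibration``: bead-only field for FM→EM leave-one-out studies.
    """
    if name == "fig2-large-shift":
        return SceneSpec(seed=seed, channel_shifts_nm={
            "red": (3098.0, 787.0), "green": (449.0, 148.0)})
    if name == "table3-case1-like":
        return SceneSpec(seed=seed, n_tetraspeck=8, n_fluosphere=8, n_event=2,
                         channel_shifts_nm={"red": (300.0, -120.0),
                                            "green": (140.0, 90.0)},
                         channel_jitter_sd_nm=8.0)
    if name == "loo-calibration":
        return SceneSpec(seed=seed, n_tetraspeck=0, n_fluosphere=10, n_event=0)
    raise ValueError(f"unknown preset {name!r}; available: fig2-large-shift, "
                     "table3-case1-like, loo-calibration")
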