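"""Monte Carlo photon transport through a turbid slab.

A pencil beam enters a slab of thickness ``t`` at normal incidence.  Photons
take free paths drawn from an exponential distribution with mean equal to
the scattering length ``s_l``; at every scattering event the propagation
direction is deflected by an angle drawn from the Henyey-Greenstein phase
function with anisotropy factor ``g`` (uniform azimuth).  A photon
terminates when it crosses the exit face (z > t), the entrance face (z < 0,
backscattered), leaves the lateral simulation window, or exceeds the
scattering-event cap.

The detector records transmitted photons at the slab exit face.  Two
physical filters of the measurement are modeled:

* a polarizer rejects the unscattered (ballistic) beam — photons with zero
  scattering events never reach the image;
* the imaging lens only accepts photons whose exit direction lies inside
  the numerical-aperture cone.

Intensities are photon counts (unit weight per photon); absorption is
assumed negligible compared to scattering and is not modeled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "SampleParams",
    "OpticsConfig",
    "PhotonRecord",
    "ScatterImage",
    "FATES",
    "hg_phase",
    "sample_hg_deflection",
    "trace_photon",
    "trace_photons",
    "render_pattern",
    "min_led_bandwidth",
]

# photon fate codes
FATE_BALLISTIC = 0
FATE_TRANSMITTED = 1  # transmitted after >= 1 scattering event
FATE_BACKSCATTERED = 2
FATE_LATERAL = 3
FATE_CAPPED = 4
FATES = ("ballistic", "transmitted_scattered", "backscattered",
         "lateral_loss", "capped")


@dataclass(frozen=True)
class SampleParams:
    """One turbid-slab setting: thickness t (µm), anisotropy g, scattering
    length s_l (µm).  ``s_l`` is carried in µm internally; the CSV/design
    boundary uses mm."""

    t: float
    g: float
    s_l: float

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError(f"thickness must be positive, got {self.t}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"anisotropy must satisfy 0 <= g < 1, got {self.g}")
        if not self.s_l > 0:
            raise ValueError(f"scattering length must be positive, got {self.s_l}")


@dataclass(frozen=True)
class OpticsConfig:
    """Measurement geometry and simulation controls.

    The lens chain is modeled as an acceptance cone: a transmitted photon is
    imaged iff the cosine of its exit polar angle is at least
    ``cos(arcsin(NA))``.  The detector is a square grid of ``detector_px``
    pixels of pitch ``pixel_pitch`` µm centered on the beam axis, imaging
    the slab exit face 1:1.  The lateral simulation window extends
    ``window_factor`` detector half-widths from the axis; photons beyond it
    are lost ("edge-scattered" light).
    """

    wavelength_nm: float = 1550.0
    led_bandwidth_nm: float = 40.0
    refractive_index: float = 1.33
    lens_focal_cm: float = 4.0
    lens_radius_mm: float = 6.0
    numerical_aperture: float = 0.15
    pixel_pitch: float = 4.0        # µm
    detector_px: int = 100
    window_factor: float = 4.0      # lateral window / detector half-width
    beam_radius_um: float = 0.0     # 0 = ideal pencil beam
    psf_sigma_px: float = 0.0       # optional detector-side Gaussian blur
    max_events: int = 100_000
    n_photons: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must lie in (0, 1)")
        if self.detector_px < 1:
            raise ValueError("detector must have at least one pixel")

    @property
    def detector_half_width_um(self) -> float:
        return 0.5 * self.detector_px * self.pixel_pitch

    @property
    def lateral_window_um(self) -> float:
        return self.window_factor * self.detector_half_width_um

    @property
    def acceptance_cos(self) -> float:
        return math.cos(math.asin(self.numerical_aperture))

    @property
    def pixel_edges_um(self) -> np.ndarray:
        """Bin edges placing the beam axis at the center of a pixel
        (pixel index = coordinate/pitch + detector_px/2 - 0.5)."""
        k = np.arange(self.detector_px + 1, dtype=float)
        return (k - (self.detector_px / 2 - 0.5) - 0.5) * self.pixel_pitch


class PhotonRecord(NamedTuple):
    """Terminal state of one traced photon."""

    fate: str
    exit_xy: tuple[float, float]
    exit_direction_cosine: float
    n_events: int


@dataclass
class ScatterImage:
    """Detector image of transmitted scattered light (photon counts)."""

    intensity: np.ndarray
    pixel_pitch: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.intensity.sum())

    def save(self, path: str | Path) -> None:
        """Write a float TIFF plus a JSON sidecar with metadata."""
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.intensity.astype(np.float32))
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps({"pixel_pitch": self.pixel_pitch, **self.meta},
                       indent=1, default=float)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ScatterImage":
        import tifffile

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        pitch = meta.pop("pixel_pitch")
        return cls(tifffile.imread(path), pitch, meta)


def hg_phase(theta: np.ndarray | float, g: float) -> np.ndarray | float:
    """Henyey-Greenstein phase function, probability per unit solid angle.

    ``P(θ) = (1/4π) (1-g²) / (1+g²-2g cosθ)^{3/2}``; integrates to 1 over
    the sphere and has mean deflection cosine g.
    """
    if not 0.0 <= g < 1.0:
        raise ValueError(f"anisotropy must satisfy 0 <= g < 1, got {g}")
    ct = np.cos(theta)
    return (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * ct) ** 1.5)


def sample_hg_deflection(g: float, u: np.ndarray | float) -> np.ndarray | float:
    """Invert the Henyey-Greenstein CDF: map uniform u in [0,1) to cosθ.

    For g=0 the distribution is isotropic and cosθ = 2u - 1.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1):
        raise ValueError("uniform variate must lie in [0, 1)")
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
    out = np.clip(out, -1.0, 1.0)
    return out if out.ndim else float(out)


def _deflect(dirs: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(mu) and azimuth phi."""
    ux, uy, uz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    sint = np.sqrt(np.maximum(0.0, 1.0 - mu * mu))
    cosp, sinp = np.cos(phi), np.sin(phi)
    out = np.empty_like(dirs)
    near_pole = np.abs(uz) > 1.0 - 1e-12
    denom = np.sqrt(np.maximum(1e-300, 1.0 - uz * uz))
    out[:, 0] = sint * (ux * uz * cosp - uy * sinp) / denom + ux * mu
    out[:, 1] = sint * (uy * uz * cosp + ux * sinp) / denom + uy * mu
    out[:, 2] = -denom * sint * cosp + uz * mu
    if np.any(near_pole):
        sgn = np.sign(uz[near_pole])
        out[near_pole, 0] = sint[near_pole] * cosp[near_pole]
        out[near_pole, 1] = sint[near_pole] * sinp[near_pole]
        out[near_pole, 2] = sgn * mu[near_pole]
    # renormalize to fight drift over many events
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def trace_photons(
    sample: SampleParams,
    optics: OpticsConfig,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Trace ``n`` photons; returns (fate codes, exit_xy, exit cosine, events).

    ``exit_xy`` and the exit direction cosine are only meaningful for
    transmitted photons (fates 0 and 1); they are NaN otherwise.
    """
    t, g, sl = sample.t, sample.g, sample.s_l
    window = optics.lateral_window_um

    fate = np.full(n, -1, dtype=np.int8)
    exit_xy = np.full((n, 2), np.nan)
    exit_mu = np.full(n, np.nan)
    n_events = np.zeros(n, dtype=np.int64)

    idx = np.arange(n)
    pos = np.zeros((idx.size, 3))
    if optics.beam_radius_um > 0:
        r = optics.beam_radius_um * np.sqrt(rng.random(idx.size))
        a = 2.0 * np.pi * rng.random(idx.size)
        pos[:, 0] = r * np.cos(a)
        pos[:, 1] = r * np.sin(a)
    dirs = np.zeros((idx.size, 3))
    dirs[:, 2] = 1.0
    events = np.zeros(idx.size, dtype=np.int64)

    while idx.size:
        step = rng.exponential(scale=sl, size=idx.size)
        new = pos + step[:, None] * dirs

        up = new[:, 2] > t
        down = ~up & (new[:, 2] < 0.0)
        scatter = ~(up | down)

        if np.any(up):
            sel = up
            lam = (t - pos[sel, 2]) / dirs[sel, 2]
            xy = pos[sel, :2] + lam[:, None] * dirs[sel, :2]
            gid = idx[sel]
            exit_xy[gid] = xy
            exit_mu[gid] = dirs[sel, 2]
            inside = np.max(np.abs(xy), axis=1) <= window
            f = np.where(
                inside,
                np.where(events[sel] == 0, FATE_BALLISTIC, FATE_TRANSMITTED),
                FATE_LATERAL,
            )
            fate[gid] = f
            n_events[gid] = events[sel]
        if np.any(down):
            gid = idx[down]
            fate[gid] = FATE_BACKSCATTERED
            n_events[gid] = events[down]

        if not np.any(scatter):
            break

        idx = idx[scatter]
        pos = new[scatter]
        dirs = dirs[scatter]
        events = events[scatter] + 1

        out_lat = np.max(np.abs(pos[:, :2]), axis=1) > window
        capped = ~out_lat & (events >= optics.max_events)
        if np.any(out_lat):
            gid = idx[out_lat]
            fate[gid] = FATE_LATERAL
            n_events[gid] = events[out_lat]
        if np.any(capped):
            gid = idx[capped]
            fate[gid] = FATE_CAPPED
            n_events[gid] = events[capped]
        keep = ~(out_lat | capped)
        if not np.all(keep):
            idx, pos, dirs, events = idx[keep], pos[keep], dirs[keep], events[keep]
        if not idx.size:
            break

        mu = sample_hg_deflection(g, rng.random(idx.size))
        phi = 2.0 * np.pi * rng.random(idx.size)
        dirs = _deflect(dirs, np.asarray(mu), phi)

    return fate, exit_xy, exit_mu, n_events


def trace_photon(
    sample: SampleParams, optics: OpticsConfig, rng: np.random.Generator
) -> PhotonRecord:
    """Trace a single photon and return its terminal record."""
    fate, exit_xy, exit_mu, n_events = trace_photons(sample, optics, 1, rng)
    return PhotonRecord(
        fate=FATES[fate[0]],
        exit_xy=(float(exit_xy[0, 0]), float(exit_xy[0, 1])),
        exit_direction_cosine=float(exit_mu[0]),
        n_events=int(n_events[0]),
    )


def render_pattern(
    sample: SampleParams,
    optics: OpticsConfig | None = None,
    seed: int | None = None,
    chunk: int = 500_000,
) -> ScatterImage:
    """Simulate the detector image of transmitted scattered light.

    Photons contribute to the image iff they are transmitted with at least
    one scattering event (polarizer rejection of the ballistic beam), exit
    within the numerical-aperture cone, and land inside the detector field
    of view.  Deterministic given ``seed``; a missing seed is refused so
    that every image is reproducible.
    """
    if seed is None:
        raise ValueError("render_pattern requires an explicit seed")
    optics = optics or OpticsConfig()
    rng = np.random.default_rng(seed)
    edges = optics.pixel_edges_um
    img = np.zeros((optics.detector_px, optics.detector_px))
    tallies = dict.fromkeys(FATES, 0)

    remaining = optics.n_photons
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        fate, exit_xy, exit_mu, _ = trace_photons(sample, optics, m, rng)
        for code, name in enumerate(FATES):
            tallies[name] += int(np.sum(fate == code))
        acc = (fate == FATE_TRANSMITTED) & (exit_mu >= optics.acceptance_cos)
        if np.any(acc):
            # rows index y, columns x; axis at pixel detector_px/2 - 0.5
            h, _, _ = np.histogram2d(
                exit_xy[acc, 1], exit_xy[acc, 0], bins=(edges, edges)
            )
            img += h

    if optics.psf_sigma_px > 0:
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, optics.psf_sigma_px, mode="wrap")

    meta = {
        "sample": asdict(sample),
        "seed": int(seed),
        "n_photons": int(optics.n_photons),
        "fates": tallies,
    }
    return ScatterImage(img, optics.pixel_pitch, meta)


def min_led_bandwidth(
    wavelength_nm: float, refractive_index: float, optical_path_um: float
) -> float:
    """Minimum LED bandwidth (nm) keeping the coherence length below one
    tenth of the optical path, so coherent artifacts do not distort the
    scattering image:  Δλ > (2 ln 2 / (π n)) · λ² / (0.1 L_opt).
    """
    if wavelength_nm <= 0 or refractive_index <= 0 or optical_path_um <= 0:
        raise ValueError("all arguments must be positive")
    lam_um = wavelength_nm * 1e-3
    dl_um = (2.0 * math.log(2.0) / (math.pi * refractive_index)) * lam_um**2 / (
        0.1 * optical_path_um
    )
    return dl_um * 1e3
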