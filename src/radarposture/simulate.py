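"""Synthetic multi-radar sleep-posture data.

Real bedside IR-UWB recordings of sleepers are rarely shareable, so this
module generates posture-labelled datasets with the statistical structure
the downstream pipeline assumes.  A body is a small set of point
scatterers (head, shoulders, torso, hips, legs) whose layout encodes the
posture; each radar sees the superposition of per-scatterer returns

    y(t) = sum_i A_i * delta(t - tau_i) + n(t)

discretised onto range bins: amplitude A_i falls off with range and
azimuth, the delta is broadened by the hardware range resolution
(a Gaussian point-spread over bins), a static clutter profile is added
constant across slow time, and i.i.d. Gaussian channel noise on top.

Bodies are not perfectly static: pulse-to-pulse scintillation (residual
micro-motion of a breathing sleeper) multiplies each scatterer's return
by a small random per-pulse factor.  This is what lets slow-time mean
subtraction cancel the static clutter yet retain the body — with a
perfectly frozen target clutter suppression would cancel the target too.
Vital-sign waveforms and posture transitions are deliberately out of
scope; the scintillation is amplitude jitter only, carrying no temporal
structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import RadarSpec, default_placement
from .labels import FINE_LABELS, coarse_map
from .preprocess import RadarFrame

__all__ = [
    "Scatterer",
    "Phantom",
    "SimParams",
    "SampleRecord",
    "BLANKETS",
    "make_phantom",
    "simulate_frame",
    "default_clutter_profile",
    "iter_samples",
    "generate_dataset",
    "dataset_manifest",
]

logger = logging.getLogger(__name__)

BLANKETS = ("thick", "medium", "thin")

_BED_MIDLINE_X = 45.0


@dataclass(frozen=True)
class Scatterer:
    """A point reflector: (x, y) position in cm and dimensionless amplitude."""

    position: tuple
    reflectivity: float

    def __post_init__(self):
        if self.reflectivity < 0:
            raise ValueError("reflectivity must be >= 0")
        x, y = self.position
        if not (-50.0 <= x <= 250.0 and -50.0 <= y <= 250.0):
            raise ValueError(f"scatterer position {self.position} outside plausible bed surround")


@dataclass(frozen=True)
class Phantom:
    """A posture-specific scatterer template for one subject."""

    posture: str
    scatterers: tuple
    subject_scale: tuple = (1.0, 1.0)

    def __post_init__(self):
        if self.posture not in FINE_LABELS:
            raise KeyError(f"unknown posture label {self.posture!r}")
        if len(self.scatterers) < 5:
            raise ValueError("phantom needs >= 5 scatterers (head, shoulders, torso, hips, legs)")


@dataclass
class SimParams:
    """Acquisition and channel parameters for the simulator.

    noise_sigma : i.i.d. Gaussian channel noise per frame element.
    clutter_profile : static per-bin amplitude added to every pulse;
        None selects the built-in room profile.
    blanket_attenuation : multiplicative factor per blanket condition.
    blanket_diffuse : amplitude coefficient of the weak diffuse return a
        blanket adds slightly nearer than each body scatterer; scales with
        (1 - attenuation) so thicker blankets scatter more.
    psf_sigma_bins : Gaussian range spread in bins; default matches the
        ~0.107 m resolution of a 1.4 GHz-bandwidth pulse (c / 2B), i.e.
        about 16.6 bins of 0.643 cm.
    amplitude_exponent : path-loss exponent on range in metres.
    scintillation : std of the per-pulse multiplicative amplitude jitter
        on body scatterers (residual micro-motion).
    n_pulses : slow-time length; default 100 pulses = 5 s at 20 Hz.
    """

    noise_sigma: float = 0.02
    clutter_profile: np.ndarray | None = None
    blanket_attenuation: dict = field(
        default_factory=lambda: {"thick": 0.5, "medium": 0.7, "thin": 0.85}
    )
    blanket_diffuse: float = 0.15
    psf_sigma_bins: float = 16.6
    amplitude_exponent: float = 2.0
    scintillation: float = 0.15
    n_pulses: int = 100

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.psf_sigma_bins <= 0:
            raise ValueError("psf_sigma_bins must be > 0")
        if self.n_pulses < 2:
            raise ValueError("n_pulses must be >= 2")
        for k, v in self.blanket_attenuation.items():
            if not (0.0 < v <= 1.0):
                raise ValueError(f"blanket_attenuation[{k!r}] must lie in (0, 1]")


@dataclass
class SampleRecord:
    """One labelled acquisition: all radars' frames for one subject/posture/blanket/trial."""

    subject_id: str
    posture: str
    blanket: str
    trial: int
    frames: dict  # radar_id -> RadarFrame

    @property
    def sample_id(self) -> str:
        return f"{self.subject_id}_{self.posture}_{self.blanket}_t{self.trial}"


# --- phantom construction ---------------------------------------------------

# Canonical template, cm, midline x = 45, head toward y = 0.  Left-side
# postures are built from this and right-side ones are its mirror image
# about the midline, so L/R pairs are exact reflections before noise.
_BASE_BODY = {
    "head": ((45.0, 18.0), 0.9),
    "shoulder_l": ((32.0, 36.0), 1.1),
    "shoulder_r": ((58.0, 36.0), 1.1),
    "chest": ((45.0, 55.0), 1.6),
    "abdomen": ((45.0, 75.0), 1.3),
    "hip_l": ((36.0, 95.0), 1.2),
    "hip_r": ((54.0, 95.0), 1.2),
    "thigh_l": ((39.0, 125.0), 0.8),
    "thigh_r": ((51.0, 125.0), 0.8),
    "leg_l": ((38.0, 160.0), 0.6),
    "leg_r": ((52.0, 160.0), 0.6),
}

_LATERAL_SHIFT = -8.0  # body centre offset when lying on the side, cm
_LATERAL_COMPRESS = 0.6  # x-spread compression (stacked shoulders/hips)
_KNEE_FORWARD = -12.0  # flexed knees point toward the facing (-x) side
_PRONE_HEAD_TURN = -8.0  # head offset when prone, toward the turned side


def _template(posture_canonical: str) -> dict:
    """Left-canonical scatterer layout for one posture family."""
    body = {k: (list(p), r) for k, (p, r) in _BASE_BODY.items()}

    def compress_shift():
        for k, (p, _r) in body.items():
            p[0] = _BED_MIDLINE_X + _LATERAL_COMPRESS * (p[0] - _BED_MIDLINE_X) + _LATERAL_SHIFT

    def flex(leg: str):
        # pull the leg cranially and push the knee toward the facing side
        body[f"thigh_{leg}"][0][1] = 115.0
        body[f"thigh_{leg}"][0][0] += _KNEE_FORWARD * 0.6
        body[f"leg_{leg}"][0][1] = 128.0
        body[f"leg_{leg}"][0][0] += _KNEE_FORWARD

    if posture_canonical == "S":
        pass
    elif posture_canonical == "Log":
        compress_shift()
    elif posture_canonical == "Sto":
        compress_shift()
        flex("l")  # top leg flexed, bottom leg stays extended
    elif posture_canonical == "Fet":
        compress_shift()
        flex("l")
        flex("r")
    elif posture_canonical == "Pr":
        body["head"][0][0] += _PRONE_HEAD_TURN
        for k in ("chest", "abdomen"):
            pos, r = body[k]
            body[k] = (pos, r * 0.7)  # back faces up: weaker trunk return
    else:  # pragma: no cover - internal
        raise AssertionError(posture_canonical)
    return body


_POSTURE_TO_CANONICAL = {
    "S": ("S", False),
    "L.Log": ("Log", False),
    "L.Sto": ("Sto", False),
    "L.Fet": ("Fet", False),
    "R.Log": ("Log", True),
    "R.Sto": ("Sto", True),
    "R.Fet": ("Fet", True),
    "L.Pr": ("Pr", False),
    "R.Pr": ("Pr", True),
}


def make_phantom(posture: str, subject_scale=(1.0, 1.0), rng=None,
                 pos_jitter: float = 1.5, refl_jitter: float = 0.08) -> Phantom:
    """Build the scatterer set for one posture and subject.

    ``subject_scale`` = (width, height) multipliers applied about the bed
    midline and the pillow line.  Anatomical jitter (``pos_jitter`` cm,
    ``refl_jitter`` relative) is drawn from ``rng`` before mirroring, so
    a left posture and its right counterpart generated from identically
    seeded rngs are exact mirror images about x = 45 cm.
    """
    if posture not in _POSTURE_TO_CANONICAL:
        raise KeyError(f"unknown posture label {posture!r}; expected one of {FINE_LABELS}")
    rng = np.random.default_rng(rng)
    canonical, mirror = _POSTURE_TO_CANONICAL[posture]
    body = _template(canonical)
    sx, sy = subject_scale
    scatterers = []
    for name in _BASE_BODY:  # fixed iteration order keeps rng draws aligned
        (x, y), refl = body[name]
        x = _BED_MIDLINE_X + sx * (x - _BED_MIDLINE_X) + pos_jitter * rng.standard_normal()
        y = 15.0 + sy * (y - 15.0) + pos_jitter * rng.standard_normal()
        refl = refl * max(0.0, 1.0 + refl_jitter * rng.standard_normal())
        if mirror:
            x = 2.0 * _BED_MIDLINE_X - x
        scatterers.append(Scatterer(position=(x, y), reflectivity=refl))
    return Phantom(posture=posture, scatterers=tuple(scatterers), subject_scale=(sx, sy))


# --- frame synthesis --------------------------------------------------------

def default_clutter_profile(n_bins: int) -> np.ndarray:
    """Deterministic static room clutter: antenna ring-down decay plus two
    fixed wall/furniture returns."""
    bins = np.arange(n_bins, dtype=float)
    prof = 0.4 * np.exp(-bins / 120.0)
    for center, amp, width in ((420.0, 0.25, 25.0), (900.0, 0.12, 40.0)):
        prof += amp * np.exp(-0.5 * ((bins - center) / width) ** 2)
    return prof


def _azimuth_taper(radar: RadarSpec, target_xy) -> float:
    """Cosine taper inside the azimuth sector, zero outside."""
    v = np.asarray(target_xy, dtype=float) - radar.xy
    norm = math.hypot(v[0], v[1])
    if norm == 0.0:
        return 1.0
    bx, by = radar.boresight[0], radar.boresight[1]
    bnorm = math.hypot(bx, by)
    cosang = (v[0] * bx + v[1] * by) / (norm * bnorm)
    theta = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
    if theta > radar.azimuth_half_angle:
        return 0.0
    return math.cos(0.5 * math.pi * theta / radar.azimuth_half_angle)


def _deposit(frame, center_bin, amplitude, psf_sigma, pulse_gain):
    """Add a Gaussian-spread return at a fractional bin, modulated per pulse."""
    n_bins = frame.shape[0]
    half = int(math.ceil(4.0 * psf_sigma))
    lo = max(0, int(math.floor(center_bin)) - half)
    hi = min(n_bins, int(math.ceil(center_bin)) + half + 1)
    if lo >= hi:
        return
    bins = np.arange(lo, hi, dtype=float)
    kernel = amplitude * np.exp(-0.5 * ((bins - center_bin) / psf_sigma) ** 2)
    frame[lo:hi, :] += kernel[:, None] * pulse_gain[None, :]


def simulate_frame(radar: RadarSpec, phantom: Phantom, params: SimParams,
                   rng=None, blanket: str = "thin") -> RadarFrame:
    """Synthesise one radar frame of a phantom under a blanket condition.

    Per scatterer: range from the radar sets the fractional bin; amplitude
    is reflectivity x blanket attenuation x azimuth cosine taper / R^k
    (R in metres, floored at 0.3 m); the return is spread over bins by the
    range point-spread and modulated by per-pulse scintillation.  The
    blanket adds a weak diffuse return just in front of each scatterer.
    Static clutter and white noise complete the frame.
    """
    if blanket not in params.blanket_attenuation:
        raise KeyError(f"unknown blanket condition {blanket!r}")
    rng = np.random.default_rng(rng)
    n_bins = radar.n_bins
    frame = np.zeros((n_bins, params.n_pulses), dtype=np.float64)
    atten = params.blanket_attenuation[blanket]
    bin_cm = radar.bin_length_cm

    for sc in phantom.scatterers:
        r_cm = float(np.hypot(*(np.asarray(sc.position) - radar.xy)))
        if r_cm > radar.max_range * 100.0:
            logger.debug("scatterer at %.1f cm beyond max range of %s; skipped", r_cm, radar.radar_id)
            # keep the rng stream aligned regardless of geometry
            rng.standard_normal(params.n_pulses)
            continue
        taper = _azimuth_taper(radar, sc.position)
        gain = 1.0 + params.scintillation * rng.standard_normal(params.n_pulses)
        np.clip(gain, 0.0, None, out=gain)
        if taper == 0.0:
            continue
        r_m = max(r_cm / 100.0, 0.3)
        amp = sc.reflectivity * atten * taper / r_m**params.amplitude_exponent
        center_bin = r_cm / bin_cm
        _deposit(frame, center_bin, amp, params.psf_sigma_bins, gain)
        if params.blanket_diffuse > 0.0 and atten < 1.0:
            diff_amp = params.blanket_diffuse * (1.0 - atten) * sc.reflectivity * taper / r_m**params.amplitude_exponent
            _deposit(frame, max(0.0, center_bin - 5.0 / bin_cm), diff_amp,
                     params.psf_sigma_bins, gain)

    clutter = params.clutter_profile
    if clutter is None:
        clutter = default_clutter_profile(n_bins)
    frame += np.asarray(clutter, dtype=float)[:, None]
    if params.noise_sigma > 0.0:
        frame += rng.normal(0.0, params.noise_sigma, size=frame.shape)
    return RadarFrame(values=frame, radar_id=radar.radar_id, bin_length=radar.bin_length)


# --- dataset generation -----------------------------------------------------

def _sample_seed(seed, si, pi, bi, trial, ri=None):
    parts = [seed, si, pi, bi, trial] + ([ri] if ri is not None else [])
    return np.random.SeedSequence(parts)


def dataset_manifest(n_subjects: int, postures=FINE_LABELS, blankets=BLANKETS,
                     trials: int = 3) -> pd.DataFrame:
    """Manifest of the full factorial design without materialising frames."""
    rows = []
    for si in range(n_subjects):
        subject = f"sub{si:03d}"
        for posture in postures:
            for blanket in blankets:
                for trial in range(1, trials + 1):
                    rows.append(
                        {
                            "sample_id": f"{subject}_{posture}_{blanket}_t{trial}",
                            "subject_id": subject,
                            "posture": posture,
                            "coarse_label": coarse_map(posture),
                            "blanket": blanket,
                            "trial": trial,
                        }
                    )
    return pd.DataFrame(rows)


def iter_samples(n_subjects: int, postures=FINE_LABELS, blankets=BLANKETS,
                 trials: int = 3, placement=None, params: SimParams | None = None,
                 seed: int = 0):
    """Yield SampleRecord objects for the factorial design, one at a time.

    Reproducibility: every (subject, posture, blanket, trial, radar) cell
    gets its own child rng keyed on the root seed and the cell indices, so
    any subset regenerates identically regardless of iteration order.
    Per-subject body scale is drawn once per subject.
    """
    if n_subjects < 1 or trials < 1 or not postures or not blankets:
        raise ValueError("all design counts must be >= 1")
    placement = placement if placement is not None else default_placement()
    params = params if params is not None else SimParams()
    for si in range(n_subjects):
        subject = f"sub{si:03d}"
        subj_rng = np.random.default_rng(np.random.SeedSequence([seed, si]))
        sx = float(np.clip(1.0 + 0.08 * subj_rng.standard_normal(), 0.8, 1.2))
        sy = float(np.clip(1.0 + 0.06 * subj_rng.standard_normal(), 0.8, 1.2))
        for pi, posture in enumerate(postures):
            for bi, blanket in enumerate(blankets):
                for trial in range(1, trials + 1):
                    ph_rng = np.random.default_rng(_sample_seed(seed, si, pi, bi, trial))
                    phantom = make_phantom(posture, subject_scale=(sx, sy), rng=ph_rng)
                    frames = {}
                    for ri, radar in enumerate(placement):
                        fr_rng = np.random.default_rng(_sample_seed(seed, si, pi, bi, trial, ri))
                        frames[radar.radar_id] = simulate_frame(
                            radar, phantom, params, rng=fr_rng, blanket=blanket
                        )
                    yield SampleRecord(
                        subject_id=subject, posture=posture, blanket=blanket,
                        trial=trial, frames=frames,
                    )


def generate_dataset(n_subjects: int, postures=FINE_LABELS, blankets=BLANKETS,
                     trials: int = 3, placement=None, params: SimParams | None = None,
                     seed: int = 0):
    """Materialise the full design; returns (records, manifest DataFrame)."""
    records = list(
        iter_samples(n_subjects, postures, blankets, trials, placement, params, seed)
    )
    manifest = dataset_manifest(n_subjects, postures, blankets, trials)
    return records, manifest
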