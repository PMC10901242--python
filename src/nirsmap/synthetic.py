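"""Synthetic spectra and mapping sessions with the statistical structure
the analysis assumes.

The forward model is semi-empirical: reflectance is a power-law
scattering baseline times a Beer-Lambert attenuation over Gaussian
absorption bands (myoglobin/hemoglobin-like bands near 560, 630 and
760 nm, a water-like band near 970 nm).  Ablation increases scattering
and shifts absorption (a metmyoglobin-like gain near 630 nm, a
deoxy-band loss near 760 nm).  Poor-contact acquisitions see an extra
absorber centered near 764 nm, which drives the contact optical index
below its threshold.  Contact angle rescales intensity (a cosine
factor) but, by default, leaves spectral morphology untouched —
encoding the observed insensitivity of the indices to angles up to
60 deg; an ``angle_effect`` knob lets tests break that assumption.

Sessions emulate the bench protocol: per heart, a line of lesion
ellipses adjacent to a circular "vein" boundary, physical points
sampled over the field, the same points re-acquired in PBS and blood,
control points related to reference-image pixels by a known ground-
truth homography.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mapping import ControlPointSet
from .preprocess import CalibrationPair
from .types import (
    Homography,
    MappedSample,
    RawSpectrum,
    TrackerPose,
    ValidationError,
)

#: Native spectrometer grid emulated by the generator (0.9 nm pitch,
#: covering more than the retained 600-1000 nm band).
RAW_WL = np.arange(560.0, 1040.0, 0.9)


@dataclass
class Band:
    """One Gaussian absorption band of the forward model."""

    center: float  # nm
    width: float  # nm (Gaussian sigma)
    strength: float  # nonlesion mean optical density at band center
    lesion_delta: float = 0.0  # additive strength change after ablation
    sample_sd: float = 0.0  # per-acquisition biological jitter
    heart_sd: float = 0.0  # per-heart random offset

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("band width must be > 0")
        if self.strength < 0:
            raise ValidationError("band strength must be >= 0")


@dataclass
class TissueOpticsParams:
    """Forward-model parameters; defaults give single-index lesion AUCs
    in the 0.7-0.9 range, keeping classification nontrivial."""

    scatter_amp: float = 1.0
    scatter_power: float = 0.60  # baseline (lambda/600)^-b exponent
    lesion_scatter_gain: float = 1.30  # amplitude gain after ablation
    lesion_power_delta: float = -0.10
    power_sample_sd: float = 0.09
    power_heart_sd: float = 0.01
    bands: tuple[Band, ...] = (
        Band(560.0, 30.0, 0.50, lesion_delta=+0.05, sample_sd=0.07, heart_sd=0.008),
        Band(630.0, 35.0, 0.10, lesion_delta=+0.09, sample_sd=0.06, heart_sd=0.005),
        Band(760.0, 30.0, 0.08, lesion_delta=-0.03, sample_sd=0.025, heart_sd=0.003),
        Band(970.0, 45.0, 0.25, lesion_delta=0.0, sample_sd=0.05, heart_sd=0.005),
    )
    noise_sd: float = 0.01  # relative multiplicative detector noise
    # poor-contact absorber (drives COI below threshold)
    noncontact_strength: float = 0.35
    noncontact_strength_sd: float = 0.07
    noncontact_center: float = 764.0
    noncontact_width: float = 18.0
    # blood medium: strong absorber seen only on poor-contact paths
    blood_strength: float = 0.5
    medium_leak: float = 0.0  # leak of the blood absorber into contact spectra
    angle_effect: float = 0.0  # morphology perturbation per deg beyond 0
    phantom_factor: float = 1.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def zero_effect(self) -> "TissueOpticsParams":
        """Copy with all lesion deltas removed (null-hypothesis tissue)."""
        return replace(
            self,
            lesion_scatter_gain=1.0,
            lesion_power_delta=0.0,
            bands=tuple(replace(b, lesion_delta=0.0) for b in self.bands),
        )


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def lamp_shape(wl: np.ndarray = RAW_WL) -> np.ndarray:
    """Smooth, strictly positive synthetic illumination/system response."""
    return 1000.0 * np.exp(-0.5 * ((wl - 800.0) / 150.0) ** 2) + 100.0


def simulate_calibration(
    params: TissueOpticsParams, rng: np.random.Generator | None = None
) -> CalibrationPair:
    """Reflectance-standard measurement + phantom factor matching the
    forward model, so calibrate(simulate(...)) recovers the ground truth."""
    lamp = lamp_shape()
    standard = RawSpectrum(RAW_WL, lamp * 0.99, meta={"kind": "standard"})
    return CalibrationPair(standard=standard, phantom_factor=params.phantom_factor)


def _draw_heart_effects(
    params: TissueOpticsParams, rng: np.random.Generator
) -> dict:
    return {
        "power": rng.normal(0.0, params.power_heart_sd),
        "bands": np.array([rng.normal(0.0, b.heart_sd) for b in params.bands]),
    }


def draw_point_effects(
    n: int, params: TissueOpticsParams, rng: np.random.Generator
) -> dict:
    """Per-point tissue variability (scatter exponent and band strengths).

    These offsets belong to the tissue location, so paired PBS/blood
    acquisitions of the same point share them; only detector noise,
    contact failures, and poses are redrawn per acquisition.
    """
    return {
        "power": rng.normal(0.0, params.power_sample_sd, n),
        "bands": np.stack(
            [rng.normal(0.0, b.sample_sd, n) for b in params.bands], axis=1
        ),
    }


def _true_reflectance_batch(
    lesion: np.ndarray,
    contact: np.ndarray,
    angles: np.ndarray,
    medium: str,
    params: TissueOpticsParams,
    heart_effects: dict | None,
    rng: np.random.Generator,
    point_effects: dict | None = None,
) -> np.ndarray:
    """Noiseless relative reflectance (n, len(RAW_WL)), before the lamp."""
    n = len(lesion)
    wl = RAW_WL
    he = heart_effects or {"power": 0.0, "bands": np.zeros(len(params.bands))}
    pe = point_effects if point_effects is not None else draw_point_effects(n, params, rng)

    power = (
        params.scatter_power
        + np.where(lesion, params.lesion_power_delta, 0.0)
        + he["power"]
        + pe["power"]
    )
    amp = params.scatter_amp * np.where(lesion, params.lesion_scatter_gain, 1.0)
    refl = amp[:, None] * (wl[None, :] / 600.0) ** (-power[:, None])

    od = np.zeros((n, len(wl)))
    for i, b in enumerate(params.bands):
        strength = (
            b.strength
            + np.where(lesion, b.lesion_delta, 0.0)
            + he["bands"][i]
            + pe["bands"][:, i]
        )
        # optional morphology drift with contact angle (off by default)
        if params.angle_effect:
            strength = strength * (1.0 + params.angle_effect * angles / 60.0)
        od += np.clip(strength, 0.0, None)[:, None] * _gauss(wl, b.center, b.width)

    nc = ~contact
    if nc.any():
        a_nc = np.clip(
            rng.normal(params.noncontact_strength, params.noncontact_strength_sd, n),
            0.05,
            None,
        )
        od[nc] += a_nc[nc, None] * _gauss(
            wl, params.noncontact_center, params.noncontact_width
        )
        if medium == "blood":
            blood_od = params.blood_strength * (
                0.8 * _gauss(wl, 577.0, 40.0) + 0.5 * _gauss(wl, 760.0, 60.0)
            )
            od[nc] += blood_od[None, :]
    if medium == "blood" and params.medium_leak:
        leak_od = params.medium_leak * (
            0.8 * _gauss(wl, 577.0, 40.0) + 0.5 * _gauss(wl, 760.0, 60.0)
        )
        od[contact] += leak_od[None, :]

    refl = refl * np.exp(-od)
    # oblique contact reduces collected intensity; morphology untouched
    refl = refl * np.cos(np.radians(np.clip(angles, 0.0, 85.0)))[:, None]
    return refl


def simulate_spectra_batch(
    lesion: np.ndarray,
    contact: np.ndarray,
    angles: np.ndarray,
    medium: str,
    params: TissueOpticsParams,
    rng: np.random.Generator,
    heart_effects: dict | None = None,
    point_effects: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw detector counts and ground-truth relative reflectance.

    Returns ``(counts, truth)``, both (n, len(RAW_WL)); ``truth`` is the
    noiseless relative reflectance that calibration should recover.
    ``point_effects`` (see :func:`draw_point_effects`) lets paired media
    share each point's tissue variability.
    """
    truth = _true_reflectance_batch(
        np.asarray(lesion, bool),
        np.asarray(contact, bool),
        np.asarray(angles, float),
        medium,
        params,
        heart_effects,
        rng,
        point_effects,
    )
    lamp = lamp_shape()
    counts = truth * lamp[None, :] * 0.99 / params.phantom_factor
    if params.noise_sd > 0:
        counts = counts * (1.0 + rng.normal(0.0, params.noise_sd, counts.shape))
    counts = np.clip(counts, 0.0, None)
    return counts, truth


def simulate_spectrum(
    state: str,
    params: TissueOpticsParams,
    contact: bool = True,
    angle: float = 0.0,
    rng: np.random.Generator | None = None,
    medium: str = "PBS",
    heart_effects: dict | None = None,
) -> tuple[RawSpectrum, np.ndarray]:
    """One synthetic acquisition; ``state`` is 'lesion' or 'nonlesion'.

    Returns the raw spectrum and the ground-truth relative reflectance
    on the same native grid.
    """
    if state not in ("lesion", "nonlesion"):
        raise ValidationError("state must be 'lesion' or 'nonlesion'")
    rng = rng if rng is not None else np.random.default_rng()
    counts, truth = simulate_spectra_batch(
        np.array([state == "lesion"]),
        np.array([contact]),
        np.array([angle]),
        medium,
        params,
        rng,
        heart_effects,
    )
    return RawSpectrum(RAW_WL, counts[0], meta={"state": state}), truth[0]


def simulate_angle_experiment(
    params: TissueOpticsParams,
    angles: np.ndarray,
    rng: np.random.Generator,
    medium: str = "blood",
) -> dict[str, np.ndarray]:
    """Dedicated contact-angle sweep at a single tissue location.

    Emulates the bench protocol where the catheter tip stays on one spot
    while its angle varies: tissue (point and heart) effects are frozen
    at zero, so repeated acquisitions differ only by detector noise and
    any configured angle effect.  Returns raw count matrices keyed by
    tissue state.
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    frozen = {"power": np.zeros(n), "bands": np.zeros((n, len(params.bands)))}
    out = {}
    for state in ("nonlesion", "lesion"):
        counts, _ = simulate_spectra_batch(
            np.full(n, state == "lesion"),
            np.ones(n, bool),
            angles,
            medium,
            params,
            rng,
            point_effects=frozen,
        )
        out[state] = counts
    return out


# ---------------------------------------------------------------------------
# session layout
# ---------------------------------------------------------------------------


@dataclass
class LesionEllipse:
    cx: float
    cy: float
    rx: float
    ry: float
    theta: float  # rad, rotation of the major axis

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.radial(x, y) <= 1.0

    def radial(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Normalized elliptical radius (1 on the boundary)."""
        dx, dy = np.asarray(x) - self.cx, np.asarray(y) - self.cy
        c, s = np.cos(self.theta), np.sin(self.theta)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return np.sqrt((u / self.rx) ** 2 + (v / self.ry) ** 2)


@dataclass
class SessionConfig:
    """Acquisition-scale knobs for one synthetic study."""

    n_hearts: int = 22
    points_per_heart: int = 800  # physical points; each sampled in both media
    field_mm: tuple[float, float] = (60.0, 80.0)
    vein_center: tuple[float, float] = (18.0, 40.0)
    vein_radius: float = 11.0
    n_lesions: int = 9
    lesion_radii: tuple[float, float] = (5.0, 3.8)  # mm semi-axes
    lesion_arc_radius: float = 16.5  # mm from vein center
    boundary_ramp_mm: float = 0.0  # linear truth falloff outside lesions
    noncontact_fraction: float = 0.15
    #: fraction of contact failures tied to the location itself (tissue
    #: folds/edges) and therefore shared between the paired media passes
    contact_correlation: float = 0.7
    angle_max: float = 60.0  # deg, uniform contact-angle range
    n_control_points: int = 8
    pose_noise_sd: float = 0.1  # mm jitter on recorded sample positions
    cp_noise_sd: float = 0.0  # mm jitter on control-point physical coords
    media: tuple[str, ...] = ("PBS", "blood")
    optics: TissueOpticsParams = field(default_factory=TissueOpticsParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noncontact_fraction <= 1.0:
            raise ValidationError("noncontact_fraction must lie in [0, 1]")
        if not 0.0 <= self.contact_correlation <= 1.0:
            raise ValidationError("contact_correlation must lie in [0, 1]")
        if self.n_hearts < 1 or self.points_per_heart < 1:
            raise ValidationError("n_hearts and points_per_heart must be >= 1")


#: Ground-truth physical->pixel homography used by every synthetic session.
TRUE_HOMOGRAPHY = np.array(
    [
        [5.2, 0.15, 25.0],
        [-0.10, -5.0, 430.0],
        [2.0e-4, 1.0e-4, 1.0],
    ]
)

IMAGE_SHAPE = (460, 380)  # (rows, cols)


@dataclass
class HeartTruth:
    heart_id: str
    lesions: list[LesionEllipse]
    points: np.ndarray  # (n, 2) true physical locations, mm
    lesion_prob: np.ndarray  # ground-truth lesion probability per point

    def truth_probability(self, x: np.ndarray, y: np.ndarray, ramp_mm: float = 0.0) -> np.ndarray:
        return _truth_probability(self.lesions, x, y, ramp_mm)


def _truth_probability(
    lesions: list[LesionEllipse], x: np.ndarray, y: np.ndarray, ramp_mm: float
) -> np.ndarray:
    x, y = np.asarray(x, float), np.asarray(y, float)
    p = np.zeros(np.broadcast(x, y).shape)
    for e in lesions:
        r = e.radial(x, y)
        if ramp_mm > 0:
            scale = ramp_mm / max(min(e.rx, e.ry), 1e-6)
            pe = np.clip(1.0 - (r - 1.0) / scale, 0.0, 1.0)
            pe[r <= 1.0] = 1.0
        else:
            pe = (r <= 1.0).astype(float)
        p = np.maximum(p, pe)
    return p


@dataclass
class SessionData:
    """Everything one synthetic study emits."""

    config: SessionConfig
    samples: list[MappedSample]
    calibration: CalibrationPair
    control_points: ControlPointSet
    true_homography: Homography
    reference_image: np.ndarray
    hearts: dict[str, HeartTruth]
    true_contact: dict[str, bool]  # sample_id -> contact ground truth


def _make_lesion_line(cfg: SessionConfig, rng: np.random.Generator) -> list[LesionEllipse]:
    vx, vy = cfg.vein_center
    arc = np.linspace(-np.pi / 3.2, np.pi / 3.2, cfg.n_lesions)
    lesions = []
    for a in arc:
        r = cfg.lesion_arc_radius + rng.normal(0.0, 0.6)
        cx = vx + r * np.cos(a)
        cy = vy + r * np.sin(a)
        rx = cfg.lesion_radii[0] * (1.0 + rng.normal(0.0, 0.08))
        ry = cfg.lesion_radii[1] * (1.0 + rng.normal(0.0, 0.08))
        theta = a + np.pi / 2 + rng.normal(0.0, 0.1)  # tangential to the arc
        lesions.append(LesionEllipse(cx, cy, rx, ry, theta))
    return lesions


def _sample_points(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    fx, fy = cfg.field_mm
    vx, vy = cfg.vein_center
    pts = np.empty((0, 2))
    while len(pts) < cfg.points_per_heart:
        cand = rng.uniform([0, 0], [fx, fy], size=(2 * cfg.points_per_heart, 2))
        keep = (cand[:, 0] - vx) ** 2 + (cand[:, 1] - vy) ** 2 > cfg.vein_radius**2
        pts = np.vstack([pts, cand[keep]])
    return pts[: cfg.points_per_heart]


def _control_points(cfg: SessionConfig, H: Homography, rng: np.random.Generator) -> ControlPointSet:
    fx, fy = cfg.field_mm
    base = np.array(
        [
            [4, 4], [fx - 4, 4], [fx - 4, fy - 4], [4, fy - 4],
            [fx / 2, 4], [fx - 4, fy / 2], [fx / 2, fy - 4], [4, fy / 2],
            [fx / 3, fy / 3], [2 * fx / 3, 2 * fy / 3],
        ],
        dtype=float,
    )
    phys = base[: max(4, cfg.n_control_points)]
    if cfg.cp_noise_sd > 0:
        phys = phys + rng.normal(0.0, cfg.cp_noise_sd, phys.shape)
    return ControlPointSet(physical=phys, pixels=H.apply(phys))


def _reference_image(cfg: SessionConfig, lesions: list[LesionEllipse], H: Homography) -> np.ndarray:
    rows, cols = IMAGE_SHAPE
    u, v = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    phys = H.inverse().apply(np.column_stack([u.ravel(), v.ravel()]))
    x, y = phys[:, 0], phys[:, 1]
    img = np.full(rows * cols, 40, dtype=np.uint8)  # outside the field
    fx, fy = cfg.field_mm
    infield = (x >= 0) & (x <= fx) & (y >= 0) & (y <= fy)
    img[infield] = 190
    vx, vy = cfg.vein_center
    vein = infield & ((x - vx) ** 2 + (y - vy) ** 2 <= cfg.vein_radius**2)
    img[vein] = 60
    lesion = np.zeros_like(infield)
    for e in lesions:
        lesion |= e.contains(x, y)
    img[infield & lesion] = 110
    return img.reshape(rows, cols)


def simulate_session(cfg: SessionConfig) -> SessionData:
    """Generate a full multi-heart, two-medium mapping study.

    Every random draw comes from one generator seeded with
    ``cfg.seed``, so identical configs give identical sessions.
    """
    rng = np.random.default_rng(cfg.seed)
    H = Homography(TRUE_HOMOGRAPHY.copy())
    cal = simulate_calibration(cfg.optics, rng)
    control_points = _control_points(cfg, H, rng)

    samples: list[MappedSample] = []
    hearts: dict[str, HeartTruth] = {}
    true_contact: dict[str, bool] = {}
    ref_image = None
    t = 0.0
    for h in range(cfg.n_hearts):
        heart_id = f"H{h + 1:02d}"
        lesions = _make_lesion_line(cfg, rng)
        pts = _sample_points(cfg, rng)
        prob = _truth_probability(lesions, pts[:, 0], pts[:, 1], cfg.boundary_ramp_mm)
        labels = np.where(prob >= 0.5, "lesion", "nonlesion")
        hearts[heart_id] = HeartTruth(heart_id, lesions, pts, prob)
        if ref_image is None:
            ref_image = _reference_image(cfg, lesions, H)
        he = _draw_heart_effects(cfg.optics, rng)
        pe = draw_point_effects(len(pts), cfg.optics, rng)
        n = len(pts)
        # location-driven contact failures, shared by both media passes
        site_fail = rng.uniform(size=n) < cfg.noncontact_fraction
        site_driven = rng.uniform(size=n) < cfg.contact_correlation
        # per-point tissue state is shared between media; acquisition
        # noise, residual contact failures and poses are redrawn per medium
        for medium in cfg.media:
            acq_fail = rng.uniform(size=n) < cfg.noncontact_fraction
            contact = ~np.where(site_driven, site_fail, acq_fail)
            angles = rng.uniform(0.0, cfg.angle_max, n)
            counts, _truth = simulate_spectra_batch(
                labels == "lesion", contact, angles, medium, cfg.optics, rng, he,
                point_effects=pe,
            )
            jitter = rng.normal(0.0, cfg.pose_noise_sd, (n, 2))
            pix = H.apply(pts)
            yaws = rng.uniform(-180.0, 180.0, n)
            rolls = rng.uniform(-180.0, 180.0, n)
            for i in range(n):
                sid = f"{heart_id}-{medium}-{i:04d}"
                pose = TrackerPose(
                    x=pts[i, 0] + jitter[i, 0],
                    y=pts[i, 1] + jitter[i, 1],
                    z=5.0,
                    pitch=float(angles[i]),
                    yaw=float(yaws[i]),
                    roll=float(rolls[i]),
                    time=t,
                )
                t += 0.5  # 2 Hz acquisition
                samples.append(
                    MappedSample(
                        sample_id=sid,
                        heart_id=heart_id,
                        medium=medium,
                        pose=pose,
                        spectrum=RawSpectrum(RAW_WL, counts[i]),
                        label=str(labels[i]),
                        pixel=(float(pix[i, 0]), float(pix[i, 1])),
                    )
                )
                true_contact[sid] = bool(contact[i])

    return SessionData(
        config=cfg,
        samples=samples,
        calibration=cal,
        control_points=control_points,
        true_homography=H,
        reference_image=ref_image,
        hearts=hearts,
        true_contact=true_contact,
    )
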