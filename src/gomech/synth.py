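"""Seeded generators for every input the analysis modules consume.

Each generator is a pure function of its parameters and an explicit seed
(identical calls are bitwise reproducible) and attaches a
:class:`GroundTruth` record so recovery tests can compare analysis output
against the generating parameters:

- :func:`gen_force_curve` — Hertzian AFM approach curves with a flat
  pre-contact baseline, unknown contact point, and Gaussian force noise;
- :func:`gen_filament_image` — filament textures whose orientation
  distribution is a pi-periodic von Mises law of controllable
  concentration;
- :func:`gen_tracks` — directed single-cell migration tracks with per-cell
  speed heterogeneity and positional jitter;
- :func:`gen_cv_samples` — bivariate-normal collective-variable ensembles
  for free-energy landscapes;
- :func:`gen_dimer_frames` — two rigid bead clusters at prescribed COM
  separations in a periodic cubic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import line_aa

from gomech import afm as _afm
from gomech import cgmd as _cgmd
from gomech.errors import InvalidParameterError
from gomech.migration import TrackSet


@dataclass
class GroundTruth:
    """Generating parameters attached to every synthetic artifact."""

    generator_name: str
    parameters: dict
    seed: int


# ---------------------------------------------------------------------------
# AFM force curves

def gen_force_curve(
    E: float,
    contact_z0: float = 100.0,
    tip_radius: float = _afm.DEFAULT_TIP_RADIUS_NM,
    poisson: float = _afm.DEFAULT_POISSON,
    noise_sd: float = 0.0,
    n_points: int = 200,
    max_depth: float = _afm.DEFAULT_MAX_DEPTH_NM,
    seed: int = 0,
) -> _afm.ForceCurve:
    """Synthetic Hertzian approach curve (z in nm, force in nN).

    The abscissa spans a flat baseline for ``z < contact_z0`` (force equal
    to noise only) and a Hertzian rise for ``z >= contact_z0`` up to
    ``max_depth`` of indentation; ``contact_z0`` itself is always a sample
    so noiseless recovery is exact.  Gaussian noise of SD ``noise_sd`` nN
    is added to the whole trace.
    """
    if E <= 0:
        raise InvalidParameterError("Young's modulus must be positive")
    if tip_radius <= 0:
        raise InvalidParameterError("tip radius must be positive")
    if not 0 <= poisson < 0.5:
        raise InvalidParameterError("Poisson ratio must lie in [0, 0.5)")
    if max_depth <= 0:
        raise InvalidParameterError("max depth must be positive")
    if contact_z0 < 0:
        raise InvalidParameterError("contact point must be non-negative")
    rng = np.random.default_rng(seed)
    span = contact_z0 + max_depth
    n_pre = int(round(n_points * contact_z0 / span))
    n_pre = min(max(n_pre, 0), n_points - 10)
    z_pre = np.linspace(0.0, contact_z0, n_pre, endpoint=False)
    z_post = np.linspace(contact_z0, span, n_points - n_pre)
    z = np.concatenate([z_pre, z_post])
    force = np.zeros(n_points)
    depth = np.clip(z - contact_z0, 0.0, None)
    force[n_pre:] = _afm.hertz_force(E, poisson, tip_radius, depth[n_pre:])
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, n_points)
    gt = GroundTruth(
        "gen_force_curve",
        {
            "E_pa": E,
            "contact_z0_nm": contact_z0,
            "tip_radius_nm": tip_radius,
            "poisson": poisson,
            "noise_sd_nN": noise_sd,
            "max_depth_nm": max_depth,
        },
        seed,
    )
    return _afm.ForceCurve(
        z_nm=z,
        force_nN=force,
        tip_radius_nm=tip_radius,
        poisson=poisson,
        meta={"ground_truth": gt},
    )


# ---------------------------------------------------------------------------
# filament images

@dataclass
class FilamentImage:
    """Synthetic actin-like texture.

    ``image`` is the noisy float image; ``canvas`` the noiseless rendered
    intensity; ``raster`` the boolean footprint of the drawn filament cores
    (anti-aliased fringe excluded); ``angles`` the sampled director angles
    in [0, pi).
    """

    image: np.ndarray
    canvas: np.ndarray
    raster: np.ndarray
    angles: np.ndarray
    ground_truth: GroundTruth


def sample_axial_von_mises(
    n: int,
    mean_angle: float,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw axial (pi-periodic) von Mises angles in [0, pi).

    A standard von Mises sample on [-pi, pi) is halved and recentred, which
    is the textbook construction for nematic director statistics; kappa=0
    gives the uniform axial law and kappa >= 1e6 collapses to the mean.
    """
    if kappa < 0:
        raise InvalidParameterError("kappa must be non-negative")
    if kappa >= 1e6:
        return np.full(n, mean_angle % np.pi)
    phi = rng.vonmises(0.0, kappa, size=n)
    return (mean_angle + 0.5 * phi) % np.pi


def gen_filament_image(
    width: int = 256,
    height: int = 256,
    n_filaments: int = 60,
    kappa: float = 5.0,
    mean_angle: float = 0.0,
    line_width: int = 2,
    snr: float = 5.0,
    seed: int = 0,
) -> FilamentImage:
    """Bright anti-aliased filament segments on a noisy background.

    Segment orientations follow the axial von Mises law of concentration
    ``kappa`` about ``mean_angle``; centres and lengths are uniform.
    Background noise is Gaussian with SD ``peak / snr``.
    """
    if width < 64 or height < 64:
        raise InvalidParameterError("image dimensions must be >= 64 px")
    if n_filaments < 1:
        raise InvalidParameterError("need at least one filament")
    if snr <= 0:
        raise InvalidParameterError("snr must be positive")
    rng = np.random.default_rng(seed)
    angles = sample_axial_von_mises(n_filaments, mean_angle, kappa, rng)
    canvas = np.zeros((height, width))
    lmin, lmax = 0.2 * min(width, height), 0.5 * min(width, height)
    offsets = np.arange(line_width) - (line_width - 1) / 2.0
    for ang in angles:
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        half = 0.5 * rng.uniform(lmin, lmax)
        dy, dx = np.sin(ang), np.cos(ang)
        for off in offsets:
            # offset perpendicular to the filament axis for thickness
            oy, ox = off * dx, -off * dy
            r0 = int(round(np.clip(cy - half * dy + oy, 0, height - 1)))
            c0 = int(round(np.clip(cx - half * dx + ox, 0, width - 1)))
            r1 = int(round(np.clip(cy + half * dy + oy, 0, height - 1)))
            c1 = int(round(np.clip(cx + half * dx + ox, 0, width - 1)))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            canvas[rr, cc] = np.maximum(canvas[rr, cc], val)
    raster = canvas >= 0.5
    image = canvas + rng.normal(0.0, 1.0 / snr, canvas.shape)
    gt = GroundTruth(
        "gen_filament_image",
        {
            "kappa": kappa,
            "mean_angle": mean_angle,
            "n_filaments": n_filaments,
            "line_width": line_width,
            "snr": snr,
        },
        seed,
    )
    return FilamentImage(
        image=image, canvas=canvas, raster=raster, angles=angles, ground_truth=gt
    )


# ---------------------------------------------------------------------------
# migration tracks

def gen_tracks(
    n_cells: int,
    mean_speed: float,
    speed_sd: float = 0.0,
    dt: float = 10.0,
    duration: float = 2.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> TrackSet:
    """Directed migration tracks along +x with per-cell speed heterogeneity.

    Per-cell speeds (µm/h) are Normal(``mean_speed``, ``speed_sd``)
    truncated at zero; each sample gets isotropic Gaussian positional
    jitter of SD ``jitter_sd`` µm.  Times are minutes, ``duration`` hours.
    """
    if n_cells < 1:
        raise InvalidParameterError("need at least one cell")
    if duration <= 0 or dt <= 0:
        raise InvalidParameterError("duration and dt must be positive")
    if mean_speed < 0:
        raise InvalidParameterError("mean speed must be non-negative")
    rng = np.random.default_rng(seed)
    if speed_sd > 0:
        a = (0.0 - mean_speed) / speed_sd
        speeds = stats.truncnorm.rvs(
            a, np.inf, loc=mean_speed, scale=speed_sd, size=n_cells, random_state=rng
        )
    else:
        speeds = np.full(n_cells, float(mean_speed))
    t = np.arange(0.0, duration * 60.0 + 0.5 * dt, dt)
    rows = []
    for i, v in enumerate(speeds):
        x0, y0 = rng.uniform(0, 50, size=2)
        x = x0 + v * t / 60.0
        y = np.full_like(t, y0)
        if jitter_sd > 0:
            x = x + rng.normal(0.0, jitter_sd, t.size)
            y = y + rng.normal(0.0, jitter_sd, t.size)
        for k in range(t.size):
            rows.append((f"cell{i:04d}", t[k], x[k], y[k]))
    data = pd.DataFrame(rows, columns=["cell_id", "t_min", "x_um", "y_um"])
    gt = GroundTruth(
        "gen_tracks",
        {
            "mean_speed_um_h": mean_speed,
            "speed_sd_um_h": speed_sd,
            "jitter_sd_um": jitter_sd,
            "per_cell_speeds": speeds.tolist(),
        },
        seed,
    )
    return TrackSet(data=data, meta={"ground_truth": gt})


# ---------------------------------------------------------------------------
# collective-variable samples

@dataclass
class CVSamples:
    """Bivariate collective-variable draws for landscape tests."""

    x: np.ndarray
    y: np.ndarray
    ground_truth: GroundTruth


def gen_cv_samples(mean_xy, cov, n: int, seed: int = 0) -> CVSamples:
    """Draw ``n`` bivariate-normal collective-variable samples."""
    mean = np.asarray(mean_xy, dtype=float)
    cov = np.asarray(cov, dtype=float)
    if n < 1:
        raise InvalidParameterError("need at least one sample")
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise InvalidParameterError("covariance must be a symmetric 2x2 matrix")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise InvalidParameterError("covariance must be positive-definite") from exc
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
    gt = GroundTruth(
        "gen_cv_samples", {"mean_xy": mean.tolist(), "cov": cov.tolist()}, seed
    )
    return CVSamples(x=draws[:, 0], y=draws[:, 1], ground_truth=gt)


# ---------------------------------------------------------------------------
# dimer bead frames

@dataclass
class DimerTrajectory:
    """Frames of a rigid two-cluster bead system plus its topology."""

    frames: list
    topology: _cgmd.Topology
    separations: np.ndarray
    ground_truth: GroundTruth


def gen_dimer_frames(
    com_separations,
    beads_per_cluster: int = 50,
    cluster_radius: float = 1.0,
    box: float = _cgmd.DEFAULT_BOX_NM,
    jitter_sd: float = 0.0,
    seed: int = 0,
    center=None,
) -> DimerTrajectory:
    """Two rigid bead clusters at prescribed COM separations along +x.

    One frame per separation.  Cluster templates are drawn once (uniform in
    a sphere of ``cluster_radius``, recentred so the template COM is
    exactly zero) and placed with the requested minimum-image COM
    separation; ``jitter_sd`` adds per-bead Gaussian noise per frame.
    ``center`` moves cluster A (default mid-box), e.g. to straddle the
    periodic boundary.
    """
    seps = np.atleast_1d(np.asarray(com_separations, dtype=float))
    if np.any(seps >= box / 2.0):
        raise InvalidParameterError(
            "separation must be < box/2 (minimum-image ambiguity)"
        )
    if np.any(seps < 0):
        raise InvalidParameterError("separations must be non-negative")
    if beads_per_cluster < 1:
        raise InvalidParameterError("need at least one bead per cluster")
    rng = np.random.default_rng(seed)

    def _template():
        u = rng.normal(size=(beads_per_cluster, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = cluster_radius * rng.uniform(size=(beads_per_cluster, 1)) ** (1.0 / 3.0)
        pts = u * r
        return pts - pts.mean(axis=0)

    tmpl_a, tmpl_b = _template(), _template()
    c_a = np.full(3, box / 2.0) if center is None else np.asarray(center, dtype=float)
    frames = []
    for k, s in enumerate(seps):
        pos_a = tmpl_a + c_a
        pos_b = tmpl_b + c_a + np.array([s, 0.0, 0.0])
        pos = np.vstack([pos_a, pos_b])
        if jitter_sd > 0:
            pos = pos + rng.normal(0.0, jitter_sd, pos.shape)
        frames.append(_cgmd.BeadFrame(positions=pos, box=box, time_ns=float(k)))
    n = 2 * beads_per_cluster
    topology = _cgmd.Topology(
        types=np.full(n, "P1", dtype=object),
        charges=np.zeros(n),
        groups=np.array(
            ["actinA"] * beads_per_cluster + ["actinB"] * beads_per_cluster,
            dtype=object,
        ),
    )
    gt = GroundTruth(
        "gen_dimer_frames",
        {
            "com_separations_nm": seps.tolist(),
            "beads_per_cluster": beads_per_cluster,
            "cluster_radius_nm": cluster_radius,
            "box_nm": box,
            "jitter_sd_nm": jitter_sd,
        },
        seed,
    )
    return DimerTrajectory(
        frames=frames, topology=topology, separations=seps, ground_truth=gt
    )
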