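"""Hertz-model analysis of AFM force–indentation curves.

A spherical probe indenting an elastic half-space obeys the Hertz relation

    F = (4/3) * E / (1 - gamma^2) * sqrt(R) * delta^(3/2)

with force ``F``, Young's modulus ``E``, Poisson ratio ``gamma``, tip
radius ``R`` and indentation depth ``delta``.  The module estimates the
contact point of an approach curve by an exhaustive piecewise fit, extracts
``E`` by linear least squares in ``delta^(3/2)`` over a configurable depth
window, and summarises fits per experimental group.

Internally everything is SI (Pa, m, N); the public surface speaks the
instrument units nm / nN / kPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from gomech.errors import (
    InsufficientDataError,
    InvalidParameterError,
    NoContactError,
)

#: default Poisson ratio for cells
DEFAULT_POISSON = 0.4
#: default probe tip radius, nm (20 nm diameter probe)
DEFAULT_TIP_RADIUS_NM = 10.0
#: default indentation-depth window for fitting, nm
DEFAULT_MAX_DEPTH_NM = 500.0

_NM = 1e-9
_NN = 1e-9


@dataclass
class ForceCurve:
    """Approach segment of an AFM force–distance record.

    Parameters
    ----------
    z_nm : array
        Piezo position, nm, monotone non-decreasing.
    force_nN : array
        Cantilever force, nN (deflection already multiplied by the spring
        constant).
    spring_constant : float
        Cantilever spring constant, N/m (metadata; used only when
        ``deflection_mode`` fitting is requested).
    tip_radius_nm : float
        Probe tip radius, nm.
    poisson : float
        Poisson ratio of the sample.
    """

    z_nm: np.ndarray
    force_nN: np.ndarray
    spring_constant: float = 0.02
    tip_radius_nm: float = DEFAULT_TIP_RADIUS_NM
    poisson: float = DEFAULT_POISSON
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.z_nm.shape != self.force_nN.shape:
            raise InvalidParameterError("z and force arrays differ in length")
        if self.z_nm.size < 20:
            raise InvalidParameterError(
                f"force curve needs >= 20 samples, got {self.z_nm.size}"
            )
        if np.any(np.diff(self.z_nm) < 0):
            raise InvalidParameterError("z must be monotone non-decreasing")
        if self.tip_radius_nm <= 0:
            raise InvalidParameterError("tip radius must be positive")
        if not 0 <= self.poisson < 0.5:
            raise InvalidParameterError("Poisson ratio must lie in [0, 0.5)")

    def __len__(self) -> int:
        return self.z_nm.size


@dataclass
class HertzFit:
    """Result of a Hertz fit: modulus, contact point, and fit diagnostics."""

    young_modulus_pa: float
    contact_z0_nm: float
    depth_used_nm: float
    rss_nn2: float
    n_points_fit: int
    boundary_contact: bool = False

    @property
    def young_modulus_kpa(self) -> float:
        return self.young_modulus_pa / 1e3


def hertz_force(
    E_pa: float,
    poisson: float,
    tip_radius_nm: float,
    depth_nm,
):
    """Spherical-indenter Hertz force, nN, at indentation ``depth_nm``.

    Linear in ``E_pa`` and proportional to ``depth_nm**1.5``.
    """
    if E_pa <= 0:
        raise InvalidParameterError("Young's modulus must be positive")
    if tip_radius_nm <= 0:
        raise InvalidParameterError("tip radius must be positive")
    if not 0 <= poisson < 0.5:
        raise InvalidParameterError("Poisson ratio must lie in [0, 0.5)")
    depth = np.asarray(depth_nm, dtype=float)
    if np.any(depth < 0):
        raise InvalidParameterError("indentation depth must be non-negative")
    force_n = (
        4.0 / 3.0
        * E_pa / (1.0 - poisson**2)
        * np.sqrt(tip_radius_nm * _NM)
        * (depth * _NM) ** 1.5
    )
    out = force_n / _NN
    return float(out) if np.isscalar(depth_nm) else out


def _piecewise_rss(z: np.ndarray, f: np.ndarray, i0: int):
    """Least-squares baseline + Hertz-rise model with contact at sample i0.

    Model: F = b for z < z0, F = b + c*(z - z0)^1.5 for z >= z0, with
    (b, c) solved in closed form.  Returns (rss, b, c).
    """
    g = np.zeros_like(z)
    g[i0:] = (z[i0:] - z[i0]) ** 1.5
    n = z.size
    sg, sgg = g.sum(), (g * g).sum()
    sf, sfg = f.sum(), (f * g).sum()
    det = n * sgg - sg * sg
    if det <= 0:  # degenerate: no rise after i0
        b = sf / n
        c = 0.0
    else:
        b = (sgg * sf - sg * sfg) / det
        c = (n * sfg - sg * sf) / det
    resid = f - (b + c * g)
    return float(resid @ resid), float(b), float(c)


def estimate_contact_point(curve: ForceCurve) -> float:
    """Estimate the contact point z0 (nm) of an approach curve.

    Fits, for every candidate contact sample, a flat baseline followed by a
    ``delta^(3/2)`` rise (both coefficients closed-form), and returns the z
    of the candidate minimising the residual sum of squares.  Deterministic
    by construction; no optimiser is involved.

    Raises
    ------
    NoContactError
        If the curve has no rising segment: the maximum force does not
        exceed the pre-contact baseline by at least 3 baseline noise SDs.
    """
    z, f = curve.z_nm, curve.force_nN
    n = z.size
    n_base = max(5, n // 5)
    base = f[:n_base]
    noise_sd = float(np.std(base))
    rise = float(f.max() - base.mean())
    if rise < max(3.0 * noise_sd, 1e-12):
        raise NoContactError(
            f"no rising segment: max rise {rise:.3g} nN < 3 x baseline SD "
            f"{noise_sd:.3g} nN"
        )
    # candidate z0 at every sample that leaves >= 3 in-contact points
    best = (np.inf, 0)
    for i0 in range(0, n - 3):
        rss, _, c = _piecewise_rss(z, f, i0)
        if c >= 0 and rss < best[0]:
            best = (rss, i0)
    i0 = best[1]
    if i0 == 0:
        warnings.warn(
            "contact point at the first sample; the curve may already be in "
            "contact at the start of the approach segment",
            stacklevel=2,
        )
    return float(z[i0])


def fit_hertz(
    curve: ForceCurve,
    max_depth_nm: float = DEFAULT_MAX_DEPTH_NM,
    contact_z0_nm: float | None = None,
    deflection_mode: bool = False,
) -> HertzFit:
    """Fit the Hertz model to an approach curve and return the modulus.

    The indentation is ``delta = z - z0`` (force-mode curves).  With
    ``deflection_mode=True`` the cantilever deflection ``F/k`` is
    subtracted: ``delta = (z - z0) - F/k``.  The force is fitted as
    ``F = c * delta^(3/2)`` by linear least squares over
    ``0 < delta <= max_depth_nm`` after baseline subtraction, and

        E = 3 c (1 - gamma^2) / (4 sqrt(R))

    converted to Pa.

    Raises
    ------
    InsufficientDataError
        If fewer than 10 samples fall inside the depth window.
    """
    if contact_z0_nm is None:
        contact_z0_nm = estimate_contact_point(curve)
    z, f = curve.z_nm, curve.force_nN
    pre = z < contact_z0_nm
    baseline = float(f[pre].mean()) if pre.any() else 0.0
    f = f - baseline

    delta = z - contact_z0_nm
    if deflection_mode:
        delta = delta - f * _NN / curve.spring_constant / _NM
    window = (delta > 0) & (delta <= max_depth_nm)
    if int(window.sum()) < 10:
        raise InsufficientDataError(
            f"only {int(window.sum())} samples with 0 < depth <= "
            f"{max_depth_nm} nm (need >= 10)"
        )
    d_m = delta[window] * _NM
    f_n = f[window] * _NN
    g = d_m**1.5
    c = float((f_n @ g) / (g @ g))
    resid = f_n - c * g
    rss_nn2 = float(resid @ resid) / _NN**2
    E_pa = 3.0 * c * (1.0 - curve.poisson**2) / (
        4.0 * np.sqrt(curve.tip_radius_nm * _NM)
    )
    if E_pa <= 0:
        raise InsufficientDataError("fitted modulus is non-positive")
    return HertzFit(
        young_modulus_pa=E_pa,
        contact_z0_nm=float(contact_z0_nm),
        depth_used_nm=float(delta[window].max()),
        rss_nn2=rss_nn2,
        n_points_fit=int(window.sum()),
        boundary_contact=bool(contact_z0_nm <= z[0]),
    )


def group_stiffness_summary(fits_by_group: dict, control: str):
    """Per-group mean/SD of the modulus (kPa) and percent change vs control.

    ``percent_change = 100 * (E_ctrl - E_grp) / E_ctrl`` so a softer group
    shows a positive stiffness reduction.

    Returns a pandas DataFrame with columns
    ``group, n, mean_E_kpa, sd_E_kpa, percent_change``.
    """
    import pandas as pd

    if control not in fits_by_group:
        raise InvalidParameterError(f"control group {control!r} not present")
    for name, fits in fits_by_group.items():
        if not fits:
            raise InvalidParameterError(f"group {name!r} is empty")

    def _kpa(fit):
        return fit.young_modulus_kpa if isinstance(fit, HertzFit) else float(fit)

    means = {g: np.mean([_kpa(f) for f in fits]) for g, fits in fits_by_group.items()}
    rows = []
    e_ctrl = means[control]
    for g, fits in fits_by_group.items():
        vals = np.array([_kpa(f) for f in fits])
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "group": g,
                "n": vals.size,
                "mean_E_kpa": float(vals.mean()),
                "sd_E_kpa": sd,
                "percent_change": 100.0 * (e_ctrl - means[g]) / e_ctrl,
            }
        )
    return pd.DataFrame(rows)
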