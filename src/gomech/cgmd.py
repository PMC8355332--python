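"""Coarse-grained GO/actin observables in a periodic cubic box.

Builds CG graphene-oxide sheets (honeycomb lattice, a random fraction of
graphene SG4 beads relabelled as oxidised SP1 beads) and computes the desk
observables of a bead trajectory: minimum-image geometry, group
centre-of-mass (COM) distances, native contacts, truncated Lennard-Jones
and reaction-field Coulomb energies, and Boltzmann-inverted 2D free-energy
landscapes with local-minima detection.

No dynamics are propagated here: frames come from files or from the
:mod:`gomech.synth` generators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from gomech.errors import AmbiguityError, InvalidParameterError

#: Boltzmann constant, kJ/(mol K)
KB_KJ_PER_MOL_K = 0.0083145
#: Coulomb prefactor f = 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_PREFACTOR = 138.935
#: default cubic box edge, nm
DEFAULT_BOX_NM = 25.0
#: default nonbonded cutoff, nm
DEFAULT_CUTOFF_NM = 1.2
#: default native-contact cutoff, nm
DEFAULT_CONTACT_CUTOFF_NM = 0.6


# ---------------------------------------------------------------------------
# containers

@dataclass
class BeadFrame:
    """One frame of bead positions (nm) in a cubic periodic box."""

    positions: np.ndarray
    box: float = DEFAULT_BOX_NM
    time_ns: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.box <= 0:
            raise InvalidParameterError("box edge must be positive")
        self.positions = np.mod(self.positions, self.box)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class Topology:
    """Per-bead type / charge / group labels plus the LJ parameter table.

    ``lj_params`` maps an unordered type pair to ``(sigma_nm, epsilon_kjmol)``;
    lookups are symmetric in the two types.
    """

    types: np.ndarray
    charges: np.ndarray
    groups: np.ndarray
    lj_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        n = self.types.size
        if not (self.charges.size == n and self.groups.size == n):
            raise InvalidParameterError("topology columns differ in length")
        self.lj_params = {frozenset(k): v for k, v in self.lj_params.items()}

    @property
    def n_beads(self) -> int:
        return self.types.size

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise InvalidParameterError(f"group {group!r} is empty")
        return idx

    def lj(self, type_a: str, type_b: str):
        key = frozenset((type_a, type_b))
        if key not in self.lj_params:
            raise InvalidParameterError(
                f"no LJ parameters for type pair ({type_a}, {type_b})"
            )
        return self.lj_params[key]


@dataclass
class GOSheet:
    """CG graphene-oxide sheet on a honeycomb lattice.

    ``types`` holds ``"SG4"`` (graphene) or ``"SP1"`` (oxidised) per bead;
    exactly ``round(oxidation_fraction * N)`` beads are SP1.
    """

    positions: np.ndarray
    types: np.ndarray
    bonds: np.ndarray
    oxidation_fraction: float
    lattice_spacing: float
    meta: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sp1(self) -> int:
        return int(np.sum(self.types == "SP1"))


@dataclass
class ContactSet:
    """Reference (native) inter-group bead pairs within a cutoff."""

    pairs: np.ndarray
    cutoff: float
    group_a: str = "actinA"
    group_b: str = "actinB"

    def __len__(self) -> int:
        return self.pairs.shape[0]


@dataclass
class FELandscape:
    """Binned 2D free-energy surface, shifted so the occupied minimum is 0.

    Empty bins carry ``nan`` as the sentinel and are never interpolated.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    kT: float
    counts: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def global_minimum(self):
        """(x_center, y_center, F) of the occupied bin with the lowest F."""
        masked = np.where(np.isnan(self.F), np.inf, self.F)
        i, j = np.unravel_index(np.argmin(masked), self.F.shape)
        return float(self.x_centers[i]), float(self.y_centers[j]), float(self.F[i, j])


# ---------------------------------------------------------------------------
# sheet construction

def build_go_sheet(
    n_cells_x: int,
    n_cells_y: int,
    oxidation_fraction: float = 0.48,
    lattice_spacing: float = 0.24,
    seed: int = 0,
) -> GOSheet:
    """Build a flat honeycomb GO sheet with randomly oxidised beads.

    The sheet has two beads per unit cell (``2 * n_cells_x * n_cells_y``
    beads); ``round(oxidation_fraction * N)`` beads, chosen uniformly
    without replacement by ``seed``, are relabelled SP1.  Bonds join
    nearest-neighbour beads at one lattice spacing.
    """
    if not 0.0 <= oxidation_fraction <= 1.0:
        raise InvalidParameterError("oxidation fraction must lie in [0, 1]")
    if n_cells_x < 1 or n_cells_y < 1:
        raise InvalidParameterError("sheet dimensions must be >= 1")
    a = lattice_spacing
    # honeycomb primitive vectors and 2-bead basis
    a1 = np.array([np.sqrt(3) * a, 0.0])
    a2 = np.array([np.sqrt(3) * a / 2.0, 1.5 * a])
    basis = np.array([[0.0, 0.0], [np.sqrt(3) * a / 2.0, 0.5 * a]])
    ii, jj = np.meshgrid(np.arange(n_cells_x), np.arange(n_cells_y), indexing="ij")
    cells = ii.reshape(-1, 1) * a1 + jj.reshape(-1, 1) * a2
    xy = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 2)
    positions = np.column_stack([xy, np.zeros(len(xy))])

    n = positions.shape[0]
    n_sp1 = int(round(oxidation_fraction * n))
    rng = np.random.default_rng(seed)
    sp1_idx = rng.choice(n, size=n_sp1, replace=False)
    types = np.full(n, "SG4", dtype=object)
    types[sp1_idx] = "SP1"

    tree = cKDTree(positions)
    bonds = np.array(sorted(tree.query_pairs(r=1.01 * a)), dtype=int)
    return GOSheet(
        positions=positions,
        types=types,
        bonds=bonds,
        oxidation_fraction=oxidation_fraction,
        lattice_spacing=a,
        meta={"seed": seed},
    )


# ---------------------------------------------------------------------------
# periodic geometry

def min_image_vector(a, b, box: float) -> np.ndarray:
    """Minimum-image displacement ``b - a``; components in (-box/2, box/2]."""
    if box <= 0:
        raise InvalidParameterError("box edge must be positive")
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.round(d / box)

def min_image_distance(a, b, box: float) -> float:
    """Euclidean distance under the minimum-image convention."""
    d = min_image_vector(a, b, box)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)


def group_com(
    frame: BeadFrame,
    topology: Topology,
    group: str,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Centre of mass of a bead group, unwrapped across the boundary.

    Positions are unwrapped relative to the first group bead by minimum
    image, averaged (equal masses unless ``masses`` is given), and the COM
    re-wrapped into [0, box).  A group spanning more than half the box in
    any dimension after unwrapping is geometrically ambiguous and raises.
    """
    idx = topology.group_indices(group)
    pos = frame.positions[idx]
    ref = pos[0]
    d = pos - ref
    d -= frame.box * np.round(d / frame.box)
    span = d.max(axis=0) - d.min(axis=0)
    if np.any(span > frame.box / 2.0):
        raise AmbiguityError(
            f"group {group!r} spans more than box/2 after unwrapping; "
            "its COM is not well defined under minimum image"
        )
    if masses is None:
        com = ref + d.mean(axis=0)
    else:
        m = np.asarray(masses, dtype=float)[idx] if np.asarray(masses).size == topology.n_beads else np.asarray(masses, dtype=float)
        com = ref + (d * m[:, None]).sum(axis=0) / m.sum()
    return np.mod(com, frame.box)


def com_distance(frame: BeadFrame, topology: Topology, group_a: str, group_b: str) -> float:
    """Minimum-image distance between two group COMs in one frame, nm."""
    ca = group_com(frame, topology, group_a)
    cb = group_com(frame, topology, group_b)
    return float(min_image_distance(ca, cb, frame.box))


def com_distance_series(frames, topology: Topology, group_a: str, group_b: str):
    """Per-frame COM distance, returned as (times_ns, distances_nm) arrays."""
    times, dists = [], []
    for k, frame in enumerate(frames):
        try:
            dists.append(com_distance(frame, topology, group_a, group_b))
        except AmbiguityError as exc:
            raise AmbiguityError(f"frame {k}: {exc}") from exc
        times.append(frame.time_ns)
    return np.asarray(times), np.asarray(dists)


# ---------------------------------------------------------------------------
# native contacts

def _pair_distances(frame: BeadFrame, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Minimum-image distance matrix between two index sets."""
    d = frame.positions[idx_a][:, None, :] - frame.positions[idx_b][None, :, :]
    d -= frame.box * np.round(d / frame.box)
    return np.linalg.norm(d, axis=-1)


def reference_contacts(
    ref_frame: BeadFrame,
    topology: Topology,
    group_a: str,
    group_b: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
) -> ContactSet:
    """Native contacts: inter-group pairs closer than ``cutoff`` in the reference."""
    idx_a = topology.group_indices(group_a)
    idx_b = topology.group_indices(group_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise InvalidParameterError("contact groups must be disjoint")
    dist = _pair_distances(ref_frame, idx_a, idx_b)
    ia, ib = np.nonzero(dist < cutoff)
    pairs = np.column_stack([idx_a[ia], idx_b[ib]])
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    if pairs.shape[0] == 0:
        warnings.warn(
            f"no native contacts between {group_a!r} and {group_b!r} at "
            f"cutoff {cutoff} nm",
            stacklevel=2,
        )
    return ContactSet(pairs=pairs, cutoff=cutoff, group_a=group_a, group_b=group_b)


def count_contacts(
    frame: BeadFrame,
    contacts: ContactSet,
    cutoff: float | None = None,
) -> int:
    """Number of reference pairs currently closer than ``cutoff``."""
    if cutoff is None:
        cutoff = contacts.cutoff
    if len(contacts) == 0:
        return 0
    if contacts.pairs.max() >= frame.n_beads:
        raise InvalidParameterError("contact index out of range for frame")
    d = frame.positions[contacts.pairs[:, 0]] - frame.positions[contacts.pairs[:, 1]]
    d -= frame.box * np.round(d / frame.box)
    r = np.linalg.norm(d, axis=1)
    return int(np.sum(r < cutoff))


# ---------------------------------------------------------------------------
# nonbonded energies

def _scope_pairs(topology: Topology, pair_scope):
    """Index pairs in scope: a (group_a, group_b) tuple or 'all'."""
    if pair_scope == "all":
        n = topology.n_beads
        ia, ib = np.triu_indices(n, k=1)
        return ia, ib
    group_a, group_b = pair_scope
    idx_a = topology.group_indices(group_a)
    idx_b = topology.group_indices(group_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise InvalidParameterError("pair-scope groups must be disjoint")
    ia, ib = np.meshgrid(idx_a, idx_b, indexing="ij")
    return ia.ravel(), ib.ravel()


def _force_switch_energy(r, c, p, r_switch, r_cut):
    """Potential of one r^-p term under the GROMACS force-switch scheme.

    The pair force ``p*c/r^(p+1)`` is supplemented on [r_switch, r_cut] by
    ``A(r-r1)^2 + B(r-r1)^3`` with A, B fixed by F(r_cut)=0 and F'(r_cut)=0;
    the potential is the matching integral, shifted so V(r_cut)=0.
    """
    d = r_cut - r_switch
    A = -p * c * ((p + 4) * r_cut - (p + 1) * r_switch) / (r_cut ** (p + 2) * d**2)
    B = p * c * ((p + 3) * r_cut - (p + 1) * r_switch) / (r_cut ** (p + 2) * d**3)
    shift = c / r_cut**p - (A / 3.0) * d**3 - (B / 4.0) * d**4
    v = c / r**p - shift
    over = r > r_switch
    rr = r[over] - r_switch
    v[over] -= (A / 3.0) * rr**3 + (B / 4.0) * rr**4
    return v


def lj_energy(
    frame: BeadFrame,
    topology: Topology,
    pair_scope,
    r_cut: float = DEFAULT_CUTOFF_NM,
    mode: str = "plain_shift",
    r_switch: float = 0.9,
) -> float:
    """Total Lennard-Jones energy over in-scope pairs within ``r_cut``, kJ/mol.

    ``mode``:

    - ``"plain"`` — bare truncated 4*eps*[(sig/r)^12 - (sig/r)^6]
      (closed-form check mode);
    - ``"plain_shift"`` — potential shifted to zero at ``r_cut`` (default);
    - ``"force_switch"`` — force smoothly switched off on
      [``r_switch``, ``r_cut``] with the matching potential offset.
    """
    if mode not in ("plain", "plain_shift", "force_switch"):
        raise InvalidParameterError(f"unknown LJ mode {mode!r}")
    ia, ib = _scope_pairs(topology, pair_scope)
    d = frame.positions[ia] - frame.positions[ib]
    d -= frame.box * np.round(d / frame.box)
    r = np.linalg.norm(d, axis=1)
    within = r < r_cut
    total = 0.0
    for k in np.flatnonzero(within):
        sigma, eps = topology.lj(topology.types[ia[k]], topology.types[ib[k]])
        rk = r[k]
        if mode == "force_switch":
            c12 = 4.0 * eps * sigma**12
            c6 = -4.0 * eps * sigma**6
            rk_arr = np.array([rk])
            v = _force_switch_energy(rk_arr, c12, 12, r_switch, r_cut)
            v += _force_switch_energy(rk_arr, c6, 6, r_switch, r_cut)
            total += float(v[0])
        else:
            sr6 = (sigma / rk) ** 6
            v = 4.0 * eps * (sr6**2 - sr6)
            if mode == "plain_shift":
                src6 = (sigma / r_cut) ** 6
                v -= 4.0 * eps * (src6**2 - src6)
            total += v
    return float(total)


def coulomb_energy(
    frame: BeadFrame,
    topology: Topology,
    pair_scope,
    r_cut: float = DEFAULT_CUTOFF_NM,
    eps_r: float = 15.0,
    mode: str = "reaction_field",
) -> float:
    """Total Coulomb energy over in-scope pairs within ``r_cut``, kJ/mol.

    ``"reaction_field"`` (default) uses the infinite-dielectric reaction
    field: ``f q_i q_j / eps_r * (1/r + r^2/(2 r_cut^3) - 3/(2 r_cut))``,
    which vanishes at the cutoff.  ``"plain"`` is the bare truncated
    ``f q_i q_j / (eps_r r)`` check mode.
    """
    if eps_r <= 0:
        raise InvalidParameterError("relative dielectric must be positive")
    if mode not in ("plain", "reaction_field"):
        raise InvalidParameterError(f"unknown Coulomb mode {mode!r}")
    ia, ib = _scope_pairs(topology, pair_scope)
    d = frame.positions[ia] - frame.positions[ib]
    d -= frame.box * np.round(d / frame.box)
    r = np.linalg.norm(d, axis=1)
    within = (r < r_cut) & (r > 0)
    qq = topology.charges[ia[within]] * topology.charges[ib[within]]
    rr = r[within]
    if mode == "plain":
        v = COULOMB_PREFACTOR * qq / (eps_r * rr)
    else:
        k_rf = 1.0 / (2.0 * r_cut**3)
        c_rf = 3.0 / (2.0 * r_cut)
        v = COULOMB_PREFACTOR * qq / eps_r * (1.0 / rr + k_rf * rr**2 - c_rf)
    return float(v.sum())


# ---------------------------------------------------------------------------
# free-energy landscapes

def free_energy_2d(
    x_samples,
    y_samples,
    x_bins,
    y_bins,
    temperature: float = 300.0,
) -> FELandscape:
    """Boltzmann-inverted 2D histogram: F = -kT ln(P / P_max), kJ/mol.

    ``x_bins`` / ``y_bins`` follow :func:`numpy.histogram2d` semantics
    (counts or explicit edges).  Occupied bins have F >= 0 with the global
    occupied minimum exactly 0; empty bins are ``nan``.
    """
    x = np.asarray(x_samples, dtype=float)
    y = np.asarray(y_samples, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("sample arrays differ in length")
    if x.size < 100:
        raise InvalidParameterError("need at least 100 samples")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=[x_bins, y_bins])
    if np.count_nonzero(counts) <= 1:
        warnings.warn("degenerate landscape: all samples in one bin", stacklevel=2)
    kT = KB_KJ_PER_MOL_K * temperature
    with np.errstate(divide="ignore"):
        F = np.where(counts > 0, -kT * np.log(counts / counts.max()), np.nan)
    return FELandscape(x_edges=x_edges, y_edges=y_edges, F=F, kT=kT, counts=counts)


def find_minima(
    landscape: FELandscape,
    depth_threshold: float = 1.0,
    min_count: int = 1,
):
    """Local minima of the landscape: (x_center, y_center, F), F ascending.

    A minimum is an occupied bin strictly below every occupied
    8-neighbour and at least ``depth_threshold`` kJ/mol below the highest
    occupied neighbour.  Empty (nan) bins are ignored; bins with no
    occupied neighbour cannot qualify.  ``min_count`` raises the occupancy
    floor: bins with fewer samples are treated as empty, which suppresses
    spurious minima from Poisson noise in sparsely sampled tail bins.
    """
    F = np.where(landscape.counts >= max(min_count, 1), landscape.F, np.nan)
    if np.count_nonzero(~np.isnan(F)) < 9:
        raise InvalidParameterError("landscape needs >= 9 occupied bins")
    nx, ny = F.shape
    out = []
    for i in range(nx):
        for j in range(ny):
            fij = F[i, j]
            if np.isnan(fij):
                continue
            neigh = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and not np.isnan(F[a, b]):
                        neigh.append(F[a, b])
            if not neigh:
                continue
            neigh = np.array(neigh)
            if np.all(fij < neigh) and (neigh.max() - fij) >= depth_threshold:
                out.append(
                    (
                        float(landscape.x_centers[i]),
                        float(landscape.y_centers[j]),
                        float(fij),
                    )
                )
    out.sort(key=lambda t: t[2])
    return out
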