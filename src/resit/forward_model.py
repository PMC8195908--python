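"""Analytical EEG forward modeling in a three-shell spherical head.

The head is modeled as three concentric spheres (brain, skull, scalp) with
piecewise-constant conductivity. The potential of a current dipole inside
the innermost sphere, measured on the scalp against a reference at
infinity, is a Legendre series whose per-degree transfer coefficients
follow from the continuity of potential and radial current at the shell
boundaries. Equivalent sources live on a closed surface made of a
spherical cap plus a transverse plane; the lead field maps unit dipole
moments on that grid to scalp electrode potentials.

All lengths are dimensionless, normalized by the scalp radius.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .montage import ElectrodeMontage

__all__ = [
    "ConcentricSphereHeadModel",
    "SourceGrid",
    "LeadField",
    "build_source_grid",
    "dipole_potential",
    "compute_leadfield",
    "apply_reference_to_leadfield",
    "read_leadfield",
    "write_leadfield",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class SeriesConvergenceWarning(UserWarning):
    """Raised when the Legendre series has not converged at n_terms_max."""


@dataclass
class ConcentricSphereHeadModel:
    """Three-shell concentric-sphere volume conductor.

    Radii are normalized by the head (scalp) radius. Defaults follow the
    classical Rush-Driscoll parameterization: inner skull radius 0.87,
    outer skull radius 0.92, scalp radius 1.0, with relative conductivities
    1.0 (brain), 0.0125 (skull) and 1.0 (scalp).
    """

    r_brain: float = 0.87
    r_skull_outer: float = 0.92
    r_scalp: float = 1.0
    sigma_brain: float = 1.0
    sigma_skull: float = 0.0125
    sigma_scalp: float = 1.0
    n_terms_max: int = 500
    series_rtol: float = 1e-12

    def __post_init__(self) -> None:
        if not (0.0 < self.r_brain < self.r_skull_outer < self.r_scalp):
            raise ValueError("radii must satisfy 0 < r_brain < r_skull_outer < r_scalp")
        if min(self.sigma_brain, self.sigma_skull, self.sigma_scalp) <= 0:
            raise ValueError("all conductivities must be positive")
        if self.n_terms_max < 1:
            raise ValueError("n_terms_max must be >= 1")
        if self.series_rtol <= 0:
            raise ValueError("series_rtol must be positive")
        self._transfer_cache: dict[int, np.ndarray] = {}

    def transfer_coefficients(self, n_max: int) -> np.ndarray:
        """Per-degree scalp transfer factors T_n, n = 1 .. n_max.

        T_n is the degree-n scalp-surface potential for a source whose
        potential inside the brain compartment is (r_brain / r)^(n+1)
        times the degree-n angular harmonic; it is independent of the
        source depth and moment, which enter through separate factors.
        """
        if n_max not in self._transfer_cache:
            self._transfer_cache[n_max] = self._solve_transfer(n_max)
        return self._transfer_cache[n_max]

    def _solve_transfer(self, n_max: int) -> np.ndarray:
        s1, s2, s3 = self.sigma_brain, self.sigma_skull, self.sigma_scalp
        q12 = self.r_brain / self.r_skull_outer
        q23 = self.r_skull_outer / self.r_scalp
        T = np.empty(n_max + 1)
        T[0] = 0.0
        for n in range(1, n_max + 1):
            a, b = q12**n, q23**n
            # Unknowns: A1, A2, B2, A3, B3 in the layer-scaled radial bases
            #   brain:  (r1/r)^{n+1} + A1 (r/r1)^n
            #   skull:  A2 (r/r2)^n + B2 (r1/r)^{n+1}
            #   scalp:  A3 (r/r3)^n + B3 (r2/r)^{n+1}
            M = np.array(
                [
                    [1.0, -a, -1.0, 0.0, 0.0],
                    [s1 * n, -s2 * n * a, s2 * (n + 1), 0.0, 0.0],
                    [0.0, 1.0, q12 * a, -b, -1.0],
                    [0.0, s2 * n, -s2 * (n + 1) * q12 * a, -s3 * n * b, s3 * (n + 1)],
                    [0.0, 0.0, 0.0, n, -(n + 1) * q23 * b],
                ]
            )
            rhs = np.array([-1.0, s1 * (n + 1), 0.0, 0.0, 0.0])
            A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
            T[n] = A3 + B3 * q23 * b
        return T


@dataclass
class SourceGrid:
    """Equivalent dipole layer: radial dipoles on a spherical cap plus
    +z-oriented dipoles on a closing transverse plane."""

    positions: np.ndarray = field(repr=False)
    orientations: np.ndarray = field(repr=False)
    n_cap: int = 2600
    n_plane: int = 400
    cap_radius: float = 0.869
    plane_z: float = -0.076

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.shape != (self.n_sources, 3):
            raise ValueError("positions shape inconsistent with n_cap + n_plane")
        if self.orientations.shape != self.positions.shape:
            raise ValueError("orientations must match positions in shape")

    @property
    def n_sources(self) -> int:
        return self.n_cap + self.n_plane

    @property
    def is_cap(self) -> np.ndarray:
        mask = np.zeros(self.n_sources, dtype=bool)
        mask[: self.n_cap] = True
        return mask

    @property
    def grid_id(self) -> str:
        key = f"cap={self.n_cap},plane={self.n_plane},r={self.cap_radius!r},z={self.plane_z!r}"
        return hashlib.sha1(key.encode()).hexdigest()[:12]


def build_source_grid(
    n_cap: int = 2600,
    n_plane: int = 400,
    cap_radius: float = 0.869,
    plane_z: float = -0.076,
) -> SourceGrid:
    """Deterministic quasi-uniform equivalent-source layout.

    Cap dipoles are placed by a Fibonacci spiral restricted to the cap
    (equal-area in z, golden-angle azimuths) and oriented radially; plane
    dipoles fill the closing disk at ``plane_z`` in a sunflower layout and
    point along +z. The default 2600 + 400 = 3000 sources close the
    surface cap_radius = 0.869 / plane_z = -0.076 inside the brain
    compartment.
    """
    if n_cap < 0 or n_plane < 0:
        raise ValueError("source counts must be non-negative")
    if n_cap + n_plane <= 0:
        raise ValueError("the grid must contain at least one source")
    if not (0.0 < cap_radius):
        raise ValueError("cap_radius must be positive")
    if plane_z >= cap_radius:
        raise ValueError("plane_z must lie below the cap apex (plane_z < cap_radius)")
    if plane_z <= -cap_radius:
        raise ValueError("plane_z must intersect the cap sphere (plane_z > -cap_radius)")

    pts = []
    ors = []
    if n_cap:
        c_min = plane_z / cap_radius
        if n_cap == 1:
            cosines = np.array([1.0])
        else:
            cosines = 1.0 - (1.0 - c_min) * (np.arange(n_cap) + 0.5) / n_cap
        sines = np.sqrt(np.clip(1.0 - cosines**2, 0.0, None))
        phi = _GOLDEN_ANGLE * np.arange(n_cap)
        cap = cap_radius * np.column_stack(
            [sines * np.cos(phi), sines * np.sin(phi), cosines]
        )
        pts.append(cap)
        ors.append(cap / cap_radius)
    if n_plane:
        rho_max = np.sqrt(cap_radius**2 - plane_z**2)
        rho = rho_max * np.sqrt((np.arange(n_plane) + 0.5) / n_plane)
        phi = _GOLDEN_ANGLE * (np.arange(n_plane) + 0.25)
        plane = np.column_stack(
            [rho * np.cos(phi), rho * np.sin(phi), np.full(n_plane, plane_z)]
        )
        pts.append(plane)
        ors.append(np.tile([0.0, 0.0, 1.0], (n_plane, 1)))
    return SourceGrid(
        np.vstack(pts), np.vstack(ors), n_cap=n_cap, n_plane=n_plane,
        cap_radius=cap_radius, plane_z=plane_z,
    )


def _potential_series(
    model: ConcentricSphereHeadModel,
    electrodes: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
) -> np.ndarray:
    """Scalp potentials (infinity reference) for dipoles inside the brain.

    Parameters are arrays: electrodes (N, 3) unit vectors, dipole_pos
    (M, 3), dipole_moment (M, 3). Returns the (N, M) potential matrix.

    The degree-n term couples the radial moment through n * P_n(cos g) and
    the tangential moment through P_n'(cos g) applied to the moment
    component transverse to the source radius, with g the angle between
    electrode and source.
    """
    E = np.atleast_2d(np.asarray(electrodes, dtype=float))
    R = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    Q = np.atleast_2d(np.asarray(dipole_moment, dtype=float))
    b = np.linalg.norm(R, axis=1)
    if np.any(b >= model.r_brain):
        j = int(np.argmax(b))
        raise ValueError(
            f"dipole {j} at radius {b[j]:.4f} is not strictly inside the brain "
            f"compartment (r_brain = {model.r_brain})"
        )
    rhat = np.where(b[:, None] > 0, R / np.where(b == 0, 1.0, b)[:, None], [0.0, 0.0, 1.0])

    X = np.clip(E @ rhat.T, -1.0, 1.0)            # (N, M) cos(angle)
    m_r = np.einsum("mi,mi->m", Q, rhat)          # radial moment component
    D = E @ Q.T - X * m_r[None, :]                # tangential coupling term

    nmax = model.n_terms_max
    T = model.transfer_coefficients(nmax)
    ratio = b / model.r_brain

    V = np.zeros_like(X)
    P_prev = np.ones_like(X)       # P_0
    P_cur = X.copy()               # P_1
    dP_prev = np.zeros_like(X)     # P_0'
    dP_cur = np.ones_like(X)       # P_1'
    bpow = np.ones_like(b)         # (b / r_brain)^(n-1)
    small_streak = 0
    converged = False
    for n in range(1, nmax + 1):
        term = (T[n] * bpow)[None, :] * (n * m_r[None, :] * P_cur + dP_cur * D)
        V += term
        vmax = np.max(np.abs(V))
        if np.max(np.abs(term)) <= model.series_rtol * max(vmax, 1e-300):
            small_streak += 1
            if small_streak >= 2:
                converged = True
                break
        else:
            small_streak = 0
        # Legendre recurrences for P_{n+1} and P_{n+1}'
        P_next = ((2 * n + 1) * X * P_cur - n * P_prev) / (n + 1)
        dP_next = dP_prev + (2 * n + 1) * P_cur
        P_prev, P_cur = P_cur, P_next
        dP_prev, dP_cur = dP_cur, dP_next
        bpow = bpow * ratio
    if not converged:
        warnings.warn(
            f"Legendre series not converged to rtol={model.series_rtol:g} within "
            f"{nmax} terms; returning the partial sum",
            SeriesConvergenceWarning,
            stacklevel=2,
        )
    return V / (4.0 * np.pi * model.sigma_brain * model.r_brain**2)


def dipole_potential(
    model: ConcentricSphereHeadModel,
    dipole_pos,
    dipole_moment,
    electrode_pos,
) -> float:
    """Scalp potential (infinity reference) of one dipole at one electrode.

    ``dipole_pos`` must lie strictly inside the brain compartment and
    ``electrode_pos`` on the unit sphere.
    """
    e = np.asarray(electrode_pos, dtype=float)
    if abs(np.linalg.norm(e) - 1.0) > 1e-6:
        raise ValueError("electrode position must be a unit vector")
    return float(_potential_series(model, e[None, :], np.asarray(dipole_pos)[None, :],
                                   np.asarray(dipole_moment)[None, :])[0, 0])


@dataclass
class LeadField:
    """N x M gain matrix with a declared reference convention."""

    matrix: np.ndarray = field(repr=False)
    reference: str
    montage_labels: list[str]
    grid_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("lead-field matrix must be 2-D")
        if len(self.montage_labels) != self.matrix.shape[0]:
            raise ValueError("one label per lead-field row is required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field contains non-finite entries")
        if self.reference == "average":
            colnorm = np.linalg.norm(self.matrix, axis=0)
            colsum = np.abs(self.matrix.sum(axis=0))
            if np.any(colsum > 1e-9 * np.maximum(colnorm, 1e-300)):
                raise ValueError("average-reference lead field columns must sum to zero")
        elif self.reference.startswith("point:"):
            lbl = self.reference.split(":", 1)[1]
            if lbl in self.montage_labels:
                row = self.matrix[self.montage_labels.index(lbl)]
                if np.any(row != 0.0):
                    raise ValueError("point-reference lead field must have a zero reference row")
        elif self.reference != "infinity":
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1]


def compute_leadfield(
    model: ConcentricSphereHeadModel,
    montage: ElectrodeMontage,
    grid: SourceGrid,
) -> LeadField:
    """Lead field of the grid's unit-moment dipoles, reference at infinity."""
    if grid.cap_radius >= model.r_brain:
        raise ValueError("source cap must lie strictly inside the brain compartment")
    try:
        mat = _potential_series(model, montage.positions, grid.positions, grid.orientations)
    except ValueError as err:
        raise ValueError(f"lead-field computation failed: {err}") from err
    return LeadField(mat, "infinity", list(montage.labels), grid.grid_id)


def apply_reference_to_leadfield(
    lf: LeadField,
    reference: str,
    channel_subset: list[str] | None = None,
) -> LeadField:
    """Restrict an infinity-reference lead field to a channel subset and
    re-express it in a new reference convention.

    For the average reference the row mean over the retained channels is
    subtracted from every row; for a point reference the reference
    electrode's row is subtracted (and that electrode must be in the
    subset).
    """
    if lf.reference != "infinity":
        raise ValueError("reference transforms start from an infinity-reference lead field")
    labels = list(lf.montage_labels) if channel_subset is None else list(channel_subset)
    if not labels:
        raise ValueError("channel subset must be non-empty")
    try:
        idx = [lf.montage_labels.index(l) for l in labels]
    except ValueError as err:
        raise ValueError(f"channel subset not in lead field: {err}") from None
    sub = lf.matrix[idx]
    if reference == "infinity":
        out = sub
    elif reference == "average":
        out = sub - sub.mean(axis=0, keepdims=True)
    elif reference.startswith("point:"):
        lbl = reference.split(":", 1)[1]
        if lbl not in labels:
            raise ValueError(f"point reference {lbl!r} must be in the channel subset")
        out = sub - sub[labels.index(lbl)]
        out[labels.index(lbl)] = 0.0  # exact zero row, not just roundoff
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return LeadField(out, reference, labels, lf.grid_id)


def write_leadfield(lf: LeadField, path) -> None:
    """Persist a lead field to HDF5 with its reference and grid metadata."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("matrix", data=lf.matrix, track_times=False)
        f.create_dataset(
            "labels",
            data=np.array(lf.montage_labels, dtype=h5py.string_dtype()),
            track_times=False,
        )
        d.attrs["reference"] = lf.reference
        d.attrs["grid_id"] = lf.grid_id


def read_leadfield(path) -> LeadField:
    with h5py.File(path, "r") as f:
        d = f["matrix"]
        return LeadField(
            d[()],
            str(d.attrs["reference"]),
            [l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]],
            str(d.attrs["grid_id"]),
        )
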