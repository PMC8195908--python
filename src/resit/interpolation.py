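"""Bad-channel interpolators and reference transforms.

Three interpolation strategies are provided as scikit-learn style
transformers operating on ``(n_times, n_channels)`` arrays:

* :class:`NeighborInterpolator` — each bad channel becomes the unweighted
  mean of its nearest good channels (angular distance on the unit sphere).
* :class:`SphericalSplineInterpolator` — scalp potentials are modeled as a
  spherical spline with a zero-sum coefficient constraint and evaluated at
  the bad-channel sites.
* :class:`ResitInterpolator` — equivalent dipole sources are estimated
  from the good channels through the Moore-Penrose pseudoinverse of the
  reference-transformed lead field and forward-projected to every
  electrode, which simultaneously standardizes the reference to infinity
  (RESIT). With no bad channels this reduces to REST reference
  standardization.

Module-level functions wrap these estimators for
:class:`~resit.recording.EEGRecording` objects (channels x time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .forward_model import LeadField
from .montage import ElectrodeMontage
from .recording import EEGRecording

__all__ = [
    "NeighborInterpolator",
    "SphericalSplineInterpolator",
    "ResitInterpolator",
    "SplineSystem",
    "spline_g",
    "rereference",
    "ni_interpolate",
    "ssi_build",
    "ssi_interpolate",
    "resit_interpolate",
    "rest_standardize",
]


def _check_X(X, n_channels: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_times, n_channels)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if n_channels is not None and X.shape[1] != n_channels:
        raise ValueError(f"X has {X.shape[1]} channels, expected {n_channels}")
    return X


def _resolve_bad(labels: list[str], bad_channels) -> np.ndarray:
    mask = np.zeros(len(labels), dtype=bool)
    if bad_channels is None:
        return mask
    for b in bad_channels:
        if b not in labels:
            raise ValueError(f"bad channel {b!r} not in montage")
        mask[labels.index(b)] = True
    return mask


class NeighborInterpolator(TransformerMixin, BaseEstimator):
    """Replace bad channels by the mean of their nearest good channels.

    Parameters
    ----------
    montage : ElectrodeMontage
        Electrode geometry; neighbor distance is the angle on the unit sphere.
    bad_channels : list of str, optional
        Labels of channels to reconstruct.
    n_neighbors : int, default 4
        Number of nearest *good* channels averaged per bad channel. Ties in
        angular distance are broken by label lexicographic order.

    Attributes
    ----------
    weights_ : ndarray, shape (n_channels, n_channels)
        Linear interpolation operator: bad-channel rows carry
        ``1 / n_neighbors`` at their selected neighbors, good rows are
        identity.
    neighbor_indices_ : dict
        Bad-channel index -> list of selected good-channel indices.
    """

    def __init__(self, montage: ElectrodeMontage | None = None, bad_channels=None,
                 n_neighbors: int = 4):
        self.montage = montage
        self.bad_channels = bad_channels
        self.n_neighbors = n_neighbors

    def fit(self, X=None, y=None):
        if self.montage is None:
            raise ValueError("a montage is required")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        labels = self.montage.labels
        bad = _resolve_bad(labels, self.bad_channels)
        good = np.flatnonzero(~bad)
        if len(good) < self.n_neighbors:
            raise ValueError(
                f"need at least {self.n_neighbors} good channels, have {len(good)}"
            )
        n = self.montage.n_channels
        W = np.zeros((n, n))
        W[good, good] = 1.0
        self.neighbor_indices_ = {}
        for b in np.flatnonzero(bad):
            nn = self.montage.nearest(int(b), candidates=good, k=self.n_neighbors)
            W[b, nn] = 1.0 / self.n_neighbors
            self.neighbor_indices_[int(b)] = nn
        self.weights_ = W
        self.bad_mask_ = bad
        self.n_features_in_ = n
        return self

    def transform(self, X) -> np.ndarray:
        X = _check_X(X, self.n_features_in_)
        return X @ self.weights_.T


def spline_g(x, order_m: int = 4, n_legendre: int = 50) -> np.ndarray:
    """Spherical-spline kernel g(x) for x = cos(angle between electrodes).

    ``g(x) = (1 / 4 pi) sum_{n=1}^{n_legendre} (2n+1) / (n (n+1))^m P_n(x)``,
    the classical stiffness-``m`` spline kernel on the sphere. The global
    ``1 / 4 pi`` prefactor cancels in the interpolation solve.
    """
    n = np.arange(1, n_legendre + 1, dtype=float)
    coeffs = np.zeros(n_legendre + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** order_m
    return npleg.legval(np.asarray(x, dtype=float), coeffs) / (4.0 * np.pi)


@dataclass
class SplineSystem:
    """Precomputed spherical-spline kernel matrices for one montage/bad split.

    ``g_good`` holds the kernel between good electrodes ((N-k) x (N-k),
    symmetric, diagonal g(1)); ``g_bad`` between each bad and the good
    electrodes (k x (N-k)).
    """

    g_good: np.ndarray = field(repr=False)
    g_bad: np.ndarray = field(repr=False)
    order_m: int = 4
    n_legendre: int = 50
    good_labels: list[str] = field(default_factory=list)
    bad_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.g_good = np.asarray(self.g_good, dtype=float)
        self.g_bad = np.asarray(self.g_bad, dtype=float)
        if not np.allclose(self.g_good, self.g_good.T):
            raise ValueError("g_good must be symmetric")
        if not (np.all(np.isfinite(self.g_good)) and np.all(np.isfinite(self.g_bad))):
            raise ValueError("spline matrices must be finite")


class SphericalSplineInterpolator(TransformerMixin, BaseEstimator):
    """Spherical-spline interpolation of bad channels.

    The good-channel potentials at each time point are fit exactly by a
    spherical spline ``v(s) = c0 + sum_i C_i g(cos angle(s, s_i))`` whose
    coefficients satisfy ``sum_i C_i = 0``; the spline is then evaluated
    at the bad-channel sites. The constraint is imposed through a bordered
    linear system factorized once and solved for all time points at once.

    Parameters
    ----------
    montage : ElectrodeMontage
    bad_channels : list of str, optional
    order : int, default 4
        Spline stiffness m.
    n_legendre : int, default 50
        Number of Legendre terms in the kernel series.

    Attributes
    ----------
    spline_system_ : SplineSystem
    transfer_ : ndarray, shape (n_bad, n_good)
        Linear map from good-channel data to bad-channel estimates.
    """

    def __init__(self, montage: ElectrodeMontage | None = None, bad_channels=None,
                 order: int = 4, n_legendre: int = 50):
        self.montage = montage
        self.bad_channels = bad_channels
        self.order = order
        self.n_legendre = n_legendre

    def fit(self, X=None, y=None):
        if self.montage is None:
            raise ValueError("a montage is required")
        labels = self.montage.labels
        bad = _resolve_bad(labels, self.bad_channels)
        good = np.flatnonzero(~bad)
        badi = np.flatnonzero(bad)
        if len(good) < 3:
            raise ValueError("spherical-spline interpolation needs at least 3 good channels")
        pos = self.montage.positions
        cos_gg = np.clip(pos[good] @ pos[good].T, -1.0, 1.0)
        dup = (cos_gg > 1.0 - 1e-12) & ~np.eye(len(good), dtype=bool)
        if np.any(dup):
            i, j = np.argwhere(dup)[0]
            raise ValueError(
                f"coincident electrode positions: {labels[good[i]]!r} and "
                f"{labels[good[j]]!r} (angle undefined)"
            )
        cos_bg = np.clip(pos[badi] @ pos[good].T, -1.0, 1.0)
        sys_ = SplineSystem(
            g_good=spline_g(cos_gg, self.order, self.n_legendre),
            g_bad=spline_g(cos_bg, self.order, self.n_legendre),
            order_m=self.order,
            n_legendre=self.n_legendre,
            good_labels=[labels[i] for i in good],
            bad_labels=[labels[i] for i in badi],
        )
        ng = len(good)
        A = np.zeros((ng + 1, ng + 1))
        A[:ng, :ng] = sys_.g_good
        A[:ng, ng] = 1.0
        A[ng, :ng] = 1.0
        try:
            lu = linalg.lu_factor(A)
        except linalg.LinAlgError as err:  # pragma: no cover - scipy raises on exact singularity
            raise ValueError(f"singular spline system (rank-deficient): {err}") from None
        if not np.all(np.isfinite(lu[0])) or np.any(np.abs(np.diag(lu[0])) < 1e-300):
            raise ValueError(
                "singular spline system: the bordered kernel matrix is rank deficient"
            )
        # transfer operator: bad estimates = [g_bad 1] A^{-1} [V_good; 0]
        B = linalg.lu_solve(lu, np.vstack([np.eye(ng), np.zeros((1, ng))]))
        self.transfer_ = np.hstack([sys_.g_bad, np.ones((len(badi), 1))]) @ B
        self._lu = lu
        self.spline_system_ = sys_
        self.good_idx_ = good
        self.bad_idx_ = badi
        self.bad_mask_ = bad
        self.n_features_in_ = self.montage.n_channels
        return self

    def solve_coefficients(self, V_good: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Spline coefficients (C, c0) for good-channel data (n_good, T)."""
        V_good = np.asarray(V_good, dtype=float)
        rhs = np.vstack([V_good, np.zeros((1, V_good.shape[1]))])
        sol = linalg.lu_solve(self._lu, rhs)
        return sol[:-1], sol[-1]

    def transform(self, X) -> np.ndarray:
        X = _check_X(X, self.n_features_in_)
        out = X.copy()
        out[:, self.bad_idx_] = X[:, self.good_idx_] @ self.transfer_.T
        return out


class ResitInterpolator(TransformerMixin, BaseEstimator):
    """Equivalent-source interpolation with reference standardization (RESIT).

    Equivalent dipole sources S are estimated from the good channels by
    ``S = pinv(L_ref) @ V_ref``, where ``L_ref`` is the infinity-reference
    lead field restricted to the good channels and transformed to the
    data's reference; the full scalp potential is then reconstructed as
    ``V = L @ S`` at every electrode with the reference standardized to
    infinity. With no bad channels this is exactly REST reference
    standardization.

    Parameters
    ----------
    leadfield : LeadField
        Infinity-reference lead field covering all montage channels.
    bad_channels : list of str, optional
    input_reference : str, default "average"
        Reference convention of the input data: ``"average"`` (over the
        good channels) or ``"point:<label>"`` with a good reference
        channel.
    output_reference : str, default "infinity"
        ``"infinity"`` (native RESIT output) or ``"average"`` to
        re-reference the reconstruction to the average over all channels.
    pinv_rtol : float, default 1e-8
        Relative singular-value cutoff of the Moore-Penrose pseudoinverse.

    Attributes
    ----------
    operator_ : ndarray, shape (n_channels, n_good)
        Reconstruction operator ``L @ pinv(L_ref)``.
    rank_ : int
        Effective rank of the reference-transformed good-channel lead field.
    """

    def __init__(self, leadfield: LeadField | None = None, bad_channels=None,
                 input_reference: str = "average", output_reference: str = "infinity",
                 pinv_rtol: float = 1e-8):
        self.leadfield = leadfield
        self.bad_channels = bad_channels
        self.input_reference = input_reference
        self.output_reference = output_reference
        self.pinv_rtol = pinv_rtol

    def fit(self, X=None, y=None):
        lf = self.leadfield
        if lf is None:
            raise ValueError("a lead field is required")
        if lf.reference != "infinity":
            raise ValueError("the lead field must use the infinity reference")
        if self.output_reference not in ("infinity", "average"):
            raise ValueError("output_reference must be 'infinity' or 'average'")
        labels = list(lf.montage_labels)
        bad = _resolve_bad(labels, self.bad_channels)
        good = np.flatnonzero(~bad)
        if len(good) == 0:
            raise ValueError("all channels are bad; nothing to interpolate from")
        if len(good) == 1:
            raise ValueError(
                "only one good channel left (k = N-1); the source estimate is "
                "rank deficient beyond tolerance"
            )
        L = lf.matrix
        Lg = L[good]
        if self.input_reference == "average":
            L_ref = Lg - Lg.mean(axis=0, keepdims=True)
        elif self.input_reference.startswith("point:"):
            ref_lbl = self.input_reference.split(":", 1)[1]
            if ref_lbl not in labels or bad[labels.index(ref_lbl)]:
                raise ValueError(
                    f"point reference {ref_lbl!r} must be a good montage channel"
                )
            ref_row = L[labels.index(ref_lbl)]
            L_ref = Lg - ref_row
        else:
            raise ValueError(
                "input_reference must be 'average' or 'point:<label>', got "
                f"{self.input_reference!r}"
            )
        U, s, Vt = np.linalg.svd(L_ref, full_matrices=False)
        cutoff = self.pinv_rtol * (s[0] if s.size else 0.0)
        rank = int(np.sum(s > cutoff))
        if rank == 0:
            raise ValueError("lead field is rank deficient beyond the pinv tolerance")
        inv_s = np.zeros_like(s)
        inv_s[:rank] = 1.0 / s[:rank]
        pinv = (Vt.T * inv_s) @ U.T
        # expected rank: N-k minus one null direction per reference constraint
        expected = len(good) - 1
        if rank < expected:
            warnings.warn(
                f"reference-transformed lead field has effective rank {rank} "
                f"< {expected}; the source estimate may be unstable",
                stacklevel=2,
            )
        self.operator_ = L @ pinv
        self.pinv_ = pinv
        self.rank_ = rank
        self.good_idx_ = good
        self.bad_mask_ = bad
        self.labels_ = labels
        self.n_features_in_ = len(labels)
        return self

    def _reference_data(self, Xg: np.ndarray) -> np.ndarray:
        if self.input_reference == "average":
            return Xg - Xg.mean(axis=1, keepdims=True)
        ref_lbl = self.input_reference.split(":", 1)[1]
        good_labels = [self.labels_[i] for i in self.good_idx_]
        return Xg - Xg[:, [good_labels.index(ref_lbl)]]

    def transform(self, X) -> np.ndarray:
        """Reconstruct all channels from the good ones.

        ``X`` may carry all ``n_channels`` columns (bad columns ignored) or
        only the ``n_good`` good columns, shape ``(n_times, .)``.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_times, n_channels)")
        if X.shape[1] == self.n_features_in_:
            Xg = X[:, self.good_idx_]
        elif X.shape[1] == len(self.good_idx_):
            Xg = X
        else:
            raise ValueError(
                f"X has {X.shape[1]} channels, expected {self.n_features_in_} "
                f"or {len(self.good_idx_)}"
            )
        out = self._reference_data(Xg) @ self.operator_.T
        if self.output_reference == "average":
            out = out - out.mean(axis=1, keepdims=True)
        return out

    def estimate_sources(self, X) -> np.ndarray:
        """Equivalent-source moment time courses, shape (n_sources, n_times)."""
        X = np.asarray(X, dtype=float)
        Xg = X[:, self.good_idx_] if X.shape[1] == self.n_features_in_ else X
        return (self._reference_data(Xg) @ self.pinv_.T).T


# ---------------------------------------------------------------------------
# EEGRecording-level wrappers


def rereference(rec: EEGRecording, target: str) -> EEGRecording:
    """Re-reference a recording to the average or to a scalp point.

    The average is taken over the good channels (for a clean recording,
    over all channels); a point reference must name a good channel.
    """
    data = rec.data.copy()
    good = ~rec.bad_mask
    if target == "average":
        data -= data[good].mean(axis=0, keepdims=True)
    elif target.startswith("point:"):
        lbl = target.split(":", 1)[1]
        if lbl not in rec.labels:
            raise ValueError(f"reference channel {lbl!r} not in recording")
        i = rec.index(lbl)
        if rec.bad_mask[i]:
            raise ValueError(f"reference channel {lbl!r} is marked bad")
        data -= data[i]
        data[i] = 0.0
    else:
        raise ValueError(f"target must be 'average' or 'point:<label>', got {target!r}")
    return rec.copy(data=data, reference=target)


def ni_interpolate(rec: EEGRecording, montage: ElectrodeMontage,
                   m_neighbors: int = 4) -> EEGRecording:
    """Neighbor-average interpolation of the recording's bad channels."""
    est = NeighborInterpolator(
        montage=montage.subset(rec.labels), bad_channels=rec.bad_labels,
        n_neighbors=m_neighbors,
    ).fit()
    return rec.copy(data=est.transform(rec.data.T).T,
                    bad_mask=np.zeros(rec.n_channels, dtype=bool))


def ssi_build(montage: ElectrodeMontage, bad_channels, order_m: int = 4,
              n_legendre: int = 50) -> SplineSystem:
    """Build the spherical-spline kernel matrices for a montage/bad split.

    ``bad_channels`` may be a label list or a boolean mask over the montage.
    """
    if not isinstance(bad_channels, (list, tuple)):
        bad_channels = [montage.labels[i] for i in np.flatnonzero(np.asarray(bad_channels))]
    est = SphericalSplineInterpolator(
        montage=montage, bad_channels=list(bad_channels),
        order=order_m, n_legendre=n_legendre,
    ).fit()
    return est.spline_system_


def ssi_interpolate(rec: EEGRecording, montage: ElectrodeMontage,
                    order_m: int = 4, n_legendre: int = 50) -> EEGRecording:
    """Spherical-spline interpolation of the recording's bad channels."""
    est = SphericalSplineInterpolator(
        montage=montage.subset(rec.labels), bad_channels=rec.bad_labels,
        order=order_m, n_legendre=n_legendre,
    ).fit()
    return rec.copy(data=est.transform(rec.data.T).T,
                    bad_mask=np.zeros(rec.n_channels, dtype=bool))


def resit_interpolate(rec: EEGRecording, lf_full: LeadField,
                      pinv_rtol: float = 1e-8,
                      output_reference: str = "infinity") -> EEGRecording:
    """Equivalent-source (RESIT) interpolation of the recording's bad channels.

    The recording must declare an average or scalp-point reference; the
    output covers all channels with the reference standardized to infinity
    (or re-referenced to the all-channel average with
    ``output_reference="average"``).
    """
    if rec.reference == "infinity":
        raise ValueError(
            "input recording must declare an 'average' or 'point:<label>' reference"
        )
    if list(lf_full.montage_labels) != list(rec.labels):
        raise ValueError("lead field channels must match the recording channels")
    est = ResitInterpolator(
        leadfield=lf_full, bad_channels=rec.bad_labels,
        input_reference=rec.reference, output_reference=output_reference,
        pinv_rtol=pinv_rtol,
    ).fit()
    return rec.copy(data=est.transform(rec.data.T).T,
                    reference=output_reference,
                    bad_mask=np.zeros(rec.n_channels, dtype=bool))


def rest_standardize(rec: EEGRecording, lf_full: LeadField,
                     pinv_rtol: float = 1e-8) -> EEGRecording:
    """REST reference standardization (no bad channels): transform a
    referenced recording to the infinity reference via the equivalent-source
    model. This is the k = 0 case of :func:`resit_interpolate` and shares
    its pseudoinverse path exactly."""
    if rec.n_bad:
        raise ValueError("REST standardization expects a recording with no bad channels")
    return resit_interpolate(rec, lf_full, pinv_rtol=pinv_rtol)
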