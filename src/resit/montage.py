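"""Labeled electrode montages on the unit sphere.

Electrode positions are head-centered and normalized to unit length
(coordinates are dimensionless, expressed in units of the scalp radius).
Convention: right-handed axes with +z toward the vertex and +x toward the
nasion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeMontage", "read_montage", "write_montage"]

_UNIT_NORM_TOL = 1e-9


@dataclass
class ElectrodeMontage:
    """A set of uniquely labeled electrodes on the unit sphere.

    Parameters
    ----------
    labels : list of str
        Unique channel identifiers.
    positions : ndarray, shape (n_channels, 3)
        Unit-length position vectors, head-centered.
    """

    labels: list[str]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("number of labels does not match positions")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.n_channels < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms <= 0):
            raise ValueError("electrode positions must be nonzero")
        if np.any(np.abs(norms - 1.0) > _UNIT_NORM_TOL):
            raise ValueError(
                "electrode positions must be unit length; call "
                "ElectrodeMontage.from_positions to normalize raw coordinates"
            )

    @classmethod
    def from_positions(
        cls,
        labels: list[str],
        positions: np.ndarray,
        center: str = "none",
    ) -> "ElectrodeMontage":
        """Build a montage from raw coordinates, projecting onto the unit sphere.

        ``center='centroid'`` first subtracts the centroid of the cloud
        (for montages not already head-centered); the default assumes
        head-centered input.
        """
        pos = np.asarray(positions, dtype=float)
        if center == "centroid":
            pos = pos - pos.mean(axis=0)
        elif center != "none":
            raise ValueError(f"unknown centering mode {center!r}")
        norms = np.linalg.norm(pos, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot normalize a zero position vector")
        return cls(list(labels), pos / norms)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=int)

    def subset(self, labels) -> "ElectrodeMontage":
        idx = self.indices(labels)
        return ElectrodeMontage([self.labels[i] for i in idx], self.positions[idx])

    def angular_distances(self, other_positions: np.ndarray | None = None) -> np.ndarray:
        """Great-circle (angular) distances in radians.

        With no argument, returns the (N, N) matrix between montage
        electrodes; otherwise the (N, K) matrix to ``other_positions``
        (unit vectors).
        """
        q = self.positions if other_positions is None else np.atleast_2d(other_positions)
        cosang = np.clip(self.positions @ q.T, -1.0, 1.0)
        return np.arccos(cosang)

    def nearest(
        self, target: int | str, candidates: np.ndarray | None = None, k: int = 1
    ) -> list[int]:
        """Indices of the ``k`` candidates nearest to ``target`` by angle.

        Ties in angular distance are broken by lexicographic label order so
        neighbor selection is deterministic.
        """
        ti = self.index(target) if isinstance(target, str) else int(target)
        cand = (
            np.arange(self.n_channels)
            if candidates is None
            else np.asarray(candidates, dtype=int)
        )
        cand = cand[cand != ti]
        d = np.arccos(np.clip(self.positions[cand] @ self.positions[ti], -1.0, 1.0))
        order = sorted(range(len(cand)), key=lambda i: (d[i], self.labels[cand[i]]))
        return [int(cand[i]) for i in order[:k]]


def read_montage(path) -> ElectrodeMontage:
    """Read an sfp-like plain-text montage: one ``label x y z`` per line.

    Blank lines and ``#`` comments are skipped; extra whitespace is
    tolerated. Positions are projected onto the unit sphere.
    """
    labels, rows = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 'label x y z', got {raw.rstrip()!r}"
                )
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad coordinate: {err}") from None
    return ElectrodeMontage.from_positions(labels, np.array(rows, dtype=float))


def write_montage(montage: ElectrodeMontage, path) -> None:
    """Write a montage in the sfp-like dialect with 9 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# label x y z (unit-sphere coordinates, +x nasion, +z vertex)\n")
        for label, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{label} {x:.9g} {y:.9g} {z:.9g}\n")
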