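"""In-memory EEG recordings and their plain-text / binary I/O.

An :class:`EEGRecording` is a channels x time matrix of scalp potentials in
microvolts, with channel labels, a sampling rate, a declared reference
("infinity", "average", or "point:<label>"), and a boolean bad-channel mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "read_data_text",
    "write_data_text",
    "read_recording",
    "write_recording",
]

_AVG_TOL = 1e-6


def _check_reference(reference: str) -> str:
    if reference in ("infinity", "average") or reference.startswith("point:"):
        return reference
    raise ValueError(
        f"reference must be 'infinity', 'average' or 'point:<label>', got {reference!r}"
    )


@dataclass
class EEGRecording:
    """Multichannel EEG data with reference and bad-channel bookkeeping.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_times)
        Potentials in microvolts.
    labels : list of str
        Channel labels, matching ``data`` rows.
    sfreq : float
        Sampling rate in Hz.
    reference : str
        ``"infinity"``, ``"average"`` or ``"point:<label>"``.
    bad_mask : ndarray of bool, optional
        True for corrupted channels. Defaults to all good.
    """

    data: np.ndarray = field(repr=False)
    labels: list[str]
    sfreq: float
    reference: str = "average"
    bad_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x time)")
        self.labels = [str(l) for l in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("number of labels does not match data rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        self.reference = _check_reference(self.reference)
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.n_channels, dtype=bool)
        else:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
            if self.bad_mask.shape != (self.n_channels,):
                raise ValueError("bad_mask must have one entry per channel")
        if int(self.bad_mask.sum()) >= self.n_channels:
            raise ValueError("at least one channel must be good")
        if self.reference.startswith("point:"):
            lbl = self.point_label
            if lbl not in self.labels:
                raise ValueError(f"point reference {lbl!r} not among channels")

    def check_average_reference(self, tol: float = _AVG_TOL) -> bool:
        """True if the good-channel means vanish at every time point.

        The reference field is declarative metadata; this checks the
        numeric zero-mean property that :func:`~resit.interpolation.rereference`
        produces, within ``tol`` times the RMS amplitude.
        """
        good = self.data[~self.bad_mask]
        rms = float(np.sqrt(np.mean(good**2)))
        return bool(np.max(np.abs(good.mean(axis=0))) <= tol * max(rms, 1e-30))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_bad(self) -> int:
        return int(self.bad_mask.sum())

    @property
    def point_label(self) -> str | None:
        if self.reference.startswith("point:"):
            return self.reference.split(":", 1)[1]
        return None

    @property
    def good_labels(self) -> list[str]:
        return [l for l, b in zip(self.labels, self.bad_mask) if not b]

    @property
    def bad_labels(self) -> list[str]:
        return [l for l, b in zip(self.labels, self.bad_mask) if b]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self, **overrides) -> "EEGRecording":
        kw = dict(
            data=self.data.copy(),
            labels=list(self.labels),
            sfreq=self.sfreq,
            reference=self.reference,
            bad_mask=self.bad_mask.copy(),
        )
        kw.update(overrides)
        return EEGRecording(**kw)

    def mark_bad(self, labels) -> "EEGRecording":
        """Return a copy with the given channels flagged bad."""
        mask = self.bad_mask.copy()
        for l in labels:
            mask[self.index(l)] = True
        return self.copy(bad_mask=mask)


def write_data_text(rec: EEGRecording, path, sep: str = "\t") -> None:
    """Write channels x time data as delimited text with a label header row."""
    df = pd.DataFrame(rec.data.T, columns=rec.labels)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_data_text(
    path,
    sfreq: float,
    reference: str = "average",
    bad_labels=(),
    sep: str = "\t",
) -> EEGRecording:
    """Read delimited text written by :func:`write_data_text`.

    The file stores one column per channel (header row of labels), one row
    per time point; ``sfreq`` and the reference are supplied by the caller
    since plain text carries no metadata.
    """
    df = pd.read_csv(path, sep=sep)
    labels = [str(c) for c in df.columns]
    unknown = [b for b in bad_labels if b not in labels]
    if unknown:
        raise ValueError(f"bad channels {unknown} not among the file's columns")
    mask = np.array([l in set(bad_labels) for l in labels])
    return EEGRecording(df.to_numpy().T, labels, sfreq, reference, mask)


def write_recording(rec: EEGRecording, path) -> None:
    """Write a recording to an HDF5 container, bitwise round-trippable."""
    with h5py.File(path, "w", track_order=True) as f:
        d = f.create_dataset("data", data=rec.data, track_times=False)
        f.create_dataset(
            "labels",
            data=np.array(rec.labels, dtype=h5py.string_dtype()),
            track_times=False,
        )
        f.create_dataset("bad_mask", data=rec.bad_mask, track_times=False)
        d.attrs["sfreq"] = rec.sfreq
        d.attrs["reference"] = rec.reference


def read_recording(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return EEGRecording(
            data=d[()],
            labels=[l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]],
            sfreq=float(d.attrs["sfreq"]),
            reference=str(d.attrs["reference"]),
            bad_mask=f["bad_mask"][()],
        )
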