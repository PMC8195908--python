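"""Interpolation assessment: inject bad channels, interpolate, score.

The protocol mirrors standard bad-channel benchmarking on clean data:
channels are declared bad at a given fraction of the montage — either
scattered (uniform draws) or as one spatially adjacent patch — each
method reconstructs them, and the reconstruction is scored against the
held-out truth by mean absolute error, relative absolute error and mean
per-channel Pearson correlation, averaged over repeats.

The equivalent-source method's output is re-referenced to the average
before scoring so all methods are compared in the same reference frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward_model import LeadField
from .interpolation import ni_interpolate, rereference, resit_interpolate, ssi_interpolate
from .montage import ElectrodeMontage
from .recording import EEGRecording

__all__ = [
    "AssessmentConfig",
    "AssessmentResult",
    "select_bad_channels",
    "interp_metrics",
    "run_assessment",
]

DEFAULT_FRACTIONS = (0.02, 0.1, 0.25, 0.5, 0.85)
_METHODS = ("resit", "ssi", "ni")


@dataclass
class AssessmentConfig:
    """Configuration of one assessment sweep.

    ``fractions`` are bad-channel fractions in (0, 1) (the benchmark range
    spans 2%-85%); ``case`` selects scattered draws or one adjacent patch;
    each (fraction, repeat) cell draws a fresh bad set.
    """

    fractions: tuple = DEFAULT_FRACTIONS
    case: str = "scattered"
    n_repeats: int = 20
    methods: tuple = _METHODS
    seed: int = 0
    n_neighbors: int = 4
    pinv_rtol: float = 1e-8

    def __post_init__(self) -> None:
        self.fractions = tuple(float(f) for f in self.fractions)
        if not self.fractions or not all(0.0 < f < 1.0 for f in self.fractions):
            raise ValueError("fractions must be strictly inside (0, 1)")
        if self.case not in ("scattered", "adjacent"):
            raise ValueError("case must be 'scattered' or 'adjacent'")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        self.methods = tuple(self.methods)
        unknown = set(self.methods) - set(_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; choose from {_METHODS}")


@dataclass
class AssessmentResult:
    """Tidy per-cell assessment table plus aggregation helpers.

    ``table`` has one row per (method, fraction, repeat) with columns
    ``mae`` (microvolts), ``rae`` (dimensionless), ``r`` (mean Pearson
    correlation) and ``error`` (failure message, empty on success).
    """

    table: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Across-repeat mean and standard error per (method, case, fraction)."""
        def sem(x):
            x = x.dropna()
            return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

        g = self.table.groupby(["method", "case", "fraction"])[["mae", "rae", "r"]]
        out = g.agg(["mean", sem])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()


def select_bad_channels(
    montage: ElectrodeMontage,
    fraction: float,
    case: str,
    rng: np.random.Generator,
) -> list[str]:
    """Draw a bad-channel label set at the given fraction of the montage.

    ``scattered``: k channels uniformly without replacement. ``adjacent``:
    a uniformly drawn seed channel grown by repeatedly adding the channel
    nearest (smallest angle to any current member) until size k
    (single-linkage growth; ties broken by label). k = round(fraction * N)
    is clamped below to 1; a fraction leaving fewer than 3 good channels
    is rejected.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = montage.n_channels
    k = int(np.rint(fraction * n))
    k = max(k, 1)
    if k > n - 3:
        raise ValueError(
            f"fraction {fraction} gives k = {k} bad channels, leaving fewer than "
            f"3 of {n} good channels to interpolate from"
        )
    if case == "scattered":
        idx = rng.choice(n, size=k, replace=False)
        return [montage.labels[i] for i in idx]
    if case != "adjacent":
        raise ValueError("case must be 'scattered' or 'adjacent'")
    members = [int(rng.integers(n))]
    ang = montage.angular_distances()
    while len(members) < k:
        outside = [i for i in range(n) if i not in members]
        d_to_set = [(min(ang[i, m] for m in members), montage.labels[i], i) for i in outside]
        members.append(min(d_to_set)[2])
    return [montage.labels[i] for i in members]


def interp_metrics(
    truth: EEGRecording,
    estimate: EEGRecording,
    bad_set,
) -> tuple[float, float, float]:
    """Score an interpolated recording against the truth on the bad channels.

    Returns ``(mean_abs_error, rel_abs_error, mean_r)``: the mean over bad
    channels and time of the absolute error; the summed absolute error
    over the summed absolute truth (scale-free); and the mean over bad
    channels of the per-channel Pearson correlation across time.
    Zero-variance true channels are excluded from the correlation mean
    with a warning.
    """
    bad_set = list(bad_set)
    if not bad_set:
        raise ValueError("bad_set must be non-empty")
    if truth.labels != estimate.labels:
        raise ValueError("truth and estimate must share channel labels")
    if truth.sfreq != estimate.sfreq:
        raise ValueError("truth and estimate must share the sampling rate")
    if truth.reference != estimate.reference:
        raise ValueError(
            f"reference mismatch: truth {truth.reference!r} vs estimate "
            f"{estimate.reference!r}; compare in a common reference"
        )
    idx = [truth.index(l) for l in bad_set]
    t = truth.data[idx]
    e = estimate.data[idx]
    err = np.abs(e - t)
    mae = float(err.mean())
    denom = float(np.abs(t).sum())
    rae = float(err.sum() / denom) if denom > 0 else np.inf
    rs = []
    for row_t, row_e, lbl in zip(t, e, bad_set):
        st, se = row_t.std(), row_e.std()
        if st == 0.0:
            warnings.warn(
                f"channel {lbl!r} has zero variance in the truth; excluded from mean_r",
                stacklevel=2,
            )
            continue
        if se == 0.0:
            rs.append(0.0)
            continue
        rs.append(float(np.corrcoef(row_t, row_e)[0, 1]))
    mean_r = float(np.mean(rs)) if rs else float("nan")
    return mae, rae, mean_r


def _run_method(
    method: str,
    rec_bad: EEGRecording,
    montage: ElectrodeMontage,
    lf_full: LeadField | None,
    config: AssessmentConfig,
) -> EEGRecording:
    if method == "ni":
        return ni_interpolate(rec_bad, montage, m_neighbors=config.n_neighbors)
    if method == "ssi":
        return ssi_interpolate(rec_bad, montage)
    if method == "resit":
        if lf_full is None:
            raise ValueError("the equivalent-source method requires a lead field")
        est = resit_interpolate(rec_bad, lf_full, pinv_rtol=config.pinv_rtol)
        return rereference(est, "average")
    raise ValueError(f"unknown method {method!r}")


def run_assessment(
    rec: EEGRecording,
    montage: ElectrodeMontage,
    lf_full: LeadField | None,
    config: AssessmentConfig,
) -> AssessmentResult:
    """Run the bad-channel injection benchmark on a clean recording.

    ``rec`` must be clean (no bad channels) and average-referenced; it is
    the ground truth. For each (fraction, repeat) a bad set is drawn with
    ``numpy.random.default_rng(SeedSequence((seed, fraction_index,
    repeat)))`` — reproducible and identical across method subsets and
    cases (paired draws in the scattered case). Method failures are
    recorded in the ``error`` column of the result rather than raised.
    """
    if rec.n_bad:
        raise ValueError("the assessment needs a clean recording (empty bad mask)")
    if rec.reference != "average":
        raise ValueError("the assessment protocol expects average-referenced truth")
    rows = []
    for fi, fraction in enumerate(config.fractions):
        for rep in range(config.n_repeats):
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, fi, rep)))
            bads = select_bad_channels(montage, fraction, config.case, rng)
            rec_bad = rec.mark_bad(bads)
            for method in config.methods:
                row = {
                    "method": method,
                    "case": config.case,
                    "fraction": fraction,
                    "repeat": rep,
                    "k": len(bads),
                    "mae": np.nan,
                    "rae": np.nan,
                    "r": np.nan,
                    "error": "",
                }
                try:
                    est = _run_method(method, rec_bad, montage, lf_full, config)
                    row["mae"], row["rae"], row["r"] = interp_metrics(rec, est, bads)
                except (ValueError, np.linalg.LinAlgError) as err:
                    row["error"] = str(err)
                rows.append(row)
    return AssessmentResult(pd.DataFrame(rows))
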