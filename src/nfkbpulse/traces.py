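"""Single-cell trace analytics.

Works on either model :class:`~nfkbpulse.model.Trajectory` objects or
measured-style :class:`TraceTable` data (total-IκBα reporter intensity and
nuclear/total NF-κB ratio per cell).  Implements the two responder rules
(model rule: net nuclear NF-κB translocation >15 % of total; experimental
rule: non-positive IκBα gradient at stimulation), response fractions, the
refractory-period distribution, amplitude ratios, AUC, trough timing,
power-spectrum periods, responder clustering, sub-trajectory PCA and
daughter-pair concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import detrend, find_peaks
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .model import Trajectory

__all__ = [
    "TraceTable", "ResponseTable", "RefractoryDistribution",
    "classify_responder_model", "classify_responder_trace",
    "fraction_responding", "refractory_distribution", "amplitude_ratio",
    "auc_nuclear", "peak_to_peak", "dominant_period", "cluster_responders",
    "pca_subtrajectories", "pair_concordance", "classify_responder_nt",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TraceTable:
    """Per-cell reporter traces on a common (near-)uniform time grid.

    ``ikba`` holds total IκBα reporter intensity (normalized to t=0 on
    load), ``nt_ratio`` the nuclear/total NF-κB reporter ratio in [0, 1].
    """

    time: np.ndarray                      # (n_t,) minutes
    ikba: pd.DataFrame                    # (n_t, n_cells)
    nt_ratio: pd.DataFrame | None = None  # (n_t, n_cells)
    lineage: pd.DataFrame | None = None   # columns: cell_id, mother_id, division_time

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.ikba):
            raise ValueError("time grid must match trace length")
        dt = np.diff(self.time)
        if len(dt) and (dt.min() <= 0 or dt.max() > 2.0 * dt.min()):
            raise ValueError("time grid must be increasing and near-uniform")
        if self.nt_ratio is not None:
            r = self.nt_ratio.to_numpy()
            if np.nanmin(r) < -1e-9 or np.nanmax(r) > 1 + 1e-9:
                raise ValueError("N/T ratio must lie in [0, 1]")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ikba.columns)

    @property
    def n_cells(self) -> int:
        return self.ikba.shape[1]

    def normalized(self) -> "TraceTable":
        """IκBα intensity normalized to its value at t = 0 per cell."""
        first = self.ikba.iloc[0]
        if (first <= 0).any():
            raise ValueError("cannot normalize: zero intensity at t=0")
        return TraceTable(self.time, self.ikba / first, self.nt_ratio, self.lineage)

    # -- I/O: long-format delimited text ---------------------------------
    def to_long(self) -> pd.DataFrame:
        rows = []
        for cid in self.cell_ids:
            df = pd.DataFrame({"cell_id": cid, "time_min": self.time,
                               "ikba_total": self.ikba[cid].to_numpy()})
            if self.nt_ratio is not None:
                df["nfkb_nt"] = self.nt_ratio[cid].to_numpy()
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def save(self, path: str | Path, sep: str = "\t") -> None:
        self.to_long().to_csv(path, sep=sep, index=False)

    @classmethod
    def load(cls, path: str | Path, sep: str = "\t", normalize: bool = True,
             ) -> "TraceTable":
        long = pd.read_csv(path, sep=sep)
        ikba = long.pivot(index="time_min", columns="cell_id", values="ikba_total")
        nt = None
        if "nfkb_nt" in long.columns:
            nt = long.pivot(index="time_min", columns="cell_id", values="nfkb_nt")
        tbl = cls(ikba.index.to_numpy(), ikba.reset_index(drop=True),
                  None if nt is None else nt.reset_index(drop=True))
        return tbl.normalized() if normalize else tbl

    @classmethod
    def from_trajectories(cls, trajs: Sequence[Trajectory], normalize: bool = True,
                          ) -> "TraceTable":
        t = trajs[0].t
        ikba = pd.DataFrame({tr.cell_id: tr.total_ikba for tr in trajs})
        nt = pd.DataFrame({tr.cell_id: tr.nfkb_nuclear_fraction for tr in trajs})
        tbl = cls(t, ikba, nt)
        return tbl.normalized() if normalize else tbl


@dataclass
class ResponseTable:
    """Per cell × pulse responder calls, net amplitudes and peak times."""
    table: pd.DataFrame   # columns: cell_id, pulse, responder, amplitude, peak_time

    @classmethod
    def from_calls(cls, records: Iterable[tuple[str, int, bool, float, float]],
                   ) -> "ResponseTable":
        df = pd.DataFrame(records, columns=["cell_id", "pulse", "responder",
                                            "amplitude", "peak_time"])
        return cls(df)

    def fraction(self, pulse: int) -> tuple[float, int]:
        return fraction_responding(self, pulse)


@dataclass
class RefractoryDistribution:
    """Probability mass of the refractory period over interval bins."""
    bin_edges: np.ndarray      # (n_bins+1,) minutes, interior edges = intervals
    mass: np.ndarray           # (n_bins,)   includes open tails at both ends
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.mass < -1e-12):
            raise ValueError("masses must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.mass, index=self.labels)


# ---------------------------------------------------------------------------
# responder classification


def classify_responder_model(traj: Trajectory, pulse_time: float,
                             window: float = 45.0, threshold: float = 0.15,
                             ) -> tuple[bool, float]:
    """Model responder rule: net peak nuclear NF-κB after the pulse,
    relative to the level at stimulation, strictly above ``threshold`` of
    the cell's total NF-κB."""
    nf = traj.nfkb_nuclear_fraction
    i0 = int(np.argmin(np.abs(traj.t - pulse_time)))
    if traj.t[-1] + 1e-9 < pulse_time + window:
        raise ValueError("trajectory does not cover the response window")
    i1 = int(np.argmin(np.abs(traj.t - (pulse_time + window))))
    net = float(nf[i0:i1 + 1].max() - nf[i0])
    return net > threshold, net


def classify_responder_trace(trace: TraceTable, pulse_time: float,
                             cell_id: str | None = None, lag: float = 5.0,
                             window: float = 20.0) -> bool | pd.Series:
    """Experimental responder rule: the least-squares slope of total IκBα
    over [pulse+lag, pulse+lag+window] is non-positive (degradation).

    Returns one bool when ``cell_id`` is given, else a per-cell Series.
    """
    t0, t1 = pulse_time + lag, pulse_time + lag + window
    sel = (trace.time >= t0 - 1e-9) & (trace.time <= t1 + 1e-9)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 samples in the gradient window")
    tt = trace.time[sel]
    def slope(col: np.ndarray) -> float:
        return float(np.polyfit(tt, col[sel], 1)[0])
    cols = [cell_id] if cell_id is not None else trace.cell_ids
    calls = pd.Series({c: slope(trace.ikba[c].to_numpy()) <= 0.0 for c in cols})
    return bool(calls.iloc[0]) if cell_id is not None else calls


def classify_responder_nt(trace: TraceTable, pulse_time: float,
                          window: float = 45.0, threshold: float = 0.15,
                          ) -> pd.Series:
    """Net-translocation responder rule applied to measured N/T traces.

    Same rule as :func:`classify_responder_model` but on the nuclear/total
    reporter ratio of a :class:`TraceTable` (the ratio is proportional to
    the nuclear fraction, so the 15 %-of-total cut carries over)."""
    if trace.nt_ratio is None:
        raise ValueError("trace table has no N/T ratio channel")
    t = trace.time
    i0 = int(np.argmin(np.abs(t - pulse_time)))
    i1 = int(np.argmin(np.abs(t - (pulse_time + window))))
    if t[-1] + 1e-9 < pulse_time + window or i1 <= i0:
        raise ValueError("trace does not cover the response window")
    nt = trace.nt_ratio
    net = nt.iloc[i0:i1 + 1].max(axis=0) - nt.iloc[i0]
    return net > threshold


def fraction_responding(responses: ResponseTable, pulse: int) -> tuple[float, int]:
    sub = responses.table[responses.table["pulse"] == pulse]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no calls for pulse {pulse}")
    return float(sub["responder"].mean()), n


# ---------------------------------------------------------------------------
# refractory-period distribution


def refractory_distribution(fractions: Mapping[float, float],
                            ) -> RefractoryDistribution:
    """Successive-difference estimator of the refractory-period distribution.

    A cell responding at interval Δ₂ but not Δ₁ < Δ₂ has its refractory
    period in [Δ₁, Δ₂); the mass of that bin is f(Δ₂) − f(Δ₁).  The mass
    below the smallest probed interval is f(Δ_min) and the mass at or above
    the largest is 1 − f(Δ_max).  Negative increments (sampling noise) are
    clipped to zero and the distribution renormalized, with a warning.
    """
    deltas = sorted(fractions)
    f = np.array([fractions[d] for d in deltas], dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must be in [0, 1]")
    mass = np.concatenate([[f[0]], np.diff(f), [1.0 - f[-1]]])
    if np.any(mass < 0):
        warnings.warn("non-monotone fractions: negative increments clipped and "
                      "distribution renormalized", stacklevel=2)
        mass = np.clip(mass, 0.0, None)
        mass = mass / mass.sum()
    edges = np.array([0.0] + deltas + [np.inf])
    labels = ([f"<{deltas[0]:g}"]
              + [f"[{a:g},{b:g})" for a, b in zip(deltas, deltas[1:])]
              + [f">={deltas[-1]:g}"])
    return RefractoryDistribution(edges, mass, labels)


# ---------------------------------------------------------------------------
# amplitudes, AUC, periods


def _nt_series(obj, cell_id: str | None):
    if isinstance(obj, Trajectory):
        return obj.t, obj.nfkb_nuclear_fraction
    if cell_id is None:
        raise ValueError("cell_id required for TraceTable input")
    return obj.time, obj.nt_ratio[cell_id].to_numpy()


def amplitude_ratio(obj, pulse_times: Sequence[float], cell_id: str | None = None,
                    window: float = 45.0) -> float:
    """Second-peak / first-peak nuclear NF-κB amplitude, each baseline
    subtracted at its own pulse time."""
    t, nt = _nt_series(obj, cell_id)
    amps = []
    for pt in pulse_times[:2]:
        i0 = int(np.argmin(np.abs(t - pt)))
        i1 = int(np.argmin(np.abs(t - (pt + window))))
        amps.append(float(nt[i0:i1 + 1].max() - nt[i0]))
    if amps[0] <= 0:
        raise ValueError("first-pulse amplitude is zero")
    return amps[1] / amps[0]


def auc_nuclear(obj, t_range: tuple[float, float] | None = None,
                cell_id: str | None = None) -> float:
    """Area under the baseline-corrected, first-peak-normalized N/T curve.

    Baseline is the value at the start of ``t_range``; normalization divides
    by the first (baseline-corrected) peak amplitude in the range.
    """
    t, nt = _nt_series(obj, cell_id)
    if t_range is not None:
        sel = (t >= t_range[0] - 1e-9) & (t <= t_range[1] + 1e-9)
        t, nt = t[sel], nt[sel]
    y = nt - nt[0]
    if np.allclose(y, 0.0):
        return 0.0
    peaks, _ = find_peaks(y)
    first_peak = y[peaks[0]] if len(peaks) else y.max()
    if first_peak <= 0:
        raise ValueError("degenerate first peak")
    return float(np.trapezoid(np.clip(y, 0.0, None) / first_peak, t))


def peak_to_peak(trace, cell_id: str | None = None,
                 prominence_frac: float = 0.05, min_separation: float = 40.0,
                 t_min: float = 0.0) -> np.ndarray:
    """Spacings between consecutive troughs of the total-IκBα signal.

    Troughs are local minima with prominence at least ``prominence_frac`` of
    the trace range, separated by at least ``min_separation`` minutes.
    ``t_min`` discards the early synchronous-degradation phase (the same
    cut used for the power spectrum) so the stimulation transient does not
    enter the spacing statistics.  Returns an empty array when fewer than
    two troughs are found.
    """
    if isinstance(trace, Trajectory):
        t, y = trace.t, trace.total_ikba
    else:
        if cell_id is None:
            raise ValueError("cell_id required for TraceTable input")
        t, y = trace.time, trace.ikba[cell_id].to_numpy()
    if t_min > 0:
        sel = t > t_min
        t, y = t[sel], np.asarray(y)[sel]
    dt = float(np.median(np.diff(t)))
    rng = float(y.max() - y.min())
    if rng <= 0:
        return np.array([])
    idx, _ = find_peaks(-y, prominence=prominence_frac * rng,
                        distance=max(1, int(round(min_separation / dt))))
    if len(idx) < 2:
        return np.array([])
    return np.diff(t[idx])


def dominant_period(trace, cell_id: str | None = None, t_min: float = 35.0,
                    band: tuple[float, float] = (40.0, 300.0),
                    pad_factor: int = 4) -> float:
    """Dominant oscillation period from the discrete-Fourier power spectrum.

    Early samples (t ≤ ``t_min``, the synchronous degradation phase) are
    discarded; the remainder is mean-removed and linearly detrended, the
    FFT zero-padded ``pad_factor``-fold, and the period of maximal power
    within ``band`` minutes returned.
    """
    if isinstance(trace, Trajectory):
        t, y = trace.t, trace.total_ikba
    else:
        if cell_id is None:
            raise ValueError("cell_id required for TraceTable input")
        t, y = trace.time, trace.ikba[cell_id].to_numpy()
    sel = t > t_min
    t, y = t[sel], np.asarray(y, dtype=float)[sel]
    if len(y) < 4:
        raise ValueError("trace too short after truncation")
    if np.allclose(y, y[0]):
        raise ValueError("constant trace has no dominant period")
    y = detrend(y)
    dt = float(np.median(np.diff(t)))
    n = pad_factor * len(y)
    power = np.abs(np.fft.rfft(y, n=n)) ** 2
    freq = np.fft.rfftfreq(n, d=dt)
    with np.errstate(divide="ignore"):
        period = np.where(freq > 0, 1.0 / freq, np.inf)
    ok = (period >= band[0]) & (period <= band[1])
    if not ok.any():
        raise ValueError("no spectral support inside the period band")
    return float(period[ok][np.argmax(power[ok])])


# ---------------------------------------------------------------------------
# clustering / PCA / concordance


def cluster_responders(trace: TraceTable, pulse_time: float,
                       window: float = 40.0, seed: int = 0) -> pd.Series:
    """Two-means clustering of normalized IκBα over the post-pulse window.

    Cells whose IκBα dips (degradation) form the responding cluster; label
    mapping is fixed by the cluster-mean dip depth (deeper = responding,
    label True).
    """
    if trace.n_cells < 2:
        raise ValueError("clustering needs at least 2 cells")
    sel = (trace.time >= pulse_time - 1e-9) & (trace.time <= pulse_time + window + 1e-9)
    X = trace.ikba.loc[sel].to_numpy().T            # cells × time
    X = X / X[:, [0]]                               # renormalize at the pulse
    if np.allclose(X, X[0]):
        warnings.warn("identical traces: single cluster", stacklevel=2)
        return pd.Series(False, index=trace.cell_ids)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(X)
    dips = [X[km.labels_ == k].min(axis=1).mean() for k in (0, 1)]
    responding_label = int(np.argmin(dips))
    return pd.Series(km.labels_ == responding_label, index=trace.cell_ids)


def pca_subtrajectories(trace: TraceTable,
                        windows: Sequence[tuple[float, float]],
                        n_components: int = 2) -> pd.DataFrame:
    """Project per-cell sub-trajectories from each window onto shared
    principal axes.

    Each sub-trajectory is z-scored per feature across the pooled set; rows
    of the result are (cell, window) pairs with the embedding coordinates.
    """
    segs, keys = [], []
    npts = None
    for w, (a, b) in enumerate(windows):
        sel = (trace.time >= a - 1e-9) & (trace.time <= b + 1e-9)
        if not sel.any():
            raise ValueError(f"window {(a, b)} outside trace")
        X = trace.ikba.loc[sel].to_numpy().T
        npts = X.shape[1] if npts is None else min(npts, X.shape[1])
        segs.append(X)
        keys.extend([(cid, w) for cid in trace.cell_ids])
    pooled = np.vstack([s[:, :npts] for s in segs])
    sd = pooled.std(axis=0)
    if np.any(sd == 0) and np.all(sd == 0):
        raise ValueError("rank-deficient pooled matrix")
    Z = (pooled - pooled.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, random_state=0)
    Y = pca.fit_transform(Z)
    idx = pd.MultiIndex.from_tuples(keys, names=["cell_id", "window"])
    cols = [f"pc{i+1}" for i in range(n_components)]
    out = pd.DataFrame(Y, index=idx, columns=cols)
    out.attrs["explained_variance"] = pca.explained_variance_.tolist()
    return out


def pair_concordance(responses: ResponseTable,
                     pairs: Sequence[tuple[str, str]], pulse: int) -> float:
    """Fraction of (daughter) pairs with identical responder calls."""
    sub = responses.table[responses.table["pulse"] == pulse]
    calls = dict(zip(sub["cell_id"], sub["responder"]))
    same = []
    for a, b in pairs:
        if a not in calls or b not in calls:
            raise ValueError(f"unmatched cell id in pair ({a}, {b})")
        same.append(calls[a] == calls[b])
    return float(np.mean(same))
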