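"""Sarcomere-nuclear strain-coupling assay.

Turns raw sarcomere-length and nuclear-dimension recordings from paced
cardiomyocytes (1-Hz field stimulation) into beat-averaged strain
transients, strain-strain coupling maps, systolic/diastolic dampening
areas and integrated nuclear strain.

Conventions
-----------
Strains are stored signed, with compression negative; coupling maps and
dampening areas work with compression magnitudes |eps|, matching the
positive "compression" axes used when reporting the assay.  The nuclear
channel is imaged at 91 Hz, and the sarcomere channel is interpolated to
the same grid before pairing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

NUCLEAR_RATE_HZ = 91.0          # fast-confocal frame rate, 11 ms/frame
BASELINE_WINDOW_S = 0.2         # pre-stimulus window used for L0
QC_MIN_BASELINE_UM = 1.7        # resting sarcomere length inclusion gate
QC_MIN_PEAK_STRAIN = 0.10       # peak sarcomere strain inclusion gate

CHANNELS = ("sarcomere_length", "nuclear_length", "nuclear_width")


class TraceValidationError(ValueError):
    """Raised when a trace violates its structural invariants."""


@dataclass
class RawTrace:
    """A single-channel length recording with stimulation timestamps.

    ``time`` is a uniform grid in seconds; ``value`` the length in µm;
    ``stim_times`` the electrical stimulation onsets.
    """
    time: np.ndarray
    value: np.ndarray
    sampling_rate: float
    stim_times: np.ndarray
    channel: str

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.stim_times = np.asarray(self.stim_times, dtype=float)
        if self.channel not in CHANNELS:
            raise TraceValidationError(f"unknown channel {self.channel!r}")
        if self.sampling_rate <= 0:
            raise TraceValidationError("sampling_rate must be positive")
        if self.time.ndim != 1 or len(self.time) != len(self.value):
            raise TraceValidationError("time and value must align")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise TraceValidationError("time must be strictly increasing")
        if not np.all(np.isfinite(self.value)) or np.any(self.value <= 0):
            raise TraceValidationError("lengths must be finite and positive")
        if len(self.stim_times) and (
                self.stim_times.min() < self.time[0] - 1e-9
                or self.stim_times.max() > self.time[-1] + 1e-9):
            raise TraceValidationError("stim_times outside recording")


@dataclass
class PairedStrainSeries:
    """Beat-averaged sarcomere and nuclear strains on a common 91-Hz grid."""
    t: np.ndarray
    eps_s: np.ndarray
    eps_nL: np.ndarray
    eps_nW: np.ndarray
    L0_s: float
    L0_nL: float
    L0_nW: float

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.eps_s) == len(self.eps_nL) == len(self.eps_nW) == n):
            raise TraceValidationError("strain series must share the grid")
        if min(self.L0_s, self.L0_nL, self.L0_nW) <= 0:
            raise TraceValidationError("baselines must be positive")


@dataclass
class CouplingCurve:
    """Ordered (|eps_s|, |eps_n|) trajectory split at peak systole."""
    eps_s: np.ndarray           # compression magnitudes, time-ordered
    eps_n: np.ndarray
    peak_index: int

    @property
    def systolic(self):
        return self.eps_s[: self.peak_index + 1], \
            self.eps_n[: self.peak_index + 1]

    @property
    def diastolic(self):
        return self.eps_s[self.peak_index:], self.eps_n[self.peak_index:]

    @property
    def phase(self) -> np.ndarray:
        p = np.full(len(self.eps_s), "diastolic", dtype=object)
        p[: self.peak_index + 1] = "systolic"
        return p


@dataclass
class CouplingMetrics:
    D_sys: float                # systolic dampening area, strain^2
    D_dia: float                # diastolic dampening area, strain^2
    S_int: float                # integrated |nuclear strain|, strain*s
    peak_eps_s: float           # peak sarcomere compression magnitude
    peak_eps_nL: float
    peak_eps_nW: float


def qc_filter(baseline_sarcomere_length_um: float,
              peak_sarcomere_strain: float) -> tuple[bool, str]:
    """Cell inclusion gate: resting sarcomere length > 1.7 µm and peak
    sarcomere strain magnitude > 10%.

    Returns (include, reason); ``reason`` names the failing criteria
    ("baseline", "strain", or "baseline+strain"), empty when included.
    """
    if not (np.isfinite(baseline_sarcomere_length_um)
            and np.isfinite(peak_sarcomere_strain)):
        raise TraceValidationError("QC inputs must be finite")
    failures = []
    if not baseline_sarcomere_length_um > QC_MIN_BASELINE_UM:
        failures.append("baseline")
    if not abs(peak_sarcomere_strain) > QC_MIN_PEAK_STRAIN:
        failures.append("strain")
    return (len(failures) == 0, "+".join(failures))


def beat_average(trace: RawTrace, n_beats: int,
                 spacing_tol: float = 0.05) -> RawTrace:
    """Average ``n_beats`` stimulus-anchored cycles into a single beat.

    Each window starts at a stimulation time and spans the median
    inter-stimulus interval; the beats are averaged pointwise.  Stimulus
    spacing deviating from the median by more than ``spacing_tol``
    (relative) raises an error naming the offending beat.
    """
    stim = trace.stim_times
    if len(stim) < n_beats:
        raise TraceValidationError(
            f"{n_beats} beats requested but only {len(stim)} stimuli")
    if n_beats < 1:
        raise TraceValidationError("n_beats must be >= 1")
    stim = stim[:n_beats]
    if len(trace.stim_times) > 1:
        intervals = np.diff(trace.stim_times)
        period = float(np.median(intervals))
        bad = np.where(np.abs(intervals - period) > spacing_tol * period)[0]
        if len(bad):
            raise TraceValidationError(
                f"irregular stimulus spacing at beat {bad[0] + 1}")
    else:
        period = float(trace.time[-1] - stim[0])
    n_samp = int(round(period * trace.sampling_rate))
    rel_t = np.arange(n_samp) / trace.sampling_rate
    beats = np.stack([
        np.interp(s + rel_t, trace.time, trace.value) for s in stim])
    return RawTrace(time=rel_t, value=beats.mean(axis=0),
                    sampling_rate=trace.sampling_rate,
                    stim_times=np.array([0.0]), channel=trace.channel)


def resample_to(trace: RawTrace,
                target_rate: float = NUCLEAR_RATE_HZ) -> RawTrace:
    """Linear interpolation onto a uniform grid at ``target_rate``.

    The grid spans the original interval with both endpoints preserved;
    the actual rate is adjusted minutely so the last sample lands exactly
    on the original end time.
    """
    if target_rate <= 0:
        raise TraceValidationError("target_rate must be positive")
    if len(trace.time) < 2:
        raise TraceValidationError("need at least 2 samples to resample")
    t0, t1 = trace.time[0], trace.time[-1]
    n = int(round((t1 - t0) * target_rate)) + 1
    if n < 2:
        n = 2
    grid = np.linspace(t0, t1, n)
    return RawTrace(time=grid, value=np.interp(grid, trace.time, trace.value),
                    sampling_rate=(n - 1) / (t1 - t0),
                    stim_times=trace.stim_times, channel=trace.channel)


def compute_strain(trace: RawTrace,
                   baseline_window: float = BASELINE_WINDOW_S) -> np.ndarray:
    """Signed strain series eps(t) = (L(t) - L0)/L0.

    L0 is the mean length over the ``baseline_window`` seconds ending at
    the first stimulation; compression is negative.  The reported "peak
    compression" elsewhere is |min eps|.
    """
    if len(trace.stim_times) == 0:
        raise TraceValidationError("no stimulation time to anchor baseline")
    s0 = trace.stim_times[0]
    sel = (trace.time >= s0 - baseline_window) & (trace.time < s0)
    if not np.any(sel):
        raise TraceValidationError("baseline window contains no samples")
    L0 = float(trace.value[sel].mean())
    return (trace.value - L0) / L0


def baseline_length(trace: RawTrace,
                    baseline_window: float = BASELINE_WINDOW_S) -> float:
    s0 = trace.stim_times[0] if len(trace.stim_times) else \
        trace.time[0] + baseline_window
    sel = (trace.time >= s0 - baseline_window) & (trace.time < s0)
    if not np.any(sel):
        raise TraceValidationError("baseline window contains no samples")
    return float(trace.value[sel].mean())


def pair_series(sarc: RawTrace, nuc_len: RawTrace, nuc_wid: RawTrace,
                n_beats: int = 5, target_rate: float = NUCLEAR_RATE_HZ,
                baseline_window: float = BASELINE_WINDOW_S
                ) -> PairedStrainSeries:
    """Beat-average, resample and strain all three channels onto one grid.

    The strain at the stimulus-anchored t = 0 sample is subtracted so the
    paired series start at exactly zero strain (the pre-stimulus baseline
    already makes it nearly so; the shift absorbs baseline noise).
    """
    L0 = {}
    eps = {}
    grid = None
    for tr in (sarc, nuc_len, nuc_wid):
        L0[tr.channel] = baseline_length(tr, baseline_window)
        beat = beat_average(tr, n_beats)
        beat = resample_to(beat, target_rate)
        e = (beat.value - L0[tr.channel]) / L0[tr.channel]
        e = e - e[0]
        n = len(beat.time) if grid is None else min(len(beat.time), grid.size)
        grid = beat.time[:n] if grid is None else grid[:n]
        eps[tr.channel] = e
    n = min(len(v) for v in eps.values())
    return PairedStrainSeries(
        t=grid[:n], eps_s=eps["sarcomere_length"][:n],
        eps_nL=eps["nuclear_length"][:n], eps_nW=eps["nuclear_width"][:n],
        L0_s=L0["sarcomere_length"], L0_nL=L0["nuclear_length"],
        L0_nW=L0["nuclear_width"])


def build_coupling_curve(series: PairedStrainSeries,
                         nuclear_axis: str = "length") -> CouplingCurve:
    """Strain-strain trajectory in compression magnitudes.

    Peak systole is the sample of maximum |eps_s| (earliest on ties);
    samples up to and including it are systolic, the rest diastolic.
    """
    if len(series.t) == 0:
        raise TraceValidationError("empty series")
    eps_n = series.eps_nL if nuclear_axis == "length" else series.eps_nW
    a_s = np.abs(series.eps_s)
    if np.allclose(a_s, a_s[0]):
        raise TraceValidationError("flat sarcomere trace: no peak systole")
    peak = int(np.argmax(a_s))
    return CouplingCurve(eps_s=a_s, eps_n=np.abs(eps_n), peak_index=peak)


def _branch_integral(x: np.ndarray, y: np.ndarray, tol: float,
                     direction: int = +1) -> float:
    """Signed trapezoidal integral of y dx along the (time-ordered) branch.

    Equals the strain-plane line integral.  A branch deviating from
    monotonicity (expected ``direction``: +1 increasing, -1 decreasing)
    by more than ``tol`` of its span at any point triggers a warning,
    but the arc-ordered integral is still well defined (sample noise
    produces only pointwise excursions, genuine loops a large one).
    """
    if len(x) < 2:
        return 0.0
    span = float(np.ptp(x))
    if direction >= 0:
        dev = float(np.max(np.maximum.accumulate(x) - x))
    else:
        dev = float(np.max(x - np.minimum.accumulate(x)))
    if span > 0 and dev > tol * span:
        warnings.warn("non-monotone |eps_s| on branch; integrating along "
                      "the arc", RuntimeWarning, stacklevel=3)
    return float(np.trapezoid(y, x))


def systolic_dampening(curve: CouplingCurve, tol: float = 0.1) -> float:
    """Area between the lossless 1:1 line and the systolic branch.

    D_sys = integral of (|eps_s| - |eps_n|) d|eps_s| from 0 to peak
    systole; zero for identity coupling, positive when nuclear strain is
    dampened.
    """
    xs, yn = curve.systolic
    return _branch_integral(xs, xs - yn, tol, direction=+1)


def diastolic_dampening(curve: CouplingCurve, tol: float = 0.1) -> float:
    """Hysteresis area of the re-lengthening branch.

    The reference is the unit-slope line through the end-systolic point
    (|eps_s|_peak, |eps_n|_es); D_dia integrates (|eps_n| - reference)
    as |eps_s| relaxes from its peak back to zero, so an exact elastic
    retrace along the reference line gives zero and a nucleus lagging
    the sarcomere gives a positive area.
    """
    xs, yn = curve.diastolic
    if len(xs) < 2:
        raise TraceValidationError("no diastolic branch")
    ref = yn[0] - (xs[0] - xs)
    # integral runs against decreasing |eps_s|; flip the sign accordingly
    return -_branch_integral(xs, yn - ref, tol, direction=-1)


def integrated_nuclear_strain(series: PairedStrainSeries) -> float:
    """S_int = integral of |eps_nL(t)| dt over the cycle (strain * s)."""
    return float(np.trapezoid(np.abs(series.eps_nL), series.t))


def coupling_metrics(series: PairedStrainSeries) -> CouplingMetrics:
    curve = build_coupling_curve(series)
    return CouplingMetrics(
        D_sys=systolic_dampening(curve),
        D_dia=diastolic_dampening(curve),
        S_int=integrated_nuclear_strain(series),
        peak_eps_s=float(np.max(np.abs(series.eps_s))),
        peak_eps_nL=float(np.max(np.abs(series.eps_nL))),
        peak_eps_nW=float(np.max(np.abs(series.eps_nW))),
    )


# ---------------------------------------------------------------------------
# CSV interfaces: long-format per-cell tables + sidecar stimulation times

def read_cell_csv(path, stim_path=None) -> dict[str, RawTrace]:
    """Read a long-format per-cell CSV with columns
    (time_s, channel, value_um); stimulation times come from a ``stim``
    channel in the same table or a sidecar JSON list."""
    df = pd.read_csv(path)
    stim = None
    if stim_path is not None:
        stim = np.asarray(json.loads(Path(stim_path).read_text()), float)
    elif "stim" in set(df["channel"]):
        stim = df.loc[df["channel"] == "stim", "time_s"].to_numpy(float)
        df = df[df["channel"] != "stim"]
    if stim is None:
        raise TraceValidationError("no stimulation times provided")
    traces = {}
    for ch, grp in df.groupby("channel"):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(float)
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        traces[ch] = RawTrace(time=t, value=grp["value_um"].to_numpy(float),
                              sampling_rate=rate, stim_times=stim, channel=ch)
    return traces


def write_metrics_csv(metrics: dict[str, CouplingMetrics], path) -> None:
    rows = [{"cell": cid, **vars(m)} for cid, m in metrics.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curve_csv(curve: CouplingCurve, path) -> None:
    pd.DataFrame({"eps_s": curve.eps_s, "eps_n": curve.eps_n,
                  "phase": curve.phase}).to_csv(path, index=False)
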