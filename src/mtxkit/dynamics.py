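"""Microtubule dynamic-instability analysis from length-history tracks.

Live-cell tracking of microtubule plus-ends yields, per microtubule, a
scalar length-versus-time series. Dynamic instability is quantified by
segmenting each track into growth (G), shortening (S) and pause (P)
phases and aggregating the standard statistic set: phase rates and
excursion lengths, percent time per phase, catastrophe and rescue
frequencies (per unit time and per unit length), and dynamicity — the
total tubulin exchange rate (length grown + length shortened) per unit
observation time.

Definitions follow the field's conventions:

* catastrophe: a G→S or P→S transition;
* rescue: an S→G or S→P transition;
* catastrophe frequency per minute is normalized by time spent in G and P
  (the phases from which a catastrophe can occur); rescue frequency per
  minute by time spent in S;
* per-µm frequencies are normalized by total length grown (catastrophes)
  or total length shortened (rescues).

Internally times are seconds and lengths µm; rates are reported per
minute. Condition comparisons report integer percent changes (rounded
half away from zero) with Welch t-test p-values coded A/B/C at the
0.001/0.01/0.05 thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "PhaseSegment",
    "TrackEvents",
    "Stat",
    "DynamicsParams",
    "ComparisonReport",
    "segment_track",
    "phase_labels",
    "track_events",
    "aggregate_params",
    "compare_conditions",
    "significance_code",
    "round_percent",
    "MicrotubuleDynamics",
    "DynamicsResults",
]

Phase = Literal["G", "S", "P"]

# Segmentation defaults: minimum net excursion (µm) and minimum sustained
# rate (µm/min) for a run to count as growth or shortening rather than
# pause. Standard practice in the dynamic-instability literature.
MIN_EXCURSION_UM = 0.5
MIN_RATE_UM_MIN = 2.0

#: p-value thresholds for significance superscripts in reports.
SIGNIFICANCE_LEVELS = (("A", 0.001), ("B", 0.01), ("C", 0.05))

#: Display order and labels for the aggregate report.
PARAM_ORDER = [
    ("growth_rate", "Growth rate (um/min)"),
    ("shortening_rate", "Shortening rate (um/min)"),
    ("growth_length", "Growth length (um)"),
    ("shortening_length", "Shortening length (um)"),
    ("pct_time_G", "% time growth"),
    ("pct_time_S", "% time shortening"),
    ("pct_time_P", "% time pause"),
    ("cat_per_min", "Catastrophes (events/min)"),
    ("res_per_min", "Rescues (events/min)"),
    ("cat_per_um", "Catastrophes (events/um)"),
    ("res_per_um", "Rescues (events/um)"),
    ("dynamicity", "Dynamicity (um/min)"),
]


@dataclass
class Track:
    """One microtubule's length history: strictly increasing time (s), length (µm)."""

    track_id: str
    time: np.ndarray
    length: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.length.shape:
            raise ValueError("time and length must be equal-length 1-D arrays")
        if len(self.time) < 3:
            raise ValueError("a track needs at least 3 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError(f"track {self.track_id}: time must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class PhaseSegment:
    """A maximal single-phase stretch of a track.

    ``rate`` is the least-squares slope over the segment's samples in
    µm/min (signed); ``delta_length`` the net length change in µm.
    ``i_start``/``i_end`` are sample indices into the parent track.
    """

    phase: Phase
    t_start: float
    t_end: float
    delta_length: float
    rate: float
    i_start: int
    i_end: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _lsq_slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope in µm/min."""
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0.0:
        return 0.0
    return float(tc @ (y - y.mean()) / denom) * 60.0


def segment_track(track: Track, min_excursion: float = MIN_EXCURSION_UM,
                  min_rate: float = MIN_RATE_UM_MIN) -> list[PhaseSegment]:
    """Partition a track into contiguous G/S/P segments.

    Sample intervals are classified by their instantaneous rate
    (up / down / flat at the ``min_rate`` threshold), consecutive
    same-direction intervals are merged into runs, and each run is called
    G (resp. S) only if its net excursion is ≥ ``min_excursion`` µm
    (resp. ≤ −``min_excursion``) and its least-squares slope clears
    ``min_rate`` µm/min; anything else is pause. Adjacent same-phase runs
    are merged, so the result is an exhaustive partition of the track.
    """
    if min_excursion <= 0 or min_rate <= 0:
        raise ValueError("segmentation thresholds must be > 0")
    t, y = track.time, track.length
    rates = np.diff(y) / np.diff(t) * 60.0  # µm/min per interval
    signs = np.where(rates >= min_rate, 1, np.where(rates <= -min_rate, -1, 0))

    # runs of equal interval sign -> candidate segments
    bounds = [0]
    for i in range(1, len(signs)):
        if signs[i] != signs[i - 1]:
            bounds.append(i)
    bounds.append(len(signs))

    phases: list[tuple[Phase, int, int]] = []  # (phase, first sample, last sample)
    for a, b in zip(bounds[:-1], bounds[1:]):
        i0, i1 = a, b  # samples i0..i1 inclusive
        net = y[i1] - y[i0]
        slope = _lsq_slope(t[i0:i1 + 1], y[i0:i1 + 1])
        if signs[a] > 0 and net >= min_excursion and slope >= min_rate:
            phase: Phase = "G"
        elif signs[a] < 0 and net <= -min_excursion and slope <= -min_rate:
            phase = "S"
        else:
            phase = "P"
        phases.append((phase, i0, i1))

    # merge adjacent same-phase runs
    merged: list[tuple[Phase, int, int]] = []
    for ph, i0, i1 in phases:
        if merged and merged[-1][0] == ph:
            merged[-1] = (ph, merged[-1][1], i1)
        else:
            merged.append((ph, i0, i1))

    return [
        PhaseSegment(phase=ph, t_start=float(t[i0]), t_end=float(t[i1]),
                     delta_length=float(y[i1] - y[i0]),
                     rate=_lsq_slope(t[i0:i1 + 1], y[i0:i1 + 1]),
                     i_start=i0, i_end=i1)
        for ph, i0, i1 in merged
    ]


def phase_labels(segments: Sequence[PhaseSegment], n_samples: int) -> np.ndarray:
    """Per-sample phase labels; a boundary sample belongs to the earlier segment."""
    labels = np.empty(n_samples, dtype="<U1")
    labels[:] = ""
    for k, seg in enumerate(segments):
        start = seg.i_start if k == 0 else seg.i_start + 1
        labels[start:seg.i_end + 1] = seg.phase
    return labels


class TrackEvents(NamedTuple):
    """Per-track event statistics from a segmentation."""

    n_catastrophes: int
    n_rescues: int
    time_in: dict[str, float]            # seconds per phase
    length_grown: float                  # µm, sum over G segments
    length_shortened: float              # µm, sum of |delta| over S segments
    growth_rates: list[float]            # µm/min, one per G segment
    shortening_rates: list[float]        # µm/min (positive), one per S segment
    growth_lengths: list[float]          # µm per G segment
    shortening_lengths: list[float]      # µm (positive) per S segment
    transitions: list[tuple[str, str]]   # consecutive phase pairs


def track_events(segments: Sequence[PhaseSegment]) -> TrackEvents:
    """Count catastrophes/rescues and accumulate phase time and excursions."""
    if not segments:
        raise ValueError("empty segmentation")
    time_in = {"G": 0.0, "S": 0.0, "P": 0.0}
    grown = shortened = 0.0
    g_rates: list[float] = []
    s_rates: list[float] = []
    g_lens: list[float] = []
    s_lens: list[float] = []
    for seg in segments:
        time_in[seg.phase] += seg.duration
        if seg.phase == "G":
            grown += seg.delta_length
            g_rates.append(seg.rate)
            g_lens.append(seg.delta_length)
        elif seg.phase == "S":
            shortened += -seg.delta_length
            s_rates.append(-seg.rate)
            s_lens.append(-seg.delta_length)
    transitions = [(a.phase, b.phase) for a, b in zip(segments[:-1], segments[1:])]
    n_cat = sum(1 for a, b in transitions if b == "S" and a in ("G", "P"))
    n_res = sum(1 for a, b in transitions if a == "S" and b in ("G", "P"))
    return TrackEvents(n_cat, n_res, time_in, grown, shortened,
                       g_rates, s_rates, g_lens, s_lens, transitions)


class Stat(NamedTuple):
    """A reported statistic: mean, SEM over tracks, number of tracks used."""

    mean: float
    sem: float
    n: int


@dataclass
class DynamicsParams:
    """The full dynamic-instability statistic set for one condition.

    Every field is a :class:`Stat` (mean, SEM, n). Point estimates pool
    events/time over all tracks; SEMs are computed over per-track values,
    with ``n`` the number of tracks contributing a defined value.
    Undefined quantities (e.g. rescue frequency with no shortening time)
    carry NaN means.
    """

    condition: str
    n_tracks: int
    growth_rate: Stat
    shortening_rate: Stat
    growth_length: Stat
    shortening_length: Stat
    pct_time_G: Stat
    pct_time_S: Stat
    pct_time_P: Stat
    cat_per_min: Stat
    res_per_min: Stat
    cat_per_um: Stat
    res_per_um: Stat
    dynamicity: Stat
    per_track: pd.DataFrame | None = field(default=None, repr=False)

    @classmethod
    def from_means(cls, condition: str, means: dict[str, float],
                   n_tracks: int = 0) -> "DynamicsParams":
        """Build from bare means (e.g. a published table) — SEMs set to NaN."""
        kw = {name: Stat(float(means[name]), math.nan, n_tracks)
              for name, _ in PARAM_ORDER}
        return cls(condition=condition, n_tracks=n_tracks, **kw)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"parameter": name, "label": label,
                 "mean": getattr(self, name).mean,
                 "sem": getattr(self, name).sem,
                 "n": getattr(self, name).n}
                for name, label in PARAM_ORDER]
        return pd.DataFrame(rows)


def _stat(pooled: float, per_track: np.ndarray) -> Stat:
    vals = per_track[np.isfinite(per_track)]
    n = len(vals)
    sem = float(stats.sem(vals)) if n >= 2 else math.nan
    return Stat(float(pooled), sem, n)


def aggregate_params(tracks: Iterable[Track], condition: str = "",
                     min_excursion: float = MIN_EXCURSION_UM,
                     min_rate: float = MIN_RATE_UM_MIN) -> DynamicsParams:
    """Segment every track and aggregate the condition-level statistic set.

    Rates and excursion lengths are averaged per event (pooled over all
    tracks); percent times and frequencies pool time/length over tracks;
    SEMs come from the per-track values. Division-by-zero cases (no
    shortening time, no grown length, ...) yield NaN.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    ev_list = [track_events(segment_track(tr, min_excursion, min_rate))
               for tr in tracks]

    def safe(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    rows = []
    for tr, ev in zip(tracks, ev_list):
        total = sum(ev.time_in.values())
        gp_min = (ev.time_in["G"] + ev.time_in["P"]) / 60.0
        s_min = ev.time_in["S"] / 60.0
        rows.append({
            "track_id": tr.track_id,
            "growth_rate": safe(sum(ev.growth_rates), len(ev.growth_rates)),
            "shortening_rate": safe(sum(ev.shortening_rates), len(ev.shortening_rates)),
            "growth_length": safe(sum(ev.growth_lengths), len(ev.growth_lengths)),
            "shortening_length": safe(sum(ev.shortening_lengths), len(ev.shortening_lengths)),
            "pct_time_G": 100.0 * safe(ev.time_in["G"], total),
            "pct_time_S": 100.0 * safe(ev.time_in["S"], total),
            "pct_time_P": 100.0 * safe(ev.time_in["P"], total),
            "cat_per_min": safe(ev.n_catastrophes, gp_min),
            "res_per_min": safe(ev.n_rescues, s_min),
            "cat_per_um": safe(ev.n_catastrophes, ev.length_grown),
            "res_per_um": safe(ev.n_rescues, ev.length_shortened),
            "dynamicity": safe(ev.length_grown + ev.length_shortened, total / 60.0),
            "n_catastrophes": ev.n_catastrophes,
            "n_rescues": ev.n_rescues,
        })
    per_track = pd.DataFrame(rows)

    tot_time = sum(sum(ev.time_in.values()) for ev in ev_list)
    tot = {ph: sum(ev.time_in[ph] for ev in ev_list) for ph in "GSP"}
    n_cat = sum(ev.n_catastrophes for ev in ev_list)
    n_res = sum(ev.n_rescues for ev in ev_list)
    grown = sum(ev.length_grown for ev in ev_list)
    shortened = sum(ev.length_shortened for ev in ev_list)
    all_g_rates = [r for ev in ev_list for r in ev.growth_rates]
    all_s_rates = [r for ev in ev_list for r in ev.shortening_rates]
    all_g_lens = [x for ev in ev_list for x in ev.growth_lengths]
    all_s_lens = [x for ev in ev_list for x in ev.shortening_lengths]

    pooled = {
        "growth_rate": safe(sum(all_g_rates), len(all_g_rates)),
        "shortening_rate": safe(sum(all_s_rates), len(all_s_rates)),
        "growth_length": safe(sum(all_g_lens), len(all_g_lens)),
        "shortening_length": safe(sum(all_s_lens), len(all_s_lens)),
        "pct_time_G": 100.0 * tot["G"] / tot_time,
        "pct_time_S": 100.0 * tot["S"] / tot_time,
        "pct_time_P": 100.0 * tot["P"] / tot_time,
        "cat_per_min": safe(n_cat, (tot["G"] + tot["P"]) / 60.0),
        "res_per_min": safe(n_res, tot["S"] / 60.0),
        "cat_per_um": safe(n_cat, grown),
        "res_per_um": safe(n_res, shortened),
        "dynamicity": (grown + shortened) / (tot_time / 60.0),
    }
    kw = {name: _stat(pooled[name], per_track[name].to_numpy())
          for name, _ in PARAM_ORDER}
    cond = condition or (tracks[0].condition if tracks[0].condition else "")
    return DynamicsParams(condition=cond, n_tracks=len(tracks),
                          per_track=per_track, **kw)


def round_percent(x: float) -> float:
    """Round to integer percent, half away from zero (−39.93 → −40, +42.67 → +43)."""
    if not math.isfinite(x):
        return math.nan
    return math.copysign(math.floor(abs(x) + 0.5), x)


def significance_code(p: float) -> str:
    """A if p < 0.001, B if p < 0.01, C if p < 0.05, else empty."""
    if not math.isfinite(p):
        return ""
    for code, level in SIGNIFICANCE_LEVELS:
        if p < level:
            return code
    return ""


@dataclass
class ComparisonReport:
    """Per-parameter percent changes and significance of treated vs control."""

    control: str
    treated: str
    table: pd.DataFrame  # parameter, control_mean, treated_mean, pct_change, p_value, code

    def pct_change(self, name: str) -> float:
        return float(self.table.set_index("parameter").loc[name, "pct_change"])

    def p_value(self, name: str) -> float:
        return float(self.table.set_index("parameter").loc[name, "p_value"])


def compare_conditions(control: DynamicsParams, treated: DynamicsParams,
                       test: Literal["welch", "mannwhitney"] = "welch",
                       ) -> ComparisonReport:
    """Percent change (integer, half-away-from-zero) and two-tailed p per parameter.

    p-values use the per-track values when both aggregates carry them
    (Welch t-test by default, Mann–Whitney U optionally) and require ≥ 2
    tracks per group; otherwise NaN.
    """
    rows = []
    for name, label in PARAM_ORDER:
        c, t = getattr(control, name), getattr(treated, name)
        if c.mean and math.isfinite(c.mean):
            pct = round_percent((t.mean - c.mean) / c.mean * 100.0)
        else:
            pct = math.nan
        p = math.nan
        if control.per_track is not None and treated.per_track is not None:
            a = control.per_track[name].dropna().to_numpy()
            b = treated.per_track[name].dropna().to_numpy()
            if len(a) >= 2 and len(b) >= 2:
                if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
                    p = 1.0  # identical constant groups
                elif test == "welch":
                    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                else:
                    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"parameter": name, "label": label,
                     "control_mean": c.mean, "treated_mean": t.mean,
                     "pct_change": pct, "p_value": p,
                     "code": significance_code(p)})
    return ComparisonReport(control=control.condition, treated=treated.condition,
                            table=pd.DataFrame(rows))


class MicrotubuleDynamics:
    """Model-style front end: tracks in, fitted dynamic-instability statistics out.

    Parameters
    ----------
    tracks : pandas.DataFrame or iterable of Track
        Long-format data with columns ``track_id, time_s, length_um,
        condition``, or already-built :class:`Track` objects.
    control : str
        Condition label to compare the others against.
    min_excursion, min_rate : float
        Segmentation thresholds (µm, µm/min).
    """

    def __init__(self, tracks: pd.DataFrame | Iterable[Track],
                 control: str = "control",
                 min_excursion: float = MIN_EXCURSION_UM,
                 min_rate: float = MIN_RATE_UM_MIN,
                 test: Literal["welch", "mannwhitney"] = "welch") -> None:
        if isinstance(tracks, pd.DataFrame):
            tracks = tracks_from_frame(tracks)
        self.tracks = list(tracks)
        if not self.tracks:
            raise ValueError("no tracks provided")
        self.control = control
        self.min_excursion = min_excursion
        self.min_rate = min_rate
        self.test = test

    def fit(self) -> "DynamicsResults":
        by_cond: dict[str, list[Track]] = {}
        for tr in self.tracks:
            by_cond.setdefault(tr.condition, []).append(tr)
        params = {cond: aggregate_params(trs, cond, self.min_excursion, self.min_rate)
                  for cond, trs in by_cond.items()}
        comparisons = {}
        if self.control in params:
            for cond, p in params.items():
                if cond != self.control:
                    comparisons[cond] = compare_conditions(
                        params[self.control], p, test=self.test)
        return DynamicsResults(params=params, comparisons=comparisons,
                               control=self.control)


@dataclass
class DynamicsResults:
    """Per-condition statistic sets plus treated-vs-control comparisons."""

    params: dict[str, DynamicsParams]
    comparisons: dict[str, ComparisonReport]
    control: str

    def summary(self) -> str:
        from .report import render_table1_report  # lazy: report imports dynamics
        return render_table1_report(self)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for cond, p in self.params.items():
            f = p.to_frame()
            f.insert(0, "condition", cond)
            f["n_tracks"] = p.n_tracks
            if cond in self.comparisons:
                cmp_tab = self.comparisons[cond].table.set_index("parameter")
                f["pct_change"] = [cmp_tab.loc[n, "pct_change"] for n in f["parameter"]]
                f["p_value"] = [cmp_tab.loc[n, "p_value"] for n in f["parameter"]]
                f["code"] = [cmp_tab.loc[n, "code"] for n in f["parameter"]]
            else:
                f["pct_change"] = math.nan
                f["p_value"] = math.nan
                f["code"] = ""
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Build Track objects from a long-format DataFrame (tracks CSV schema)."""
    required = {"track_id", "time_s", "length_um", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracks data missing column(s): {sorted(missing)}")
    out = []
    for (cond, tid), grp in df.groupby(["condition", "track_id"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(Track(track_id=str(tid), time=grp["time_s"].to_numpy(),
                         length=grp["length_um"].to_numpy(), condition=str(cond)))
    return out
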