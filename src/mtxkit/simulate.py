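"""Seeded synthetic-data generators with known ground truth.

Every downstream analysis stage in this package has a matching generator
here, so that recovery can be tested without any external data:

* :func:`simulate_tracks` — microtubule length histories from an exact
  (Gillespie) simulation of a three-state continuous-time Markov chain
  over growth / shortening / pause, resampled onto a regular observation
  grid (default 2-s intervals for 1 min, the usual live-cell protocol),
  with the hidden state sequence and event log retained;
* :func:`simulate_turbidity` — Gompertz sigmoid A350 time courses with a
  directly parameterized lag and plateau;
* :func:`simulate_itc` — one-site titration heats from the forward
  Wiseman model plus Gaussian noise and an optional dilution offset;
* :func:`simulate_isd_peaks` — singly-protonated c/z ISD ladders with
  dropout and m/z jitter, restricted to a mass window;
* :func:`make_fixture_suite` — writes a complete set of CSV/FASTA
  fixtures plus a JSON ground-truth manifest.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Track
from .itc import BindingParams, ITCSchedule, Titration, predict_heats
from .peptides import FragmentIon, Peptide, isd_ladder
from .polymerization import TurbidityCurve

__all__ = [
    "MYOTOXIN3_SEQUENCE",
    "DIParams",
    "SimulatedTrack",
    "TrackSet",
    "generator_matrix",
    "stationary_distribution",
    "simulate_tracks",
    "simulate_turbidity",
    "simulate_itc",
    "SimulatedSpectrum",
    "simulate_isd_peaks",
    "make_fixture_suite",
    "CONDITION_PARAMS",
    "ITC_TRUTH",
    "TURBIDITY_TRUTH",
]

#: The 45-residue crotamine-family peptide characterized by this toolkit.
MYOTOXIN3_SEQUENCE = "YKRCHKKGGHCFPKTVICLPPSSDFGKMDCRWKWKCCKKGSVNNA"

STATES = ("G", "S", "P")


@dataclass(frozen=True)
class DIParams:
    """Mechanistic dynamic-instability parameters of the three-state chain.

    Speeds in µm/min, transition rates in events/min, lengths in µm.
    Catastrophes are the G→S and P→S transitions, rescues S→G and S→P.
    Defaults are fixture conventions tuned to give statistics of the same
    order of magnitude as highly dynamic epithelial-cell microtubules
    (growth ~26 µm/min, ~29/18/53 % time in G/S/P, rescue rate ~19/min);
    they are not claims about any particular cell line.
    """

    v_g: float = 25.9        # growth speed, µm/min
    v_s: float = 31.1        # shortening speed, µm/min
    k_gs: float = 5.0        # G -> S, events/min (catastrophe from growth)
    k_gp: float = 9.0        # G -> P
    k_pg: float = 5.3        # P -> G
    k_ps: float = 3.8        # P -> S (catastrophe from pause)
    k_sg: float = 7.0        # S -> G (rescue to growth)
    k_sp: float = 12.0       # S -> P (rescue to pause)
    noise_sd: float = 0.05   # measurement noise on length, µm
    l0: float = 5.0          # initial length, µm

    def __post_init__(self) -> None:
        for name in ("v_g", "v_s", "k_gs", "k_gp", "k_pg", "k_ps",
                     "k_sg", "k_sp", "noise_sd", "l0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def rates(self) -> dict[str, dict[str, float]]:
        return {"G": {"S": self.k_gs, "P": self.k_gp},
                "S": {"G": self.k_sg, "P": self.k_sp},
                "P": {"G": self.k_pg, "S": self.k_ps}}

    @property
    def speeds(self) -> dict[str, float]:
        return {"G": self.v_g, "S": -self.v_s, "P": 0.0}


def generator_matrix(params: DIParams) -> np.ndarray:
    """CTMC generator Q (events/min) over states (G, S, P); rows sum to zero."""
    q = np.zeros((3, 3))
    for i, a in enumerate(STATES):
        for j, b in enumerate(STATES):
            if a != b:
                q[i, j] = params.rates[a][b]
        q[i, i] = -q[i].sum()
    return q


def stationary_distribution(params: DIParams) -> np.ndarray:
    """Stationary distribution of the chain over (G, S, P).

    Solved from pi Q = 0 with sum(pi) = 1 by least squares. For the
    degenerate all-zero-rate chain every distribution is stationary and
    the uniform one is returned.
    """
    q = generator_matrix(params)
    if np.all(q == 0):
        return np.full(3, 1.0 / 3.0)
    a = np.vstack([q.T, np.ones(3)])
    b = np.array([0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass
class SimulatedTrack:
    """One simulated track: observed lengths plus hidden ground truth.

    ``states`` gives the true hidden state at each sample time; ``events``
    is the full transition log (columns ``time_s, from_state, to_state,
    forced``), where forced marks the boundary rescue imposed when the
    length reaches zero.
    """

    track_id: str
    time: np.ndarray
    length_obs: np.ndarray
    length_true: np.ndarray
    states: np.ndarray
    events: pd.DataFrame
    condition: str = ""
    hit_boundary: bool = False

    def to_track(self) -> Track:
        return Track(track_id=self.track_id, time=self.time,
                     length=self.length_obs, condition=self.condition)


@dataclass
class TrackSet:
    """A batch of simulated tracks sharing parameters and observation grid."""

    tracks: list[SimulatedTrack]
    params: DIParams
    dt: float
    duration: float
    condition: str = ""

    def __len__(self) -> int:
        return len(self.tracks)

    def to_tracks(self) -> list[Track]:
        return [tr.to_track() for tr in self.tracks]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for tr in self.tracks:
            frames.append(pd.DataFrame({
                "track_id": tr.track_id, "time_s": tr.time,
                "length_um": tr.length_obs, "condition": tr.condition}))
        return pd.concat(frames, ignore_index=True)


def _gillespie_track(params: DIParams, duration: float, rng: np.random.Generator,
                     start_state: str) -> tuple[list, list, bool]:
    """Exact event-driven simulation; returns (piecewise segments, events, hit0).

    Segments are (t0, t1, state, length_at_t0); speeds per second. When a
    shortening excursion reaches zero length a rescue to growth is forced
    at the crossing time and logged with ``forced=True``.
    """
    speeds = {s: v / 60.0 for s, v in params.speeds.items()}  # µm/s
    rates_s = {s: {t: k / 60.0 for t, k in d.items()}
               for s, d in params.rates.items()}
    t, state, length = 0.0, start_state, params.l0
    segments, events = [], []
    hit_boundary = False
    while t < duration:
        total = sum(rates_s[state].values())
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        t_event = t + wait
        v = speeds[state]
        # time at which the length would hit zero in this state
        t_zero = t + length / (-v) if v < 0 and length > 0 else math.inf
        if state == "S" and length == 0.0:
            t_zero = t  # already at the boundary: rescue immediately
        if t_zero <= min(t_event, duration):
            segments.append((t, t_zero, state, length))
            events.append({"time_s": t_zero, "from_state": state,
                           "to_state": "G", "forced": True})
            t, state, length = t_zero, "G", 0.0
            hit_boundary = True
            continue
        if t_event >= duration:
            segments.append((t, duration, state, length))
            break
        targets = list(rates_s[state])
        weights = np.array([rates_s[state][x] for x in targets])
        nxt = targets[rng.choice(len(targets), p=weights / weights.sum())]
        segments.append((t, t_event, state, length))
        events.append({"time_s": t_event, "from_state": state,
                       "to_state": nxt, "forced": False})
        length = max(length + v * wait, 0.0)
        t, state = t_event, nxt
    return segments, events, hit_boundary


def simulate_tracks(params: DIParams, n_tracks: int, duration: float = 60.0,
                    dt: float = 2.0, seed: int | None = None,
                    start_state: str = "stationary",
                    condition: str = "") -> TrackSet:
    """Simulate ``n_tracks`` length histories sampled every ``dt`` seconds.

    Each track has floor(duration/dt) + 1 samples. ``start_state`` is one
    of ``"G"``, ``"S"``, ``"P"`` or ``"stationary"`` (initial state drawn
    from the chain's stationary distribution, which removes initial-state
    bias from occupancy statistics). Observed lengths are the true
    lengths plus Gaussian noise, clipped at zero. Identical seeds give
    identical output.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if start_state not in STATES and start_state != "stationary":
        raise ValueError("start_state must be G, S, P or 'stationary'")
    rng = np.random.default_rng(seed)
    n_samples = int(math.floor(duration / dt)) + 1
    grid = np.arange(n_samples) * dt
    pi = stationary_distribution(params)
    tracks = []
    for i in range(n_tracks):
        s0 = (STATES[rng.choice(3, p=pi)] if start_state == "stationary"
              else start_state)
        segments, events, hit0 = _gillespie_track(params, grid[-1] + dt * 1e-9,
                                                  rng, s0)
        starts = np.array([s[0] for s in segments])
        idx = np.searchsorted(starts, grid, side="right") - 1
        true = np.empty(n_samples)
        states = np.empty(n_samples, dtype="<U1")
        speeds = {s: v / 60.0 for s, v in params.speeds.items()}
        for k, (tq, j) in enumerate(zip(grid, idx)):
            t0, _, st, l0 = segments[j]
            true[k] = max(l0 + speeds[st] * (tq - t0), 0.0)
            states[k] = st
        obs = true + (rng.normal(0.0, params.noise_sd, n_samples)
                      if params.noise_sd > 0 else 0.0)
        obs = np.clip(obs, 0.0, None)
        tracks.append(SimulatedTrack(
            track_id=f"{condition or 'track'}_{i:03d}", time=grid,
            length_obs=obs, length_true=true, states=states,
            events=pd.DataFrame(events, columns=["time_s", "from_state",
                                                 "to_state", "forced"]),
            condition=condition, hit_boundary=hit0))
    return TrackSet(tracks=tracks, params=params, dt=dt,
                    duration=float(grid[-1]), condition=condition)


# Gompertz time shift between the inflection point and the 10%-amplitude
# crossing: exp(-exp(-r (t - t_m))) = 0.1  at  t = t_m - ln(ln 10)/r.
_LN_LN10 = math.log(math.log(10.0))


def simulate_turbidity(plateau: float, lag: float, rate: float,
                       baseline: float = 0.0, noise_sd: float = 0.0,
                       n_points: int = 361, dt: float = 10.0,
                       seed: int | None = None,
                       condition: str = "") -> TurbidityCurve:
    """Gompertz A350 curve: a(t) = baseline + plateau exp(−exp(−rate (t − t_m))).

    ``plateau`` is the amplitude above baseline and ``lag`` is defined as
    the time at which the noiseless curve crosses baseline + 10% of the
    amplitude, so the generating lag is directly comparable to the lag
    metric of :func:`mtxkit.polymerization.curve_metrics`. ``rate`` (1/s)
    sets the steepness. plateau = 0 gives a flat baseline curve.
    """
    if plateau < 0:
        raise ValueError("plateau must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    if plateau > 0 and rate <= 0:
        raise ValueError("rate must be > 0 for a rising curve")
    t = np.arange(n_points) * dt
    if plateau == 0:
        y = np.full(n_points, baseline, dtype=float)
    else:
        t_m = lag + _LN_LN10 / rate
        y = baseline + plateau * np.exp(-np.exp(-rate * (t - t_m)))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, n_points)
    return TurbidityCurve(time=t, a350=y, condition=condition)


def simulate_itc(truth: BindingParams, schedule: ITCSchedule,
                 noise_sd: float = 0.0, seed: int | None = None,
                 dilution_offset: float = 0.0) -> Titration:
    """Synthetic titration: forward-model heats + noise + constant dilution heat.

    When ``dilution_offset`` is non-zero a matching constant blank series
    is attached so the blank-subtraction stage can recover the offset-free
    heats exactly in the noiseless case. Heats in µJ.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    q = predict_heats(truth, schedule) + dilution_offset
    if noise_sd > 0:
        q = q + np.random.default_rng(seed).normal(0.0, noise_sd, len(q))
    blank = (np.full(schedule.n_injections, float(dilution_offset))
             if dilution_offset != 0.0 else None)
    return Titration(schedule=schedule, heats=q, blank_heats=blank)


@dataclass
class SimulatedSpectrum:
    """An ISD peak list plus its generating ground truth (kept/dropped ions)."""

    peaks: pd.DataFrame            # columns mz, intensity, sorted by mz
    kept: list[FragmentIon]
    dropped: list[FragmentIon]
    window: tuple[float, float]


def simulate_isd_peaks(peptide: Peptide, dropout: float = 0.0,
                       mz_noise_sd: float = 0.0,
                       window: tuple[float, float] = (1000.0, 5000.0),
                       seed: int | None = None) -> SimulatedSpectrum:
    """Singly-protonated c/z ladder with per-ion dropout and m/z jitter.

    The ladder is restricted to ions whose [M+H]+ falls inside ``window``
    (default the 1000–5000 Da acquisition window typical of ISD); each
    surviving ion is dropped independently with probability ``dropout``.
    """
    if not 0.0 <= dropout <= 1.0:
        raise ValueError("dropout must be in [0, 1]")
    if mz_noise_sd < 0:
        raise ValueError("mz_noise_sd must be >= 0")
    lo, hi = window
    rng = np.random.default_rng(seed)
    ladder = [ion for ion in isd_ladder(peptide) if lo <= ion.mz_1plus <= hi]
    kept, dropped = [], []
    for ion in ladder:
        (dropped if rng.random() < dropout else kept).append(ion)
    mz = np.array([ion.mz_1plus for ion in kept])
    if mz_noise_sd > 0 and len(mz):
        mz = mz + rng.normal(0.0, mz_noise_sd, len(mz))
    intensity = rng.uniform(0.2, 1.0, len(mz))
    order = np.argsort(mz)
    peaks = pd.DataFrame({"mz": mz[order], "intensity": intensity[order]})
    return SimulatedSpectrum(peaks=peaks, kept=kept, dropped=dropped,
                             window=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# fixture suite

#: Per-condition chain parameters for the track fixtures. The control
#: column uses the defaults; the dosed conditions slow both speeds and
#: lengthen pauses so that dynamicity falls dose-dependently.
CONDITION_PARAMS: dict[str, DIParams] = {
    "control": DIParams(),
    "myotoxin3_1uM": DIParams(v_g=26.7, v_s=32.7, k_gs=5.4, k_gp=12.4,
                              k_pg=6.0, k_ps=4.1, k_sg=7.4, k_sp=11.7),
    "myotoxin3_5uM": DIParams(v_g=26.9, v_s=31.4, k_gs=5.8, k_gp=12.5,
                              k_pg=4.9, k_ps=3.9, k_sg=7.6, k_sp=13.1),
    "myotoxin3_25uM": DIParams(v_g=20.3, v_s=24.5, k_gs=6.0, k_gp=12.1,
                               k_pg=3.85, k_ps=3.73, k_sg=7.5, k_sp=12.5),
}

#: Tracked microtubules per condition in the fixture set.
CONDITION_N_TRACKS = {"control": 54, "myotoxin3_1uM": 44,
                      "myotoxin3_5uM": 44, "myotoxin3_25uM": 68}

#: Generating one-site binding truth: two sites per heterodimer, Kd 5.3 µM,
#: exothermic with a conventional −40 kJ/mol enthalpy.
ITC_TRUTH = BindingParams(N=2.0, Ka=1.0 / 5.3e-6, dH=-40.0, T=293.15)

#: Turbidity fixture truths: the peptide curve nucleates earlier (shorter
#: lag) and assembles more polymer (higher plateau) than the control.
TURBIDITY_TRUTH = {
    "control": dict(plateau=0.25, lag=420.0, rate=0.010, baseline=0.05),
    "myotoxin3": dict(plateau=0.45, lag=180.0, rate=0.015, baseline=0.05),
}

TURBIDITY_NOISE_SD = 0.002
ISD_FIXTURE = dict(dropout=0.15, mz_noise_sd=0.02, window=(1000.0, 5000.0))
ITC_NOISE_FRAC = 0.01       # noise SD as fraction of the largest |heat|
ITC_DILUTION_OFFSET = -0.5  # µJ constant dilution heat


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Write the full fixture set (CSV/FASTA + JSON manifest) and return it.

    Files written: ``tracks.csv``, ``turbidity.csv``, ``itc.csv``,
    ``itc_blank.csv``, ``isd_peaks.csv``, ``myotoxin3.fasta`` and
    ``manifest.json``. Byte-identical for identical seeds.
    """
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(seed).spawn(4)
    child_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]

    # tracks
    frames = []
    for k, (cond, params) in enumerate(CONDITION_PARAMS.items()):
        ts = simulate_tracks(params, CONDITION_N_TRACKS[cond], duration=60.0,
                             dt=2.0, seed=child_seeds[0] + k, condition=cond)
        frames.append(ts.to_dataframe())
    tracks_df = pd.concat(frames, ignore_index=True)
    mio.write_tracks(tracks_df, outdir / "tracks.csv")

    # turbidity
    curves = []
    for k, (cond, tp) in enumerate(TURBIDITY_TRUTH.items()):
        curves.append(simulate_turbidity(**tp, noise_sd=TURBIDITY_NOISE_SD,
                                         seed=child_seeds[1] + k,
                                         condition=cond))
    mio.write_turbidity(curves, outdir / "turbidity.csv")

    # ITC
    schedule = ITCSchedule()
    noiseless = predict_heats(ITC_TRUTH, schedule)
    itc_noise = ITC_NOISE_FRAC * float(np.max(np.abs(noiseless)))
    tit = simulate_itc(ITC_TRUTH, schedule, noise_sd=itc_noise,
                       seed=child_seeds[2], dilution_offset=ITC_DILUTION_OFFSET)
    mio.write_itc(tit, outdir / "itc.csv")
    mio.write_itc(Titration(schedule=schedule, heats=tit.blank_heats),
                  outdir / "itc_blank.csv")

    # ISD spectrum + FASTA
    peptide = Peptide(MYOTOXIN3_SEQUENCE, n_disulfides=3, name="myotoxin3")
    spec = simulate_isd_peaks(peptide, seed=child_seeds[3], **ISD_FIXTURE)
    mio.write_peaks(spec.peaks, outdir / "isd_peaks.csv")
    mio.write_fasta([peptide], outdir / "myotoxin3.fasta")

    manifest = {
        "seed": seed,
        "files": {
            "tracks": "tracks.csv", "turbidity": "turbidity.csv",
            "itc": "itc.csv", "itc_blank": "itc_blank.csv",
            "isd_peaks": "isd_peaks.csv", "fasta": "myotoxin3.fasta",
        },
        "tracks": {
            "dt_s": 2.0, "duration_s": 60.0,
            "n_tracks": CONDITION_N_TRACKS,
            "params": {c: asdict(p) for c, p in CONDITION_PARAMS.items()},
        },
        "turbidity": {"noise_sd": TURBIDITY_NOISE_SD,
                      "params": TURBIDITY_TRUTH},
        "itc": {
            "truth": {"N": ITC_TRUTH.N, "Ka_per_M": ITC_TRUTH.Ka,
                      "Kd_M": ITC_TRUTH.Kd, "dH_kJ_mol": ITC_TRUTH.dH,
                      "T_K": ITC_TRUTH.T},
            "schedule": asdict(schedule) | {"inj_volumes": list(schedule.inj_volumes)},
            "noise_sd_uJ": itc_noise,
            "dilution_offset_uJ": ITC_DILUTION_OFFSET,
        },
        "isd": {"sequence": MYOTOXIN3_SEQUENCE, "n_disulfides": 3,
                **{k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in ISD_FIXTURE.items()},
                "n_kept": len(spec.kept), "n_dropped": len(spec.dropped)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
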