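"""One-set-of-sites isothermal titration calorimetry (ITC) analysis.

Implements the Wiseman single-class-of-sites binding model for a
perfusion-cell calorimeter: a macromolecule M in the cell (concentration
diluted by each injection) is titrated with ligand X from the syringe; at
each injection the bound fraction follows the one-site quadratic and the
measured heat is the change in bound ligand times the molar binding
enthalpy, corrected for the volume displaced from the active cell.

Concentration bookkeeping per injection of volume v into active volume V0:

    [M] <- [M] (1 - v/V0)
    [X] <- [X] (1 - v/V0) + [X]_syringe (v/V0)

Bound fraction of sites (theta) from

    theta = (a - sqrt(a^2 - 4 r)) / 2,   a = 1 + r + 1/(N Ka [M]),
    r = [X] / (N [M])

and the differential heat of injection i (in µJ)

    q_i = dH * (B_i - B_{i-1} (1 - v_i/V0)),   B_i = N theta_i [M]_i V0

with dH in J/mol and B in mol. The fit estimates (N, Ka, dH) by
least squares with multi-start initialization (one-site fits are
multimodal at low c-value), and derives dG = -RT ln Ka, dS = (dH - dG)/T
and Kd = 1/Ka. Temperature defaults to 293.15 K (20 °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "R_GAS",
    "ITCSchedule",
    "BindingParams",
    "Titration",
    "predict_heats",
    "subtract_blank",
    "derive_thermodynamics",
    "OneSiteBindingModel",
    "BindingResults",
    "fit_one_site",
]

R_GAS = 8.314  # J / mol / K


@dataclass(frozen=True)
class ITCSchedule:
    """Titration schedule: concentrations (µM), injection volumes (µL), cell.

    Defaults follow a typical perfusion-cell experiment on tubulin:
    55 µM macromolecule in a 200 µL cell titrated with 2.2 mM ligand in
    19 injections of 2 µL at 20 °C.
    """

    cell_conc: float = 55.0           # µM macromolecule in cell
    syringe_conc: float = 2200.0      # µM ligand in syringe
    inj_volumes: tuple[float, ...] = (2.0,) * 19  # µL
    cell_volume: float = 200.0        # µL active cell volume
    temperature: float = 293.15       # K

    def __post_init__(self) -> None:
        if self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be > 0")
        if self.cell_volume <= 0 or self.temperature <= 0:
            raise ValueError("cell volume and temperature must be > 0")
        if len(self.inj_volumes) == 0:
            raise ValueError("need at least one injection")
        if any(v <= 0 for v in self.inj_volumes):
            raise ValueError("injection volumes must be > 0")
        object.__setattr__(self, "inj_volumes", tuple(float(v) for v in self.inj_volumes))

    @property
    def n_injections(self) -> int:
        return len(self.inj_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Ligand:macromolecule molar ratio in the cell after each injection."""
        m, x, _ = _concentration_series(self)
        return x / m


@dataclass(frozen=True)
class BindingParams:
    """One-site binding parameters and derived thermodynamics.

    N sites per macromolecule, Ka in M^-1, dH in kJ/mol, T in K.
    dG (kJ/mol), dS (J/mol/K) and Kd (M) are derived; ``se`` holds
    asymptotic standard errors keyed by parameter name when fitted.
    """

    N: float
    Ka: float
    dH: float
    T: float = 293.15
    se: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N <= 0 or self.Ka <= 0:
            raise ValueError("N and Ka must be > 0")
        if self.T <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def Kd(self) -> float:
        return 1.0 / self.Ka

    @property
    def dG(self) -> float:
        return -R_GAS * self.T * math.log(self.Ka) / 1000.0  # kJ/mol

    @property
    def dS(self) -> float:
        return (self.dH - self.dG) * 1000.0 / self.T  # J/mol/K


def derive_thermodynamics(N: float, Ka: float, dH: float,
                          T: float = 293.15) -> tuple[float, float, float]:
    """(dG kJ/mol, dS J/mol/K, Kd M) from Ka (M^-1), dH (kJ/mol) and T (K)."""
    if Ka <= 0 or T <= 0:
        raise ValueError("Ka and T must be > 0")
    dG = -R_GAS * T * math.log(Ka) / 1000.0
    dS = (dH - dG) * 1000.0 / T
    return dG, dS, 1.0 / Ka


@dataclass
class Titration:
    """Per-injection integrated heats (µJ) under a schedule, plus optional blank."""

    schedule: ITCSchedule
    heats: np.ndarray
    blank_heats: np.ndarray | None = None
    note: str = ""

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if len(self.heats) != self.schedule.n_injections:
            raise ValueError("heats length must equal the number of injections")
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)
            if self.blank_heats.shape != self.heats.shape:
                raise ValueError("blank_heats must match heats in shape")


def _concentration_series(schedule: ITCSchedule):
    """Per-injection cell concentrations [M]_i, [X]_i (M) and dilution factors."""
    v0 = schedule.cell_volume
    m = schedule.cell_conc * 1e-6
    x = 0.0
    x_syr = schedule.syringe_conc * 1e-6
    ms, xs, fs = [], [], []
    for v in schedule.inj_volumes:
        f = v / v0
        m *= (1.0 - f)
        x = x * (1.0 - f) + x_syr * f
        ms.append(m)
        xs.append(x)
        fs.append(f)
    return np.array(ms), np.array(xs), np.array(fs)


def predict_heats(params: BindingParams, schedule: ITCSchedule) -> np.ndarray:
    """Forward one-site model: per-injection heats in µJ (exothermic < 0)."""
    ms, xs, fs = _concentration_series(schedule)
    n, ka = params.N, params.Ka
    v0_l = schedule.cell_volume * 1e-6
    r = xs / (n * ms)
    a = 1.0 + r + 1.0 / (n * ka * ms)
    disc = a * a - 4.0 * r
    if np.any(disc < 0):
        raise ValueError("no physical root for the bound fraction; "
                         "check concentrations and parameters")
    theta = (a - np.sqrt(disc)) / 2.0
    bound = n * theta * ms * v0_l  # mol ligand bound
    dh_j = params.dH * 1000.0
    q = np.empty_like(bound)
    prev = 0.0
    for i, (b, f) in enumerate(zip(bound, fs)):
        q[i] = dh_j * (b - prev * (1.0 - f)) * 1e6  # µJ
        prev = b
    return q


def subtract_blank(titration: Titration, offset: float | None = None) -> Titration:
    """Subtract a blank titration (or a constant dilution-heat offset) element-wise."""
    if offset is not None:
        blank = np.full_like(titration.heats, float(offset))
        note = f"constant dilution offset {offset} uJ subtracted"
    elif titration.blank_heats is not None:
        blank = titration.blank_heats
        note = "blank titration subtracted"
    else:
        raise ValueError("no blank heats present and no constant offset given")
    return Titration(schedule=titration.schedule,
                     heats=titration.heats - blank,
                     blank_heats=None, note=note)


class OneSiteBindingModel:
    """Least-squares one-set-of-sites model for an integrated-heat titration.

    Parameters
    ----------
    titration : Titration
        Blank-corrected per-injection heats.
    discard_first : bool
        Exclude the first injection from the residuals (its concentration
        bookkeeping is still performed). Common ITC practice because of
        diffusion across the syringe tip; off by default.

    Examples
    --------
    >>> model = OneSiteBindingModel(titration)
    >>> res = model.fit()
    >>> res.params.Kd, res.params.dG
    """

    #: multi-start grid: one-site fits are multimodal at low c-value
    KA_STARTS = (1e3, 1e4, 1e5, 1e6, 1e7, 1e8)
    N_STARTS = (0.5, 1.0, 2.0, 4.0)

    def __init__(self, titration: Titration, discard_first: bool = False) -> None:
        self.titration = titration
        self.discard_first = discard_first
        if titration.schedule.n_injections - int(discard_first) < 5:
            raise ValueError("need at least 5 informative injections")

    def _residuals(self, p: lmfit.Parameters) -> np.ndarray:
        bp = BindingParams(N=p["N"].value, Ka=10.0 ** p["logKa"].value,
                           dH=p["dH"].value, T=self.titration.schedule.temperature)
        resid = predict_heats(bp, self.titration.schedule) - self.titration.heats
        return resid[1:] if self.discard_first else resid

    def fit(self) -> "BindingResults":
        sched = self.titration.schedule
        heats = self.titration.heats
        # rough dH scale: total heat / total sites, sign included
        cell_mol = sched.cell_conc * 1e-6 * sched.cell_volume * 1e-6
        best = None
        for n0 in self.N_STARTS:
            dh0 = float(np.sum(heats)) * 1e-6 / (n0 * cell_mol) / 1000.0  # kJ/mol
            if dh0 == 0.0:
                dh0 = -1.0
            for ka0 in self.KA_STARTS:
                p = lmfit.Parameters()
                p.add("N", value=n0, min=0.05, max=20.0)
                p.add("logKa", value=math.log10(ka0), min=0.0, max=12.0)
                p.add("dH", value=dh0)
                try:
                    out = lmfit.minimize(self._residuals, p, method="least_squares")
                except Exception:
                    continue
                if best is None or out.chisqr < best.chisqr:
                    best = out
        if best is None:
            raise RuntimeError("all fit starts failed")
        return self._package(best)

    def _package(self, out: lmfit.minimizer.MinimizerResult) -> "BindingResults":
        sched = self.titration.schedule
        n = out.params["N"].value
        log_ka = out.params["logKa"].value
        ka = 10.0 ** log_ka
        dh = out.params["dH"].value
        se: dict[str, float] = {}
        if out.params["N"].stderr is not None:
            se["N"] = out.params["N"].stderr
            # delta method: Ka = 10^logKa
            se["Ka"] = (out.params["logKa"].stderr or math.nan) * ka * math.log(10.0)
            se["dH"] = out.params["dH"].stderr or math.nan
        params = BindingParams(N=n, Ka=ka, dH=dh, T=sched.temperature, se=se)
        fitted = predict_heats(params, sched)
        c_value = n * ka * sched.cell_conc * 1e-6
        flags = []
        if not out.success:
            flags.append("optimizer did not report convergence")
        if not (1.0 <= c_value <= 1000.0):
            flags.append(f"c-value {c_value:.3g} outside [1, 1000]; "
                         "parameters may be poorly identified")
        return BindingResults(params=params, model=self, fitted=fitted,
                              residuals=fitted - self.titration.heats,
                              chisqr=float(out.chisqr), converged=bool(out.success),
                              c_value=float(c_value), flags=flags,
                              minimizer_result=out)


@dataclass
class BindingResults:
    """Fitted one-site parameters with uncertainties and fit diagnostics."""

    params: BindingParams
    model: OneSiteBindingModel
    fitted: np.ndarray
    residuals: np.ndarray
    chisqr: float
    converged: bool
    c_value: float
    flags: list[str]
    minimizer_result: object = field(repr=False, default=None)

    def summary(self) -> str:
        p = self.params
        se = p.se

        def fmt(name: str, value: float, unit: str) -> str:
            s = se.get(name, math.nan)
            err = f" +/- {s:.3g}" if math.isfinite(s) else ""
            return f"  {name:<3} = {value:.6g}{err} {unit}"

        lines = [
            "One-set-of-sites ITC fit",
            "=" * 40,
            fmt("N", p.N, "sites"),
            fmt("Ka", p.Ka, "1/M"),
            fmt("dH", p.dH, "kJ/mol"),
            f"  Kd  = {p.Kd * 1e6:.4g} uM",
            f"  dG  = {p.dG:.4g} kJ/mol",
            f"  dS  = {p.dS:.4g} J/mol/K",
            f"  T   = {p.T:.2f} K",
            f"  chi-square = {self.chisqr:.6g}",
            f"  c-value    = {self.c_value:.4g}",
            f"  converged  = {self.converged}",
        ]
        for fl in self.flags:
            lines.append(f"  WARNING: {fl}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "N": p.N, "Ka_per_M": p.Ka, "Kd_M": p.Kd,
            "dH_kJ_mol": p.dH, "dG_kJ_mol": p.dG, "dS_J_mol_K": p.dS,
            "T_K": p.T, "se": {k: float(v) for k, v in p.se.items()},
            "chisqr": self.chisqr, "c_value": self.c_value,
            "converged": self.converged, "flags": list(self.flags),
        }


def fit_one_site(titration: Titration, discard_first: bool = False) -> BindingResults:
    """Convenience wrapper: ``OneSiteBindingModel(titration).fit()``."""
    return OneSiteBindingModel(titration, discard_first=discard_first).fit()
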