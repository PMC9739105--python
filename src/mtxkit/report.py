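"""Configurable analysis pipeline and consolidated reporting.

A YAML config (versioned schema, unknown keys rejected) selects which
stages to run — peptide masses, ISD annotation, polymerization metrics,
microtubule dynamics, ITC binding — on which input files, with optional
parameter overrides. Each stage writes its own JSON/CSV output; a
consolidated ``report.json`` ties them together and a structured log
records versions, seeds and parameters so stochastic stages are
replayable. Identical config + seed give byte-identical outputs
(timestamps appear only in the log).
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from . import io as mio
from .dynamics import DynamicsResults, MicrotubuleDynamics, significance_code
from .itc import OneSiteBindingModel, subtract_blank
from .peptides import Peptide, annotate_peaks, peptide_mass
from .polymerization import compare_curves, curve_metrics

__all__ = ["PipelineConfig", "run_pipeline", "render_table1_report"]

CONFIG_VERSION = 1

#: Allowed keys per stage; values are defaults for optional keys.
_STAGE_KEYS: dict[str, dict[str, Any]] = {
    "mass": {"fasta": None},
    "annotate": {"fasta": None, "peaks": None, "tolerance": 0.1},
    "polym": {"turbidity": None, "control": "control", "treated": None,
              "smooth_window": 5},
    "dynamics": {"tracks": None, "control": "control", "min_excursion": 0.5,
                 "min_rate": 2.0, "test": "welch"},
    "itc": {"itc": None, "blank": None, "cell_conc": 55.0,
            "syringe_conc": 2200.0, "cell_volume": 200.0,
            "temperature": 293.15, "discard_first": False},
}
_REQUIRED = {"mass": ["fasta"], "annotate": ["fasta", "peaks"],
             "polym": ["turbidity"], "dynamics": ["tracks"], "itc": ["itc"]}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for schema)."""

    outdir: Path
    stages: dict[str, dict[str, Any]]
    seed: int = 0
    report_format: str = "json"
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | Path = ".") -> "PipelineConfig":
        raw = dict(raw)
        version = raw.pop("version", None)
        if version != CONFIG_VERSION:
            raise ValueError(f"config version must be {CONFIG_VERSION}, got {version}")
        outdir = raw.pop("outdir", None)
        if outdir is None:
            raise ValueError("config must set 'outdir'")
        seed = int(raw.pop("seed", 0))
        report_format = raw.pop("report_format", "json")
        if report_format not in ("json", "csv"):
            raise ValueError("report_format must be 'json' or 'csv'")
        stages_raw = raw.pop("stages", {})
        if raw:
            raise ValueError(f"unknown config key(s): {sorted(raw)}")
        if not isinstance(stages_raw, dict):
            raise ValueError("'stages' must be a mapping of stage name to options")
        stages = {}
        for name, opts in stages_raw.items():
            if name not in _STAGE_KEYS:
                raise ValueError(f"unknown stage {name!r}; "
                                 f"expected one of {sorted(_STAGE_KEYS)}")
            opts = dict(opts or {})
            unknown = set(opts) - set(_STAGE_KEYS[name])
            if unknown:
                raise ValueError(f"stage {name!r}: unknown key(s) {sorted(unknown)}")
            merged = {**_STAGE_KEYS[name], **opts}
            for req in _REQUIRED[name]:
                if merged[req] is None:
                    raise ValueError(f"stage {name!r}: missing required key {req!r}")
            stages[name] = merged
        return cls(outdir=Path(outdir), stages=stages, seed=seed,
                   report_format=report_format, base_dir=Path(base_dir))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(raw, base_dir=path.parent)

    def resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        return None if math.isnan(x) else x
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    return x


def _stage_mass(cfg: PipelineConfig, opts: dict) -> dict:
    peptides = mio.read_fasta(cfg.resolve(opts["fasta"]))
    out = {}
    for p in peptides:
        reduced = Peptide(p.sequence, 0, p.name)
        out[p.name] = {
            "length": len(p), "n_disulfides": p.n_disulfides,
            "average_oxidized_Da": peptide_mass(p, "average"),
            "average_reduced_Da": peptide_mass(reduced, "average"),
            "mono_oxidized_Da": peptide_mass(p, "mono"),
            "mono_reduced_Da": peptide_mass(reduced, "mono"),
        }
    return out


def _stage_annotate(cfg: PipelineConfig, opts: dict) -> dict:
    peptides = mio.read_fasta(cfg.resolve(opts["fasta"]))
    peaks = mio.read_peaks(cfg.resolve(opts["peaks"]))
    ann = annotate_peaks(peaks, peptides[0], tolerance=float(opts["tolerance"]))
    return {"candidate": peptides[0].name, "n_peaks": len(peaks),
            "n_matched": len(ann.matches), "coverage": ann.coverage,
            "terminal_span": ann.terminal_span, "n_bonds": ann.n_bonds}


def _stage_polym(cfg: PipelineConfig, opts: dict) -> dict:
    curves = mio.read_turbidity(cfg.resolve(opts["turbidity"]))
    window = int(opts["smooth_window"])
    metrics = {c: curve_metrics(curve, smooth_window=window)
               for c, curve in curves.items()}
    out = {c: {"lag_time_s": m.lag_time, "plateau": m.plateau,
               "baseline": m.baseline, "amplitude": m.amplitude,
               "vmax_per_s": m.vmax} for c, m in metrics.items()}
    control = opts["control"]
    treated = opts["treated"]
    if treated is None:
        others = [c for c in metrics if c != control]
        treated = others[0] if len(others) == 1 else None
    if control in metrics and treated in metrics:
        cmp_ = compare_curves(metrics[control], metrics[treated])
        out["comparison"] = {"control": control, "treated": treated,
                             "plateau_ratio": cmp_.plateau_ratio,
                             "lag_diff_s": cmp_.lag_diff,
                             "vmax_ratio": cmp_.vmax_ratio}
    return out


def _stage_dynamics(cfg: PipelineConfig, opts: dict,
                    outdir: Path) -> tuple[dict, DynamicsResults]:
    df = mio.read_tracks(cfg.resolve(opts["tracks"]))
    model = MicrotubuleDynamics(df, control=opts["control"],
                                min_excursion=float(opts["min_excursion"]),
                                min_rate=float(opts["min_rate"]),
                                test=opts["test"])
    results = model.fit()
    table = results.to_frame()
    # full precision so the written table parses back to the exact aggregates
    table.to_csv(outdir / "dynamics_table.csv", index=False, float_format="%.17g")
    with open(outdir / "dynamics_table.txt", "w") as fh:
        fh.write(render_table1_report(results))
    out = {
        "conditions": {c: {"n_tracks": p.n_tracks} for c, p in results.params.items()},
        "table_csv": "dynamics_table.csv",
        "comparisons": {
            c: r.table[["parameter", "pct_change", "p_value", "code"]]
                .set_index("parameter").to_dict("index")
            for c, r in results.comparisons.items()},
    }
    return out, results


def _stage_itc(cfg: PipelineConfig, opts: dict) -> dict:
    blank = cfg.resolve(opts["blank"]) if opts["blank"] else None
    tit = mio.read_itc(cfg.resolve(opts["itc"]), blank_path=blank,
                       cell_conc=float(opts["cell_conc"]),
                       syringe_conc=float(opts["syringe_conc"]),
                       cell_volume=float(opts["cell_volume"]),
                       temperature=float(opts["temperature"]))
    if tit.blank_heats is not None:
        tit = subtract_blank(tit)
    res = OneSiteBindingModel(tit, discard_first=bool(opts["discard_first"])).fit()
    return res.to_dict()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write per-stage plus consolidated outputs.

    Returns the consolidated report as a dict. An empty stage list is a
    no-op (logged as such). Any stage error propagates after being logged.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"mtxkit {__version__} | numpy {np.__version__} | scipy {scipy.__version__}"
        f" | pandas {pd.__version__}",
        f"started: {datetime.datetime.now().isoformat()}",
        f"seed: {config.seed}",
    ]
    report: dict[str, Any] = {"mtxkit_version": __version__, "seed": config.seed}
    if not config.stages:
        log_lines.append("no stages configured: nothing to do")
    for name, opts in config.stages.items():
        log_lines.append(f"stage {name}: {json.dumps(_jsonable(opts), sort_keys=True)}")
        try:
            if name == "mass":
                result = _stage_mass(config, opts)
            elif name == "annotate":
                result = _stage_annotate(config, opts)
            elif name == "polym":
                result = _stage_polym(config, opts)
            elif name == "dynamics":
                result, _ = _stage_dynamics(config, opts, outdir)
            elif name == "itc":
                result = _stage_itc(config, opts)
        except Exception as exc:
            log_lines.append(f"stage {name} FAILED: {exc}")
            with open(outdir / "run.log", "w") as fh:
                fh.write("\n".join(log_lines) + "\n")
            raise
        result = _jsonable(result)
        with open(outdir / f"{name}.json", "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report[name] = result
        log_lines.append(f"stage {name}: ok -> {name}.json")
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return report


def render_table1_report(results: DynamicsResults) -> str:
    """Human-readable dynamic-instability table: mean ± SEM, n, % change, codes.

    One column per condition (control first), one row per statistic, with
    significance superscripts (A: p < 0.001, B: p < 0.01, C: p < 0.05)
    on the treated columns.
    """
    conds = [results.control] + [c for c in results.params if c != results.control]
    conds = [c for c in conds if c in results.params]
    from .dynamics import PARAM_ORDER

    def cell(cond: str, name: str) -> str:
        st = getattr(results.params[cond], name)
        txt = f"{st.mean:.2f}" if math.isfinite(st.mean) else "n.d."
        if math.isfinite(st.sem):
            txt += f" +/- {st.sem:.2f}"
        if cond in results.comparisons:
            code = results.comparisons[cond].table.set_index("parameter") \
                .loc[name, "code"]
            if code:
                txt += f" ^{code}"
        return txt

    width = 24
    header = ["Variable".ljust(30)] + [c.ljust(width) for c in conds]
    lines = ["".join(header), "-" * (30 + width * len(conds))]
    for name, label in PARAM_ORDER:
        row = [label.ljust(30)] + [cell(c, name).ljust(width) for c in conds]
        lines.append("".join(row))
    ns = ["n (microtubules)".ljust(30)] + \
        [str(results.params[c].n_tracks).ljust(width) for c in conds]
    lines.append("".join(ns))
    lines.append("significance vs control: ^A p<0.001, ^B p<0.01, ^C p<0.05")
    return "\n".join(lines)
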