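"""Configuration loading, trajectory/report writers and experiment presets."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from . import __version__
from .core import FRAME_COLS, Trajectory, integrate, nullclines
from .coupled import CoupledParams, coupled_step_response
from .estimation import report_dataset
from .frequency import response_map
from .jamming import (carrier_ratio_perturbation, initial_state_jam,
                      kin_threshold, relaxation_scan, step_response)
from .params import CCCParams, ConservedTriple
from .stochastic import SSAConfig, count_statistics, ssa_double_mm, ssa_limit

log = logging.getLogger("cccsim")

_PARAM_KEYS = {f.name for f in dataclasses.fields(CCCParams)}
_CONFIG_KEYS = _PARAM_KEYS | {
    "cpool", "csum", "model", "t_end", "sample_dt", "seed", "initial_state",
}
_STATE_KEYS = {"m0", "m1", "m2", "c_t", "cstar_t", "c", "cstar", "cm0", "cstarm1"}

CONFIG_DEFAULTS = {
    "cpool": 2.0, "csum": 2.0, "model": "reduced5",
    "t_end": 1000.0, "sample_dt": 1.0, "seed": 0,
}


class ConfigError(ValueError):
    pass


def validate_config(raw: Mapping) -> dict:
    """Validate a flat key/value configuration and fill defaults.

    Unknown keys are rejected by name; numeric invariants are enforced
    by the CCCParams constructor.
    """
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    merged = {**CONFIG_DEFAULTS, **{k: v for k, v in raw.items()}}
    param_kwargs = {}
    for k in _PARAM_KEYS & set(merged):
        v = merged.pop(k)
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigError(f"configuration key {k!r} must be numeric, got {v!r}")
        param_kwargs[k] = float(v)
    try:
        params = CCCParams(**param_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    state = merged.pop("initial_state", None)
    if state is not None:
        bad = set(state) - _STATE_KEYS
        if bad:
            raise ConfigError(f"unknown initial_state key(s): {sorted(bad)}")
        state = {k: float(v) for k, v in state.items()}
    if merged["model"] not in ("full", "reduced5", "reduced2"):
        raise ConfigError(f"unknown model tag {merged['model']!r}")
    conserved = ConservedTriple.from_pool_sum(float(merged["cpool"]),
                                              float(merged["csum"]))
    return {
        "params": params,
        "conserved": conserved,
        "model": merged["model"],
        "t_end": float(merged["t_end"]),
        "sample_dt": float(merged["sample_dt"]),
        "seed": int(merged["seed"]),
        "initial_state": state,
    }


def load_config(path) -> dict:
    """Load and validate a YAML/JSON configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    return validate_config(raw)


def dump_config(bundle: Mapping, path) -> None:
    """Write a validated bundle back to a flat YAML file (round-trips)."""
    out = dict(dataclasses.asdict(bundle["params"]))
    out.update(cpool=bundle["conserved"].cpool, csum=bundle["conserved"].csum,
               model=bundle["model"], t_end=bundle["t_end"],
               sample_dt=bundle["sample_dt"], seed=bundle["seed"])
    if bundle.get("initial_state"):
        out["initial_state"] = dict(bundle["initial_state"])
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


def _fmt(x) -> str:
    return "%.12g" % x


def write_trajectory(traj: Trajectory, path) -> None:
    """Trajectory as TSV: time column plus the model's state columns,
    full double precision, deterministic bytes."""
    cols = [c for c in FRAME_COLS.get(traj.model_tag, traj.frame.columns)
            if c in traj.frame.columns and c not in ("c_t", "cstar_t")] \
        if traj.model_tag in FRAME_COLS else list(traj.frame.columns)
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(cols) + "\n")
        for t, row in zip(traj.times, traj.frame[cols].itertuples(index=False)):
            fh.write(_fmt(t) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_trajectory(path) -> tuple:
    """Read back a trajectory TSV as (times, frame)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    return df["time"].to_numpy(), df.drop(columns=["time"])


def write_report(mapping: Mapping, path) -> None:
    """Key/value report as JSON with sorted keys (reproducible diffs)."""
    def conv(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        return v
    with open(path, "w") as fh:
        json.dump({k: conv(v) for k, v in mapping.items()}, fh,
                  sort_keys=True, indent=1)
        fh.write("\n")


def _log_run(name: str, config: Mapping, seed) -> None:
    digest = hashlib.sha256(
        json.dumps({k: repr(v) for k, v in sorted(config.items())}).encode()
    ).hexdigest()[:16]
    log.info("run %s: config sha256=%s seed=%s cccsim=%s python=%s",
             name, digest, seed, __version__, sys.version.split()[0])


# ---------------------------------------------------------------------------
# experiment presets
# ---------------------------------------------------------------------------

def _preset_step(outdir: Path, seed: int, params: CCCParams,
                 conserved: ConservedTriple) -> dict:
    traj = step_response(params, kin_before=1.1, kin_after=0.9,
                         pre_run=100.0, t_end=2000.0, conserved=conserved)
    write_trajectory(traj, outdir / "fig2a_trajectory.tsv")
    return {"kin_before": 1.1, "kin_after": 0.9,
            "m0_at_switch": float(traj.frame["m0"].iloc[0])}


def _preset_relax_scan(outdir: Path, seed: int, params: CCCParams,
                       conserved: ConservedTriple) -> dict:
    kins = [0.90, 0.92, 0.94, 0.96, 0.97, 0.98]
    res = relaxation_scan(params.replace(kleak=0.0), kins, conserved)
    with open(outdir / "fig2b_scan.tsv", "w") as fh:
        fh.write("kin\ttau\n")
        for k, tau in zip(res.kin_values, res.tau_values):
            fh.write(f"{_fmt(k)}\t{_fmt(tau)}\n")
    return {"fitted_exponent": res.fitted_exponent,
            "kin_th": res.kin_th_used}


def _preset_nullclines(outdir: Path, seed: int, params: CCCParams,
                       conserved: ConservedTriple) -> dict:
    grid = np.linspace(1e-6, conserved.csum * 0.999, 200)
    out = {}
    for kin in (0.8, kin_threshold(params.replace(kleak=0.0),
                                   conserved.cpool, conserved.csum), 1.2):
        nc = nullclines(params.replace(kin=kin, kleak=0.0), conserved, grid)
        tag = f"kin_{kin:.6g}"
        with open(outdir / f"fig3_nullclines_{tag}.tsv", "w") as fh:
            fh.write("m1\tm0_nullcline\tm1_nullcline\n")
            for a, b, c in zip(grid, nc.m0_nullcline, nc.m1_nullcline):
                fh.write(f"{_fmt(a)}\t{_fmt(b)}\t{_fmt(c)}\n")
        diff = nc.m0_nullcline - nc.m1_nullcline
        ok = np.isfinite(diff)
        out[tag] = bool(np.any(np.sign(diff[ok])[:-1] != np.sign(diff[ok])[1:]))
    return {"crossing": out}


def _preset_freq_sweep(outdir: Path, seed: int, params: CCCParams,
                       conserved: ConservedTriple) -> dict:
    p = params.replace(kleak=1e-3)
    ains = [0.1, 0.4, 0.7, 1.0]
    freqs = np.geomspace(1e-4, 3e-2, 8)
    grid = response_map(p, ains, freqs, kin0=1.0, conserved=conserved)
    with open(outdir / "fig4_response.tsv", "w") as fh:
        fh.write("f\t" + "\t".join(f"Ain_{a:g}" for a in ains)
                 + "\tcutoff_of_row_Ain\n")
        for i, f in enumerate(freqs):
            fh.write(_fmt(f) + "\t"
                     + "\t".join(_fmt(v) for v in grid.response[i]) + "\t-\n")
        fh.write("cutoff\t" + "\t".join(_fmt(v) for v in grid.cutoff_curve)
                 + "\t-\n")
    return {"cutoffs": {f"{a:g}": float(c)
                        for a, c in zip(ains, grid.cutoff_curve)}}


def _preset_fig5(outdir: Path, seed: int, params: CCCParams,
                 conserved: ConservedTriple) -> dict:
    rows = []
    for i, cpool in enumerate([20, 50, 100, 150, 200, 250, 300, 400]):
        kin = 100.0
        saturated = cpool < 2 * kin
        cfg = SSAConfig(seed=seed + i, t_end=30_000.0 / max(cpool, 100),
                        burn_in=50.0 / max(params.kc, params.kp))
        traj = ssa_limit(params.kc, params.kp, cmax=cpool, kin=kin,
                         saturated=saturated, config=cfg,
                         n0=cpool // 2 if saturated else int(kin / params.kp))
        st = count_statistics(traj, cfg.burn_in)
        rows.append((cpool, st.mean, st.fano))
    with open(outdir / "fig5a_sweep.tsv", "w") as fh:
        fh.write("cpool\tmean_m1\tfano\n")
        for r in rows:
            fh.write("\t".join(_fmt(v) for v in r) + "\n")
    return {"fano_smallest_pool": rows[0][2], "fano_largest_pool": rows[-1][2]}


def _preset_s1fig(outdir: Path, seed: int, params: CCCParams,
                  conserved: ConservedTriple) -> dict:
    traj = carrier_ratio_perturbation(params.replace(kin=0.6, kleak=0.0),
                                      ratio_active_after=0.99,
                                      conserved=conserved)
    write_trajectory(traj, outdir / "s1fig_trajectory.tsv")
    return {"t_end": float(traj.times[-1])}


def _preset_s6fig(outdir: Path, seed: int, params: CCCParams,
                  conserved: ConservedTriple) -> dict:
    paths = []
    for i in range(3):
        cfg = SSAConfig(seed=seed + i, t_end=50.0)
        traj = ssa_double_mm(1.0, 1.0, c1=100, c2=100, n0=100, config=cfg)
        fname = outdir / f"s6fig_path{i}.tsv"
        with open(fname, "w") as fh:
            fh.write("time\tn\n")
            for t, n in zip(traj.times, traj.counts):
                fh.write(f"{_fmt(t)}\t{int(n)}\n")
        paths.append(str(fname))
    return {"paths": len(paths)}


def _preset_s8fig(outdir: Path, seed: int, params: CCCParams,
                  conserved: ConservedTriple) -> dict:
    base = params.replace(kleak=0.0)
    variants = {
        "A": CoupledParams((base, base.replace(kin=1.0, K0=1e2)),
                           cpool=conserved.cpool),
        "B": CoupledParams((base, base.replace(kin=0.1, kleak=1.0, K0=1e-3)),
                           cpool=conserved.cpool),
    }
    out = {}
    for tag, cp in variants.items():
        traj = coupled_step_response(cp, 1.1, 0.9, t_end=2000.0)
        write_trajectory(traj, outdir / f"s8fig_{tag}.tsv")
        out[tag] = float(traj.frame["m0_1"].iloc[-1])
    return {"final_m0_1": out}


PRESETS = {
    "fig2a": _preset_step,
    "fig2b-scan": _preset_relax_scan,
    "fig3-nullclines": _preset_nullclines,
    "fig4-sweep": _preset_freq_sweep,
    "fig5-sweep": _preset_fig5,
    "s1fig": _preset_s1fig,
    "s6fig": _preset_s6fig,
    "s8fig": _preset_s8fig,
}


def run_preset(name: str, outdir, seed: int = 0,
               params: Optional[CCCParams] = None,
               conserved: Optional[ConservedTriple] = None) -> dict:
    """Run a named figure protocol; writes files and returns a summary."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = CCCParams()
    if conserved is None:
        from .params import DEFAULT_CONSERVED
        conserved = DEFAULT_CONSERVED
    _log_run(name, {"params": params, "conserved": conserved}, seed)
    summary = PRESETS[name](outdir, seed, params, conserved)
    summary = {"preset": name, "seed": seed, **summary}
    write_report(summary, outdir / f"{name.replace('-', '_')}_summary.json")
    return summary
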