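"""Persistence: run manifests, CSV summary tables, and XYZ snapshots.

All outputs are plain text. Every table starts with a ``#`` comment line
stating the units (time in MCS, energies in k_B*T, lengths in units of
the maximum bond extension); read them back with ``comment='#'``.
A manifest plus the package reproduces every output bit-exactly
(timestamps aside), since each sample is determined by one integer seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import EnsembleResult
from .geometry import Conformation
from .observables import tau_histogram, waiting_profile
from .params import SimParams
from .scaling import SweepResult, SweepSpec

__all__ = ["write_xyz", "read_xyz", "write_ensemble", "write_sweep",
           "load_sweep_spec", "read_records"]

_UNITS = "# units: time in MCS, energy in kBT, length in units of lmax"


def _prepare_dir(out_dir: str | Path, force: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"{out} is not empty; pass force=True (--force) to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_UNITS + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# XYZ snapshots
# ---------------------------------------------------------------------------

def write_xyz(path: str | Path, frames, comments=None) -> None:
    """Write one or more conformations as standard XYZ frames."""
    if isinstance(frames, Conformation):
        frames = [frames]
    arrs = [f.positions if isinstance(f, Conformation) else np.asarray(f)
            for f in frames]
    with open(path, "w") as fh:
        for k, pos in enumerate(arrs):
            comment = (comments[k] if comments is not None
                       else f"frame {k}")
            fh.write(f"{len(pos)}\n{comment}\n")
            for x, y, z in pos:
                fh.write(f"C {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str | Path) -> list[Conformation]:
    """Read an XYZ trajectory back into a list of conformations."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        pos = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(Conformation(pos))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# ensemble outputs
# ---------------------------------------------------------------------------

def _manifest(params: SimParams, base_seed: int, n_samples: int,
              outputs: list[str]) -> dict:
    return {
        "poreslab_version": __version__,
        "params": params.to_dict(),
        "base_seed": int(base_seed),
        "n_samples": int(n_samples),
        "sample_seeds": [int(base_seed) + i for i in range(int(n_samples))],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }


def write_ensemble(ens: EnsembleResult, out_dir: str | Path, *,
                   base_seed: int | None = None,
                   force: bool = False) -> Path:
    """Write manifest, summary, per-sample records, W(s) table, histogram
    (when enough samples), and the final conformations as XYZ."""
    out = _prepare_dir(out_dir, force)
    p = ens.params
    seed0 = p.base_seed if base_seed is None else int(base_seed)
    n_total = ens.n_success + ens.n_failed

    summary = pd.DataFrame([{
        "n_bonds": p.n_bonds, "kappa": p.kappa, "e_field": p.e_field,
        "r_sep": p.r_sep, "n_success": ens.n_success, "n_failed": ens.n_failed,
        "tau_mean": ens.tau_mean, "tau_se": ens.tau_se,
        "acceptance_mean": ens.acceptance_mean,
    }])
    _write_csv(summary, out / "summary.csv")

    records = pd.DataFrame([{
        "seed": r.seed, "tau": r.tau, "attempts": r.attempts,
        "acceptance_rate": r.acceptance_rate,
        "relax_mcs": r.relax_mcs_used,
    } for r in ens.records])
    _write_csv(records, out / "records.csv")

    wmean, wse = waiting_profile(ens)
    wtab = pd.DataFrame({"s": np.arange(len(wmean)), "w_mean": wmean,
                         "w_se": wse})
    _write_csv(wtab, out / "waiting.csv")

    # full per-sample waiting matrix so observables can be recomputed
    wmat = pd.DataFrame(
        np.stack([r.waiting for r in ens.records]),
        columns=[f"s{j}" for j in range(len(wmean))])
    wmat.insert(0, "seed", [r.seed for r in ens.records])
    _write_csv(wmat, out / "waiting_matrix.csv")

    outputs = ["summary.csv", "records.csv", "waiting.csv",
               "waiting_matrix.csv", "final.xyz"]
    if ens.n_success >= 20:
        h = tau_histogram(ens)
        htab = pd.DataFrame({"bin_lo": h.bin_edges[:-1],
                             "bin_hi": h.bin_edges[1:],
                             "density": h.densities})
        _write_csv(htab, out / "histogram.csv")
        outputs.append("histogram.csv")

    write_xyz(out / "final.xyz",
              [r.final_conformation for r in ens.records],
              comments=[f"seed {r.seed} tau {r.tau}" for r in ens.records])

    (out / "manifest.json").write_text(
        json.dumps(_manifest(p, seed0, n_total, outputs), indent=2) + "\n")
    return out


def read_records(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back (records, waiting_matrix) tables written by write_ensemble."""
    out = Path(out_dir)
    return (_read_csv(out / "records.csv"),
            _read_csv(out / "waiting_matrix.csv"))


# ---------------------------------------------------------------------------
# sweep outputs
# ---------------------------------------------------------------------------

def write_sweep(res: SweepResult, out_dir: str | Path, *,
                force: bool = False) -> Path:
    """Write the sweep table and the power-law fit record."""
    out = _prepare_dir(out_dir, force)
    _write_csv(pd.DataFrame(res.table()), out / "sweep.csv")
    fit = dataclasses.asdict(res.fit)
    fit["parameter"] = res.spec.parameter
    fit["fit_range"] = list(res.spec.fit_range) if res.spec.fit_range else None
    (out / "fit.json").write_text(json.dumps(fit, indent=2) + "\n")
    manifest = {
        "poreslab_version": __version__,
        "spec": {
            "parameter": res.spec.parameter,
            "grid": [float(v) for v in res.spec.grid],
            "n_samples": res.spec.n_samples,
            "base_seed": res.spec.base_seed,
            "fit_range": (list(res.spec.fit_range)
                          if res.spec.fit_range else None),
            "base_params": res.spec.base.to_dict(),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": ["sweep.csv", "fit.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def load_sweep_spec(path: str | Path) -> SweepSpec:
    """Load a SweepSpec from YAML/JSON.

    Schema: ``parameter`` (str), ``grid`` (list of numbers), optional
    ``n_samples``, ``base_seed``, ``fit_range`` ([lo, hi]) and ``base``
    (a SimParams mapping; missing keys take the model defaults).
    """
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text)) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: sweep spec must be a mapping")
    known = {"parameter", "grid", "n_samples", "base_seed", "fit_range", "base"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown sweep-spec keys: {sorted(unknown)}")
    if "parameter" not in data or "grid" not in data:
        raise ValueError("sweep spec requires 'parameter' and 'grid'")
    base = SimParams.from_dict(data.get("base", {}))
    kwargs = {}
    if "n_samples" in data:
        kwargs["n_samples"] = int(data["n_samples"])
    if "base_seed" in data:
        kwargs["base_seed"] = int(data["base_seed"])
    if data.get("fit_range") is not None:
        lo, hi = data["fit_range"]
        kwargs["fit_range"] = (float(lo), float(hi))
    return SweepSpec(parameter=str(data["parameter"]),
                     grid=tuple(float(v) for v in data["grid"]),
                     base=base, **kwargs)
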