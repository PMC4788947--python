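"""Persistence of run artifacts: versioned CSV tables plus a JSON manifest.

Every CSV starts with a ``# schema: <name>-v1`` comment line (pandas reads
them back with ``comment='#'``); the manifest records the schema versions,
the seed, a hash of the configuration and the list of files written, so a
results directory is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import DECISION_NAMES
from .optimize import Individual, ParetoApproximation

__all__ = [
    "SCHEMA_VERSION",
    "write_table",
    "read_table",
    "write_pareto",
    "read_pareto",
    "persist_results",
]

SCHEMA_VERSION = 1


def write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> None:
    """CSV with a schema tag comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema: {schema}-v{SCHEMA_VERSION}\n")
        # %.17g round-trips float64 exactly
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_pareto(pareto: ParetoApproximation, path: str | Path,
                 names=DECISION_NAMES) -> None:
    write_table(pareto.to_frame(names=names), path, "pareto")


def read_pareto(path: str | Path, names=DECISION_NAMES) -> ParetoApproximation:
    """Rebuild a Pareto approximation from its CSV.

    Archive members were admissible when written, so flags are restored
    as pertinent/feasible with zero violation.
    """
    frame = read_table(path)
    missing = {"J1", "J2", "P", *names} - set(frame.columns)
    if missing:
        raise ConfigError(f"pareto CSV missing columns: {sorted(missing)}")
    individuals = [
        Individual(
            theta=np.array([row[n] for n in names], dtype=float),
            J=(float(row["J1"]), float(row["J2"])),
            P=float(row["P"]),
            violation=0.0,
            pertinent=True,
            feasible=True,
        )
        for _, row in frame.iterrows()
    ]
    return ParetoApproximation(individuals=individuals)


def persist_results(
    outdir: str | Path,
    seed: int,
    config_hash: str,
    pareto: Optional[ParetoApproximation] = None,
    guidelines=None,
    ld_table: Optional[pd.DataFrame] = None,
    sweeps: Optional[dict] = None,
    load_comparison=None,
    extra: Optional[dict] = None,
) -> dict:
    """Write all provided artifacts and a manifest enumerating them.

    Returns the manifest dict (also saved as ``manifest.json``).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise ConfigError(f"output directory {outdir} is not writable: {exc}") from exc

    files: dict[str, str] = {}
    if pareto is not None:
        write_pareto(pareto, outdir / "pareto.csv")
        files["pareto"] = "pareto.csv"
        meta = {
            "seed": pareto.seed,
            "evaluations": pareto.evaluations,
            **pareto.meta,
        }
        (outdir / "pareto_meta.json").write_text(json.dumps(meta, indent=2))
        files["pareto_meta"] = "pareto_meta.json"
    if guidelines is not None:
        write_table(guidelines.to_frame(), outdir / "guidelines.csv", "guidelines")
        files["guidelines"] = "guidelines.csv"
        pvals = {
            e.name: {"H": e.H, "p": e.p_value, "category": e.category}
            for e in guidelines.entries
        }
        (outdir / "guidelines_stats.json").write_text(
            json.dumps({"k": guidelines.k, "alpha": guidelines.alpha,
                        "parameters": pvals}, indent=2)
        )
        files["guidelines_stats"] = "guidelines_stats.json"
    if ld_table is not None:
        write_table(ld_table, outdir / "ld.csv", "leveldiagram")
        files["leveldiagram"] = "ld.csv"
    if sweeps:
        for name, sweep in sweeps.items():
            fname = f"sweep_{name}.csv"
            write_table(sweep.to_frame(), outdir / fname, "sweep")
            files[f"sweep_{name}"] = fname
    if load_comparison is not None:
        write_table(load_comparison.to_frame(), outdir / "load.csv", "load")
        files["load"] = "load.csv"

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config_hash": config_hash,
        "files": files,
        **(extra or {}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
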