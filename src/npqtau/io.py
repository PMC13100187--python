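"""Delimited-text I/O for snapshot series, pigment tables and results.

All formats are plain text so fixtures and measured data interchange:
snapshot CSVs (``genotype, sequence, time_s, tau_ns, se_ns, n_reps``),
pigment CSVs (``genotype, condition, pigment, concentration``), decay
histograms (two-column ``time_ps, counts``) and JSON parameter files
(see :mod:`npqtau.parameters`).  Validation failures name the offending
row and field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecayHistogram
from .fitting import Dataset, FitResult

SNAPSHOT_COLUMNS = ["genotype", "sequence", "time_s", "tau_ns", "se_ns",
                    "n_reps"]
PIGMENT_COLUMNS = ["genotype", "condition", "pigment", "concentration"]


class SchemaError(ValueError):
    """A data file violates the expected schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def write_snapshots(path: str | Path, datasets: list[Dataset]) -> None:
    rows = []
    for ds in datasets:
        for t, tau, se in zip(ds.times, ds.tau, ds.se):
            rows.append({"genotype": ds.genotype, "sequence": ds.sequence,
                         "time_s": t, "tau_ns": tau, "se_ns": se,
                         "n_reps": ds.n_replicates})
    pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS).to_csv(path, index=False)


def read_snapshots(path: str | Path) -> list[Dataset]:
    df = pd.read_csv(path)
    _require_columns(df, SNAPSHOT_COLUMNS, path)
    bad = df.index[df["tau_ns"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive tau_ns at row {bad[0] + 2}")
    bad = df.index[df["se_ns"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive se_ns at row {bad[0] + 2}")
    datasets = []
    for (genotype, sequence), grp in df.groupby(["genotype", "sequence"],
                                                sort=False):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise SchemaError(
                f"{path}: non-monotone time_s for {genotype}:{sequence}")
        datasets.append(Dataset(
            genotype=str(genotype), sequence=str(sequence), times=times,
            tau=grp["tau_ns"].to_numpy(dtype=float),
            se=grp["se_ns"].to_numpy(dtype=float),
            n_replicates=int(grp["n_reps"].iloc[0]),
        ))
    return datasets


def write_pigments(path: str | Path, table: pd.DataFrame) -> None:
    _require_columns(table, PIGMENT_COLUMNS, path)
    table[PIGMENT_COLUMNS].to_csv(path, index=False)


def read_pigments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PIGMENT_COLUMNS, path)
    bad = df.index[df["concentration"] < 0]
    if len(bad):
        raise SchemaError(
            f"{path}: negative concentration at row {bad[0] + 2}")
    return df


def pigment_overrides(table: pd.DataFrame,
                      condition: str = "dark") -> dict[str, dict[str, float]]:
    """Per-genotype dark pigment pools {V_0, A_0, Z_0, L_0} from a table.

    Genotype names are matched case-insensitively by callers via
    :func:`npqtau.genotypes.get_genotype`.
    """
    out: dict[str, dict[str, float]] = {}
    sel = table[table["condition"].str.lower() == condition.lower()]
    for genotype, grp in sel.groupby("genotype"):
        pools = {}
        for _, row in grp.iterrows():
            pools[f"{row['pigment']}_0"] = float(row["concentration"])
        out[str(genotype)] = pools
    return out


def write_histogram(path: str | Path, h: DecayHistogram) -> None:
    pd.DataFrame({"time_ps": h.bin_times, "counts": h.counts}).to_csv(
        path, index=False)


def read_histogram(path: str | Path, integration_s: float = 1.0,
                   snapshot_time: float = 0.0) -> DecayHistogram:
    df = pd.read_csv(path)
    _require_columns(df, ["time_ps", "counts"], path)
    return DecayHistogram(
        bin_times=df["time_ps"].to_numpy(dtype=float),
        counts=df["counts"].to_numpy(),
        integration_s=integration_s, snapshot_time=snapshot_time,
    )


def write_registry(path: str | Path,
                   registry: dict[str, "GenotypeSpec"]) -> None:
    """Serialize a genotype registry as a JSON list of records."""
    import json

    records = []
    for g in registry.values():
        records.append({
            "name": g.name,
            "zeroed_rates": list(g.zeroed_rates),
            "scaled_rates": {n: f for n, f in g.scaled_rates},
            "use_starred_PX": g.use_starred_PX,
            "initial_pigments": g.pigments,
            "tau_dark0": g.tau_dark0,
        })
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_registry(path: str | Path) -> dict[str, "GenotypeSpec"]:
    import json

    from .parameters import GenotypeSpec

    registry = {}
    for rec in json.loads(Path(path).read_text()):
        g = GenotypeSpec(
            name=rec["name"],
            zeroed_rates=tuple(rec.get("zeroed_rates", ())),
            scaled_rates=tuple(sorted(rec.get("scaled_rates", {}).items())),
            use_starred_PX=bool(rec.get("use_starred_PX", False)),
            initial_pigments=tuple(
                sorted(rec.get("initial_pigments", {}).items())),
            tau_dark0=float(rec.get("tau_dark0", 2.0)),
        )
        registry[g.name] = g
    return registry


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "theta": fit.theta,
        "kinetic": fit.kinetic.as_dict(),
        "quenching": fit.quenching.as_dict(),
        "v0": fit.v0,
        "delta2": fit.delta2,
        "rmsd_tau_ns": fit.rmsd_tau,
        "rmsd_rate_ns_inv": fit.rmsd_rate,
        "ci95": {k: list(v) for k, v in fit.ci.items()},
        "seed": fit.seed,
        "stage_delta2": fit.stage_delta2,
    }
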