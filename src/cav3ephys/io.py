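"""File formats: tidy sweep CSVs with '#' metadata headers, YAML parameter
configs, and cohort manifests."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .channel_model import GatingParams, TauParams
from .protocols import VoltageProtocol

__all__ = [
    "save_params",
    "load_params",
    "write_traces_csv",
    "read_traces_csv",
    "write_cohort",
    "read_cohort",
]


def save_params(p: GatingParams, path) -> None:
    """GatingParams -> YAML, one key per field (units: mV, ms, nS)."""
    d = dataclasses.asdict(p)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_params(path) -> GatingParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["tau_m_params"] = TauParams(**d["tau_m_params"])
    d["tau_h_params"] = TauParams(**d["tau_h_params"])
    return GatingParams(**d)


def write_traces_csv(df: pd.DataFrame, path, protocol: VoltageProtocol, meta: dict | None = None) -> None:
    """Sweep table CSV with '#'-prefixed JSON header lines carrying the
    protocol descriptor and free-form metadata."""
    with open(path, "w") as fh:
        fh.write("# protocol: " + json.dumps(protocol.to_dict()) + "\n")
        if meta:
            fh.write("# meta: " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False)


def read_traces_csv(path):
    """Returns ``(df, protocol, meta)``."""
    protocol = None
    meta: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, payload = line[1:].partition(":")
            key = key.strip()
            if key == "protocol":
                protocol = VoltageProtocol.from_dict(json.loads(payload))
            elif key == "meta":
                meta = json.loads(payload)
    df = pd.read_csv(path, skiprows=skip)
    return df, protocol, meta


def write_cohort(cohort, outdir) -> Path:
    """Write a cohort as per-cell trace CSVs plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        act_path = outdir / f"{rec.cell_id}_activation.csv"
        inact_path = outdir / f"{rec.cell_id}_inactivation.csv"
        truth = dataclasses.asdict(rec.truth)
        meta = {"cell_id": rec.cell_id, "group": rec.group, "mode": rec.mode,
                "noise_sd": rec.noise_sd, "seed": rec.seed, "truth": truth}
        write_traces_csv(rec.activation_sweeps, act_path, rec.act_protocol, meta)
        write_traces_csv(rec.inactivation_sweeps, inact_path, rec.inact_protocol, meta)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "group": rec.group,
                "mode": rec.mode,
                "noise_sd": rec.noise_sd,
                "seed": rec.seed,
                "activation_file": act_path.name,
                "inactivation_file": inact_path.name,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(outdir) -> list:
    """Rebuild CellRecording objects from a written cohort directory."""
    from .synthetic_data import CellRecording

    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    cohort = []
    for _, row in manifest.iterrows():
        act_df, act_proto, meta = read_traces_csv(outdir / row["activation_file"])
        inact_df, inact_proto, _ = read_traces_csv(outdir / row["inactivation_file"])
        truth = meta.get("truth")
        params = None
        if truth:
            truth["tau_m_params"] = TauParams(**truth["tau_m_params"])
            truth["tau_h_params"] = TauParams(**truth["tau_h_params"])
            params = GatingParams(**truth)
        cohort.append(
            CellRecording(
                cell_id=row["cell_id"],
                group=row["group"],
                truth=params,
                act_protocol=act_proto,
                inact_protocol=inact_proto,
                activation_sweeps=act_df,
                inactivation_sweeps=inact_df,
                noise_sd=float(row["noise_sd"]),
                mode=row["mode"],
                seed=None if pd.isna(row["seed"]) else int(row["seed"]),
            )
        )
    return cohort
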