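"""Parameter, forcing and dataset file I/O plus run manifests.

Parameter files are flat YAML key-value tables using the tabulated DEB
symbol names plus an ``aux`` block; three species fixtures ship with the
package (``o_edulis``, ``c_gigas_amp``, ``c_gigas_std``). Delimited
tables are comma-separated UTF-8 with a mandatory header row and "."
decimals; dates are converted to days-since-start at ingest.
"""

from __future__ import annotations

import json
import platform
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .environment import Forcing
from .params import DEBParams

__all__ = [
    "SPECIES",
    "load_species",
    "read_params",
    "write_params",
    "read_forcing",
    "write_forcing",
    "save_observations",
    "load_observations",
    "write_run_manifest",
]

SPECIES = ("o_edulis", "c_gigas_amp", "c_gigas_std")


def load_species(name: str) -> DEBParams:
    """Load one of the packaged species parameter sets by name."""
    if name not in SPECIES:
        raise KeyError(f"unknown species {name!r}; packaged: {list(SPECIES)}")
    with resources.files("oysterdeb.data").joinpath(f"{name}.yaml").open("r") as fh:
        return DEBParams.from_dict(yaml.safe_load(fh))


def read_params(path: Union[str, Path]) -> DEBParams:
    """Read a parameter file (flat YAML key-value table)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return DEBParams.from_dict(data)


def write_params(params: DEBParams, path: Union[str, Path]) -> None:
    """Write a parameter set; ``read_params(write_params(p)) == p``."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def read_forcing(path: Union[str, Path], food_mode: str = "auto") -> Forcing:
    """Read a forcing table (columns: day or date, temperature_C, chl_ugL or f).

    A ``date`` column is converted to days since the first record.
    """
    df = pd.read_csv(path)
    if "day" not in df.columns:
        if "date" not in df.columns:
            raise ValueError("forcing table needs a 'day' or 'date' column")
        dates = pd.to_datetime(df["date"])
        df = df.assign(day=(dates - dates.iloc[0]).dt.total_seconds() / 86400.0)
    return Forcing.from_dataframe(df, food_mode=food_mode)


def write_forcing(forcing: Forcing, path: Union[str, Path]) -> None:
    forcing.to_dataframe().to_csv(path, index=False)


def save_observations(datasets, out_dir: Union[str, Path]) -> Path:
    """Write an observation collection to a directory.

    Zero-variate data go to ``zero_variate.csv`` (name, value, unit,
    weight, context columns, ref); each uni-variate dataset gets its own
    CSV (x, y, weight) plus, if its context carries a Forcing, a forcing
    CSV; ``manifest.yaml`` ties everything together.
    """
    from .estimation import UniVariateDataset, ZeroVariateDatum

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    zrows, manifest = [], []
    for ds in datasets:
        if isinstance(ds, ZeroVariateDatum):
            row = {"name": ds.name, "value": ds.value, "unit": ds.unit,
                   "weight": ds.weight, "ref": ds.ref}
            for k, v in ds.context.items():
                row[k] = v
            zrows.append(row)
            continue
        assert isinstance(ds, UniVariateDataset)
        fname = f"{ds.name}.csv"
        pd.DataFrame({"x": ds.x, "y": ds.y, "weight": ds.weights}).to_csv(
            out / fname, index=False
        )
        ctx = dict(ds.context)
        forcing = ctx.pop("forcing", None)
        entry = {"name": ds.name, "kind": ds.kind, "response": ds.response,
                 "file": fname, "context": _jsonable(ctx), "ref": ds.ref}
        if forcing is not None:
            ffile = f"{ds.name}_forcing.csv"
            write_forcing(forcing, out / ffile)
            entry["forcing_file"] = ffile
        manifest.append(entry)
    if zrows:
        pd.DataFrame(zrows).to_csv(out / "zero_variate.csv", index=False)
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out


def load_observations(data_dir: Union[str, Path]) -> list:
    """Read back an observation collection written by :func:`save_observations`."""
    from .estimation import UniVariateDataset, ZeroVariateDatum

    data_dir = Path(data_dir)
    datasets: list = []
    zv = data_dir / "zero_variate.csv"
    if zv.exists():
        df = pd.read_csv(zv)
        meta = {"name", "value", "unit", "weight", "ref"}
        for _, row in df.iterrows():
            ctx = {k: row[k] for k in df.columns
                   if k not in meta and pd.notna(row[k])}
            datasets.append(ZeroVariateDatum(
                name=str(row["name"]), value=float(row["value"]),
                unit=str(row.get("unit", "") or ""),
                weight=float(row.get("weight", 1.0)),
                context=ctx, ref=str(row.get("ref", "") or ""),
            ))
    man = data_dir / "manifest.yaml"
    if man.exists():
        with open(man, "r", encoding="utf-8") as fh:
            entries = yaml.safe_load(fh) or []
        for e in entries:
            df = pd.read_csv(data_dir / e["file"])
            ctx = dict(e.get("context") or {})
            if e.get("forcing_file"):
                ctx["forcing"] = read_forcing(data_dir / e["forcing_file"])
            datasets.append(UniVariateDataset(
                name=e["name"], kind=e["kind"], x=df["x"].to_numpy(),
                y=df["y"].to_numpy(),
                weights=df["weight"].to_numpy() if "weight" in df else None,
                context=ctx, response=e.get("response", "dw_g"),
                ref=e.get("ref", ""),
            ))
    if not datasets:
        raise FileNotFoundError(f"no observations found under {data_dir}")
    return datasets


def write_run_manifest(out_dir: Union[str, Path], config: dict) -> Path:
    """Write a machine-readable manifest sufficient to reproduce a run."""
    import oysterdeb

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "oysterdeb",
        "version": getattr(oysterdeb, "__version__", "unknown"),
        "python": platform.python_version(),
        "config": _jsonable(config),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    import dataclasses

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, DEBParams):
        return obj.to_dict()
    if isinstance(obj, Forcing):
        return {k: _jsonable(list(v)) for k, v in obj.to_dataframe().items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)
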