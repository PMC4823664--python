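"""Reading and writing parameter configs and dose-response tables.

Parameter sets travel as YAML (one record per odor: name, n, eta, K);
curves and predictions as comma-separated tables with a header row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .models import OdorParams

__all__ = ["read_params", "write_params", "read_table", "write_table"]


def read_params(path) -> dict[str, OdorParams]:
    """Read odor parameter records from a YAML file.

    Accepts either a mapping ``{name: {n, eta, K}}`` or a list of records
    with a ``name`` key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raise ValidationError(f"empty parameter file: {path}")
    if isinstance(raw, list):
        records = {}
        for rec in raw:
            if "name" not in rec:
                raise ValidationError("list-style parameter records need a 'name'")
            records[rec["name"]] = rec
    elif isinstance(raw, dict):
        records = raw
    else:
        raise ValidationError("parameter file must hold a mapping or a list of records")
    out = {}
    for name, rec in records.items():
        try:
            out[name] = OdorParams(n=float(rec["n"]), eta=float(rec["eta"]),
                                   K=float(rec["K"]), name=name)
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"record {name!r} needs numeric n, eta, K") from exc
    return out


def write_params(params: dict[str, OdorParams], path) -> None:
    data = {
        name: {"n": float(p.n), "eta": float(p.eta), "K": float(p.K)}
        for name, p in params.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_table(path, units: str = "linear", odor: str | None = None) -> pd.DataFrame:
    """Read a delimited dose-response table (concentration, response)."""
    df = pd.read_csv(path)
    if not {"concentration", "response"} <= set(df.columns):
        raise ValidationError(f"{path}: table needs 'concentration' and 'response' columns")
    df.attrs["units"] = units
    df.attrs["odor"] = odor
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
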