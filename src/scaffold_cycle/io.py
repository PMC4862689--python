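"""Result serialization: fixed-column TSV/CSV tables with manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from scaffold_cycle.config import RunConfig

#: locale-independent numeric rendering: 9 significant digits, scientific
FLOAT_FORMAT = "%.9e"


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if np.issubdtype(out[col].dtype, np.floating):
            out[col] = out[col].map(lambda v: FLOAT_FORMAT % v)
    return out


def write_results(records: pd.DataFrame, path, fmt: str = "tsv",
                  config: RunConfig | None = None,
                  seed: int | None = None) -> dict:
    """Write a results table plus a sidecar manifest; return the manifest.

    The table has one header row and a documented fixed column order
    (whatever order ``records`` carries).  The manifest records the config
    hash, seed, software version, row count and the table's own sha256, so
    re-runs are verifiable byte-for-byte.
    """
    from scaffold_cycle import __version__

    if fmt not in ("tsv", "csv"):
        raise ValueError("format must be 'tsv' or 'csv'")
    sep = "\t" if fmt == "tsv" else ","
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = _format_frame(records).to_csv(sep=sep, index=False,
                                         lineterminator="\n")
    path.write_text(text)
    manifest = {
        "table": path.name,
        "format": fmt,
        "rows": int(len(records)),
        "columns": list(map(str, records.columns)),
        "sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": seed,
        "config_hash": config.content_hash() if config is not None else None,
        "version": __version__,
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_timecourse_tsv(timecourse, path) -> None:
    """Tidy TSV of a trajectory: time, nine species, four totals."""
    df = timecourse.to_frame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")
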