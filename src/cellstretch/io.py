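"""CSV/JSON persistence with provenance.

Every table written by the command-line tool is accompanied by a
``*.provenance.json`` sidecar carrying the full configuration echo, the
seed and the tool version, so any output can be regenerated exactly.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .config import RunConfig

log = logging.getLogger("cellstretch")


def setup_logging(verbose: int = 0) -> None:
    """Route log output to stderr; it never contaminates data streams."""
    level = logging.WARNING if verbose == 0 else logging.INFO if verbose == 1 else logging.DEBUG
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def provenance(config: RunConfig, subcommand: str, seed: Optional[int] = None) -> dict:
    return {
        "tool": "cellstretch",
        "version": __version__,
        "subcommand": subcommand,
        "seed": config.seed if seed is None else seed,
        "config": config.to_dict(),
    }


def write_table(
    df: pd.DataFrame,
    path: Union[str, Path],
    config: RunConfig,
    subcommand: str,
    seed: Optional[int] = None,
) -> Path:
    """Write a CSV (RFC-4180 style, UTF-8, '.' decimal) plus provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    side = path.with_suffix(path.suffix + ".provenance.json")
    side.write_text(
        json.dumps(provenance(config, subcommand, seed), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    log.info("wrote %s (%d rows)", path, len(df))
    return path


def write_summary(
    payload: dict,
    path: Union[str, Path],
    config: RunConfig,
    subcommand: str,
    seed: Optional[int] = None,
) -> Path:
    """Write a JSON summary embedding its provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = dict(payload)
    body["provenance"] = provenance(config, subcommand, seed)
    path.write_text(json.dumps(body, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    log.info("wrote %s", path)
    return path
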