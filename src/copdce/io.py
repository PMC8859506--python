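"""Result serialisation and run manifests.

CSV cells are numeric or plain labels (no currency symbols); a sidecar
metadata JSON names units and records the run manifest: command, config
digest, seeds, package version, timestamp and the files written.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd


@dataclass
class RunManifest:
    command: str
    config_digest: str
    seed: int | None
    package_version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)
    units: dict[str, str] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


DEFAULT_UNITS = {
    "costs": "GBP at 2018 prices",
    "lys": "life-years, discounted unless suffixed _undiscounted",
    "qalys": "quality-adjusted life-years, discounted",
    "icer": "GBP per QALY (or per LY where named)",
    "wtp": "GBP per QALY",
    "events": "expected lifetime events per patient, undiscounted",
}


def config_digest(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def make_manifest(command: str, config_path: Union[str, Path], seed: int | None,
                  outputs: list[Path], notes: dict[str, str] | None = None) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        config_digest=config_digest(config_path),
        seed=seed,
        package_version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=[str(p) for p in outputs],
        units=dict(DEFAULT_UNITS),
        notes=notes or {
            "person_time": "decedents credited 0.5 cycle of LYs/QALYs/costs",
            "trial_year_discounting": "year 1 is discount period 0 (undiscounted)",
        },
    )


def write_table(df: pd.DataFrame, path: Union[str, Path], index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, index=index)
    return path
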