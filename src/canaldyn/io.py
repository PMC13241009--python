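"""Cohort container formats and run configuration.

Two interchangeable on-disk dialects hold a cohort of trace sets:

* an HDF5 file (``.h5``/``.hdf5``) with one group per fish (``dff``
  dataset; ``fish_id``/``genotype``/``protocol`` attributes), full float64
  precision;
* a directory of per-fish CSV matrices plus a ``metadata.json`` carrying
  fish metadata and the protocol; CSV values are written with 17
  significant digits so the round trip is bit-exact.

``write_cohort`` followed by ``read_cohort`` is the identity on values and
metadata in both dialects.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .protocol import StimulusProtocol
from .synthetic import TraceSet, CohortSpec


def _is_hdf5_path(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_cohort(cohort: list[TraceSet], path: str | Path) -> None:
    """Write a cohort to an HDF5 file or a CSV+JSON directory (by extension)."""
    path = Path(path)
    if not cohort:
        raise ValueError("cannot write an empty cohort")
    if _is_hdf5_path(path):
        with h5py.File(path, "w") as f:
            f.attrs["protocol"] = cohort[0].protocol.to_json()
            for ts in cohort:
                g = f.create_group(ts.fish_id)
                g.create_dataset("dff", data=ts.dff)
                g.attrs["fish_id"] = ts.fish_id
                g.attrs["genotype"] = ts.genotype
                g.attrs["protocol"] = ts.protocol.to_json()
    else:
        path.mkdir(parents=True, exist_ok=True)
        meta = {"protocol": cohort[0].protocol.to_dict(), "fish": {}}
        for ts in cohort:
            np.savetxt(path / f"{ts.fish_id}.csv", ts.dff, delimiter=",", fmt="%.17g")
            meta["fish"][ts.fish_id] = {"genotype": ts.genotype}
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))


def read_cohort(path: str | Path) -> list[TraceSet]:
    """Read a cohort container written by :func:`write_cohort`."""
    path = Path(path)
    if path.is_dir():
        meta_path = path / "metadata.json"
        if not meta_path.exists():
            raise ValueError(f"cohort directory {path} is missing metadata.json")
        meta = json.loads(meta_path.read_text())
        protocol = StimulusProtocol.from_dict(meta["protocol"])
        cohort = []
        for fish_id in sorted(meta["fish"]):
            entry = meta["fish"][fish_id]
            if "genotype" not in entry:
                raise ValueError(f"fish {fish_id!r} in {path} has no genotype attribute")
            csv_path = path / f"{fish_id}.csv"
            if not csv_path.exists():
                raise ValueError(f"missing trace file for fish {fish_id!r}: {csv_path}")
            dff = np.atleast_2d(np.loadtxt(csv_path, delimiter=","))
            cohort.append(
                TraceSet(fish_id=fish_id, genotype=entry["genotype"], dff=dff, protocol=protocol)
            )
        return cohort
    if not path.exists():
        raise FileNotFoundError(path)
    cohort = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            if "genotype" not in g.attrs:
                raise ValueError(f"group {name!r} in {path} has no genotype attribute")
            protocol = StimulusProtocol.from_json(g.attrs["protocol"])
            cohort.append(
                TraceSet(
                    fish_id=str(g.attrs.get("fish_id", name)),
                    genotype=str(g.attrs["genotype"]),
                    dff=g["dff"][...],
                    protocol=protocol,
                )
            )
    return cohort


@dataclasses.dataclass
class RunConfig:
    """Analysis-run configuration; round-trips losslessly through YAML/JSON."""

    protocol: dict = dataclasses.field(
        default_factory=lambda: dict(
            directions_count=12, stim_s=5.0, gap_s=10.0, n_trials=3,
            inter_trial_s=50.0, lead_in_s=45.0, rate_hz=1.0,
        )
    )
    z_thresh: float = 3.0
    k: int = 5
    reference_policy: str = "first"
    dsi_threshold: float = 1.0 / 3.0
    seed: int = 0
    control_path: str = ""
    group_paths: dict = dataclasses.field(default_factory=dict)
    out_dir: str = "report"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def build_protocol(self) -> StimulusProtocol:
        from .protocol import build_protocol

        return build_protocol(**self.protocol)


def spec_from_file(path: str | Path) -> CohortSpec:
    """Load a CohortSpec from a YAML/JSON mapping."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return CohortSpec.from_dict(data)
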