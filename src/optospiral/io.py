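"""Configuration, recording files and run manifests.

Configuration is YAML with one named block per model (tissue geometry,
membrane kinetics, ChR2 photocycle, analysis settings); a frozen default
ships with the package.  Recordings are HDF5 containers holding the voltage
movie (3D array with axis metadata), probe traces, the light log, and a full
configuration echo under a versioned schema.  Every campaign directory gets
a run manifest sufficient to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .cellmodels import ChR2Params, IonicParams
from .errors import ConfigError, RecordingIOError, StabilityError
from .tissue import Recording, TissueParams

SCHEMA_VERSION = "1"

DEFAULT_ANALYSIS = {
    "v_threshold": -50.0,       # binarization level before Canny (mV)
    "v_iso": -50.0,             # tip-tracking isopotential (mV)
    "canny_sigma": 1.0,         # Gaussian sigma, nodes
    "hough_radius_range": [2, 45],   # nodes
    "peak_prominence": 20.0,    # mV
    "peak_min_separation": 10.0,     # ms
}


@dataclass
class Config:
    tissue: TissueParams = field(default_factory=TissueParams)
    ionic: IonicParams = field(default_factory=IonicParams)
    chr2: ChR2Params = field(default_factory=ChR2Params)
    analysis: dict = field(default_factory=lambda: dict(DEFAULT_ANALYSIS))

    def to_dict(self) -> dict:
        return {
            "tissue": dataclasses.asdict(self.tissue),
            "ionic": dataclasses.asdict(self.ionic),
            "chr2": dataclasses.asdict(self.chr2),
            "analysis": dict(self.analysis),
        }


def default_config_path() -> Path:
    return Path(resources.files("optospiral").joinpath("data/default_config.yaml"))


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a configuration file (package default when ``path``
    is None).

    Unknown keys and stability violations raise :class:`ConfigError` listing
    the offenders; section contents are type-checked by the parameter
    dataclasses themselves.
    """
    path = default_config_path() if path is None else Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}

    known_sections = {"tissue", "ionic", "chr2", "analysis"}
    unknown = sorted(set(raw) - known_sections)
    if unknown:
        raise ConfigError(f"unknown config sections: {unknown}")

    def build(cls, section):
        data = raw.get(section, {}) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(data) - fields)
        if bad:
            raise ConfigError(f"unknown keys in [{section}]: {bad}")
        try:
            return cls(**data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid [{section}] parameters: {exc}") from exc

    cfg = Config(
        tissue=build(TissueParams, "tissue"),
        ionic=build(IonicParams, "ionic"),
        chr2=build(ChR2Params, "chr2"),
        analysis={**DEFAULT_ANALYSIS, **(raw.get("analysis", {}) or {})},
    )
    bad_analysis = sorted(set(cfg.analysis) - set(DEFAULT_ANALYSIS))
    if bad_analysis:
        raise ConfigError(f"unknown keys in [analysis]: {bad_analysis}")
    try:
        cfg.tissue.validate()
    except StabilityError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Recording HDF5
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    """Lossless HDF5 round-trip of frames, probes, light log and metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["package_version"] = __version__
        d = f.create_dataset("frames", data=rec.frames)
        d.attrs["axes"] = "t,y,x"
        d.attrs["units"] = "mV"
        f.create_dataset("frame_times", data=rec.frame_times)
        f.create_dataset("probe_times", data=rec.probe_times)
        g = f.create_group("probes")
        for name, trace in rec.probes.items():
            g.create_dataset(name, data=trace)
        f.attrs["light_log"] = json.dumps(rec.light_log)
        f.attrs["meta"] = json.dumps(rec.meta, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_recording(path: str | Path, migrate: bool = False) -> Recording:
    """Read a Recording container, optionally migrating a legacy layout.

    Version "0" files (pre-release layout: the movie stored as dataset ``V``
    with no schema attribute) are upgraded in place when ``migrate`` is set;
    otherwise a schema mismatch raises :class:`RecordingIOError`.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version is None and "V" in f:
                if not migrate:
                    raise RecordingIOError(
                        f"{path} uses the legacy (v0) layout; pass migrate=True to upgrade")
                rec = _read_legacy(f)
            elif version != SCHEMA_VERSION:
                if version is None:
                    raise RecordingIOError(f"{path} is not a recording container")
                raise RecordingIOError(
                    f"unsupported recording schema version {version!r} (expected {SCHEMA_VERSION!r})")
            else:
                rec = Recording(
                    frames=f["frames"][()],
                    frame_times=f["frame_times"][()],
                    probes={k: v[()] for k, v in f["probes"].items()},
                    probe_times=f["probe_times"][()],
                    light_log=json.loads(f.attrs["light_log"]),
                    meta=json.loads(f.attrs["meta"]),
                )
    except OSError as exc:
        raise RecordingIOError(f"cannot read {path}: {exc}") from exc
    if migrate and _is_legacy(path):
        write_recording(rec, path)
    return rec


def _is_legacy(path) -> bool:
    try:
        with h5py.File(path, "r") as f:
            return f.attrs.get("schema_version") is None and "V" in f
    except OSError:
        return False


def _read_legacy(f) -> Recording:
    frames = f["V"][()]
    times = f["t"][()] if "t" in f else np.arange(frames.shape[0], dtype=float)
    return Recording(frames=frames, frame_times=times,
                     probes={}, probe_times=np.array([]),
                     light_log=[], meta={"migrated_from": "0"})


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to re-execute a run: resolved config, seed, versions."""

    config_echo: dict
    seed: int | None = None
    code_version: str = __version__
    created: str = ""
    platform: str = ""

    def __post_init__(self):
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()
        if not self.platform:
            self.platform = platform.platform()


def write_manifest(directory: str | Path, cfg: Config, seed: int | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_echo=cfg.to_dict(), seed=seed)
    out = directory / "manifest.json"
    out.write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    return out


def read_manifest(directory: str | Path) -> RunManifest:
    data = json.loads((Path(directory) / "manifest.json").read_text())
    return RunManifest(**data)
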