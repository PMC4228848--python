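"""Trace/table file formats, run configuration and provenance.

Time convention: milliseconds internally, seconds in trace files; currents
always pA.  First-class trace dialects are tab-delimited text
(``time_s<TAB>current_pA`` with ``#`` comment headers) and a minimal Axon
Text File (ATF) dialect; Axon ABF is available through an optional adapter
(requires ``pyabf``).  All report writers embed a provenance block
(package version, seed, config hash) and use deterministic field ordering
and float formatting so a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

logger = logging.getLogger("patchdose")

__all__ = [
    "Trace",
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "write_report",
    "load_config",
    "config_hash",
]

_FLOAT_FMT = "{:.10g}"
# traces round-trip bit-exactly: full float64 precision
_TRACE_FLOAT_FMT = "{:.17g}"


def _fmt(x) -> str:
    if isinstance(x, float):
        return _FLOAT_FMT.format(x)
    return str(x)


@dataclass
class Trace:
    """Uniformly sampled current trace."""

    dt_ms: float
    samples: np.ndarray      # pA
    units: str = "pA"
    metadata: dict = field(default_factory=dict)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms / 1000.0


def _check_uniform(time_s: np.ndarray) -> float:
    """Return dt_ms, raising on the first non-uniform timestamp."""
    if len(time_s) < 2:
        raise ValueError("trace needs at least 2 samples")
    dts = np.diff(time_s)
    dt = dts[0]
    bad = np.flatnonzero(np.abs(dts - dt) > 1e-6 * max(dt, 1e-12))
    if bad.size:
        raise ValueError(f"non-uniform sampling at index {int(bad[0]) + 1}")
    return float(dt * 1000.0)


def _read_tsv(path: Path) -> Trace:
    meta: dict = {}
    times, currents = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line.lstrip("# ").partition(":")
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed line {ln} (expected 2 columns)")
            try:
                times.append(float(parts[0]))
                currents.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: unparsable number at line {ln}") from exc
    if not times:
        raise ValueError(f"{path}: no data rows")
    units = meta.get("units", "pA")
    if units != "pA":
        raise ValueError(f"{path}: unknown units {units!r} (expected pA)")
    dt_ms = _check_uniform(np.asarray(times))
    return Trace(dt_ms=dt_ms, samples=np.asarray(currents), units="pA", metadata=meta)


def _write_tsv(trace: Trace, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# patchdose trace\n")
        fh.write("# units: pA\n")
        fh.write(f"# dt_ms: {_fmt(trace.dt_ms)}\n")
        for k, v in sorted(trace.metadata.items()):
            if k in ("units", "dt_ms"):
                continue
            fh.write(f"# {k}: {v}\n")
        fh.write("# time_s\tcurrent_pA\n")
        t = trace.time_s
        for ti, ci in zip(t, trace.samples):
            fh.write(f"{_TRACE_FLOAT_FMT.format(ti)}\t{_TRACE_FLOAT_FMT.format(ci)}\n")


def _read_atf(path: Path) -> Trace:
    """Minimal ATF dialect reader: signature line, header-record count line,
    that many quoted header records, a column-title line, tab-separated data."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise ValueError(f"{path}: missing ATF signature")
    try:
        n_header, n_cols = (int(v) for v in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: malformed ATF header-count line") from exc
    meta: dict = {"dialect": "atf"}
    for rec in lines[2: 2 + n_header]:
        rec = rec.strip().strip('"')
        if "=" in rec:
            k, _, v = rec.partition("=")
            meta[k.strip()] = v.strip()
    data_lines = lines[2 + n_header + 1:]  # skip the column-title line
    times, currents = [], []
    for ln, line in enumerate(data_lines, 2 + n_header + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed ATF data line {ln}")
        times.append(float(parts[0]))
        currents.append(float(parts[1]))
    if not times:
        raise ValueError(f"{path}: no ATF data rows")
    if n_cols < 2:
        raise ValueError(f"{path}: ATF needs a time and a current column")
    dt_ms = _check_uniform(np.asarray(times))
    return Trace(dt_ms=dt_ms, samples=np.asarray(currents), units="pA", metadata=meta)


def _write_atf(trace: Trace, path: Path) -> None:
    headers = [f'"units=pA"', f'"dt_ms={_fmt(trace.dt_ms)}"']
    for k, v in sorted(trace.metadata.items()):
        if k in ("units", "dt_ms", "dialect"):
            continue
        headers.append(f'"{k}={v}"')
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(headers)}\t2\n")
        for h in headers:
            fh.write(h + "\n")
        fh.write('"Time (s)"\t"Current (pA)"\n')
        for ti, ci in zip(trace.time_s, trace.samples):
            fh.write(f"{_TRACE_FLOAT_FMT.format(ti)}\t{_TRACE_FLOAT_FMT.format(ci)}\n")


def _read_abf(path: Path) -> Trace:  # pragma: no cover - optional adapter
    try:
        import pyabf
    except ImportError as exc:
        raise ImportError(
            "reading ABF files requires the optional 'pyabf' dependency "
            "(pip install patchdose[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))
    abf.setSweep(0)
    dt_ms = 1000.0 / abf.dataRate
    return Trace(
        dt_ms=dt_ms,
        samples=np.asarray(abf.sweepY, float),
        units="pA",
        metadata={"dialect": "abf", "channel_count": abf.channelCount},
    )


_READERS = {"tsv": _read_tsv, "atf": _read_atf, "abf": _read_abf}
_WRITERS = {"tsv": _write_tsv, "atf": _write_atf}


def read_trace(path: str | Path, dialect: str | None = None) -> Trace:
    """Read a current trace; dialect inferred from the extension if omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower() or "tsv"
        if dialect not in _READERS:
            dialect = "tsv"
    if dialect not in _READERS:
        raise ValueError(f"unknown trace dialect {dialect!r}")
    return _READERS[dialect](path)


def write_trace(trace: Trace, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
        if dialect not in _WRITERS:
            dialect = "tsv"
    if dialect not in _WRITERS:
        raise ValueError(f"cannot write dialect {dialect!r}")
    _WRITERS[dialect](trace, path)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_events(record, path: str | Path, provenance: dict | None = None) -> None:
    """Events CSV: level,start_ms,duration_ms with a provenance comment block."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line)
        fh.write(f"# total_duration_ms: {_fmt(float(record.total_duration_ms))}\n")
        fh.write(f"# dt_ms: {_fmt(float(record.dt_ms)) if record.dt_ms else ''}\n")
        fh.write("level,start_ms,duration_ms\n")
        for lv, st, du in zip(record.levels, record.starts_ms, record.durations_ms):
            fh.write(f"{int(lv)},{_FLOAT_FMT.format(st)},{_FLOAT_FMT.format(du)}\n")


def read_events(path: str | Path):
    """Read an events CSV back into an :class:`~patchdose.idealize.IdealizedRecord`."""
    from .idealize import IdealizedRecord

    path = Path(path)
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
                continue
            if line.startswith("level,") or not line:
                continue
            lv, st, du = line.split(",")
            rows.append((int(lv), float(st), float(du)))
    if not rows:
        raise ValueError(f"{path}: no events")
    levels = np.array([r[0] for r in rows])
    starts = np.array([r[1] for r in rows])
    durations = np.array([r[2] for r in rows])
    total = float(meta.get("total_duration_ms", starts[-1] + durations[-1]))
    dt = float(meta["dt_ms"]) if meta.get("dt_ms") else None
    return IdealizedRecord(
        levels=levels,
        starts_ms=starts,
        durations_ms=durations,
        total_duration_ms=total,
        n_levels_observed=int(levels.max()),
        dt_ms=dt,
    )


# ---------------------------------------------------------------------------
# run configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every tunable of a pipeline run, with explicit values after load."""

    seed: int = 0
    # speciation
    nahs_uM: float = 300.0
    ph: float = 7.21
    temperature_K: float = 293.15
    salinity: float = 11.5
    retention: tuple[float, float] = (0.5, 0.6)
    # simulation
    preset: str = "gh3-atp1"
    n_channels: int = 2
    duration_s: float = 10.0
    dt_ms: float = 0.05
    unitary_amplitude_pA: float = 5.0
    noise_sd_pA: float = 0.625
    filter_khz: float = 1.0
    # idealization
    dead_time_ms: float = 0.1
    hysteresis_frac: float = 0.1
    max_levels: int = 4
    # stats
    adjust: str = "max-t"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["retention"] = list(self.retention)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unspecified keys keep (and log) their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    unknown = set(raw) - set(cfg.to_dict())
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in raw.items():
        if k == "retention":
            v = tuple(float(x) for x in v)
        setattr(cfg, k, v)
    for k, v in cfg.to_dict().items():
        if k not in raw:
            logger.info("config default: %s = %r", k, v)
    return cfg


def config_hash(config: RunConfig | dict) -> str:
    d = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(seed: int | None, config: RunConfig | dict | None) -> dict:
    prov = {"package": "patchdose", "version": __version__}
    if seed is not None:
        prov["seed"] = int(seed)
    if config is not None:
        prov["config_hash"] = config_hash(config)
    return prov


def _provenance_lines(prov: dict | None):
    for k, v in sorted((prov or {}).items()):
        yield f"# {k}: {v}\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float):
        return obj
    return obj


def write_report(
    results: dict | pd.DataFrame,
    path: str | Path,
    fmt: str | None = None,
    seed: int | None = None,
    config: RunConfig | dict | None = None,
) -> None:
    """Write a results report (csv or json) with a provenance block.

    Field order and float formatting are deterministic: identical inputs and
    seed produce identical bytes.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "json"
    prov = _provenance(seed, config)
    if fmt == "json":
        payload = {
            "provenance": prov,
            "results": _jsonable(
                results.to_dict(orient="records")
                if isinstance(results, pd.DataFrame)
                else results
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif fmt == "csv":
        if isinstance(results, dict):
            results = pd.DataFrame([results])
        with open(path, "w") as fh:
            for line in _provenance_lines(prov):
                fh.write(line)
            cols = list(results.columns)
            fh.write(",".join(cols) + "\n")
            for _, row in results.iterrows():
                fh.write(",".join(_fmt(row[c]) for c in cols) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    logger.info("wrote %s (%s)", path, fmt)
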