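"""File round-tripping: spike times, stimuli, models, run manifests.

Spike times travel as plain text (one time in seconds per line, one file
or column per trial); stimuli as single-column text; fitted models in a
versioned ``.npz`` container that stores the family tag, dimensions and
all arrays bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from .containers import BinnedSpikeTrain
from .params import (FactoredSTMParams, GLMParams, QuadraticParams, STMParams,
                     family_of)
from .simulate import StimulusWaveform

logger = logging.getLogger("spikemix")

MODEL_FORMAT_VERSION = 1


def bin_spike_times(times, dt: float, n_bins: int | None = None,
                    trial_id=0) -> BinnedSpikeTrain:
    """Bin sorted spike times (seconds) on a [t, t+dt) grid, 0-based, floor
    convention.  Two spikes in one bin collapse to 1 with a warning."""
    times = np.asarray(times, dtype=float)
    if times.size and (np.diff(times) < 0).any():
        bad = int(np.flatnonzero(np.diff(times) < 0)[0]) + 2
        raise ValueError(f"spike times not sorted (line {bad})")
    if times.size and times[0] < 0:
        raise ValueError("negative spike time (line 1)")
    idx = np.floor(times / dt).astype(int)
    if n_bins is None:
        n_bins = int(idx.max()) + 1 if idx.size else 1
    idx = idx[idx < n_bins]
    counts = np.bincount(idx, minlength=n_bins)
    if (counts > 1).any():
        logger.warning("collapsing %d bins with multiple spikes to 1",
                       int((counts > 1).sum()))
        counts = np.minimum(counts, 1)
    return BinnedSpikeTrain(counts, dt, trial_id)


def load_spike_times(path, dt: float, n_bins: int | None = None):
    """Read spike-time files into binned trains.

    ``path`` may be one file (one trial) or a directory of ``*.txt``
    files (one per trial).  Empty files yield no trains.
    """
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    trains = []
    for i, f in enumerate(files):
        rows = [ln for ln in f.read_text().split("\n") if ln.strip()]
        times = []
        for lineno, ln in enumerate(rows, start=1):
            try:
                times.append(float(ln))
            except ValueError:
                raise ValueError(
                    f"{f}: line {lineno}: not a number: {ln!r}") from None
        if not times:
            continue
        trains.append(bin_spike_times(times, dt, n_bins, trial_id=i))
    return trains


def save_spike_times(trains, path):
    """Write each train's spike times (bin centers, seconds) to
    ``<path>/trial_<k>.txt``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, tr in enumerate(trains):
        out = path / f"trial_{i:03d}.txt"
        out.write_text("".join(f"{t:.9f}\n" for t in tr.spike_times()))
    return path


def save_stimulus(waveform: StimulusWaveform, path):
    path = Path(path)
    header = f"fs={waveform.fs} cutoff={waveform.cutoff}"
    np.savetxt(path, waveform.samples, fmt="%.17g", header=header)
    return path


def load_stimulus(path) -> StimulusWaveform:
    path = Path(path)
    header = path.read_text().split("\n", 1)[0]
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    samples = np.loadtxt(path)
    return StimulusWaveform(samples, float(meta["fs"]), float(meta["cutoff"]))


def save_model(params, path):
    """Write a parameter set to a versioned ``.npz`` container (bit-exact
    round trip)."""
    path = Path(path)
    family = family_of(params)
    arrays = {"__format_version__": np.int64(MODEL_FORMAT_VERSION),
              "__family__": np.bytes_(family.encode())}
    if isinstance(params, GLMParams):
        arrays.update(w=params.w, h=params.h, b=np.float64(params.b))
    elif isinstance(params, QuadraticParams):
        arrays.update(A=params.A, w=params.w, h=params.h,
                      b=np.float64(params.b))
    elif isinstance(params, STMParams):
        arrays.update(A=params.A, W=params.W, a=params.a, h=params.h)
    elif isinstance(params, FactoredSTMParams):
        arrays.update(U=params.U, B=params.B, W=params.W, a=params.a,
                      h=params.h)
    np.savez(path, **arrays)
    return path


def load_model(path):
    """Read a model container; errors on version mismatch or truncation
    rather than returning a partial model."""
    path = Path(path)
    try:
        with np.load(path) as data:
            version = int(data["__format_version__"])
            if version != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model container version {version} is not supported "
                    f"(expected {MODEL_FORMAT_VERSION})")
            family = bytes(data["__family__"].item()).decode()
            if family == "glm":
                return GLMParams(data["w"], data["h"], float(data["b"]))
            if family == "quadratic":
                return QuadraticParams(data["A"], data["w"], data["h"],
                                       float(data["b"]))
            if family == "stm":
                return STMParams(data["A"], data["W"], data["a"], data["h"])
            if family == "fstm":
                return FactoredSTMParams(data["U"], data["B"], data["W"],
                                         data["a"], data["h"])
            raise ValueError(f"unknown model family in container: {family!r}")
    except (KeyError, OSError, EOFError) as exc:
        raise ValueError(f"corrupt or truncated model file: {path}") from exc


def config_hash(config) -> str:
    payload = json.dumps(
        {k: getattr(config, k) for k in vars(config)}, sort_keys=True,
        default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path, command: str, seeds, inputs, outputs, config=None):
    """Record what produced an artifact: command, seeds, paths, config
    hash, package version, timestamp."""
    from . import __version__
    manifest = {
        "command": command,
        "seeds": seeds,
        "inputs": [str(p) for p in inputs],
        "outputs": [str(p) for p in outputs],
        "config_hash": config_hash(config) if config is not None else None,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_config_file(path) -> dict:
    """Parse a plain ``key = value`` config file (ints, floats, strings)."""
    out = {}
    for lineno, ln in enumerate(Path(path).read_text().split("\n"), start=1):
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in ln.split("=", 1))
        for cast in (int, float):
            try:
                value = cast(value)
                break
            except ValueError:
                continue
        out[key] = value
    return out
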