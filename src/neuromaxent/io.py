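"""Plain-text interchange formats.

Event lists, rasters, moment sets, model parameter files and thermo
curves are all tab-separated text with ``#key=value`` headers, so every
artifact in a pipeline run remains diffable and versionable.  Model
files round-trip bit-exactly (floats serialized with ``repr``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .ifnet import SpikeEventList
from .maxent import KPairwiseModel
from .spike_stats import BinnedRaster, MomentSet, pair_index
from .thermo import ThermoCurve

__all__ = [
    "write_events", "read_events",
    "write_raster", "read_raster",
    "write_moments", "read_moments",
    "write_model", "read_model",
    "write_curve", "read_curve",
    "read_config", "write_config",
]


def _header(lines, path):
    meta = {}
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        key, _, val = line[1:].strip().partition("=")
        if _:
            meta[key.strip()] = val.strip()
    return meta, n_header


def write_events(path, events: SpikeEventList) -> None:
    with open(path, "w") as fh:
        fh.write(f"#channels={events.n_channels}\n")
        fh.write(f"#timesteps={events.n_timesteps}\n")
        if events.dt_ms is not None:
            fh.write(f"#dt_ms={float(events.dt_ms)!r}\n")
        for t, c in zip(events.times, events.channels):
            fh.write(f"{t}\t{c}\n")


def read_events(path) -> SpikeEventList:
    """Read an event list; raises with the line number on malformed rows."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta, n_header = _header(lines, path)
    try:
        n_channels = int(meta["channels"])
        n_timesteps = int(meta["timesteps"])
    except KeyError as exc:
        raise ValueError(f"{path}: missing header key {exc}") from None
    dt_ms = float(meta["dt_ms"]) if "dt_ms" in meta else None
    times, channels = [], []
    for ln, line in enumerate(lines[n_header:], start=n_header + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            t, c = int(parts[0]), int(parts[1])
        except (ValueError, IndexError):
            raise ValueError(f"{path}:{ln}: malformed event row {line!r}") from None
        if not 0 <= c < n_channels:
            raise ValueError(f"{path}:{ln}: channel {c} out of range")
        times.append(t)
        channels.append(c)
    return SpikeEventList(np.asarray(times, np.int64), np.asarray(channels, np.int32),
                          n_channels, n_timesteps, dt_ms)


def write_raster(path, raster: BinnedRaster) -> None:
    with open(path, "w") as fh:
        fh.write(f"#channels={raster.n_channels}\n")
        fh.write(f"#bins={raster.n_bins}\n")
        fh.write(f"#bin_width={float(raster.bin_width)!r}\n")
        for row in raster.sigma:
            fh.write("\t".join("1" if x > 0 else "-1" for x in row) + "\n")


def read_raster(path) -> BinnedRaster:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta, n_header = _header(lines, path)
    width = float(meta["bin_width"])
    rows = [np.array(line.split("\t"), dtype=np.int8)
            for line in lines[n_header:] if line.strip()]
    sigma = np.vstack(rows) if rows else np.empty((int(meta["channels"]), 0), np.int8)
    return BinnedRaster(sigma, width)


def write_moments(path, m: MomentSet) -> None:
    """Long format: kind <TAB> indices <TAB> value <TAB> se."""
    iu, ju = pair_index(m.n_channels)
    with open(path, "w") as fh:
        fh.write(f"#channels={m.n_channels}\n#bins={m.n_bins}\n")
        fh.write("kind\ti\tj\tvalue\tse\n")

        def se(arr, idx):
            return repr(float(arr[idx])) if arr is not None else ""

        for i in range(m.n_channels):
            fh.write(f"mean\t{i}\t\t{float(m.mean_sigma[i])!r}\t{se(m.se_mean, i)}\n")
        for p, (i, j) in enumerate(zip(iu, ju)):
            fh.write(f"pair\t{i}\t{j}\t{float(m.pair_sigma[p])!r}\t{se(m.se_pair, p)}\n")
        for k in range(m.n_channels + 1):
            fh.write(f"pk\t{k}\t\t{float(m.pk[k])!r}\t{se(m.se_pk, k)}\n")


def read_moments(path) -> MomentSet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta, n_header = _header(lines, path)
    n = int(meta["channels"])
    nb = int(meta["bins"])
    iu, ju = pair_index(n)
    mean = np.zeros(n)
    pair = np.zeros(iu.size)
    pk = np.zeros(n + 1)
    se_mean = np.zeros(n)
    se_pair = np.zeros(iu.size)
    se_pk = np.zeros(n + 1)
    pidx = {(int(i), int(j)): p for p, (i, j) in enumerate(zip(iu, ju))}
    for line in lines[n_header + 1:]:
        if not line.strip():
            continue
        kind, i, j, value, se = line.split("\t")
        v = float(value)
        s = float(se) if se else 0.0
        if kind == "mean":
            mean[int(i)], se_mean[int(i)] = v, s
        elif kind == "pair":
            p = pidx[(int(i), int(j))]
            pair[p], se_pair[p] = v, s
        elif kind == "pk":
            pk[int(i)], se_pk[int(i)] = v, s
    return MomentSet(n, nb, mean, pair, pair - mean[iu] * mean[ju], pk,
                     se_mean, se_pair, se_pk)


def write_model(path, model: KPairwiseModel) -> None:
    """Sectioned text format ([h], [J], [V]); bit-exact float round-trip."""
    n = model.n_spins
    with open(path, "w") as fh:
        fh.write(f"#n_spins={n}\n")
        fh.write("#fitted_mask=" + "".join("1" if b else "0" for b in model.fitted_mask) + "\n")
        fh.write("[h]\n")
        for i in range(n):
            fh.write(f"{i}\t{float(model.h[i])!r}\n")
        fh.write("[J]\n")
        for i in range(n):
            for j in range(i + 1, n):
                if model.J[i, j] != 0.0:
                    fh.write(f"{i}\t{j}\t{float(model.J[i, j])!r}\n")
        fh.write("[V]\n")
        for k in range(n + 1):
            if model.V[k] != 0.0 or model.fitted_mask[k]:
                fh.write(f"{k}\t{float(model.V[k])!r}\n")


def read_model(path) -> KPairwiseModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta, n_header = _header(lines, path)
    n = int(meta["n_spins"])
    mask = np.array([c == "1" for c in meta["fitted_mask"]], dtype=np.bool_)
    h = np.zeros(n)
    J = np.zeros((n, n))
    V = np.zeros(n + 1)
    section = None
    for line in lines[n_header:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("["):
            section = line
            continue
        parts = line.split("\t")
        if section == "[h]":
            h[int(parts[0])] = float(parts[1])
        elif section == "[J]":
            i, j = int(parts[0]), int(parts[1])
            J[i, j] = J[j, i] = float(parts[2])
        elif section == "[V]":
            V[int(parts[0])] = float(parts[1])
    return KPairwiseModel(h, J, V, mask)


def write_curve(path, curve: ThermoCurve) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_spins={curve.n_spins}\n#init_mode={curve.init_mode}\n")
        fh.write("T\tcv\tcv_se\tchi\tchi_se\n")
        for row in zip(curve.temperatures, curve.cv, curve.cv_se, curve.chi, curve.chi_se):
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_curve(path) -> ThermoCurve:
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta, n_header = _header(lines, path)
    data = np.array([[float(x) for x in line.split("\t")]
                     for line in lines[n_header + 1:] if line.strip()])
    return ThermoCurve(data[:, 0], data[:, 1], data[:, 3], data[:, 2], data[:, 4],
                       meta.get("init_mode", "random"), int(meta.get("n_spins", 0)))


def read_config(path) -> dict:
    """Flat ``key = value`` text config; values parsed as int/float/str."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, val = (x.strip() for x in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out


def write_config(path, mapping: dict) -> None:
    with open(path, "w") as fh:
        for key, val in mapping.items():
            fh.write(f"{key} = {val}\n")
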