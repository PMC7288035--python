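"""Recording I/O: delimited text, EDF, and dataset manifests.

EDF (European Data Format) is the de-facto interchange format for EEG; the
codec here covers the classic subset this package needs — a fixed ASCII
header plus little-endian int16 data records with per-channel physical
scaling.  Delimited text (one row per sample, one column per channel) is
kept for inspection and for lossless round trips.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .montage import Montage, default_montage
from .recording import Recording

DIG_MIN, DIG_MAX = -32768, 32767


class FormatError(ValueError):
    """Raised for files that do not parse or do not match the montage."""


# ---------------------------------------------------------------------------
# delimited text

def write_delimited(rec: Recording, path) -> None:
    """One row per sample, one column per channel; header = channel names.

    A leading comment line carries the recording metadata so a round trip
    preserves labels; samples are written at full float64 precision.
    """
    path = Path(path)
    meta = (f"# rate_hz={rec.rate:g} pair={rec.pair_id} role={rec.role} "
            f"system={rec.system} phase_boundary_s={rec.phase_boundary_s:g} "
            f"normalized={int(rec.normalized)}")
    header = meta + "\n" + "\t".join(rec.montage.names)
    np.savetxt(path, rec.data.T, fmt="%.17g", delimiter="\t",
               header=header, comments="")


def read_delimited(path, montage: Montage | None = None) -> Recording:
    montage = montage or default_montage()
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        meta = {}
        if first.startswith("#"):
            for token in first[1:].split():
                k, _, v = token.partition("=")
                meta[k] = v
            header = fh.readline().strip()
        else:
            header = first
        names = tuple(header.split("\t"))
        data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    if names != montage.names:
        raise FormatError(
            f"channel header {list(names)} does not match the montage"
        )
    return Recording(
        data, float(meta.get("rate_hz", 128.0)), montage,
        pair_id=int(meta.get("pair", 0)),
        role=meta.get("role", "process_owner"),
        system=meta.get("system", "HKT"),
        phase_boundary_s=float(meta.get("phase_boundary_s", 10.0)),
        normalized=bool(int(meta.get("normalized", 0))),
    )


# ---------------------------------------------------------------------------
# EDF

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a classic EDF file, one data record per second.

    Physical min/max per channel come from the data, so the quantisation
    step is (phys_max - phys_min) / 65535 per channel.
    """
    n_ch = rec.n_channels
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per record (1 s records)
    if rec.n_samples % spr:
        raise FormatError("EDF writer requires a whole number of seconds")
    n_rec = rec.n_samples // spr

    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    def fmt8(x: float) -> str:
        for p in (6, 5, 4, 3, 2, 1):
            s = f"{x:.{p}g}"
            if len(s) <= 8:
                return s
        return f"{x:.0f}"[:8]

    recording_id = f"pair={rec.pair_id} role={rec.role} system={rec.system}"
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii(recording_id, 80),
        _ascii("01.01.20", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (1 + n_ch), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii("1", 8),
        _ascii(n_ch, 4),
    ])
    fields = [
        [(name, 16) for name in rec.montage.names],
        [("", 80)] * n_ch,
        [("uV", 8)] * n_ch,
        [(fmt8(v), 8) for v in pmin],
        [(fmt8(v), 8) for v in pmax],
        [(str(DIG_MIN), 8)] * n_ch,
        [(str(DIG_MAX), 8)] * n_ch,
        [("", 80)] * n_ch,
        [(str(spr), 8)] * n_ch,
        [("", 32)] * n_ch,
    ]
    sig_header = b"".join(_ascii(v, w) for group in fields for v, w in group)

    # re-read the formatted physical bounds so scaling matches the header
    pmin_h = np.array([float(fmt8(v)) for v in pmin])
    pmax_h = np.array([float(fmt8(v)) for v in pmax])
    scale = (DIG_MAX - DIG_MIN) / (pmax_h - pmin_h)
    digital = np.rint((rec.data - pmin_h[:, None]) * scale[:, None] + DIG_MIN)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


@dataclass
class EDFHeader:
    labels: list[str]
    phys_min: np.ndarray
    phys_max: np.ndarray
    dig_min: np.ndarray
    dig_max: np.ndarray
    samples_per_record: list[int]
    n_records: int
    record_duration_s: float
    recording_id: str

    @property
    def quantization_step(self) -> np.ndarray:
        """Physical units per digital unit, per channel."""
        return (self.phys_max - self.phys_min) / (self.dig_max - self.dig_min)


def read_edf_header(path) -> EDFHeader:
    with open(path, "rb") as fh:
        head = fh.read(256).decode("ascii")
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        n_ch = int(head[252:256])
        sig = fh.read(256 * n_ch).decode("ascii")

    def block(offset: int, width: int) -> list[str]:
        start = offset * n_ch
        return [sig[start + i * width:start + (i + 1) * width].strip()
                for i in range(n_ch)]

    labels = block(0, 16)
    phys_min = np.array([float(v) for v in block(16 + 80 + 8, 8)])
    phys_max = np.array([float(v) for v in block(16 + 80 + 8 + 8, 8)])
    dig_min = np.array([float(v) for v in block(16 + 80 + 8 + 16, 8)])
    dig_max = np.array([float(v) for v in block(16 + 80 + 8 + 24, 8)])
    spr = [int(v) for v in block(16 + 80 + 8 + 32 + 80, 8)]
    return EDFHeader(labels, phys_min, phys_max, dig_min, dig_max, spr,
                     n_rec, rec_dur, head[88:168].strip())


def read_edf(path, montage: Montage | None = None) -> Recording:
    montage = montage or default_montage()
    hdr = read_edf_header(path)
    n_ch = len(hdr.labels)
    if tuple(hdr.labels) != montage.names:
        raise FormatError(
            f"EDF channels {hdr.labels} do not match the {len(montage)}-channel montage"
        )
    spr = hdr.samples_per_record
    with open(path, "rb") as fh:
        fh.seek(256 * (1 + n_ch))
        raw = np.frombuffer(fh.read(), dtype="<i2")
    per_rec = sum(spr)
    if len(raw) != per_rec * hdr.n_records:
        raise FormatError("EDF data size does not match its header")
    data = np.empty((n_ch, spr[0] * hdr.n_records))
    recs = raw.reshape(hdr.n_records, per_rec)
    offsets = np.cumsum([0] + spr)
    scale = hdr.quantization_step
    for ch in range(n_ch):
        dig = recs[:, offsets[ch]:offsets[ch + 1]].reshape(-1)
        data[ch] = (dig - hdr.dig_min[ch]) * scale[ch] + hdr.phys_min[ch]
    rate = spr[0] / hdr.record_duration_s

    meta = dict(re.findall(r"(\w+)=(\S+)", hdr.recording_id))
    return Recording(data, rate, montage,
                     pair_id=int(meta.get("pair", 0)),
                     role=meta.get("role", "process_owner"),
                     system=meta.get("system", "HKT"))


# ---------------------------------------------------------------------------
# datasets and manifests

def recording_filename(rec: Recording, fmt: str) -> str:
    ext = {"edf": "edf", "delimited": "tsv"}[fmt]
    return f"pair{rec.pair_id:02d}_{rec.system}_{rec.role}.{ext}"


def write_recording(rec: Recording, path, fmt: str = "delimited") -> None:
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt == "delimited":
        write_delimited(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_recording(path, fmt: str | None = None,
                   montage: Montage | None = None) -> Recording:
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return read_edf(path, montage)
    if fmt == "delimited":
        return read_delimited(path, montage)
    raise FormatError(f"unknown format {fmt!r}")


def write_dataset(dataset, out_dir, fmt: str = "delimited",
                  seed: int | None = None) -> Path:
    """Write every recording plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in dataset:
        fname = recording_filename(rec, fmt)
        write_recording(rec, out_dir / fname, fmt)
        entries.append({
            "filename": fname, "pair": rec.pair_id, "role": rec.role,
            "system": rec.system, "category": rec.category, "format": fmt,
        })
    manifest = {"n_pairs": dataset.n_pairs,
                "seed": seed if seed is not None else dataset.seed,
                "recordings": entries}
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_dataset(in_dir, montage: Montage | None = None):
    """Load a dataset directory written by :func:`write_dataset`."""
    from .recording import Dataset

    in_dir = Path(in_dir)
    mpath = in_dir / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"no manifest.json in {in_dir}")
    manifest = json.loads(mpath.read_text())
    recs = [read_recording(in_dir / e["filename"], e.get("format"), montage)
            for e in manifest["recordings"]]
    return Dataset(recs, manifest["n_pairs"], manifest.get("seed"))
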