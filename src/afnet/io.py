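"""Record I/O: WFDB-style (.hea/.dat format 16), .mat payloads, CSV dialect.

The WFDB writer emits the minimal single-signal subset of the header
format (record line, one signal-spec line, a ``# label:`` comment) with
16-bit little-endian samples and the ADC gain recorded in the header.
The reader additionally accepts the .mat signal payloads used by the
CPSC2018 challenge (struct ``ECG`` with a ``data`` matrix) and the
CinC2017 style (``val`` array).

The CSV dialect is one sample per line after a single header line
``fs=<Hz>,lead=<name>,label=<class>``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from scipy.io import loadmat

from .synth import ECGRecord, RhythmClass

__all__ = [
    "write_wfdb",
    "read_wfdb",
    "write_csv_record",
    "read_csv_record",
    "write_dataset",
    "read_dataset",
    "read_mat_record",
]

_DEFAULT_GAIN = 200.0  # adu per mV, the common WFDB convention


def write_wfdb(record: ECGRecord, directory: str | Path, gain: float = _DEFAULT_GAIN) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (format 16); returns the .hea path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(np.asarray(record.samples) * gain)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal exceeds the int16 range at this gain")
    adc = adc.astype("<i2")
    dat_name = f"{record.record_id}.dat"
    (directory / dat_name).write_bytes(adc.tobytes())
    checksum = int(adc.astype(np.int64).sum() % 65536)
    fs = int(record.fs) if float(record.fs).is_integer() else record.fs
    lines = [
        f"{record.record_id} 1 {fs} {adc.size}",
        f"{dat_name} 16 {gain:g}/mV 16 0 {int(adc[0])} {checksum} 0 {record.lead}",
        f"# label: {record.label.value}",
    ]
    hea = directory / f"{record.record_id}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def read_wfdb(hea_path: str | Path, label: RhythmClass | None = None) -> ECGRecord:
    """Read a single-signal format-16 record; 0-based sample indexing."""
    hea_path = Path(hea_path)
    lines = [ln.strip() for ln in hea_path.read_text().splitlines() if ln.strip()]
    head = lines[0].split()
    record_id, nsig, fs = head[0], int(head[1]), float(head[2].split("/")[0])
    sig = lines[1].split()
    dat_name, fmt = sig[0], sig[1]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB format {fmt!r}; only format 16 is handled")
    gain = float(sig[2].split("/")[0].split("(")[0]) if len(sig) > 2 else _DEFAULT_GAIN
    if gain == 0:
        gain = _DEFAULT_GAIN
    lead = sig[-1] if len(sig) > 8 else "II"
    for ln in lines[2:]:
        if ln.startswith("#") and "label:" in ln:
            label = RhythmClass(ln.split("label:")[1].strip())
    raw = np.frombuffer((hea_path.parent / dat_name).read_bytes(), dtype="<i2")
    if nsig > 1:  # interleaved multi-signal file: take the first channel
        raw = raw.reshape(-1, nsig)[:, 0]
    if label is None:
        raise ValueError(f"{hea_path.name}: no '# label:' comment and no label given")
    return ECGRecord(record_id, raw.astype(float) / gain, fs, lead, label)


def read_mat_record(
    mat_path: str | Path,
    label: RhythmClass,
    fs: float = 500.0,
    lead_index: int = 1,
) -> ECGRecord:
    """Read a CPSC2018-style (``ECG.data``, 12 x N) or CinC2017-style (``val``) .mat payload."""
    mat_path = Path(mat_path)
    payload = loadmat(str(mat_path))
    if "ECG" in payload:
        data = payload["ECG"]["data"][0, 0]
        samples = np.asarray(data[lead_index], dtype=float)
    elif "val" in payload:
        samples = np.asarray(payload["val"], dtype=float).ravel()
    else:
        raise ValueError(f"{mat_path.name}: neither 'ECG' struct nor 'val' array found")
    return ECGRecord(mat_path.stem, samples, fs, "II", label)


def write_csv_record(record: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fs = int(record.fs) if float(record.fs).is_integer() else record.fs
    with path.open("w") as fh:
        fh.write(f"fs={fs},lead={record.lead},label={record.label.value}\n")
        for v in record.samples:
            fh.write(f"{v:.6f}\n")
    return path


def read_csv_record(path: str | Path) -> ECGRecord:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=", 1) for kv in header.split(","))
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return ECGRecord(
        path.stem, samples, float(meta["fs"]), meta.get("lead", "II"),
        RhythmClass(meta["label"]),
    )


def write_dataset(
    records: list[ECGRecord], directory: str | Path, fmt: str = "wfdb"
) -> Path:
    """Write all records plus a ``manifest.csv`` (record_id,label); returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        if fmt == "wfdb":
            write_wfdb(rec, directory)
        elif fmt == "csv":
            write_csv_record(rec, directory / f"{rec.record_id}.csv")
        else:
            raise ValueError(f"unknown dataset format {fmt!r} (expected 'wfdb' or 'csv')")
    manifest = directory / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "label"])
        for rec in records:
            writer.writerow([rec.record_id, rec.label.value])
    return manifest


def read_dataset(directory: str | Path) -> list[ECGRecord]:
    """Read every record listed in ``manifest.csv`` (wfdb or csv layout)."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    records = []
    with manifest.open() as fh:
        for row in csv.DictReader(fh):
            rid = row["record_id"]
            label = RhythmClass(row["label"])
            hea = directory / f"{rid}.hea"
            csv_path = directory / f"{rid}.csv"
            if hea.exists():
                records.append(read_wfdb(hea, label))
            elif csv_path.exists():
                records.append(read_csv_record(csv_path))
            else:
                raise FileNotFoundError(f"record {rid} listed in manifest but not found")
    return records
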