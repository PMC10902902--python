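"""Recording readers and writers.

Three on-disk forms are supported: single-column text (one sample per
line), two-column CSV (``time_ms,value``), and EDF (European Data
Format).  EDF files are read through :mod:`mne`; writing uses a minimal
in-package 16-bit EDF encoder sufficient for single-channel exports.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .signalprep import DEFAULT_DT_MS, Recording


def read_recording(
    path: str | Path,
    dt_ms: float = DEFAULT_DT_MS,
    channel: int = 0,
    subject_id: str | None = None,
) -> Recording:
    """Load a recording, dispatching on file extension.

    ``.edf`` goes through mne (``channel`` selects the channel, first by
    default, and dt is taken from the file header); ``.csv`` expects
    ``time_ms,value`` columns with dt inferred from the time stamps;
    anything else is parsed as one sample per line with ``dt_ms`` taken
    from the argument.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return _read_edf(path, channel=channel, subject_id=sid)
    if suffix == ".csv":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        if data.shape[1] < 2:
            raise InvalidInputError(f"{path}: CSV needs time_ms,value columns")
        t, v = data[:, 0], data[:, 1]
        dt = float(np.median(np.diff(t))) if len(t) > 1 else dt_ms
        return Recording(v, dt_ms=dt, subject_id=sid)
    samples = np.loadtxt(path, ndmin=1)
    return Recording(samples, dt_ms=dt_ms, subject_id=sid)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the format implied by the file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        write_edf(rec, path)
    elif suffix == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_ms", "value"])
            for k, v in enumerate(rec.samples):
                writer.writerow([repr(k * rec.dt_ms), repr(float(v))])
    else:
        np.savetxt(path, rec.samples)


def _read_edf(path: Path, channel: int, subject_id: str) -> Recording:
    import mne  # heavy import, deferred

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if not (0 <= channel < len(raw.ch_names)):
        raise InvalidInputError(
            f"{path}: channel {channel} out of range ({len(raw.ch_names)} channels)"
        )
    data = raw.get_data(picks=[channel])[0]
    return Recording(data, dt_ms=1000.0 / raw.info["sfreq"], subject_id=subject_id)


def write_edf(rec: Recording, path: str | Path, label: str = "LFP") -> None:
    """Encode a single-channel recording as a 16-bit EDF file.

    Samples are linearly mapped onto the full signed-16-bit range with
    the physical min/max stored in the header, so round-trip error is
    bounded by the 16-bit quantization step.  The record duration equals
    one second's worth of samples (padded with the last value).
    """
    x = np.asarray(rec.samples, dtype=float)
    if x.size == 0:
        raise InvalidInputError("cannot write an empty recording")
    sfreq = 1000.0 / rec.dt_ms
    spr = max(1, int(round(sfreq)))  # samples per 1 s data record
    n_records = int(np.ceil(x.size / spr))
    padded = np.concatenate([x, np.full(n_records * spr - x.size, x[-1])])

    pmin, pmax = float(np.min(x)), float(np.max(x))
    if pmax == pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    digital = np.round(
        (padded - pmin) / (pmax - pmin) * (dmax - dmin) + dmin
    ).astype("<i2")

    def f(value, width):
        s = f"{value:<{width}}"[:width]
        return s.encode("ascii")

    header = b"".join([
        f("0", 8),                      # version
        f(rec.subject_id or "X", 80),   # patient id
        f("synthetic recording", 80),   # recording id
        f("01.01.20", 8), f("00.00.00", 8),
        f(str(256 + 256), 8),           # header bytes: fixed + 1 channel
        f("", 44),
        f(str(n_records), 8),
        f(f"{spr / sfreq:.6g}", 8),     # record duration, s
        f("1", 4),                      # number of signals
        # per-signal fields (one channel)
        f(label, 16), f("", 80), f("uV", 8),
        f(f"{pmin:.6g}", 8), f(f"{pmax:.6g}", 8),
        f(str(dmin), 8), f(str(dmax), 8),
        f("", 80), f(str(spr), 8), f("", 32),
    ])
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
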