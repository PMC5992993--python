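"""Reading and writing EEG data in European Data Format (EDF).

EDF is the de-facto exchange format for continuous clinical EEG: an ASCII
header (256 bytes, plus 256 bytes per signal) followed by data records of
little-endian 16-bit integers.  Physical values are recovered per channel by
the linear map defined by the header's physical/digital minima and maxima.

The reader accepts plain EDF and continuous EDF+ ("EDF+C"); annotation
channels ("EDF Annotations") are discarded so that the returned array holds
EEG signals only.  All retained channels must share one sampling rate.
Data are returned as a (n_t, n_ch) array — time samples along the rows —
which is the contract every downstream function in this package assumes.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EEGRecord",
    "ElectrodeLayout",
    "read_edf",
    "write_edf",
    "read_xyz",
]

_ANNOTATION_LABEL = "EDF Annotations"
_DIG_MAX = 32767  # symmetric 16-bit digital range used by write_edf


@dataclass
class ElectrodeLayout:
    """Electrode positions as (label, x, y, z) cartesian coordinates.

    Units are arbitrary; only relative geometry is ever used.  Labels must
    be unique and at least two electrodes are required.
    """

    entries: list[tuple[str, float, float, float]]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("an electrode layout needs at least 2 entries")
        labels = [e[0] for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) array of cartesian coordinates, row order as in the file."""
        return np.array([e[1:] for e in self.entries], dtype=float)


@dataclass
class EEGRecord:
    """Multichannel EEG: data in microvolts, shape (n_t, n_ch).

    Time runs along the first axis.  ``layout`` is optional; when present its
    labels must cover all channel names.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    layout: ElectrodeLayout | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_t, n_ch) array")
        n_t, n_ch = self.data.shape
        if n_t < 1 or n_ch < 2:
            raise ValueError("need n_t >= 1 and n_ch >= 2")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length must equal n_ch")
        if self.layout is not None:
            missing = set(self.channel_names) - set(self.layout.labels)
            if missing:
                raise ValueError(f"layout lacks electrodes {sorted(missing)}")

    @property
    def n_t(self) -> int:
        return self.data.shape[0]

    @property
    def n_ch(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# EDF header plumbing
# ---------------------------------------------------------------------------

def _ascii(raw: bytes) -> str:
    try:
        return raw.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise ValueError("malformed EDF header: non-ASCII bytes") from exc


def _ascii_num(raw: bytes, kind=float):
    s = _ascii(raw)
    try:
        return kind(s)
    except ValueError as exc:
        raise ValueError(f"malformed EDF header field: {s!r}") from exc


def read_edf(path: str | os.PathLike) -> EEGRecord:
    """Read an EDF/EDF+C file into an :class:`EEGRecord`.

    Digital values are scaled to physical units (microvolts for EEG channels)
    using each channel's header calibration.  Annotation channels are dropped.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On a malformed header, zero data records, a discontinuous (EDF+D)
        file, or heterogeneous sampling rates across retained channels.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise ValueError("malformed EDF header: file shorter than 256 bytes")
        _ascii(fixed[:8])  # version
        reserved = _ascii(fixed[192:236])
        if reserved.startswith("EDF+D"):
            raise ValueError("discontinuous EDF+D files are not supported")
        header_bytes = _ascii_num(fixed[184:192], int)
        n_records = _ascii_num(fixed[236:244], int)
        duration = _ascii_num(fixed[244:252], float)
        n_sig = _ascii_num(fixed[252:256], int)
        if n_sig < 1:
            raise ValueError("malformed EDF header: no signals")
        if header_bytes != 256 + 256 * n_sig:
            raise ValueError("malformed EDF header: inconsistent header size")
        if n_records <= 0:
            raise ValueError("EDF file declares zero data records")
        if duration <= 0:
            raise ValueError("malformed EDF header: non-positive record duration")

        sig = fh.read(256 * n_sig)
        if len(sig) < 256 * n_sig:
            raise ValueError("malformed EDF header: truncated signal headers")

        # per-signal field blocks, stored column-major on disk:
        # all labels, then all transducers, etc.
        pos = 0
        blocks = {}
        for name, width in [("label", 16), ("transducer", 80), ("dim", 8),
                            ("phys_min", 8), ("phys_max", 8),
                            ("dig_min", 8), ("dig_max", 8),
                            ("prefilter", 80), ("spr", 8), ("reserved", 32)]:
            blocks[name] = [sig[pos + i * width: pos + (i + 1) * width] for i in range(n_sig)]
            pos += width * n_sig

        labels = [_ascii(b) for b in blocks["label"]]
        phys_min = [_ascii_num(b) for b in blocks["phys_min"]]
        phys_max = [_ascii_num(b) for b in blocks["phys_max"]]
        dig_min = [_ascii_num(b, int) for b in blocks["dig_min"]]
        dig_max = [_ascii_num(b, int) for b in blocks["dig_max"]]
        spr = [_ascii_num(b, int) for b in blocks["spr"]]

        rec_len = sum(spr)
        payload = fh.read(2 * rec_len * n_records)
        if len(payload) < 2 * rec_len * n_records:
            raise ValueError("EDF payload shorter than declared by the header")

    raw = np.frombuffer(payload, dtype="<i2").reshape(n_records, rec_len)

    keep = [i for i in range(n_sig) if labels[i] != _ANNOTATION_LABEL]
    if not keep:
        raise ValueError("EDF file contains only annotation channels")
    rates = {spr[i] for i in keep}
    if len(rates) > 1:
        raise ValueError(
            f"heterogeneous sampling rates across signal channels: {sorted(rates)}"
        )
    samples = spr[keep[0]]
    fs = samples / duration

    starts = np.concatenate(([0], np.cumsum(spr)))
    data = np.empty((n_records * samples, len(keep)), dtype=float)
    for col, i in enumerate(keep):
        dig = raw[:, starts[i]: starts[i] + spr[i]].reshape(-1).astype(float)
        denom = dig_max[i] - dig_min[i]
        if denom == 0:
            raise ValueError(f"malformed EDF header: zero digital range on channel {labels[i]}")
        gain = (phys_max[i] - phys_min[i]) / denom
        offset = phys_min[i] - gain * dig_min[i]
        data[:, col] = dig * gain + offset

    return EEGRecord(data=data, fs=fs, channel_names=[labels[i] for i in keep])


def _fmt(value, width: int) -> bytes:
    """Format a header field into exactly ``width`` ASCII bytes."""
    s = str(value)
    if isinstance(value, float):
        if value == int(value) and abs(value) < 10 ** (width - 2):
            s = str(int(value))
        else:
            s = f"{value:.{width}g}"[:width]
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write an :class:`EEGRecord` as a plain EDF file.

    The physical range of each channel is set symmetrically from its data
    range (never zero-width), against a symmetric 16-bit digital range, so
    the round-trip error is at most one quantization step,
    (phys_max − phys_min) / (2^16 − 1).

    One-second data records are used when the sampling rate is an integer
    dividing ``n_t``; otherwise the whole signal is written as one record.
    """
    data = np.asarray(record.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot write non-finite samples to EDF")
    n_t, n_ch = data.shape

    fs = float(record.fs)
    if abs(fs - round(fs)) < 1e-9 and n_t % int(round(fs)) == 0:
        spr = int(round(fs))
        duration = 1.0
        n_records = n_t // spr
    else:
        spr = n_t
        duration = n_t / fs
        n_records = 1

    pmax = np.maximum(np.max(np.abs(data), axis=0), 1.0)
    scale = _DIG_MAX / pmax
    dig = np.rint(data * scale).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    fixed = b"".join([
        _fmt("0", 8),
        _fmt("", 80),                    # patient id
        _fmt("", 80),                    # recording id
        _fmt("01.01.00", 8),
        _fmt("00.00.00", 8),
        _fmt(header_bytes, 8),
        _fmt("", 44),
        _fmt(n_records, 8),
        _fmt(duration, 8),
        _fmt(n_ch, 4),
    ])

    def col(values, width):
        return b"".join(_fmt(v, width) for v in values)

    sig = b"".join([
        col(record.channel_names, 16),
        col([""] * n_ch, 80),
        col(["uV"] * n_ch, 8),
        col([float(-p) for p in pmax], 8),
        col([float(p) for p in pmax], 8),
        col([-_DIG_MAX] * n_ch, 8),
        col([_DIG_MAX] * n_ch, 8),
        col([""] * n_ch, 80),
        col([spr] * n_ch, 8),
        col([""] * n_ch, 32),
    ])

    with open(path, "wb") as fh:
        fh.write(fixed + sig)
        for r in range(n_records):
            block = dig[r * spr:(r + 1) * spr]  # (spr, n_ch)
            fh.write(block.T.tobytes())         # channel-sequential within record


def read_xyz(path: str | os.PathLike) -> ElectrodeLayout:
    """Read an electrode coordinate file: one ``label x y z`` row per electrode.

    Fields may be separated by whitespace or commas; a single leading header
    row (non-numeric coordinates) is tolerated and skipped.
    """
    entries: list[tuple[str, float, float, float]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for idx, line in enumerate(lines):
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 4:
            raise ValueError(f"line {idx + 1}: expected 'label x y z', got {line!r}")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            if idx == 0:
                continue  # header row
            raise ValueError(f"line {idx + 1}: non-numeric coordinate in {line!r}")
        entries.append((parts[0], x, y, z))
    return ElectrodeLayout(entries)
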