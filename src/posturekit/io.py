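"""Recording file format, the multiplexed frame protocol, and parse errors.

Recordings are plain CSV with a versioned header:

    # posturekit-recording v1
    # spec: {"range_g": 2.0, ...}
    # seed: 1
    # label: 0.0000,10.0000,static pitch=30 roll=0
    placement,t,ax,ay,az,label
    CERVICAL,0.0000,0,0,1024,static

Counts are integers, t in seconds with 4 decimals; the structured ``#``
header lines carry the sensor spec, seed and authoritative ground-truth
labels so the round-trip is lossless (the per-row label column lists the
kinds active at that sample for human readability).  Serialisation is
byte-deterministic for a fixed recording.

The frame stream mirrors the gateway's round-robin acquisition: one sample
per channel per tick, channel ids 1–5 following the five enable lines, with
contiguous sequence numbers; a dropped frame is detected as a sequence gap
and reported as the missing (tick, channel) pairs.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .sensor import AccelTriplet, Label, Placement, Recording, SensorSpec

__all__ = [
    "FORMAT_HEADER",
    "Frame",
    "ParseError",
    "FrameGapError",
    "write_recording",
    "read_recording",
    "frames_from_recording",
    "recording_from_frames",
    "frames_to_bytes",
    "frames_from_bytes",
]

FORMAT_HEADER = "# posturekit-recording v1"
_N_CHANNELS = len(Placement)


class ParseError(ValueError):
    """Malformed recording file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


class FrameGapError(ValueError):
    """Missing frames in a stream; lists the absent (tick, channel) pairs."""

    def __init__(self, gaps: list[tuple[int, int]]):
        self.gaps = gaps
        super().__init__(f"missing frames at (tick, channel): {gaps}")


class Frame(NamedTuple):
    """One multiplexed acquisition frame: channel 1–5, sample, sequence no."""

    seq: int
    channel: int
    sample: AccelTriplet


# ---------------------------------------------------------------------------
# Recording CSV


def write_recording(recording: Recording, path) -> None:
    lines = [FORMAT_HEADER]
    lines.append("# spec: " + json.dumps(asdict(recording.spec), sort_keys=True))
    if recording.seed is not None:
        lines.append(f"# seed: {recording.seed}")
    for lab in recording.labels:
        lines.append(f"# label: {lab.start:.4f},{lab.end:.4f},{lab.kind}")
    lines.append("placement,t,ax,ay,az,label")
    placements = [p for p in Placement if p in recording.channels]
    labs = recording.labels
    for i, t in enumerate(recording.t):
        active = ";".join(l.kind.split()[0] for l in labs
                          if l.start - 1e-9 <= t <= l.end + 1e-9)
        for p in placements:
            ax, ay, az = recording.channels[p][i]
            lines.append(f"{p.value},{t:.4f},{ax},{ay},{az},{active}")
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_recording(path) -> Recording:
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or raw[0].strip() != FORMAT_HEADER:
        raise ParseError("missing or unsupported format header "
                         f"(expected {FORMAT_HEADER!r})", 1)
    spec = SensorSpec()
    seed = None
    labels: list[Label] = []
    body_start = None
    for ln, line in enumerate(raw[1:], start=2):
        s = line.strip()
        if s.startswith("# spec:"):
            d = json.loads(s[len("# spec:"):])
            d["bias_g"] = tuple(d.get("bias_g", (0.0, 0.0, 0.0)))
            spec = SensorSpec(**d)
        elif s.startswith("# seed:"):
            seed = int(s[len("# seed:"):])
        elif s.startswith("# label:"):
            start_s, end_s, kind = s[len("# label:"):].strip().split(",", 2)
            labels.append(Label(float(start_s), float(end_s), kind))
        elif s.startswith("#") or not s:
            continue
        else:
            if s != "placement,t,ax,ay,az,label":
                raise ParseError("expected column header "
                                 "'placement,t,ax,ay,az,label'", ln)
            body_start = ln + 1
            break
    if body_start is None:
        raise ParseError("no data rows found")

    data: dict[Placement, list[tuple[float, int, int, int]]] = {}
    for ln, line in enumerate(raw[body_start - 1:], start=body_start):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise ParseError(f"expected 6 fields, got {len(parts)}", ln)
        name, ts, axs, ays, azs, _lab = parts
        try:
            p = Placement(name)
        except ValueError:
            raise ParseError(f"unknown placement {name!r}", ln) from None
        try:
            row = (float(ts), int(axs), int(ays), int(azs))
        except ValueError:
            raise ParseError("malformed numeric field", ln) from None
        data.setdefault(p, []).append(row)

    if not data:
        raise ParseError("no data rows found")
    channels: dict[Placement, np.ndarray] = {}
    t_ref = None
    for p, rows in data.items():
        arr = np.array(rows)
        t = arr[:, 0]
        if np.any(np.diff(t) <= 0):
            raise ParseError(f"timestamps of {p.value} are not strictly increasing")
        if t_ref is None:
            t_ref = t
        elif t.shape != t_ref.shape or not np.allclose(t, t_ref, atol=1e-6):
            raise ParseError(f"channel {p.value} timestamps differ from the others")
        channels[p] = arr[:, 1:].astype(np.int64)
    try:
        return Recording(spec, t_ref, channels, labels, seed)
    except ValueError as e:
        raise ParseError(str(e)) from None


# ---------------------------------------------------------------------------
# Frame protocol


def frames_from_recording(recording: Recording) -> Iterator[Frame]:
    """Serialise a recording in round-robin channel order, one frame per
    channel per tick, with contiguous sequence numbers."""
    placements = list(Placement)
    for p in placements:
        if p not in recording.channels:
            raise ValueError(f"frame stream needs all channels; missing {p.value}")
    seq = 0
    for i, t in enumerate(recording.t):
        for ch, p in enumerate(placements, start=1):
            ax, ay, az = recording.channels[p][i]
            yield Frame(seq, ch, AccelTriplet(int(ax), int(ay), int(az), float(t)))
            seq += 1


def recording_from_frames(frames: Iterable[Frame], spec: SensorSpec | None = None,
                          labels: list[Label] | None = None,
                          seed: int | None = None) -> Recording:
    """Reassemble a recording from a frame stream.

    Raises :class:`FrameGapError` listing every missing (tick, channel) if
    the sequence numbers are not contiguous.
    """
    spec = spec or SensorSpec()
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame stream")
    seqs = {f.seq for f in frames}
    n_total = max(seqs) + 1
    missing = sorted(set(range(n_total)) - seqs)
    if missing:
        gaps = [(s // _N_CHANNELS, s % _N_CHANNELS + 1) for s in missing]
        raise FrameGapError(gaps)
    n_ticks = n_total // _N_CHANNELS
    placements = list(Placement)
    t = np.zeros(n_ticks)
    channels = {p: np.zeros((n_ticks, 3), dtype=np.int64) for p in placements}
    for f in sorted(frames, key=lambda f: f.seq):
        tick = f.seq // _N_CHANNELS
        p = placements[f.channel - 1]
        if f.channel != f.seq % _N_CHANNELS + 1:
            raise ValueError(f"frame {f.seq} breaks round-robin channel order")
        channels[p][tick] = (f.sample.ax, f.sample.ay, f.sample.az)
        t[tick] = f.sample.t
    return Recording(spec, t, channels, labels or [], seed)


_FRAME_STRUCT = struct.Struct("<IBfhhh")  # seq, channel, t, ax, ay, az


def frames_to_bytes(frames: Iterable[Frame]) -> bytes:
    """Length-prefixed binary frame stream (for the streaming demo)."""
    out = bytearray()
    for f in frames:
        payload = _FRAME_STRUCT.pack(f.seq, f.channel, f.sample.t,
                                     f.sample.ax, f.sample.ay, f.sample.az)
        out.append(len(payload))
        out += payload
    return bytes(out)


def frames_from_bytes(blob: bytes) -> Iterator[Frame]:
    i = 0
    while i < len(blob):
        n = blob[i]
        i += 1
        seq, ch, t, ax, ay, az = _FRAME_STRUCT.unpack(blob[i:i + n])
        i += n
        yield Frame(seq, ch, AccelTriplet(ax, ay, az, t))
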