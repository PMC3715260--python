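"""Alignment of the master serial stream into beacon-delimited frames.

The master mirrors every beacon as a ``TXMST`` marker on the serial
line, which divides time into frames of one expected data packet per
slave. This module reconstructs that frame structure from the recorded
stream: it assigns every data packet to its frame, marks the slots of
packets that never arrived as *missing*, recognises duplicates caused by
lost acknowledgements, re-attaches late packets to the frame they belong
to, and finally interpolates the missing samples so downstream feature
extraction sees a gap-free multi-channel signal.

Frame membership is decided by stream order (packets between marker *k*
and *k+1* belong to frame *k*) refined by per-slave sequence-number
tracking, with all comparisons modulo 256.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import packet_codec as pc

#: classification window (frames) for modular sequence comparisons
SEQ_WINDOW = 8

FILLED = "filled"
MISSING = "missing"
INTERPOLATED = "interpolated"


def seq_delta(a: int, b: int) -> int:
    """Signed distance a→b modulo 256, in [-128, 127]."""
    return ((b - a + 128) % 256) - 128


@dataclass
class Slot:
    """One (frame, slave) cell of the alignment grid."""

    status: str = MISSING
    seq: int = -1
    samples: Optional[np.ndarray] = None  # (samples_per_packet, 3) int


@dataclass
class Frame:
    """One beacon-delimited frame: one slot per configured slave."""

    index: int
    marker_seq: int = -1
    synthetic: bool = False  # opened without a marker (lost-marker recovery)
    slots: Dict[int, Slot] = field(default_factory=dict)

    def complete(self, n_slaves: int) -> bool:
        return all(
            self.slots.get(s, Slot()).status == FILLED
            for s in range(1, n_slaves + 1)
        )


@dataclass
class Diagnostics:
    """Counts of alignment anomalies over one stream."""

    frames: int = 0
    markers: int = 0
    missing: int = 0
    duplicates: int = 0
    late: int = 0
    seq_gaps: int = 0
    unknown_source: int = 0
    corrupt_records: int = 0

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


def align(
    records: Sequence[pc.SerialRecord],
    n_slaves: int,
    samples_per_packet: int = pc.SAMPLES_PER_PACKET,
) -> Tuple[List[Frame], Diagnostics]:
    """Group serial records into frames, marking absent packets missing.

    Implements the alignment procedure branch by branch: a marker closes
    the running frame (absent slaves are marked missing) and opens the
    next; a data packet whose (source, sequence) repeats an already
    filled slot is a retransmission duplicate and leaves the frame
    unchanged; a packet whose expected sequence number matches a
    still-missing slot of the immediately preceding frame is the late
    arrival of that frame's packet and cancels the missing mark; a new
    packet hitting an already-filled slot means its frame marker was
    never seen, so the running frame is closed and a synthetic one is
    opened. Per-slave expected sequence numbers are updated after every
    accepted packet (modulo 256).
    """
    diags = Diagnostics()
    frames: List[Frame] = []
    current: Optional[Frame] = None
    expected_seq: Dict[int, Optional[int]] = {
        s: None for s in range(1, n_slaves + 1)
    }

    def close_current() -> None:
        nonlocal current
        if current is None:
            return
        for s in range(1, n_slaves + 1):
            slot = current.slots.setdefault(s, Slot())
            if slot.status != FILLED:
                slot.status = MISSING
                diags.missing += 1
        frames.append(current)
        current = None

    def open_frame(marker_seq: int = -1, synthetic: bool = False) -> None:
        nonlocal current
        current = Frame(index=len(frames), marker_seq=marker_seq,
                        synthetic=synthetic)

    for rec in records:
        if rec.corrupt:
            diags.corrupt_records += 1
            continue
        if rec.kind == "master_marker":
            diags.markers += 1
            close_current()
            open_frame(marker_seq=rec.payload[0] if rec.payload else -1)
            continue

        # data record
        try:
            packet = rec.packet()
        except ValueError:
            diags.corrupt_records += 1
            continue
        s = packet.source_slave
        q = packet.header.sequence_number
        if not 1 <= s <= n_slaves:
            diags.unknown_source += 1
            continue
        samples = np.array(
            [[sm.x, sm.y, sm.z] for sm in packet.samples], dtype=np.int32
        )
        if current is None:
            open_frame(synthetic=True)

        exp = expected_seq[s]
        slot = current.slots.get(s)

        if slot is not None and slot.status == FILLED:
            if slot.seq == q:
                # retransmission after a lost ACK: same packet twice
                diags.duplicates += 1
                continue
            # genuinely new packet: its marker was lost — new frame
            close_current()
            open_frame(synthetic=True)

        if exp is not None and q == exp and frames and not current.slots:
            prev_slot = frames[-1].slots.get(s)
            if prev_slot is not None and prev_slot.status == MISSING:
                # the packet the previous frame waited for arrived late,
                # right after the marker: cancel the missing mark
                prev_slot.status = FILLED
                prev_slot.seq = q
                prev_slot.samples = samples
                diags.missing -= 1
                diags.late += 1
                expected_seq[s] = (q + 1) % 256
                continue

        if exp is not None and q != exp:
            delta = seq_delta(exp, q)
            if 0 < delta <= SEQ_WINDOW:
                # at least one earlier packet from this slave was lost
                diags.seq_gaps += 1
            # behind-window or ahead-of-window sequences are still stored;
            # the slot grid, not the counter, is authoritative

        current.slots[s] = Slot(status=FILLED, seq=q, samples=samples)
        expected_seq[s] = (q + 1) % 256

    # trailing partial frame: closed, absentees marked missing
    close_current()
    diags.frames = len(frames)
    return frames, diags


# ---------------------------------------------------------------------------
# Aligned session container
# ---------------------------------------------------------------------------

class AlignedSession:
    """Frame-aligned multi-slave sample matrix with validity mask.

    ``values`` has one row per sample time and three columns per slave
    (x, y, z in raw counts, NaN where missing); ``status`` holds one
    label per (row, slave) in {filled, missing, interpolated}.
    """

    def __init__(
        self,
        frames: List[Frame],
        diagnostics: Diagnostics,
        n_slaves: int,
        sampling_rate_hz: float = 160.0,
        samples_per_packet: int = pc.SAMPLES_PER_PACKET,
    ) -> None:
        self.frames = frames
        self.diagnostics = diagnostics
        self.n_slaves = n_slaves
        self.sampling_rate_hz = sampling_rate_hz
        self.samples_per_packet = samples_per_packet

        n_rows = len(frames) * samples_per_packet
        self.values = np.full((n_rows, 3 * n_slaves), np.nan)
        self.status = np.full((n_rows, n_slaves), MISSING, dtype=object)
        for f_i, frame in enumerate(frames):
            r0 = f_i * samples_per_packet
            for s in range(1, n_slaves + 1):
                slot = frame.slots.get(s, Slot())
                if slot.status == FILLED and slot.samples is not None:
                    c0 = 3 * (s - 1)
                    self.values[r0:r0 + samples_per_packet, c0:c0 + 3] = \
                        slot.samples
                    self.status[r0:r0 + samples_per_packet, s - 1] = FILLED

    # -- views -------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_rows) / self.sampling_rate_hz

    def valid_mask(self) -> np.ndarray:
        """(rows, slaves) boolean: True where data came from a packet."""
        return self.status == FILLED

    def missing_fraction(self) -> float:
        total = len(self.frames) * self.n_slaves
        return self.diagnostics.missing / total if total else 0.0

    def slave_xyz(self, slave_id: int) -> np.ndarray:
        c0 = 3 * (slave_id - 1)
        return self.values[:, c0:c0 + 3]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: time, frame, slave, x, y, z, status."""
        rows = []
        t = self.times
        for s in range(1, self.n_slaves + 1):
            xyz = self.slave_xyz(s)
            rows.append(pd.DataFrame({
                "time_s": t,
                "frame": np.repeat(np.arange(len(self.frames)),
                                   self.samples_per_packet),
                "slave": s,
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "status": self.status[:, s - 1],
            }))
        return pd.concat(rows, ignore_index=True)


def align_stream(
    serial_bytes: bytes,
    n_slaves: int,
    sampling_rate_hz: float = 160.0,
) -> AlignedSession:
    """Parse a raw serial byte stream and align it in one call."""
    records = pc.parse_serial_stream(serial_bytes)
    frames, diags = align(records, n_slaves)
    return AlignedSession(frames, diags, n_slaves, sampling_rate_hz)


def interpolate(session: AlignedSession) -> AlignedSession:
    """Fill missing sample runs by per-channel linear interpolation.

    Interior gaps are linearly interpolated between the nearest valid
    samples of the same channel; leading/trailing gaps are held at the
    nearest valid value. The status mask keeps interpolated samples
    distinguishable from received ones. Idempotent: a session without
    missing samples is returned as an identical copy.
    """
    out = AlignedSession.__new__(AlignedSession)
    out.frames = session.frames
    out.diagnostics = session.diagnostics
    out.n_slaves = session.n_slaves
    out.sampling_rate_hz = session.sampling_rate_hz
    out.samples_per_packet = session.samples_per_packet
    out.values = session.values.copy()
    out.status = session.status.copy()

    for s in range(1, session.n_slaves + 1):
        col_valid = session.status[:, s - 1] == FILLED
        already = session.status[:, s - 1] == INTERPOLATED
        gaps = ~(col_valid | already)
        if not gaps.any():
            continue
        if not (col_valid | already).any():
            raise ValueError(
                f"slave {s} has no valid samples in any channel; "
                "cannot interpolate"
            )
        for axis in range(3):
            c = 3 * (s - 1) + axis
            series = pd.Series(out.values[:, c])
            out.values[:, c] = series.interpolate(
                method="linear", limit_direction="both"
            ).to_numpy()
        out.status[gaps, s - 1] = INTERPOLATED
    return out
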