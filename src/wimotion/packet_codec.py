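"""Byte-exact packet encoders/decoders for the body-area-network dialect.

The wireless dialect follows IEEE 802.15.4 framing with fixed 8-byte
addresses. Sizes are structural constants of the system:

======================  =====
header                   21 B
data payload (16 × 6 B)  96 B
data, pre-transceiver   118 B
data, on-air            121 B
beacon (MAC command)     23 B
acknowledgement           5 B
======================  =====

All multi-byte integers are little-endian (native to the transceiver
family used by the hardware this models). The on-air form prepends a
header-length byte and appends a CRC-16/CCITT frame check sequence; the
full on-air frame never exceeds the 127-byte MAC frame ceiling.

The master forwards every received data packet to the monitoring station
over a serial line, bracketed by 5-byte ASCII delimiters ``TXSTR`` /
``TXEND``; each beacon is mirrored on the serial line as a small marker
record introduced by ``TXMST``, which the alignment stage uses to cut the
stream into frames.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

# ---------------------------------------------------------------------------
# Structural constants
# ---------------------------------------------------------------------------

HEADER_LEN = 21
SAMPLES_PER_PACKET = 16
SAMPLE_LEN = 6
PAYLOAD_LEN = SAMPLES_PER_PACKET * SAMPLE_LEN  # 96
DATA_PACKET_LEN = 1 + HEADER_LEN + PAYLOAD_LEN  # 118 pre-transceiver
DATA_ON_AIR_LEN = DATA_PACKET_LEN + 3  # 121 on-air
BEACON_LEN = 23
ACK_LEN = 5
MAC_FRAME_CEILING = 127

# Frame types carried in the low bits of the first frame-control byte
# (802.15.4 frame-type field).
FRAME_TYPE_BEACON = 0x0
FRAME_TYPE_DATA = 0x1
FRAME_TYPE_ACK = 0x2
FRAME_TYPE_MAC_CMD = 0x3

#: MAC-command identifier used for the internally implemented beacon.
CMD_BEACON_REQUEST = 0x07

DEFAULT_PAN = 0xCAFE
MASTER_ADDR = 0x0000_0000_0000_0001

TXSTR = b"TXSTR"
TXEND = b"TXEND"
TXMST = b"TXMST"

_SAMPLE_STRUCT = struct.Struct("<hhh")
_HEADER_STRUCT = struct.Struct("<HBHQQ")


def slave_addr(slave_id: int) -> int:
    """64-bit source address assigned to slave ``slave_id`` (1-based)."""
    if not 1 <= slave_id <= 0xFF:
        raise ValueError(f"slave_id out of range: {slave_id}")
    return 0x0000_0000_0000_0100 | slave_id


def addr_to_slave(addr: int) -> int:
    """Inverse of :func:`slave_addr`."""
    return addr & 0xFF


# ---------------------------------------------------------------------------
# CRC-16/CCITT (the 802.15.4 FCS: poly x^16 + x^12 + x^5 + 1, init 0)
# ---------------------------------------------------------------------------

def _crc_table() -> List[int]:
    table = []
    for byte in range(256):
        crc = byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ 0x1021) if crc & 0x8000 else (crc << 1)
        table.append(crc & 0xFFFF)
    return table


_CRC_TABLE = _crc_table()


def crc16(data: bytes, init: int = 0x0000) -> int:
    """CRC-16/CCITT over ``data``, as used for the frame check sequence."""
    crc = init
    for b in data:
        crc = ((crc << 8) & 0xFFFF) ^ _CRC_TABLE[((crc >> 8) ^ b) & 0xFF]
    return crc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccelSample:
    """One tri-axial accelerometer sample in raw signed 16-bit counts.

    Counts are device units at the ±6 g full scale; ``index`` is the
    acquisition-order counter and is bookkeeping only — the wire format
    carries exactly the six axis bytes.
    """

    x: int
    y: int
    z: int
    index: int = 0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not -32768 <= v <= 32767:
                raise ValueError(f"axis {name}={v} does not fit in 16 bits")

    def to_bytes(self) -> bytes:
        return _SAMPLE_STRUCT.pack(self.x, self.y, self.z)

    @classmethod
    def from_bytes(cls, raw: bytes, index: int = 0) -> "AccelSample":
        x, y, z = _SAMPLE_STRUCT.unpack(raw)
        return cls(x, y, z, index)


@dataclass(frozen=True)
class MacHeader:
    """21-byte MAC header: frame control, sequence number, PAN, addresses."""

    frame_control: int
    sequence_number: int
    dest_pan: int = DEFAULT_PAN
    dest_addr: int = MASTER_ADDR
    src_addr: int = MASTER_ADDR

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence_number", self.sequence_number % 256)

    @property
    def frame_type(self) -> int:
        return self.frame_control & 0x7

    def to_bytes(self) -> bytes:
        return _HEADER_STRUCT.pack(
            self.frame_control,
            self.sequence_number,
            self.dest_pan,
            self.dest_addr,
            self.src_addr,
        )

    @classmethod
    def from_bytes(cls, raw: bytes) -> "MacHeader":
        fc, seq, pan, dest, src = _HEADER_STRUCT.unpack(raw)
        return cls(fc, seq, pan, dest, src)


@dataclass(frozen=True)
class DataPacket:
    """A data packet: length byte, 21-byte header, 16-sample payload."""

    header: MacHeader
    samples: tuple

    def __post_init__(self) -> None:
        if len(self.samples) != SAMPLES_PER_PACKET:
            raise ValueError(
                f"data packet payload must hold exactly {SAMPLES_PER_PACKET} "
                f"samples, got {len(self.samples)}"
            )
        object.__setattr__(self, "samples", tuple(self.samples))

    @property
    def length_byte(self) -> int:
        return HEADER_LEN + PAYLOAD_LEN  # 117

    @property
    def source_slave(self) -> int:
        return addr_to_slave(self.header.src_addr)

    def to_bytes(self) -> bytes:
        payload = b"".join(s.to_bytes() for s in self.samples)
        return bytes([self.length_byte]) + self.header.to_bytes() + payload

    @classmethod
    def from_bytes(cls, raw: bytes) -> "DataPacket":
        if len(raw) != DATA_PACKET_LEN:
            raise ValueError(
                f"data packet must be {DATA_PACKET_LEN} bytes, got {len(raw)}"
            )
        if raw[0] != HEADER_LEN + PAYLOAD_LEN:
            raise ValueError(f"bad length byte {raw[0]}")
        header = MacHeader.from_bytes(raw[1 : 1 + HEADER_LEN])
        body = raw[1 + HEADER_LEN :]
        samples = tuple(
            AccelSample.from_bytes(body[i * SAMPLE_LEN : (i + 1) * SAMPLE_LEN], i)
            for i in range(SAMPLES_PER_PACKET)
        )
        return cls(header, samples)


@dataclass(frozen=True)
class BeaconPacket:
    """The periodic beacon, carried as a MAC command frame with no payload.

    Like the ACK, the beacon is generated inside the transceiver and its
    quoted 23-byte size is the complete on-air frame: the 21-byte header
    followed by the 2-byte FCS. The beacon-request command identifier is
    carried in the high byte of the frame-control field (dialect choice;
    only the 23-byte total and the MAC-command frame type are fixed by
    the system).
    """

    header: MacHeader

    def to_bytes(self) -> bytes:
        body = self.header.to_bytes()
        return body + struct.pack("<H", crc16(body))

    @classmethod
    def from_bytes(cls, raw: bytes) -> "BeaconPacket":
        if len(raw) != BEACON_LEN:
            raise ValueError(f"beacon must be {BEACON_LEN} bytes, got {len(raw)}")
        (fcs,) = struct.unpack("<H", raw[HEADER_LEN:])
        if fcs != crc16(raw[:HEADER_LEN]):
            raise ValueError("beacon frame check sequence mismatch")
        return cls(MacHeader.from_bytes(raw[:HEADER_LEN]))


@dataclass(frozen=True)
class AckPacket:
    """5-byte acknowledgement: frame control, echoed sequence number, FCS."""

    sequence_number: int
    frame_control: int = FRAME_TYPE_ACK

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence_number", self.sequence_number % 256)

    def to_bytes(self) -> bytes:
        body = struct.pack("<HB", self.frame_control, self.sequence_number)
        return body + struct.pack("<H", crc16(body))

    @classmethod
    def from_bytes(cls, raw: bytes) -> "AckPacket":
        if len(raw) != ACK_LEN:
            raise ValueError(f"ACK must be {ACK_LEN} bytes, got {len(raw)}")
        fc, seq = struct.unpack("<HB", raw[:3])
        (fcs,) = struct.unpack("<H", raw[3:])
        if fcs != crc16(raw[:3]):
            raise ValueError("ACK frame check sequence mismatch")
        return cls(seq, fc)


@dataclass(frozen=True)
class SerialRecord:
    """One record of the master → monitoring-station serial stream.

    ``kind`` is ``"master_marker"`` (a TXMST beacon mirror whose payload
    is the beacon sequence number byte) or ``"data_record"`` (TXSTR +
    118-byte data packet + TXEND). ``corrupt`` marks records the parser
    recovered delimiters for but whose interior failed to parse.
    """

    kind: str
    payload: bytes = b""
    corrupt: bool = False

    def packet(self) -> DataPacket:
        if self.kind != "data_record":
            raise ValueError("only data records contain a data packet")
        return DataPacket.from_bytes(self.payload)


# ---------------------------------------------------------------------------
# Encoding operations
# ---------------------------------------------------------------------------

def encode_data_packet(
    samples: Sequence[AccelSample],
    seq: int,
    src_slave: int,
    dest_addr: int = MASTER_ADDR,
    dest_pan: int = DEFAULT_PAN,
) -> bytes:
    """Encode 16 samples into the 118-byte pre-transceiver data packet."""
    if len(samples) != SAMPLES_PER_PACKET:
        raise ValueError(
            f"exactly {SAMPLES_PER_PACKET} samples required, got {len(samples)}"
        )
    header = MacHeader(
        frame_control=FRAME_TYPE_DATA,
        sequence_number=seq,
        dest_pan=dest_pan,
        dest_addr=dest_addr,
        src_addr=slave_addr(src_slave),
    )
    return DataPacket(header, tuple(samples)).to_bytes()


def decode_data_packet(raw: bytes) -> DataPacket:
    return DataPacket.from_bytes(raw)


def encode_beacon(seq: int, src_addr: int = MASTER_ADDR) -> bytes:
    """Encode the 23-byte beacon (MAC command frame, broadcast, no payload)."""
    header = MacHeader(
        frame_control=FRAME_TYPE_MAC_CMD | (CMD_BEACON_REQUEST << 8),
        sequence_number=seq,
        dest_pan=DEFAULT_PAN,
        dest_addr=0xFFFF_FFFF_FFFF_FFFF,  # broadcast
        src_addr=src_addr,
    )
    return BeaconPacket(header).to_bytes()


def decode_beacon(raw: bytes) -> BeaconPacket:
    return BeaconPacket.from_bytes(raw)


def encode_ack(seq: int) -> bytes:
    """Encode the 5-byte acknowledgement echoing ``seq``."""
    return AckPacket(seq).to_bytes()


def decode_ack(raw: bytes) -> AckPacket:
    return AckPacket.from_bytes(raw)


def to_on_air(packet_bytes: bytes) -> bytes:
    """Wrap a pre-transceiver packet into its on-air form.

    The transceiver prepends one byte holding the header length and
    appends the two-byte CRC-16 frame check sequence; a 118-byte data
    packet becomes the 121-byte on-air frame.
    """
    framed = bytes([HEADER_LEN]) + packet_bytes
    out = framed + struct.pack("<H", crc16(framed))
    if len(out) > MAC_FRAME_CEILING:
        raise ValueError(f"on-air frame of {len(out)} bytes exceeds 127")
    return out


def from_on_air(frame: bytes) -> bytes:
    """Strip the on-air wrapper, verifying the frame check sequence."""
    if len(frame) < 3:
        raise ValueError("on-air frame too short")
    body, fcs_raw = frame[:-2], frame[-2:]
    (fcs,) = struct.unpack("<H", fcs_raw)
    if fcs != crc16(body):
        raise ValueError("frame check sequence mismatch")
    if body[0] != HEADER_LEN:
        raise ValueError(f"unexpected header-length byte {body[0]}")
    return body[1:]


def check_on_air(frame: bytes) -> bool:
    """True iff the trailing FCS matches the frame body."""
    if len(frame) < 3:
        return False
    (fcs,) = struct.unpack("<H", frame[-2:])
    return fcs == crc16(frame[:-2])


# ---------------------------------------------------------------------------
# Serial stream
# ---------------------------------------------------------------------------

def write_serial_stream(records: Iterable[SerialRecord]) -> bytes:
    """Serialize records, in order, into the monitoring-station byte stream."""
    out = bytearray()
    for rec in records:
        if rec.kind == "master_marker":
            out += TXMST + rec.payload[:1].ljust(1, b"\x00")
        elif rec.kind == "data_record":
            if len(rec.payload) != DATA_PACKET_LEN:
                raise ValueError(
                    f"data record payload must be {DATA_PACKET_LEN} bytes"
                )
            out += TXSTR + rec.payload + TXEND
        else:
            raise ValueError(f"unknown record kind {rec.kind!r}")
    return bytes(out)


def parse_serial_stream(stream: bytes) -> List[SerialRecord]:
    """Parse the serial byte stream back into records.

    The parser is resynchronising: after corrupted or foreign bytes it
    scans forward to the next TXMST/TXSTR delimiter and resumes, so a
    burst of line noise loses at most the record it fell inside.
    """
    records: List[SerialRecord] = []
    i = 0
    n = len(stream)
    while i < n:
        mst = stream.find(TXMST, i)
        str_ = stream.find(TXSTR, i)
        candidates = [p for p in (mst, str_) if p != -1]
        if not candidates:
            break
        pos = min(candidates)
        if pos == mst:
            if pos + 6 <= n:
                records.append(
                    SerialRecord("master_marker", stream[pos + 5 : pos + 6])
                )
                i = pos + 6
            else:  # truncated marker at stream end
                records.append(SerialRecord("master_marker", b"", corrupt=True))
                i = n
        else:
            body_start = pos + 5
            body_end = body_start + DATA_PACKET_LEN
            if body_end + 5 <= n and stream[body_end : body_end + 5] == TXEND:
                payload = stream[body_start:body_end]
                try:
                    DataPacket.from_bytes(payload)
                    records.append(SerialRecord("data_record", payload))
                except ValueError:
                    records.append(
                        SerialRecord("data_record", payload, corrupt=True)
                    )
                i = body_end + 5
            else:
                # Truncated or corrupted record: flag it and resynchronise
                # at the next delimiter after the TXSTR we just consumed.
                records.append(SerialRecord("data_record", b"", corrupt=True))
                i = pos + 5
    return records
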