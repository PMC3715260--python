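# Binary dialect

All multi-byte integers are **little-endian**. Sequence numbers are one
byte and wrap modulo 256; all sequence comparisons are modular.

## MAC header (21 bytes)

| offset | size | field           |
|-------:|-----:|-----------------|
| 0      | 2    | frame control (low 3 bits: frame type — 0 beacon, 1 data, 2 ACK, 3 MAC command; for the internal beacon the high byte carries the command identifier 0x07) |
| 2      | 1    | sequence number |
| 3      | 2    | destination PAN |
| 5      | 8    | destination address |
| 13     | 8    | source address  |

Addresses are fixed 64-bit values: master `0x…0001`, slave *k*
`0x…0100 | k`, broadcast `0xFFFF…FFFF`.

## Data packet — 118 bytes pre-transceiver, 121 on-air

```
[1] length byte = 117 (header 21 + payload 96)
[21] MAC header (frame type 1)
[96] payload: 16 samples × 6 bytes (int16 x, y, z raw counts)
```

The on-air form prepends one byte holding the header length (21) and
appends the 2-byte CRC-16/CCITT frame check sequence (polynomial
x¹⁶+x¹²+x⁵+1, init 0x0000) over everything before it: 121 bytes total,
under the 127-byte MAC frame ceiling.

## Beacon — 23 bytes

The beacon is produced inside the transceiver (like the ACK) and its
quoted size is the complete on-air frame: the 21-byte MAC header
(frame type 3, MAC command; command id 0x07 in the frame-control high
byte; broadcast destination) followed by the 2-byte FCS. *Dialect
choice:* only the 23-byte total and the MAC-command type are fixed by
the system; the interior split is ours.

## Acknowledgement — 5 bytes

```
[2] frame control (type 2)   [1] echoed sequence number   [2] FCS
```

## Serial stream (master → monitoring station)

A concatenation of records, in chronological order:

* **master marker** — `TXMST` (5 ASCII bytes) + 1 byte beacon sequence
  number. Emitted when the master sends a beacon; delimits frames.
  *Dialect choice:* the payload byte beyond the delimiter is ours.
* **data record** — `TXSTR` + 118-byte data packet + `TXEND`.

The parser resynchronises on the next delimiter after corrupted bytes.

## CSV layouts

Sensor/session CSVs: `time_s, slave(_id), x, y, z[, status]`, comma
separated, dot decimal, with `#`-prefixed metadata lines (tool version,
configuration, config hash) before the header row. Feature CSVs:
`time_s, theta_1..5, dtheta_1..5` (degrees, degrees/s).
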