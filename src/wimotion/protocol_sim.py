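"""Discrete-event simulation of the beacon/TDMA body-network protocol.

One master module periodically broadcasts a beacon; up to five slave
modules use the beacon arrival (reference-broadcast style: the beacon
carries no timestamp) to start sampling each new data packet
synchronously, then transmit the previous packet in their TDMA slot and
wait for an acknowledgement, retransmitting up to three times. The
master forwards every received data packet — and a small marker for
every beacon it sends — to the monitoring station over a serial line.

The simulator reproduces the protocol's behaviours event by event:

- master beacon-period estimation from observed packet-fill durations,
  then a programmed timer with configurable Gaussian jitter;
- slave synchronisation from the mean of N consecutive beacon intervals,
  with restart when a beacon is missed mid-sync;
- double buffering with timer-driven buffer swap when a beacon is lost;
- late-beacon handling (partial samples discarded, new packet started);
- an energy-save resynchronisation mode after a threshold of
  consecutive lost beacons;
- CSMA-CA modelled as a bounded random backoff before channel access;
- independent per-link packet loss for beacon, data and ACK frames.

Outputs are the raw master serial byte stream plus a time-ordered event
log that doubles as ground truth for the alignment stage.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import packet_codec as pc

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: seconds of airtime per on-air byte at the nominal 250 kbit/s of the
#: 2.4 GHz band.
AIRTIME_PER_BYTE = 32e-6
ACK_TURNAROUND = 192e-6
UNIT_BACKOFF = 320e-6


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated session.

    Defaults describe the nominal system: five slaves sampling at
    160 Hz, sixteen samples per packet (hence a ~100 ms beacon period),
    13 ms TDMA slots and three retransmissions. Jitter defaults come
    from the hardware characterisation of the modelled modules
    (master timer jitter σ = 11.7 µs, max 67.17 µs) and are model
    parameters, not reproduction targets.
    """

    n_slaves: int = 5
    sampling_rate_hz: float = 160.0
    samples_per_packet: int = 16
    session_duration_s: float = 900.0

    # per-transmission loss probabilities
    beacon_loss: float = 0.0
    data_loss: float = 0.0
    ack_loss: float = 0.0

    # timing
    slot_duration_ms: float = 13.0
    max_retransmissions: int = 3
    ack_timeout_ms: float = 2.0

    # jitter model (zero-mean Gaussian, clipped at max)
    master_jitter_sigma_us: float = 11.70
    master_jitter_max_us: float = 67.17
    slave_jitter_sigma_us: float = 100.0
    slave_jitter_max_us: float = 1000.0
    accel_jitter_sigma_us: float = 20.76

    # synchronisation
    pre_synchronized: bool = True
    slave_sync_beacons: int = 5
    lost_beacon_resync_threshold: int = 10
    master_sync_observations: int = 32
    beacon_margin_ms: float = 2.0

    # CSMA-CA bounded backoff (unslotted style)
    csma_enabled: bool = True
    csma_min_be: int = 3
    csma_max_be: int = 5

    # per-module clocks: phase offset (s) and drift (ppm), master first
    clock_phase_s: Tuple[float, ...] = ()
    clock_drift_ppm: Tuple[float, ...] = ()

    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_slaves <= 5:
            raise ValueError("n_slaves must be between 1 and 5")
        for name in ("beacon_loss", "data_loss", "ack_loss"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.session_duration_s <= 0:
            raise ValueError("session_duration_s must be positive")
        if self.samples_per_packet < 1 or self.sampling_rate_hz <= 0:
            raise ValueError("invalid sampling configuration")

    @property
    def nominal_period_s(self) -> float:
        return self.samples_per_packet / self.sampling_rate_hz


@dataclass(frozen=True)
class Event:
    """One timestamped entry of the session event log."""

    time: float
    kind: str
    module: str
    seq: int = -1
    frame: int = -1
    detail: str = ""


class EventLog:
    """Time-ordered protocol event log; the oracle for alignment tests."""

    def __init__(self) -> None:
        self.events: List[Event] = []

    def add(self, time: float, kind: str, module: str, seq: int = -1,
            frame: int = -1, detail: str = "") -> None:
        self.events.append(Event(time, kind, module, seq, frame, detail))

    def count(self, kind: str, module: Optional[str] = None) -> int:
        return sum(
            1 for e in self.events
            if e.kind == kind and (module is None or e.module == module)
        )

    def of_kind(self, *kinds: str) -> List[Event]:
        return [e for e in self.events if e.kind in kinds]

    def to_rows(self) -> List[dict]:
        return [e.__dict__.copy() for e in self.events]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


# ---------------------------------------------------------------------------
# Synchronisation estimators (used both standalone and inside the loop)
# ---------------------------------------------------------------------------

def master_sync(observed_fill_durations: Sequence[float]) -> float:
    """Beacon period from observed packet-fill durations.

    The master measures how long it takes on average to fill one data
    packet from its own accelerometer and programs its beacon timer with
    the mean; the crystal-driven timer then has far less jitter than
    triggering directly off the accelerometer.
    """
    durations = np.asarray(observed_fill_durations, dtype=float)
    if durations.size == 0:
        raise ValueError("at least one fill duration is required")
    return float(durations.mean())


def slave_sync(beacon_arrival_times: Sequence[float], n_intervals: int) -> float:
    """Sampling-timer period from N consecutive beacon intervals.

    Requires at least ``n_intervals + 1`` consecutive arrivals; returns
    the mean of the last ``n_intervals`` inter-beacon intervals.
    """
    arrivals = np.asarray(beacon_arrival_times, dtype=float)
    if arrivals.size < n_intervals + 1:
        raise ValueError(
            f"need at least {n_intervals + 1} consecutive beacon arrivals, "
            f"got {arrivals.size}"
        )
    return float(np.diff(arrivals[-(n_intervals + 1):]).mean())


def jitter_stats(log: EventLog, nominal_period_s: float) -> Dict[str, Dict[str, float]]:
    """σ and max of timing deviations for beacon and data packets.

    Deviation is (observed − nominal) consecutive inter-packet interval.
    Because each transmission time carries its own independent timing
    error around a non-accumulating schedule, an interval deviation is
    the difference of two such errors; its standard deviation is √2
    times the per-packet σ, so the estimator divides by √2 to report
    the per-packet timing jitter. Values are given in microseconds and
    as a percentage of the beacon period.
    """
    out: Dict[str, Dict[str, float]] = {}

    def stats(times: np.ndarray) -> Optional[Dict[str, float]]:
        if times.size < 2:
            return None
        dev = np.diff(np.sort(times)) - nominal_period_s
        sigma = float(dev.std() / np.sqrt(2.0))
        return {
            "mean_us": float(dev.mean() * 1e6),
            "sigma_us": sigma * 1e6,
            "max_us": float(np.abs(dev).max() * 1e6),
            "sigma_pct": sigma / nominal_period_s * 100.0,
            "max_pct": float(np.abs(dev).max() / nominal_period_s * 100.0),
            "n_intervals": float(dev.size),
        }

    beacon_times = np.array([e.time for e in log.of_kind("beacon_sent")])
    if beacon_times.size < 2:
        raise ValueError("jitter statistics need at least two beacons")
    out["beacon"] = stats(beacon_times)

    modules = sorted({e.module for e in log.of_kind("data_sent")})
    per_slave = []
    for m in modules:
        t = np.array([e.time for e in log if e.kind == "data_sent"
                      and e.module == m and e.detail != "retransmission"])
        s = stats(t)
        if s is not None:
            per_slave.append(s)
    if per_slave:
        out["data"] = {
            k: float(np.mean([s[k] for s in per_slave]))
            for k in per_slave[0]
        }
    return out


# ---------------------------------------------------------------------------
# Session simulation
# ---------------------------------------------------------------------------

class _Clock:
    """Per-module free-running clock: local = (1 + drift) * global + phase."""

    def __init__(self, phase_s: float, drift_ppm: float) -> None:
        self.phase = phase_s
        self.rate = 1.0 + drift_ppm * 1e-6

    def local(self, t_global: float) -> float:
        return t_global * self.rate + self.phase

    def global_duration(self, local_duration: float) -> float:
        return local_duration / self.rate


class _Slave:
    SYNCING = "synchronizing"
    OPERATING = "operating"

    def __init__(self, slave_id: int, cfg: SimConfig, clock: _Clock) -> None:
        self.id = slave_id
        self.name = f"slave{slave_id}"
        self.cfg = cfg
        self.clock = clock
        self.mode = self.OPERATING if cfg.pre_synchronized else self.SYNCING
        self.period_local = (
            cfg.nominal_period_s * clock.rate if cfg.pre_synchronized else None
        )
        self.sync_arrivals: List[float] = []  # local timestamps
        self.lost_count = 0
        self.seq = 0
        self.sample_counter = 0
        self.buffer_start: Optional[float] = None  # global time
        self.ready_packet: Optional[Tuple[int, int]] = None  # (seq, sample_start)
        self.timer_generation = 0
        self.last_beacon_frame = -1
        self.t_last_swap = -1e9
        self.last_swap_by_timer = False

    def buffer_full(self, now: float) -> bool:
        if self.buffer_start is None:
            return False
        need = self.cfg.samples_per_packet / self.cfg.sampling_rate_hz
        return (now - self.buffer_start) * self.clock.rate >= need * 0.999

    def swap_buffers(self, now: float) -> Tuple[int, int]:
        """Close the active buffer into a ready packet, start the standby one."""
        packet = (self.seq, self.sample_counter)
        self.seq = (self.seq + 1) % 256
        self.sample_counter += self.cfg.samples_per_packet
        self.buffer_start = now
        self.ready_packet = packet
        return packet


class SessionResult:
    """Everything a session produced: bytes, log, config, truth helpers."""

    def __init__(self, serial_bytes: bytes, log: EventLog, config: SimConfig):
        self.serial_bytes = serial_bytes
        self.log = log
        self.config = config

    # -- ground-truth views -------------------------------------------------
    def packet_counts(self) -> Dict[str, int]:
        return {
            "beacon": self.log.count("beacon_sent"),
            "data": self.log.count("data_sent"),
            "ack": self.log.count("ack_sent"),
        }

    def total_transmissions(self) -> int:
        return sum(self.packet_counts().values())

    def n_frames(self) -> int:
        return self.log.count("beacon_sent")

    def delivered_map(self) -> Dict[Tuple[int, int], int]:
        """(frame, slave_id) -> seq for every packet the master received
        (first delivery only; duplicates do not add entries)."""
        out: Dict[Tuple[int, int], int] = {}
        for e in self.log.of_kind("data_received"):
            slave_id = int(e.module.replace("slave", ""))
            key = (e.frame, slave_id)
            out.setdefault(key, e.seq)
        return out

    def undelivered(self) -> List[Tuple[int, int, int]]:
        """(frame, slave_id, seq) for packets that failed all attempts."""
        out = []
        for e in self.log.of_kind("delivery_failed"):
            out.append((e.frame, int(e.module.replace("slave", "")), e.seq))
        return out

    def loss_fraction(self) -> float:
        """Fraction of generated data packets that never reached the master."""
        attempted = {(e.module, e.seq, e.frame)
                     for e in self.log.of_kind("data_sent")}
        failed = len(self.log.of_kind("delivery_failed"))
        return failed / len(attempted) if attempted else 0.0


def run_session(
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    payload: Optional[Dict[int, np.ndarray]] = None,
) -> SessionResult:
    """Simulate one session and return the serial stream plus event log.

    Time starts at 0 = first beacon of the measured session; with
    ``pre_synchronized`` (the default) every slave enters the session
    already synchronised and with a full standby buffer, so the session
    is pure steady-state: every beacon triggers one data packet per
    slave. With ``pre_synchronized=False`` the master first estimates
    its beacon period from packet-fill observations and the slaves run
    the full beacon-interval estimation before sending anything.

    ``payload`` optionally maps slave id → integer count array of shape
    (n, 3); each slave consumes consecutive rows (cycling, tracked by a
    per-slave sample counter that also advances over discarded samples)
    as its accelerometer stream, so the serial stream carries
    reconstructible signals. Without it payloads are zero counts.
    """
    cfg = config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    log = EventLog()
    serial = bytearray()

    n_modules = cfg.n_slaves + 1
    phases = list(cfg.clock_phase_s) + [0.0] * n_modules
    drifts = list(cfg.clock_drift_ppm) + [0.0] * n_modules
    clocks = [_Clock(phases[i], drifts[i]) for i in range(n_modules)]

    slaves = {i: _Slave(i, cfg, clocks[i]) for i in range(1, cfg.n_slaves + 1)}

    # --- master beacon period --------------------------------------------
    if cfg.pre_synchronized:
        beacon_period = cfg.nominal_period_s
    else:
        fills = cfg.nominal_period_s + rng.normal(
            0.0, cfg.accel_jitter_sigma_us * 1e-6, cfg.master_sync_observations
        )
        beacon_period = master_sync(fills)
        log.add(0.0, "master_sync_done", "master",
                detail=f"period={beacon_period:.6f}")

    slot = cfg.slot_duration_ms * 1e-3
    margin = cfg.beacon_margin_ms * 1e-3
    data_airtime = pc.DATA_ON_AIR_LEN * AIRTIME_PER_BYTE
    beacon_airtime = pc.BEACON_LEN * AIRTIME_PER_BYTE
    ack_airtime = pc.ACK_LEN * AIRTIME_PER_BYTE

    def clipped_jitter(sigma_us: float, max_us: float) -> float:
        if sigma_us <= 0:
            return 0.0
        j = rng.normal(0.0, sigma_us)
        return float(np.clip(j, -max_us, max_us)) * 1e-6

    def backoff() -> float:
        if not cfg.csma_enabled:
            return 0.0
        be = int(rng.integers(cfg.csma_min_be, cfg.csma_max_be + 1))
        return float(rng.integers(0, 2 ** be)) * UNIT_BACKOFF

    # --- event queue -------------------------------------------------------
    # entries: (time, tiebreak, handler_name, payload)
    queue: List[tuple] = []
    counter = itertools.count()

    def push(t: float, handler: str, payload: tuple) -> None:
        heapq.heappush(queue, (t, next(counter), handler, payload))

    beacon_seq = [0]
    frame_index = [-1]

    def emit_marker(seq: int) -> None:
        serial.extend(pc.TXMST + bytes([seq % 256]))

    payload_source: Dict[int, np.ndarray] = dict(payload) if payload else {}

    def emit_data_record_with_payload(slave_id: int, seq: int,
                                      sample_start: int) -> None:
        src = payload_source.get(slave_id)
        n = cfg.samples_per_packet
        if src is None:
            samples = [pc.AccelSample(0, 0, 0, sample_start + i)
                       for i in range(n)]
        else:
            idx = (sample_start + np.arange(n)) % len(src)
            samples = [
                pc.AccelSample(int(src[j, 0]), int(src[j, 1]), int(src[j, 2]),
                               sample_start + i)
                for i, j in enumerate(idx)
            ]
        raw = pc.encode_data_packet(samples, seq, slave_id)
        serial.extend(pc.TXSTR + raw + pc.TXEND)

    # ---- handlers ---------------------------------------------------------

    def schedule_slave_timer(sl: _Slave, t_from: float) -> None:
        sl.timer_generation += 1
        wait = sl.clock.global_duration(sl.period_local) + margin
        push(t_from + wait, "slave_timer", (sl.id, sl.timer_generation))

    def start_transmission(sl: _Slave, t_slot_base: float, frame: int) -> None:
        if sl.ready_packet is None:
            return
        seq, sample_start = sl.ready_packet
        sl.ready_packet = None
        t_tx = (t_slot_base + (sl.id - 1) * slot + backoff()
                + clipped_jitter(cfg.slave_jitter_sigma_us,
                                 cfg.slave_jitter_max_us))
        push(t_tx, "data_tx", (sl.id, seq, sample_start, 0, frame))

    def handle_beacon_send(payload: tuple) -> None:
        (k,) = payload
        # schedule by index to keep the count free of float accumulation
        t_sched = k * beacon_period
        t = t_sched + clipped_jitter(cfg.master_jitter_sigma_us,
                                     cfg.master_jitter_max_us)
        if t_sched >= cfg.session_duration_s - 1e-12:
            return
        frame_index[0] = k
        seq = beacon_seq[0]
        beacon_seq[0] = (seq + 1) % 256
        log.add(t, "beacon_sent", "master", seq=seq, frame=k)
        emit_marker(seq)
        t_arrive = t + beacon_airtime
        for sl in slaves.values():
            if rng.random() < cfg.beacon_loss:
                log.add(t_arrive, "beacon_lost", sl.name, seq=seq, frame=k)
            else:
                push(t_arrive, "beacon_rx", (sl.id, seq, k))
        push(t_sched + beacon_period, "beacon_send", (k + 1,))

    def handle_beacon_rx(payload: tuple) -> None:
        slave_id, seq, k = payload
        sl = slaves[slave_id]
        t = payload_time[0]
        log.add(t, "beacon_received", sl.name, seq=seq, frame=k)
        if sl.mode == _Slave.SYNCING:
            t_local = sl.clock.local(t)
            if sl.sync_arrivals:
                gap = t_local - sl.sync_arrivals[-1]
                if len(sl.sync_arrivals) >= 2:
                    mean_gap = (sl.sync_arrivals[-1] - sl.sync_arrivals[0]) / (
                        len(sl.sync_arrivals) - 1)
                    if gap > 1.5 * mean_gap:
                        # missed a beacon mid-sync: restart estimation
                        sl.sync_arrivals = []
                        log.add(t, "sync_restart", sl.name, frame=k)
            sl.sync_arrivals.append(t_local)
            if len(sl.sync_arrivals) >= cfg.slave_sync_beacons + 1:
                sl.period_local = slave_sync(sl.sync_arrivals,
                                             cfg.slave_sync_beacons)
                sl.mode = _Slave.OPERATING
                sl.sync_arrivals = []
                sl.lost_count = 0
                sl.buffer_start = t
                sl.ready_packet = None
                sl.last_swap_by_timer = False
                log.add(t, "resync_exit", sl.name, frame=k,
                        detail=f"period={sl.period_local:.6f}")
                schedule_slave_timer(sl, t)
            return

        # operating mode
        sl.lost_count = 0
        period_g = sl.clock.global_duration(sl.period_local)
        if (sl.last_swap_by_timer
                and (t - sl.t_last_swap) < 0.5 * period_g):
            # The timer already swapped and sent this frame's packet; this
            # beacon is the delayed one. Discard the partial samples
            # acquired since the swap and start a fresh packet so the
            # sampling grid stays aligned with the other slaves.
            n_disc = int((t - sl.buffer_start) * cfg.sampling_rate_hz
                         * sl.clock.rate)
            sl.sample_counter += n_disc
            sl.buffer_start = t
            sl.last_swap_by_timer = False
            log.add(t, "late_beacon_discard", sl.name, frame=k,
                    detail=f"discarded={n_disc}")
            schedule_slave_timer(sl, t)
            sl.last_beacon_frame = k
            return

        if sl.buffer_start is None:
            sl.buffer_start = t
        else:
            sl.swap_buffers(t)
            sl.t_last_swap = t
            log.add(t, "buffer_swap", sl.name, frame=k, detail="beacon")
            start_transmission(sl, t, k)
        sl.last_swap_by_timer = False
        sl.last_beacon_frame = k
        schedule_slave_timer(sl, t)

    def handle_slave_timer(payload: tuple) -> None:
        slave_id, generation = payload
        sl = slaves[slave_id]
        t = payload_time[0]
        if generation != sl.timer_generation or sl.mode != _Slave.OPERATING:
            return
        if t >= cfg.session_duration_s:
            return  # session over; let the queue drain
        # No beacon arrived within period + margin: beacon considered lost
        # by the slave (the master-side loss event is logged separately).
        sl.lost_count += 1
        log.add(t, "beacon_timeout", sl.name, frame=frame_index[0],
                detail=f"consecutive={sl.lost_count}")
        if sl.lost_count >= cfg.lost_beacon_resync_threshold:
            sl.mode = _Slave.SYNCING
            sl.sync_arrivals = []
            sl.ready_packet = None
            sl.buffer_start = None
            log.add(t, "resync_entry", sl.name, frame=frame_index[0])
            return
        if sl.buffer_full(t):
            sl.swap_buffers(t)
            sl.t_last_swap = t
            sl.last_swap_by_timer = True
            log.add(t, "buffer_swap", sl.name, frame=frame_index[0],
                    detail="timer")
            start_transmission(sl, t - margin, frame_index[0])
        schedule_slave_timer(sl, t - margin)

    def handle_data_tx(payload: tuple) -> None:
        slave_id, seq, sample_start, attempt, frame = payload
        sl = slaves[slave_id]
        t = payload_time[0]
        detail = "retransmission" if attempt > 0 else ""
        log.add(t, "data_sent", sl.name, seq=seq, frame=frame, detail=detail)
        if attempt > 0:
            log.add(t, "retransmission", sl.name, seq=seq, frame=frame)
        t_rx = t + data_airtime
        if rng.random() < cfg.data_loss:
            log.add(t_rx, "data_lost", sl.name, seq=seq, frame=frame)
            _maybe_retry(sl, seq, sample_start, attempt, frame, t)
            return
        log.add(t_rx, "data_received", sl.name, seq=seq, frame=frame)
        emit_data_record_with_payload(slave_id, seq, sample_start)
        t_ack = t_rx + ACK_TURNAROUND
        log.add(t_ack, "ack_sent", "master", seq=seq, frame=frame)
        if rng.random() < cfg.ack_loss:
            log.add(t_ack + ack_airtime, "ack_lost", sl.name, seq=seq,
                    frame=frame)
            _maybe_retry(sl, seq, sample_start, attempt, frame, t)
        # ACK received: transaction complete.

    def _maybe_retry(sl: _Slave, seq: int, sample_start: int, attempt: int,
                     frame: int, t_sent: float) -> None:
        if attempt < cfg.max_retransmissions:
            t_retry = (t_sent + data_airtime + ACK_TURNAROUND + ack_airtime
                       + cfg.ack_timeout_ms * 1e-3 + backoff())
            push(t_retry, "data_tx",
                 (sl.id, seq, sample_start, attempt + 1, frame))
        else:
            log.add(t_sent, "delivery_failed", sl.name, seq=seq, frame=frame)

    # --- initial state -----------------------------------------------------
    if cfg.pre_synchronized:
        for sl in slaves.values():
            # warm start: standby buffer filled during the preceding frame
            sl.buffer_start = -cfg.nominal_period_s

    handlers = {
        "beacon_send": handle_beacon_send,
        "beacon_rx": handle_beacon_rx,
        "slave_timer": handle_slave_timer,
        "data_tx": handle_data_tx,
    }
    payload_time = [0.0]

    push(0.0, "beacon_send", (0,))
    while queue:
        t, _, name, payload = heapq.heappop(queue)
        if t > cfg.session_duration_s + 2 * beacon_period:
            break
        payload_time[0] = t
        handlers[name](payload)

    return SessionResult(bytes(serial), log, cfg)


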