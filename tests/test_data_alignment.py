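"""Frame alignment against simulator ground truth, and interpolation."""

import numpy as np
import pytest

from wimotion import data_alignment as da, packet_codec as pc, protocol_sim as ps


def make_packet(slave, seq, fill=0):
    samples = [pc.AccelSample(fill, fill, fill, i) for i in range(16)]
    raw = pc.encode_data_packet(samples, seq, slave)
    return pc.SerialRecord("data_record", raw)


def marker(seq):
    return pc.SerialRecord("master_marker", bytes([seq % 256]))


class TestAlignBranches:
    def test_lossless_session_all_filled(self, small_lossless_session):
        sess = da.align_stream(small_lossless_session.serial_bytes, 5)
        d = sess.diagnostics
        assert d.frames == 50
        assert d.missing == d.duplicates == d.late == d.seq_gaps == 0
        assert all(f.complete(5) for f in sess.frames)

    def test_simulator_dropped_packet_marked_missing(self):
        cfg = ps.SimConfig(n_slaves=5, session_duration_s=30.0,
                           data_loss=0.18, seed=17)
        res = ps.run_session(cfg)
        lost = res.undelivered()
        assert lost, "expected at least one fully lost packet at this rate"
        sess = da.align_stream(res.serial_bytes, 5)
        for frame_idx, slave, _seq in lost:
            assert sess.frames[frame_idx].slots[slave].status == da.MISSING

    def test_duplicate_from_ack_loss_detected_and_content_unchanged(self):
        cfg = ps.SimConfig(n_slaves=3, session_duration_s=20.0,
                           ack_loss=0.3, seed=8)
        res = ps.run_session(cfg)
        sess = da.align_stream(res.serial_bytes, 3)
        assert sess.diagnostics.duplicates > 0
        # duplicates must not corrupt the grid: truth still matches
        truth = res.delivered_map()
        filled = {
            (f.index, s): slot.seq
            for f in sess.frames for s, slot in f.slots.items()
            if slot.status == da.FILLED
        }
        assert filled == truth

    def test_late_packet_reattached_to_its_frame(self):
        # constructed trace: slave 2's frame-1 packet arrives after the
        # frame-2 marker; its expected sequence number identifies it
        records = [
            marker(0), make_packet(1, 10), make_packet(2, 20),
            marker(1), make_packet(1, 11),
            marker(2), make_packet(2, 21),  # late: belongs to frame 1
            make_packet(1, 12), make_packet(2, 22),
        ]
        frames, diags = da.align(records, n_slaves=2)
        assert diags.late == 1
        assert frames[1].slots[2].status == da.FILLED
        assert frames[1].slots[2].seq == 21
        assert frames[2].slots[2].seq == 22
        assert diags.missing == 0

    def test_lost_marker_opens_synthetic_frame(self):
        records = [
            marker(0), make_packet(1, 0), make_packet(2, 0),
            # marker 1 lost in serial link:
            make_packet(1, 1), make_packet(2, 1),
        ]
        frames, diags = da.align(records, n_slaves=2)
        assert len(frames) == 2
        assert frames[1].synthetic
        assert frames[1].slots[1].seq == 1

    def test_unknown_slave_skipped_with_diagnostic(self):
        records = [marker(0), make_packet(5, 0), make_packet(1, 0)]
        frames, diags = da.align(records, n_slaves=2)
        assert diags.unknown_source == 1
        assert frames[0].slots[1].status == da.FILLED

    def test_empty_input(self):
        frames, diags = da.align([], n_slaves=3)
        assert frames == [] and diags.frames == 0

    def test_missing_fraction_matches_event_log(self):
        cfg = ps.SimConfig(n_slaves=4, session_duration_s=40.0,
                           data_loss=0.15, ack_loss=0.05, seed=23)
        res = ps.run_session(cfg)
        sess = da.align_stream(res.serial_bytes, 4)
        total = res.n_frames() * 4
        expected = total - len(res.delivered_map())
        assert sess.diagnostics.missing == expected

    def test_alignment_is_stable_under_reserialisation(self):
        # write the aligned frames back to a stream and re-align
        cfg = ps.SimConfig(n_slaves=3, session_duration_s=10.0,
                           data_loss=0.1, seed=2)
        res = ps.run_session(cfg)
        frames1, diags1 = da.align(
            pc.parse_serial_stream(res.serial_bytes), 3)
        records = []
        for f in frames1:
            records.append(marker(f.marker_seq if f.marker_seq >= 0 else 0))
            for s in sorted(f.slots):
                slot = f.slots[s]
                if slot.status == da.FILLED:
                    samples = [pc.AccelSample(*map(int, row), i)
                               for i, row in enumerate(slot.samples)]
                    records.append(pc.SerialRecord(
                        "data_record",
                        pc.encode_data_packet(samples, slot.seq, s)))
        frames2, diags2 = da.align(records, 3)
        grid1 = {(f.index, s): (sl.status, sl.seq)
                 for f in frames1 for s, sl in f.slots.items()}
        grid2 = {(f.index, s): (sl.status, sl.seq)
                 for f in frames2 for s, sl in f.slots.items()}
        assert grid1 == grid2


class TestInterpolate:
    def _session_from_sine(self, loss_frames=(), n_frames=40):
        """1-slave session whose payload is a 1 Hz sine, some frames lost."""
        t = np.arange(n_frames * 16) / 160.0
        signal = np.rint(200 * np.sin(2 * np.pi * 1.0 * t)).astype(int)
        frames = []
        for f in range(n_frames):
            slot = da.Slot()
            if f not in loss_frames:
                block = np.zeros((16, 3), dtype=int)
                block[:, 2] = signal[f * 16:(f + 1) * 16]
                slot = da.Slot(status=da.FILLED, seq=f % 256, samples=block)
            frames.append(da.Frame(index=f, slots={1: slot}))
        diags = da.Diagnostics(frames=n_frames, missing=len(loss_frames))
        return da.AlignedSession(frames, diags, 1), signal

    def test_identity_when_nothing_missing(self):
        sess, _ = self._session_from_sine()
        out = da.interpolate(sess)
        np.testing.assert_array_equal(out.values, sess.values)
        assert (out.status == sess.status).all()

    def test_constant_block_gap_filled_with_constant(self):
        frames = []
        for f in range(3):
            slot = da.Slot()
            if f != 1:
                block = np.full((16, 3), 7, dtype=int)
                slot = da.Slot(status=da.FILLED, seq=f, samples=block)
            frames.append(da.Frame(index=f, slots={1: slot}))
        sess = da.AlignedSession(frames, da.Diagnostics(frames=3, missing=1), 1)
        out = da.interpolate(sess)
        assert (out.values[16:32, :] == 7).all()
        assert (out.status[16:32, 0] == da.INTERPOLATED).all()

    def test_sine_reconstruction_error_small(self, rng):
        n_frames = 120
        lost = set(rng.choice(np.arange(1, n_frames - 1),
                              size=int(0.03 * n_frames), replace=False))
        sess, signal = self._session_from_sine(lost, n_frames)
        out = da.interpolate(sess)
        recon = out.values[:, 2]
        gaps = sess.status[:, 0] != da.FILLED
        rms = np.sqrt(np.mean((recon[gaps] - signal[gaps]) ** 2))
        assert rms < 0.05 * 200  # < 5 % of amplitude

    def test_idempotent(self, rng):
        sess, _ = self._session_from_sine({3, 10})
        once = da.interpolate(sess)
        twice = da.interpolate(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert (once.status == twice.status).all()

    def test_all_missing_channel_raises(self):
        frames = [da.Frame(index=0, slots={1: da.Slot()})]
        sess = da.AlignedSession(frames, da.Diagnostics(frames=1, missing=1), 1)
        with pytest.raises(ValueError, match="slave 1"):
            da.interpolate(sess)
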