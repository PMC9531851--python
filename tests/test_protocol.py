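"""Wire format, polling reads, change detection, and race tolerance."""

import threading
import time

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosimloop import protocol as proto
from cosimloop.protocol import (
    ConfigError,
    MalformedMessage,
    Message,
    PortBinding,
    ProtocolError,
    RuntimeState,
    load_maxtime,
    parse_message,
    read_port,
    serialize_message,
    unchanged,
    write_port,
    write_raw,
)

finite = st.floats(allow_nan=False, allow_infinity=False,
                   min_value=-1e6, max_value=1e6)


def _in(d, idx=1, label="E"):
    return PortBinding("in", idx, label, d)


def _out(d, idx=1, label="E"):
    return PortBinding("out", idx, label, d)


def _fast_state(**kw):
    return RuntimeState(delay=0.001, **kw)


class TestCodec:
    @settings(max_examples=300, derandomize=True)
    @given(simtime=finite, values=st.lists(finite, max_size=16))
    def test_round_trip_is_exact(self, simtime, values):
        m = Message(float(simtime), tuple(float(v) for v in values))
        assert parse_message(serialize_message(m)) == m

    @pytest.mark.parametrize("msg,text", [
        (Message(0.0, (0.0,) * 6), "[0.0,0.0,0.0,0.0,0.0,0.0,0.0]"),
        (Message(3.0, ()), "[3.0]"),
        (Message(3.0, (110.4, 374.5)), "[3.0,110.4,374.5]"),
    ])
    def test_serialization_format(self, msg, text):
        assert serialize_message(msg) == text

    def test_non_finite_values_refused(self):
        with pytest.raises(ProtocolError):
            serialize_message(Message(0.0, (float("inf"),)))
        with pytest.raises(ProtocolError):
            serialize_message(Message(float("nan"), ()))

    def test_parse_splits_timestamp_from_values(self):
        assert parse_message("[5.0,1.5,-2.0]") == Message(5.0, (1.5, -2.0))

    def test_zero_length_is_incomplete_not_error(self):
        assert parse_message("") is None
        assert parse_message("   \n") is None

    @pytest.mark.parametrize("bad", ["[1.0,2.0", "1.0,2.0]", "[]", "[a,b]", "x"])
    def test_malformed_is_distinct_from_incomplete(self, bad):
        with pytest.raises(MalformedMessage):
            parse_message(bad)


class TestReadPort:
    def test_missing_file_falls_back_to_initial(self, tmp_path):
        state = _fast_state()
        vals = read_port(state, _in(tmp_path), "ym", "[0.0,0.0,0.0]")
        assert vals == [0.0, 0.0]
        assert state.simtime == 0.0

    def test_simtime_is_max_of_observed_times(self, tmp_path):
        state = _fast_state(simtime=2.0)
        (tmp_path / "ym").write_text("[5.0,1.0]")
        assert read_port(state, _in(tmp_path), "ym", "[0.0,0.0]") == [1.0]
        assert state.simtime == 5.0
        # an older stamp never rolls time back
        (tmp_path / "ym").write_text("[3.0,2.0]")
        read_port(state, _in(tmp_path), "ym", "[0.0,0.0]")
        assert state.simtime == 5.0

    def test_zero_byte_file_is_retried_and_counted(self, tmp_path):
        state = _fast_state()
        (tmp_path / "u").write_text("")

        def finish():
            time.sleep(0.02)
            (tmp_path / "u").write_text("[1.0,7.0]")

        t = threading.Thread(target=finish)
        t.start()
        vals = read_port(state, _in(tmp_path), "u", "[0.0,0.0]")
        t.join()
        assert vals == [7.0]
        assert state.retrycount >= 1

    def test_persistent_malformed_content_is_a_protocol_error(self, tmp_path):
        state = _fast_state(malformed_limit=3)
        (tmp_path / "u").write_text("[1.0,2.0")
        with pytest.raises(ProtocolError, match="u"):
            read_port(state, _in(tmp_path), "u", "[0.0,0.0]")

    def test_vector_length_is_fixed_after_first_accept(self, tmp_path):
        state = _fast_state()
        (tmp_path / "u").write_text("[1.0,1.0,2.0]")
        read_port(state, _in(tmp_path), "u", "[0.0,0.0,0.0]")
        (tmp_path / "u").write_text("[2.0,1.0]")
        with pytest.raises(ProtocolError, match="length"):
            read_port(state, _in(tmp_path), "u", "[0.0,0.0,0.0]")

    def test_direction_is_enforced(self, tmp_path):
        with pytest.raises(ProtocolError):
            read_port(_fast_state(), _out(tmp_path), "u", "[0.0]")
        with pytest.raises(ProtocolError):
            write_port(_fast_state(), _in(tmp_path), "u", [1.0])


class TestWritePort:
    def test_delta_advances_time_before_writing(self, tmp_path):
        state = _fast_state(simtime=4.0)
        write_port(state, _out(tmp_path), "u", [1.0, 2.0], delta=1.0)
        assert state.simtime == 5.0
        assert (tmp_path / "u").read_text() == "[5.0,1.0,2.0]"

    def test_zero_delta_writes_are_byte_identical(self, tmp_path):
        state = _fast_state(simtime=2.0)
        write_port(state, _out(tmp_path), "u", [1.0], delta=0.0)
        first = (tmp_path / "u").read_text()
        write_port(state, _out(tmp_path), "u", [1.0], delta=0.0)
        assert (tmp_path / "u").read_text() == first
        assert state.simtime == 2.0

    def test_negative_delta_refused(self, tmp_path):
        with pytest.raises(ProtocolError):
            write_port(_fast_state(), _out(tmp_path), "u", [1.0], delta=-1.0)

    def test_atomic_mode_round_trips(self, tmp_path):
        state = _fast_state(write_mode="atomic")
        write_port(state, _out(tmp_path), "u", [3.0], delta=2.0)
        assert (tmp_path / "u").read_text() == "[2.0,3.0]"
        assert not (tmp_path / "u.tmp~").exists()


class TestUnchanged:
    def test_reactive_port_waits_for_content_beyond_initial(self, tmp_path):
        state = _fast_state()
        binding = _in(tmp_path)
        assert unchanged(state)  # nothing registered yet: enter the loop
        read_port(state, binding, "ym", "[0.0,0.0]")
        assert unchanged(state)  # initial value does not count as new
        (tmp_path / "ym").write_text("[1.0,5.0]")
        read_port(state, binding, "ym", "[0.0,0.0]")
        assert not unchanged(state)

    def test_initiating_port_fires_on_first_read(self, tmp_path):
        state = _fast_state()
        read_port(state, _in(tmp_path), "u", "[0.0,0.0]", fire_on_initial=True)
        assert not unchanged(state)
        # ... but only once
        read_port(state, _in(tmp_path), "u", "[0.0,0.0]")
        assert unchanged(state)

    def test_byte_identical_rewrite_is_not_a_change(self, tmp_path):
        state = _fast_state()
        (tmp_path / "ym").write_text("[1.0,2.0]")
        read_port(state, _in(tmp_path), "ym", "[0.0,0.0]", fire_on_initial=True)
        assert not unchanged(state)
        (tmp_path / "ym").write_text("[1.0,2.0]")  # same bytes
        read_port(state, _in(tmp_path), "ym", "[0.0,0.0]")
        assert unchanged(state)

    def test_any_of_several_inputs_waking_suffices(self, tmp_path):
        state = _fast_state()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        d1.mkdir(), d2.mkdir()
        b1, b2 = _in(d1, 1, "E1"), _in(d2, 2, "E2")
        (d1 / "p").write_text("[1.0,1.0]")
        (d2 / "q").write_text("[1.0,2.0]")
        read_port(state, b1, "p", "[0.0,0.0]", fire_on_initial=True)
        read_port(state, b2, "q", "[0.0,0.0]", fire_on_initial=True)
        assert not unchanged(state)
        # only the second input changes
        (d2 / "q").write_text("[2.0,3.0]")
        read_port(state, b1, "p", "[0.0,0.0]")
        read_port(state, b2, "q", "[0.0,0.0]")
        assert not unchanged(state)

    def test_registerless_read_never_paces(self, tmp_path):
        state = _fast_state()
        (tmp_path / "knob").write_text("[0.0,0.5]")
        read_port(state, _in(tmp_path), "knob", "[0.0,1.0]", register=False)
        assert unchanged(state)


class TestMaxtime:
    def test_default_when_no_files(self, tmp_path):
        state = _fast_state()
        assert load_maxtime(state, [_in(tmp_path)], default=300) == 300.0

    def test_maximum_across_edge_directories(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        d1.mkdir(), d2.mkdir()
        (d1 / proto.MAXTIME_FILENAME).write_text("100")
        (d2 / proto.MAXTIME_FILENAME).write_text("250.0")
        state = _fast_state()
        assert load_maxtime(state, [_in(d1, 1, "A"), _in(d2, 2, "B")]) == 250.0

    def test_unparsable_file_is_a_config_error(self, tmp_path):
        (tmp_path / proto.MAXTIME_FILENAME).write_text("soon")
        with pytest.raises(ConfigError):
            load_maxtime(_fast_state(), [_in(tmp_path)])


class TestConcurrency:
    def test_reader_only_sees_complete_messages(self, tmp_path):
        """Adversarial writer interleaving truncation with full rewrites:
        every vector the reader returns was a complete written message (or
        the initial value)."""
        written = {serialize_message(Message(float(i), (float(i),)))
                   for i in range(1, 60)}
        stop = threading.Event()

        def writer():
            for i in range(1, 60):
                path = tmp_path / "u"
                with open(path, "w") as fh:  # zero-byte window on purpose
                    time.sleep(0.0005)
                    fh.write(serialize_message(Message(float(i), (float(i),))))
                time.sleep(0.0005)
            stop.set()

        state = _fast_state()
        state.delay = 0.0002
        binding = _in(tmp_path)
        seen = []
        t = threading.Thread(target=writer)
        t.start()
        while not stop.is_set():
            seen.append(tuple(read_port(state, binding, "u", "[0.0,0.0]")))
        t.join()
        legal = {(0.0,)} | {(float(i),) for i in range(1, 60)}
        assert set(seen) <= legal
        assert state.retrycount > 0  # the zero-byte window was actually hit

    def test_two_node_loop_reaches_maxtime_when_one_delta_positive(self, tmp_path):
        """Progress: with one initiating node advancing time, both halves of
        the loop reach the horizon in finitely many polls, and every observed
        timestamp sequence is non-decreasing."""
        ea, eb = tmp_path / "EA", tmp_path / "EB"
        ea.mkdir(), eb.mkdir()
        horizon, errors = 5.0, []
        times_a, times_b = [], []

        def node_a():  # initiator: writes with delta 1
            try:
                st_ = _fast_state()
                while st_.simtime < horizon:
                    while unchanged(st_):
                        read_port(st_, _in(eb, 1, "EB"), "b", "[0.0,0.0]",
                                  fire_on_initial=True)
                    times_a.append(st_.simtime)
                    write_port(st_, _out(ea, 1, "EA"), "a", [st_.simtime], delta=1.0)
            except Exception as exc:  # pragma: no cover
                errors.append(exc)

        def node_b():  # reactive echo: delta 0
            try:
                st_ = _fast_state()
                while st_.simtime < horizon:
                    while unchanged(st_):
                        vals = read_port(st_, _in(ea, 1, "EA"), "a", "[0.0,0.0]")
                    times_b.append(st_.simtime)
                    write_port(st_, _out(eb, 1, "EB"), "b", vals, delta=0.0)
            except Exception as exc:  # pragma: no cover
                errors.append(exc)

        ta, tb = threading.Thread(target=node_a), threading.Thread(target=node_b)
        ta.start(), tb.start()
        ta.join(timeout=20), tb.join(timeout=20)
        assert not ta.is_alive() and not tb.is_alive()
        assert not errors
        assert times_a == sorted(times_a) and times_b == sorted(times_b)
        assert max(times_b) >= horizon

    def test_all_zero_delta_never_wakes_the_reader(self, tmp_path):
        """Documented deadlock: constant payload and delta 0 produce
        byte-identical files, so the reader never proceeds."""
        state = _fast_state()
        writer = _fast_state()
        read_port(state, _in(tmp_path), "a", "[0.0,1.0]")
        for _ in range(20):
            write_port(writer, _out(tmp_path), "a", [1.0], delta=0.0)
            read_port(state, _in(tmp_path), "a", "[0.0,1.0]")
            assert unchanged(state)
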