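"""Two-file transmission protocol: marker-gated receipt, atomicity, transports."""

import os
import threading
import time
from pathlib import Path

import pytest

from fedbids.protocol import (
    CommandTransport,
    FLPlan,
    LocalTransport,
    Message,
    ServerSettings,
    TransportError,
    WorkspaceConflictError,
    init_workspace,
    receive,
    receive_any,
    send,
)


def test_workspace_init_creates_subfolders(tmp_path):
    ws = init_workspace(tmp_path / "w", "server")
    for sub in ("inbox", "outbox", "state", "logs", "preproc_cache"):
        assert (tmp_path / "w" / sub).is_dir()
    assert ws.inbox == tmp_path / "w" / "inbox"


def test_workspace_reinit_same_role_is_idempotent(tmp_path):
    init_workspace(tmp_path / "w", "client")
    init_workspace(tmp_path / "w", "client")  # no error


def test_workspace_reinit_other_role_conflicts(tmp_path):
    init_workspace(tmp_path / "w", "client")
    with pytest.raises(WorkspaceConflictError, match="client"):
        init_workspace(tmp_path / "w", "server")


def _payload(tmp_path, content=b"weights", name="update.fcp"):
    p = tmp_path / name
    p.write_bytes(content)
    return p


def test_send_places_payload_then_marker(tmp_path):
    inbox = tmp_path / "inbox"
    payload = _payload(tmp_path)
    msg = Message("client_update", 3, payload, "brussels")
    send(msg, LocalTransport(inbox))
    wire = inbox / "client_update_round3_brussels.fcp"
    marker = inbox / "client_update_round3_brussels.done"
    assert wire.read_bytes() == b"weights"
    assert marker.stat().st_size == 0
    assert marker.stat().st_mtime_ns >= wire.stat().st_mtime_ns


def test_send_missing_payload_leaves_no_marker(tmp_path):
    inbox = tmp_path / "inbox"
    msg = Message("plan", 0, tmp_path / "ghost.json", "server")
    with pytest.raises(FileNotFoundError):
        send(msg, LocalTransport(inbox))
    assert not list(inbox.glob("*")) if inbox.exists() else True


def test_resend_overwrites_single_logical_message(tmp_path):
    inbox = tmp_path / "inbox"
    t = LocalTransport(inbox)
    send(Message("global_model", 1, _payload(tmp_path, b"v1", "m.fcp"),
                 "server"), t)
    send(Message("global_model", 1, _payload(tmp_path, b"v2", "m.fcp"),
                 "server"), t)
    files = sorted(p.name for p in inbox.iterdir())
    assert files == ["global_model_round1_server.done",
                     "global_model_round1_server.fcp"]
    assert (inbox / "global_model_round1_server.fcp").read_bytes() == b"v2"


def test_receive_returns_immediately_when_marker_present(tmp_path):
    inbox = tmp_path / "inbox"
    send(Message("stop", 0, _payload(tmp_path, b"{}", "s.json"), "server"),
         LocalTransport(inbox))
    t0 = time.monotonic()
    msg = receive(inbox, "stop", 0, "server", timeout_s=5, poll_s=0.5)
    assert time.monotonic() - t0 < 0.4
    assert msg.payload_path.name == "stop_round0_server.json"


def test_receive_blocks_on_payload_without_marker(tmp_path):
    inbox = tmp_path / "inbox"
    inbox.mkdir()
    (inbox / "client_update_round1_x.fcp").write_bytes(b"half")
    with pytest.raises(TimeoutError, match="client_update_round1_x"):
        receive(inbox, "client_update", 1, "x", timeout_s=0.4, poll_s=0.05)


def test_receive_picks_up_marker_appearing_mid_poll(tmp_path):
    inbox = tmp_path / "inbox"
    inbox.mkdir()

    def late_send():
        time.sleep(0.3)
        send(Message("plan", 0, _payload(tmp_path, b"{}", "p.json"),
                     "server"), LocalTransport(inbox))

    thread = threading.Thread(target=late_send)
    thread.start()
    msg = receive(inbox, "plan", 0, "server", timeout_s=5, poll_s=0.05)
    thread.join()
    assert msg.payload_path.read_bytes() == b"{}"


def test_chaos_slow_writer_never_yields_partial_payload(tmp_path):
    """A payload trickled onto disk is only ever read complete, because the
    marker is written strictly after the last payload byte."""
    inbox = tmp_path / "inbox"
    inbox.mkdir()
    target = inbox / "global_model_round1_server.fcp"
    chunks = [b"a" * 100] * 20

    def slow_writer():
        with open(target, "wb") as fh:
            for chunk in chunks:
                fh.write(chunk)
                fh.flush()
                os.fsync(fh.fileno())
                time.sleep(0.02)
        (inbox / "global_model_round1_server.done").touch()

    thread = threading.Thread(target=slow_writer)
    thread.start()
    msg = receive(inbox, "global_model", 1, "server", timeout_s=10,
                  poll_s=0.01)
    data = msg.payload_path.read_bytes()
    thread.join()
    assert data == b"a" * 2000


def test_receive_any_prefers_whichever_arrives(tmp_path):
    inbox = tmp_path / "inbox"
    send(Message("final_model", 0, _payload(tmp_path, b"w", "f.fcp"),
                 "server"), LocalTransport(inbox))
    msg = receive_any(inbox, [("global_model", 4, "server"),
                              ("final_model", 0, "server")],
                      timeout_s=2, poll_s=0.05)
    assert msg.kind == "final_model"


def test_command_transport_with_cp_is_equivalent_to_local(tmp_path):
    """Loopback check of the remote-copy contract using plain cp."""
    payload = _payload(tmp_path, b"remote-bytes")
    local_inbox = tmp_path / "local_inbox"
    remote_inbox = tmp_path / "remote_inbox"
    remote_inbox.mkdir()
    msg = Message("client_update", 2, payload, "prague")
    send(msg, LocalTransport(local_inbox))
    send(msg, CommandTransport("cp {src} {dst}", str(remote_inbox)))
    a = sorted(p.name for p in local_inbox.iterdir())
    b = sorted(p.name for p in remote_inbox.iterdir())
    assert a == b
    assert (local_inbox / "client_update_round2_prague.fcp").read_bytes() \
        == (remote_inbox / "client_update_round2_prague.fcp").read_bytes()


def test_command_transport_failure_reports_attempts(tmp_path):
    payload = _payload(tmp_path)
    t = CommandTransport("false", "/nowhere", attempts=2, retry_wait_s=0.01)
    with pytest.raises(TransportError, match="2 attempts"):
        send(Message("plan", 0, payload, "server"), t)


def test_plan_json_roundtrip_and_validation(tmp_path):
    plan = FLPlan(n_rounds_max=10, clients_per_round=2, learning_rate=3e-3,
                  freeze_mode="shallow", seed=5)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    assert FLPlan.from_json(path) == plan
    with pytest.raises(ValueError):
        FLPlan(n_rounds_max=0, clients_per_round=1)
    with pytest.raises(ValueError):
        FLPlan(n_rounds_max=1, clients_per_round=1, val_fraction=1.5)
    with pytest.raises(ValueError):
        FLPlan(n_rounds_max=1, clients_per_round=1, freeze_mode="half")


def test_server_settings_require_unique_clients(tmp_path):
    with pytest.raises(ValueError, match="unique"):
        ServerSettings(workspace_root=tmp_path,
                       clients=({"name": "a", "address": "x",
                                 "workspace_root": "wa"},
                                {"name": "a", "address": "y",
                                 "workspace_root": "wb"}))
    with pytest.raises(ValueError, match="client"):
        ServerSettings(workspace_root=tmp_path, clients=())
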