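"""Workspace layout, settings/plan schemas and the two-file transfer protocol.

Every transmission is two files sent strictly in order: the payload (weights
checkpoint, plan JSON, ...) and then a zero-byte ``<stem>.done`` marker.  A
receiver only ever reads a payload whose marker exists, so a slow or failed
transfer can never be consumed half-written.  Message file names are
deterministic (``<kind>_round<r>_<sender><ext>``), which doubles as an
idempotency key — re-sending a message simply overwrites it.

Two transports are provided: ``LocalTransport`` copies into a destination
workspace on a shared filesystem (simulation, CI) and ``CommandTransport``
delegates to a configured copy command such as ``scp`` for genuinely remote
clients.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "MESSAGE_KINDS", "Workspace", "ServerSettings", "ClientSettings",
    "FLPlan", "Message", "TransportError", "WorkspaceConflictError",
    "LocalTransport", "CommandTransport", "init_workspace", "send", "receive",
]

MESSAGE_KINDS = ("plan", "global_model", "client_update", "final_model",
                 "stop")
WORKSPACE_SUBDIRS = ("inbox", "outbox", "state", "logs", "preproc_cache")
MARKER_SUFFIX = ".done"


class TransportError(RuntimeError):
    """A transfer failed after the configured number of attempts."""


class WorkspaceConflictError(RuntimeError):
    """The workspace root is already initialised for a different role."""


@dataclass(frozen=True)
class Workspace:
    root: Path
    role: str

    @property
    def inbox(self) -> Path:
        return self.root / "inbox"

    @property
    def outbox(self) -> Path:
        return self.root / "outbox"

    @property
    def state(self) -> Path:
        return self.root / "state"

    @property
    def logs(self) -> Path:
        return self.root / "logs"

    @property
    def preproc_cache(self) -> Path:
        return self.root / "preproc_cache"


def init_workspace(root: str | Path, role: str) -> Workspace:
    """Create (or re-open) an FL workspace; idempotent per role."""
    if role not in ("server", "client"):
        raise ValueError("role must be 'server' or 'client'")
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    marker = root / ".role"
    if marker.exists():
        existing = marker.read_text().strip()
        if existing != role:
            raise WorkspaceConflictError(
                f"{root} is already a {existing!r} workspace")
    else:
        marker.write_text(role)
    for sub in WORKSPACE_SUBDIRS:
        (root / sub).mkdir(exist_ok=True)
    return Workspace(root=root, role=role)


@dataclass(frozen=True)
class FLPlan:
    """Server-held hyperparameters governing the federation."""

    n_rounds_max: int
    clients_per_round: int
    epochs_per_round: int = 1
    learning_rate: float = 1e-3
    n_bootstraps: int = 5
    val_fraction: float = 0.25
    test_fraction: float = 0.2
    batch_size: int = 10
    patience: int = 20
    freeze_mode: str = "none"
    seed: int = 0
    bootstrap_selection: str = "best"
    model: dict | None = None

    def __post_init__(self):
        for name in ("n_rounds_max", "clients_per_round", "epochs_per_round",
                     "n_bootstraps", "batch_size", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("val_fraction", "test_fraction"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.freeze_mode not in ("shallow", "deep", "none"):
            raise ValueError("freeze_mode must be shallow, deep or none")
        if self.bootstrap_selection not in ("best", "average"):
            raise ValueError("bootstrap_selection must be 'best' or 'average'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FLPlan":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ServerSettings:
    workspace_root: Path
    clients: tuple[dict, ...]  # each: {name, address, workspace_root}
    model_definition: Path | None = None
    plan_path: Path | None = None

    def __post_init__(self):
        if not self.clients:
            raise ValueError("at least one client is required")
        names = [c["name"] for c in self.clients]
        if len(set(names)) != len(names):
            raise ValueError("client names must be unique")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "workspace_root": str(self.workspace_root),
            "clients": [{k: str(v) for k, v in c.items()}
                        for c in self.clients],
            "model_definition": str(self.model_definition)
            if self.model_definition else None,
            "plan_path": str(self.plan_path) if self.plan_path else None,
        }, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ServerSettings":
        d = json.loads(Path(path).read_text())
        return cls(
            workspace_root=Path(d["workspace_root"]),
            clients=tuple(d["clients"]),
            model_definition=Path(d["model_definition"])
            if d.get("model_definition") else None,
            plan_path=Path(d["plan_path"]) if d.get("plan_path") else None)


@dataclass(frozen=True)
class ClientSettings:
    workspace_root: Path
    dataset_root: Path
    target_column: str
    server: str
    client_name: str
    preprocess: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "workspace_root": str(self.workspace_root),
            "dataset_root": str(self.dataset_root),
            "target_column": self.target_column,
            "server": str(self.server),
            "client_name": self.client_name,
            "preprocess": self.preprocess,
        }, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClientSettings":
        d = json.loads(Path(path).read_text())
        return cls(workspace_root=Path(d["workspace_root"]),
                   dataset_root=Path(d["dataset_root"]),
                   target_column=d["target_column"], server=d["server"],
                   client_name=d["client_name"],
                   preprocess=d.get("preprocess", {}))


@dataclass(frozen=True)
class Message:
    kind: str
    round_index: int
    payload_path: Path
    sender: str

    def __post_init__(self):
        if self.kind not in MESSAGE_KINDS:
            raise ValueError(f"unknown message kind {self.kind!r}")

    @property
    def stem(self) -> str:
        return f"{self.kind}_round{self.round_index}_{self.sender}"

    @property
    def wire_name(self) -> str:
        return self.stem + "".join(Path(self.payload_path).suffixes)


class LocalTransport:
    """Shared-filesystem transport: atomic copy into a destination inbox."""

    def __init__(self, destination_inbox: str | Path):
        self.destination_inbox = Path(destination_inbox)

    def put(self, src: Path, name: str) -> Path:
        self.destination_inbox.mkdir(parents=True, exist_ok=True)
        dest = self.destination_inbox / name
        tmp = dest.with_name(dest.name + ".part")
        shutil.copyfile(src, tmp)
        tmp.replace(dest)
        return dest


class CommandTransport:
    """Copy-command transport (e.g. ``scp {src} host:{dst}``) with retries."""

    def __init__(self, template: str, destination_inbox: str,
                 attempts: int = 3, retry_wait_s: float = 1.0):
        self.template = template
        self.destination_inbox = destination_inbox
        self.attempts = attempts
        self.retry_wait_s = retry_wait_s

    def put(self, src: Path, name: str) -> str:
        dst = f"{self.destination_inbox.rstrip('/')}/{name}"
        cmd = self.template.format(src=str(src), dst=dst)
        last = None
        for attempt in range(1, self.attempts + 1):
            proc = subprocess.run(cmd, shell=True, capture_output=True,
                                  text=True)
            if proc.returncode == 0:
                return dst
            last = proc
            if attempt < self.attempts:
                time.sleep(self.retry_wait_s)
        raise TransportError(
            f"transfer of {name} failed after {self.attempts} attempts "
            f"(exit {last.returncode}): {last.stderr.strip() or cmd}")


def send(message: Message, transport) -> str:
    """Transmit payload first, completion marker second."""
    payload = Path(message.payload_path)
    if not payload.is_file():
        raise FileNotFoundError(f"payload {payload} does not exist")
    wire = message.wire_name
    transport.put(payload, wire)
    marker = payload.with_name(message.stem + MARKER_SUFFIX)
    marker.touch()
    try:
        transport.put(marker, message.stem + MARKER_SUFFIX)
    finally:
        marker.unlink(missing_ok=True)
    return wire


def _find_marker(inbox: Path, stem: str) -> Path | None:
    marker = inbox / (stem + MARKER_SUFFIX)
    return marker if marker.exists() else None


def receive(inbox: str | Path, kind: str, round_index: int, sender: str,
            timeout_s: float = 86400.0, poll_s: float = 5.0) -> Message:
    """Poll the inbox until the completion marker of the expected message
    appears; never reads a payload whose marker is absent."""
    if not (timeout_s > poll_s > 0):
        raise ValueError("need timeout_s > poll_s > 0")
    inbox = Path(inbox)
    stem = f"{kind}_round{round_index}_{sender}"
    deadline = time.monotonic() + timeout_s
    while True:
        if _find_marker(inbox, stem) is not None:
            candidates = [p for p in inbox.glob(stem + "*")
                          if (p.name == stem or p.name.startswith(stem + "."))
                          and not p.name.endswith(MARKER_SUFFIX)
                          and not p.name.endswith(".part")]
            if candidates:
                payload = sorted(candidates)[0]
                return Message(kind=kind, round_index=round_index,
                               payload_path=payload, sender=sender)
        if time.monotonic() >= deadline:
            raise TimeoutError(
                f"timed out waiting for {stem}{MARKER_SUFFIX} in {inbox}")
        time.sleep(min(poll_s, max(deadline - time.monotonic(), 0.01)))


def receive_any(inbox: str | Path, expected: list[tuple[str, int, str]],
                timeout_s: float = 86400.0, poll_s: float = 5.0) -> Message:
    """Like :func:`receive` but returns the first of several expected
    messages to arrive (used by clients awaiting next-round weights OR a
    final-model/stop notice)."""
    inbox = Path(inbox)
    deadline = time.monotonic() + timeout_s
    while True:
        for kind, round_index, sender in expected:
            stem = f"{kind}_round{round_index}_{sender}"
            if _find_marker(inbox, stem) is not None:
                candidates = [p for p in inbox.glob(stem + "*")
                              if not p.name.endswith(MARKER_SUFFIX)
                              and not p.name.endswith(".part")]
                if candidates:
                    return Message(kind=kind, round_index=round_index,
                                   payload_path=sorted(candidates)[0],
                                   sender=sender)
        if time.monotonic() >= deadline:
            names = ", ".join(f"{k}_round{r}_{s}" for k, r, s in expected)
            raise TimeoutError(f"timed out waiting for any of [{names}] "
                               f"in {inbox}")
        time.sleep(min(poll_s, max(deadline - time.monotonic(), 0.01)))
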