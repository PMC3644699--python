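"""Remote-control protocol: wire syntax, command set, and dispatch.

A controller (typically the stimulus-generation program) drives
acquisition over a plain TCP text protocol.  One message per line, syntax::

    COMMAND | DATA !

— command and payload separated by a vertical bar, message terminated by an
exclamation mark; commands without payload omit the bar (``STOP !``).  The
acquisition side acts as the TCP *client* and dials the controller, so
several engines can connect to one controller for large rigs.

Trial flow is two-stage: ``INIT`` names the recording, ``START`` prepares
and arms a trial, and acquisition begins only on the (software) trigger
event; ``STOP`` finalizes the trial files.

``RUNFUN`` executes only pre-registered routine names.  This deliberately
refuses arbitrary code strings: remote eval is convenient on a trusted rig
but indefensible on an open socket.
"""

from __future__ import annotations

import re
import socket
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator

from .dsp import SampleBlock
from .engine import AcquisitionConfig, RawWriter, TrialRecord

__all__ = [
    "Message",
    "ProtocolError",
    "COMMANDS",
    "TERMINATOR",
    "format_message",
    "parse_message",
    "RemoteSession",
    "run_client",
    "ControllerStub",
]

COMMANDS = frozenset(
    {"INIT", "START", "STOP", "COMTEST", "RUNFUN", "GETVAR", "SETVAR"}
)
TERMINATOR = "!"
SEPARATOR = "|"


class ProtocolError(ValueError):
    """Malformed message or command refused in the current state."""


@dataclass(frozen=True)
class Message:
    """One remote-control command with its (possibly empty) payload."""

    command: str
    payload: str = ""

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ProtocolError(f"unknown command {self.command!r}")
        if TERMINATOR in self.payload:
            raise ProtocolError(
                f"payload may not contain the terminator {TERMINATOR!r}"
            )


def format_message(m: Message) -> str:
    """Wire text for a message: ``CMD | PAYLOAD !`` or ``CMD !``."""
    if m.payload:
        return f"{m.command} {SEPARATOR} {m.payload} {TERMINATOR}"
    return f"{m.command} {TERMINATOR}"


def parse_message(text: str) -> Message:
    """Inverse of :func:`format_message`; tolerant of surrounding whitespace.

    The first bar splits command from payload; any further bars belong to
    the payload.
    """
    text = text.strip()
    if not text.endswith(TERMINATOR):
        raise ProtocolError(f"message not terminated by {TERMINATOR!r}: {text!r}")
    body = text[: -len(TERMINATOR)].strip()
    if SEPARATOR in body:
        command, payload = body.split(SEPARATOR, 1)
    else:
        command, payload = body, ""
    return Message(command.strip(), payload.strip())


def _reply(ok: bool, detail: str = "") -> str:
    verb = "OK" if ok else "ERR"
    body = f"{verb} {SEPARATOR} {detail}" if detail else verb
    return f"{body} {TERMINATOR}"


_TRIAL_NAME = re.compile(r"^(?P<base>.+)-(?P<index>\d+)$")


class RemoteSession:
    """Engine state driven by protocol messages.

    Parameters
    ----------
    config
        Acquisition configuration (sampling rate, channels, scale, paths).
    source
        Block iterator supplying samples; one continuous stream shared by
        all trials of the session (as a DAQ card would).
    callbacks
        Per-block processing/display callables; exceptions in them are
        counted, never propagated (write-first protection).
    routines
        Whitelist of names RUNFUN may execute; each is called with the
        session as its only argument.
    """

    def __init__(
        self,
        config: AcquisitionConfig,
        source: Iterator[SampleBlock] | None = None,
        callbacks: Iterable[Callable[[SampleBlock], None]] = (),
        routines: dict[str, Callable[["RemoteSession"], object]] | None = None,
    ) -> None:
        self.config = config
        self.source = iter(source) if source is not None else iter(())
        self.callbacks = list(callbacks)
        self.routines = dict(routines or {})
        self.variables: dict[str, str] = {}
        self.base_name: str | None = None
        self.trial_index = 0
        self.trials: list[TrialRecord] = []
        self.samples_consumed = 0
        self._writer: RawWriter | None = None
        self._record: TrialRecord | None = None
        self._triggered = False

    # -- hardware trigger stand-in -------------------------------------
    def trigger(self, max_samples: int | None = None) -> int:
        """Fire the start trigger and acquire until the source pauses.

        Pulls whole blocks from the source until at least ``max_samples``
        samples were written (or the source is exhausted).  Returns the
        number of samples acquired in this call.  A trial must be armed
        (``START``) first; acquisition never begins before the trigger.
        """
        if self._writer is None:
            raise ProtocolError("no trial armed: send START first")
        self._triggered = True
        written = 0
        for block in self.source:
            self.samples_consumed += block.n_samples
            self._writer.write(block)  # raw-first
            written += block.n_samples
            for cb in self.callbacks:
                try:
                    cb(block)
                except Exception:
                    self._record.callback_errors += 1
            if max_samples is not None and written >= max_samples:
                break
        self._record.status = "running"
        return written

    # -- dispatch ------------------------------------------------------
    def dispatch(self, m: Message) -> str:
        """Apply one message to the session; returns the wire reply."""
        handler = getattr(self, f"_cmd_{m.command.lower()}")
        try:
            return handler(m.payload)
        except ProtocolError as e:
            return _reply(False, str(e))

    def dispatch_text(self, text: str) -> str:
        try:
            m = parse_message(text)
        except ProtocolError as e:
            return _reply(False, str(e))
        return self.dispatch(m)

    def _cmd_comtest(self, payload: str) -> str:
        return _reply(True, "COMTEST")

    def _cmd_init(self, payload: str) -> str:
        if not payload:
            raise ProtocolError("INIT requires a base filename")
        self.base_name = payload
        self.trial_index = 0
        Path(self.config.save_dir).mkdir(parents=True, exist_ok=True)
        return _reply(True, f"INIT {payload}")

    def _cmd_start(self, payload: str) -> str:
        if self.base_name is None:
            raise ProtocolError("START before INIT")
        if self._writer is not None:
            raise ProtocolError("trial already armed")
        if payload:
            match = _TRIAL_NAME.match(payload)
            if match:
                trial_name = Path(match.group("base")).name
                self.trial_index = int(match.group("index"))
                trial_name = f"{trial_name}-{self.trial_index}"
            else:
                trial_name = Path(payload).name
        else:
            trial_name = f"{Path(self.base_name).name}-{self.trial_index}"
        base = Path(self.config.save_dir) / trial_name
        self._writer = RawWriter(
            base, self.config.fs, self.config.n_channels, self.config.scale
        )
        self._record = TrialRecord(
            index=self.trial_index,
            base_name=str(base),
            raw_file=str(self._writer.raw_path),
            event_file=None,
            n_samples=0,
            status="prepared",
        )
        self._triggered = False
        return _reply(True, f"START {trial_name}")

    def _cmd_stop(self, payload: str) -> str:
        if self._writer is None:
            raise ProtocolError("STOP without an armed trial")
        self._writer.close()
        self._record.n_samples = self._writer.n_samples
        self._record.clip_count = self._writer.clip_count
        self._record.status = "stopped"
        self.trials.append(self._record)
        n = self._record.n_samples
        self._writer = None
        self._record = None
        self.trial_index += 1
        return _reply(True, f"STOP {n}")

    def _cmd_runfun(self, payload: str) -> str:
        name = payload.strip().rstrip(";").removesuffix("()")
        if name not in self.routines:
            raise ProtocolError(f"routine {name!r} not registered")
        result = self.routines[name](self)
        return _reply(True, f"RUNFUN {name}" + (f" {result}" if result is not None else ""))

    def _cmd_getvar(self, payload: str) -> str:
        name = payload.strip()
        if name not in self.variables:
            raise ProtocolError(f"unknown variable {name!r}")
        return _reply(True, self.variables[name])

    def _cmd_setvar(self, payload: str) -> str:
        if "=" not in payload:
            raise ProtocolError("SETVAR payload must be 'name = value'")
        name, value = payload.split("=", 1)
        name = name.strip()
        if not name:
            raise ProtocolError("SETVAR with empty variable name")
        self.variables[name] = value.strip().rstrip(";").strip()
        return _reply(True, f"SETVAR {name}")


# --------------------------------------------------------------------------
# TCP transport

def run_client(
    session: RemoteSession,
    host: str,
    port: int,
    max_messages: int | None = None,
    timeout: float | None = 10.0,
) -> int:
    """Dial the controller and serve messages until the connection closes.

    The acquisition side is the TCP client: it connects to
    ``host:port``, reads ``!``-terminated messages, dispatches each against
    ``session`` and sends the reply line back.  Returns the number of
    messages handled.
    """
    handled = 0
    with socket.create_connection((host, port), timeout=timeout) as sock:
        buf = ""
        while max_messages is None or handled < max_messages:
            try:
                chunk = sock.recv(4096)
            except socket.timeout:
                break
            if not chunk:
                break
            buf += chunk.decode("utf-8")
            while TERMINATOR in buf:
                raw, buf = buf.split(TERMINATOR, 1)
                reply = session.dispatch_text(raw + TERMINATOR)
                sock.sendall((reply + "\n").encode("utf-8"))
                handled += 1
                if max_messages is not None and handled >= max_messages:
                    break
    return handled


class ControllerStub:
    """Minimal controller for loopback integration tests.

    Listens on an ephemeral port, accepts one engine connection, sends a
    scripted sequence of command lines and records the replies.
    """

    def __init__(self, host: str = "127.0.0.1") -> None:
        self._srv = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._srv.bind((host, 0))
        self._srv.listen(1)
        self.address = self._srv.getsockname()
        self.replies: list[str] = []

    def run_script(self, commands: list[str], timeout: float = 10.0) -> list[str]:
        """Send each command, wait for its reply line; returns the replies."""
        self._srv.settimeout(timeout)
        conn, _ = self._srv.accept()
        conn.settimeout(timeout)
        with conn:
            fh = conn.makefile("rw", encoding="utf-8", newline="\n")
            for cmd in commands:
                fh.write(cmd + "\n")
                fh.flush()
                reply = fh.readline().rstrip("\n")
                self.replies.append(reply)
        return self.replies

    def close(self) -> None:
        self._srv.close()
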