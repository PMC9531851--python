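"""Distributed execution: an HTTP mediator plus node-side wrappers.

When the two halves of a loop run at different sites, each site replaces its
missing peer with a *wrapper*: a bridge that speaks the file protocol locally
and HTTP remotely.  The mediator is a small multi-tenant store-and-forward
server: each workflow's channel files live in a session directory named
``sanitize(dirname)_apikey``, so two tenants choosing the same dirname can
never collide, and every user-supplied name is sanitized so no request can
touch a file outside its own session.  Per-file locks serialize concurrent
read/write access, so a fetched payload is always a complete previously
stored message.

Endpoints (all POST, multipart uploads)::

    /init/<dirname>?apikey=KEY           store initial payload values
    /cleanup/<dirname>?apikey=KEY        delete the session
    /ctl/<dirname>?fetch=u&apikey=KEY    store uploads, return payload "u"
    /pm/<dirname>?fetch=ym&apikey=KEY    store uploads, return payload "ym"

``/ctl`` and ``/pm`` are symmetric exchange services distinguished by
convention: the wrapper standing in for the physiological model calls
``/ctl`` to fetch the controller's output, and vice versa.
"""

from __future__ import annotations

import json
import re
import threading
import time
import urllib.error
import urllib.parse
import urllib.request
import uuid
from email.parser import BytesParser
from email.policy import default as _email_policy
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Mapping, Optional

from .protocol import (
    MAXTIME_FILENAME,
    MalformedMessage,
    Message,
    parse_message,
    read_raw,
    write_raw,
)

__all__ = [
    "MediatorError",
    "AuthError",
    "NotFound",
    "Busy",
    "BridgeError",
    "sanitize_name",
    "MediatorApp",
    "make_server",
    "serve_background",
    "MediatorClient",
    "run_wrapper",
]

DEFAULT_POLL = 0.5  # wrapper re-post interval, seconds
DEFAULT_DEADLINE = 60.0  # wrapper gives up after this long without progress


class MediatorError(RuntimeError):
    pass


class AuthError(MediatorError):
    pass


class NotFound(MediatorError):
    pass


class Busy(MediatorError):
    pass


class BridgeError(MediatorError):
    """The wrapper exceeded its agreed-upon global delay without progress."""


_UNSAFE = re.compile(r"[/\\\x00-\x1f\x7f]")


def sanitize_name(raw: str) -> str:
    """Collapse a user-supplied name to a single safe path component.

    Path separators, parent references and control characters become ``_``,
    so neither a dirname nor a payload name can climb out of its session
    directory.  A name that sanitizes to nothing is rejected.
    """
    if not raw:
        raise ValueError("empty name")
    safe = _UNSAFE.sub("_", raw.replace("..", "_"))
    if not safe or set(safe) <= {"."}:
        raise ValueError(f"name {raw!r} sanitizes to nothing")
    return safe


class MediatorApp:
    """Transport-independent mediator logic (the HTTP layer is separate)."""

    def __init__(self, root: Path | str, apikeys=(), lock_timeout: float = 10.0):
        self.root = Path(root).resolve()
        self.root.mkdir(parents=True, exist_ok=True)
        self.apikeys = set(apikeys)
        self.lock_timeout = lock_timeout
        self._locks: dict[str, threading.Lock] = {}
        self._registry_lock = threading.Lock()

    def add_key(self, apikey: str) -> None:
        self.apikeys.add(apikey)

    # -- internals ----------------------------------------------------------

    def _check_key(self, apikey: Optional[str]) -> str:
        if not apikey or apikey not in self.apikeys:
            raise AuthError("missing or unknown API key")
        return apikey

    def _session_dir(self, dirname: str, apikey: str) -> Path:
        # dirname and key each sanitize to one component; two sessions that
        # differ in key land in different directories by construction.
        d = self.root / f"{sanitize_name(dirname)}_{sanitize_name(apikey)}"
        resolved = d.resolve()
        if resolved != self.root and self.root not in resolved.parents:
            raise NotFound("session path escapes the store")  # pragma: no cover
        return d

    def _lock(self, path: Path) -> threading.Lock:
        key = str(path)
        with self._registry_lock:
            lock = self._locks.get(key)
            if lock is None:
                lock = self._locks[key] = threading.Lock()
        return lock

    def _store(self, session: Path, name: str, text: str) -> None:
        path = session / sanitize_name(name)
        lock = self._lock(path)
        if not lock.acquire(timeout=self.lock_timeout):
            raise Busy(f"lock timeout storing {name!r}")
        try:
            path.write_text(text)
        finally:
            lock.release()

    # -- services -----------------------------------------------------------

    def handle_init(self, dirname: str, apikey: str, uploads: Mapping[str, str]) -> dict:
        """Create the session and store initial payloads (re-init replaces)."""
        key = self._check_key(apikey)
        session = self._session_dir(dirname, key)
        session.mkdir(parents=True, exist_ok=True)
        for name, text in uploads.items():
            self._store(session, name, text)
        return {"status": "success", "service": "init",
                "dirname": dirname, "files": sorted(uploads)}

    def handle_cleanup(self, dirname: str, apikey: str) -> dict:
        """Delete the session directory; cleaning a missing session succeeds."""
        import shutil

        key = self._check_key(apikey)
        session = self._session_dir(dirname, key)
        with self._registry_lock:
            stale = [k for k in self._locks if k.startswith(str(session))]
            for k in stale:
                del self._locks[k]
        shutil.rmtree(session, ignore_errors=True)
        return {"status": "success", "service": "cleanup", "dirname": dirname}

    def handle_exchange(self, service: str, dirname: str, apikey: str,
                        fetch: Optional[str], uploads: Mapping[str, str]) -> str:
        """Store the uploads, then return the current ``fetch`` payload."""
        if service not in ("ctl", "pm"):
            raise NotFound(f"unknown service {service!r}")
        key = self._check_key(apikey)
        session = self._session_dir(dirname, key)
        if not session.is_dir():
            raise NotFound(f"session {dirname!r} not initialized")
        if not fetch:
            raise MediatorError(f"service {service!r} requires a fetch name")
        for name, text in uploads.items():
            self._store(session, name, text)
        path = session / sanitize_name(fetch)
        lock = self._lock(path)
        if not lock.acquire(timeout=self.lock_timeout):
            raise Busy(f"lock timeout fetching {fetch!r}")
        try:
            if not path.exists():
                raise NotFound(f"no payload named {fetch!r}")
            return path.read_text()
        finally:
            lock.release()


# ---------------------------------------------------------------------------
# HTTP layer (stdlib threading server)

_INFO_PAGE = """<html><head><title>co-simulation mediator</title></head>
<body><h1>Co-simulation mediator</h1>
<p>Store-and-forward exchange of channel files between the remote halves of a
closed simulation loop.  POST to /init, /cleanup, /ctl or /pm with
?apikey=... (and ?fetch=... for the exchange services).</p>
</body></html>
"""


def _parse_uploads(content_type: str, body: bytes) -> dict[str, str]:
    uploads: dict[str, str] = {}
    if content_type.startswith("multipart/"):
        head = f"Content-Type: {content_type}\r\nMIME-Version: 1.0\r\n\r\n".encode()
        msg = BytesParser(policy=_email_policy).parsebytes(head + body)
        for part in msg.iter_parts():
            name = part.get_param("name", header="content-disposition") or part.get_filename()
            if not name:
                continue
            payload = part.get_payload(decode=True)
            uploads[name] = (payload or b"").decode("utf-8", "replace")
    elif content_type.startswith("application/x-www-form-urlencoded"):
        for name, vals in urllib.parse.parse_qs(body.decode("utf-8", "replace")).items():
            uploads[name] = vals[-1]
    return uploads


def make_server(app: MediatorApp, host: str = "127.0.0.1", port: int = 0) -> ThreadingHTTPServer:
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet
            pass

        def _send(self, code: int, body: bytes, ctype: str) -> None:
            self.send_response(code)
            self.send_header("Content-Type", ctype)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _send_json(self, code: int, obj: dict) -> None:
            self._send(code, json.dumps(obj).encode(), "application/json")

        def do_GET(self):
            self._send(200, _INFO_PAGE.encode(), "text/html")

        def do_POST(self):
            parsed = urllib.parse.urlsplit(self.path)
            parts = [p for p in parsed.path.split("/") if p]
            query = urllib.parse.parse_qs(parsed.query)
            apikey = (query.get("apikey") or [None])[0]
            fetch = (query.get("fetch") or [None])[0]
            length = int(self.headers.get("Content-Length") or 0)
            body = self.rfile.read(length) if length else b""
            uploads = _parse_uploads(self.headers.get("Content-Type", ""), body)
            if len(parts) != 2:
                self._send_json(404, {"status": "error", "reason": "bad path"})
                return
            service, dirname = parts
            try:
                if service == "init":
                    self._send_json(200, app.handle_init(dirname, apikey, uploads))
                elif service == "cleanup":
                    self._send_json(200, app.handle_cleanup(dirname, apikey))
                elif service in ("ctl", "pm"):
                    payload = app.handle_exchange(service, dirname, apikey, fetch, uploads)
                    self._send(200, payload.encode(), "text/plain")
                else:
                    self._send_json(404, {"status": "error",
                                          "reason": f"unknown service {service!r}"})
            except AuthError as exc:
                self._send_json(401, {"status": "error", "reason": str(exc)})
            except NotFound as exc:
                self._send_json(404, {"status": "error", "reason": str(exc)})
            except Busy as exc:
                self._send_json(503, {"status": "error", "reason": str(exc)})
            except (MediatorError, ValueError) as exc:
                self._send_json(400, {"status": "error", "reason": str(exc)})

    return ThreadingHTTPServer((host, port), Handler)


def serve_background(app: MediatorApp, host: str = "127.0.0.1", port: int = 0):
    """Start the mediator in a daemon thread; returns (server, url)."""
    server = make_server(app, host, port)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    url = f"http://{server.server_address[0]}:{server.server_address[1]}"
    return server, url


class MediatorClient:
    """Thin HTTP client for the mediator endpoints (multipart uploads)."""

    def __init__(self, base_url: str, apikey: str, timeout: float = 10.0):
        self.base_url = base_url.rstrip("/")
        self.apikey = apikey
        self.timeout = timeout

    def _post(self, service: str, dirname: str, uploads: Mapping[str, str],
              fetch: Optional[str] = None) -> tuple[int, bytes]:
        query = {"apikey": self.apikey}
        if fetch is not None:
            query["fetch"] = fetch
        url = f"{self.base_url}/{service}/{urllib.parse.quote(dirname, safe='')}?" + \
            urllib.parse.urlencode(query)
        boundary = uuid.uuid4().hex
        lines = []
        for name, text in uploads.items():
            lines += [
                f"--{boundary}",
                f'Content-Disposition: form-data; name="{name}"; filename="{name}"',
                "Content-Type: text/plain",
                "",
                text,
            ]
        lines += [f"--{boundary}--", ""]
        body = "\r\n".join(lines).encode()
        req = urllib.request.Request(
            url, data=body, method="POST",
            headers={"Content-Type": f"multipart/form-data; boundary={boundary}"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return resp.status, resp.read()
        except urllib.error.HTTPError as exc:
            return exc.code, exc.read()

    def init(self, dirname: str, uploads: Mapping[str, str]) -> dict:
        code, body = self._post("init", dirname, uploads)
        out = json.loads(body)
        if code != 200:
            raise MediatorError(out.get("reason", f"init failed ({code})"))
        return out

    def cleanup(self, dirname: str) -> dict:
        code, body = self._post("cleanup", dirname, {})
        out = json.loads(body)
        if code != 200:
            raise MediatorError(out.get("reason", f"cleanup failed ({code})"))
        return out

    def exchange(self, service: str, dirname: str, fetch: str,
                 uploads: Mapping[str, str]) -> str:
        code, body = self._post(service, dirname, uploads, fetch=fetch)
        if code == 503:
            raise Busy("server busy")
        if code != 200:
            try:
                reason = json.loads(body).get("reason", "")
            except (ValueError, AttributeError):
                reason = body[:100]
            raise (NotFound if code == 404 else MediatorError)(
                f"{service} failed ({code}): {reason}")
        return body.decode()


# ---------------------------------------------------------------------------
# Node-side wrapper bridge


def _load_maxtime_from_dirs(dirs, default: float) -> float:
    found = []
    for d in dirs:
        p = Path(d) / MAXTIME_FILENAME
        if p.exists():
            found.append(float(p.read_text().strip()))
    return max(found) if found else default


def run_wrapper(
    *,
    in_dir: Path | str,
    out_dir: Path | str,
    upload_name: str,
    fetch_name: str,
    initial_local: str,
    initial_peer: str,
    client: MediatorClient,
    dirname: str,
    service: str,
    poll: float = DEFAULT_POLL,
    deadline: float = DEFAULT_DEADLINE,
    default_maxtime: float = 300.0,
) -> None:
    """Bridge a local node to its remote peer through the mediator.

    Reads the local node's output file (``upload_name`` in ``in_dir``),
    posts it to ``service`` while fetching the peer payload, and -- once the
    peer's simulation timestamp changes -- writes the fetched text verbatim
    into the local node's input (``fetch_name`` in ``out_dir``).  Timestamps
    are preserved end to end, so the bridged loop is byte-identical to a
    local one.  The first local read fires immediately (falling back to
    ``initial_local`` if the file does not exist yet) so one side can seed
    the exchange.  Transient HTTP failures are retried; the bridge fails only
    after ``deadline`` seconds without progress.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    maxtime = _load_maxtime_from_dirs([in_dir, out_dir], default_maxtime)
    last_local: Optional[str] = None
    local_t = _must_parse(initial_local).simtime
    last_peer_t = _must_parse(initial_peer).simtime
    last_progress = time.monotonic()

    while True:
        progressed = False

        # --- pick up new local output (the first read falls back to the
        #     initial string, seeding the exchange)
        text = read_raw(in_dir, upload_name)
        if text is None:
            text = initial_local
        if text.strip() and text != last_local:
            try:
                local_t = _must_parse(text).simtime
                last_local = text
                progressed = True
            except MalformedMessage:
                pass  # caught mid-write; try again next cycle

        # --- one exchange round trip: post current local text, fetch peer
        resp = None
        if last_local is not None:
            try:
                resp = client.exchange(service, dirname, fetch_name,
                                       {upload_name: last_local})
            except (Busy, urllib.error.URLError, ConnectionError, TimeoutError, OSError):
                resp = None  # dropped/timed-out request: re-issue next cycle
        if resp is not None:
            try:
                peer = _must_parse(resp)
            except MalformedMessage:
                peer = None
            if peer is not None and peer.simtime != last_peer_t:
                # deliver the peer payload verbatim (timestamp preserved)
                last_peer_t = peer.simtime
                write_raw(out_dir, fetch_name, resp)
                progressed = True
                if last_peer_t >= maxtime and local_t >= maxtime:
                    return
            elif local_t >= maxtime:
                return  # final local payload posted; peer has nothing newer

        if progressed:
            last_progress = time.monotonic()
            continue
        if time.monotonic() - last_progress > deadline:
            raise BridgeError(
                f"no progress (local t={local_t}, peer t={last_peer_t}) "
                f"within {deadline}s deadline")
        time.sleep(poll)


def _must_parse(text: str) -> Message:
    msg = parse_message(text)
    if msg is None:
        raise MalformedMessage("empty payload")
    return msg
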