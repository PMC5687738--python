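"""HTTP/JSON query-and-edit API.

A single-store, single-process server on the stdlib HTTP stack. The store
is loaded at startup; endpoints are versioned under ``/api/v1``:

``GET /api/v1/points?mzmin&mzmax&rtmin&rtmax[&n]``
    JSON array of point objects ``{id, mz, rt, intensity, traceid,
    envelopeid}`` — exactly the library query for the same window. When
    ``n`` is omitted the server's default summarization budget (5,000
    points) applies. Responses are a pure function of (store state,
    request): repeated identical requests return byte-identical bodies.

``POST /api/v1/segmentation``
    Body ``{"pointids": [...], "traceid": t}`` assigns points to a trace;
    ``{"traceids": [...], "envelopeid": e}`` attaches traces to an
    envelope. Returns ``{"updated": count}``; changes are visible to the
    next GET. Unknown ids give 404 with the offender list.
"""

from __future__ import annotations

import json
from http.server import BaseHTTPRequestHandler, HTTPServer
from typing import List, Optional
from urllib.parse import parse_qs, urlparse

from .model import MsPoint, QueryWindow, ValidationError
from .storage import MzStore

__all__ = ["DEFAULT_BUDGET", "make_server", "serve"]

#: Result-cardinality budget applied when a GET omits ``n``.
DEFAULT_BUDGET = 5000


def _point_obj(p: MsPoint) -> dict:
    return {
        "id": p.id,
        "mz": p.mz,
        "rt": p.rt,
        "intensity": p.intensity,
        "traceid": p.trace_id,
        "envelopeid": p.envelope_id,
    }


class _Handler(BaseHTTPRequestHandler):
    store: Optional[MzStore] = None
    default_budget: int = DEFAULT_BUDGET

    # silence per-request stderr logging
    def log_message(self, fmt, *args):  # noqa: D102
        pass

    def _send(self, code: int, payload) -> None:
        body = json.dumps(payload, sort_keys=True).encode("utf-8")
        self.send_response(code)
        self.send_header("Content-Type", "application/json; charset=utf-8")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _error(self, code: int, message: str, **extra) -> None:
        self._send(code, {"error": message, **extra})

    def do_GET(self) -> None:  # noqa: N802
        url = urlparse(self.path)
        if url.path != "/api/v1/points":
            self._error(404, f"unknown endpoint {url.path}")
            return
        if self.store is None:
            self._error(503, "no store loaded")
            return
        params = parse_qs(url.query)

        def need(name: str) -> float:
            if name not in params:
                raise ValidationError(name, "missing query parameter")
            return float(params[name][0])

        try:
            mzmin, mzmax = need("mzmin"), need("mzmax")
            rtmin, rtmax = need("rtmin"), need("rtmax")
            n = int(params["n"][0]) if "n" in params else self.default_budget
            window = QueryWindow(mzmin, mzmax, rtmin, rtmax, n)
        except (ValidationError, ValueError) as exc:
            self._error(400, str(exc))
            return
        self._send(200, [_point_obj(p) for p in self.store.query(window)])

    def do_POST(self) -> None:  # noqa: N802
        url = urlparse(self.path)
        if url.path != "/api/v1/segmentation":
            self._error(404, f"unknown endpoint {url.path}")
            return
        if self.store is None:
            self._error(503, "no store loaded")
            return
        try:
            length = int(self.headers.get("Content-Length", "0"))
            body = json.loads(self.rfile.read(length) or b"{}")
            if not isinstance(body, dict):
                raise ValueError("body must be a JSON object")
        except (ValueError, json.JSONDecodeError) as exc:
            self._error(400, f"malformed body: {exc}")
            return
        try:
            if "pointids" in body and "traceid" in body:
                ids = [int(i) for i in body["pointids"]]
                updated = self.store.assign_trace(ids, int(body["traceid"]))
            elif "traceids" in body and "envelopeid" in body:
                ids = [int(i) for i in body["traceids"]]
                updated = self.store.assign_envelope(ids, int(body["envelopeid"]))
            else:
                self._error(
                    400,
                    "body must carry pointids+traceid or traceids+envelopeid",
                )
                return
        except KeyError as exc:
            self._error(404, str(exc.args[0] if exc.args else exc))
            return
        except (TypeError, ValueError) as exc:
            self._error(400, str(exc))
            return
        self._send(200, {"updated": updated})


def make_server(
    store: MzStore,
    host: str = "127.0.0.1",
    port: int = 0,
    default_budget: int = DEFAULT_BUDGET,
) -> HTTPServer:
    """Build (but do not start) the HTTP server bound to ``host:port``.

    The server handles requests sequentially: a single store backs a
    single process, and response determinism is easiest to guarantee
    without interleaved segmentation writes.
    """
    handler = type(
        "BoundHandler", (_Handler,), {"store": store, "default_budget": default_budget}
    )
    return HTTPServer((host, port), handler)


def serve(store: MzStore, host: str = "127.0.0.1", port: int = 8080) -> None:
    """Run the server until interrupted."""
    httpd = make_server(store, host, port)
    try:
        httpd.serve_forever()
    finally:
        httpd.server_close()
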