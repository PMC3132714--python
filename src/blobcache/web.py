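"""HTTP surface: query-parameter GET endpoints over the library.

Routes::

    GET /ProxyWS/Proxy?url=<absolute upstream URL>
    GET /<ServiceName>?operation=<op>&...      (or enrichType=<op>)

The proxy endpoint answers 200 from cache or upstream, 429 with a
Retry-After header on rate denial, and 502 on upstream failure.  Data
services accept ``operation`` or ``enrichType`` (the enrichment dialect)
plus an optional ``versionIdentifier`` and ``format``; errors are
serialized in the same formats as success payloads with an explicit
error field.
"""

from __future__ import annotations

import http.server
import logging
import threading
import urllib.parse

from .errors import (
    BlobcacheError,
    NoCommittedVersionError,
    RateLimitExceeded,
    UnknownOperationError,
    UnsupportedFormatError,
    UpstreamError,
    ValidationError,
    VersionGoneError,
    VersionNotFoundError,
)
from .proxy import CachingProxy
from .service import (
    DEFAULT_FORMAT,
    RebuildableService,
    ServiceRequest,
    error_payload,
    handle,
    serialize,
)
from .store import BlobStore

log = logging.getLogger(__name__)

_STATUS = {
    ValidationError: 400,
    UnknownOperationError: 400,
    UnsupportedFormatError: 400,
    VersionNotFoundError: 404,
    VersionGoneError: 410,
    RateLimitExceeded: 429,
    UpstreamError: 502,
    NoCommittedVersionError: 503,
}


class AppServer:
    """Threaded HTTP server hosting one proxy plus registered services."""

    def __init__(self, proxy: CachingProxy | None = None):
        self.proxy = proxy
        self.services: dict[str, tuple[RebuildableService, BlobStore]] = {}
        self._server: http.server.ThreadingHTTPServer | None = None

    def register(self, name: str, service: RebuildableService, store: BlobStore) -> None:
        self.services[name] = (service, store)

    # -- request handling (exposed for direct, serverless use in tests) --

    def dispatch(self, path: str, query: str) -> tuple[int, bytes, str, dict[str, str]]:
        """Handle one GET; returns (status, body, media type, headers)."""
        params = {
            k: v[-1] for k, v in urllib.parse.parse_qs(query, keep_blank_values=True).items()
        }
        segment = path.strip("/").split("/")[0]
        try:
            if segment == "ProxyWS":
                if self.proxy is None:
                    raise ValidationError("no proxy configured")
                url = params.get("url")
                if not url:
                    raise ValidationError("missing url parameter")
                resp = self.proxy.fetch(url)
                return 200, resp.body, resp.content_type, {
                    "X-From-Cache": str(resp.from_cache).lower()
                }
            if segment in self.services:
                service, store = self.services[segment]
                operation = params.get("operation") or params.get("enrichType")
                if not operation:
                    raise ValidationError("missing operation/enrichType parameter")
                fmt = params.get("format", DEFAULT_FORMAT)
                request = ServiceRequest(operation=operation, params=params, accept_format=fmt)
                response = handle(request, service, store)
                body, media = serialize(response.payload, response.format)
                return 200, body, media, {
                    "X-Version-Identifier": str(response.version_id)
                }
            return 404, b"not found", "text/plain", {}
        except BlobcacheError as exc:
            status = next(
                (code for cls, code in _STATUS.items() if isinstance(exc, cls)), 500
            )
            headers: dict[str, str] = {}
            if isinstance(exc, RateLimitExceeded):
                headers["Retry-After"] = f"{max(exc.retry_after, 0.001):.3f}"
            fmt = params.get("format", DEFAULT_FORMAT)
            try:
                body, media = serialize(error_payload(exc), fmt)
            except BlobcacheError:
                body, media = serialize(error_payload(exc), DEFAULT_FORMAT)
            return status, body, media, headers

    # -- lifecycle -------------------------------------------------------

    def start(self, host: str = "127.0.0.1", port: int = 0) -> str:
        app = self

        class Handler(http.server.BaseHTTPRequestHandler):
            def log_message(self, *args):
                pass

            def do_GET(self) -> None:
                parsed = urllib.parse.urlsplit(self.path)
                status, body, media, headers = app.dispatch(parsed.path, parsed.query)
                self.send_response(status)
                self.send_header("Content-Type", media)
                self.send_header("Content-Length", str(len(body)))
                for k, v in headers.items():
                    self.send_header(k, v)
                self.end_headers()
                self.wfile.write(body)

        self._server = http.server.ThreadingHTTPServer((host, port), Handler)
        threading.Thread(target=self._server.serve_forever, daemon=True).start()
        bound_host, bound_port = self._server.server_address[:2]
        return f"http://{bound_host}:{bound_port}"

    def stop(self) -> None:
        if self._server is not None:
            self._server.shutdown()
            self._server.server_close()
            self._server = None

    def serve_forever(self, host: str = "127.0.0.1", port: int = 8080) -> None:
        url = self.start(host, port)
        log.info("serving on %s", url)
        assert self._server is not None
        try:
            threading.Event().wait()
        except KeyboardInterrupt:
            self.stop()
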