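"""Client for a Pathway Commons cPath2-style REST service.

Everything network-shaped goes through an injectable *transport* (any
object with ``get(url) -> TransportResponse``), so the whole client is
exercisable offline against canned responses; a stdlib ``urllib``
transport is provided for live use.  Request construction is a pure
function of the query, which makes the exact URLs snapshot-testable.

Keywords pass through verbatim: Boolean ``AND``/``OR``, ``field:term``
pairs and ``*`` wildcards are the service's own query syntax.  Searches
return pages of at most 500 hits.  Species names are resolved from a
small bundled NCBI taxonomy table (pluggable resolver hook) rather than
a live lookup.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Iterator, Protocol

from lxml import etree

from .errors import (
    ContentError,
    NotBiopaxError,
    NotFoundError,
    ParseError,
    PreconditionError,
    TransportError,
)
from .graph import TypedGraph, build_graph
from .model import local_fragment
from .owl import OwlDocument, load_document, read_biopax
from .queries import QuerySpec, merge_networks, run_query

SEARCH_TYPES = ("Pathway", "Interaction", "PhysicalEntity", "EntityReference", "TopPathways")

#: "Popular species" presets, keyed by common name.
POPULAR_SPECIES = {
    "human": 9606,
    "mouse": 10090,
    "rat": 10116,
    "fruit fly": 7227,
    "nematode": 6239,
    "budding yeast": 4932,
    "zebrafish": 7955,
    "thale cress": 3702,
    "chicken": 9031,
    "cow": 9913,
}

#: Static NCBI taxon id -> scientific name table (replaces live lookup).
TAXON_NAMES = {
    9606: "Homo sapiens",
    10090: "Mus musculus",
    10116: "Rattus norvegicus",
    7227: "Drosophila melanogaster",
    6239: "Caenorhabditis elegans",
    4932: "Saccharomyces cerevisiae",
    7955: "Danio rerio",
    3702: "Arabidopsis thaliana",
    9031: "Gallus gallus",
    9913: "Bos taurus",
}


@dataclass
class TransportResponse:
    status: int
    body: bytes
    content_type: str = ""

    @property
    def text(self) -> str:
        return self.body.decode("utf-8")


class Transport(Protocol):
    def get(self, url: str) -> TransportResponse: ...


class UrllibTransport:
    """Live HTTP transport over stdlib urllib (no third-party dependency)."""

    def __init__(self, timeout: float = 60.0):
        self.timeout = timeout

    def get(self, url: str) -> TransportResponse:
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return TransportResponse(
                    status=resp.status,
                    body=resp.read(),
                    content_type=resp.headers.get("Content-Type", ""),
                )
        except urllib.error.HTTPError as exc:
            return TransportResponse(status=exc.code, body=exc.read() or b"")
        except urllib.error.URLError as exc:
            raise TransportError(f"transport failure for {url}: {exc}") from exc


@dataclass
class ClientConfig:
    base_url: str = "https://www.pathwaycommons.org/pc2"
    page_size: int = 500
    search_path: str = "search"
    top_pathways_path: str = "top_pathways"
    get_path: str = "get"
    traverse_path: str = "traverse"
    graph_path: str = "graph"
    #: taxon id -> scientific name; replace to plug in a live resolver
    taxon_resolver: Callable[[int], str | None] = field(
        default=lambda taxon: TAXON_NAMES.get(taxon)
    )


@dataclass
class SearchQuery:
    keywords: str
    name_only: bool = False
    organisms: list = field(default_factory=list)
    datasources: list = field(default_factory=list)
    biopax_type: str = "Pathway"
    page: int = 0

    def __post_init__(self) -> None:
        if self.biopax_type not in SEARCH_TYPES:
            raise PreconditionError(f"biopax_type must be one of {SEARCH_TYPES}")
        if self.page < 0:
            raise PreconditionError("page must be >= 0")


@dataclass
class SearchHit:
    uri: str
    name: str = ""
    excerpt: str = ""
    organism: int | None = None
    organism_name: str | None = None
    source: str = ""
    num_interactions: int | None = None


@dataclass
class SearchPage:
    hits: list[SearchHit]
    total_hits: int
    page: int
    page_size: int = 500


def build_search_url(q: SearchQuery, config: ClientConfig | None = None) -> str:
    """Exact request URL for a search — a pure function of the query."""
    config = config or ClientConfig()
    keywords = q.keywords
    if q.name_only:
        keywords = f"name:({keywords})"
    params: list[tuple[str, str]] = [("q", keywords), ("page", str(q.page))]
    if q.biopax_type == "TopPathways":
        path = config.top_pathways_path
    else:
        path = config.search_path
        params.append(("type", q.biopax_type))
    for org in q.organisms:
        params.append(("organism", str(org)))
    for ds in q.datasources:
        params.append(("datasource", str(ds)))
    return f"{config.base_url}/{path}?{urllib.parse.urlencode(params)}"


def _check_status(resp: TransportResponse, url: str) -> TransportResponse:
    if resp.status == 404:
        raise NotFoundError(f"not found: {url}", status=404)
    if resp.status != 200:
        raise TransportError(f"HTTP {resp.status} for {url}", status=resp.status)
    return resp


def _parse_taxon(value: str | None) -> int | None:
    if not value:
        return None
    tail = value.rstrip("/").rsplit("/", 1)[-1]
    try:
        return int(tail)
    except ValueError:
        return None


def _parse_search_xml(text: str) -> tuple[list[dict], int]:
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ContentError(f"unparseable search response: {exc}") from exc
    total = int(root.get("numHits") or root.findtext("numHits") or 0)
    hits = []
    for hit in root.iter("searchHit"):
        hits.append(
            {
                "uri": hit.findtext("uri") or "",
                "name": hit.findtext("name") or "",
                "excerpt": hit.findtext("excerpt") or "",
                "organism": hit.findtext("organism"),
                "dataSource": hit.findtext("dataSource") or "",
            }
        )
    return hits, total


def _parse_search_json(text: str) -> tuple[list[dict], int]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ContentError(f"unparseable search response: {exc}") from exc
    raw_hits = payload.get("searchHit", [])
    hits = [
        {
            "uri": h.get("uri", ""),
            "name": h.get("name", ""),
            "excerpt": h.get("excerpt", ""),
            "organism": (h.get("organism") or [None])[0]
            if isinstance(h.get("organism"), list)
            else h.get("organism"),
            "dataSource": (h.get("dataSource") or [""])[0]
            if isinstance(h.get("dataSource"), list)
            else h.get("dataSource", ""),
        }
        for h in raw_hits
    ]
    return hits, int(payload.get("numHits", 0))


def search(q: SearchQuery, transport: Transport,
           config: ClientConfig | None = None) -> SearchPage:
    """Run one search request and parse the returned page of hits."""
    config = config or ClientConfig()
    url = build_search_url(q, config)
    resp = _check_status(transport.get(url), url)
    text = resp.text.strip()
    if not text:
        return SearchPage(hits=[], total_hits=0, page=q.page, page_size=config.page_size)
    if text.startswith("{") or "json" in resp.content_type:
        raw, total = _parse_search_json(text)
    else:
        raw, total = _parse_search_xml(text)
    hits = []
    for h in raw:
        taxon = _parse_taxon(h["organism"])
        hits.append(
            SearchHit(
                uri=h["uri"],
                name=h["name"],
                excerpt=h["excerpt"],
                organism=taxon,
                organism_name=config.taxon_resolver(taxon) if taxon else None,
                source=h["dataSource"],
            )
        )
    return SearchPage(hits=hits, total_hits=total, page=q.page, page_size=config.page_size)


def iter_pages(q: SearchQuery, transport: Transport,
               config: ClientConfig | None = None) -> Iterator[SearchPage]:
    """Walk pages from ``q.page`` until page * 500 covers the hit total."""
    config = config or ClientConfig()
    page_no = q.page
    while True:
        page = search(
            SearchQuery(q.keywords, q.name_only, q.organisms, q.datasources,
                        q.biopax_type, page_no),
            transport, config,
        )
        yield page
        page_no += 1
        if page_no * config.page_size >= page.total_hits:
            break


def fetch_owl(uri: str, transport: Transport,
              config: ClientConfig | None = None) -> OwlDocument:
    """Download a record's BioPAX OWL payload."""
    if not uri:
        raise PreconditionError("uri must be non-empty")
    config = config or ClientConfig()
    url = f"{config.base_url}/{config.get_path}?{urllib.parse.urlencode([('uri', uri)])}"
    resp = _check_status(transport.get(url), url)
    try:
        return load_document(resp.text)
    except (ParseError, NotBiopaxError) as exc:
        raise ContentError(f"payload for {uri} is not BioPAX OWL: {exc}") from exc


def count_pathway_interactions(uri: str, transport: Transport,
                               config: ClientConfig | None = None) -> int:
    """Interactions inside a pathway, via a traverse request.

    The property path recurses through sub-pathway components, mirroring
    the local :func:`biopaxnet.graph.count_interactions` semantics.
    """
    if not uri:
        raise PreconditionError("uri must be non-empty")
    config = config or ClientConfig()
    params = [("uri", uri), ("path", "Pathway/pathwayComponent*:Interaction")]
    url = f"{config.base_url}/{config.traverse_path}?{urllib.parse.urlencode(params)}"
    resp = _check_status(transport.get(url), url)
    try:
        root = etree.fromstring(resp.body)
    except etree.XMLSyntaxError as exc:
        raise ContentError(f"unparseable traverse response: {exc}") from exc
    return len(root.findall(".//value"))


_REMOTE_GRAPH_KINDS = {
    "neighborhood": "neighborhood",
    "common-stream": "commonstream",
    "paths-between": "pathsbetween",
    "paths-from-to": "pathsfromto",
}


def advanced_query(spec: QuerySpec, hit_uris: list[str], transport: Transport,
                   config: ClientConfig | None = None,
                   mode: str = "local") -> TypedGraph:
    """Evaluate an advanced query over a set of search-hit URIs.

    ``local`` mode (default) fetches each hit's OWL, builds and merges
    the graphs, and runs the matching local query with seeds resolved by
    URI.  ``remote`` mode issues the corresponding service ``graph``
    (or multi-uri ``get``) request and parses the returned OWL.
    """
    if not hit_uris:
        raise PreconditionError("advanced query requires at least one hit URI")
    config = config or ClientConfig()

    if mode == "remote":
        if spec.kind == "get":
            params = [("uri", u) for u in hit_uris]
            url = f"{config.base_url}/{config.get_path}?{urllib.parse.urlencode(params)}"
        else:
            params = [("kind", _REMOTE_GRAPH_KINDS[spec.kind])]
            params += [("source", u) for u in sorted(spec.sources) or hit_uris]
            params += [("target", u) for u in sorted(spec.targets)]
            params.append(("limit", str(spec.limit)))
            url = f"{config.base_url}/{config.graph_path}?{urllib.parse.urlencode(params)}"
        resp = _check_status(transport.get(url), url)
        return build_graph(read_biopax(resp.text))

    graphs = []
    for uri in hit_uris:
        doc = fetch_owl(uri, transport, config)
        graphs.append(build_graph(read_biopax(doc.text)))
    merged = merge_networks(graphs)
    if spec.kind == "get":
        return merged

    def resolve(uris) -> set[str]:
        return {local_fragment(u) for u in uris}

    local_spec = QuerySpec(
        kind=spec.kind,
        sources=resolve(spec.sources) if spec.sources else set(),
        targets=resolve(spec.targets) if spec.targets else set(),
        direction=spec.direction,
        limit=spec.limit,
    )
    return run_query(merged, local_spec)
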