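"""The cPath2 client, exercised offline against a canned transport.

Every request goes through an injectable transport, so the example runs
with no network: the canned transport plays back a search page and the
toy OWL document.  Swap in UrllibTransport for a live service.
"""

from biopaxnet import (
    QuerySpec,
    SearchQuery,
    advanced_query,
    build_search_url,
    fixture_text,
    search,
)
from biopaxnet.client import TransportResponse

SEARCH_BODY = (
    '<searchResponse numHits="1"><searchHit>'
    "<uri>http://pc/toy-pathway</uri><name>Toy signalling pathway</name>"
    "<organism>http://identifiers.org/taxonomy/9606</organism>"
    "<dataSource>reactome</dataSource>"
    "</searchHit></searchResponse>"
)


class CannedTransport:
    def get(self, url: str) -> TransportResponse:
        body = SEARCH_BODY if "/search?" in url else fixture_text("toy_l3")
        print("  GET", url)
        return TransportResponse(status=200, body=body.encode())


query = SearchQuery("signalling", organisms=[9606], datasources=["reactome"])
print("request URL:", build_search_url(query))
# Keywords pass through verbatim; filters become repeated service parameters.

page = search(query, CannedTransport())
hit = page.hits[0]
print(f"{page.total_hits} hit: {hit.name} [{hit.organism_name}] via {hit.source}")
# Species names come from the bundled taxonomy table (9606 -> Homo sapiens).

graph = advanced_query(QuerySpec(kind="get"), [hit.uri], CannedTransport())
print(f"fetched and built network: {graph.n_nodes} nodes, {graph.n_edges} edges")
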