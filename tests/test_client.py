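"""cPath2 client: request construction snapshots, parsing, offline chains."""

import math

import pytest

from biopaxnet import (
    QuerySpec,
    SearchQuery,
    advanced_query,
    build_search_url,
    count_pathway_interactions,
    fetch_owl,
    iter_pages,
    read_biopax,
    search,
)
from biopaxnet.client import TransportResponse
from biopaxnet.errors import ContentError, NotFoundError, PreconditionError, TransportError


class MockTransport:
    """Canned-response transport that records every requested URL."""

    def __init__(self, handler):
        self.handler = handler
        self.calls: list[str] = []

    def get(self, url: str) -> TransportResponse:
        self.calls.append(url)
        response = self.handler(url)
        if isinstance(response, TransportResponse):
            return response
        return TransportResponse(status=200, body=response.encode("utf-8"))


def search_xml(hits: list[dict], total: int) -> str:
    rows = "".join(
        "<searchHit>"
        + "".join(f"<{k}>{v}</{k}>" for k, v in hit.items())
        + "</searchHit>"
        for hit in hits
    )
    return f'<searchResponse numHits="{total}">{rows}</searchResponse>'


SNAPSHOT_PANEL = [
    (SearchQuery("interferon AND signaling"),
     "https://www.pathwaycommons.org/pc2/search?q=interferon+AND+signaling&page=0&type=Pathway"),
    (SearchQuery("glycolysis OR gluconeogenesis", biopax_type="Interaction"),
     "https://www.pathwaycommons.org/pc2/search?q=glycolysis+OR+gluconeogenesis&page=0&type=Interaction"),
    (SearchQuery("kinase*", biopax_type="PhysicalEntity"),
     "https://www.pathwaycommons.org/pc2/search?q=kinase%2A&page=0&type=PhysicalEntity"),
    (SearchQuery("name:BRCA1", biopax_type="EntityReference"),
     "https://www.pathwaycommons.org/pc2/search?q=name%3ABRCA1&page=0&type=EntityReference"),
    (SearchQuery("apoptosis", name_only=True),
     "https://www.pathwaycommons.org/pc2/search?q=name%3A%28apoptosis%29&page=0&type=Pathway"),
    (SearchQuery("TP53", organisms=[9606]),
     "https://www.pathwaycommons.org/pc2/search?q=TP53&page=0&type=Pathway&organism=9606"),
    (SearchQuery("insulin", organisms=[9606, 10090], datasources=["reactome"]),
     "https://www.pathwaycommons.org/pc2/search?q=insulin&page=0&type=Pathway"
     "&organism=9606&organism=10090&datasource=reactome"),
    (SearchQuery("cell cycle", datasources=["reactome", "humancyc"]),
     "https://www.pathwaycommons.org/pc2/search?q=cell+cycle&page=0&type=Pathway"
     "&datasource=reactome&datasource=humancyc"),
    (SearchQuery("signal", biopax_type="TopPathways"),
     "https://www.pathwaycommons.org/pc2/top_pathways?q=signal&page=0"),
    (SearchQuery("xref:P04637 AND organism:9606", page=2),
     "https://www.pathwaycommons.org/pc2/search?q=xref%3AP04637+AND+organism%3A9606&page=2&type=Pathway"),
    (SearchQuery("wnt", name_only=True, biopax_type="TopPathways",
                 organisms=["Homo sapiens"]),
     "https://www.pathwaycommons.org/pc2/top_pathways?q=name%3A%28wnt%29&page=0&organism=Homo+sapiens"),
]


class TestRequestConstruction:
    @pytest.mark.parametrize("query,expected", SNAPSHOT_PANEL,
                             ids=[q.keywords for q, _ in SNAPSHOT_PANEL])
    def test_url_snapshot(self, query, expected):
        assert build_search_url(query) == expected

    def test_invalid_type_rejected(self):
        with pytest.raises(PreconditionError):
            SearchQuery("x", biopax_type="Gene")

    def test_top_pathways_dispatches_to_dedicated_endpoint(self):
        transport = MockTransport(lambda url: search_xml([], 0))
        search(SearchQuery("wnt", biopax_type="TopPathways"), transport)
        assert "/top_pathways?" in transport.calls[0]


class TestSearchParsing:
    def test_three_hits_parsed(self):
        xml = search_xml(
            [
                {"uri": "http://pc/p1", "name": "Pathway one",
                 "organism": "http://identifiers.org/taxonomy/9606",
                 "dataSource": "reactome", "excerpt": "term <b>hit</b>"},
                {"uri": "http://pc/p2", "name": "Pathway two",
                 "organism": "10090", "dataSource": "panther"},
                {"uri": "http://pc/p3", "name": "Pathway three"},
            ],
            total=3,
        )
        page = search(SearchQuery("hit"), MockTransport(lambda url: xml))
        assert page.total_hits == 3 and len(page.hits) == 3
        assert page.hits[0].organism == 9606
        assert page.hits[0].organism_name == "Homo sapiens"
        assert page.hits[1].organism_name == "Mus musculus"
        assert page.hits[2].organism is None

    def test_empty_response(self):
        page = search(SearchQuery("nohit"), MockTransport(lambda url: search_xml([], 0)))
        assert page.hits == [] and page.total_hits == 0

    def test_json_response_supported(self):
        body = ('{"numHits": 1, "searchHit": [{"uri": "http://pc/p", '
                '"name": "N", "organism": ["9606"], "dataSource": ["pid"]}]}')
        page = search(SearchQuery("x"), MockTransport(lambda url: body))
        assert page.hits[0].organism == 9606 and page.hits[0].source == "pid"

    def test_http_failure_raises_with_status(self):
        transport = MockTransport(lambda url: TransportResponse(status=500, body=b""))
        with pytest.raises(TransportError) as err:
            search(SearchQuery("x"), transport)
        assert err.value.status == 500

    def test_pagination_issues_ceil_total_over_500_requests(self):
        total = 1733  # -> 4 pages of 500

        def handler(url):
            hits = [{"uri": f"http://pc/{i}"} for i in range(3)]
            return search_xml(hits, total)

        transport = MockTransport(handler)
        pages = list(iter_pages(SearchQuery("big"), transport))
        assert len(pages) == math.ceil(total / 500) == len(transport.calls)
        assert [f"page={i}" in url for i, url in enumerate(transport.calls)]


class TestFetchAndTraverse:
    def test_fetch_owl_chains_into_model(self, docs):
        transport = MockTransport(lambda url: docs["toy_l3"])
        doc = fetch_owl("http://pc/toy", transport)
        assert len(read_biopax(doc.text)) == 11

    def test_fetch_404(self):
        transport = MockTransport(lambda url: TransportResponse(status=404, body=b""))
        with pytest.raises(NotFoundError):
            fetch_owl("http://pc/gone", transport)

    def test_fetch_html_error_page_is_content_error(self):
        transport = MockTransport(lambda url: "<html><body>oops</body></html>")
        with pytest.raises(ContentError):
            fetch_owl("http://pc/html", transport)

    def test_traverse_count(self):
        xml = ("<traverseResponse><traverseEntry uri='http://pc/p'>"
               + "".join(f"<value>http://pc/i{i}</value>" for i in range(5))
               + "</traverseEntry></traverseResponse>")
        transport = MockTransport(lambda url: xml)
        assert count_pathway_interactions("http://pc/p", transport) == 5
        assert "path=Pathway%2FpathwayComponent%2A%3AInteraction" in transport.calls[0]

    def test_traverse_empty_and_malformed(self):
        empty = "<traverseResponse/>"
        assert count_pathway_interactions(
            "http://pc/p", MockTransport(lambda url: empty)) == 0
        with pytest.raises(ContentError):
            count_pathway_interactions(
                "http://pc/p", MockTransport(lambda url: "not xml <<<"))


class TestAdvancedQuery:
    def test_get_merges_shared_protein(self, docs):
        # two single-reaction models sharing protein P2
        base = "http://biopaxnet.example/toy#"
        doc_a = docs["toy_l3"]

        doc_b = doc_a.replace("toy#R1", "other#R9").replace("toy#P1", "other#P9")

        def handler(url):
            return doc_a if "uri=http%3A%2F%2Fpc%2Fa" in url else doc_b

        transport = MockTransport(handler)
        merged = advanced_query(QuerySpec(kind="get"), ["http://pc/a", "http://pc/b"],
                                transport)
        # shared fragments unify; R9/P9 are the only additions
        assert merged.n_nodes == 8 + 2
        assert base  # silence unused

    def test_local_neighborhood_equals_direct_query(self, docs, toy_l3_graph):
        from biopaxnet import neighborhood

        transport = MockTransport(lambda url: docs["toy_l3"])
        result = advanced_query(
            QuerySpec(kind="neighborhood",
                      sources={"http://biopaxnet.example/toy#C1"}, direction="both",
                      limit=1),
            ["http://pc/toy"], transport)
        direct = neighborhood(toy_l3_graph, {"C1"}, "both", 1)
        assert set(result.nodes) == set(direct.nodes)
        assert result.edge_multiset() == direct.edge_multiset()

    def test_zero_hits_rejected(self):
        with pytest.raises(PreconditionError):
            advanced_query(QuerySpec(kind="get"), [], MockTransport(lambda url: ""))

    def test_remote_mode_builds_graph_request(self, docs):
        transport = MockTransport(lambda url: docs["diamond"])
        result = advanced_query(
            QuerySpec(kind="paths-between",
                      sources={"http://pc/e1", "http://pc/e2"}, limit=2),
            ["http://pc/e1", "http://pc/e2"], transport, mode="remote")
        assert "kind=pathsbetween" in transport.calls[0]
        assert "limit=2" in transport.calls[0]
        assert result.n_nodes == 7  # whole returned diamond document
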