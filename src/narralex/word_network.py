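"""Word co-occurrence networks and betweenness-centrality bridge ranking.

For each narrative group the texts are tokenized, stopwords / excluded words
/ numeric tokens are dropped, and an undirected graph is built in which two
words are linked when they appear in the same co-occurrence unit (a sentence
by default, or a sliding token window).  Edge weight counts the units in
which the pair co-occurs; within one unit a pair co-occurs at most once.

Betweenness centrality is computed on the FULL retained-vocabulary graph;
the top-k most frequent words control display only.  The word with the
highest betweenness among displayed words is the network's "bridge": the
node through which shortest paths between otherwise-separate semantic
clusters must pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .corpus_io import CorpusTable
from .lexicon_engine import tokenize

__all__ = [
    "NetworkConfig", "WordGraph", "load_stopwords", "network_tokens",
    "word_frequencies", "build_cooccurrence_graph", "betweenness_centrality",
    "bridge_ranking", "style_edges", "export_graph", "import_graphml",
    "build_group_network", "DEFAULT_EXTRA_EXCLUSIONS",
]

#: non-meaningful words excluded on top of the stopword list
DEFAULT_EXTRA_EXCLUSIONS = frozenset({"things", "one", "will", "much"})


def load_stopwords(path: Optional[Path] = None) -> frozenset[str]:
    """The packaged (or a user-supplied) one-word-per-line stopword list."""
    path = Path(path) if path else Path(__file__).parent / "data" / "stopwords.txt"
    words = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


@dataclass
class NetworkConfig:
    """Construction and styling parameters for the word network."""

    top_k: int = 20
    highlight_quantile: float = 0.40
    cooccurrence_unit: str = "sentence"  # "sentence" | "window"
    window_size: int = 10
    stopword_list: frozenset[str] = field(default_factory=load_stopwords)
    extra_exclusions: frozenset[str] = DEFAULT_EXTRA_EXCLUSIONS
    distance_mode: str = "unweighted"  # "unweighted" | "inverse_weight"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.highlight_quantile <= 1:
            raise ValueError("highlight_quantile must lie in (0, 1]")
        if self.cooccurrence_unit not in ("sentence", "window"):
            raise ValueError(f"unknown cooccurrence_unit {self.cooccurrence_unit!r}")
        if self.distance_mode not in ("unweighted", "inverse_weight"):
            raise ValueError(f"unknown distance_mode {self.distance_mode!r}")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        self.stopword_list = frozenset(w.lower() for w in self.stopword_list)
        self.extra_exclusions = frozenset(w.lower() for w in self.extra_exclusions)


@dataclass
class WordGraph:
    """Co-occurrence network: a networkx Graph plus the subset label.

    Node attributes: frequency (int), betweenness (float), displayed (bool).
    Edge attributes: weight (int), highlighted (bool).
    """

    graph: nx.Graph
    subset: str = ""

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("WordGraph: self-loops not allowed")


def network_tokens(
    corpus_subset: CorpusTable, config: NetworkConfig
) -> list[list[str]]:
    """Per-unit token lists after stopword / exclusion / numeric filtering.

    Units are sentences or sliding windows, never crossing narrative
    boundaries.  An empty subset yields an empty list.
    """
    drop = config.stopword_list | config.extra_exclusions
    units: list[list[str]] = []
    for rec in corpus_subset:
        stream = tokenize(rec.text, rec.narrative_id)
        kept = [
            (tok, s)
            for tok, s in zip(stream.tokens, stream.sentence_index)
            if tok not in drop and not tok.isdigit()
        ]
        if not kept:
            continue
        if config.cooccurrence_unit == "sentence":
            current: list[str] = []
            current_sent = kept[0][1]
            for tok, s in kept:
                if s != current_sent:
                    if current:
                        units.append(current)
                    current, current_sent = [], s
                current.append(tok)
            if current:
                units.append(current)
        else:
            toks = [tok for tok, _ in kept]
            w = config.window_size
            if len(toks) <= w:
                units.append(toks)
            else:
                units.extend(toks[i:i + w] for i in range(len(toks) - w + 1))
    return units


def word_frequencies(units: Iterable[Iterable[str]]) -> dict[str, int]:
    """Token occurrence counts aggregated over all units."""
    freq: dict[str, int] = {}
    for unit in units:
        for tok in unit:
            freq[tok] = freq.get(tok, 0) + 1
    return freq


def build_cooccurrence_graph(
    units: Iterable[Iterable[str]],
    config: Optional[NetworkConfig] = None,
    subset: str = "",
) -> WordGraph:
    """Undirected graph over retained words; weight = number of shared units.

    Within one unit every unordered pair of distinct words co-occurs exactly
    once, regardless of repetition.
    """
    config = config or NetworkConfig()
    units = [list(u) for u in units]
    freq = word_frequencies(units)
    g = nx.Graph()
    for word, count in freq.items():
        g.add_node(word, frequency=count)
    for unit in units:
        vocab = sorted(set(unit))
        for i, u in enumerate(vocab):
            for v in vocab[i + 1:]:
                if g.has_edge(u, v):
                    g[u][v]["weight"] += 1
                else:
                    g.add_edge(u, v, weight=1)
    # display flag: top-k by frequency, ties broken alphabetically for
    # a deterministic display set
    ranked = sorted(freq, key=lambda w: (-freq[w], w))
    displayed = set(ranked[: config.top_k])
    for word in g.nodes:
        g.nodes[word]["displayed"] = word in displayed
        g.nodes[word]["betweenness"] = 0.0
    return WordGraph(graph=g, subset=subset)


def betweenness_centrality(
    graph: WordGraph, config: Optional[NetworkConfig] = None
) -> dict[str, float]:
    """Unnormalized betweenness over unordered pairs, on the FULL graph.

    For every node v: sum over pairs {s, t} (s, t != v) of the fraction of
    shortest s-t paths through v.  Shortest paths are unweighted by default;
    with distance_mode="inverse_weight", edge length is 1/weight so heavier
    co-occurrence means closer.  Values are stored on the node attributes
    and returned.
    """
    config = config or NetworkConfig()
    g = graph.graph
    if g.number_of_nodes() == 0:
        return {}
    if config.distance_mode == "inverse_weight":
        for u, v, data in g.edges(data=True):
            data["_distance"] = 1.0 / data["weight"]
        bc = nx.betweenness_centrality(g, normalized=False, weight="_distance")
        for u, v, data in g.edges(data=True):
            del data["_distance"]
    else:
        bc = nx.betweenness_centrality(g, normalized=False)
    for node, value in bc.items():
        g.nodes[node]["betweenness"] = float(value)
    return {n: float(v) for n, v in bc.items()}


def bridge_ranking(graph: WordGraph) -> list[str]:
    """Displayed words by betweenness desc, then frequency desc, then A-Z.

    The first element is the network's most central (bridge) word.
    """
    g = graph.graph
    displayed = [n for n, d in g.nodes(data=True) if d.get("displayed")]
    return sorted(
        displayed,
        key=lambda w: (
            -g.nodes[w].get("betweenness", 0.0),
            -g.nodes[w].get("frequency", 0),
            w,
        ),
    )


def style_edges(graph: WordGraph, config: Optional[NetworkConfig] = None) -> WordGraph:
    """Flag the heaviest *highlight_quantile* share of edges as highlighted.

    The threshold is the weight of the ceil(q * m)-th heaviest edge; ties at
    the threshold are included.  All edges are retained either way.
    """
    config = config or NetworkConfig()
    g = graph.graph
    weights = sorted((d["weight"] for _, _, d in g.edges(data=True)), reverse=True)
    if weights:
        k = min(len(weights), max(1, math.ceil(len(weights) * config.highlight_quantile)))
        threshold = weights[k - 1]
        for u, v, data in g.edges(data=True):
            data["highlighted"] = data["weight"] >= threshold
    return graph


def export_graph(graph: WordGraph, path, fmt: str = "graphml") -> Path:
    """Write the graph as GraphML or as node/edge TSV mirrors.

    GraphML keeps all node attributes (frequency, betweenness, displayed)
    and edge attributes (weight, highlighted); a round-trip through
    :func:`import_graphml` reproduces the graph exactly.
    """
    path = Path(path)
    g = graph.graph
    if fmt == "graphml":
        export = nx.Graph(subset=graph.subset)
        for n, d in g.nodes(data=True):
            export.add_node(
                n,
                frequency=int(d.get("frequency", 0)),
                betweenness=float(d.get("betweenness", 0.0)),
                displayed=bool(d.get("displayed", False)),
            )
        for u, v, d in g.edges(data=True):
            export.add_edge(
                u, v,
                weight=int(d["weight"]),
                highlighted=bool(d.get("highlighted", False)),
            )
        nx.write_graphml(export, path, named_key_ids=True)
    elif fmt == "node_tsv":
        lines = ["word\tfrequency\tbetweenness\tdisplayed"]
        for n in sorted(g.nodes):
            d = g.nodes[n]
            lines.append(
                f"{n}\t{d.get('frequency', 0)}\t"
                f"{d.get('betweenness', 0.0):.10g}\t"
                f"{str(bool(d.get('displayed', False))).lower()}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif fmt == "edge_tsv":
        lines = ["word1\tword2\tweight\thighlighted"]
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            d = g[u][v]
            lines.append(
                f"{u}\t{v}\t{d['weight']}\t"
                f"{str(bool(d.get('highlighted', False))).lower()}"
            )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_graphml(path) -> WordGraph:
    """Read a GraphML file written by :func:`export_graph`."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(
            n,
            frequency=int(d.get("frequency", 0)),
            betweenness=float(d.get("betweenness", 0.0)),
            displayed=bool(d.get("displayed", False)),
        )
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, weight=int(d["weight"]),
                     highlighted=bool(d.get("highlighted", False)))
    return WordGraph(graph=out, subset=str(g.graph.get("subset", "")))


def build_group_network(
    corpus_subset: CorpusTable,
    config: Optional[NetworkConfig] = None,
    subset: str = "",
) -> WordGraph:
    """Full pipeline for one group: units -> graph -> betweenness -> styling."""
    config = config or NetworkConfig()
    units = network_tokens(corpus_subset, config)
    graph = build_cooccurrence_graph(units, config, subset=subset)
    betweenness_centrality(graph, config)
    style_edges(graph, config)
    return graph
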