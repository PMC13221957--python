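"""End-to-end study replica: features -> comparisons -> group networks.

One call produces, under an output directory:

* ``features.csv`` — one row of linguistic features per (author-merged)
  narrative;
* two comparison tables (first- vs third-person accounts, and within
  first-person accounts with vs without interpersonal difficulties), each
  with summary/basic and pronoun blocks BH-adjusted separately;
* four network bundles (FPA, TPA, FPA_ID, FPA_noID): GraphML, node/edge
  TSVs, and a bridge-ranking file;
* ``manifest.json`` — every output with a sha256 content hash, the echoed
  configuration, and library versions, so a rerun can be verified
  byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx
import numpy
import pandas
import scipy
import statsmodels
import yaml

from . import __version__
from .corpus_io import (
    GROUP_FPA, GROUP_FPA_ID, GROUP_FPA_NOID, GROUP_TPA,
    CorpusTable, load_corpus, merge_by_author, split_groups,
)
from .group_stats import (
    DEFAULT_FAMILIES, DEFAULT_LEVENE_GATE, comparison_frame,
    run_comparison_battery,
)
from .lexicon_engine import (
    DEFAULT_NEGATION_WINDOW, SUMMARY_LABEL, Lexicon, default_lexicon,
    features_frame, load_lexicon,
)
from .word_network import NetworkConfig, bridge_ranking, build_group_network, export_graph

logger = logging.getLogger(__name__)

MIN_TOKENS_FLAG = 25  # narratives shorter than this are flagged, never dropped


@dataclass
class RunConfig:
    """Single configuration object for the full pipeline."""

    metadata_path: Optional[Path] = None
    text_dir: Optional[Path] = None
    lexicon_path: Optional[Path] = None
    negation_window: int = DEFAULT_NEGATION_WINDOW
    families: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FAMILIES.items()})
    levene_gate: float = DEFAULT_LEVENE_GATE
    network: NetworkConfig = field(default_factory=NetworkConfig)
    output_dir: Path = Path("narralex_out")
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        net = NetworkConfig(**raw.pop("network", {}))
        fams = raw.pop("families", None)
        cfg = cls(network=net, **{
            k: (Path(v) if k.endswith(("_path", "_dir")) and v is not None else v)
            for k, v in raw.items()
        })
        if fams:
            cfg.families = {k: tuple(v) for k, v in fams.items()}
        return cfg

    def echo(self) -> dict:
        return {
            "metadata_path": str(self.metadata_path) if self.metadata_path else None,
            "text_dir": str(self.text_dir) if self.text_dir else None,
            "lexicon_path": str(self.lexicon_path) if self.lexicon_path else None,
            "negation_window": self.negation_window,
            "families": {k: list(v) for k, v in self.families.items()},
            "levene_gate": self.levene_gate,
            "network": {
                "top_k": self.network.top_k,
                "highlight_quantile": self.network.highlight_quantile,
                "cooccurrence_unit": self.network.cooccurrence_unit,
                "window_size": self.network.window_size,
                "distance_mode": self.network.distance_mode,
                "n_stopwords": len(self.network.stopword_list),
                "extra_exclusions": sorted(self.network.extra_exclusions),
            },
            "seed": self.seed,
            "summary_scores": SUMMARY_LABEL,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


CONTRASTS = (
    ("fpa_vs_tpa", GROUP_FPA, GROUP_TPA),
    ("fpa_id_vs_noid", GROUP_FPA_ID, GROUP_FPA_NOID),
)


def run_full_pipeline(
    config: RunConfig,
    corpus: Optional[CorpusTable] = None,
    lexicon: Optional[Lexicon] = None,
) -> dict:
    """Run the whole study replica; returns the manifest (also written to disk).

    *corpus* may be passed directly (e.g. a synthetic one); otherwise it is
    loaded from config.metadata_path / config.text_dir.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if corpus is None:
        if config.metadata_path is None or config.text_dir is None:
            raise ValueError("run_full_pipeline: no corpus and no paths configured")
        corpus = load_corpus(config.metadata_path, config.text_dir)
    lex = lexicon or (load_lexicon(config.lexicon_path)
                      if config.lexicon_path else default_lexicon())

    merged = merge_by_author(corpus)
    groups = split_groups(merged)
    logger.info(
        "corpus: %d narratives, %d after author merge (%s)",
        len(corpus), len(merged),
        ", ".join(f"{k}={len(v)}" for k, v in groups.items()),
    )

    stage = "features"
    features = features_frame(merged, lex, config.negation_window)
    short = features.loc[features["word_count"] < MIN_TOKENS_FLAG, "narrative_id"]
    for nid in short:
        logger.warning("narrative %r has fewer than %d tokens (retained)",
                       nid, MIN_TOKENS_FLAG)
    outputs: list[Path] = []
    fpath = out / "features.csv"
    features.to_csv(fpath, index=False, float_format="%.6f")
    outputs.append(fpath)
    logger.info("stage %s: %d rows in %.2fs", stage, len(features), time.time() - t0)

    comparison_files: list[str] = []
    skipped: list[str] = []
    group_of = {}
    for label, table in groups.items():
        for rec in table:
            group_of.setdefault(rec.narrative_id, set()).add(label)
    for name, g1, g2 in CONTRASTS:
        mask_ids = [
            (nid, g1 if g1 in group_of.get(nid, ()) else g2)
            for nid in features["narrative_id"]
            if group_of.get(nid, set()) & {g1, g2}
        ]
        sub = features[features["narrative_id"].isin([i for i, _ in mask_ids])]
        labels = [g for _, g in mask_ids]
        n1, n2 = labels.count(g1), labels.count(g2)
        if n1 < 2 or n2 < 2:
            logger.warning("contrast %s skipped: group sizes %d vs %d", name, n1, n2)
            skipped.append(name)
            continue
        try:
            results = run_comparison_battery(
                sub, (g1, g2, labels), config.families, config.levene_gate)
        except Exception as exc:
            raise RuntimeError(f"stage comparisons[{name}]: {exc}") from exc
        cpath = out / f"comparison_{name}.csv"
        comparison_frame(results).to_csv(cpath, index=False, float_format="%.6f")
        outputs.append(cpath)
        comparison_files.append(cpath.name)

    network_bundles: dict[str, dict] = {}
    for label in (GROUP_FPA, GROUP_TPA, GROUP_FPA_ID, GROUP_FPA_NOID):
        table = groups[label]
        if len(table) == 0:
            logger.warning("network for %s skipped: empty subset", label)
            continue
        try:
            graph = build_group_network(table, config.network, subset=label)
        except Exception as exc:
            raise RuntimeError(f"stage network[{label}]: {exc}") from exc
        bundle = {}
        for fmt, suffix in (("graphml", ".graphml"),
                            ("node_tsv", "_nodes.tsv"),
                            ("edge_tsv", "_edges.tsv")):
            p = out / f"network_{label}{suffix}"
            export_graph(graph, p, fmt)
            outputs.append(p)
            bundle[fmt] = p.name
        ranking = bridge_ranking(graph)
        rpath = out / f"network_{label}_bridge_ranking.txt"
        rpath.write_text("\n".join(ranking) + ("\n" if ranking else ""),
                         encoding="utf-8")
        outputs.append(rpath)
        bundle["bridge_ranking"] = rpath.name
        bundle["most_central"] = ranking[0] if ranking else None
        network_bundles[label] = bundle

    manifest = {
        "narralex_version": __version__,
        "libraries": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__,
            "networkx": networkx.__version__,
        },
        "config": config.echo(),
        "group_sizes": {k: len(v) for k, v in groups.items()},
        "n_narratives_merged": len(merged),
        "comparison_tables": comparison_files,
        "skipped_contrasts": skipped,
        "network_bundles": network_bundles,
        "outputs": {p.name: _sha256(p) for p in outputs},
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                     encoding="utf-8")
    return manifest
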