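"""Calibration and validation experiments for the pipeline.

Because the narratives the method was designed for cannot be redistributed,
the package validates itself on synthetic corpora with known ground truth:
oracle checks for the graph statistics, null calibration and planted-effect
recovery for the comparison battery, bridge detection for the network
module, and agreement recovery for the reliability statistic.  Each function
here runs one such experiment end to end through the public API and returns
plain numbers; the test suite asserts on them and the acceptance script
reports them.

Every experiment takes a base seed and derives per-replicate seeds by
offset, so whole experiments are reproducible from a single integer.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import networkx as nx
import numpy as np

from .corpus_io import split_groups
from .group_stats import (
    DEFAULT_FAMILIES, cohens_d, krippendorff_alpha, run_comparison_battery,
    two_sample_t,
)
from .lexicon_engine import adjusted_tone, default_lexicon, features_frame, tokenize
from .pipeline import RunConfig, run_full_pipeline
from .synthetic_corpus import (
    DEFAULT_CATEGORY_RATES, BridgePlan, RaterPlan, SyntheticSpec,
    generate_bridge_corpus, generate_corpus, generate_rater_codes,
    generate_true_labels,
)
from .word_network import (
    NetworkConfig, WordGraph, betweenness_centrality, bridge_ranking,
    build_group_network,
)

__all__ = [
    "betweenness_exhaustive", "betweenness_oracle_check",
    "bh_reference_check", "null_calibration", "effect_recovery",
    "bridge_detection", "reliability_recovery", "negation_exclusion_check",
    "welch_student_consistency", "structural_replica",
]

_MOD = 2**31  # all derived seeds stay below 2**31


def _seed(base: int, offset: int) -> int:
    return int((base * 100_003 + offset) % _MOD)


# --------------------------------------------------------------------------
# graph statistics vs exhaustive oracle

def betweenness_exhaustive(g: nx.Graph) -> dict:
    """Betweenness by explicit enumeration of every shortest path.

    Independent of the production route (Brandes accumulation): for each
    node pair it lists all simple paths of minimal length and credits
    intermediate nodes directly.  Feasible only for small graphs.
    """
    nodes = list(g.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        dist = nx.shortest_path_length(g, s, t)
        paths = [p for p in nx.all_simple_paths(g, s, t, cutoff=dist)
                 if len(p) - 1 == dist]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                bc[v] += through / len(paths)
    return bc


def betweenness_oracle_check(n_graphs: int = 200, seed: int = 0,
                             max_nodes: int = 8) -> dict:
    """Compare production betweenness with the exhaustive oracle.

    Random Erdos-Renyi graphs with 2..max_nodes nodes; returns the number of
    graphs in exact agreement (within 1e-9 per node) and the largest
    per-node discrepancy seen.
    """
    rng = np.random.default_rng(_seed(seed, 1))
    agree = 0
    max_diff = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.95))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, _MOD)))
        for node in g.nodes:
            g.nodes[node].update(frequency=1, displayed=True)
        for u, v in g.edges:
            g[u][v]["weight"] = 1
        ours = betweenness_centrality(WordGraph(graph=g))
        oracle = betweenness_exhaustive(g)
        diff = max((abs(ours[v] - oracle[v]) for v in g.nodes), default=0.0)
        max_diff = max(max_diff, diff)
        agree += diff <= 1e-9
    return {"n_graphs": n_graphs, "n_agree": agree, "max_abs_diff": max_diff}


def bh_reference_check(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Compare bh_adjust with an independent step-up reference on random vectors.

    The reference is statsmodels' fdr_bh implementation; also re-checks the
    hand-computed fixed vector {.01, .02, .04} -> {.03, .03, .04}.
    """
    from statsmodels.stats.multitest import multipletests

    from .group_stats import bh_adjust

    rng = np.random.default_rng(_seed(seed, 2))
    max_diff = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 25))
        p = rng.random(m)
        if rng.random() < 0.3:  # exercise ties
            p = np.round(p, 2)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        max_diff = max(max_diff, float(np.abs(ours - ref).max()))
    fixed = bh_adjust([0.01, 0.02, 0.04])
    fixed_diff = float(np.abs(fixed - np.array([0.03, 0.03, 0.04])).max())
    return {"n_vectors": n_vectors, "max_abs_diff": max(max_diff, fixed_diff)}


# --------------------------------------------------------------------------
# comparison battery calibration on synthetic corpora

#: within-FPA simulation conditions: both groups share the no-ID emission
#: profile and a common length distribution so only planted effects differ
_SIM_LENGTH = (250.0, 120.0)


def _sim_spec(seed: int, n_per_group: int, d: float = 0.0) -> SyntheticSpec:
    rates = {
        "FPA_ID": dict(DEFAULT_CATEGORY_RATES["FPA_noID"]),
        "FPA_noID": dict(DEFAULT_CATEGORY_RATES["FPA_noID"]),
    }
    planted = {"neg_tone": ("FPA_ID", "FPA_noID", d)} if d else {}
    return SyntheticSpec(
        n_per_group={"FPA_ID": n_per_group, "FPA_noID": n_per_group},
        length_distribution={"FPA_ID": _SIM_LENGTH, "FPA_noID": _SIM_LENGTH},
        category_rates=rates,
        planted_effects=planted,
        seed=seed,
    )


def _battery_once(spec: SyntheticSpec, family: Sequence[str]):
    corpus, _ = generate_corpus(spec)
    lex = default_lexicon()
    df = features_frame(corpus, lex)
    labels = ["FPA_ID" if flag else "FPA_noID"
              for flag in df["interpersonal_difficulties"]]
    return run_comparison_battery(
        df, ("FPA_ID", "FPA_noID", labels),
        families={"summary_basic": tuple(family)},
    )


def null_calibration(n_seeds: int = 400, n_per_group: int = 60,
                     seed: int = 0) -> dict:
    """Family-wise false-rejection rate with identical group rates.

    Runs the full generate -> extract -> battery pipeline per seed on a
    7-variable family and counts corpora with any BH-adjusted p < .05.
    """
    family = DEFAULT_FAMILIES["summary_basic"]
    rejections = 0
    for k in range(n_seeds):
        results = _battery_once(_sim_spec(_seed(seed, 10_000 + k),
                                          n_per_group), family)
        rejections += any(r.p_adj < 0.05 for r in results)
    return {"n_seeds": n_seeds, "n_rejections": rejections,
            "rejection_rate": rejections / n_seeds}


def effect_recovery(n_seeds: int = 100, n_per_group: int = 60,
                    d_small: float = 0.5, d_large: float = 1.0,
                    seed: int = 0) -> dict:
    """Planted negative-tone effect: d estimate and family-wise detection.

    Returns the median estimated Cohen's d at *d_small* and the share of
    seeds where the planted variable has the family's smallest adjusted p
    at *d_large*.
    """
    family = DEFAULT_FAMILIES["summary_basic"]
    estimates = []
    for k in range(n_seeds):
        results = _battery_once(
            _sim_spec(_seed(seed, 20_000 + k), n_per_group, d=d_small), family)
        planted = next(r for r in results if r.variable == "neg_tone")
        estimates.append(planted.cohen_d)
    top1 = 0
    for k in range(n_seeds):
        results = _battery_once(
            _sim_spec(_seed(seed, 30_000 + k), n_per_group, d=d_large), family)
        best = min(results, key=lambda r: (r.p_adj, r.p_raw))
        top1 += best.variable == "neg_tone"
    return {
        "n_seeds": n_seeds,
        "median_estimated_d": float(np.median(estimates)),
        "planted_d": d_small,
        "top1_rate_at_d1": top1 / n_seeds,
    }


# --------------------------------------------------------------------------
# bridge detection

def bridge_detection(n_seeds: int = 100, leak_grid: Sequence[float] = (0.0, 0.1, 0.3, 0.5),
                     seeds_per_leak: int = 50, seed: int = 0) -> dict:
    """Planted-bridge recovery rate at zero leak and rank decay over the grid.

    Rank is the bridge word's 1-based position in the betweenness ranking
    (worst rank if absent); the grid reports the mean rank per leak level.
    """
    cfg = NetworkConfig(top_k=20)

    def bridge_rank(leak: float, s: int) -> int:
        plan = BridgePlan(leak=leak)
        corpus = generate_bridge_corpus(SyntheticSpec(seed=s, bridge_plan=plan))
        graph = build_group_network(corpus, cfg)
        ranking = bridge_ranking(graph)
        return (ranking.index(plan.bridge) + 1 if plan.bridge in ranking
                else len(ranking) + 1)

    top_first = sum(
        bridge_rank(0.0, _seed(seed, 40_000 + k)) == 1 for k in range(n_seeds))
    mean_ranks = []
    for i, leak in enumerate(leak_grid):
        ranks = [bridge_rank(leak, _seed(seed, 50_000 + 1000 * i + k))
                 for k in range(seeds_per_leak)]
        mean_ranks.append(float(np.mean(ranks)))
    return {
        "n_seeds": n_seeds,
        "top_rank_rate_leak0": top_first / n_seeds,
        "leak_grid": list(leak_grid),
        "mean_rank_by_leak": mean_ranks,
    }


# --------------------------------------------------------------------------
# reliability

def reliability_recovery(seed: int = 0, n_items_chance: int = 1000,
                         accuracy_grid: Sequence[float] = (0.6, 0.7, 0.8, 0.9),
                         seeds_per_level: int = 50,
                         n_items_grid: int = 120) -> dict:
    """Alpha under perfect, chance, and graded rater accuracy."""
    plan = RaterPlan()
    labels = generate_true_labels(60, plan, _seed(seed, 3))
    perfect = krippendorff_alpha(
        generate_rater_codes(labels, RaterPlan(accuracy=1.0), _seed(seed, 4)),
        bootstrap_reps=0).alpha

    chance_labels = generate_true_labels(n_items_chance, plan, _seed(seed, 5))
    chance = krippendorff_alpha(
        generate_rater_codes(chance_labels, RaterPlan(accuracy=0.5),
                             _seed(seed, 6)),
        bootstrap_reps=0).alpha

    medians = []
    for i, acc in enumerate(accuracy_grid):
        alphas = []
        for k in range(seeds_per_level):
            s = _seed(seed, 60_000 + 1000 * i + k)
            lab = generate_true_labels(n_items_grid, plan, s)
            codes = generate_rater_codes(lab, RaterPlan(accuracy=acc), s)
            alphas.append(krippendorff_alpha(codes, bootstrap_reps=0).alpha)
        medians.append(float(np.median(alphas)))
    return {
        "alpha_perfect": perfect,
        "alpha_chance": chance,
        "accuracy_grid": list(accuracy_grid),
        "median_alpha_by_accuracy": medians,
    }


# --------------------------------------------------------------------------
# negation semantics and t-test consistency

def negation_exclusion_check(seed: int = 0, n_per_group: int = 5) -> dict:
    """With every emotion token negated, adjusted tones must be exactly zero."""
    spec = SyntheticSpec(
        n_per_group={"FPA_ID": n_per_group, "FPA_noID": n_per_group,
                     "TPA": n_per_group},
        length_distribution={g: (400.0, 150.0)
                             for g in ("FPA_ID", "FPA_noID", "TPA")},
        negation_rate=1.0,
        seed=seed,
    )
    corpus, _ = generate_corpus(spec)
    lex = default_lexicon()
    worst = 0.0
    n_narratives = 0
    for rec in corpus:
        pos, neg = adjusted_tone(tokenize(rec.text, rec.narrative_id), lex)
        worst = max(worst, pos, neg)
        n_narratives += 1
    return {"n_narratives": n_narratives, "max_adjusted_tone": worst}


def welch_student_consistency(n_trials: int = 200, seed: int = 0) -> dict:
    """Welch vs Student agreement with equal n and exactly equal variances.

    Each trial draws one sample and shifts a copy, so the two group
    variances are identical by construction; also checks that swapping the
    groups negates t and preserves p.
    """
    rng = np.random.default_rng(_seed(seed, 7))
    max_t_diff = 0.0
    max_swap_err = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(5, 40))
        x = rng.normal(0, rng.uniform(0.5, 3.0), n)
        y = x + rng.uniform(-2, 2)
        student = two_sample_t(x, y, gate=0.0)
        welch = two_sample_t(x, y, gate=1.01)
        max_t_diff = max(max_t_diff, abs(student.t - welch.t))
        fwd, rev = two_sample_t(x, y), two_sample_t(y, x)
        max_swap_err = max(max_swap_err, abs(fwd.t + rev.t),
                           abs(fwd.p_raw - rev.p_raw))
    return {"n_trials": n_trials, "max_welch_student_t_diff": max_t_diff,
            "max_swap_asymmetry": max_swap_err}


# --------------------------------------------------------------------------
# end-to-end structural replica

def structural_replica(seed: int = 0, out_dir=None,
                       length_scale: float = 0.1) -> dict:
    """Study-shaped end-to-end run: 56 + 77 first-person, 44 third-person.

    Group sizes and length *ratios* mirror the study design; lengths are
    scaled down (default 10x) to keep the run light.  The pipeline is run
    twice to verify byte-identical outputs.
    """
    import tempfile
    from pathlib import Path

    lengths = {g: (m * length_scale, s * length_scale)
               for g, (m, s) in SyntheticSpec().length_distribution.items()}
    spec = SyntheticSpec(seed=seed, length_distribution=lengths)
    corpus, _ = generate_corpus(spec)
    groups = split_groups(corpus)

    with tempfile.TemporaryDirectory() as tmp:
        base = Path(out_dir) if out_dir else Path(tmp)
        m1 = run_full_pipeline(RunConfig(output_dir=base / "run1", seed=seed),
                               corpus=corpus)
        m2 = run_full_pipeline(RunConfig(output_dir=base / "run2", seed=seed),
                               corpus=corpus)
    return {
        "group_sizes": {k: len(v) for k, v in groups.items()},
        "n_comparison_tables": len(m1["comparison_tables"]),
        "n_network_bundles": len(m1["network_bundles"]),
        "deterministic": m1["outputs"] == m2["outputs"],
        "most_central": {k: v["most_central"]
                         for k, v in m1["network_bundles"].items()},
    }
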