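"""Sequence-similarity network construction, topology and robustness.

Nodes are genes; an undirected edge joins two genes when the best alignment
hit between them (either direction) clears the similarity threshold
(default E <= 1e-5), weighted by the maximum bit score.  On the resulting
simple graph the module computes degree distributions, PageRank, K-shell
(k-core) decomposition, and attack-robustness trajectories:

* RS — relative size of the largest connected component, Nt / n0, where n0
  is the initial node count;
* RE — relative global efficiency, E(G_t) / E(G_0), with global efficiency
  the mean over ordered node pairs of 1 / shortest-path-length (0 for
  disconnected pairs).

Attack strategies: uniform random removal, highest-degree-first and
highest-PageRank-first; targeted strategies re-rank after every removal by
default (adaptive), with a static rank-once mode behind a flag.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .screen import ScreenHit

ATTACK_STRATEGIES = ("random", "max_degree", "max_pagerank")


@dataclasses.dataclass
class NetworkConfig:
    """Edge criterion for the similarity network."""

    max_evalue: float = 1e-5
    min_bitscore: float = 0.0


@dataclasses.dataclass
class KShellResult:
    shell: dict  # node -> core index
    max_shell: int


@dataclasses.dataclass
class AttackCurve:
    strategy: str
    fractions: np.ndarray
    rs: np.ndarray
    re: np.ndarray
    n0: int

    def to_frame(self, seed=None) -> pd.DataFrame:
        return pd.DataFrame({
            "strategy": self.strategy,
            "fraction": self.fractions,
            "rs": self.rs,
            "re": self.re,
            "seed": seed if seed is not None else -1,
        })


def build_network(
    hits: Iterable[ScreenHit],
    node_meta: pd.DataFrame | Mapping[str, dict] | None = None,
    config: NetworkConfig | None = None,
) -> nx.Graph:
    """Build the similarity network from all-vs-all hits.

    For each unordered gene pair the better-direction hit (max bitscore)
    decides edge existence (E <= threshold) and the edge weight (bitscore).
    Self-hits are ignored.  ``node_meta`` (columns/keys: category, phylum,
    indexed by gene id) annotates nodes; genes seen in hits but missing
    from the metadata are kept with empty metadata after a warning.
    """
    config = config or NetworkConfig()
    best: dict[tuple[str, str], ScreenHit] = {}
    nodes: set[str] = set()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        nodes.update((h.query_id, h.subject_id))
        key = tuple(sorted((h.query_id, h.subject_id)))
        cur = best.get(key)
        if cur is None or h.bitscore > cur.bitscore:
            best[key] = h
    g = nx.Graph()
    meta: dict[str, dict] = {}
    if node_meta is not None:
        if isinstance(node_meta, pd.DataFrame):
            frame = node_meta.set_index("id") if "id" in node_meta.columns else node_meta
            meta = frame.to_dict(orient="index")
        else:
            meta = dict(node_meta)
        g.add_nodes_from(meta.keys())
    missing = nodes - set(meta)
    if node_meta is not None and missing:
        warnings.warn(f"{len(missing)} node(s) in hits absent from metadata; kept with empty metadata")
    g.add_nodes_from(nodes)
    for node, attrs in meta.items():
        g.nodes[node].update({k: v for k, v in attrs.items() if pd.notna(v)})
    for (u, v), h in best.items():
        if h.evalue <= config.max_evalue and h.bitscore >= config.min_bitscore:
            g.add_edge(u, v, weight=float(h.bitscore))
    return g


def degree_distribution(g: nx.Graph) -> dict[int, int]:
    """Histogram degree -> node count (counts sum to the node count)."""
    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    return hist


def kshell(g: nx.Graph) -> KShellResult:
    """K-core decomposition by iterative minimum-degree peeling.

    shell(v) is the largest k such that v belongs to the k-core of the
    unweighted simple graph.
    """
    core = nx.core_number(g)
    max_shell = max(core.values()) if core else 0
    return KShellResult(dict(core), int(max_shell))


def core_fraction(ks: KShellResult) -> float:
    """Fraction of nodes sitting in the maximum shell (the network core)."""
    if not ks.shell:
        raise ValueError("empty graph has no core")
    n_core = sum(1 for v in ks.shell.values() if v == ks.max_shell)
    return n_core / len(ks.shell)


def pagerank(g: nx.Graph, damping: float = 0.85, tol: float = 1e-10) -> dict:
    """PageRank by power iteration; scores sum to 1.

    Isolated nodes are allowed (treated as dangling, redistributing their
    mass uniformly).
    """
    if g.number_of_nodes() == 0:
        return {}
    # networkx's convergence test is err < n * tol, so tighten accordingly
    return nx.pagerank(g, alpha=damping, tol=tol / max(g.number_of_nodes(), 1),
                       max_iter=1000)


def global_efficiency(g: nx.Graph) -> float:
    """Mean over ordered pairs of inverse shortest-path length."""
    return nx.global_efficiency(g)


def attack(
    g: nx.Graph,
    strategy: str,
    step: float = 0.05,
    *,
    adaptive: bool = True,
    seed: int | None = None,
    compute_re: bool = True,
) -> AttackCurve:
    """Remove nodes per strategy, recording RS and RE at each checkpoint.

    Checkpoints are the removal fractions 0, step, 2*step, ..., 1.  The
    random strategy uses ``seed``; targeted strategies re-rank after each
    removal when ``adaptive`` (the default) and once up front otherwise.
    """
    if strategy not in ATTACK_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {ATTACK_STRATEGIES}")
    n0 = g.number_of_nodes()
    if n0 == 0:
        raise ValueError("cannot attack an empty graph")
    n_steps = int(round(1.0 / step))
    if n_steps < 2:
        raise ValueError("step must partition the removal into >= 2 checkpoints")
    fractions = np.linspace(0.0, 1.0, n_steps + 1)
    checkpoints = [int(round(f * n0)) for f in fractions]

    work = g.copy()
    rng = np.random.default_rng(seed)
    static_order: list | None = None
    if not adaptive and strategy != "random":
        if strategy == "max_degree":
            ranked = sorted(work.degree(), key=lambda kv: (-kv[1], str(kv[0])))
        else:
            pr = pagerank(work)
            ranked = sorted(pr.items(), key=lambda kv: (-kv[1], str(kv[0])))
        static_order = [n for n, _ in ranked]
    if strategy == "random":
        static_order = list(work.nodes())
        rng.shuffle(static_order)

    e0 = global_efficiency(work) if compute_re else 1.0
    rs_vals, re_vals = [], []
    removed = 0
    for target in checkpoints:
        while removed < target:
            if strategy == "random" or static_order is not None and not adaptive:
                victim = static_order[removed]
            elif strategy == "max_degree":
                victim = max(work.degree(), key=lambda kv: (kv[1], str(kv[0])))[0]
            else:  # max_pagerank, adaptive
                pr = pagerank(work)
                victim = max(pr.items(), key=lambda kv: (kv[1], str(kv[0])))[0]
            work.remove_node(victim)
            removed += 1
        if work.number_of_nodes() == 0:
            rs = 0.0
            eff = 0.0
        else:
            rs = max(len(c) for c in nx.connected_components(work)) / n0
            eff = global_efficiency(work) if compute_re else 0.0
        rs_vals.append(rs)
        re_vals.append(eff / e0 if e0 > 0 else (1.0 if removed == 0 else 0.0))
    return AttackCurve(strategy, fractions, np.array(rs_vals), np.array(re_vals), n0)


def attack_auc(curve: AttackCurve) -> float:
    """Area under the RS-vs-fraction curve (trapezoidal); lower = more fragile."""
    return float(np.trapezoid(curve.rs, curve.fractions))


def export_graphml(g: nx.Graph, path, *, with_analysis: bool = True) -> None:
    """Write GraphML with node attributes (category, phylum, shell, pagerank)."""
    out = g.copy()
    if with_analysis and out.number_of_nodes() > 0:
        ks = kshell(out)
        pr = pagerank(out)
        nx.set_node_attributes(out, ks.shell, "shell")
        nx.set_node_attributes(out, pr, "pagerank")
    nx.write_graphml(out, path)
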