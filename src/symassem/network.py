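"""Statistical-parsimony haplotype networks with a 95% connection limit.

The connection limit is the largest number of mutational steps ``j`` for which
the probability of parsimony — the probability that ``j`` observed differences
between two aligned sequences arose from exactly ``j`` substitutions, with no
superimposed changes anywhere in the alignment — still meets the confidence
level. Following the statistical-parsimony framework of Templeton, Crandall &
Sing (1992), that probability is computed under a finite-sites model, here a
Jukes–Cantor model with per-site substitution counts Poisson(theta), with the
unknown pairwise divergence theta integrated out under a uniform prior:

    P(parsimony | j, m) =
        int theta^j exp(-m*theta) dtheta
        / int D(theta)^j (1 - D(theta))^(m-j) dtheta,

where m is the aligned length and D(theta) = 3/4 (1 - exp(-4*theta/3)) is the
probability a site shows a difference. The prior upper bound (2 substitutions
per site, far beyond saturation for this marker) and quadrature grid are fixed
and documented in the methods note.

Network construction is a deterministic simplified TCS procedure: candidate
pairs sorted by (steps, label order); an edge is added iff its step count is
within the limit and it joins two previously separate components — so each
subnetwork carries a minimum-spanning forest of the admissible connections and
the component structure matches full TCS. Unsampled intermediate haplotypes
are not materialised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .distance import DistanceMatrix

__all__ = ["ParsimonyNetwork", "parsimony_probability", "parsimony_limit", "build_network", "export_network"]

_PRIOR_MAX_DIVERGENCE = 2.0  # substitutions per site; beyond saturation
_GRID_POINTS = 4001


def parsimony_probability(steps: int, aligned_length: int) -> float:
    """Probability that ``steps`` observed differences are all single substitutions.

    Evaluated by fixed-grid quadrature in log space; monotonically decreasing
    in ``steps`` at fixed length and increasing in length at fixed steps.
    """
    m = int(aligned_length)
    j = int(steps)
    if m < 1:
        raise ValueError("aligned_length must be >= 1")
    if j < 0 or j > m:
        raise ValueError(f"steps must be in [0, {m}], got {j}")
    if j == 0:
        return 1.0
    theta = np.linspace(1e-9, _PRIOR_MAX_DIVERGENCE, _GRID_POINTS)
    log_theta = np.log(theta)
    d = 0.75 * (1.0 - np.exp(-4.0 * theta / 3.0))
    log_num = j * log_theta - m * theta
    log_den = j * np.log(d) + (m - j) * np.log1p(-d)
    return float(np.exp(logsumexp(log_num) - logsumexp(log_den)))


def parsimony_limit(aligned_length: int, confidence: float = 0.95) -> int:
    """Largest step count whose probability of parsimony is >= ``confidence``."""
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    m = int(aligned_length)
    if m < 1:
        raise ValueError("aligned_length must be >= 1")
    limit = 0
    for j in range(1, m + 1):
        if parsimony_probability(j, m) >= confidence:
            limit = j
        else:
            break
    return limit


@dataclass
class ParsimonyNetwork:
    """Variant network under a step limit: nodes carry recovery counts, edges steps."""

    graph: nx.Graph
    connection_limit: int

    @property
    def subnetworks(self) -> list[set[str]]:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: sorted(c)[0])

    @property
    def n_subnetworks(self) -> int:
        return len(self.subnetworks)

    def edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), int(d["steps"])) for u, v, d in self.graph.edges(data=True)
        )


def build_network(
    variant_matrix: DistanceMatrix,
    counts: Mapping[str, Mapping[str, int]] | None,
    limit: int,
) -> ParsimonyNetwork:
    """Join variants in order of increasing step distance, never above the limit.

    ``counts`` maps label -> {"adult": n, "egg": n} recovery tallies (missing
    stages default to 0); pass None for a bare topology. Ties broken by
    lexicographic label order, so the result is deterministic.
    """
    labels = list(variant_matrix.labels)
    if not labels:
        raise ValueError("empty variant set")
    g = nx.Graph()
    for lab in labels:
        stage = dict(counts.get(lab, {})) if counts else {}
        adult = int(stage.get("adult", 0))
        egg = int(stage.get("egg", 0))
        g.add_node(lab, adult=adult, egg=egg, total=adult + egg, clade=lab[:1].upper())

    pairs = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            steps = int(round(variant_matrix[a, b]))
            if steps <= limit:
                pairs.append((steps, min(a, b), max(a, b)))
    pairs.sort()

    parent = {lab: lab for lab in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for steps, a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            g.add_edge(a, b, steps=steps)
            parent[rb] = ra
    return ParsimonyNetwork(graph=g, connection_limit=int(limit))


def export_network(network: ParsimonyNetwork, edge_tsv, graphml_path=None) -> None:
    """Write the network as an edge-list TSV and (optionally) GraphML."""
    rows = [{"from": u, "to": v, "steps": s} for u, v, s in network.edges()]
    pd.DataFrame(rows, columns=["from", "to", "steps"]).to_csv(edge_tsv, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(network.graph, str(graphml_path))
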