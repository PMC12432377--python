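"""Specificity grouping of CDR3 sequences, GLIPH2-style.

Two edge types link CDR3s predicted to share antigen specificity:

* **local** — both interiors contain a k-mer motif (k in {2,3,4} by default)
  that is enriched in the analysed sample set relative to a reference
  repertoire (fold >= 10, one-sided Fisher exact p <= 1e-3, seen in >= 3
  distinct CDR3s);
* **global** — the two CDR3s have equal length and Hamming distance <= 1
  over their interiors.

Interiors remove the conserved framing: 3 leading residues (the C-anchor and
neighbours) and 2 trailing residues (the F-anchor region).  Clusters are the
connected components of the resulting graph; singleton CDR3s form singleton
clusters.  The clusters feed the cluster-extended definition of
tumor-reactive TILs: tumor CDR3s similar, but not identical, to a
blood-derived tumor-reactive CDR3.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Optional

import networkx as nx
from scipy.stats import fisher_exact

from .errors import ParameterError


@dataclass(frozen=True)
class Cdr3Interior:
    full: str
    interior: str

    @property
    def usable(self) -> bool:
        """Interiors of length 0 are excluded from motif search."""
        return len(self.interior) > 0


@dataclass(frozen=True)
class GliphParams:
    n_head: int = 3
    n_tail: int = 2
    k_set: frozenset = frozenset({2, 3, 4})
    min_fold: float = 10.0
    max_p: float = 1e-3
    min_occurrences: int = 3


@dataclass(frozen=True)
class EnrichedMotif:
    motif: str
    sample_count: int
    reference_count: int
    fold: float
    p_value: float


@dataclass
class MotifClusterSet:
    """Clustering result: node labels, typed edges, connected components."""

    graph: nx.Graph
    clusters: list[frozenset]
    cluster_of: dict[str, int]
    origins: dict[str, frozenset]
    motifs: list[EnrichedMotif]
    params: GliphParams

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_types(self, a: str, b: str) -> frozenset:
        return self.graph.edges[a, b]["types"]

    def cluster_members(self, cdr3: str) -> frozenset:
        return self.clusters[self.cluster_of[cdr3]]

    def cluster_flags(
        self, reactive_label: str = "reactive", til_label: str = "til"
    ) -> list[dict]:
        """Per-cluster summary: size, contains_reactive/til, multi-patient."""
        out = []
        for i, members in enumerate(self.clusters):
            labels = set().union(*(self.origins.get(m, frozenset()) for m in members))
            compartments = {lab.split(":", 1)[0] for lab in labels}
            patients = {lab.split(":", 1)[1] for lab in labels if ":" in lab}
            out.append(
                {
                    "cluster_id": i,
                    "size": len(members),
                    "contains_reactive": reactive_label in compartments,
                    "contains_til": til_label in compartments,
                    "multi_patient": len(patients) > 1,
                }
            )
        return out


def interior(cdr3: str, n_head: int = 3, n_tail: int = 2) -> Cdr3Interior:
    """Trim the conserved head/tail framing off a CDR3.

    Too-short CDR3s yield an empty interior and are flagged unusable rather
    than raising; they simply take no part in motif search or global pairing.
    """
    if n_head < 0 or n_tail < 0:
        raise ParameterError("n_head and n_tail must be >= 0")
    if len(cdr3) < n_head + n_tail:
        return Cdr3Interior(full=cdr3, interior="")
    end = len(cdr3) - n_tail
    return Cdr3Interior(full=cdr3, interior=cdr3[n_head:end])


def _kmer_presence(interiors: Iterable[str], k_set: Iterable[int]) -> Counter:
    """Number of distinct interiors containing each k-mer (counted once per
    interior regardless of multiplicity)."""
    counts: Counter = Counter()
    for seq in interiors:
        kmers = set()
        for k in k_set:
            kmers.update(seq[i : i + k] for i in range(len(seq) - k + 1))
        counts.update(kmers)
    return counts


def enriched_motifs(
    sample_cdr3s: Iterable[str],
    reference_cdr3s: Iterable[str],
    params: GliphParams = GliphParams(),
) -> list[EnrichedMotif]:
    """Motifs over-represented in the sample interiors vs the reference.

    A motif is retained iff it occurs in >= ``min_occurrences`` distinct
    sample CDR3s, its fold enrichment over the reference is >=
    ``min_fold`` (pseudocount 1 in the reference numerator when the
    reference count is 0), and the one-sided Fisher exact p-value of the
    2x2 containment table is <= ``max_p``.  Output sorted by (p, motif).
    """
    sample = sorted(
        {interior(c, params.n_head, params.n_tail).interior for c in set(sample_cdr3s)}
        - {""}
    )
    reference = sorted(
        {interior(c, params.n_head, params.n_tail).interior
         for c in set(reference_cdr3s)} - {""}
    )
    if not sample:
        return []
    if not reference:
        raise ParameterError("reference repertoire must be non-empty")
    n_s, n_r = len(sample), len(reference)
    sample_counts = _kmer_presence(sample, params.k_set)
    ref_counts = _kmer_presence(reference, params.k_set)

    out = []
    for motif, a in sample_counts.items():
        if a < params.min_occurrences:
            continue
        b = ref_counts.get(motif, 0)
        fold = (a / n_s) / (max(b, 1) / n_r)
        if fold < params.min_fold:
            continue
        _, p = fisher_exact([[a, n_s - a], [b, n_r - b]], alternative="greater")
        if p <= params.max_p:
            out.append(EnrichedMotif(motif, a, b, fold, float(p)))
    out.sort(key=lambda m: (m.p_value, m.motif))
    return out


def global_pairs(
    cdr3s: Iterable[str], n_head: int = 3, n_tail: int = 2
) -> set[frozenset]:
    """Unordered pairs of distinct same-length CDR3s whose interiors differ
    by at most one residue (Hamming distance <= 1)."""
    by_len: dict[int, list[str]] = defaultdict(list)
    for c in sorted(set(cdr3s)):
        by_len[len(c)].append(c)
    pairs: set[frozenset] = set()
    for length, group in by_len.items():
        # empty interiors carry no sequence information and are never paired
        ints = {c: interior(c, n_head, n_tail).interior for c in group}
        usable = [c for c in group if ints[c]]
        for a, b in itertools.combinations(usable, 2):
            ia, ib = ints[a], ints[b]
            mismatches = sum(x != y for x, y in zip(ia, ib))
            if mismatches <= 1:
                pairs.add(frozenset((a, b)))
    return pairs


def build_clusters(
    samples: Mapping[str, Iterable[str]],
    reference: Iterable[str] = (),
    params: GliphParams = GliphParams(),
) -> MotifClusterSet:
    """Cluster CDR3s from labeled samples into specificity groups.

    ``samples`` maps an origin label (convention: ``"<compartment>:<patient>"``,
    e.g. ``"reactive:Br1"`` or ``"til:Br1"``) to its CDR3 set.  Local edges
    need a non-empty ``reference``; with an empty reference only global edges
    are built.  Output is invariant to input ordering and to relabeling.
    """
    origins: dict[str, set] = defaultdict(set)
    for label in sorted(samples):
        for c in samples[label]:
            origins[c].add(label)
    nodes = sorted(origins)

    graph = nx.Graph()
    graph.add_nodes_from(nodes)

    for pair in global_pairs(nodes, params.n_head, params.n_tail):
        a, b = sorted(pair)
        graph.add_edge(a, b, types=frozenset({"global"}))

    reference = list(reference)
    motifs: list[EnrichedMotif] = []
    if reference:
        motifs = enriched_motifs(nodes, reference, params)
        for m in motifs:
            carriers = [
                c for c in nodes
                if m.motif in interior(c, params.n_head, params.n_tail).interior
            ]
            for a, b in itertools.combinations(carriers, 2):
                types = set(graph.edges[a, b]["types"]) if graph.has_edge(a, b) else set()
                types.add(f"local:{m.motif}")
                graph.add_edge(a, b, types=frozenset(types))

    components = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: min(c),
    )
    cluster_of = {c: i for i, members in enumerate(components) for c in members}
    return MotifClusterSet(
        graph=graph,
        clusters=components,
        cluster_of=cluster_of,
        origins={c: frozenset(v) for c, v in origins.items()},
        motifs=motifs,
        params=params,
    )


def expand_reactive_set(
    reactive_cdr3s: Iterable[str],
    til_cdr3s: Iterable[str],
    cluster_set: MotifClusterSet,
) -> set[str]:
    """TIL CDR3s sharing a specificity cluster with a reactive CDR3.

    Exact reactive/TIL matches are *excluded* (they are counted separately
    as exact matches); the union of this set with the exact matches is by
    construction a superset of the exact matches.
    """
    reactive = set(reactive_cdr3s)
    til = set(til_cdr3s)
    missing = (reactive | til) - cluster_set.nodes
    if missing:
        raise ParameterError(
            f"cluster set does not cover {len(missing)} input CDR3s "
            f"(e.g. {sorted(missing)[:3]})"
        )
    reactive_clusters = {cluster_set.cluster_of[c] for c in reactive}
    return {
        c for c in til - reactive
        if cluster_set.cluster_of[c] in reactive_clusters
    }
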