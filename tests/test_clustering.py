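"""Specificity clustering: interiors, motif enrichment, global pairs,
connected components, and reactive-set expansion."""

import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

from tcrtrack.clustering import (
    GliphParams,
    build_clusters,
    enriched_motifs,
    expand_reactive_set,
    global_pairs,
    interior,
)
from tcrtrack.errors import ParameterError


class TestInterior:
    def test_default_trim_of_known_sequence(self):
        assert interior("CASSKGASGNEQFF").interior == "SKGASGNEQ"

    def test_five_residue_cdr3_excluded(self):
        it = interior("CASSF")
        assert it.interior == "" and not it.usable

    def test_zero_trim_is_identity(self):
        assert interior("CASSF", 0, 0).interior == "CASSF"


class TestGlobalPairs:
    def test_one_interior_mismatch_pairs(self):
        pairs = global_pairs(["CASSLGQETQYF", "CASSLGRETQYF"])
        assert frozenset(("CASSLGQETQYF", "CASSLGRETQYF")) in pairs

    def test_identical_sequences_never_pair(self):
        assert global_pairs(["CASSLGQETQYF", "CASSLGQETQYF"]) == set()

    def test_dissimilar_same_length_sequences_do_not_pair(self):
        # the two expanded clonotypes sharing TRBV27 usage but different CDR3s
        assert global_pairs(["CASSPLGPQETQYF", "CASSKGASGNEQFF"]) == set()

    def test_length_mismatch_never_pairs(self):
        assert global_pairs(["CASSLGQETQYF", "CASSLGQETQYFF"]) == set()


def brute_force_fisher_greater(a, n_s, b, n_r):
    """One-sided Fisher p via the hypergeometric survival function."""
    return float(hypergeom.sf(a - 1, n_s + n_r, a + b, n_s))


class TestEnrichedMotifs:
    def test_sample_equal_to_reference_yields_nothing(self):
        seqs = [f"CASS{x}GGGQETQYF" for x in "ACDEFGHIK"]
        assert enriched_motifs(seqs, seqs) == []

    def test_strongly_enriched_motif_retained_with_oracle_p(self):
        rng = np.random.default_rng(11)
        aa = list("ACDEGHIKLMNPQRSTVWY")  # no F to keep the motif unique
        sample = ["CAS" + "WWW" + "".join(rng.choice(aa, 6)) + "FF"
                  for _ in range(5)]
        sample += ["CAS" + "".join(rng.choice(aa, 9)) + "FF" for _ in range(5)]
        reference = ["CAS" + "".join(rng.choice(aa, 9)) + "FF"
                     for _ in range(1000)]
        reference = [r for r in reference if "WWW" not in r]
        motifs = enriched_motifs(sample, reference, GliphParams(k_set=frozenset({3})))
        found = {m.motif: m for m in motifs}
        assert "WWW" in found
        m = found["WWW"]
        oracle_p = brute_force_fisher_greater(
            m.sample_count, 10, m.reference_count, len(set(reference))
        )
        assert m.p_value == pytest.approx(oracle_p, rel=1e-9)
        # fold with pseudocount-1 reference numerator
        assert m.fold == pytest.approx(
            (m.sample_count / 10) / (1 / len(set(reference)))
        )

    def test_below_min_occurrences_rejected(self):
        sample = ["CASWWWAAAAF", "CASWWWCCCCF", "CASDDDDDDDF"]
        reference = [f"CAS{x}AAAAAAF" for x in "ACDEGHIKLMNPQRSTVWY"]
        motifs = enriched_motifs(
            sample, reference,
            GliphParams(k_set=frozenset({3}), min_occurrences=3),
        )
        assert "WWW" not in {m.motif for m in motifs}

    def test_empty_sample_returns_empty(self):
        assert enriched_motifs([], ["CASSAAAAAAF"]) == []


class TestBuildClusters:
    def test_no_edges_gives_singletons(self):
        cdr3s = {"CASSAAAAAAAAF", "CASSCCCCCCCF", "CADDDDDDDF"}
        cs = build_clusters({"s:1": cdr3s})
        assert len(cs.clusters) == 3
        assert all(len(c) == 1 for c in cs.clusters)

    def test_components_are_transitive(self):
        a, b, c = "CASSLGQETQYF", "CASSLGRETQYF", "CASSLGRETQAF"
        cs = build_clusters({"s:1": {a, b, c}})
        assert cs.cluster_members(a) == frozenset({a, b, c})

    def test_invariant_to_input_order_and_labels(self):
        seqs = ["CASSLGQETQYF", "CASSLGRETQYF", "CASSKGASGNEQFF",
                "CASSKGASGNEQFA"]
        cs1 = build_clusters({"x:1": seqs})
        cs2 = build_clusters({"zzz:9": list(reversed(seqs))})
        assert cs1.clusters == cs2.clusters

    def test_cluster_flags_report_origins(self):
        cs = build_clusters({
            "reactive:p1": {"CASSLGQETQYF"},
            "til:p1": {"CASSLGRETQYF"},
            "til:p2": {"CASSDDDDDDDF"},
        })
        flags = {f["cluster_id"]: f for f in cs.cluster_flags()}
        joint = cs.cluster_of["CASSLGQETQYF"]
        assert flags[joint]["contains_reactive"] and flags[joint]["contains_til"]
        lone = cs.cluster_of["CASSDDDDDDDF"]
        assert not flags[lone]["contains_reactive"]

    def test_randomized_components_match_transitive_closure_oracle(self):
        """Components from the graph library equal a brute-force closure."""
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        base = ["C" + "".join(rng.choice(aa, 10)) + "F" for _ in range(12)]
        nodes = set(base)
        while len(nodes) < 50:
            src = base[int(rng.integers(len(base)))]
            pos = int(rng.integers(1, len(src) - 1))
            nodes.add(src[:pos] + str(rng.choice(aa)) + src[pos + 1:])
        nodes = sorted(nodes)[:50]
        cs = build_clusters({"s:1": nodes})
        oracle = brute_force_components(nodes)
        assert set(cs.clusters) == oracle


def brute_force_components(nodes, n_head=3, n_tail=2):
    """Independent oracle: O(n^2) edge test + iterated transitive closure."""
    def linked(a, b):
        if a == b or len(a) != len(b):
            return False
        ia, ib = a[n_head:len(a) - n_tail], b[n_head:len(b) - n_tail]
        return sum(x != y for x, y in zip(ia, ib)) <= 1 and len(ia) > 0

    comps = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(comps)), 2):
            if comps[i] and comps[j] and any(
                linked(a, b) for a in comps[i] for b in comps[j]
            ):
                comps[i] |= comps[j]
                comps[j] = set()
                changed = True
    return {frozenset(c) for c in comps if c}


class TestExpandReactiveSet:
    def test_disjoint_clusters_expand_to_nothing(self):
        reactive = {"CASSAAAAAAAAF"}
        til = {"CASSGGGGGGGF"}
        cs = build_clusters({"r:1": reactive, "t:1": til})
        assert expand_reactive_set(reactive, til, cs) == set()

    def test_near_miss_included_exact_excluded(self):
        reactive = {"CASSLGQETQYF"}
        til = {"CASSLGQETQYF", "CASSLGRETQYF"}
        cs = build_clusters({"r:1": reactive, "t:1": til})
        expanded = expand_reactive_set(reactive, til, cs)
        assert expanded == {"CASSLGRETQYF"}

    def test_uncovered_inputs_rejected(self):
        cs = build_clusters({"r:1": {"CASSLGQETQYF"}})
        with pytest.raises(ParameterError):
            expand_reactive_set({"CASSLGQETQYF"}, {"CASSNOTTHEREF"}, cs)


def test_more_permissive_params_never_increase_cluster_count():
    """Lower fold / higher p admit more local edges, merging components."""
    rng = np.random.default_rng(3)
    aa = list("ACDEGHIKLMNPQRSTVWY")
    sample = ["CAS" + "QQQ" + "".join(rng.choice(aa, 7)) + "FF" for _ in range(6)]
    sample += ["CAS" + "".join(rng.choice(aa, 10)) + "FF" for _ in range(20)]
    reference = ["CAS" + "".join(rng.choice(aa, 10)) + "FF" for _ in range(500)]
    strict = build_clusters({"s:1": sample}, reference,
                            GliphParams(min_fold=1e6, max_p=1e-12))
    loose = build_clusters({"s:1": sample}, reference,
                           GliphParams(min_fold=2, max_p=0.05))
    assert len(loose.clusters) <= len(strict.clusters)
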