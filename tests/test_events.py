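"""Intron clustering, AS-event typing, protein effects and domain statistics."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import madsplice as M
from madsplice.events import (
    DomainASCounts,
    assign_domain,
    cluster_introns,
    cluster_is_as,
    detect_events,
    domain_as_counts,
    fisher_domain_enrichment,
)
from madsplice.models import GenomicInterval, Intron, ResidueInterval
from madsplice.simulate import EventSpec, SimConfig, implant_event, simulate_locus

from conftest import make_transcript


def _intron(start, end, tid="t1", index=0):
    return Intron(GenomicInterval("chrT", start, end, "+"), index, tid)


def _brute_force_clusters(intervals):
    """Transitive closure of pairwise >=1-nt overlap (independent oracle)."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClusterIntrons:
    def test_overlap_groups_and_singletons(self):
        introns = [_intron(100, 200), _intron(100, 250, "t2"), _intron(300, 400)]
        clusters = cluster_introns(introns)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_empty_and_singleton(self):
        assert cluster_introns([]) == []
        (c,) = cluster_introns([_intron(5, 10)])
        assert len(c.members) == 1

    def test_mixed_strand_raises(self):
        a = _intron(0, 10)
        b = Intron(GenomicInterval("chrT", 0, 10, "-"), 0, "t2")
        with pytest.raises(ValueError):
            cluster_introns([a, b])

    @settings(derandomize=True, max_examples=300)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=200),
                st.integers(min_value=1, max_value=60),
            ),
            min_size=0,
            max_size=20,
        )
    )
    def test_matches_transitive_closure_oracle(self, raw):
        """Single-linkage clustering equals brute-force transitive closure."""
        intervals = [(s, s + L) for s, L in raw]
        introns = [
            _intron(s, e, tid=f"t{i}", index=i) for i, (s, e) in enumerate(intervals)
        ]
        clusters = cluster_introns(introns)
        got = {
            frozenset(int(m.transcript_id[1:]) for m in c.members)
            for c in clusters
        }
        assert got == _brute_force_clusters(intervals)


class TestClusterIsAs:
    def _locus(self):
        # t1 splices (100,200); t2 splices (100,250); t3 retains everything
        t1 = make_transcript("t1", [(0, 100), (200, 300)])
        t2 = make_transcript("t2", [(0, 100), (250, 300)])
        t3 = make_transcript("t3", [(0, 300)])
        return [t1, t2, t3]

    def test_multi_intron_cluster_is_as(self):
        transcripts = self._locus()
        introns = [_intron(100, 200, "t1"), _intron(100, 250, "t2")]
        (cluster,) = cluster_introns(introns)
        assert cluster_is_as(cluster, transcripts)

    def test_retained_singleton_is_as(self):
        transcripts = self._locus()
        (cluster,) = cluster_introns([_intron(100, 200, "t1")])
        assert cluster_is_as(cluster, transcripts)  # fully inside t3's exon

    def test_unretained_singleton_is_not_as(self):
        t1 = make_transcript("t1", [(0, 100), (200, 300)])
        t2 = make_transcript("t2", [(0, 100), (200, 300)])
        (cluster,) = cluster_introns([_intron(100, 200, "t1"), _intron(100, 200, "t2")])
        assert not cluster_is_as(cluster, [t1, t2])


class TestDetectEvents:
    def test_identical_chains_yield_nothing(self):
        t1 = make_transcript("t1", [(0, 100), (200, 300)], [(0, 100), (200, 300)])
        t2 = make_transcript("t2", [(0, 100), (200, 300)], [(0, 100), (200, 300)])
        assert detect_events(t1, t2) == []

    def test_different_loci_raise(self):
        t1 = make_transcript("t1", [(0, 100)], locus="a")
        t2 = make_transcript("t2", [(0, 100)], locus="b")
        with pytest.raises(ValueError):
            detect_events(t1, t2)

    def test_alt_donor_plus_strand(self):
        t1 = make_transcript("t1", [(0, 100), (200, 300)])
        t2 = make_transcript("t2", [(0, 112), (200, 300)])
        (ev,) = detect_events(t1, t2)
        assert ev.event_type == "alt_donor"

    def test_alt_donor_on_minus_strand_is_strand_aware(self):
        # the same genomic change on the minus strand is an acceptor shift
        t1 = make_transcript("t1", [(0, 100), (200, 300)], strand="-")
        t2 = make_transcript("t2", [(0, 112), (200, 300)], strand="-")
        (ev,) = detect_events(t1, t2)
        assert ev.event_type == "alt_acceptor"

    @pytest.mark.parametrize(
        "event_type,kwargs",
        [
            ("alt_donor", dict(size_nt=12, target_domain="I")),
            ("alt_acceptor", dict(size_nt=15, target_domain="K_cterm")),
            ("exon_skip", dict(size_nt=42, target_domain="K")),
            ("intron_retention", dict(target_domain="K")),
            ("mutually_exclusive", dict(size_nt=45, size2_nt=90, target_domain="K")),
            ("cryptic_exon", dict(size_nt=30, target_domain="C")),
        ],
    )
    def test_implanted_type_round_trip(self, event_type, kwargs):
        """Each implanted event type is recovered exactly, on both strands."""
        for seed in range(6):
            spec = EventSpec(event_type, **kwargs)
            sim = simulate_locus(SimConfig(seed=seed, events=[spec]), seed)
            _, truth = implant_event(sim, spec, seed + 77)
            events = detect_events(sim.reference, sim.transcript(truth.isoform_b))
            assert [e.event_type for e in events] == [event_type]


class TestEventEffect:
    def _clean_effect(self, event_type, seed=0, **kwargs):
        spec = EventSpec(event_type, **kwargs)
        sim = simulate_locus(SimConfig(seed=seed, events=[spec]), seed)
        _, truth = implant_event(sim, spec, seed + 1)
        (ev,) = detect_events(sim.reference, sim.transcript(truth.isoform_b))
        genome = sim.genome
        pa = M.translate_isoform(sim.reference, genome)
        pb = M.translate_isoform(sim.transcript(truth.isoform_b), genome)
        return M.event_effect(ev, pa, pb), truth

    def test_in_frame_skip_counts_exon_residues(self):
        effect, truth = self._clean_effect("exon_skip", size_nt=42, target_domain="K")
        assert effect.aa_difference == 14
        assert not effect.frame_shift
        assert effect.truncation_aa == 0

    def test_identical_proteins_have_zero_difference(self):
        spec = EventSpec("exon_skip", size_nt=42, target_domain="K")
        sim = simulate_locus(SimConfig(seed=3, events=[spec]), 3)
        _, truth = implant_event(sim, spec, 4)
        (ev,) = detect_events(sim.reference, sim.transcript(truth.isoform_b))
        genome = sim.genome
        pa = M.translate_isoform(sim.reference, genome)
        effect = M.event_effect(ev, pa, pa)
        assert effect.aa_difference == 0

    def test_frame_breaking_event_flags_frame_shift(self):
        spec = EventSpec(
            "alt_acceptor", size_nt=10, frame_preserving=False, target_domain="K"
        )
        sim = simulate_locus(SimConfig(seed=5, events=[spec]), 5)
        _, truth = implant_event(sim, spec, 6)
        (ev,) = detect_events(sim.reference, sim.transcript(truth.isoform_b))
        genome = sim.genome
        pa = M.translate_isoform(sim.reference, genome)
        pb = M.translate_isoform(sim.transcript(truth.isoform_b), genome)
        effect = M.event_effect(ev, pa, pb)
        assert effect.frame_shift

    @pytest.mark.parametrize(
        "event_type,kwargs,expected",
        [
            ("alt_donor", dict(size_nt=12, target_domain="I"), 4),
            ("alt_acceptor", dict(size_nt=15, target_domain="K_cterm"), 5),
            ("cryptic_exon", dict(size_nt=30, target_domain="C"), 10),
        ],
    )
    def test_clean_indel_difference_is_size_over_three(
        self, event_type, kwargs, expected
    ):
        for seed in range(5):
            effect, truth = self._clean_effect(event_type, seed=seed, **kwargs)
            assert effect.aa_difference == expected


class TestAssignDomain:
    def test_interior_interval(self, standard_domains):
        assert assign_domain(ResidueInterval(70, 75), standard_domains) == "I"

    def test_boundary_interval_is_border(self, standard_domains):
        assert assign_domain(ResidueInterval(88, 92), standard_domains) == "border-I/K"
        assert assign_domain(ResidueInterval(90, 90), standard_domains) == "border-I/K"

    def test_past_c_terminus_is_outside(self, standard_domains):
        assert assign_domain(ResidueInterval(241, 250), standard_domains) == "outside"
        assert assign_domain(None, standard_domains) == "outside"


class TestDomainCounts:
    def _clusters(self, labels):
        out = []
        for label in labels:
            (c,) = cluster_introns([_intron(0, 10)])
            c.domain_label = label
            out.append(c)
        return out

    def test_counts_and_fractions(self):
        clusters = self._clusters(["I", "I", "K"])
        counts = domain_as_counts(clusters, [True, False, True])
        assert counts.counts == {"I": (2, 1), "K": (1, 1)}
        assert counts.fraction("I") == 0.5

    def test_total_invariant_under_label_permutation(self):
        rng = np.random.default_rng(0)
        labels = list(rng.choice(["I", "K", "C"], size=30))
        flags = list(rng.random(30) < 0.3)
        c1 = domain_as_counts(self._clusters(labels), flags)
        perm = rng.permutation(30)
        c2 = domain_as_counts(
            self._clusters([labels[i] for i in perm]), [flags[i] for i in perm]
        )
        total = lambda c: sum(t for t, _ in c.counts.values())
        assert total(c1) == total(c2) == 30


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher by exact hypergeometric enumeration (Fractions)."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    denom = comb(N, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(min(total, Fraction(1)))


class TestFisher:
    def test_printed_cluster_counts_give_p_003(self):
        """I-domain 11/46 vs K 16/147 + C 2/22 combined: p rounds to 0.03."""
        counts = DomainASCounts({"I": (46, 11), "K": (147, 16), "C": (22, 2)})
        p = fisher_domain_enrichment(counts)["I"]
        assert round(p, 2) == 0.03

    def test_zero_margin_gives_p_one(self):
        counts = DomainASCounts({"I": (5, 0), "K": (7, 0)})
        assert fisher_domain_enrichment(counts) == {"I": 1.0, "K": 1.0}

    def test_two_by_two_enumeration_example(self):
        # [[2,0],[0,2]]: only the diagonal tables are as extreme -> p = 1/3
        assert _fisher_oracle(2, 0, 0, 2) == pytest.approx(1 / 3)
        counts = DomainASCounts({"I": (2, 2), "K": (2, 0)})
        assert fisher_domain_enrichment(counts)["I"] == pytest.approx(1 / 3)

    def test_matches_enumeration_oracle_exhaustively_small(self):
        """All tables with N <= 14 agree with the enumeration to 1e-12."""
        for n1 in range(0, 8):
            for n2 in range(0, 8):
                if n1 + n2 == 0 or n1 + n2 > 14:
                    continue
                for a in range(n1 + 1):
                    for c in range(n2 + 1):
                        if a + c == 0 or (n1 - a) + (n2 - c) == 0:
                            continue
                        counts = DomainASCounts(
                            {"X": (n1, a), "rest": (n2, c)}
                        )
                        p = fisher_domain_enrichment(counts)["X"]
                        assert p == pytest.approx(
                            _fisher_oracle(a, n1 - a, c, n2 - c), abs=1e-12
                        )

    def test_matches_enumeration_oracle_random_up_to_60(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            N = int(rng.integers(4, 61))
            n1 = int(rng.integers(1, N))
            n2 = N - n1
            if n2 == 0:
                continue
            a = int(rng.integers(0, n1 + 1))
            c = int(rng.integers(0, n2 + 1))
            if a + c == 0 or (n1 - a) + (n2 - c) == 0:
                continue
            counts = DomainASCounts({"X": (n1, a), "rest": (n2, c)})
            p = fisher_domain_enrichment(counts)["X"]
            assert p == pytest.approx(
                _fisher_oracle(a, n1 - a, c, n2 - c), abs=1e-12
            )
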