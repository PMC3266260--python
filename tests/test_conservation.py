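"""Six-frame translation, homolog filtering, AIP detection and exonization."""

import numpy as np
import pytest
from Bio.Seq import Seq

import madsplice as M
from madsplice.conservation import (
    best_homolog,
    call_conservation,
    detect_aips,
    exonization_scan,
    isoform_pair_aips,
    map_intron_positions,
    six_frame_orfs,
    TranslatedFragment,
)
from madsplice.models import GenomicInterval, Intron, PipelineConfig
from madsplice.sequence import get_introns
from madsplice.simulate import (
    EventSpec,
    SimConfig,
    SpeciesSpec,
    _random_protein,
    implant_cryptic_exon_remnant,
    implant_event,
    simulate_locus,
    simulate_orthologs,
)


def _fragment(peptide, **kw):
    defaults = dict(contig_id="c", species="s", frame=1, nt_start=0,
                    nt_end=3 * len(peptide))
    defaults.update(kw)
    return TranslatedFragment(peptide=peptide, **defaults)


def _intron_at(position, index=0, phase=0):
    return Intron(
        GenomicInterval("c", 10, 20, "+"), index, "ref",
        phase=phase, protein_position=position,
    )


class TestSixFrameOrfs:
    def test_forward_orf_found_with_coordinates(self):
        rng = np.random.default_rng(0)
        protein = _random_protein(rng, 40)
        contig = "TAA" + str(Seq(protein).back_transcribe()) if False else None
        from madsplice.simulate import _codons_for

        cds = "".join(_codons_for(rng, protein))
        contig = "TAA" + cds + "TGA"
        frags = [f for f in six_frame_orfs(contig, 30) if f.frame > 0]
        assert any(f.peptide == protein for f in frags)
        hit = next(f for f in frags if f.peptide == protein)
        assert (hit.nt_start, hit.nt_end) == (3, 3 + 3 * 40)

    def test_reverse_complement_found_in_minus_frame(self):
        rng = np.random.default_rng(1)
        from madsplice.simulate import _codons_for

        protein = _random_protein(rng, 35)
        cds = "".join(_codons_for(rng, protein))
        contig = str(Seq("TAA" + cds + "TAA").reverse_complement())
        frags = six_frame_orfs(contig, 30)
        assert any(f.peptide == protein and f.frame < 0 for f in frags)

    def test_poly_n_contig_yields_nothing(self):
        assert six_frame_orfs("N" * 300, 30) == []

    def test_exactly_one_fragment_for_one_orf(self):
        """A contig with a single 40-aa ORF above threshold in one frame."""
        rng = np.random.default_rng(2)
        from madsplice.simulate import _codons_for

        protein = _random_protein(rng, 40)
        cds = "".join(_codons_for(rng, protein))
        # stops immediately flanking in the same frame; other frames too
        # short: frame shifts of a 126-nt island rarely clear 30 aa, so pad
        # with stop-dense sequence
        contig = ("TAATAATAA" * 4) + cds + ("TAATAATAA" * 4)
        frags = six_frame_orfs(contig, 30)
        assert len([f for f in frags if f.peptide == protein]) == 1


class TestBestHomolog:
    def test_identical_fragment_hits_full_identity(self, config):
        rng = np.random.default_rng(3)
        ref = _random_protein(rng, 100)
        hit = best_homolog(_fragment(ref), {"p1": ref}, config)
        assert hit is not None
        assert hit.identity_pct == 100.0 and hit.coverage_pct == 100.0

    def test_half_coverage_rejected_despite_high_identity(self, config):
        rng = np.random.default_rng(4)
        ref = _random_protein(rng, 100)
        assert best_homolog(_fragment(ref[:50]), {"p1": ref}, config) is None

    def test_identity_threshold_sweep_flips_near_40(self, config):
        """Walking identity 100% -> 25% by single mutations flips acceptance
        at the 40% floor; the flip lands within the trimming slack of the
        local alignment (a few columns of mutated ends may be clipped)."""
        from madsplice.align import align_local

        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for seed in (5, 17):
            rng = np.random.default_rng(seed)
            ref = _random_protein(rng, 100)
            seq = list(ref)
            positions = rng.permutation(100)[:75]
            for k, pos in enumerate(positions):
                others = [a for a in alphabet if a != seq[pos]]
                seq[pos] = others[int(rng.integers(len(others)))]
                nominal = 100 - (k + 1)
                if nominal > 50 or nominal < 25:
                    continue
                hit = best_homolog(_fragment("".join(seq)), {"p1": ref}, config)
                if hit is not None:
                    assert hit.identity_pct >= 40 and hit.coverage_pct >= 60
                if nominal >= 45:
                    assert hit is not None
                # acceptance is consistent with the measured quantities
                view = align_local("".join(seq), ref, config)
                coverage = 100.0 * sum(
                    1 for c in range(view.n_columns) if view.b_idx[c] >= 0
                ) / len(ref)
                should = view.identity_pct() >= 40 and coverage >= 60
                assert (hit is not None) == should

    def test_ties_broken_by_identity_then_id(self, config):
        rng = np.random.default_rng(6)
        ref = _random_protein(rng, 80)
        hit = best_homolog(_fragment(ref), {"b": ref, "a": ref}, config)
        assert hit.protein_id == "a"


class TestMapIntronPositions:
    def test_identity_maps_to_same_positions(self, config):
        rng = np.random.default_rng(7)
        ref = _random_protein(rng, 120)
        introns = [_intron_at(40), _intron_at(80, index=1)]
        out = map_intron_positions(ref, ref, introns, config)
        assert [e.subject_residue for e in out.entries] == [40, 80]
        assert all(e.mapped and e.gapless_window for e in out.entries)

    def test_nterminal_extension_shifts_every_position(self, config):
        rng = np.random.default_rng(8)
        ref = _random_protein(rng, 120)
        subject = "MAA" + ref
        introns = [_intron_at(40), _intron_at(80, index=1)]
        out = map_intron_positions(subject, ref, introns, config)
        assert [e.subject_residue for e in out.entries] == [43, 83]

    def test_position_inside_subject_gap_is_unmapped(self, config):
        rng = np.random.default_rng(9)
        ref = _random_protein(rng, 120)
        subject = ref[:35] + ref[45:]  # deletion spanning position 40
        introns = [_intron_at(40)]
        out = map_intron_positions(subject, ref, introns, config)
        assert not out.entries[0].mapped

    def test_unrelated_alignment_leaves_all_unmapped(self, config):
        ref = _random_protein(np.random.default_rng(10), 120)
        subject = _random_protein(np.random.default_rng(11), 120)
        out = map_intron_positions(subject, ref, [_intron_at(40)], config)
        assert not any(e.mapped for e in out.entries)


class TestDetectAips:
    def test_hand_built_indel_at_intron(self, config):
        iso_a = ("a", "MKTLVQWEQEIDRSWHYA")
        iso_b = ("b", "MKTLVEIDRSWHYA")
        ref = iso_b[1]
        introns = [_intron_at(5)]
        aips = isoform_pair_aips(iso_a, iso_b, ref, introns, config)
        assert len(aips) == 1
        assert aips[0].indel_peptide == "QWEQ"
        assert aips[0].intron_index == 0
        assert aips[0].passes_flank_rule and aips[0].gapless_anchor

    def test_identical_isoforms_have_no_aips(self, config):
        seq = _random_protein(np.random.default_rng(12), 80)
        assert isoform_pair_aips(("a", seq), ("b", seq), seq, [_intron_at(30)], config) == []

    def test_indel_away_from_introns_is_not_called(self, config):
        rng = np.random.default_rng(13)
        long = _random_protein(rng, 120)
        short = long[:60] + long[66:]  # indel at 60, intron at 20
        aips = isoform_pair_aips(("a", long), ("b", short), long, [_intron_at(20)], config)
        assert aips == []

    def test_degraded_flanks_fail_the_flank_rule(self, config):
        """Fewer than four identical flanking pairs rejects the candidate."""
        anchor5 = "MAEKTWHRCDYNPGSVLFIQ"
        anchor3 = "HETNRKWYCVDSAGPLMFIQ"
        long = anchor5 + "DEDED" + "WFWFWW" + "EDEDE" + anchor3
        short = anchor5 + "KRKRK" + "RKRKR" + anchor3  # flanks fully corrupted
        imap = map_intron_positions(
            long, long, [_intron_at(len(anchor5) + 5)], config, subject_id="a"
        )
        assert detect_aips(("a", long), ("b", short), imap, config) == []
        (rejected,) = detect_aips(
            ("a", long), ("b", short), imap, config, keep_rejected=True
        )
        assert not rejected.passes_flank_rule
        assert rejected.flank_identical < 4

    def test_second_gap_in_flank_window_rejects(self, config):
        """More than one gapped flanking position violates the quality rule."""
        anchor5 = "MAEKTWHRCDYNPGSVLFIQ"
        anchor3 = "HETNRKWYCVDSAGPLMFIQ"
        long = anchor5 + "CDEFG" + "WFWYWW" + "HIKLM" + anchor3
        short = anchor5 + "CDEFG" + "HIK" + anchor3[2:]  # nearby 2nd deletion
        imap = map_intron_positions(
            long, long, [_intron_at(len(anchor5) + 5)], config, subject_id="a"
        )
        assert detect_aips(("a", long), ("b", short), imap, config) == []
        candidates = detect_aips(
            ("a", long), ("b", short), imap, config, keep_rejected=True
        )
        assert any(
            c.flank_gapped > config.flank_max_gapped for c in candidates
        )

    def test_empty_sequence_raises(self, config):
        with pytest.raises(ValueError):
            detect_aips(("a", ""), ("b", "MK"), [], config)


class TestCallConservation:
    def _aip(self, seq):
        from madsplice.conservation import AIP

        return AIP(
            isoform_long="x", isoform_short="y", intron_index=0,
            indel_peptide="QQ", region_start_long=1, flank_identical=10,
            flank_gapped=0, passes_flank_rule=True, gapless_anchor=True,
            carrier_sequence=seq,
        )

    def test_self_similarity_is_100(self, config):
        seq = _random_protein(np.random.default_rng(15), 90)
        call = call_conservation(self._aip(seq), self._aip(seq), config)
        assert call.similarity_pct == 100.0 and call.conserved

    def test_symmetry(self, config):
        a = self._aip(_random_protein(np.random.default_rng(16), 90))
        b = self._aip(_random_protein(np.random.default_rng(17), 90))
        assert call_conservation(a, b, config).similarity_pct == pytest.approx(
            call_conservation(b, a, config).similarity_pct
        )

    def test_unrelated_random_pairs_fall_below_40(self, config):
        """Random 100-mers are on average far below the 40% threshold."""
        rng = np.random.default_rng(18)
        sims = []
        for _ in range(40):
            a = self._aip(_random_protein(rng, 100))
            b = self._aip(_random_protein(rng, 100))
            sims.append(call_conservation(a, b, config).similarity_pct)
        assert np.mean(sims) < 40
        assert np.mean([s < 40 for s in sims]) > 0.8


class TestAipRecovery:
    def test_recovery_and_specificity_on_diverged_orthologs(self, config):
        """Implanted AIPs at d <= 0.1 are recovered; decoys never called."""
        species = [
            SpeciesSpec("near", 0.05, True),
            SpeciesSpec("far", 0.10, True),
            SpeciesSpec("decoy", 0.05, False, decoy_indel=True),
        ]
        tp = fn = fp = 0
        for seed in range(10):
            spec = EventSpec("alt_acceptor", 15, target_domain="K_cterm")
            sim = simulate_locus(SimConfig(seed=seed, events=[spec]), seed)
            implant_event(sim, spec, seed + 500)
            contigs, truths = simulate_orthologs(sim, species, seed + 900)
            ref = sim.truth.protein
            introns = [
                i for i in get_introns(sim.reference) if i.protein_position is not None
            ]
            for sp, truth in zip(species, truths):
                peps = {}
                for cid, seq in contigs[sp.name].items():
                    best = None
                    for frag in six_frame_orfs(seq, 30, cid, sp.name):
                        h = best_homolog(frag, {"ref": ref}, config)
                        if h and (best is None or h.score > best.score):
                            best = h
                    if best:
                        peps[cid] = best.fragment.peptide
                found = []
                if len(peps) >= 2:
                    cids = sorted(peps, key=lambda c: -len(peps[c]))
                    found = isoform_pair_aips(
                        (cids[0], peps[cids[0]]), (cids[1], peps[cids[1]]),
                        ref, introns, config,
                    )
                if truth.present:
                    tp += bool(found)
                    fn += not found
                else:
                    fp += bool(found)
        assert fp == 0
        assert tp / (tp + fn) >= 0.9


class TestExonizationScan:
    EXON = ("GAAGATCTTGTTCAAGCTCCACTTCCAGAAGATGATAAC"
            "GAAGGAAGCTCCGTTGAAGCTGAACTT")  # 66 nt, stop-free in frame 0

    def test_clean_remnant_is_translatable(self):
        intron = implant_cryptic_exon_remnant(self.EXON, seed=1, ag_offset=0)
        rep = exonization_scan(self.EXON, intron)
        assert rep.has_hit and rep.acceptor_offset == 0
        assert rep.frame_preserved and not rep.in_frame_stop
        assert rep.translatable

    def test_acceptor_2nt_upstream_breaks_frame(self):
        intron = implant_cryptic_exon_remnant(self.EXON, seed=2, ag_offset=2)
        rep = exonization_scan(self.EXON, intron)
        assert rep.acceptor_offset == 2
        assert not rep.frame_preserved and not rep.translatable

    def test_in_frame_stop_blocks_translation(self):
        intron = implant_cryptic_exon_remnant(
            self.EXON, seed=3, ag_offset=0, implant_stop=True
        )
        rep = exonization_scan(self.EXON, intron)
        assert rep.frame_preserved and rep.in_frame_stop
        assert not rep.translatable

    def test_no_hit_below_score_floor(self):
        rng = np.random.default_rng(4)
        intron = "GT" + "".join(rng.choice(list("CT"), size=200)) + "AG"
        rep = exonization_scan(self.EXON, intron)
        assert not rep.has_hit and not rep.translatable

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            exonization_scan("ACGT", "ACGT" * 20)
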