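"""Reference generation, probe checks, placement and event simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smtseq as s
from smtseq.simcore import TEMPLATE_LENGTH, noise_free_extension


class TestReferences:
    def test_eight_wild_mutant_pairs_of_length_70(self, refs):
        assert len(refs.templates) == 8
        kinds = [t.variant.kind for t in refs.templates]
        assert kinds.count("point") == 6 and kinds.count("deletion") == 2
        for t in refs.templates:
            assert len(t.wild) == TEMPLATE_LENGTH
            assert t.mutant == t.variant.apply(t.wild)

    def test_same_seed_is_byte_identical(self):
        a = s.make_references(8, seed=11)
        b = s.make_references(8, seed=11)
        assert [t.wild for t in a.templates] == [t.wild for t in b.templates]
        assert a.probes == b.probes

    def test_deletion_surgery(self):
        spec = s.VariantSpec("d15", "deletion", 30, del_length=15)
        wild = "".join("ACGT"[i % 4] for i in range(70))
        mutant = spec.apply(wild)
        assert len(mutant) == 55
        assert mutant == wild[:30] + wild[45:]

    def test_point_alt_differs_from_reference(self, refs):
        for t in refs.templates:
            if t.variant.kind == "point":
                assert t.wild[t.variant.position] != t.variant.alt_base
                assert t.mutant[t.variant.position] == t.variant.alt_base

    def test_out_of_range_variant_rejected(self):
        bad = s.VariantSpec("far", "deletion", 60, del_length=15)
        with pytest.raises(ValueError, match="far"):
            s.make_references(1, [bad], seed=0)

    def test_probes_are_60nt_with_dt10_linker(self, refs):
        for name, seq in refs.probes:
            assert len(seq) == 60
            assert seq.endswith("T" * 10)

    def test_probe_specific_region_is_revcomp_of_template_tail(self, refs):
        t = refs.templates[0]
        _, probe = refs.probes[0]
        assert probe[:50] == s.reverse_complement(t.wild[20:70])


class TestProbeCheck:
    def test_all_gc_fails_upper_bound(self):
        rep = s.check_probe("G" * 50)
        assert rep.gc_fraction == 1.0 and not rep.passes

    def test_at_only_fails_lower_bound(self):
        rep = s.check_probe("AT" * 25)
        assert rep.gc_fraction == 0.0 and not rep.passes

    def test_half_gc_50mer_tm_formula(self):
        # 25 G/C in 50 nt: Tm = 64.9 + 41*(25 - 16.4)/50 = 71.952
        probe = "GC" * 12 + "G" + "AT" * 12 + "A"
        assert probe.count("G") + probe.count("C") == 25 and len(probe) == 50
        rep = s.check_probe(probe)
        assert rep.gc_fraction == pytest.approx(0.5)
        assert rep.tm == pytest.approx(64.9 + 41 * (25 - 16.4) / 50)
        assert rep.passes  # 71.95 > 65 and GC in bounds

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            s.check_probe("ACGTN")


class TestPlacement:
    def test_expected_molecule_count_matches_density(self, refs):
        geom = s.FieldGeometry()
        mean = geom.density * geom.area
        assert mean == pytest.approx(2235.87, abs=0.01)  # 0.75 * 54.6^2
        counts = [
            s.place_molecules(refs, geom, seed=k).n_sites for k in range(5)
        ]
        # Poisson(2236): 5-field mean within 5 sigma of the mean
        assert abs(np.mean(counts) - mean) < 5 * np.sqrt(mean / 5)

    def test_pure_wild_mixture_labels(self, refs):
        geom = s.FieldGeometry(pixel_count=(64, 64))
        mol = s.place_molecules(refs, geom, (1.0, 0.0), seed=0, n_sites=200)
        assert not mol.origin.any()

    def test_mixture_fraction_within_binomial_ci(self, refs):
        geom = s.FieldGeometry(pixel_count=(256, 256))
        mol = s.place_molecules(refs, geom, (0.97, 0.03), seed=1, n_sites=10_000)
        n = mol.n_molecules
        frac = mol.origin.mean()
        ci = 2.58 * np.sqrt(0.03 * 0.97 / n)  # 99% CI
        assert abs(frac - 0.03) < ci

    def test_occupancy_fractions(self, refs):
        geom = s.FieldGeometry()
        mol = s.place_molecules(refs, geom, seed=5, n_sites=5000)
        occ = np.bincount(mol.site_index)
        fr = np.array([(occ == k).mean() for k in (1, 2, 3)])
        assert np.allclose(fr, [0.38, 0.36, 0.26], atol=0.03)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            s.FieldGeometry(density=0.0)


class TestEvents:
    def test_noise_free_roundtrip_in_phase_template(self, refs):
        # extension exactly in phase with flow order G,C,T,A
        spec = s.VariantSpec("p", "point", 30, "A")
        wild = "GCTAGCTAGC" + "G" * 60
        tmpl = s.TemplateRecord("t", wild, spec.apply(wild), spec)
        rs = s.ReferenceSet([tmpl], [refs.probes[0]], seed=0)
        mol = _molecules(20, 0)
        ev = s.simulate_events(mol, rs, s.FlowProtocol(n_cycles=10), s.ErrorModel(0, 0, 0), seed=1)
        reads = s.events_to_reads(ev, mol)
        assert all(r == "GCTAGCTAGC" for r in reads.seqs)

    def test_noise_free_reads_are_extension_prefixes(self, refs, protocol):
        reads = s.simulate_readset(refs, (1.0, 0.0), 500, protocol, s.ErrorModel(0, 0, 0), seed=3)
        for seq, ti in zip(reads.seqs, reads.template_index):
            ext = noise_free_extension(refs.templates[ti].wild, protocol)
            assert seq == ext

    def test_deletion_only_thinning_is_binomial(self, refs):
        protocol = s.FlowProtocol()
        errors = s.ErrorModel(p_sub=0.0, p_del=0.1, p_ins=0.0)
        reads = s.simulate_readset(refs, (1.0, 0.0), 10_000, protocol, errors, seed=4)
        # with p_del only, the pointer trajectory matches the noise-free walk,
        # so read length ~ Binomial(K, 1 - p_del) with K the noise-free length
        exp = 0.0
        for t in refs.templates:
            exp += len(noise_free_extension(t.wild, protocol)) * 0.9 / len(refs.templates)
        obs = np.mean([len(r) for r in reads.seqs])
        assert abs(obs - exp) < 0.05

    def test_determinism(self, refs, protocol):
        a = s.simulate_readset(refs, (0.9, 0.1), 300, protocol, seed=9)
        b = s.simulate_readset(refs, (0.9, 0.1), 300, protocol, seed=9)
        assert a.seqs == b.seqs and np.array_equal(a.origin, b.origin)

    def test_event_table_shape_and_single_event_per_cycle(self, refs, protocol):
        mol = _molecules(10, 0)
        ev = s.simulate_events(mol, refs, protocol, seed=2)
        assert ev.outcome.shape == (10, protocol.n_cycles)
        # recorded base only where an incorporation or spurious event happened
        has_base = ev.recorded >= 0
        event_codes = np.isin(ev.outcome, (1, 2, 4))
        assert np.array_equal(has_base, event_codes)


class TestDecoding:
    @pytest.mark.parametrize(
        "cycles,expected",
        [((1, 2, 5), "GCG"), ((), ""), ((3, 4, 7), "TAT")],
    )
    def test_cycle_to_base_mapping(self, refs, protocol, cycles, expected):
        n_cyc = protocol.n_cycles
        outcome = np.zeros((1, n_cyc), dtype=np.int8)
        recorded = np.full((1, n_cyc), -1, dtype=np.int8)
        for c in cycles:
            outcome[0, c - 1] = 1
            recorded[0, c - 1] = s.simcore.encode(protocol.flow_base(c))[0]
        ev = s.EventTable(outcome=outcome, recorded=recorded, protocol=protocol)
        reads = s.events_to_reads(ev)
        assert reads.seqs[0] == expected

    @given(st.sets(st.integers(min_value=1, max_value=24), max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_decoding_matches_flow_enumeration(self, cycles):
        protocol = s.FlowProtocol()
        n_cyc = protocol.n_cycles
        outcome = np.zeros((1, n_cyc), dtype=np.int8)
        recorded = np.full((1, n_cyc), -1, dtype=np.int8)
        for c in cycles:
            outcome[0, c - 1] = 1
            recorded[0, c - 1] = s.simcore.encode(protocol.flow_base(c))[0]
        ev = s.EventTable(outcome=outcome, recorded=recorded, protocol=protocol)
        expected = "".join("GCTA"[(c - 1) % 4] for c in sorted(cycles))
        assert s.events_to_reads(ev).seqs[0] == expected


def _molecules(n, template_index):
    return s.MoleculeSet(
        x=np.zeros(n),
        y=np.zeros(n),
        template_index=np.full(n, template_index, dtype=np.int32),
        origin=np.zeros(n, dtype=np.int8),
        site_index=np.arange(n),
        site_occupancy=np.ones(n, dtype=int),
    )
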