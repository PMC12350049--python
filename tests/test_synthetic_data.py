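import pytest

from mitochar.architecture import STOP_CODONS, build_ledger, conservation_check
from mitochar.codon_usage import STOPS2, split_codons
from mitochar.io_annotation import extract_gene_sequence
from mitochar.molevol import nei_gojobori, pair_diffs
from mitochar.synthetic_data import (
    DEFAULT_COMPOSITION, SimulationConfig, evolve, make_ancestor,
    simulate_codon_pair,
)


class TestAncestor:
    def test_gene_census_matches_template(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        assert len(ann) == 38
        assert seq.length == ann.genome_length == 16571

    def test_annotation_passes_architecture_validation(self, synthetic_genome):
        _, ann, _ = synthetic_genome
        assert conservation_check(ann)

    def test_atp8_atp6_overlap_in_ledger(self, synthetic_genome):
        _, ann, _ = synthetic_genome
        led = build_ledger(ann)
        pair = next(p for p in led.pairs
                    if (p.upstream, p.downstream) == ("ATP8", "ATP6"))
        assert pair.intergenic == -7

    def test_pcgs_have_no_internal_stops(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        for f in ann.pcgs:
            codons = split_codons(extract_gene_sequence(seq, f))
            internal = codons[1:-1] if f.size % 3 == 0 else codons[1:]
            assert not any(c in STOPS2 for c in internal), f.name

    def test_complete_stop_genes_end_in_stop(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        for f in ann.pcgs:
            if f.size % 3 == 0:
                assert extract_gene_sequence(seq, f)[-3:] in STOP_CODONS

    def test_same_seed_gives_identical_bytes(self):
        a, _, _ = make_ancestor(SimulationConfig(seed=5))
        b, _, _ = make_ancestor(SimulationConfig(seed=5))
        assert a.residues == b.residues

    def test_different_seed_differs(self):
        a, _, _ = make_ancestor(SimulationConfig(seed=5))
        b, _, _ = make_ancestor(SimulationConfig(seed=6))
        assert a.residues != b.residues

    def test_partition_composition_near_targets(self, synthetic_genome):
        """Each partition hits its composition target within 1% (small
        partitions get a sampling-noise allowance)."""
        from mitochar.composition import summarize_partitions

        seq, ann, truth = synthetic_genome
        parts = summarize_partitions(seq, ann)
        # tRNA carries fixed anticodon implants on top of sampling noise,
        # hence its wider allowance
        for cls, tol in (("PCG", 0.01), ("rRNA", 0.01), ("tRNA", 0.03)):
            s = parts[cls]
            target = DEFAULT_COMPOSITION[cls]
            for base, obs in zip("ACGT", (s.a, s.c, s.g, s.t)):
                assert abs(obs / s.counted - target[base]) < tol, (cls, base)
        # CR: measured outside the implanted CSB/repeat windows, which have
        # their own fixed composition by construction
        cr = ann.of_class("CR")[0]
        crseq = list(seq.residues[cr.start - 1:cr.end])
        spans = [(truth["repeat"]["cr_start"], truth["repeat"]["cr_end"])]
        spans += [(w["cr_start"], w["cr_end"])
                  for w in truth["csb_positions"].values()]
        for lo, hi in spans:
            crseq[lo - 1:hi] = [""] * (hi - lo + 1)
        rest = "".join(crseq)
        for base in "ACGT":
            frac = rest.count(base) / len(rest)
            # ~3 binomial SE for an 800-bp sample
            assert abs(frac - DEFAULT_COMPOSITION["CR"][base]) < 0.05, base

    def test_genome_composition_matches_partition_mixture(self, synthetic_genome):
        """Whole-genome composition equals the size-weighted mixture of the
        partition targets within 1% (the published whole-genome row is not
        exactly that mixture, so the mixture is the generator's truth)."""
        seq, ann, _ = synthetic_genome
        sizes = {cls: sum(f.size for f in ann.of_class(cls))
                 for cls in ("PCG", "rRNA", "tRNA", "CR")}
        total = sum(sizes.values())
        for i, base in enumerate("ACGT"):
            mix = sum(sizes[cls] * DEFAULT_COMPOSITION[cls][base]
                      for cls in sizes) / total
            frac = seq.residues.count(base) / seq.length
            assert abs(frac - mix) < 0.01

    def test_infeasible_composition_rejected(self):
        comp = {k: dict(v) for k, v in DEFAULT_COMPOSITION.items()}
        comp["PCG"] = {"A": 0.9, "C": 0.04, "G": 0.03, "T": 0.06}
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, composition=comp, kappa=-1)

    def test_truth_bundle_records_implants(self, synthetic_genome):
        _, _, truth = synthetic_genome
        assert truth["repeat"]["period"] == 17
        assert set(truth["csb_positions"]) == {"CSB-D", "CSB-1", "CSB-2", "CSB-3"}


class TestEvolve:
    def test_zero_branch_length_is_identity(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        cfg = SimulationConfig(seed=2, tree={"x": 0.0})
        taxa, _ = evolve(seq, ann, cfg)
        assert taxa[0][0].residues == seq.residues

    def test_branches_accumulate_divergence(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        cfg = SimulationConfig(seed=3, tree={"near": 0.01, "far": 0.08})
        taxa, truth = evolve(seq, ann, cfg)
        by_label = {g.id: g for g, _ in taxa}
        d_near = pair_diffs(seq.residues, by_label["near"].residues).p_distance
        d_far = pair_diffs(seq.residues, by_label["far"].residues).p_distance
        assert 0 < d_near < d_far

    def test_truth_counts_match_realized_divergence(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        cfg = SimulationConfig(seed=4, tree={"x": 0.05})
        taxa, truth = evolve(seq, ann, cfg)
        branch = truth["branches"][0]
        assert branch["accepted_substitutions"] <= branch["candidate_events"]
        total = sum(v["syn"] + v["nonsyn"] for v in branch["per_gene"].values())
        assert total <= branch["accepted_substitutions"]

    def test_omega_zero_means_no_nonsynonymous_fixation(self, synthetic_genome):
        seq, ann, _ = synthetic_genome
        cfg = SimulationConfig(seed=6, tree={"x": 0.05},
                               omega={}, default_omega=0.0)
        taxa, truth = evolve(seq, ann, cfg)
        branch = truth["branches"][0]
        assert all(v["nonsyn"] == 0 for v in branch["per_gene"].values())
        # and the NG86 estimate agrees: Ka == 0 on every gene
        child = taxa[0][0]
        for f in ann.pcgs[:3]:
            g1 = extract_gene_sequence(seq, f)
            g2 = extract_gene_sequence(child, f)
            trim = len(g1) - len(g1) % 3 - (3 if f.size % 3 == 0 else 0)
            r = nei_gojobori(g1[:trim], g2[:trim])
            assert r.ka == 0


def test_codon_pair_truth_bookkeeping():
    c1, c2, truth = simulate_codon_pair(200, 0.3, 4.0, 0.0, seed=9)
    assert truth["nonsyn"] == 0
    r = nei_gojobori(c1, c2)
    assert r.ka == 0 and r.ks > 0
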