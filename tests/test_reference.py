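"""Reference construction: CCA tailing, identity collapse, masking, flanks."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from boseq.reference import (
    Locus,
    TRNAGene,
    append_cca,
    build_reference,
    collapse_identical,
    extract_flanks,
    mask_genome,
    write_reference,
)

seq_strategy = st.text(alphabet="ACGTUN", min_size=1, max_size=120)


def make_gene(gene_id, seq, iso="LysCTT", **kw):
    return TRNAGene(gene_id=gene_id, sequence=seq, isoacceptor=iso, **kw)


class TestAppendCCA:
    def test_concatenates(self):
        assert append_cca("GGGAAAUCC") == "GGGAAATCCCCA"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            append_cca("")

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError):
            append_cca("ACGX")

    @given(seq_strategy)
    def test_postcondition(self, seq):
        out = append_cca(seq)
        normalized = seq.upper().replace("U", "T")
        assert out.endswith("CCA")
        assert out.startswith(normalized)
        assert len(out) == len(seq) + 3

    def test_unconditional_by_default_but_flag_skips(self):
        assert append_cca("AAACCA") == "AAACCACCA"
        assert append_cca("AAACCA", only_if_absent=True) == "AAACCA"


class TestCollapse:
    def test_identical_pair_collapses(self):
        genes = [
            make_gene("g1", "ACGTCCA"),
            make_gene("g2", "ACGTCCA"),
            make_gene("g3", "TTTTCCA"),
        ]
        ref = collapse_identical(genes)
        assert len(ref.contigs) == 2
        assert ref.members["g1"] == ["g1", "g2"]

    def test_empty_input(self):
        ref = collapse_identical([])
        assert ref.contigs == {} and ref.members == {}

    def test_duplicate_gene_ids_rejected(self):
        genes = [make_gene("g1", "ACGT"), make_gene("g1", "TTTT")]
        with pytest.raises(ValueError, match="duplicate"):
            collapse_identical(genes)

    def test_contig_count_matches_distinct_sequence_oracle(self):
        # 535 genes with planted duplicates, oracle = set of post-CCA strings
        from boseq.simulate import synthetic_genes

        genes = synthetic_genes(n_genes=535, seed=3, duplicate_rate=0.25)
        tailed = [append_cca(g.sequence) for g in genes]
        ref = build_reference(genes)
        assert len(ref.contigs) == len(set(tailed))
        assert len(set(tailed)) < 535  # duplicates were actually planted
        assert all(s.endswith("CCA") for s in ref.contigs.values())
        covered = sorted(itertools.chain.from_iterable(ref.members.values()))
        assert covered == sorted(g.gene_id for g in genes)

    def test_order_independence(self):
        genes = [
            make_gene("b", "ACGTCCA"),
            make_gene("a", "ACGTCCA"),
            make_gene("c", "GGGGCCA"),
        ]
        ref1 = collapse_identical(genes)
        ref2 = collapse_identical(list(reversed(genes)))
        assert ref1.contigs == ref2.contigs
        assert ref1.members == ref2.members

    def test_exclusion_requires_all_members_flagged(self):
        genes = [
            make_gene("p1", "ACGTCCA", pseudogene=True),
            make_gene("f1", "ACGTCCA"),  # functional copy keeps the contig
            make_gene("p2", "GGGGCCA", pseudogene=True),
            make_gene("m1", "TTTTCCA", source="mito_prediction"),
        ]
        ref = collapse_identical(genes)
        assert ref.excluded == {"m1", "p2"}


class TestMaskGenome:
    def test_direct_substitution(self):
        assert mask_genome({"c": "ACGTACGT"}, [Locus("c", 2, 4)])["c"] == "ACNNACGT"

    def test_empty_interval_list_is_identity(self):
        assert mask_genome({"c": "ACGT"}, [])["c"] == "ACGT"

    def test_overlapping_intervals_match_per_base_oracle(self):
        loci = [Locus("c", 1, 4), Locus("c", 3, 6)]
        out = mask_genome({"c": "AAAAAAAA"}, loci)["c"]
        oracle = "".join(
            "N" if any(s <= i < e for _, s, e, _ in loci) else b
            for i, b in enumerate("AAAAAAAA")
        )
        assert out == "ANNNNNAA" == oracle

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            mask_genome({"c": "ACGT"}, [Locus("c", 2, 9)])

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=60),
        st.lists(st.tuples(st.integers(0, 59), st.integers(0, 59)), max_size=5),
    )
    def test_idempotent_and_masked_count_equals_interval_union(self, seq, pairs):
        loci = [
            Locus("c", min(a, b), max(a, b) + 1)
            for a, b in pairs
            if max(a, b) < len(seq)
        ]
        once = mask_genome({"c": seq}, loci)
        twice = mask_genome(once, loci)
        assert once == twice
        assert len(once["c"]) == len(seq)
        union = set().union(*(range(l.start, l.end) for l in loci)) if loci else set()
        assert sum(b == "N" for b in once["c"]) == len(union)


class TestExtractFlanks:
    def test_stated_shift_arithmetic(self):
        # locus [100,172) on +: up [100-50-3, 100-3), down [172+6, 172+6+50)
        flanks = extract_flanks([Locus("c", 100, 172, "+")])
        assert [(f.start, f.end) for f in flanks] == [(47, 97), (178, 228)]

    def test_minus_strand_mirrors(self):
        flanks = extract_flanks([Locus("c", 100, 172, "-")])
        assert [(f.start, f.end) for f in sorted(flanks)] == [(44, 94), (175, 225)]

    def test_zero_flank_len_rejected(self):
        with pytest.raises(ValueError):
            extract_flanks([Locus("c", 100, 172)], flank_len=0)

    def test_clipping_at_chromosome_start(self):
        flanks = extract_flanks([Locus("c", 10, 80, "+")], chrom_sizes={"c": 100})
        up = [f for f in flanks if f.end <= 10][0]
        assert up.start == 0 and up.end == 7

    @given(st.integers(60, 500), st.integers(1, 80), st.sampled_from("+-"))
    def test_flanks_never_overlap_their_locus(self, start, length, strand):
        loc = Locus("c", start, start + length, strand)
        for f in extract_flanks([loc]):
            assert f.end <= loc.start or f.start >= loc.end


class TestBuildReference:
    def test_contigs_end_cca_and_flanks_from_genome(self):
        from boseq.simulate import synthetic_genes, synthetic_genome

        genes = synthetic_genes(n_genes=5, seed=0)
        genome, placed = synthetic_genome(genes, seed=1)
        ref = build_reference(placed, genome=genome)
        assert len(ref.contigs) <= 5
        assert all(s.endswith("CCA") for s in ref.contigs.values())
        assert len(ref.flanks) == 2 * len(placed)
        masked = ref.masked_genome["chrSim"]
        for gene in placed:
            loc = gene.locus
            assert set(masked[loc.start : loc.end]) == {"N"}

    def test_genes_only_mode_has_no_genome_artifacts(self):
        ref = build_reference([make_gene("g1", "ACGT")])
        assert ref.masked_genome is None and ref.flanks == []

    def test_rerun_writes_byte_identical_outputs(self, tmp_path):
        from boseq.simulate import synthetic_genes, synthetic_genome

        genes = synthetic_genes(n_genes=6, seed=2)
        genome, placed = synthetic_genome(genes, seed=3)
        blobs = []
        for sub in ("a", "b"):
            ref = build_reference(placed, genome=genome)
            paths = write_reference(ref, str(tmp_path / sub))
            blobs.append(
                {k: open(p, "rb").read() for k, p in sorted(paths.items())}
            )
        assert blobs[0] == blobs[1]

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            build_reference([])
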