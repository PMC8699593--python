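"""Genomic-position -> codon mapping, checked against a full-CDS
translation-diff oracle and explicit strand-mirror constructions."""

import numpy as np
import pandas as pd
import pytest

from argskew import codon_mapper as cm
from argskew import genetic_code as gc
from argskew.synthetic_data import SimulationConfig, generate_reference

from conftest import translation_diff_oracle


@pytest.fixture
def simple_gene():
    """Plus-strand gene, single CDS 101-160, phase 0."""
    return cm.GeneModel(
        gene_symbol="GX", chromosome="chr1", strand="+",
        cds_intervals=[(101, 160)], phase=0,
    )


class TestCodonRange:
    def test_mid_codon_offsets(self, simple_gene):
        loc = cm.codon_range(107, simple_gene)
        assert loc.ranges == ((107, 109),)
        assert loc.offset == 1
        assert loc.protein_position == 3

    def test_third_offset(self, simple_gene):
        loc = cm.codon_range(103, simple_gene)
        assert loc.ranges == ((101, 103),)
        assert loc.offset == 3
        assert loc.protein_position == 1

    def test_outside_cds_raises(self, simple_gene):
        with pytest.raises(cm.NonCodingPositionError):
            cm.codon_range(100, simple_gene)
        with pytest.raises(cm.NonCodingPositionError):
            cm.codon_range(161, simple_gene)

    def test_intron_split_codon_has_two_subranges(self):
        # codon 2 split 1 base | 2 bases across a 10 bp intron
        model = cm.GeneModel(
            gene_symbol="GI", chromosome="chr1", strand="+",
            cds_intervals=[(11, 14), (25, 29)], phase=0,
        )
        loc = cm.codon_range(14, model)
        assert loc.ranges == ((14, 14), (25, 26))
        assert loc.offset == 1
        assert loc.protein_position == 2


class TestFetchCodon:
    def test_plus_strand_direct_read(self):
        assert cm.fetch_codon("AACGTAG", (3, 5), "+") == "CGT"

    def test_minus_strand_reverse_complement(self):
        assert cm.fetch_codon("AACGTAG", (3, 5), "-") == "ACG"

    def test_round_trip_involution(self):
        seq = "ACGTAGGCTA"
        rc = gc.reverse_complement(seq)
        n = len(seq)
        # range (4,6) on seq mirrors to (n-6+1, n-4+1) on the revcomp
        assert cm.fetch_codon(seq, (4, 6), "+") == cm.fetch_codon(rc, (n - 5, n - 3), "-")

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            cm.fetch_codon("ACGT", (3, 5), "+")


def _toy_reference():
    """10 bp flank + ATG CGA TAA + 10 bp flank; gene at 11-19, plus strand."""
    chrom = "A" * 10 + "ATGCGATAA" + "C" * 10
    model = cm.GeneModel(
        gene_symbol="GX", chromosome="chr1", strand="+",
        cds_intervals=[(11, 19)], phase=0,
    )
    return {"chr1": chrom}, {"GX": model}


class TestAnnotateRecord:
    def test_cga_to_caa_glutamine(self):
        """G>A at the middle base of a CGA codon gives R->Q missense."""
        reference, models = _toy_reference()
        rec = cm.MutationRecord(
            gene_symbol="GX", sample_id="S1", chromosome="chr1", position=15,
            wt_allele="G", mut_allele="A", gene_strand="+",
        )
        ann = cm.annotate_record(rec, reference, models)
        assert (ann.event.ref_codon, ann.event.alt_codon) == ("CGA", "CAA")
        assert (ann.event.ref_aa, ann.event.alt_aa) == ("R", "Q")
        assert ann.event.functional_class == gc.MISSENSE
        assert ann.protein_position == 2

    def test_minus_strand_mirror(self):
        """The same CGA->CAA event annotated from the opposite strand."""
        reference, _ = _toy_reference()
        chrom = reference["chr1"]
        rc = gc.reverse_complement(chrom)
        n = len(chrom)
        model = cm.GeneModel(
            gene_symbol="GX", chromosome="chr1", strand="-",
            cds_intervals=[(n - 19 + 1, n - 11 + 1)], phase=0,
        )
        # genomic position mirroring 15; plus-strand alleles complemented
        rec = cm.MutationRecord(
            gene_symbol="GX", sample_id="S1", chromosome="chr1",
            position=n - 15 + 1, wt_allele="C", mut_allele="T", gene_strand="-",
        )
        ann = cm.annotate_record(rec, {"chr1": rc}, {"GX": model})
        assert (ann.event.ref_codon, ann.event.alt_codon) == ("CGA", "CAA")
        assert ann.protein_position == 2

    def test_reference_mismatch_raises(self):
        reference, models = _toy_reference()
        rec = cm.MutationRecord(
            gene_symbol="GX", sample_id="S1", chromosome="chr1", position=15,
            wt_allele="T", mut_allele="A", gene_strand="+",
        )
        with pytest.raises(cm.ReferenceMismatchError):
            cm.annotate_record(rec, reference, models)

    def test_protein_change_concordance_flag(self):
        reference, models = _toy_reference()
        good = cm.MutationRecord(
            gene_symbol="GX", sample_id="S1", chromosome="chr1", position=15,
            wt_allele="G", mut_allele="A", gene_strand="+", mutation_aa="p.R2Q",
        )
        bad = cm.MutationRecord(
            gene_symbol="GX", sample_id="S1", chromosome="chr1", position=15,
            wt_allele="G", mut_allele="A", gene_strand="+", mutation_aa="p.R2H",
        )
        assert cm.annotate_record(good, reference, models).discordant is False
        assert cm.annotate_record(bad, reference, models).discordant is True


def test_annotation_counts_conserved(study, annotation):
    """input = annotated + mismatched + non-coding, with no silent drops."""
    counts = annotation.counts
    assert sum(counts.values()) == len(study.mutations)
    assert counts["mismatched"] == 0  # simulator guarantees wt == reference


def test_mismatched_records_counted_not_fatal(study):
    mutated = study.mutations.copy()
    row = mutated.index[mutated["gene_symbol"] != ""][0]
    wt = mutated.loc[row, "wt_allele"]
    mutated.loc[row, "wt_allele"] = "A" if wt != "A" else "C"
    mutated.loc[row, "mut_allele"] = "G" if wt == "G" else wt
    result = cm.annotate_table(mutated, study.reference, study.models)
    assert result.counts["mismatched"] == 1
    assert sum(result.counts.values()) == len(mutated)


def test_annotation_matches_translation_diff_oracle():
    """Random genes on both strands, intron-split codons included: the
    annotated (protein_pos, ref_aa, alt_aa) equals diffing the full
    wild-type vs mutant CDS translations."""
    cfg = SimulationConfig(
        seed=29, n_genes=30, codons_per_gene=40, intron_fraction=0.5,
        arginine_fraction=0.3,
    )
    reference, models = generate_reference(cfg)
    rng = np.random.default_rng(5)
    genes = sorted(models)
    n_checked = 0
    for _ in range(300):
        model = models[genes[rng.integers(len(genes))]]
        cp = model.coding_positions
        pos = int(cp[rng.integers(len(cp))])
        chrom = reference[model.chromosome]
        wt = chrom[pos - 1]
        mut = "ACGT".replace(wt, "")[rng.integers(3)]
        rec = cm.MutationRecord(
            gene_symbol=model.gene_symbol, sample_id="S1",
            chromosome=model.chromosome, position=pos,
            wt_allele=wt, mut_allele=mut, gene_strand=model.strand,
        )
        ann = cm.annotate_record(rec, reference, models)
        expected = translation_diff_oracle(reference, model, pos, mut)
        if expected is None:
            assert ann.event.functional_class == gc.SYNONYMOUS
        else:
            assert (
                ann.protein_position, ann.event.ref_aa, ann.event.alt_aa
            ) == expected
        n_checked += 1
    assert n_checked == 300


def test_gff3_fasta_round_trip(tmp_path, study):
    """Models and reference written to disk reload to equivalent objects."""
    paths = study.write(tmp_path)
    reference = cm.load_reference(paths["fasta"])
    models = cm.load_gene_models(paths["gff3"])
    assert reference == study.reference
    assert set(models) == set(study.models)
    for gene, model in study.models.items():
        loaded = models[gene]
        assert loaded.strand == model.strand
        assert loaded.cds_intervals == model.cds_intervals
        assert loaded.coding_positions == model.coding_positions
    table = cm.read_mutation_csv(paths["csv"])
    pd.testing.assert_frame_equal(table, study.mutations)


def test_annotated_tsv_round_trip(tmp_path, annotated):
    path = tmp_path / "annotated.tsv"
    cm.write_annotated_tsv(annotated, path)
    back = cm.read_annotated_tsv(path)
    assert back["is_transition"].dtype == bool
    pd.testing.assert_frame_equal(
        back, annotated.reset_index(drop=True), check_dtype=False
    )
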