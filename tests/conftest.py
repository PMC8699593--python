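"""Shared fixtures: a seeded synthetic study, its annotation, and builders
for hand-constructed annotated record frames."""

from __future__ import annotations

import itertools

import pandas as pd
import pytest
from Bio.Seq import Seq

from argskew import codon_mapper
from argskew import genetic_code as gc
from argskew.synthetic_data import SimulationConfig, SkewSpec, simulate_study

_counter = itertools.count(1)


def make_records(entries, strand="+", chromosome="chr1"):
    """Build an annotated-record frame from (gene, sample, codon, codon_pos,
    alt_base) tuples, each at a fresh genomic position.

    Bases are coding-strand; genomic alleles assume a plus-strand gene
    unless *strand* says otherwise.
    """
    rows = []
    for gene, sample, codon, codon_pos, alt in entries:
        event = gc.substitute(codon, codon_pos, alt)
        position = next(_counter)
        wt, mut = event.ref_base, event.alt_base
        if strand == "-":
            wt, mut = gc.COMPLEMENT[wt], gc.COMPLEMENT[mut]
        rows.append(
            {
                "gene_symbol": gene,
                "transcript_id": f"T-{gene}",
                "sample_id": sample,
                "chromosome": chromosome,
                "position": position,
                "gene_strand": strand,
                "wt_allele": wt,
                "mut_allele": mut,
                "mutation_aa": "",
                "mutation_class": "",
                "ref_codon": event.ref_codon,
                "alt_codon": event.alt_codon,
                "codon_pos": event.codon_pos,
                "ref_base": event.ref_base,
                "alt_base": event.alt_base,
                "ref_aa": event.ref_aa,
                "alt_aa": event.alt_aa,
                "functional_class": event.functional_class,
                "is_transition": event.is_transition,
                "protein_position": 1,
                "codon_range": "",
                "discordant": False,
            }
        )
    return pd.DataFrame(rows)


def extract_cds(chrom_seq: str, model) -> str:
    """Independent CDS extraction: slice exons genomically, reverse-
    complement with biopython on the minus strand, then trim the phase."""
    seq = "".join(chrom_seq[s - 1 : e] for s, e in sorted(model.cds_intervals))
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    seq = seq[model.phase :]
    return seq[: len(seq) - len(seq) % 3]


def translation_diff_oracle(reference, model, position, mut_allele):
    """Brute-force oracle: apply the plus-strand point mutation to the whole
    chromosome, re-extract and translate the full CDS with biopython, and
    diff the wild-type and mutant protein sequences.

    Returns None for a synonymous change, else (protein_pos, ref_aa, alt_aa).
    """
    chrom = reference[model.chromosome]
    mutant = chrom[: position - 1] + mut_allele + chrom[position:]
    wt_protein = str(Seq(extract_cds(chrom, model)).translate())
    mut_protein = str(Seq(extract_cds(mutant, model)).translate())
    diffs = [i for i, (a, b) in enumerate(zip(wt_protein, mut_protein)) if a != b]
    if not diffs:
        return None
    assert len(diffs) == 1
    i = diffs[0]
    return i + 1, wt_protein[i], mut_protein[i]


@pytest.fixture(scope="session")
def study():
    """Mid-sized seeded study with two injected skews (His and Trp)."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=12,
        codons_per_gene=90,
        n_samples=160,
        mutations_per_sample=18.0,
        skew_specs=[
            SkewSpec("G002", "H", 0.70, 50),
            SkewSpec("G007", "W", 0.80, 45),
        ],
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def annotation(study):
    return codon_mapper.annotate_table(study.mutations, study.reference, study.models)


@pytest.fixture(scope="session")
def annotated(annotation):
    return annotation.annotated
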