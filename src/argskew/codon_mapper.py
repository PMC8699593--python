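"""Map genomic point mutations to codon-level substitution events.

COSMIC-style mutation rows carry a chromosome, a 1-based genomic position and
plus-strand alleles, but not the codon that was hit.  Given a reference FASTA
and a GFF3 gene model (CDS features with phase), this module recovers, for
each record, the codon's genomic range (possibly split across an intron), the
in-codon offset in translation order, the protein position, and the fully
classified ref->alt codon change.  For minus-strand genes the codon is read
as the reverse complement and the record's alleles are complemented onto the
coding strand -- strand conversion happens in exactly this one place.

All coordinates are 1-based inclusive, matching both COSMIC exports and
GFF3.  Records are never dropped silently: each input row ends up annotated,
counted as a reference mismatch, or routed to the non-coding stream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from . import genetic_code as gc

logger = logging.getLogger(__name__)

#: internal column names of the mutation table, in order
MUTATION_COLUMNS = [
    "gene_symbol",
    "transcript_id",
    "sample_id",
    "chromosome",
    "position",
    "gene_strand",
    "wt_allele",
    "mut_allele",
    "mutation_aa",
    "mutation_class",
]

#: CSV header used by the COSMIC-like dialect (synthetic_data writes it)
CSV_HEADER = [
    "GENE_SYMBOL",
    "TRANSCRIPT",
    "SAMPLE_ID",
    "CHROMOSOME",
    "GENOME_START",
    "STRAND",
    "WT_ALLELE",
    "MUT_ALLELE",
    "MUTATION_AA",
    "MUTATION_CLASS",
]

ANNOTATED_COLUMNS = MUTATION_COLUMNS + [
    "ref_codon",
    "alt_codon",
    "codon_pos",
    "ref_base",
    "alt_base",
    "ref_aa",
    "alt_aa",
    "functional_class",
    "is_transition",
    "protein_position",
    "codon_range",
    "discordant",
]

_PROTEIN_CHANGE_RE = re.compile(r"^p\.([A-Z*])(\d+)(=|[A-Z*])$")


class ReferenceMismatchError(ValueError):
    """Record's wild-type allele disagrees with the reference base."""


class NonCodingPositionError(LookupError):
    """Position not inside a complete codon of the record's gene model."""


class GeneModelError(ValueError):
    """Malformed or inconsistent CDS model."""


@dataclass(frozen=True)
class MutationRecord:
    """One COSMIC-like mutation row; alleles are genomic plus-strand."""

    gene_symbol: str
    sample_id: str
    chromosome: str
    position: int
    wt_allele: str
    mut_allele: str
    gene_strand: str
    transcript_id: str = ""
    mutation_aa: str = ""
    mutation_class: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.wt_allele == self.mut_allele:
            raise ValueError("wt_allele equals mut_allele; not a mutation")
        if self.gene_strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.gene_strand!r}")


@dataclass
class GeneModel:
    """CDS model of one gene: intervals 1-based inclusive, listed in
    transcription order (descending genomic coordinates on the minus
    strand); ``phase`` bases of the first interval are skipped."""

    gene_symbol: str
    chromosome: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    phase: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"bad strand {self.strand!r}")
        if not self.cds_intervals:
            raise GeneModelError(f"{self.gene_symbol}: no CDS intervals")
        if self.phase not in (0, 1, 2):
            raise GeneModelError(f"{self.gene_symbol}: bad phase {self.phase}")
        starts = [s for s, _ in self.cds_intervals]
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(
            starts, reverse=True
        )
        if not ordered:
            raise GeneModelError(
                f"{self.gene_symbol}: CDS intervals not in transcription order"
            )

    @cached_property
    def coding_positions(self) -> tuple[int, ...]:
        """Genomic positions of the CDS in translation order, phase-trimmed
        to whole codons."""
        pos: list[int] = []
        for start, end in self.cds_intervals:
            if start > end:
                raise GeneModelError(f"{self.gene_symbol}: interval {start}>{end}")
            rng = range(start, end + 1) if self.strand == "+" else range(end, start - 1, -1)
            pos.extend(rng)
        pos = pos[self.phase :]
        tail = len(pos) % 3
        if tail:
            logger.warning(
                "%s: CDS length not divisible by 3 after phase; trimming %d base(s)",
                self.gene_symbol,
                tail,
            )
            pos = pos[: len(pos) - tail]
        return tuple(pos)

    @cached_property
    def _position_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self.coding_positions)}

    def coding_index(self, position: int) -> int:
        try:
            return self._position_index[position]
        except KeyError:
            raise NonCodingPositionError(
                f"position {position} is non-coding for {self.gene_symbol}"
            ) from None

    @property
    def n_codons(self) -> int:
        return len(self.coding_positions) // 3


@dataclass(frozen=True)
class CodonLocation:
    """Genomic footprint of one codon: up to two ascending sub-ranges (two
    when the codon spans an intron), the 1-3 offset of the query position in
    translation order, and the 1-based protein position."""

    ranges: tuple[tuple[int, int], ...]
    offset: int
    protein_position: int


@dataclass(frozen=True)
class AnnotatedMutation:
    record: MutationRecord
    event: gc.SubstitutionEvent
    protein_position: int
    codon_genomic_range: tuple[tuple[int, int], ...]
    discordant: bool = False


@dataclass
class AnnotationResult:
    """Outcome of batch annotation; input rows = annotated + mismatched +
    noncoding, always."""

    annotated: pd.DataFrame
    noncoding: pd.DataFrame
    mismatched: pd.DataFrame

    @property
    def counts(self) -> dict[str, int]:
        return {
            "annotated": len(self.annotated),
            "noncoding": len(self.noncoding),
            "mismatched": len(self.mismatched),
        }


# ---------------------------------------------------------------------------
# input readers


def load_reference(fasta_path) -> dict[str, str]:
    """Read a reference FASTA into {chromosome: uppercase sequence}."""
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not seqs:
        raise ValueError(f"no sequences found in {fasta_path}")
    return seqs


def load_gene_models(gff3_path) -> dict[str, GeneModel]:
    """Parse CDS features (grouped by gene_name) from a GFF3 file.

    The first model per gene symbol wins; further models for the same symbol
    are ignored with a warning.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    grouped: dict[str, list] = {}
    for feat in db.features_of_type("CDS"):
        names = feat.attributes.get("gene_name") or feat.attributes.get("Parent")
        if not names:
            raise GeneModelError(f"CDS feature without gene_name/Parent: {feat}")
        grouped.setdefault(names[0], []).append(feat)
    models: dict[str, GeneModel] = {}
    for symbol, feats in grouped.items():
        chroms = {f.seqid for f in feats}
        strands = {f.strand for f in feats}
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning("%s: multiple models; keeping the first", symbol)
            first = feats[0]
            feats = [
                f for f in feats if f.seqid == first.seqid and f.strand == first.strand
            ]
        strand = feats[0].strand
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        phase = feats[0].frame
        models[symbol] = GeneModel(
            gene_symbol=symbol,
            chromosome=feats[0].seqid,
            strand=strand,
            cds_intervals=[(f.start, f.end) for f in feats],
            phase=int(phase) if phase not in (None, ".") else 0,
        )
    if not models:
        raise GeneModelError(f"no CDS features found in {gff3_path}")
    return models


def read_mutation_csv(path) -> pd.DataFrame:
    """Read the COSMIC-like mutation CSV into a frame with internal column
    names (see MUTATION_COLUMNS)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[CSV_HEADER].copy()
    df.columns = MUTATION_COLUMNS
    df["position"] = df["position"].astype(int)
    return df


def iter_records(df: pd.DataFrame) -> Iterable[MutationRecord]:
    for row in df.itertuples(index=False):
        yield MutationRecord(
            gene_symbol=row.gene_symbol,
            transcript_id=row.transcript_id,
            sample_id=row.sample_id,
            chromosome=row.chromosome,
            position=int(row.position),
            wt_allele=row.wt_allele,
            mut_allele=row.mut_allele,
            gene_strand=row.gene_strand if row.gene_strand in ("+", "-") else "+",
            mutation_aa=row.mutation_aa,
            mutation_class=row.mutation_class,
        )


# ---------------------------------------------------------------------------
# core operations


def codon_range(position: int, model: GeneModel) -> CodonLocation:
    """Locate the codon containing genomic *position* within *model*.

    Raises NonCodingPositionError when the position is not inside a complete
    codon of the model (introns, UTR-side flanks, phase-trimmed bases).
    """
    idx = model.coding_index(position)
    codon_idx, offset = divmod(idx, 3)
    codon_positions = model.coding_positions[3 * codon_idx : 3 * codon_idx + 3]
    ordered = sorted(codon_positions)
    ranges: list[list[int]] = [[ordered[0], ordered[0]]]
    for p in ordered[1:]:
        if p == ranges[-1][1] + 1:
            ranges[-1][1] = p
        else:
            ranges.append([p, p])
    return CodonLocation(
        ranges=tuple((s, e) for s, e in ranges),
        offset=offset + 1,
        protein_position=codon_idx + 1,
    )


def fetch_codon(chrom_seq: str, ranges, strand: str) -> str:
    """Read the codon covered by *ranges* (ascending 1-based inclusive
    sub-ranges) from a chromosome sequence; reverse-complement on the minus
    strand so the triplet comes back in translation order."""
    if isinstance(ranges[0], int):  # single (start, end) pair
        ranges = (ranges,)
    parts = []
    for start, end in ranges:
        if start < 1 or end > len(chrom_seq):
            raise ValueError(f"range {start}-{end} out of reference bounds")
        parts.append(chrom_seq[start - 1 : end])
    seq = "".join(parts)
    if strand == "-":
        seq = gc.reverse_complement(seq)
    return gc.validate_codon(seq)


def parse_protein_change(text: str):
    """Parse a 'p.R132H'-style string into (ref_aa, protein_pos, alt_aa);
    None when absent or unparseable.  'p.R132=' means synonymous."""
    m = _PROTEIN_CHANGE_RE.match(text.strip()) if text else None
    if not m:
        return None
    ref_aa, pos, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    if alt_aa == "=":
        alt_aa = ref_aa
    return ref_aa, pos, alt_aa


def annotate_record(
    record: MutationRecord,
    reference: Mapping[str, str],
    models: Mapping[str, GeneModel],
) -> AnnotatedMutation:
    """Annotate one record to a codon-level event.

    Raises NonCodingPositionError (route to the non-coding stream) or
    ReferenceMismatchError (exclude and count).
    """
    model = models.get(record.gene_symbol)
    if model is None or model.chromosome != record.chromosome:
        raise NonCodingPositionError(
            f"no gene model covers {record.gene_symbol} on {record.chromosome}"
        )
    chrom_seq = reference[record.chromosome]
    if record.position > len(chrom_seq):
        raise ValueError(
            f"position {record.position} beyond end of {record.chromosome}"
        )
    ref_plus = chrom_seq[record.position - 1]
    if ref_plus != record.wt_allele.upper():
        raise ReferenceMismatchError(
            f"{record.gene_symbol}:{record.chromosome}:{record.position} "
            f"wt_allele {record.wt_allele} != reference base {ref_plus}"
        )
    loc = codon_range(record.position, model)
    ref_codon = fetch_codon(chrom_seq, loc.ranges, model.strand)
    # single strand-conversion point: plus-strand alleles -> coding strand
    if model.strand == "-":
        alt_coding = gc.COMPLEMENT[record.mut_allele.upper()]
    else:
        alt_coding = record.mut_allele.upper()
    event = gc.substitute(ref_codon, loc.offset, alt_coding)
    discordant = False
    parsed = parse_protein_change(record.mutation_aa)
    if parsed is not None:
        discordant = parsed != (event.ref_aa, loc.protein_position, event.alt_aa)
        if discordant:
            logger.warning(
                "%s: protein change %s disagrees with computed %s%d%s",
                record.gene_symbol,
                record.mutation_aa,
                event.ref_aa,
                loc.protein_position,
                event.alt_aa,
            )
    return AnnotatedMutation(
        record=record,
        event=event,
        protein_position=loc.protein_position,
        codon_genomic_range=loc.ranges,
        discordant=discordant,
    )


def _format_ranges(ranges) -> str:
    return ",".join(f"{s}-{e}" for s, e in ranges)


def annotate_table(
    mutations: pd.DataFrame,
    reference: Mapping[str, str],
    models: Mapping[str, GeneModel],
) -> AnnotationResult:
    """Annotate a mutation frame; rows split into annotated / noncoding /
    reference-mismatched streams with conserved counts."""
    annotated_rows, noncoding_idx, mismatch_idx = [], [], []
    n_discordant = 0
    for i, rec in enumerate(iter_records(mutations)):
        try:
            ann = annotate_record(rec, reference, models)
        except NonCodingPositionError:
            noncoding_idx.append(i)
            continue
        except ReferenceMismatchError as exc:
            logger.warning("reference mismatch: %s", exc)
            mismatch_idx.append(i)
            continue
        e = ann.event
        n_discordant += ann.discordant
        annotated_rows.append(
            (
                rec.gene_symbol,
                rec.transcript_id,
                rec.sample_id,
                rec.chromosome,
                rec.position,
                rec.gene_strand,
                rec.wt_allele,
                rec.mut_allele,
                rec.mutation_aa,
                rec.mutation_class,
                e.ref_codon,
                e.alt_codon,
                e.codon_pos,
                e.ref_base,
                e.alt_base,
                e.ref_aa,
                e.alt_aa,
                e.functional_class,
                e.is_transition,
                ann.protein_position,
                _format_ranges(ann.codon_genomic_range),
                ann.discordant,
            )
        )
    annotated = pd.DataFrame(annotated_rows, columns=ANNOTATED_COLUMNS)
    result = AnnotationResult(
        annotated=annotated,
        noncoding=mutations.iloc[noncoding_idx].reset_index(drop=True),
        mismatched=mutations.iloc[mismatch_idx].reset_index(drop=True),
    )
    logger.info(
        "annotated %d / noncoding %d / mismatched %d (discordant protein "
        "changes: %d)",
        *result.counts.values(),
        n_discordant,
    )
    return result


def write_annotated_tsv(annotated: pd.DataFrame, path) -> None:
    annotated.to_csv(path, sep="\t", index=False)


def read_annotated_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_symbol": str},
                     keep_default_na=False, na_values=[])
    for col in ("is_transition", "discordant"):
        if df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df
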