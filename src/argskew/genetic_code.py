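"""Combinatorics of the standard genetic code.

Every single-nucleotide substitution of a codon is enumerable: 3 positions
x 3 alternative bases = 9 events per codon, each synonymous, missense or
nonsense under the standard (NCBI table 1) code.  The arginine family -- six
synonymous codons (AGA, AGG, CGA, CGC, CGG, CGT) -- is the instance of
interest for tumor-mutation analysis: its 54-change substitution space
contains 18 synonymous changes, 2 stop-producing changes and 34 missense
changes reaching 12 distinct residues, and its CpG-rich codons make it a
magnet for C>T / G>A deamination-driven transitions.

The code table here is hard-coded (DNA alphabet, uppercase) and is the single
source of truth for the whole package; no alternative genetic codes are
supported since only human somatic data is in scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

STOP = "*"

# Standard code, laid out in the canonical TCAG codon order.
_TCAG = "TCAG"
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
GENETIC_CODE: Mapping[str, str] = {
    "".join(bases): aa for bases, aa in zip(product(_TCAG, repeat=3), _AA_STRING)
}

STOP_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa == STOP))
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != STOP))
ARGININE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa == "R"))

TRANSITION = "transition"
TRANSVERSION = "transversion"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"


class InvalidCodonError(ValueError):
    """Raised for codons that are not 3 uppercase-normalizable ACGT bases."""


def _validate_base(base: str) -> str:
    b = str(base).upper()
    if len(b) != 1 or b not in BASES:
        raise InvalidCodonError(f"invalid base {base!r}: expected one of A/C/G/T")
    return b


def validate_codon(codon: str) -> str:
    """Normalize *codon* to uppercase and verify it is a 3-mer over ACGT."""
    c = str(codon).upper()
    if len(c) != 3 or any(b not in BASES for b in c):
        raise InvalidCodonError(
            f"invalid codon {codon!r}: expected 3 bases over A/C/G/T"
        )
    return c


def translate(codon: str) -> str:
    """Translate a codon under the standard genetic code; ``'*'`` for stops."""
    return GENETIC_CODE[validate_codon(codon)]


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise InvalidCodonError(f"non-ACGT base in {seq!r}") from exc


def classify_base_change(ref_base: str, alt_base: str) -> str:
    """Return ``'transition'`` (purine<->purine or pyrimidine<->pyrimidine)
    or ``'transversion'`` for an ordered base change."""
    ref, alt = _validate_base(ref_base), _validate_base(alt_base)
    if ref == alt:
        raise InvalidCodonError("ref and alt base are identical; not a change")
    same_class = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return TRANSITION if same_class else TRANSVERSION


def is_transition(ref_base: str, alt_base: str) -> bool:
    return classify_base_change(ref_base, alt_base) == TRANSITION


def classify_substitution(ref_aa: str, alt_aa: str) -> str:
    """synonymous iff the residue is unchanged; nonsense iff a sense codon
    gains a stop; everything else (including stop-loss) is missense."""
    if ref_aa == alt_aa:
        return SYNONYMOUS
    if alt_aa == STOP:
        return NONSENSE
    return MISSENSE


@dataclass(frozen=True)
class SubstitutionEvent:
    """A single-nucleotide codon change, fully classified.

    ``codon_pos`` is 1-based within the codon in translation order; bases are
    coding-strand.
    """

    ref_codon: str
    alt_codon: str
    codon_pos: int
    ref_base: str
    alt_base: str
    ref_aa: str
    alt_aa: str
    functional_class: str
    is_transition: bool


def substitute(codon: str, codon_pos: int, alt_base: str) -> SubstitutionEvent:
    """Build the classified event for replacing position *codon_pos* (1-3)
    of *codon* with *alt_base*."""
    c = validate_codon(codon)
    if codon_pos not in (1, 2, 3):
        raise InvalidCodonError(f"codon_pos must be 1-3, got {codon_pos}")
    alt = _validate_base(alt_base)
    ref = c[codon_pos - 1]
    if alt == ref:
        raise InvalidCodonError(f"alt base {alt} equals the reference base")
    alt_codon = c[: codon_pos - 1] + alt + c[codon_pos:]
    ref_aa, alt_aa = GENETIC_CODE[c], GENETIC_CODE[alt_codon]
    return SubstitutionEvent(
        ref_codon=c,
        alt_codon=alt_codon,
        codon_pos=codon_pos,
        ref_base=ref,
        alt_base=alt,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        functional_class=classify_substitution(ref_aa, alt_aa),
        is_transition=is_transition(ref, alt),
    )


def enumerate_substitutions(codon: str) -> list[SubstitutionEvent]:
    """All 9 single-base substitutions of *codon* (3 positions x 3 alt
    bases), ordered by position then alt base alphabetically."""
    c = validate_codon(codon)
    return [
        substitute(c, pos, alt)
        for pos in (1, 2, 3)
        for alt in BASES
        if alt != c[pos - 1]
    ]


@dataclass
class SpaceSummary:
    """Aggregate of a codon family's single-nucleotide substitution space."""

    total_changes: int
    synonymous: int
    missense: int
    nonsense: int
    distinct_target_aas: int
    target_aa_counts: dict[str, int] = field(default_factory=dict)


def substitution_space(codons: Iterable[str]) -> SpaceSummary:
    """Aggregate ``enumerate_substitutions`` over a codon family.

    ``target_aa_counts`` counts missense targets only: stops and the source
    residue(s) are excluded.
    """
    codon_list = [validate_codon(c) for c in codons]
    if not codon_list:
        raise InvalidCodonError("empty codon family")
    events = [e for c in codon_list for e in enumerate_substitutions(c)]
    source_aas = {GENETIC_CODE[c] for c in codon_list}
    target_counts: dict[str, int] = {}
    n_syn = n_mis = n_non = 0
    for e in events:
        if e.functional_class == SYNONYMOUS:
            n_syn += 1
        elif e.functional_class == NONSENSE:
            n_non += 1
        else:
            n_mis += 1
        if e.alt_aa != STOP and e.alt_aa not in source_aas:
            target_counts[e.alt_aa] = target_counts.get(e.alt_aa, 0) + 1
    return SpaceSummary(
        total_changes=len(events),
        synonymous=n_syn,
        missense=n_mis,
        nonsense=n_non,
        distinct_target_aas=len(target_counts),
        target_aa_counts=dict(sorted(target_counts.items())),
    )


def synonymous_codons(residue: str) -> tuple[str, ...]:
    """All codons encoding *residue* (sorted)."""
    r = str(residue).upper()
    fam = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa == r))
    if not fam:
        raise InvalidCodonError(f"unknown residue {residue!r}")
    return fam


def first_position_synonymous_residues() -> frozenset[str]:
    """Residues with at least one synonymous single-base change at codon
    position 1, by brute-force scan of the 61 sense codons.

    Only two amino acids qualify genome-code-wide: arginine and leucine.
    """
    hits = set()
    for codon in SENSE_CODONS:
        for e in enumerate_substitutions(codon):
            if e.codon_pos == 1 and e.functional_class == SYNONYMOUS:
                hits.add(GENETIC_CODE[codon])
    return frozenset(hits)


def first_position_synonymous_codons(residue: str = "R") -> tuple[str, ...]:
    """Codons of *residue* admitting a synonymous change at position 1."""
    return tuple(
        sorted(
            c
            for c in synonymous_codons(residue)
            if any(
                e.functional_class == SYNONYMOUS and e.codon_pos == 1
                for e in enumerate_substitutions(c)
            )
        )
    )


def substitution_table(codons: Iterable[str] = ARGININE_CODONS) -> pd.DataFrame:
    """Full substitution table of a codon family as a tidy frame, one row
    per event (54 rows for arginine)."""
    rows = [
        {
            "ref_codon": e.ref_codon,
            "pos": e.codon_pos,
            "ref_base": e.ref_base,
            "alt_base": e.alt_base,
            "alt_codon": e.alt_codon,
            "ref_aa": e.ref_aa,
            "alt_aa": e.alt_aa,
            "class": e.functional_class,
            "transition": e.is_transition,
        }
        for c in codons
        for e in enumerate_substitutions(c)
    ]
    if not rows:
        raise InvalidCodonError("empty codon family")
    return pd.DataFrame(rows)


def write_substitution_table(path, codons: Iterable[str] = ARGININE_CODONS) -> None:
    substitution_table(codons).to_csv(path, sep="\t", index=False)
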