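"""Detection of genes with a skewed arginine substitution bias.

A gene is called *skewed* when at least 60% of its missense arginine
substitutions produce a single target residue, and at least 40 independent
tumor samples carry that dominant substitution.  Synonymous and nonsense
records are excluded from the denominator: neither produces an amino acid.
The per-gene report mirrors a driver-flagged table: dominant residue and its
fraction, the dominant nucleotide-change category (coding orientation, so
CGG->TGG reads as C>T) with its fraction, and the supporting sample count.

Ties in the dominant residue cannot reach the 60% threshold (two residues at
>=60% each would exceed 100%), so tied genes are never skewed; the
lexicographically first residue is reported for determinism and the tie is
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from . import genetic_code as gc
from .spectra import deduplicate

DEFAULT_MIN_FRACTION = 0.60
DEFAULT_MIN_SAMPLES = 40


@dataclass
class SkewRow:
    """Per-gene skew verdict over missense arginine substitutions."""

    gene_symbol: str
    residue_counts: dict[str, int]
    total_missense: int
    dominant_residue: str
    dominant_fraction: float
    dominant_nt_change: str
    dominant_nt_fraction: float
    supporting_samples: int  # unique samples carrying the dominant substitution
    samples_any: int  # unique samples with any missense arginine substitution
    is_skewed: bool
    is_driver: bool
    residue_tie: bool = False
    nt_tie: bool = False


def dominant_nt_change(gene_df: pd.DataFrame) -> tuple[str, float, bool]:
    """Most frequent of the 12 base-change categories among a gene's
    arginine missense records (coding orientation).

    Returns (category, fraction of the gene's arginine missense records,
    tie flag); ties break to the lexicographically first category.
    """
    if gene_df.empty:
        raise ValueError("no records for gene")
    changes = gene_df["ref_base"].str.cat(gene_df["alt_base"], sep=">")
    counts = changes.value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    return winners[0], top / len(gene_df), len(winners) > 1


def load_driver_list(path) -> frozenset[str]:
    """Read a driver-gene list: one symbol per line, '#' comments allowed."""
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def detect_skewed_genes(
    df: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    driver_genes: Iterable[str] = (),
    verbose: bool = False,
    dedup: bool = True,
) -> list[SkewRow]:
    """Scan annotated records for genes with a skewed arginine substitution
    bias.

    Only rows with ``ref_aa == 'R'`` and a missense outcome enter the
    denominator.  By default only qualifying genes are returned, sorted by
    dominant residue then gene symbol; ``verbose=True`` keeps every gene
    with at least one missense arginine record.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if min_samples < 0:
        raise ValueError(f"min_samples must be >= 0, got {min_samples}")
    drivers = frozenset(driver_genes)
    if df.empty:
        return []
    if dedup:
        df = deduplicate(df)
    arg = df[(df["ref_aa"] == "R") & (df["functional_class"] == gc.MISSENSE)]
    rows: list[SkewRow] = []
    for gene, gdf in arg.groupby("gene_symbol", sort=True):
        counts = gdf["alt_aa"].value_counts()
        total = int(counts.sum())
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        dominant = winners[0]
        tie = len(winners) > 1
        fraction = top / total
        carriers = int(gdf.loc[gdf["alt_aa"] == dominant, "sample_id"].nunique())
        nt_cat, nt_frac, nt_tie = dominant_nt_change(gdf)
        skewed = (not tie) and fraction >= min_fraction and carriers >= min_samples
        rows.append(
            SkewRow(
                gene_symbol=str(gene),
                residue_counts={k: int(v) for k, v in sorted(counts.items())},
                total_missense=total,
                dominant_residue=dominant,
                dominant_fraction=float(fraction),
                dominant_nt_change=nt_cat,
                dominant_nt_fraction=float(nt_frac),
                supporting_samples=carriers,
                samples_any=int(gdf["sample_id"].nunique()),
                is_skewed=skewed,
                is_driver=str(gene) in drivers,
                residue_tie=tie,
                nt_tie=nt_tie,
            )
        )
    if not verbose:
        rows = [r for r in rows if r.is_skewed]
    rows.sort(key=lambda r: (r.dominant_residue, r.gene_symbol))
    return rows


def skew_report_frame(rows: Iterable[SkewRow]) -> pd.DataFrame:
    """Tabular report with percentages at 2 decimals."""
    records = [
        {
            "gene_symbol": r.gene_symbol,
            "dominant_residue": r.dominant_residue,
            "dominant_residue_pct": round(100.0 * r.dominant_fraction, 2),
            "dominant_nt_change": r.dominant_nt_change,
            "dominant_nt_pct": round(100.0 * r.dominant_nt_fraction, 2),
            "total_missense": r.total_missense,
            "supporting_samples": r.supporting_samples,
            "samples_any": r.samples_any,
            "is_skewed": r.is_skewed,
            "driver_gene": "YES" if r.is_driver else "NO",
        }
        for r in rows
    ]
    columns = [
        "gene_symbol",
        "dominant_residue",
        "dominant_residue_pct",
        "dominant_nt_change",
        "dominant_nt_pct",
        "total_missense",
        "supporting_samples",
        "samples_any",
        "is_skewed",
        "driver_gene",
    ]
    return pd.DataFrame(records, columns=columns)


def write_skew_tsv(rows: Iterable[SkewRow], path) -> None:
    skew_report_frame(rows).to_csv(path, sep="\t", index=False)
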