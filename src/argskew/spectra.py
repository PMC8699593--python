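"""Mutation-spectrum tables for annotated somatic point mutations.

Covers the figure-style summaries of an arginine-centric reanalysis:

* the 12-category base-change spectrum (A>C ... T>G) and its fold onto the
  six pyrimidine-centric COSMIC classes;
* strand-specific C>T / G>A frequencies with a symmetry statistic;
* per-arginine-codon mutation shares against a reference codon-usage table;
* the amino-acid-by-source-codon substitution matrix (which codons feed
  His, Cys, Gln, Trp ...), with silent and stop outcomes kept as labeled
  columns and a grand-total row of nucleotide-change percentages;
* coding-vs-noncoding transition enrichment.

The counting unit everywhere is the mutation record after de-duplication on
(sample, chromosome, position, mutant allele), since one mutation can appear
in several rows of a COSMIC-like export.  Percentages are kept at full
precision internally and rounded only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetic_code as gc

#: the 12 ordered base changes
CATEGORIES_12 = [
    f"{r}>{a}" for r in gc.BASES for a in gc.BASES if r != a
]
#: the 6 pyrimidine-centric COSMIC classes
CATEGORIES_6 = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

DEDUP_KEY = ["sample_id", "chromosome", "position", "mut_allele"]

#: default non-cancer arginine codon usage (fractions): four codons are each
#: used ~20% of the time, CGA and CGT ~10%
DEFAULT_ARG_USAGE = {
    "AGA": 0.20,
    "AGG": 0.20,
    "CGA": 0.10,
    "CGC": 0.20,
    "CGG": 0.20,
    "CGT": 0.10,
}


class EmptyStreamError(ValueError):
    """Raised when a spectrum is requested on an empty record stream."""


def deduplicate(df: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate rows describing the same mutation in the same sample."""
    return df.drop_duplicates(subset=DEDUP_KEY, ignore_index=True)


def complement_category(category: str) -> str:
    r, a = category.split(">")
    return f"{gc.COMPLEMENT[r]}>{gc.COMPLEMENT[a]}"


@dataclass
class SpectrumTable:
    """Ordered category -> count table with derived percentages."""

    categories: list[str]
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        tot = self.total
        return {c: 100.0 * self.counts[c] / tot for c in self.categories}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "category": self.categories,
                "count": [self.counts[c] for c in self.categories],
                "percent": [pct[c] for c in self.categories],
            }
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame["percent"] = frame["percent"].round(2)
        frame.to_csv(path, sep="\t", index=False)


def _change_series(df: pd.DataFrame, orientation: str) -> pd.Series:
    if orientation == "coding":
        if "ref_base" not in df.columns:
            raise ValueError("coding orientation requires annotated records")
        return df["ref_base"].str.cat(df["alt_base"], sep=">")
    if orientation == "genomic":
        return df["wt_allele"].str.cat(df["mut_allele"], sep=">")
    raise ValueError(f"orientation must be 'coding' or 'genomic', got {orientation!r}")


def base_change_spectrum(
    df: pd.DataFrame,
    orientation: str = "coding",
    split12: bool = True,
    dedup: bool = True,
) -> SpectrumTable:
    """Base-change spectrum of a record stream.

    ``split12`` keeps the 12 strand-resolved categories; otherwise each
    purine-initiated change is folded onto its pyrimidine complement, giving
    the six COSMIC classes.
    """
    if df.empty:
        raise EmptyStreamError("no records to tabulate")
    if dedup:
        df = deduplicate(df)
    changes = _change_series(df, orientation)
    raw = changes.value_counts().to_dict()
    counts12 = {c: int(raw.get(c, 0)) for c in CATEGORIES_12}
    if split12:
        return SpectrumTable(categories=list(CATEGORIES_12), counts=counts12)
    counts6 = {
        c: counts12[c] + counts12[complement_category(c)] for c in CATEGORIES_6
    }
    return SpectrumTable(categories=list(CATEGORIES_6), counts=counts6)


def fold_to_six(table: SpectrumTable) -> SpectrumTable:
    """Fold a 12-category spectrum onto the 6 pyrimidine-centric classes;
    total count is conserved."""
    counts6 = {
        c: table.counts[c] + table.counts[complement_category(c)]
        for c in CATEGORIES_6
    }
    return SpectrumTable(categories=list(CATEGORIES_6), counts=counts6)


@dataclass
class StrandSpectrum:
    """Per-gene-strand counts of genomic C>T and G>A changes.

    ``ratios`` holds, per category, plus-strand count over minus-strand
    count -- approximately 1 when mutagenesis is strand-symmetric.
    """

    frame: pd.DataFrame
    ratios: dict[str, float]

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out["percent_plus"] = out["percent_plus"].round(2)
        out["percent_minus"] = out["percent_minus"].round(2)
        out.to_csv(path, sep="\t", index=False)


def strand_spectrum(df: pd.DataFrame, dedup: bool = True) -> StrandSpectrum:
    """Strand-specific C>T and G>A frequencies (genomic orientation, split
    by the strand of the mutated gene)."""
    if df.empty:
        raise EmptyStreamError("no records to tabulate")
    if dedup:
        df = deduplicate(df)
    changes = _change_series(df, "genomic")
    rows, ratios = [], {}
    for cat in ("C>T", "G>A"):
        on_cat = df[changes == cat]
        n_plus = int((on_cat["gene_strand"] == "+").sum())
        n_minus = int((on_cat["gene_strand"] == "-").sum())
        denom_plus = int((df["gene_strand"] == "+").sum())
        denom_minus = int((df["gene_strand"] == "-").sum())
        rows.append(
            {
                "category": cat,
                "count_plus": n_plus,
                "count_minus": n_minus,
                "percent_plus": 100.0 * n_plus / denom_plus if denom_plus else np.nan,
                "percent_minus": 100.0 * n_minus / denom_minus
                if denom_minus
                else np.nan,
            }
        )
        ratios[cat] = n_plus / n_minus if n_minus else np.inf
    return StrandSpectrum(frame=pd.DataFrame(rows), ratios=ratios)


def arginine_codon_shares(
    df: pd.DataFrame, usage: dict[str, float] | None = None, dedup: bool = True
) -> pd.DataFrame:
    """Share of arginine mutations attributed to each of the six codons,
    next to a non-cancer usage reference.

    Returns a frame indexed by codon with mutation_count,
    mutation_share_pct and usage_pct columns; both percentage columns sum
    to 100.
    """
    usage = dict(DEFAULT_ARG_USAGE if usage is None else usage)
    arg = df[df["ref_aa"] == "R"] if "ref_aa" in df.columns else df.iloc[0:0]
    if arg.empty:
        raise EmptyStreamError("no arginine records")
    if dedup:
        arg = deduplicate(arg)
    counts = arg["ref_codon"].value_counts()
    total_usage = sum(usage.values())
    out = pd.DataFrame(
        {
            "mutation_count": [int(counts.get(c, 0)) for c in gc.ARGININE_CODONS],
            "mutation_share_pct": [
                100.0 * counts.get(c, 0) / len(arg) for c in gc.ARGININE_CODONS
            ],
            "usage_pct": [
                100.0 * usage.get(c, 0.0) / total_usage for c in gc.ARGININE_CODONS
            ],
        },
        index=pd.Index(gc.ARGININE_CODONS, name="codon"),
    )
    return out


@dataclass
class AaBySourceCodon:
    """Substitution outcomes of the six arginine codons.

    ``counts`` rows are source codons, columns target residues plus the
    'silent' and 'stop' classes; ``percentages`` divides by the grand total;
    ``nt_change_pct`` is the 12-category base-change distribution over the
    same records (the figure's grand-total row).
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    nt_change_pct: pd.Series

    def to_tsv(self, path) -> None:
        pct = self.percentages.round(2)
        with open(path, "w") as fh:
            pct_out = pct.copy()
            pct_out.insert(0, "source_codon", pct_out.index)
            pct_out.to_csv(fh, sep="\t", index=False)
            fh.write("\n# grand total: nucleotide-change percentages\n")
            self.nt_change_pct.round(2).rename("percent").to_csv(fh, sep="\t")


def aa_by_source_codon(df: pd.DataFrame, dedup: bool = True) -> AaBySourceCodon:
    """Distribution of substitution outcomes by source arginine codon
    (missense targets by residue; synonymous and nonsense kept as 'silent'
    and 'stop')."""
    arg = df[df["ref_aa"] == "R"]
    if arg.empty:
        raise EmptyStreamError("no arginine records")
    if dedup:
        arg = deduplicate(arg)
    outcome = arg["alt_aa"].where(arg["functional_class"] == gc.MISSENSE)
    outcome = outcome.mask(arg["functional_class"] == gc.SYNONYMOUS, "silent")
    outcome = outcome.mask(arg["functional_class"] == gc.NONSENSE, "stop")
    residue_cols = sorted(set(outcome) - {"silent", "stop"})
    columns = residue_cols + ["silent", "stop"]
    counts = (
        pd.crosstab(arg["ref_codon"], outcome)
        .reindex(index=list(gc.ARGININE_CODONS), columns=columns, fill_value=0)
        .astype(int)
    )
    counts.index.name = "source_codon"
    total = counts.to_numpy().sum()
    percentages = 100.0 * counts / total
    nt = base_change_spectrum(arg, orientation="coding", split12=True, dedup=False)
    nt_pct = pd.Series(nt.percentages, name="percent")
    nt_pct.index.name = "category"
    return AaBySourceCodon(counts=counts, percentages=percentages, nt_change_pct=nt_pct)


@dataclass
class EnrichmentTable:
    """Transition percentages of three record streams and their ratios.

    Streams: arginine-codon records, all coding records, noncoding records.
    ``pct_CT_GA`` aggregates the two dominant transitions only;
    ``pct_transitions`` aggregates all four transition categories (both
    aggregations are reported since they answer different questions).
    """

    frame: pd.DataFrame
    ratios: dict[str, float | None]

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        for col in out.columns:
            if col != "stream":
                out[col] = out[col].round(2)
        out.to_csv(path, sep="\t", index=False)


def _stream_percentages(df: pd.DataFrame | None) -> dict[str, float] | None:
    if df is None or df.empty:
        return None
    spec = base_change_spectrum(df, orientation="genomic", split12=True)
    pct = spec.percentages
    transitions = sum(
        pct[c] for c in CATEGORIES_12 if gc.is_transition(*c.split(">"))
    )
    return {
        "pct_CT": pct["C>T"],
        "pct_GA": pct["G>A"],
        "pct_CT_GA": pct["C>T"] + pct["G>A"],
        "pct_transitions": transitions,
    }


def transition_enrichment(
    arginine_df: pd.DataFrame,
    coding_df: pd.DataFrame,
    noncoding_df: pd.DataFrame,
) -> EnrichmentTable:
    """Compare C>T / G>A transition loads across the arginine, all-coding
    and noncoding streams (genomic orientation, so the three streams are
    directly comparable).  Empty streams are flagged and their ratios
    reported as undefined (None)."""
    streams = {
        "arginine": _stream_percentages(arginine_df),
        "coding": _stream_percentages(coding_df),
        "noncoding": _stream_percentages(noncoding_df),
    }
    rows = []
    for name, pct in streams.items():
        row = {"stream": name}
        row.update(
            pct
            if pct is not None
            else {k: np.nan for k in ("pct_CT", "pct_GA", "pct_CT_GA", "pct_transitions")}
        )
        rows.append(row)

    def ratio(a, b, key):
        if a is None or b is None or not b[key]:
            return None
        return a[key] / b[key]

    ratios = {
        "arginine_vs_coding_CT": ratio(streams["arginine"], streams["coding"], "pct_CT"),
        "arginine_vs_coding_GA": ratio(streams["arginine"], streams["coding"], "pct_GA"),
        "coding_vs_noncoding_CT": ratio(streams["coding"], streams["noncoding"], "pct_CT"),
        "coding_vs_noncoding_GA": ratio(streams["coding"], streams["noncoding"], "pct_GA"),
        "coding_vs_noncoding_CT_GA": ratio(
            streams["coding"], streams["noncoding"], "pct_CT_GA"
        ),
        "coding_vs_noncoding_transitions": ratio(
            streams["coding"], streams["noncoding"], "pct_transitions"
        ),
    }
    return EnrichmentTable(frame=pd.DataFrame(rows), ratios=ratios)
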