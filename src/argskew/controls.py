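"""Control datasets for the arginine-substitution analysis.

Three controls put the arginine numbers in context:

* **coding control** -- per-residue percentages over *all* coding point
  mutations: a missense or stop-loss record is attributed to the residue it
  produced (alt residue), a silent record to its unchanged residue, and
  nonsense records to a separate 'stop' category (no residue results).
* **silent coding control** -- the same, restricted to synonymous records;
  the category is the (unchanged) residue the silent mutation codes for.
* **noncoding control** -- the 12-category base-change distribution of
  records that fall outside any CDS (genomic orientation; noncoding records
  carry no reading frame).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import genetic_code as gc
from .spectra import (
    CATEGORIES_12,
    EmptyStreamError,
    base_change_spectrum,
    deduplicate,
)

CODING = "coding"
SILENT_CODING = "silent_coding"
NONCODING = "noncoding"


@dataclass
class ControlTable:
    """Category -> numerator over a single shared denominator."""

    control_kind: str
    categories: list[str]
    numerators: dict[str, int]
    denominator: int

    @property
    def percentages(self) -> dict[str, float]:
        return {
            c: 100.0 * self.numerators[c] / self.denominator
            for c in self.categories
        }

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "category": self.categories,
                "count": [self.numerators[c] for c in self.categories],
                "percent": [pct[c] for c in self.categories],
            }
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame["percent"] = frame["percent"].round(2)
        frame.to_csv(path, sep="\t", index=False)


def _residue_outcomes(df: pd.DataFrame) -> pd.Series:
    outcome = df["alt_aa"].copy()
    outcome = outcome.mask(df["functional_class"] == gc.SYNONYMOUS, df["ref_aa"])
    outcome = outcome.mask(df["functional_class"] == gc.NONSENSE, "stop")
    return outcome


def coding_control(df: pd.DataFrame, dedup: bool = True) -> ControlTable:
    """Per-residue percentages over all coding point mutations.

    The denominator is every coding record (silent included); numerators
    attribute each record to its resulting residue ('stop' for nonsense).
    """
    if df.empty:
        raise EmptyStreamError("no coding records")
    if dedup:
        df = deduplicate(df)
    outcomes = _residue_outcomes(df)
    counts = outcomes.value_counts().to_dict()
    categories = sorted(set(counts) - {"stop"}) + (["stop"] if "stop" in counts else [])
    return ControlTable(
        control_kind=CODING,
        categories=categories,
        numerators={c: int(counts[c]) for c in categories},
        denominator=len(df),
    )


def silent_control(df: pd.DataFrame, dedup: bool = True) -> ControlTable:
    """Per-residue percentages over silent mutations only."""
    if dedup:
        df = deduplicate(df)
    silent = df[df["functional_class"] == gc.SYNONYMOUS]
    if silent.empty:
        raise EmptyStreamError("no silent records")
    counts = silent["ref_aa"].value_counts().to_dict()
    categories = sorted(counts)
    return ControlTable(
        control_kind=SILENT_CODING,
        categories=categories,
        numerators={c: int(counts[c]) for c in categories},
        denominator=len(silent),
    )


def noncoding_control(df: pd.DataFrame, dedup: bool = True) -> ControlTable:
    """12-category base-change percentages over noncoding point mutations."""
    if df.empty:
        raise EmptyStreamError("no noncoding records")
    spec = base_change_spectrum(df, orientation="genomic", split12=True, dedup=dedup)
    return ControlTable(
        control_kind=NONCODING,
        categories=list(CATEGORIES_12),
        numerators=dict(spec.counts),
        denominator=spec.total,
    )
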