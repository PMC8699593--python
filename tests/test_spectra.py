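"""Spectrum tables: folding, parameter recovery against binomial /
multinomial sampling oracles, and figure-level constraints."""

import numpy as np
import pandas as pd
import pytest

from argskew import genetic_code as gc
from argskew import spectra

from conftest import make_records


def _frame_from_categories(categories, strands=None):
    """Minimal record frame whose genomic changes are the given category
    strings (all rows unique under the dedup key)."""
    wt, mut = zip(*(c.split(">") for c in categories))
    n = len(categories)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "chromosome": "chr1",
            "position": np.arange(1, n + 1),
            "wt_allele": wt,
            "mut_allele": mut,
            "gene_strand": strands if strands is not None else ["+"] * n,
        }
    )


def test_single_record_spectrum():
    table = spectra.base_change_spectrum(
        _frame_from_categories(["C>T"]), orientation="genomic"
    )
    assert table.percentages["C>T"] == 100.0
    assert table.total == 1


def test_percentages_sum_to_100(annotated):
    table = spectra.base_change_spectrum(annotated, orientation="coding")
    assert sum(table.percentages.values()) == pytest.approx(100.0, abs=1e-9)


def test_folding_conserves_counts(annotated):
    twelve = spectra.base_change_spectrum(annotated, orientation="coding")
    six = spectra.fold_to_six(twelve)
    assert six.total == twelve.total
    for cat in spectra.CATEGORIES_6:
        comp = spectra.complement_category(cat)
        assert six.counts[cat] == twelve.counts[cat] + twelve.counts[comp]
    direct = spectra.base_change_spectrum(annotated, orientation="coding", split12=False)
    assert direct.counts == six.counts


def test_deduplication_is_the_counting_unit():
    df = _frame_from_categories(["C>T", "G>A"])
    dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    table = spectra.base_change_spectrum(dup, orientation="genomic")
    assert table.total == 2


def test_uniform_signature_recovered_within_3se():
    """n = 120,000 uniform draws over the 12 channels: each recovered
    percentage within 3 binomial SEs of 8.33%."""
    rng = np.random.default_rng(123)
    n = 120_000
    cats = [spectra.CATEGORIES_12[i] for i in rng.integers(12, size=n)]
    table = spectra.base_change_spectrum(
        _frame_from_categories(cats), orientation="genomic"
    )
    p = 1 / 12
    tol = 100 * 3 * np.sqrt(p * (1 - p) / n)
    for cat in spectra.CATEGORIES_12:
        assert table.percentages[cat] == pytest.approx(100 * p, abs=tol)


class TestStrandSpectrum:
    def test_all_plus_strand_degenerate(self):
        table = spectra.strand_spectrum(_frame_from_categories(["C>T", "G>A", "C>T"]))
        row = table.frame.set_index("category")
        assert row.loc["C>T", "count_minus"] == 0
        assert np.isinf(table.ratios["C>T"])

    def test_balanced_strands_ratio_near_one(self):
        rng = np.random.default_rng(7)
        n = 40_000
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        table = spectra.strand_spectrum(
            _frame_from_categories(["C>T"] * n, strands=list(strands))
        )
        se = np.sqrt(0.25 / n)
        p = table.frame.loc[0, "count_plus"] / n
        assert abs(p - 0.5) <= 3 * se

    def test_injected_two_to_one_bias_recovered(self):
        """Strand drawn Bernoulli(2/3): the recovered count ratio lies in
        the 3-SE band of the binomial oracle around 2."""
        rng = np.random.default_rng(19)
        n = 30_000
        strands = np.where(rng.random(n) < 2 / 3, "+", "-")
        table = spectra.strand_spectrum(
            _frame_from_categories(["G>A"] * n, strands=list(strands))
        )
        p0 = 2 / 3
        band = 3 * np.sqrt(p0 * (1 - p0) / n)
        lo, hi = (p0 - band) / (1 - p0 + band), (p0 + band) / (1 - p0 - band)
        assert lo <= table.ratios["G>A"] <= hi


class TestArginineCodonShares:
    def test_single_codon_share(self):
        df = make_records([("G1", f"S{i}", "CGC", 2, "A") for i in range(5)])
        shares = spectra.arginine_codon_shares(df)
        assert shares.loc["CGC", "mutation_share_pct"] == 100.0
        assert shares["mutation_share_pct"].sum() == pytest.approx(100.0)
        assert shares["usage_pct"].sum() == pytest.approx(100.0)

    def test_usage_proportional_placement_recovered(self):
        """Codons drawn from the usage weights are recovered within 3
        multinomial SEs at n = 20,000."""
        rng = np.random.default_rng(23)
        n = 20_000
        codons = list(spectra.DEFAULT_ARG_USAGE)
        weights = np.array(list(spectra.DEFAULT_ARG_USAGE.values()))
        draws = rng.choice(codons, size=n, p=weights / weights.sum())
        entries = [("G1", f"S{i}", c, 2, "A") for i, c in enumerate(draws)]
        shares = spectra.arginine_codon_shares(make_records(entries))
        for codon, p in spectra.DEFAULT_ARG_USAGE.items():
            tol = 100 * 3 * np.sqrt(p * (1 - p) / n)
            assert shares.loc[codon, "mutation_share_pct"] == pytest.approx(
                100 * p, abs=tol
            )

    def test_no_arginine_records_flagged(self):
        df = make_records([("G1", "S1", "GGA", 2, "A")])  # glycine codon
        with pytest.raises(spectra.EmptyStreamError):
            spectra.arginine_codon_shares(df)


class TestAaBySourceCodon:
    def test_single_trp_event(self):
        df = make_records([("G1", "S1", "CGG", 1, "T")])  # CGG -> TGG, R -> W
        matrix = spectra.aa_by_source_codon(df)
        assert matrix.counts.loc["CGG", "W"] == 1
        assert matrix.percentages.loc["CGG", "W"] == 100.0

    def test_his_only_from_cgc_cgt(self, annotated):
        matrix = spectra.aa_by_source_codon(annotated)
        if "H" in matrix.counts.columns:
            feeders = matrix.counts.index[matrix.counts["H"] > 0]
            assert set(feeders) <= {"CGC", "CGT"}

    def test_gln_only_from_cga_cgg(self, annotated):
        matrix = spectra.aa_by_source_codon(annotated)
        if "Q" in matrix.counts.columns:
            feeders = matrix.counts.index[matrix.counts["Q"] > 0]
            assert set(feeders) <= {"CGA", "CGG"}

    def test_grand_total_matches_base_change_spectrum(self, annotated):
        """The nucleotide-change row equals the 12-category spectrum of the
        arginine records."""
        matrix = spectra.aa_by_source_codon(annotated)
        arg = annotated[annotated["ref_aa"] == "R"]
        direct = spectra.base_change_spectrum(arg, orientation="coding")
        for cat in spectra.CATEGORIES_12:
            assert matrix.nt_change_pct[cat] == pytest.approx(direct.percentages[cat])

    def test_silent_and_stop_columns_present(self, annotated):
        matrix = spectra.aa_by_source_codon(annotated)
        assert {"silent", "stop"} <= set(matrix.counts.columns)
        assert matrix.percentages.to_numpy().sum() == pytest.approx(100.0)


class TestTransitionEnrichment:
    def test_identical_streams_unit_ratios(self, annotated):
        table = spectra.transition_enrichment(annotated, annotated, annotated)
        for value in table.ratios.values():
            assert value == pytest.approx(1.0)

    def test_empty_stream_flagged_undefined(self, annotated):
        empty = annotated.iloc[0:0]
        table = spectra.transition_enrichment(annotated, annotated, empty)
        assert table.ratios["coding_vs_noncoding_CT"] is None
        assert table.frame.set_index("stream").loc["noncoding"].isna().all()

    def test_two_fold_coding_transition_rate_recovered(self):
        """Coding stream simulated with doubled C>T weight vs noncoding:
        the C>T ratio is ~2 within 3 binomial SEs."""
        rng = np.random.default_rng(31)
        n = 50_000
        base = {c: 1.0 for c in spectra.CATEGORIES_12}
        hot = dict(base, **{"C>T": 2 * 11 / (11 - 2)})  # doubles the C>T share

        def draw(weights):
            cats = list(weights)
            p = np.array([weights[c] for c in cats], dtype=float)
            return [cats[i] for i in rng.choice(len(cats), size=n, p=p / p.sum())]

        coding = _frame_from_categories(draw(hot))
        noncoding = _frame_from_categories(draw(base))
        table = spectra.transition_enrichment(coding, coding, noncoding)
        p_cod = hot["C>T"] / sum(hot.values())
        p_non = 1 / 12
        expected = p_cod / p_non
        se = 3 * expected * np.sqrt(
            (1 - p_cod) / (p_cod * n) + (1 - p_non) / (p_non * n)
        )
        assert table.ratios["coding_vs_noncoding_CT"] == pytest.approx(
            expected, abs=se
        )

    def test_arginine_stream_with_extra_ct_weight(self):
        arg = _frame_from_categories(["C>T"] * 80 + ["C>A"] * 20)
        coding = _frame_from_categories(["C>T"] * 50 + ["C>A"] * 50)
        table = spectra.transition_enrichment(arg, coding, coding)
        assert table.ratios["arginine_vs_coding_CT"] > 1
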