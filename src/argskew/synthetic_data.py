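"""Self-contained synthetic study generator.

Emits a complete COSMIC-like study from one seeded configuration: a
reference FASTA with non-overlapping genes on two synthetic chromosomes, a
GFF3 gene model (CDS features with phase, including intron-split codons),
and a mutation CSV whose rows carry plus-strand alleles -- plus a ground-
truth manifest recording exactly what was injected, so every downstream
stage (annotation, spectra, controls, skew detection) can be validated
without any external download.

What it emulates: the COSMIC Mutation export's fields and point-mutation
classes (missense / nonsense / coding silent / noncoding), a configurable
12-category base-substitution signature (C>T / G>A dominant by default, as
in pan-cancer data), arginine codon usage weights seeded into gene bodies,
strand placement of genes, and per-gene injected arginine-substitution
skews with a known dominant residue, dominant fraction, and carrier-sample
count.

Construction guarantees worth knowing:

* every emitted record's wild-type allele matches the reference, so the
  annotator sees zero reference mismatches;
* (sample, chromosome, position, mutant allele) tuples are unique, so
  downstream de-duplication is a no-op and manifest counts equal pipeline
  counts exactly;
* background mutations are never placed inside genes named in
  ``skew_specs``, so each injected dominant fraction is construction-exact;
* the terminal stop codon of each gene is not mutagenized.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .codon_mapper import CSV_HEADER, GeneModel, MUTATION_COLUMNS
from .spectra import CATEGORIES_12, DEFAULT_ARG_USAGE

#: default 12-channel signature: C>T / G>A dominant, other transitions
#: modest, transversions uniform and rare
DEFAULT_SIGNATURE = {
    "A>C": 0.04,
    "A>G": 0.06,
    "A>T": 0.04,
    "C>A": 0.04,
    "C>G": 0.04,
    "C>T": 0.28,
    "G>A": 0.28,
    "G>C": 0.04,
    "G>T": 0.04,
    "T>A": 0.04,
    "T>C": 0.06,
    "T>G": 0.04,
}

_CLASS_LABEL = {
    gc.SYNONYMOUS: "coding silent",
    gc.MISSENSE: "missense",
    gc.NONSENSE: "nonsense",
}

BACKGROUND = "background"
NONCODING = "noncoding"
SKEW_DOMINANT = "skew_dominant"
SKEW_BACKGROUND = "skew_background"


class ConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SkewSpec:
    """One injected per-gene skew: *fraction* of the gene's missense
    arginine records hit *target_residue*, carried by *n_carriers* distinct
    samples."""

    gene_symbol: str
    target_residue: str
    fraction: float
    n_carriers: int

    def __post_init__(self):
        if not 0.5 < self.fraction <= 1.0:
            raise ConfigError(
                f"injected fraction must be in (0.5, 1], got {self.fraction}"
            )
        if self.n_carriers < 1:
            raise ConfigError("n_carriers must be >= 1")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic COSMIC-like dataset."""

    seed: int
    n_genes: int = 24
    codons_per_gene: int = 120
    fraction_minus_strand: float = 0.5
    arginine_fraction: float = 0.15
    arginine_codon_usage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARG_USAGE)
    )
    signature: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE)
    )
    n_samples: int = 400
    mutations_per_sample: float = 15.0
    noncoding_fraction: float = 0.25
    skew_specs: list[SkewSpec] = field(default_factory=list)
    intron_fraction: float = 0.25
    intron_length: int = 60
    spacer_length: int = 150
    n_chromosomes: int = 2
    #: emit genes in +/- pairs whose plus-strand genomic sequence is
    #: identical (the minus partner's CDS is the reverse complement), so the
    #: two strand groups have exactly equal mutable-site composition -- the
    #: clean null for strand-bias checks; overrides fraction_minus_strand
    strand_paired: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for name, weights, keys in (
            ("arginine_codon_usage", self.arginine_codon_usage, gc.ARGININE_CODONS),
            ("signature", self.signature, CATEGORIES_12),
        ):
            if any(w < 0 for w in weights.values()):
                raise ConfigError(f"{name}: negative weight")
            unknown = set(weights) - set(keys)
            if unknown:
                raise ConfigError(f"{name}: unknown keys {sorted(unknown)}")
            if sum(weights.values()) <= 0:
                raise ConfigError(f"{name}: all-zero weights")
        if self.codons_per_gene < 5:
            raise ConfigError("codons_per_gene must be >= 5")
        if self.strand_paired and self.n_genes % 2:
            raise ConfigError("strand_paired requires an even n_genes")
        if not 0 <= self.fraction_minus_strand <= 1:
            raise ConfigError("fraction_minus_strand must be in [0, 1]")
        for spec in self.skew_specs:
            if spec.n_carriers > self.n_samples:
                raise ConfigError(
                    f"{spec.gene_symbol}: n_carriers {spec.n_carriers} exceeds "
                    f"n_samples {self.n_samples}"
                )

    @classmethod
    def from_file(cls, path, **overrides) -> "SimulationConfig":
        """Build a config from a plain key=value text file.

        List-valued fields use compact syntax, e.g.
        ``signature = C>T:0.3,G>A:0.3,A>G:0.05,...`` and
        ``skew_specs = G001:H:0.7:70;G002:C:0.8:60``.
        Keyword *overrides* (e.g. from CLI flags) win over file values.
        """
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected key = value")
                key, value = (s.strip() for s in line.split("=", 1))
                raw[key] = value
        kwargs: dict = {}
        int_fields = {
            "seed", "n_genes", "codons_per_gene", "n_samples", "intron_length",
            "spacer_length", "n_chromosomes",
        }
        float_fields = {
            "fraction_minus_strand", "arginine_fraction", "mutations_per_sample",
            "noncoding_fraction", "intron_fraction",
        }
        for key, value in raw.items():
            if key in int_fields:
                kwargs[key] = int(value)
            elif key in float_fields:
                kwargs[key] = float(value)
            elif key in ("arginine_codon_usage", "signature"):
                kwargs[key] = {
                    k.strip(): float(v)
                    for k, v in (item.split(":") for item in value.split(","))
                }
            elif key == "skew_specs":
                specs = []
                for item in value.split(";"):
                    gene, res, frac, n = item.split(":")
                    specs.append(SkewSpec(gene, res, float(frac), int(n)))
                kwargs[key] = specs
            else:
                raise ConfigError(f"{path}: unknown config key {key!r}")
        kwargs.update(overrides)
        if "seed" not in kwargs:
            raise ConfigError(f"{path}: seed is mandatory")
        return cls(**kwargs)


@dataclass
class TruthManifest:
    """Ground truth of one simulated study; counts match the emitted CSV
    exactly."""

    signature_counts: dict[str, int]
    per_gene_outcomes: dict[str, dict[str, int]]
    skewed_genes: list[dict]
    provenance: list[str]
    n_records: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    reference: dict[str, str]
    models: dict[str, GeneModel]
    mutations: pd.DataFrame
    manifest: TruthManifest

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "reference.fa",
            "gff3": outdir / "genes.gff3",
            "csv": outdir / "mutations.csv",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.reference, paths["fasta"])
        write_gff3(self.models, self.reference, paths["gff3"])
        out = self.mutations.copy()
        out.columns = CSV_HEADER
        out.to_csv(paths["csv"], index=False)
        self.manifest.to_json(paths["manifest"])
        return paths


# ---------------------------------------------------------------------------
# reference generation


def _normalized(weights: dict[str, float], keys) -> np.ndarray:
    w = np.array([weights.get(k, 0.0) for k in keys], dtype=float)
    return w / w.sum()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(gc.BASES), size=length))


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, GeneModel]]:
    """Build the synthetic reference genome and gene models.

    Genes are placed non-overlapping with random spacers; each gene's CDS
    starts with ATG, ends with a stop codon, and its internal codons are
    arginine codons (drawn from the usage weights) with probability
    ``arginine_fraction``, otherwise uniform non-arginine sense codons.
    A configurable fraction of genes receives a single intron inserted at
    an offset that is not a multiple of 3, producing an intron-split codon;
    at least one gene always gets one.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes
    if config.strand_paired:
        minus_idx = set(range(1, n, 2))
    else:
        n_minus = int(round(n * config.fraction_minus_strand))
        minus_idx = set(rng.choice(n, size=n_minus, replace=False).tolist())
    has_intron = rng.random(n) < config.intron_fraction
    if not has_intron.any():
        has_intron[0] = True

    usage_p = _normalized(config.arginine_codon_usage, gc.ARGININE_CODONS)
    non_arg = [c for c in gc.SENSE_CODONS if gc.translate(c) != "R"]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    assemblies: dict[str, list[str]] = {c: [] for c in chrom_names}
    lengths: dict[str, int] = {c: 0 for c in chrom_names}
    models: dict[str, GeneModel] = {}

    prev: tuple[str, list[tuple[int, int]]] | None = None
    for i in range(n):
        name = f"G{i + 1:03d}"
        strand = "-" if i in minus_idx else "+"
        if config.strand_paired and i % 2 == 1:
            # minus-strand partner of gene i-1: its pre-mRNA is the reverse
            # complement, so the *plus-strand genomic* sequence of the two
            # gene bodies is identical and the strand groups have exactly
            # equal mutable-site composition
            prev_premrna, prev_exons = prev
            L = len(prev_premrna)
            premrna = gc.reverse_complement(prev_premrna)
            exons = [(L - b, L - a) for a, b in reversed(prev_exons)]
        else:
            n_internal = config.codons_per_gene - 2
            is_arg = rng.random(n_internal) < config.arginine_fraction
            internal = [
                str(rng.choice(gc.ARGININE_CODONS, p=usage_p))
                if flag
                else str(rng.choice(non_arg))
                for flag in is_arg
            ]
            coding = "ATG" + "".join(internal) + str(rng.choice(gc.STOP_CODONS))
            if has_intron[i]:
                codon_idx = int(rng.integers(1, config.codons_per_gene - 1))
                split = 3 * codon_idx + int(rng.integers(1, 3))  # not a codon boundary
                intron = _random_seq(rng, config.intron_length)
                premrna = coding[:split] + intron + coding[split:]
                exons = [(0, split), (split + config.intron_length, len(premrna))]
            else:
                premrna = coding
                exons = [(0, len(premrna))]
            prev = (premrna, exons)

        chrom = chrom_names[i % config.n_chromosomes]
        spacer = _random_seq(rng, config.spacer_length)
        g0 = lengths[chrom] + config.spacer_length + 1  # 1-based start of insert
        insert = premrna if strand == "+" else gc.reverse_complement(premrna)
        assemblies[chrom].extend([spacer, insert])
        lengths[chrom] += config.spacer_length + len(insert)

        if strand == "+":
            intervals = [(g0 + a, g0 + b - 1) for a, b in exons]
        else:
            L = len(premrna)
            intervals = [(g0 + L - b, g0 + L - 1 - a) for a, b in exons]
        models[name] = GeneModel(
            gene_symbol=name,
            chromosome=chrom,
            strand=strand,
            cds_intervals=intervals,
            phase=0,
        )

    for chrom in chrom_names:
        assemblies[chrom].append(_random_seq(rng, config.spacer_length))
        lengths[chrom] += config.spacer_length
    reference = {c: "".join(assemblies[c]) for c in chrom_names}
    return reference, models


def coding_sequence(reference: dict[str, str], model: GeneModel) -> str:
    """Reconstruct a gene's CDS in translation order from the reference."""
    chrom = reference[model.chromosome]
    if model.strand == "+":
        return "".join(chrom[p - 1] for p in model.coding_positions)
    return "".join(gc.COMPLEMENT[chrom[p - 1]] for p in model.coding_positions)


# ---------------------------------------------------------------------------
# mutation simulation


def _protein_change(event: gc.SubstitutionEvent, protein_pos: int) -> str:
    return f"p.{event.ref_aa}{protein_pos}{event.alt_aa}"


def _outcome_label(event: gc.SubstitutionEvent) -> str:
    if event.functional_class == gc.SYNONYMOUS:
        return "silent"
    if event.functional_class == gc.NONSENSE:
        return "stop"
    return event.alt_aa


def simulate_mutations(
    reference: dict[str, str],
    models: dict[str, GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthManifest]:
    """Simulate the mutation table and its ground-truth manifest.

    Background mutations are drawn from the 12-channel signature and placed
    uniformly among eligible sites whose plus-strand reference base matches
    the channel's source base (coding sites outside skew genes, or
    noncoding sites).  Injected skews place the exact codon changes that
    yield the target residue in the stated number of distinct carrier
    samples, topped up with non-target missense arginine changes so the
    dominant fraction is realized exactly.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    skew_genes = {s.gene_symbol for s in config.skew_specs}
    for s in config.skew_specs:
        if s.gene_symbol not in models:
            raise ConfigError(f"skew spec names unknown gene {s.gene_symbol!r}")

    coding_seqs = {g: coding_sequence(reference, m) for g, m in models.items()}

    # eligible background coding sites, keyed by plus-strand base
    coding_sites: dict[str, list[tuple[str, int, str, int]]] = {b: [] for b in gc.BASES}
    for gene, model in models.items():
        if gene in skew_genes:
            continue
        chrom = reference[model.chromosome]
        cp = model.coding_positions
        for idx, pos in enumerate(cp[:-3]):  # terminal stop codon untouched
            coding_sites[chrom[pos - 1]].append((gene, pos, model.chromosome, idx))

    # noncoding sites: every position not covered by any CDS interval
    covered: dict[str, set[int]] = {c: set() for c in reference}
    for model in models.values():
        covered[model.chromosome].update(model.coding_positions)
    nc_sites: dict[str, list[tuple[str, int]]] = {b: [] for b in gc.BASES}
    for chrom_name, seq in reference.items():
        cov = covered[chrom_name]
        for pos in range(1, len(seq) + 1):
            if pos not in cov:
                nc_sites[seq[pos - 1]].append((chrom_name, pos))

    sig_p = _normalized(config.signature, CATEGORIES_12)
    samples = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    per_sample = rng.poisson(config.mutations_per_sample, size=config.n_samples)
    total = int(per_sample.sum())
    sample_idx = np.repeat(np.arange(config.n_samples), per_sample)
    nc_flags = rng.random(total) < config.noncoding_fraction
    cat_draw = rng.choice(len(CATEGORIES_12), size=total, p=sig_p)

    rows: list[tuple] = []
    provenance: list[str] = []
    signature_counts: Counter[str] = Counter()
    per_gene_outcomes: dict[str, Counter] = {}
    seen: set[tuple[str, str, int, str]] = set()

    def emit(gene, transcript, sample, chrom_name, pos, strand, wt, alt, aa, klass, tag):
        rows.append(
            (gene, transcript, sample, chrom_name, pos, strand, wt, alt, aa, klass)
        )
        provenance.append(tag)

    for i in range(total):
        sample = samples[sample_idx[i]]
        category = CATEGORIES_12[cat_draw[i]]
        src, alt = category.split(">")
        pool = nc_sites[src] if nc_flags[i] else coding_sites[src]
        if not pool:
            continue  # no eligible site for this source base
        placed = False
        for _ in range(50):
            site = pool[int(rng.integers(len(pool)))]
            chrom_name, pos = (site[0], site[1]) if nc_flags[i] else (site[2], site[1])
            key = (sample, chrom_name, pos, alt)
            if key not in seen:
                seen.add(key)
                placed = True
                break
        if not placed:
            continue
        signature_counts[category] += 1
        if nc_flags[i]:
            emit("", "", sample, chrom_name, pos, "+",
                 reference[chrom_name][pos - 1], alt, "", "noncoding", NONCODING)
            continue
        gene, pos, chrom_name, idx = site
        model = models[gene]
        codon_idx, off = divmod(idx, 3)
        ref_codon = coding_seqs[gene][3 * codon_idx : 3 * codon_idx + 3]
        alt_coding = alt if model.strand == "+" else gc.COMPLEMENT[alt]
        event = gc.substitute(ref_codon, off + 1, alt_coding)
        per_gene_outcomes.setdefault(gene, Counter())[_outcome_label(event)] += 1
        emit(
            gene, f"T-{gene}", sample, chrom_name, pos, model.strand,
            reference[chrom_name][pos - 1], alt,
            _protein_change(event, codon_idx + 1), _CLASS_LABEL[event.functional_class],
            BACKGROUND,
        )

    skewed_truth: list[dict] = []
    for spec in config.skew_specs:
        model = models[spec.gene_symbol]
        cseq = coding_seqs[spec.gene_symbol]
        chrom = reference[model.chromosome]
        arg_codon_idx = [
            ci for ci in range(len(cseq) // 3)
            if gc.translate(cseq[3 * ci : 3 * ci + 3]) == "R"
        ]
        if not arg_codon_idx:
            raise ConfigError(f"{spec.gene_symbol}: no arginine codons in CDS")
        events_by_target: dict[str, list[tuple[int, gc.SubstitutionEvent]]] = {}
        for ci in arg_codon_idx:
            for ev in gc.enumerate_substitutions(cseq[3 * ci : 3 * ci + 3]):
                if ev.functional_class == gc.MISSENSE:
                    events_by_target.setdefault(ev.alt_aa, []).append((ci, ev))
        if spec.target_residue not in events_by_target:
            raise ConfigError(
                f"{spec.gene_symbol}: residue {spec.target_residue} unreachable "
                f"from its arginine codons; reachable: "
                f"{sorted(events_by_target)}"
            )

        def place(sample, choices, tag):
            for _ in range(200):
                ci, ev = choices[int(rng.integers(len(choices)))]
                idx = 3 * ci + ev.codon_pos - 1
                pos = model.coding_positions[idx]
                alt_plus = (
                    ev.alt_base if model.strand == "+" else gc.COMPLEMENT[ev.alt_base]
                )
                key = (sample, model.chromosome, pos, alt_plus)
                if key in seen:
                    continue
                seen.add(key)
                per_gene_outcomes.setdefault(spec.gene_symbol, Counter())[
                    _outcome_label(ev)
                ] += 1
                emit(
                    spec.gene_symbol, f"T-{spec.gene_symbol}", sample,
                    model.chromosome, pos, model.strand, chrom[pos - 1], alt_plus,
                    _protein_change(ev, ci + 1), _CLASS_LABEL[ev.functional_class],
                    tag,
                )
                return True
            return False

        carrier_ids = rng.choice(config.n_samples, size=spec.n_carriers, replace=False)
        dominant_choices = events_by_target[spec.target_residue]
        n_placed = sum(
            place(samples[j], dominant_choices, SKEW_DOMINANT) for j in carrier_ids
        )
        other_choices = [
            pair
            for target, pairs in events_by_target.items()
            if target != spec.target_residue
            for pair in pairs
        ]
        n_other_wanted = int(np.floor(n_placed * (1 - spec.fraction) / spec.fraction))
        if n_other_wanted and not other_choices:
            raise ConfigError(
                f"{spec.gene_symbol}: no non-target missense changes available"
            )
        n_other, attempts = 0, 0
        while n_other < n_other_wanted and attempts < 100 * max(n_other_wanted, 1):
            attempts += 1
            sample = samples[int(rng.integers(config.n_samples))]
            if place(sample, other_choices, SKEW_BACKGROUND):
                n_other += 1
        skewed_truth.append(
            {
                "gene_symbol": spec.gene_symbol,
                "target_residue": spec.target_residue,
                "injected_fraction": spec.fraction,
                "n_carriers": int(n_placed),
                "n_other_missense": n_other,
                "realized_fraction": n_placed / (n_placed + n_other),
            }
        )

    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    manifest = TruthManifest(
        signature_counts={c: int(signature_counts.get(c, 0)) for c in CATEGORIES_12},
        per_gene_outcomes={
            g: {k: int(v) for k, v in sorted(cnt.items())}
            for g, cnt in sorted(per_gene_outcomes.items())
        },
        skewed_genes=skewed_truth,
        provenance=provenance,
        n_records=len(df),
    )
    return df, manifest


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate reference, gene models, mutations and manifest from one
    seeded config (fully deterministic)."""
    rng = np.random.default_rng(config.seed)
    reference, models = generate_reference(config, rng)
    mutations, manifest = simulate_mutations(reference, models, config, rng)
    return SimulatedStudy(
        config=config,
        reference=reference,
        models=models,
        mutations=mutations,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# writers


def write_fasta(reference: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: dict[str, GeneModel], reference: dict[str, str], path) -> None:
    lines = ["##gff-version 3"]
    for chrom in sorted(reference):
        lines.append(f"##sequence-region {chrom} 1 {len(reference[chrom])}")
    feats = []
    for gene, model in models.items():
        cum = 0
        for k, (start, end) in enumerate(model.cds_intervals):  # transcription order
            phase = (3 - cum % 3) % 3 if k else model.phase
            feats.append((model.chromosome, start, end, model.strand, phase, gene, k))
            cum += end - start + 1
    feats.sort(key=lambda f: (f[0], f[1]))
    for chrom, start, end, strand, phase, gene, k in feats:
        attrs = f"ID=cds-{gene}-{k};gene_name={gene}"
        lines.append(
            "\t".join(
                [chrom, "argskew_sim", "CDS", str(start), str(end), ".", strand,
                 str(phase), attrs]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
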