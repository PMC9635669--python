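"""Seeded generators for every input the pipeline consumes, with truth.

The generator emulates the study's inputs: an AT-rich multi-chromosome
genome partitioned into recombination domains (arm/core/tip laid out as
tip|arm|core|arm|tip per chromosome at the genome-wide 45.7/47/7.3%
proportions) and chromatin-state blocks; gene models with exon/intron
structure; TA-motif-constrained Tc1 insertions with per-category rate
multipliers; caller outputs with configurable sensitivity, false-positive
rate and positional jitter; nested phenotype data with strain/line/
subline variance components; and Poisson-distributed droplet counts.

All randomness flows through a single :class:`numpy.random.Generator`;
identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ddpcr import DropletWell
from .genome import FeatureTrack, GenomeBuild, Interval, merge_intervals, write_bed
from .motif import TC1_MOTIF_8MER, scan_motif
from .te_calls import TECallSet

__all__ = [
    "CallerSpec",
    "PhenotypeDesign",
    "DropletDesign",
    "SimConfig",
    "SimGenome",
    "simulate_genome",
    "simulate_insertions",
    "simulate_caller_outputs",
    "simulate_phenotypes",
    "simulate_droplets",
    "simulate_ddpcr_wells",
    "write_dataset",
]

TC1_LENGTH_BP = 1610  # full-length Tc1 element span

# index of the T of the central TA inside the 8-mer AYATATRT
_MOTIF_T_OFFSET = 3


@dataclass
class CallerSpec:
    """Error model for one simulated TE caller."""

    name: str
    sensitivity: float = 0.9
    false_positive_rate: float = 0.05  # expected false calls per true insertion
    jitter_bp: int = 100
    calls_reference: bool = True

    def __post_init__(self):
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.false_positive_rate < 0 or self.jitter_bp < 0:
            raise ValueError("negative error rates")


def default_callers() -> list[CallerSpec]:
    """Five callers mirroring the study's ensemble; one (RetroSeq-like)
    does not call reference elements."""
    return [
        CallerSpec("ngs_te_mapper2"),
        CallerSpec("relocate"),
        CallerSpec("temp2"),
        CallerSpec("retroseq", calls_reference=False),
        CallerSpec("teflon"),
    ]


@dataclass
class PhenotypeDesign:
    """Nested strain/line/subline design with variance components.

    Defaults follow the fitness-assay design: 15 lines for the control
    strain, 20 per treatment strain, 5 sublines each; group effects
    emulate productivity-scale means, and the line/error components are
    on the scale of the published productivity mean squares.
    """

    group_effects: dict[str, float] = field(default_factory=lambda: {
        "N2": 308.7, "CB4851": 75.5, "RW6999": 106.9, "RW7000": 42.3,
    })
    lines_per_group: dict[str, int] = field(default_factory=lambda: {
        "N2": 15, "CB4851": 20, "RW6999": 20, "RW7000": 20,
    })
    sublines_per_line: int = 5
    sigma2_line: float = 145.0
    sigma2_error: float = 2533.0
    dropout: float = 0.0
    trait: str = "productivity"


@dataclass
class DropletDesign:
    """ddPCR well design: reference concentration and dilution factor."""

    n_droplets: int = 20_000
    lambda_reference: float = 0.5
    dilution_factor: float = 100.0
    copy_number: float = 600.0


@dataclass
class SimConfig:
    """Full study-conditions configuration for the generator."""

    chromosome_lengths: dict[str, int] = field(default_factory=lambda: {
        "chrI": 1_000_000, "chrII": 1_000_000, "chrIII": 1_000_000,
    })
    at_fraction: float = 0.64
    domain_proportions: dict[str, float] = field(default_factory=lambda: {
        "arm": 0.457, "core": 0.47, "tip": 0.073,
    })
    chromatin_proportions: dict[str, float] = field(default_factory=lambda: {
        "H3K27me3": 0.25, "H3K9me": 0.20, "dosage": 0.15,
        "promoter": 0.15, "active": 0.25,
    })
    chromatin_block_bp: int = 5_000
    gene_spacing_bp: int = 6_000
    exons_per_gene: int = 4
    exon_bp: int = 250
    intron_bp: int = 400
    n_insertions: int = 300
    insertion_mode: str = "motif_sites"  # or "uniform_bp"
    category_system: str = "chromatin"   # or "domain"
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    n_reference_elements: int = 30
    callers: list[CallerSpec] = field(default_factory=default_callers)
    phenotypes: PhenotypeDesign = field(default_factory=PhenotypeDesign)
    droplets: DropletDesign = field(default_factory=DropletDesign)
    strain: str = "simBergerac"

    def __post_init__(self):
        for name, props in (("domain", self.domain_proportions),
                            ("chromatin", self.chromatin_proportions)):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if not 0 < self.at_fraction <= 1:
            raise ValueError("at_fraction must be in (0, 1]")


@dataclass
class SimGenome:
    """Simulated genome with annotation tracks and the motif-site list."""

    seqs: dict[str, str]
    build: GenomeBuild
    domain_tracks: dict[str, FeatureTrack]
    chromatin_tracks: dict[str, FeatureTrack]
    exon_track: FeatureTrack
    intron_track: FeatureTrack
    motif_sites: list[Interval]  # 1-bp intervals at the T of each TA site

    def motif_site_positions(self) -> list[tuple[str, int]]:
        return [(iv.chrom, iv.start) for iv in self.motif_sites]


def simulate_genome(config: SimConfig, rng: np.random.Generator) -> SimGenome:
    """Generate sequence, domain/chromatin/gene tracks and motif sites.

    Bases are i.i.d. at the configured AT fraction (no dinucleotide
    structure). The motif-site list holds one 1-bp interval at the T of
    the central TA of every AYATATRT match.
    """
    at = config.at_fraction
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, str] = {}
    for chrom, length in config.chromosome_lengths.items():
        idx = rng.choice(4, size=length, p=p)
        seqs[chrom] = bases[idx].tobytes().decode("ascii")
    build = GenomeBuild({c: len(s) for c, s in seqs.items()})

    # domains: tip | arm | core | arm | tip, halving arm/tip per side
    dom_ivs: dict[str, list[Interval]] = {d: [] for d in config.domain_proportions}
    for chrom, length in config.chromosome_lengths.items():
        tip = config.domain_proportions["tip"] / 2
        arm = config.domain_proportions["arm"] / 2
        bounds = np.cumsum([tip, arm, config.domain_proportions["core"], arm, tip])
        cuts = [0] + [int(round(b * length)) for b in bounds]
        cuts[-1] = length
        for (s, e), name in zip(zip(cuts[:-1], cuts[1:]),
                                ("tip", "arm", "core", "arm", "tip")):
            if e > s:
                dom_ivs[name].append(Interval(chrom, s, e))
    domain_tracks = {d: merge_intervals(ivs, label=d) for d, ivs in dom_ivs.items()}

    # chromatin states: fixed-size blocks with i.i.d. state labels
    states = list(config.chromatin_proportions)
    probs = np.array([config.chromatin_proportions[s] for s in states])
    chrom_ivs: dict[str, list[Interval]] = {s: [] for s in states}
    for chrom, length in config.chromosome_lengths.items():
        n_blocks = -(-length // config.chromatin_block_bp)
        labels = rng.choice(len(states), size=n_blocks, p=probs)
        for b, lab in enumerate(labels):
            s = b * config.chromatin_block_bp
            e = min(s + config.chromatin_block_bp, length)
            chrom_ivs[states[lab]].append(Interval(chrom, s, e))
    chromatin_tracks = {s: merge_intervals(ivs, label=s) if ivs else FeatureTrack(s)
                        for s, ivs in chrom_ivs.items()}

    # gene models: genes at regular spacing, alternating exons/introns
    exons, introns = [], []
    gene_len = config.exons_per_gene * config.exon_bp + \
        (config.exons_per_gene - 1) * config.intron_bp
    for chrom, length in config.chromosome_lengths.items():
        pos = config.gene_spacing_bp
        while pos + gene_len < length:
            cursor = pos
            for e in range(config.exons_per_gene):
                exons.append(Interval(chrom, cursor, cursor + config.exon_bp))
                cursor += config.exon_bp
                if e < config.exons_per_gene - 1:
                    introns.append(Interval(chrom, cursor, cursor + config.intron_bp))
                    cursor += config.intron_bp
            pos += gene_len + config.gene_spacing_bp
    exon_track = merge_intervals(exons, label="exon") if exons else FeatureTrack("exon")
    intron_track = merge_intervals(introns, label="intron") if introns else FeatureTrack("intron")

    motif_sites = []
    for chrom, seq in seqs.items():
        for start in scan_motif(seq, TC1_MOTIF_8MER):
            t_pos = int(start) + _MOTIF_T_OFFSET
            motif_sites.append(Interval(chrom, t_pos, t_pos + 1, name="TA"))

    return SimGenome(
        seqs=seqs, build=build, domain_tracks=domain_tracks,
        chromatin_tracks=chromatin_tracks, exon_track=exon_track,
        intron_track=intron_track, motif_sites=motif_sites,
    )


def _category_tracks(genome: SimGenome, system: str) -> dict[str, FeatureTrack]:
    if system == "chromatin":
        return genome.chromatin_tracks
    if system == "domain":
        return genome.domain_tracks
    raise ValueError(f"unknown category system {system!r}")


def _site_categories(sites: list[Interval], tracks: dict[str, FeatureTrack]) -> list[str]:
    """Label each site with the first category whose track covers it."""
    from .genome import overlap_mask

    labels = ["none"] * len(sites)
    for name, track in tracks.items():
        for i, hit in enumerate(overlap_mask(sites, track)):
            if hit and labels[i] == "none":
                labels[i] = name
    return labels


def simulate_insertions(genome: SimGenome, config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Sample true insertions from motif sites with per-category bias.

    Returns the truth table (chrom, t_pos, category); every insertion
    sits at a TA site. Sampling is without replacement with weight =
    the configured multiplier of the site's category (default 1).
    In ``uniform_bp`` mode positions are drawn uniformly over the genome
    instead, to exercise the length-vs-motif exposure contrast.
    """
    tracks = _category_tracks(genome, config.category_system)
    if config.insertion_mode == "uniform_bp":
        lengths = np.array(list(config.chromosome_lengths.values()), dtype=float)
        chroms = list(config.chromosome_lengths)
        picks_chrom = rng.choice(len(chroms), size=config.n_insertions,
                                 p=lengths / lengths.sum())
        rows = []
        for ci in picks_chrom:
            pos = int(rng.integers(1, int(lengths[ci]) - 1))
            rows.append(Interval(chroms[ci], pos, pos + 1))
        cats = _site_categories(rows, tracks)
        return pd.DataFrame({
            "chrom": [iv.chrom for iv in rows],
            "t_pos": [iv.start for iv in rows],
            "category": cats,
        })
    if config.insertion_mode != "motif_sites":
        raise ValueError(f"unknown insertion_mode {config.insertion_mode!r}")

    sites = genome.motif_sites
    if len(sites) < config.n_insertions:
        raise ValueError(
            f"only {len(sites)} motif sites for {config.n_insertions} insertions"
        )
    cats = _site_categories(sites, tracks)
    weights = np.array([config.rate_multipliers.get(c, 1.0) for c in cats], dtype=float)
    if np.all(weights == 0):
        raise ValueError("all site weights are zero")
    probs = weights / weights.sum()
    chosen = rng.choice(len(sites), size=config.n_insertions, replace=False, p=probs)
    chosen.sort()
    return pd.DataFrame({
        "chrom": [sites[i].chrom for i in chosen],
        "t_pos": [sites[i].start for i in chosen],
        "category": [cats[i] for i in chosen],
    })


def simulate_reference_elements(genome: SimGenome, config: SimConfig,
                                rng: np.random.Generator) -> list[Interval]:
    """Full-length element spans at random TA sites (reference insertions)."""
    if config.n_reference_elements == 0:
        return []
    usable = [iv for iv in genome.motif_sites
              if iv.start + TC1_LENGTH_BP < genome.build.length(iv.chrom)]
    idx = rng.choice(len(usable), size=min(config.n_reference_elements, len(usable)),
                     replace=False)
    return [Interval(usable[i].chrom, usable[i].start,
                     usable[i].start + TC1_LENGTH_BP, name="reference")
            for i in sorted(idx)]


def simulate_caller_outputs(truth: pd.DataFrame, genome: SimGenome,
                            config: SimConfig, rng: np.random.Generator,
                            reference_elements: list[Interval] | None = None,
                            ) -> list[TECallSet]:
    """Emit per-caller call sets from the truth under each caller's
    sensitivity / false-positive / jitter model.

    Each true insertion is emitted independently per caller with
    probability = sensitivity; emitted positions get uniform jitter in
    [-jitter_bp, +jitter_bp] (clipped to the chromosome). False positives
    are placed at motif sites chosen uniformly at random, Poisson in
    number with mean false_positive_rate x n_true.
    """
    reference_elements = reference_elements or []
    n_true = len(truth)
    out = []
    for spec in config.callers:
        calls: list[Interval] = []
        detected = rng.random(n_true) < spec.sensitivity
        jitters = (rng.integers(-spec.jitter_bp, spec.jitter_bp + 1, size=n_true)
                   if spec.jitter_bp > 0 else np.zeros(n_true, dtype=int))
        for (row, det, jit) in zip(truth.itertuples(index=False), detected, jitters):
            if not det:
                continue
            pos = int(np.clip(row.t_pos + jit, 0, genome.build.length(row.chrom) - 2))
            calls.append(Interval(row.chrom, pos, pos + 1, name="nonreference"))
        n_fp = int(rng.poisson(spec.false_positive_rate * max(n_true, 1)))
        if n_fp > 0 and genome.motif_sites:
            fp_idx = rng.integers(0, len(genome.motif_sites), size=n_fp)
            for i in fp_idx:
                site = genome.motif_sites[i]
                calls.append(Interval(site.chrom, site.start, site.start + 1,
                                      name="nonreference"))
        ref_calls = []
        if spec.calls_reference:
            ref_detected = rng.random(len(reference_elements)) < spec.sensitivity
            ref_calls = [iv for iv, det in zip(reference_elements, ref_detected) if det]
        out.append(TECallSet(strain=config.strain, caller=spec.name,
                             nonreference=calls, reference=ref_calls))
    return out


def simulate_phenotypes(design: PhenotypeDesign, rng: np.random.Generator
                        ) -> pd.DataFrame:
    """Nested phenotype observations: y = group effect + line + error.

    Line effects are N(0, sigma2_line), subline errors N(0, sigma2_error);
    sublines drop out independently with the configured probability,
    producing the unequal-n designs the quasi-F machinery handles.
    """
    rows = []
    for group, effect in design.group_effects.items():
        n_lines = design.lines_per_group.get(group, 20)
        line_effects = rng.normal(0.0, np.sqrt(design.sigma2_line), size=n_lines)
        for li in range(n_lines):
            for si in range(design.sublines_per_line):
                if design.dropout > 0 and rng.random() < design.dropout:
                    continue
                value = effect + line_effects[li] + \
                    rng.normal(0.0, np.sqrt(design.sigma2_error))
                rows.append({
                    "strain": group,
                    "line": f"{group}_L{li + 1}",
                    "subline": f"S{si + 1}",
                    "trait": design.trait,
                    "value": value,
                })
    return pd.DataFrame(rows)


def simulate_droplets(lam: float, n_droplets: int, rng: np.random.Generator) -> int:
    """Positive-droplet count: Binomial(n, 1 - exp(-lambda))."""
    if lam < 0 or n_droplets <= 0:
        raise ValueError("need lambda >= 0 and n_droplets > 0")
    return int(rng.binomial(n_droplets, 1.0 - np.exp(-lam)))


def simulate_ddpcr_wells(design: DropletDesign, rng: np.random.Generator
                         ) -> tuple[DropletWell, DropletWell, dict[str, float]]:
    """Target and reference wells at matched molecule densities.

    The target well is diluted by the design's dilution factor, so its
    lambda is lambda_reference x copy_number / dilution_factor; the truth
    dict records both lambdas and the planted copy number.
    """
    lam_ref = design.lambda_reference
    lam_target = lam_ref * design.copy_number / design.dilution_factor
    target = DropletWell(
        target="Tc1",
        positives=simulate_droplets(lam_target, design.n_droplets, rng),
        total=design.n_droplets,
    )
    reference = DropletWell(
        target="daf-3",
        positives=simulate_droplets(lam_ref, design.n_droplets, rng),
        total=design.n_droplets,
    )
    truth = {"lambda_target": lam_target, "lambda_reference": lam_ref,
             "copy_number": design.copy_number}
    return target, reference, truth


def _config_to_dict(config: SimConfig) -> dict:
    return dataclasses.asdict(config)


def write_dataset(out_dir: str | Path, config: SimConfig, seed: int) -> dict:
    """Generate a complete dataset on disk in the formats the pipeline reads.

    Writes genome FASTA, annotation BEDs, motif-site BED, per-caller call
    BEDs, phenotype and droplet TSVs, the truth tables, and a YAML config
    echo with the seed. Returns a manifest of written paths.
    """
    from .genome import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = simulate_genome(config, rng)
    truth = simulate_insertions(genome, config, rng)
    ref_elements = simulate_reference_elements(genome, config, rng)
    callsets = simulate_caller_outputs(truth, genome, config, rng, ref_elements)
    pheno = simulate_phenotypes(config.phenotypes, rng)
    target, reference, ddpcr_truth = simulate_ddpcr_wells(config.droplets, rng)

    paths: dict[str, str] = {}
    write_fasta(genome.seqs, out / "genome.fa")
    paths["genome"] = "genome.fa"
    for name, track in {**genome.domain_tracks, **genome.chromatin_tracks,
                        "exon": genome.exon_track, "intron": genome.intron_track}.items():
        fn = f"track_{name}.bed"
        write_bed(track.intervals, out / fn)
        paths[f"track_{name}"] = fn
    write_bed(genome.motif_sites, out / "motif_sites.bed")
    paths["motif_sites"] = "motif_sites.bed"
    for cs in callsets:
        fn = f"calls_{cs.caller}.bed"
        write_bed(cs.nonreference + cs.reference, out / fn)
        paths[f"calls_{cs.caller}"] = fn
    truth.to_csv(out / "truth_insertions.tsv", sep="\t", index=False)
    paths["truth_insertions"] = "truth_insertions.tsv"
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    paths["phenotypes"] = "phenotypes.tsv"
    droplet_rows = pd.DataFrame([
        {"well": "target", "target": target.target, "positives": target.positives,
         "total": target.total},
        {"well": "reference", "target": reference.target,
         "positives": reference.positives, "total": reference.total},
    ])
    droplet_rows.to_csv(out / "droplets.tsv", sep="\t", index=False)
    paths["droplets"] = "droplets.tsv"
    echo = {"seed": seed, "config": _config_to_dict(config),
            "ddpcr_truth": ddpcr_truth}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
    paths["config"] = "config.yaml"
    return paths
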