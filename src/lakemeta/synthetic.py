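"""Synthetic stratified-lake communities with known ground truth.

Every downstream stage of the pipeline gets a generator that *inverts*
it: compartment-structured genome abundances across depth samples
(log-normal depths, breadth drawn clear of the 0.5 detection boundary),
planted per-genome marker complements with sub-threshold noise, protein
families with planted compartment enrichment, phage QC records whose
true triage class is guaranteed by rejection sampling against the rule
cascade, and nucleotide scaffolds with planted ORFs whose internal stop
codons are reassigned under genetic code 15 or 4.

A single integer seed drives one independent pseudo-random stream per
generator stage (stable CRC-based sub-seeding), so stages remain
reproducible when run alone.
"""

from __future__ import annotations

import zlib
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .phage import code_selection_from_sequence, triage, TriageStatus
from .records import (
    COMPARTMENT_ORDER,
    Compartment,
    CoverageRecord,
    FamilyMembership,
    GenomeRecord,
    LineageClass,
    MarkerHit,
    PathwayDefinition,
    PhageQCRecord,
    SampleRecord,
)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, stage))


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class CommunityConfig:
    """Shape of the synthetic depth series.

    Defaults give four compartments (oxygen maximum, interface, anoxic
    zone, sediment) of 30 genomes each with 3 samples per compartment —
    a desk-scale stand-in for a stratified-lake depth series.  Breadth
    ranges deliberately avoid the interval (0.3, 0.6) so planted
    presence is unambiguous under the breadth >= 0.5 detection rule.
    """

    n_compartments: int = 4
    samples_per_compartment: int = 3
    genomes_per_compartment: int = 30
    overlap_fraction: float = 0.2
    abundance_lognormal_mu: float = 1.0
    abundance_lognormal_sigma: float = 1.0
    breadth_present_range: tuple[float, float] = (0.6, 1.0)
    breadth_absent_range: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compartments < 1 or self.n_compartments > len(COMPARTMENT_ORDER):
            raise ValueError(f"n_compartments must be in [1, {len(COMPARTMENT_ORDER)}]")
        if self.genomes_per_compartment < 1:
            raise ValueError("need at least one genome per compartment")
        if self.samples_per_compartment < 1:
            raise ValueError("need at least one sample per compartment")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        for lo, hi in (self.breadth_present_range, self.breadth_absent_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("breadth ranges must be ordered sub-intervals of [0, 1]")
        if self.breadth_present_range[0] <= 0.5:
            raise ValueError(
                "breadth_present_range must start above the 0.5 detection "
                "threshold so planted presence is detectable"
            )
        if self.breadth_absent_range[1] >= 0.5:
            raise ValueError("breadth_absent_range must stay below the 0.5 threshold")

    @property
    def compartments(self) -> list[Compartment]:
        return COMPARTMENT_ORDER[: self.n_compartments]


@dataclass
class PlantedTruth:
    """Ground-truth labels for one synthetic dataset."""

    genome_compartments: dict[str, set[str]] = field(default_factory=dict)
    genome_pathways: dict[str, set[str]] = field(default_factory=dict)
    family_enrichment: dict[str, tuple[str | None, float]] = field(default_factory=dict)
    phage_class: dict[str, str] = field(default_factory=dict)
    scaffold_code: dict[str, int] = field(default_factory=dict)


#: synthetic marker-gene pathway table in the style of a curated
#: C1/carbon-fixation HMM set: per-model bit-score thresholds plus the
#: minimum number of distinct markers for a presence call (1 by default;
#: 2/3/2 for formate oxidation, CO oxidation, Wood-Ljungdahl)
DEFAULT_PATHWAY_DEFINITIONS: list[PathwayDefinition] = [
    PathwayDefinition("co_oxidation", {"coxL": 428.0, "coxM": 215.0, "coxS": 155.0}, 3),
    PathwayDefinition("formate_oxidation", {"fdhA": 370.0, "fdoG": 520.0}, 2),
    PathwayDefinition("wood_ljungdahl", {"acsB": 390.0, "cdhC": 280.0}, 2),
    PathwayDefinition("methanogenesis_mcr", {"mcrA": 450.0, "mcrB": 410.0, "mcrG": 170.0}, 1),
    PathwayDefinition("methanotrophy_pmo", {"pmoA": 205.0, "pmoB": 240.0, "pmoC": 180.0}, 1),
    PathwayDefinition("methylotrophy_mdh", {"mxaF": 315.0, "xoxF": 300.0}, 1),
    PathwayDefinition("reductive_tca", {"aclA": 480.0, "aclB": 330.0}, 1),
    PathwayDefinition("formaldehyde_h4mpt", {"fae": 120.0}, 1),
]

_PHYLUM_POOL = [
    "Actinobacteria", "Proteobacteria", "Bacteroidetes", "Chloroflexi",
    "Planctomycetes", "Verrucomicrobia", "Euryarchaeota", "Bipolaricaulota",
    "Saccharibacteria", "Pacearchaeota",
]

_DEPTH_BY_COMPARTMENT = {
    Compartment.OXYGEN_MAX: (10.0, 15.0, "m"),
    Compartment.INTERFACE: (50.0, 60.0, "m"),
    Compartment.ANOXIC: (60.0, 90.0, "m"),
    Compartment.SEDIMENT: (3.0, 58.0, "cm"),
}


# ---------------------------------------------------------------------------
# community
# ---------------------------------------------------------------------------

def simulate_community(
    config: CommunityConfig,
) -> tuple[list[GenomeRecord], list[SampleRecord], list[CoverageRecord], PlantedTruth]:
    """Generate a compartment-structured community with coverage tables.

    Each compartment owns ``genomes_per_compartment`` genomes; the first
    ``round(overlap_fraction * genomes_per_compartment)`` of them are
    additionally planted in the next-deeper compartment.  Present
    (genome, sample) pairs draw log-normal mean coverage and breadth
    from the present range; absent pairs get low residual coverage and
    breadth from the absent range.  Deterministic given the seed.
    """
    rng = _rng(config.seed, "community")
    comps = config.compartments
    truth = PlantedTruth()

    genomes: list[GenomeRecord] = []
    for ci, comp in enumerate(comps):
        n_overlap = round(config.overlap_fraction * config.genomes_per_compartment)
        for gi in range(config.genomes_per_compartment):
            gid = f"g_{comp.value}_{gi:03d}"
            present = {comp.value}
            if gi < n_overlap and ci + 1 < len(comps):
                present.add(comps[ci + 1].value)
            truth.genome_compartments[gid] = present
            lineage = str(rng.choice(["CPR", "DPANN", "other"], p=[0.15, 0.05, 0.80]))
            genomes.append(
                GenomeRecord(
                    genome_id=gid,
                    phylum=str(rng.choice(_PHYLUM_POOL)),
                    lineage_class=LineageClass(lineage),
                    completeness=float(rng.uniform(70.0, 100.0)),
                    redundancy=float(rng.uniform(0.0, 10.0)),
                )
            )

    samples: list[SampleRecord] = []
    for comp in comps:
        lo, hi, unit = _DEPTH_BY_COMPARTMENT[comp]
        depths = np.sort(rng.uniform(lo, hi, size=config.samples_per_compartment))
        for si, depth in enumerate(depths):
            samples.append(
                SampleRecord(f"s_{comp.value}_{si:02d}", round(float(depth), 1), unit, comp)
            )

    coverage: list[CoverageRecord] = []
    b_lo, b_hi = config.breadth_present_range
    a_lo, a_hi = config.breadth_absent_range
    for g in genomes:
        for s in samples:
            if s.compartment.value in truth.genome_compartments[g.genome_id]:
                cov = float(
                    rng.lognormal(config.abundance_lognormal_mu, config.abundance_lognormal_sigma)
                )
                breadth = float(rng.uniform(b_lo, b_hi))
            else:
                # residual cross-mapping signal, clearly below detection
                cov = float(rng.lognormal(config.abundance_lognormal_mu - 3.0, 0.5))
                breadth = float(rng.uniform(a_lo, a_hi))
            coverage.append(CoverageRecord(g.genome_id, s.sample_id, cov, breadth))
    return genomes, samples, coverage, truth


# ---------------------------------------------------------------------------
# marker hits
# ---------------------------------------------------------------------------

def plant_pathways(
    truth: PlantedTruth,
    defs: Iterable[PathwayDefinition] = DEFAULT_PATHWAY_DEFINITIONS,
    prob: float = 0.4,
    seed: int = 0,
) -> PlantedTruth:
    """Assign each genome a random pathway complement (independent
    Bernoulli per pathway)."""
    rng = _rng(seed, "plant_pathways")
    defs = list(defs)
    for gid in truth.genome_compartments:
        truth.genome_pathways[gid] = {
            d.pathway_id for d in defs if rng.random() < prob
        }
    return truth


def simulate_marker_hits(
    truth: PlantedTruth,
    defs: Iterable[PathwayDefinition] = DEFAULT_PATHWAY_DEFINITIONS,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[MarkerHit], dict[str, str]]:
    """Marker hits realizing the planted genome -> pathway truth.

    For each planted (genome, pathway) a random subset of at least
    ``min_markers`` of the pathway's models receives an above-threshold
    hit with E-value <= 1e-8.  ``noise`` is the per-(genome, model)
    probability of a spurious hit with a bit score strictly below the
    model threshold — it exercises the score screen without ever
    flipping a presence call.

    Returns the hit list and the protein -> genome map.
    """
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    rng = _rng(seed, "marker_hits")
    defs = {d.pathway_id: d for d in defs}
    hits: list[MarkerHit] = []
    protein_to_genome: dict[str, str] = {}
    counter = 0

    def emit(genome: str, model: str, score: float, evalue: float) -> None:
        nonlocal counter
        pid = f"{genome}|p{counter:05d}"
        counter += 1
        protein_to_genome[pid] = genome
        hits.append(MarkerHit(pid, model, round(score, 1), evalue))

    for genome in sorted(truth.genome_compartments):
        planted = truth.genome_pathways.get(genome, set())
        for pathway_id in sorted(planted):
            d = defs[pathway_id]
            models = sorted(d.marker_models)
            n = int(rng.integers(d.min_markers, len(models) + 1))
            chosen = rng.choice(models, size=n, replace=False)
            for model in sorted(chosen):
                thr = d.per_model_threshold[model]
                emit(genome, model, thr + rng.uniform(5.0, 50.0),
                     10.0 ** -rng.uniform(8.0, 20.0))
        if noise > 0:
            for d in defs.values():
                for model in sorted(d.marker_models):
                    if rng.random() < noise:
                        thr = d.per_model_threshold[model]
                        emit(genome, model, max(0.0, thr - rng.uniform(1.0, 20.0)),
                             10.0 ** -rng.uniform(2.0, 10.0))
    return hits, protein_to_genome


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

def simulate_family_table(
    genome_compartments: Mapping[str, Iterable[str]],
    n_families: int = 50,
    n_planted: int = 10,
    ratio: float = 5.0,
    base_freq: float = 0.15,
    seed: int = 0,
) -> tuple[list[FamilyMembership], dict[str, tuple[str | None, float]]]:
    """Protein-family table with planted compartment enrichment.

    Planted families have per-genome inclusion probability
    ``ratio * base_freq`` inside their target compartment and
    ``base_freq`` outside; null families use ``base_freq`` everywhere.
    Target compartments cycle through the compartment list.  Whenever a
    family's genome draw is non-empty, member proteins are padded to at
    least 6 so the family-size filter keeps it.
    """
    if ratio * base_freq > 1.0:
        raise ValueError(f"infeasible: ratio * base_freq = {ratio * base_freq} > 1")
    if n_planted > n_families:
        raise ValueError("n_planted exceeds n_families")
    rng = _rng(seed, "families")
    comp_of = {g: frozenset(c) for g, c in genome_compartments.items()}
    compartments = sorted(set().union(*comp_of.values()))
    genomes = sorted(comp_of)

    members: list[FamilyMembership] = []
    truth: dict[str, tuple[str | None, float]] = {}
    pcount = 0
    for fi in range(n_families):
        fam = f"fam{fi:04d}"
        if fi < n_planted:
            target = compartments[fi % len(compartments)]
            truth[fam] = (target, ratio)
        else:
            target = None
            truth[fam] = (None, 1.0)
        included = []
        for g in genomes:
            p = ratio * base_freq if (target is not None and target in comp_of[g]) else base_freq
            if rng.random() < p:
                included.append(g)
        fam_members = []
        for g in included:
            for _ in range(int(rng.integers(1, 3))):
                fam_members.append(FamilyMembership(fam, f"fp{pcount:06d}", g))
                pcount += 1
        idx = 0
        while fam_members and len(fam_members) < 6:  # keep past the >5-protein filter
            g = included[idx % len(included)]
            fam_members.append(FamilyMembership(fam, f"fp{pcount:06d}", g))
            pcount += 1
            idx += 1
        members.extend(fam_members)
    return members, truth


# ---------------------------------------------------------------------------
# phage records
# ---------------------------------------------------------------------------

_CLASS_NAMES = {s.value for s in TriageStatus}


def simulate_phage_records(
    n_per_class: Mapping[str, int], seed: int = 0
) -> tuple[list[PhageQCRecord], PlantedTruth]:
    """Phage QC records whose true class is certified by the rule cascade.

    Gene counts, provirus flags and lengths are drawn at random and
    rejection-sampled until the triage cascade — run as its own oracle —
    returns the requested class, so the planted label can never drift
    from the classifier's semantics.
    """
    unknown = set(n_per_class) - _CLASS_NAMES
    if unknown:
        raise ValueError(f"unknown triage classes: {sorted(unknown)}")
    rng = _rng(seed, "phage")
    records: list[PhageQCRecord] = []
    truth = PlantedTruth()
    idx = 0
    for cls in sorted(n_per_class):
        for _ in range(n_per_class[cls]):
            while True:
                rec = PhageQCRecord(
                    scaffold_id=f"phage{idx:04d}",
                    length=int(rng.integers(50_000, 300_001)),
                    viral_genes=int(rng.integers(0, 31)),
                    host_genes=int(rng.integers(0, 31)),
                    provirus_call=bool(rng.random() < 0.5),
                    complete_100=bool(rng.random() < 0.2),
                )
                if triage(rec).status.value == cls:
                    break
            records.append(rec)
            truth.phage_class[rec.scaffold_id] = cls
            idx += 1
    return records, truth


# ---------------------------------------------------------------------------
# alternatively coded scaffolds
# ---------------------------------------------------------------------------

_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: spacer unit with TAA stops in all six frames under every code
#: (TTAA is its own reverse complement as a repeat unit)
_SPACER_UNIT = "TTAA"

_REASSIGNED_STOP = {15: "TAG", 4: "TGA"}


def _make_orf(
    rng: np.random.Generator, n_codons: int, true_code: int, clean: bool = False
) -> str:
    codons = ["ATG"]
    body = [
        _SAFE_CODONS[int(rng.integers(len(_SAFE_CODONS)))] for _ in range(n_codons - 2)
    ]
    if not clean and true_code in _REASSIGNED_STOP:
        # in-frame read-through codons every 20-40 codons: translated
        # under the true code, premature stops under the standard code
        stop = _REASSIGNED_STOP[true_code]
        pos = int(rng.integers(20, 41))
        while pos < len(body) - 5:
            body[pos] = stop
            pos += int(rng.integers(20, 41))
    codons.extend(body)
    codons.append("TAA")
    return "".join(codons)


def simulate_coded_scaffold(
    length: int,
    true_code: int,
    orf_density: float = 0.9,
    seed: int = 0,
    min_orf_nt: int = 300,
    _verify: bool = True,
) -> str:
    """Nucleotide scaffold with planted ORFs in a chosen genetic code.

    ORFs (start ATG, stop TAA) are separated by stop-saturated spacers
    so the non-coding background calls no genes under any code.  For
    codes 15 and 4 the ORF bodies carry in-frame TAG / TGA read-through
    codons spaced so that standard-code translation truncates every ORF
    below the caller's minimum length; the coding-density gain of the
    true code over code 11 therefore far exceeds the 10% selection rule.
    """
    if length < 5000:
        raise ValueError("length must be >= 5000 to plant ORFs")
    if not 0.0 < orf_density <= 1.0:
        raise ValueError("orf_density must be in (0, 1]")
    if true_code not in (11, 15, 4):
        raise ValueError(f"unsupported genetic code {true_code}")

    for attempt in range(8):
        rng = _rng(seed + attempt, f"coded_scaffold_{true_code}")
        target_coding = int(orf_density * length)
        parts: list[str] = []
        coding = 0
        budget_left = length
        first = True
        while coding < target_coding and budget_left > 600:
            n_codons = int(rng.integers(150, 301))  # 450-900 nt
            # one clean ORF per scaffold keeps standard-code density
            # positive, as a stop-codon-free gene complement would
            orf = _make_orf(rng, n_codons, true_code, clean=first)
            first = False
            spacer = _SPACER_UNIT * int(rng.integers(3, 8))
            if len(orf) + len(spacer) > budget_left:
                break
            parts.append(spacer)
            parts.append(orf)
            coding += len(orf)
            budget_left -= len(orf) + len(spacer)
        tail = budget_left
        seq = "".join(parts) + (_SPACER_UNIT * (tail // 4 + 1))[:tail]
        assert len(seq) == length
        if not _verify:
            return seq
        sel = code_selection_from_sequence("check", seq, min_orf_nt=min_orf_nt)
        if sel.selected_code == true_code:
            return seq
    raise RuntimeError(
        f"could not realize a code-{true_code} scaffold at density {orf_density}"
    )


# ---------------------------------------------------------------------------
# marker protein sequence clusters
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_marker_sequences(
    n_groups: int = 5,
    members_per_group: int = 3,
    length: int = 200,
    within_identity: float = 0.995,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Amino-acid marker sequences forming clusters at controlled identity.

    Each group has a random founder; members differ from it at
    ``round((1 - within_identity) * length)`` positions.  Independent
    random founders sit near the ~5% background identity of unrelated
    proteins, far below any species-level threshold.  Returns
    (sequences, sequence -> group truth).
    """
    rng = _rng(seed, "marker_seqs")
    n_mut = round((1.0 - within_identity) * length)
    seqs: dict[str, str] = {}
    truth: dict[str, str] = {}
    for gi in range(n_groups):
        founder = "".join(rng.choice(list(_AA), size=length))
        for mi in range(members_per_group):
            sid = f"grp{gi}_m{mi}"
            seq = list(founder)
            if mi > 0 and n_mut > 0:
                pos = rng.choice(length, size=n_mut, replace=False)
                for p in pos:
                    choices = [a for a in _AA if a != seq[p]]
                    seq[p] = choices[int(rng.integers(len(choices)))]
            seqs[sid] = "".join(seq)
            truth[sid] = f"grp{gi}"
    return seqs, truth


# ---------------------------------------------------------------------------
# full bundle (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_simulation_bundle(out_dir: str | Path, config: CommunityConfig) -> None:
    """Generate and write the full labeled dataset as TSV/FASTA, with a
    ``truth/`` directory of ground-truth tables."""
    out = Path(out_dir)
    truth_dir = out / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    genomes, samples, coverage, truth = simulate_community(config)
    plant_pathways(truth, seed=seed)
    hits, protein_map = simulate_marker_hits(truth, noise=0.3, seed=seed)
    families, fam_truth = simulate_family_table(truth.genome_compartments, seed=seed)
    phage_records, phage_truth = simulate_phage_records(
        {"likely_virus": 10, "likely_provirus": 5, "discard": 5, "manual_curation": 5},
        seed=seed,
    )
    scaffolds = {}
    for code in (11, 15, 4):
        for i in range(3):
            sid = f"scaf_code{code}_{i}"
            scaffolds[sid] = simulate_coded_scaffold(8000, code, seed=seed + i)
            truth.scaffold_code[sid] = code

    io_formats.write_genome_table(genomes, out / "genomes.tsv")
    io_formats.write_sample_table(samples, out / "samples.tsv")
    io_formats.write_coverage_table(coverage, out / "coverage.tsv")
    io_formats.write_marker_hits(hits, out / "marker_hits.tsv")
    io_formats.write_pathway_definitions(
        DEFAULT_PATHWAY_DEFINITIONS, out / "pathway_definitions.tsv"
    )
    io_formats.write_family_table(families, out / "families.tsv")
    io_formats.write_phage_qc(phage_records, out / "phage_qc.tsv")
    io_formats.write_fasta(scaffolds, out / "scaffolds.fasta")
    with (out / "protein_map.tsv").open("w", encoding="utf-8") as fh:
        fh.write("protein_id\tgenome_id\n")
        for pid, gid in sorted(protein_map.items()):
            fh.write(f"{pid}\t{gid}\n")

    with (truth_dir / "genome_compartments.tsv").open("w", encoding="utf-8") as fh:
        fh.write("genome_id\tcompartments\n")
        for gid, comps in sorted(truth.genome_compartments.items()):
            fh.write(f"{gid}\t{','.join(sorted(comps))}\n")
    with (truth_dir / "genome_pathways.tsv").open("w", encoding="utf-8") as fh:
        fh.write("genome_id\tpathways\n")
        for gid, pws in sorted(truth.genome_pathways.items()):
            fh.write(f"{gid}\t{','.join(sorted(pws))}\n")
    with (truth_dir / "family_enrichment.tsv").open("w", encoding="utf-8") as fh:
        fh.write("family_id\ttarget_compartment\tratio\n")
        for fam, (comp, ratio) in sorted(fam_truth.items()):
            fh.write(f"{fam}\t{comp or ''}\t{ratio}\n")
    with (truth_dir / "phage_classes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("scaffold_id\ttrue_class\n")
        for sid, cls in sorted(phage_truth.phage_class.items()):
            fh.write(f"{sid}\t{cls}\n")
    with (truth_dir / "scaffold_codes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("scaffold_id\ttrue_code\n")
        for sid, code in sorted(truth.scaffold_code.items()):
            fh.write(f"{sid}\t{code}\n")
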