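"""Pathway presence calling and RuBisCO form classification.

Marker hits are screened by E-value, reduced to the best hit per
protein, then held to manually curated per-model bit-score thresholds.
A pathway is present in a genome when at least ``min_markers`` distinct
marker models pass (1 by default; 2/3/2 for formate oxidation, CO
oxidation and Wood-Ljungdahl).  Pathway abundance is the summed relative
coverage of encoding genomes, optionally aggregated by phylum and depth
compartment with a 1% phylum floor.

RuBisCO proteins are assigned to sequence forms (I, II, II/III, III) by
per-form HMM score cutoffs; the form III cutoff is lowered to 380.3 bits
to admit the divergent III-a form of methanogens.  Calvin-cycle capacity
is derived from form I/II assignments rather than from a marker-count
rule.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

from .community import detect_and_normalize
from .records import CoverageRecord, GenomeRecord, MarkerHit, PathwayDefinition

logger = logging.getLogger("lakemeta")

#: default E-value ceiling for annotation hits
MAX_EVALUE = 1e-6

#: lowered bit-score cutoff for the form III RuBisCO model, tuned on
#: divergent III-a reference sequences from methanogens
FORM_III_SCORE_THRESHOLD = 380.3

RUBISCO_FORMS = ("I", "II", "II/III", "III", "III-a", "III-b")

#: RuBisCO forms whose presence implies Calvin-cycle carbon fixation
CALVIN_FORMS = frozenset({"I", "II"})


@dataclass
class RubiscoAssignment:
    """Form call for one RuBisCO-encoding scaffold."""

    scaffold_id: str
    form: str = "unassigned"
    bitscore: float = 0.0
    taxonomy: str | None = None
    binned: bool = False
    length: int = 0


def _model_thresholds(defs: Iterable[PathwayDefinition]) -> dict[str, float]:
    thresholds: dict[str, float] = {}
    for d in defs:
        for model, thr in d.per_model_threshold.items():
            if model in thresholds and thresholds[model] != thr:
                raise ValueError(f"model {model!r} has conflicting thresholds across pathways")
            thresholds[model] = thr
    return thresholds


def filter_hits(
    hits: Iterable[MarkerHit],
    defs: Iterable[PathwayDefinition],
    max_evalue: float = MAX_EVALUE,
) -> list[MarkerHit]:
    """E-value screen, best-hit-per-protein reduction, then per-model
    score thresholds — in that order.

    The ordering matters: a protein whose single best hit fails its
    model's threshold contributes nothing, even if a weaker hit to a
    laxer model would have passed.  Hits against models not defined in
    any pathway are ignored with a warning.
    """
    defs = list(defs)
    thresholds = _model_thresholds(defs)
    best: dict[str, MarkerHit] = {}
    unknown: set[str] = set()
    for h in hits:
        if h.evalue > max_evalue:
            continue
        cur = best.get(h.protein_id)
        # deterministic tie-break on model id
        if cur is None or (h.bitscore, h.model_id) > (cur.bitscore, cur.model_id):
            best[h.protein_id] = h
    passing = []
    for h in best.values():
        thr = thresholds.get(h.model_id)
        if thr is None:
            unknown.add(h.model_id)
            continue
        if h.bitscore >= thr:
            passing.append(h)
    if unknown:
        logger.warning("ignored hits to %d undefined models: %s", len(unknown), sorted(unknown))
    return sorted(passing, key=lambda h: (h.protein_id, h.model_id))


def call_presence(
    passing_hits: Iterable[MarkerHit],
    defs: Iterable[PathwayDefinition],
    protein_to_genome: Mapping[str, str],
    genome_ids: Iterable[str],
) -> pd.DataFrame:
    """Boolean presence matrix (genome x pathway).

    A pathway is present when the genome has passing hits to at least
    ``min_markers`` *distinct* marker models of that pathway; hit
    multiplicity within one model does not count.
    """
    defs = list(defs)
    genome_ids = sorted(set(genome_ids))
    models_per_genome: dict[str, set[str]] = {}
    for h in passing_hits:
        genome = protein_to_genome.get(h.protein_id)
        if genome is None:
            logger.warning("passing hit for unmapped protein %s ignored", h.protein_id)
            continue
        models_per_genome.setdefault(genome, set()).add(h.model_id)
    data = {}
    for d in defs:
        col = []
        for g in genome_ids:
            found = models_per_genome.get(g, set()) & d.marker_models
            col.append(len(found) >= d.min_markers)
        data[d.pathway_id] = col
    return pd.DataFrame(data, index=pd.Index(genome_ids, name="genome_id"), dtype=bool)


def flag_methanogens(
    genomes: Iterable[GenomeRecord],
    presence: pd.DataFrame,
    mcr_pathway_id: str,
    lineage_list: Iterable[str] = (),
) -> dict[str, bool]:
    """Potential methane producers: genomes carrying the mcr operon
    pathway OR taxonomically affiliated with a known methanogenic
    lineage (some methanogen bins lack mcr through genome incompleteness)."""
    lineages = set(lineage_list)
    flags = {}
    for g in genomes:
        has_mcr = bool(
            mcr_pathway_id in presence.columns
            and g.genome_id in presence.index
            and presence.at[g.genome_id, mcr_pathway_id]
        )
        flags[g.genome_id] = has_mcr or g.phylum in lineages
    return flags


def aggregate_pathway_abundance(
    presence: pd.DataFrame, abundance: pd.DataFrame
) -> pd.DataFrame:
    """Summed relative coverage of pathway-encoding genomes, per sample
    (pathway x sample).  Genomes undetected in a sample contribute 0
    there even when they encode the pathway."""
    genomes = presence.index.intersection(abundance.index)
    p = presence.loc[genomes].astype(float)
    a = abundance.loc[genomes]
    return p.T @ a


def aggregate_by_phylum_compartment(
    presence: pd.DataFrame,
    abundance: pd.DataFrame,
    genome_phyla: Mapping[str, str],
    sample_compartments: Mapping[str, str],
    floor: float = 0.01,
    per_pathway_floor: bool = False,
) -> pd.DataFrame:
    """Pathway abundance by phylum and depth compartment.

    Per (pathway, phylum, sample): summed relative coverage of encoding
    genomes of that phylum; then the arithmetic mean over the samples of
    each compartment.  Phyla that never reach ``floor`` mean relative
    coverage in any compartment (for any pathway, unless
    ``per_pathway_floor``) are removed.

    Returns a long frame with columns pathway_id, phylum, compartment,
    mean_relative_coverage.
    """
    genomes = presence.index.intersection(abundance.index)
    rows = []
    phyla = pd.Series({g: genome_phyla.get(g, "") for g in genomes})
    comp_of = pd.Series(dict(sample_compartments))
    for pathway in presence.columns:
        encoders = presence.index[presence[pathway]].intersection(genomes)
        if len(encoders) == 0:
            continue
        sub = abundance.loc[encoders]
        by_phylum = sub.groupby(phyla.loc[encoders]).sum()  # phylum x sample
        comps = comp_of.reindex(by_phylum.columns)
        means = by_phylum.T.groupby(comps).mean().T  # phylum x compartment
        for phylum, row in means.iterrows():
            for compartment, value in row.items():
                rows.append((pathway, phylum, compartment, float(value)))
    long = pd.DataFrame(
        rows, columns=["pathway_id", "phylum", "compartment", "mean_relative_coverage"]
    )
    if long.empty:
        return long
    group_cols = ["pathway_id", "phylum"] if per_pathway_floor else ["phylum"]
    peak = long.groupby(group_cols)["mean_relative_coverage"].transform("max")
    return long[peak >= floor].reset_index(drop=True)


# ---------------------------------------------------------------------------
# RuBisCO
# ---------------------------------------------------------------------------

def assign_rubisco_form(
    scaffold_id: str,
    scores: Mapping[str, float],
    thresholds: Mapping[str, float],
    taxonomy: str | None = None,
    binned: bool = False,
    length: int = 0,
    subform_labels: Mapping[str, str] | None = None,
) -> RubiscoAssignment:
    """Assign a RuBisCO form from per-form model bit scores.

    Candidate forms are those whose score meets their threshold
    (inclusive); the highest-scoring candidate wins; no candidate means
    unassigned.  ``subform_labels`` optionally refines a form III call
    into III-a / III-b from a reference label table; without it the call
    is reported as plain III.
    """
    candidates = [
        (score, form)
        for form, score in scores.items()
        if form in thresholds and score >= thresholds[form]
    ]
    unknown = [f for f in scores if f not in thresholds]
    if unknown:
        logger.warning("%s: no threshold for forms %s; ignored", scaffold_id, sorted(unknown))
    if not candidates:
        return RubiscoAssignment(scaffold_id, "unassigned", 0.0, taxonomy, binned, length)
    score, form = max(candidates)
    if form == "III" and subform_labels and scaffold_id in subform_labels:
        form = subform_labels[scaffold_id]
    return RubiscoAssignment(scaffold_id, form, score, taxonomy, binned, length)


def select_rubisco_representatives(
    clusters: Mapping[str, Iterable[str]],
    binned: Mapping[str, bool],
    lengths: Mapping[str, int],
) -> dict[str, str]:
    """Representative scaffold per 95%-ANI cluster: a binned member when
    one exists (ties by length then id), else simply the longest."""
    reps = {}
    for cid, members in clusters.items():
        members = list(members)
        if not members:
            raise ValueError(f"cluster {cid!r} is empty")
        binned_members = [m for m in members if binned.get(m, False)]
        pool = binned_members or members
        reps[cid] = max(pool, key=lambda m: (lengths.get(m, 0), m))
    return reps


def rubisco_abundance(
    coverage: Iterable[CoverageRecord],
    scaffold_form: Mapping[str, str],
    scaffold_taxonomy: Mapping[str, str],
    sample_compartments: Mapping[str, str],
    deny_list: Iterable[str] = (),
    breadth_threshold: float = 0.5,
) -> pd.DataFrame:
    """Relative coverage of RuBisCO scaffolds by (phylum, form, compartment).

    Within each sample coverage is normalized over *present* RuBisCO
    scaffolds only (breadth >= 0.5), summed by (phylum, form), then
    averaged over the samples of each compartment.  Scaffolds on the
    deny list (e.g. flagged eukaryotic) are excluded from numerator and
    denominator alike.
    """
    deny = set(deny_list)
    kept = [r for r in coverage if r.entity_id not in deny]
    rel = detect_and_normalize(kept, breadth_threshold=breadth_threshold)
    if rel.empty:
        return pd.DataFrame(
            columns=["phylum", "form", "compartment", "mean_fraction"]
        )
    keys = pd.DataFrame(
        {
            "phylum": [scaffold_taxonomy.get(s, "") for s in rel.index],
            "form": [scaffold_form.get(s, "unassigned") for s in rel.index],
        },
        index=rel.index,
    )
    summed = rel.groupby([keys["phylum"], keys["form"]]).sum()
    comps = pd.Series(dict(sample_compartments)).reindex(summed.columns)
    means = summed.T.groupby(comps).mean().T
    long = (
        means.stack()
        .rename("mean_fraction")
        .reset_index()
        .rename(columns={"level_2": "compartment", "sample_id": "compartment"})
    )
    long.columns = ["phylum", "form", "compartment", "mean_fraction"]
    return long


def derive_calvin_presence(
    genome_forms: Mapping[str, Iterable[str]], calvin_forms: frozenset[str] = CALVIN_FORMS
) -> dict[str, bool]:
    """Calvin-cycle capacity per genome from RuBisCO form content: present
    iff the genome encodes a form I or II enzyme."""
    return {g: bool(set(forms) & calvin_forms) for g, forms in genome_forms.items()}


@dataclass
class PmoAmoPolicy:
    """Stand-in for phylogenetic curation of copper membrane monooxygenase
    hits: explicit allow/deny lists of (model, taxon) combinations decide
    whether a pmoA-like hit counts as methane monooxygenase."""

    deny_taxa: frozenset[str] = field(default_factory=frozenset)
    allow_taxa: frozenset[str] | None = None  # None == allow all not denied

    def accepts(self, taxon: str) -> bool:
        if taxon in self.deny_taxa:
            return False
        return self.allow_taxa is None or taxon in self.allow_taxa
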