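"""Marker-gene community profiling.

Builds species-level community units ("species groups") from ribosomal
protein S3 sequences, assigns consensus taxonomy from three evidence
lines, converts coverage/breadth tables into relative-coverage abundance
profiles, gates and dereplicates draft genomes, and ordains samples with
Bray-Curtis + principal coordinates analysis.

Conventions used throughout: every score/threshold comparison is
inclusive (``>=``); breadth-based detection requires breadth >= 0.5;
relative coverage of an entity is its mean depth divided by the summed
depth of all *detected* entities in the sample.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Callable, Iterable, Mapping
from collections import Counter

import numpy as np
import pandas as pd
from Bio import Align

from .records import CoverageRecord, GenomeRecord, MarkerHit, SpeciesGroup, TaxonomyEvidence

logger = logging.getLogger("lakemeta")

#: breadth at or above which an entity counts as detected in a sample
BREADTH_THRESHOLD = 0.5

#: default HMM alignment score cutoff for ribosomal protein S3 screening
RPS3_SCORE_THRESHOLD = 40.0


def screen_marker_sequences(
    hits: Iterable[MarkerHit], score_threshold: float = RPS3_SCORE_THRESHOLD
) -> set[str]:
    """Return protein ids whose marker-HMM bit score passes the cutoff."""
    return {h.protein_id for h in hits if h.bitscore >= score_threshold}


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global alignment of two sequences.

    Alignment scoring is match +1, mismatch 0, gap -1; the score is used
    only to pick the alignment — identity is exact matches divided by
    total alignment columns (gap columns included).
    """
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    return matches / len(sa)


def cluster_species_groups(
    sequences: Mapping[str, str],
    identity_threshold: float = 0.99,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
    scaffold_of: Mapping[str, str] | None = None,
) -> list[SpeciesGroup]:
    """Greedy centroid clustering of marker sequences into species groups.

    Sequences are processed longest-first (ties broken by id for
    determinism).  Each sequence joins the first existing centroid whose
    pairwise identity is >= ``identity_threshold``, otherwise it founds a
    new group.  The representative is the longest member; when two
    members come from the same scaffold (assembly fragmentation), only
    the longer fragment remains a representative candidate.

    ``identity_fn`` is an injection point for alternative identity
    definitions.
    """
    if not 0.0 <= identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in [0, 1]")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    centroids: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        seq = sequences[sid]
        for cid in centroids:
            if identity_fn(sequences[cid], seq) >= identity_threshold:
                members[cid].append(sid)
                break
        else:
            centroids.append(sid)
            members[cid := sid] = [sid]

    groups: list[SpeciesGroup] = []
    for i, cid in enumerate(centroids):
        mem = members[cid]
        candidates = list(mem)
        if scaffold_of is not None:
            by_scaffold: dict[str, str] = {}
            for m in sorted(mem, key=lambda sid: (-len(sequences[sid]), sid)):
                by_scaffold.setdefault(scaffold_of.get(m, m), m)
            candidates = list(by_scaffold.values())
        rep = max(candidates, key=lambda sid: (len(sequences[sid]), sid))
        groups.append(
            SpeciesGroup(
                group_id=f"sg{i:04d}",
                member_ids=mem,
                representative_protein_id=rep,
                representative_scaffold_id=(
                    scaffold_of.get(rep, rep) if scaffold_of is not None else rep
                ),
            )
        )
    return groups


def filter_short_representatives(
    lengths: Mapping[str, int], n_sd: float = 1.0, ddof: int = 1
) -> set[str]:
    """Drop representatives shorter than ``n_sd`` standard deviations below
    the mean length (sample SD by default).  With fewer than two
    sequences the SD is undefined and everything is retained."""
    if len(lengths) < 2:
        return set(lengths)
    values = np.array(list(lengths.values()), dtype=float)
    cutoff = values.mean() - n_sd * values.std(ddof=ddof)
    return {sid for sid, ln in lengths.items() if ln >= cutoff}


def scaffold_consensus_taxonomy(
    protein_hits: Iterable[tuple[str, float, float]],
    min_query_coverage: float = 0.70,
    max_evalue: float = 1e-10,
) -> str | None:
    """Modal phylum of a scaffold's per-protein reference hits.

    Each hit is (phylum, query_coverage, evalue); hits must already be
    best-per-protein.  Hits below 70% query coverage or above the
    E-value cutoff are ignored.  A tie for the mode (or no surviving
    hit) returns ``None`` — unresolved, to be escalated rather than
    silently picked.
    """
    surviving = [
        taxon
        for taxon, qcov, ev in protein_hits
        if qcov >= min_query_coverage and ev <= max_evalue
    ]
    if not surviving:
        return None
    counts = Counter(surviving).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return None
    return counts[0][0]


def consensus_taxonomy(evidence: TaxonomyEvidence) -> str | None:
    """Two-of-three consensus: if any two present evidence lines agree on a
    phylum, that phylum is final; otherwise unresolved (``None``)."""
    present = [t for t in evidence.lines() if t is not None]
    for a, b in itertools.combinations(present, 2):
        if a == b:
            return a
    return None


def coverage_frame(records: Iterable[CoverageRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot coverage records into aligned (coverage, breadth) matrices of
    shape entity x sample; missing pairs are treated as unobserved
    (coverage 0, breadth 0)."""
    recs = list(records)
    if not recs:
        empty = pd.DataFrame(dtype=float)
        return empty, empty.copy()
    df = pd.DataFrame(
        {
            "entity_id": [r.entity_id for r in recs],
            "sample_id": [r.sample_id for r in recs],
            "mean_coverage": [r.mean_coverage for r in recs],
            "breadth": [r.breadth for r in recs],
        }
    )
    cov = df.pivot_table(
        index="entity_id", columns="sample_id", values="mean_coverage", fill_value=0.0
    ).sort_index(axis=0).sort_index(axis=1)
    brd = df.pivot_table(
        index="entity_id", columns="sample_id", values="breadth", fill_value=0.0
    ).reindex(index=cov.index, columns=cov.columns, fill_value=0.0)
    return cov, brd


def detect_and_normalize(
    records: Iterable[CoverageRecord], breadth_threshold: float = BREADTH_THRESHOLD
) -> pd.DataFrame:
    """Relative-coverage abundance matrix (entity x sample, values in [0, 1]).

    An entity is *present* in a sample iff its breadth >= the threshold
    (0.5 by default, boundary inclusive).  Within each sample, present
    entities get mean_coverage divided by the summed mean coverage of
    all present entities; absent entities get 0.  Columns therefore sum
    to 1 wherever anything is detected, and to 0 otherwise.
    """
    cov, brd = coverage_frame(records)
    if cov.empty:
        return cov
    present = brd >= breadth_threshold
    masked = cov.where(present, 0.0)
    totals = masked.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = masked.div(totals.where(totals > 0), axis=1).fillna(0.0)
    return rel


def quality_gate(
    genomes: Iterable[GenomeRecord], min_completeness: float = 70.0
) -> list[GenomeRecord]:
    """Retain genomes with completeness >= ``min_completeness`` percent."""
    return [g for g in genomes if g.completeness >= min_completeness]


def marker_completeness(n_markers: int, n_present: int, n_duplicated: int) -> tuple[float, float]:
    """Completeness/redundancy percentages from marker-gene inventories:
    percent of expected single-copy markers present, and percent duplicated."""
    if n_markers <= 0:
        raise ValueError("marker set must be non-empty")
    return 100.0 * n_present / n_markers, 100.0 * n_duplicated / n_markers


def dereplicate(
    genomes: Iterable[GenomeRecord],
    pairwise_ani: Mapping[tuple[str, str], float],
    threshold: float = 95.0,
) -> dict[str, list[GenomeRecord]]:
    """Single-linkage dereplication of genomes at an ANI threshold.

    ``pairwise_ani`` maps (genome, genome) to percent identity; missing
    pairs are below threshold; entries given in both orientations must
    agree within 0.1.  Returns representative genome id -> cluster
    members.  The representative is the most complete member, ties
    broken by lower redundancy then lexicographic id.
    """
    genomes = list(genomes)
    by_id = {g.genome_id: g for g in genomes}
    for (g1, g2), ani in pairwise_ani.items():
        rev = pairwise_ani.get((g2, g1))
        if rev is not None and abs(rev - ani) > 0.1:
            raise ValueError(f"asymmetric ANI for ({g1}, {g2}): {ani} vs {rev}")

    parent = {g.genome_id: g.genome_id for g in genomes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (g1, g2), ani in pairwise_ani.items():
        if ani >= threshold and g1 in parent and g2 in parent:
            r1, r2 = find(g1), find(g2)
            if r1 != r2:
                parent[r2] = r1

    clusters: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        clusters.setdefault(find(g.genome_id), []).append(g)

    out: dict[str, list[GenomeRecord]] = {}
    for members in clusters.values():
        rep = min(members, key=lambda g: (-g.completeness, g.redundancy, g.genome_id))
        out[rep.genome_id] = sorted(members, key=lambda g: g.genome_id)
    return dict(sorted(out.items()))


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample columns of an abundance
    matrix: ``1 - 2 * sum(min(u, v)) / (sum(u) + sum(v))``.

    Two all-zero profiles are defined as identical (distance 0) so that
    empty samples do not propagate NaN into the ordination.
    """
    cols = list(matrix.columns)
    vals = matrix.to_numpy(dtype=float)
    n = len(cols)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u, v = vals[:, i], vals[:, j]
            denom = u.sum() + v.sum()
            d = 0.0 if denom == 0 else 1.0 - 2.0 * np.minimum(u, v).sum() / denom
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=cols, columns=cols)


def pcoa(distances: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical-scaling principal coordinates analysis.

    Double-centers ``-D**2 / 2``, eigendecomposes, and embeds samples on
    the top-``k`` non-negative eigenpairs.  Explained-variance fractions
    are eigenvalue / sum(positive eigenvalues); negative eigenvalues
    (semimetric distortion) are dropped from the embedding and logged.

    Returns (coordinates sample x axis, explained-variance fractions for
    the returned axes).
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    n_neg = int((eigvals < -1e-12).sum())
    if n_neg:
        logger.info("pcoa: dropped %d negative eigenvalues", n_neg)
    total = eigvals[pos].sum()
    keep = min(k, int(pos.sum()))
    coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep]) if keep else np.zeros((n, 0))
    explained = (eigvals[:keep] / total) if total > 0 else np.zeros(keep)
    frame = pd.DataFrame(
        coords, index=distances.index, columns=[f"PC{i + 1}" for i in range(keep)]
    )
    return frame, explained
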