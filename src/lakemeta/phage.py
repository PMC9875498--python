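"""Viral-scaffold triage, genetic-code selection and host assignment.

Candidate viral scaffolds >= 50 kb are classified from their viral/host
gene counts and provirus flag by an ordered rule cascade (first match
wins); each result records which rule fired, so borderline calls stay
auditable.  Scaffolds with >= 25% of annotated proteins affiliated with
eukaryotes are discarded.  Stop-codon reassignment (genetic codes 15 and
4, common in large phages) is detected by comparing coding density under
codes 11/15/4 and requiring a >= 10% density gain over the standard
code.  Host assignments from multiple methods are resolved by priority:
CRISPR targeting, then prophage flanking-region taxonomy, then gene
taxonomic profile.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .records import PhageQCRecord

#: triage applies to large phages only
MIN_TRIAGE_LENGTH = 50_000

#: relative coding-density gain required to accept an alternate code
CODE_GAIN_THRESHOLD = 0.10

#: stop codons per genetic code: 15 reads TAG as Gln, 4 reads TGA as Trp
STOP_CODONS = {
    11: frozenset({"TAA", "TAG", "TGA"}),
    15: frozenset({"TAA", "TGA"}),
    4: frozenset({"TAA", "TAG"}),
}

START_CODONS = frozenset({"ATG", "GTG", "TTG"})


class TriageStatus(str, Enum):
    LIKELY_VIRUS = "likely_virus"
    LIKELY_PROVIRUS = "likely_provirus"
    DISCARD = "discard"
    MANUAL_CURATION = "manual_curation"


@dataclass(frozen=True)
class TriageResult:
    scaffold_id: str
    status: TriageStatus
    rule_fired: str


class HostMethod(str, Enum):
    CRISPR = "crispr"
    PROPHAGE_CONTEXT = "prophage_context"
    GENE_PROFILE = "gene_profile"


_HOST_PRIORITY = [HostMethod.CRISPR, HostMethod.PROPHAGE_CONTEXT, HostMethod.GENE_PROFILE]


@dataclass(frozen=True)
class HostAssignment:
    scaffold_id: str
    host_taxon: str | None
    method: HostMethod
    conflict: bool = False


@dataclass
class CodeSelection:
    scaffold_id: str
    density_by_code: dict[int, float]
    selected_code: int


# Ordered triage cascade; first predicate returning True wins.
# host/viral are the upstream QC tool's "host gene" / "viral gene" counts.
_TRIAGE_RULES: Sequence[tuple[str, TriageStatus, object]] = (
    ("R1_no_host_5plus_viral", TriageStatus.LIKELY_VIRUS,
     lambda h, v, p: h == 0 and v >= 5),
    ("R2_viral_exceeds_host_no_provirus", TriageStatus.LIKELY_VIRUS,
     lambda h, v, p: h >= 1 and v > h and not p),
    ("R3_host_5x_viral_no_provirus", TriageStatus.DISCARD,
     lambda h, v, p: h >= 5 * v and not p),
    ("R4_host_5x_viral_provirus", TriageStatus.LIKELY_PROVIRUS,
     lambda h, v, p: h >= 5 * v and p),
    ("R5_viral_below_5x_host", TriageStatus.MANUAL_CURATION,
     lambda h, v, p: v < 5 * h),
    ("R6_no_viral_under_4_host", TriageStatus.MANUAL_CURATION,
     lambda h, v, p: v == 0 and h < 4),
)


def triage(record: PhageQCRecord) -> TriageResult:
    """Classify one candidate viral scaffold.

    Rules are evaluated in their stated order with first-match-wins
    semantics; gene-count combinations no rule covers fall back to
    manual curation so the mapping is total, and ``rule_fired`` exposes
    when that happened.  Scaffolds shorter than 50 kb are out of scope
    and rejected.
    """
    if record.length < MIN_TRIAGE_LENGTH:
        raise ValueError(
            f"{record.scaffold_id}: triage is defined for scaffolds >= "
            f"{MIN_TRIAGE_LENGTH} bp (got {record.length})"
        )
    h, v, p = record.host_genes, record.viral_genes, record.provirus_call
    for name, status, predicate in _TRIAGE_RULES:
        if predicate(h, v, p):
            return TriageResult(record.scaffold_id, status, name)
    return TriageResult(record.scaffold_id, TriageStatus.MANUAL_CURATION, "fallback_uncovered")


def eukaryote_filter(
    protein_taxa: Iterable[tuple[str, bool, bool]], threshold: float = 0.25
) -> bool:
    """Keep/discard decision from per-protein annotations.

    Each element is (protein_id, annotated, eukaryotic).  Returns True
    (keep) unless >= 25% of *annotated* proteins are affiliated with
    eukaryotes or eukaryotic viruses.  With no annotated proteins there
    is no evidence either way, and the scaffold is kept.
    """
    annotated = euk = 0
    for _pid, is_annotated, is_euk in protein_taxa:
        if is_annotated:
            annotated += 1
            if is_euk:
                euk += 1
    if annotated == 0:
        return True
    return (euk / annotated) < threshold


def coding_density(
    sequence_length: int, gene_intervals: Iterable[tuple[int, int]]
) -> float:
    """Fraction of bases covered by the union of gene intervals.

    Intervals are 0-based half-open and strand-collapsed: a base is
    coding if any gene on either strand covers it.
    """
    if sequence_length <= 0:
        raise ValueError("sequence_length must be positive")
    ivs = sorted(gene_intervals)
    covered = 0
    cur_start = cur_end = None
    for start, end in ivs:
        if start < 0 or end > sequence_length or start > end:
            raise ValueError(f"interval [{start}, {end}) outside sequence bounds")
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered / sequence_length


def select_genetic_code(
    scaffold_id: str,
    densities: Mapping[int, float],
    gain_threshold: float = CODE_GAIN_THRESHOLD,
    absolute: bool = False,
) -> CodeSelection:
    """Pick the genetic code whose gene predictions best explain a scaffold.

    An alternate code (15 or 4) is accepted only if its coding density
    exceeds the standard-code density by ``gain_threshold`` — read as a
    *relative* gain (x1.10) by default; ``absolute=True`` switches to
    +10 percentage points.  Among qualifying alternates the denser wins,
    ties going to code 15.  Otherwise the standard code 11 is retained.
    """
    for code in (11, 15, 4):
        if code not in densities:
            raise ValueError(f"{scaffold_id}: missing density for code {code}")
    d11 = densities[11]
    if d11 > 0:
        cutoff = d11 + gain_threshold if absolute else (1.0 + gain_threshold) * d11
        qualifying = [c for c in (15, 4) if densities[c] >= cutoff]
    else:
        # degenerate: no standard-code genes at all — any code that finds
        # genes beats it (the relative rule would admit density 0)
        qualifying = [c for c in (15, 4) if densities[c] > 0]
    if not qualifying:
        selected = 11
    else:
        # ties break toward 15 because max() keeps the first maximum
        selected = max(qualifying, key=lambda c: (densities[c], c == 15))
    return CodeSelection(scaffold_id, dict(densities), selected)


def resolve_host(candidates: Iterable[HostAssignment]) -> HostAssignment | None:
    """Resolve multi-method host predictions for one scaffold by method
    priority (CRISPR > prophage context > gene profile).  Conflicting
    taxa *within* the winning method yield an unassigned result with the
    conflict flag set.  No candidates -> None."""
    candidates = list(candidates)
    if not candidates:
        return None
    sid = candidates[0].scaffold_id
    for method in _HOST_PRIORITY:
        taxa = sorted({c.host_taxon for c in candidates if c.method == method and c.host_taxon})
        if len(taxa) == 1:
            return HostAssignment(sid, taxa[0], method)
        if len(taxa) > 1:
            return HostAssignment(sid, None, method, conflict=True)
    return None


def size_class_report(
    records: Iterable[PhageQCRecord],
    abundance: pd.DataFrame,
    classes: Sequence[int] = (50_000, 100_000),
) -> pd.DataFrame:
    """Per-size-class detection table for phage scaffolds.

    For every class minimum length, every member scaffold and every
    sample: presence (nonzero relative coverage under the breadth rule
    already encoded in ``abundance``), the relative coverage itself, and
    the circularity flag (100% completeness via terminal repeats implies
    a circularized genome).
    """
    rows = []
    recs = list(records)
    for min_len in classes:
        for rec in recs:
            if rec.length < min_len:
                continue
            for sample in abundance.columns:
                rel = (
                    float(abundance.at[rec.scaffold_id, sample])
                    if rec.scaffold_id in abundance.index
                    else 0.0
                )
                rows.append(
                    (min_len, rec.scaffold_id, sample, rel > 0.0, rel, rec.complete_100)
                )
    return pd.DataFrame(
        rows,
        columns=["min_length", "scaffold_id", "sample_id", "present",
                 "relative_coverage", "circular"],
    )


# ---------------------------------------------------------------------------
# bundled ORF scanner (used for synthetic code-selection tests; real
# pipelines inject gene intervals from a dedicated gene caller)
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _frame_orfs(seq: str, offset: int, stops: frozenset[str], min_orf_nt: int):
    """Yield [start, end) ORF intervals for one forward reading frame."""
    start = None
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in stops:
            if start is not None and (i + 3 - start) >= min_orf_nt:
                yield (start, i + 3)
            start = None
        elif start is None and codon in START_CODONS:
            start = i
    # open ORFs running off the end are not reported


def find_gene_intervals(
    sequence: str, code: int, min_orf_nt: int = 300
) -> list[tuple[int, int]]:
    """Longest-ORF gene caller for one genetic code.

    Scans all six frames for start(ATG/GTG/TTG)-to-stop ORFs of at least
    ``min_orf_nt`` bases under the code's stop-codon table, and returns
    0-based half-open intervals in forward-strand coordinates.
    """
    if code not in STOP_CODONS:
        raise ValueError(f"unsupported genetic code {code}")
    seq = sequence.upper()
    stops = STOP_CODONS[code]
    intervals: list[tuple[int, int]] = []
    for offset in range(3):
        intervals.extend(_frame_orfs(seq, offset, stops, min_orf_nt))
    rc = seq.translate(_COMPLEMENT)[::-1]
    n = len(seq)
    for offset in range(3):
        for s, e in _frame_orfs(rc, offset, stops, min_orf_nt):
            intervals.append((n - e, n - s))
    return sorted(intervals)


def code_selection_from_sequence(
    scaffold_id: str,
    sequence: str,
    min_orf_nt: int = 300,
    gain_threshold: float = CODE_GAIN_THRESHOLD,
    absolute: bool = False,
) -> CodeSelection:
    """Convenience path: call ORFs under codes 11/15/4 with the bundled
    scanner, compute densities, and select the code."""
    densities = {
        code: coding_density(len(sequence), find_gene_intervals(sequence, code, min_orf_nt))
        for code in (11, 15, 4)
    }
    return select_genetic_code(scaffold_id, densities, gain_threshold, absolute)
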