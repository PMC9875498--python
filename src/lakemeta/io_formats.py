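"""Readers and writers for every external table the pipeline touches.

The canonical interchange format is headered, UTF-8, tab-separated text;
lines starting with ``#`` are comments everywhere.  Marker hits are
additionally accepted in hmmsearch ``--tblout`` layout.  All readers
validate aggressively and report offending line numbers, because silent
coercion of upstream-tool output is the classic source of wrong-but-
plausible community profiles.
"""

from __future__ import annotations

import logging
import sys
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
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

logger = logging.getLogger("lakemeta")


class ParseError(ValueError):
    """Raised when an input table violates its contract; message names the
    file and, where possible, the 1-based line number."""


def setup_logging(level: str = "INFO") -> None:
    """Configure timestamped logging to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# marker hits (hmmsearch-style)
# ---------------------------------------------------------------------------

def read_marker_hits(path: str | Path) -> list[MarkerHit]:
    """Read hmmsearch-style tabular hits.

    Two layouts are accepted, distinguished by column count:

    * compact 4-column: ``target model evalue score``
    * hmmsearch ``--tblout`` (>= 6 columns): target name in column 1,
      query/model name in column 3, full-sequence E-value and score in
      columns 5 and 6.

    Comment lines start with ``#``.  Malformed rows raise :class:`ParseError`
    naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[MarkerHit] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 4:
                target, model, ev_s, score_s = fields
            elif len(fields) >= 6:
                target, model = fields[0], fields[2]
                ev_s, score_s = fields[4], fields[5]
            else:
                raise ParseError(f"{path}:{lineno}: expected 4 or >=6 columns, got {len(fields)}")
            try:
                evalue = float(ev_s)
                bitscore = float(score_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score/e-value ({exc})") from None
            try:
                hits.append(MarkerHit(target, model, bitscore, evalue))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_marker_hits(hits: Iterable[MarkerHit], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# target model evalue score\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.model_id}\t{h.evalue:g}\t{h.bitscore:g}\n")


# ---------------------------------------------------------------------------
# generic headered-TSV helpers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=required)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _num(df: pd.DataFrame, col: str, path: str | Path) -> pd.Series:
    try:
        return df[col].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value in column {col!r} ({exc})") from None


def _bool(series: pd.Series) -> pd.Series:
    return series.str.strip().str.lower().isin(("true", "1", "yes", "t"))


# ---------------------------------------------------------------------------
# coverage tables
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path) -> list[CoverageRecord]:
    """Read a coverage-summary TSV (columns ``entity_id``, ``sample_id``,
    ``mean_coverage``, ``breadth``).

    The breadth dialect is auto-detected per file: if any value exceeds 1
    the whole column is treated as percent and divided by 100, otherwise
    it is already fractional.  Duplicate (entity, sample) keys are an
    error — they would silently double coverage downstream.
    """
    df = _read_tsv(path, ["entity_id", "sample_id", "mean_coverage", "breadth"])
    if df.empty:
        return []
    dup = df.duplicated(subset=["entity_id", "sample_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate (entity, sample) key "
            f"({first['entity_id']}, {first['sample_id']})"
        )
    cov = _num(df, "mean_coverage", path)
    breadth = _num(df, "breadth", path)
    if (breadth > 100).any() or (breadth < 0).any():
        raise ParseError(f"{path}: breadth outside [0, 100]")
    if (breadth > 1).any():  # percent dialect
        breadth = breadth / 100.0
    out = []
    for ent, samp, c, b in zip(df["entity_id"], df["sample_id"], cov, breadth):
        out.append(CoverageRecord(ent, samp, float(c), float(b)))
    return out


def write_coverage_table(records: Iterable[CoverageRecord], path: str | Path) -> None:
    """Write coverage records as fractional-breadth TSV (round-trip safe)."""
    rows = [
        (r.entity_id, r.sample_id, repr(r.mean_coverage), repr(r.breadth))
        for r in records
    ]
    pd.DataFrame(rows, columns=["entity_id", "sample_id", "mean_coverage", "breadth"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# pathway definitions
# ---------------------------------------------------------------------------

def read_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Read the pathway-marker table (columns ``model_id``, ``pathway_id``,
    ``threshold``, ``min_markers``).

    One row per marker model; ``min_markers`` is repeated on every row of
    a pathway and must be consistent.  A model listed under two pathways
    with different thresholds is an error (shared markers with one agreed
    threshold are allowed).
    """
    df = _read_tsv(path, ["model_id", "pathway_id", "threshold", "min_markers"])
    if df.empty:
        return []
    df = df.assign(
        threshold=_num(df, "threshold", path),
        min_markers=_num(df, "min_markers", path).astype(int),
    )
    seen_thresholds: dict[str, float] = {}
    for _, row in df.iterrows():
        prev = seen_thresholds.get(row["model_id"])
        if prev is not None and prev != row["threshold"]:
            raise ParseError(
                f"{path}: model {row['model_id']!r} has conflicting thresholds "
                f"{prev} and {row['threshold']}"
            )
        seen_thresholds[row["model_id"]] = row["threshold"]
    defs = []
    for pid, grp in df.groupby("pathway_id", sort=True):
        mins = set(grp["min_markers"])
        if len(mins) != 1:
            raise ParseError(f"{path}: pathway {pid!r} has inconsistent min_markers {sorted(mins)}")
        thresholds = dict(zip(grp["model_id"], grp["threshold"]))
        try:
            defs.append(PathwayDefinition(str(pid), thresholds, int(mins.pop())))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    return defs


def write_pathway_definitions(defs: Iterable[PathwayDefinition], path: str | Path) -> None:
    rows = []
    for d in defs:
        for model, thr in sorted(d.per_model_threshold.items()):
            rows.append((model, d.pathway_id, repr(thr), d.min_markers))
    pd.DataFrame(rows, columns=["model_id", "pathway_id", "threshold", "min_markers"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# genome / sample / phage / family tables
# ---------------------------------------------------------------------------

def read_genome_table(path: str | Path) -> list[GenomeRecord]:
    df = _read_tsv(
        path,
        ["genome_id", "phylum", "lineage_class", "completeness", "redundancy",
         "methanogenic_lineage"],
    )
    if df.empty:
        return []
    comp = _num(df, "completeness", path)
    red = _num(df, "redundancy", path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                GenomeRecord(
                    genome_id=row["genome_id"],
                    phylum="" if pd.isna(row["phylum"]) else str(row["phylum"]),
                    lineage_class=LineageClass(row["lineage_class"]),
                    completeness=float(comp[i]),
                    redundancy=float(red[i]),
                    methanogenic_lineage=str(row["methanogenic_lineage"]).strip().lower()
                    in ("true", "1", "yes", "t"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from None
    return out


def write_genome_table(records: Iterable[GenomeRecord], path: str | Path) -> None:
    rows = [
        (r.genome_id, r.phylum, r.lineage_class.value, repr(r.completeness),
         repr(r.redundancy), str(r.methanogenic_lineage).lower())
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["genome_id", "phylum", "lineage_class", "completeness",
                 "redundancy", "methanogenic_lineage"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    df = _read_tsv(path, ["sample_id", "depth", "depth_unit", "compartment"])
    if df.empty:
        return []
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    depth = _num(df, "depth", path)
    out = []
    for i, row in df.iterrows():
        try:
            comp = Compartment(row["compartment"])
        except ValueError:
            raise ParseError(
                f"{path}: row {i + 2}: unknown compartment {row['compartment']!r}"
            ) from None
        out.append(SampleRecord(row["sample_id"], float(depth[i]), row["depth_unit"], comp))
    return out


def write_sample_table(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [(r.sample_id, repr(r.depth), r.depth_unit, r.compartment.value) for r in records]
    pd.DataFrame(rows, columns=["sample_id", "depth", "depth_unit", "compartment"]).to_csv(
        path, sep="\t", index=False
    )


def read_phage_qc(path: str | Path) -> list[PhageQCRecord]:
    df = _read_tsv(
        path,
        ["scaffold_id", "length", "viral_genes", "host_genes", "provirus_call",
         "complete_100"],
    )
    if df.empty:
        return []
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                PhageQCRecord(
                    scaffold_id=row["scaffold_id"],
                    length=int(row["length"]),
                    viral_genes=int(row["viral_genes"]),
                    host_genes=int(row["host_genes"]),
                    provirus_call=str(row["provirus_call"]).strip().lower()
                    in ("true", "1", "yes", "t"),
                    complete_100=str(row["complete_100"]).strip().lower()
                    in ("true", "1", "yes", "t"),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from None
    return out


def write_phage_qc(records: Iterable[PhageQCRecord], path: str | Path) -> None:
    rows = [
        (r.scaffold_id, r.length, r.viral_genes, r.host_genes,
         str(r.provirus_call).lower(), str(r.complete_100).lower())
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["scaffold_id", "length", "viral_genes", "host_genes",
                 "provirus_call", "complete_100"],
    ).to_csv(path, sep="\t", index=False)


def read_family_table(path: str | Path) -> list[FamilyMembership]:
    """Read protein-family membership (family_id, protein_id, genome_id).

    Each protein must map to exactly one family.
    """
    df = _read_tsv(path, ["family_id", "protein_id", "genome_id"])
    if df.empty:
        return []
    multi = df.groupby("protein_id")["family_id"].nunique()
    bad = multi[multi > 1]
    if not bad.empty:
        raise ParseError(f"{path}: protein {bad.index[0]!r} belongs to multiple families")
    return [
        FamilyMembership(f, p, g)
        for f, p, g in zip(df["family_id"], df["protein_id"], df["genome_id"])
    ]


def write_family_table(records: Iterable[FamilyMembership], path: str | Path) -> None:
    rows = [(r.family_id, r.protein_id, r.genome_id) for r in records]
    pd.DataFrame(rows, columns=["family_id", "protein_id", "genome_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a run configuration file.

    Accepts either YAML mappings or plain ``key=value`` lines ('#'
    comments allowed in both).
    """
    text = Path(path).read_text(encoding="utf-8")
    stripped = [
        ln for ln in text.splitlines() if ln.strip() and not ln.strip().startswith("#")
    ]
    if stripped and all("=" in ln and ":" not in ln.split("=")[0] for ln in stripped):
        cfg: dict = {}
        for ln in stripped:
            key, _, value = ln.partition("=")
            cfg[key.strip()] = yaml.safe_load(value.strip())
        return cfg
    loaded = yaml.safe_load(text)
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return loaded
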