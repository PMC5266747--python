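"""Input/output: protein FASTA, external-annotation reports, result files.

The screen consumes three kinds of externally produced annotation, each as a
plain-text report: a signal-peptide prediction summary (SignalP-4.1 "short"
style, or a generic two-column ``id<TAB>yes/no`` fallback), a 12-column
tabular BLASTP hit table (``-outfmt 6``), and a conserved-domain hit table
(NCBI CD-search hit-table style).  The predictors themselves are never run
here — only their reports are parsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DECISION_TOKENS = {"Y": True, "YES": True, "N": False, "NO": False}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: unique identifier plus uppercase amino-acid sequence."""

    id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class SignalPeptideCall:
    protein_id: str
    has_signal_peptide: bool
    d_score: float | None = None


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    e_value: float


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain hit; start/end are 1-based inclusive on the query."""

    query_id: str
    domain_name: str
    start: int
    end: int


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The identifier is the first whitespace-delimited header token; the rest
    of the header is kept as an opaque description.  Sequences are
    uppercased and a single trailing translation stop ("*") is stripped.
    Records with an *internal* stop are skipped with a warning; duplicate
    identifiers raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            logger.warning(
                "skipping record %s: internal translation stop", rec.id
            )
            continue
        if not seq:
            logger.warning("skipping record %s: empty sequence", rec.id)
            continue
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA identifier: {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records to FASTA, preserving order and descriptions."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _parse_signalp_line(
    tokens: list[str], d_cutoff: float, lineno: int
) -> SignalPeptideCall:
    protein_id = tokens[0]
    decision: bool | None = None
    d_score: float | None = None
    for tok in tokens[1:]:
        upper = tok.upper()
        if upper in _DECISION_TOKENS and decision is None:
            decision = _DECISION_TOKENS[upper]
        elif upper.startswith("D=") and d_score is None:
            try:
                d_score = float(tok[2:])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: bad D-score token {tok!r}"
                ) from exc
    if d_score is None:
        # SignalP-4.1 short format: 12 columns, D-score is the 9th.
        if len(tokens) >= 12:
            try:
                d_score = float(tokens[8])
            except ValueError:
                d_score = None
        elif len(tokens) == 2 and decision is None:
            try:
                d_score = float(tokens[1])
            except ValueError:
                d_score = None
    if decision is None and d_score is None:
        raise ValueError(
            f"line {lineno}: no decision (Y/N) or D-score found for "
            f"{protein_id!r}"
        )
    if decision is None:
        decision = d_score >= d_cutoff
    return SignalPeptideCall(protein_id, decision, d_score)


def parse_signalp_report(
    path: str | Path, d_cutoff: float = 0.34
) -> dict[str, SignalPeptideCall]:
    """Parse a per-protein signal-peptide report.

    Accepted dialects: the SignalP-4.1 "short" summary (whitespace columns,
    ``#`` comments, D-score in column 9, Y/N decision in column 10), lines
    carrying explicit ``D=<score>`` and/or YES/NO tokens, and a generic
    two-column ``id  yes/no`` or ``id  d-score`` table.  When both a
    decision and a D-score are present the decision wins; from a D-score
    alone the call is ``d_score >= d_cutoff`` (the predictor's own
    sensitive-mode convention).
    """
    if not 0 < d_cutoff < 1:
        raise ValueError(f"d_cutoff must be in (0, 1), got {d_cutoff}")
    calls: dict[str, SignalPeptideCall] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            call = _parse_signalp_line(line.split(), d_cutoff, lineno)
            calls[call.protein_id] = call
    return calls


def parse_blast_hits(path: str | Path, e_cutoff: float = 1e-3) -> list[BlastHit]:
    """Parse a 12-column tabular BLAST hit table, keeping e-value <= cutoff."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                e_value = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: unparseable e-value {fields[10]!r}"
                ) from exc
            if e_value < 0:
                raise ValueError(f"line {lineno}: negative e-value {e_value}")
            if e_value <= e_cutoff:
                hits.append(BlastHit(fields[0], fields[1], e_value))
    return hits


def _clean_cd_query(raw: str) -> str:
    """Strip CD-search query decoration, e.g. ``Q#1 - >p9`` -> ``p9``."""
    token = raw.split(">")[-1].strip()
    return token.split()[0] if token else raw.strip()


def parse_domain_hits(path: str | Path) -> dict[str, list[DomainHit]]:
    """Parse a CD-search-style tab-separated domain hit table.

    Expected columns (extra columns are ignored): query id, hit type,
    domain short name, query start, query end — with the interval 1-based
    inclusive as printed.  A header line mentioning "Query" is skipped.
    """
    by_query: dict[str, list[DomainHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if lineno == 1 and fields[0].lower().startswith("query"):
                continue
            if len(fields) < 5:
                raise ValueError(
                    f"line {lineno}: expected >= 5 tab-separated columns, "
                    f"got {len(fields)}"
                )
            query = _clean_cd_query(fields[0])
            name = fields[2]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: unparseable interval "
                    f"{fields[3]!r}..{fields[4]!r}"
                ) from exc
            if start > end or start < 1:
                raise ValueError(
                    f"line {lineno}: invalid interval {start}..{end}"
                )
            by_query.setdefault(query, []).append(
                DomainHit(query, name, start, end)
            )
    return by_query


CANDIDATE_TABLE_HEADER = (
    "id",
    "branch",
    "group",
    "subfamily",
    "Length_T",
    "PAST_T%",
    "GlycoNo_T",
    "Length_P",
    "PAST_P%",
    "GlycoNo_P",
    "GlycoIndex",
    "agp_like_sequence",
)


def write_candidate_report(candidates, table_path, fasta_path) -> None:
    """Write the candidate TSV table and the candidate FASTA, in input order.

    GlycoIndex and percentages are printed with 2 decimals (half away from
    zero); the stored values stay unrounded.
    """
    from .glyco import fmt2  # local import to avoid cycle at module load

    with open(table_path, "w") as fh:
        fh.write("\t".join(CANDIDATE_TABLE_HEADER) + "\n")
        for c in candidates:
            v = c.variables
            row = (
                c.record.id,
                c.branch,
                str(c.group) if c.group is not None else "none",
                c.subfamily,
                str(v.length_t),
                fmt2(v.past_t_pct),
                str(v.glyco_no_t),
                str(v.length_p),
                fmt2(v.past_p_pct),
                str(v.glyco_no_p),
                fmt2(v.glyco_index),
                c.agp_like_sequence,
            )
            fh.write("\t".join(row) + "\n")
    write_fasta([c.record for c in candidates], fasta_path)
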