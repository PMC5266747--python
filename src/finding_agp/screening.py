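"""The two-branch integrated AGP screen.

Candidates are assembled from two independent branches and then filtered:

* **Signal-peptide branch** — proteins with a predicted signal peptide are
  split by length and whole-sequence PAST% into three groups (AG-peptides;
  long, PAST-rich; long, PAST-poor) and each group applies its own minima
  on the glycomodule index, AGP-like PAST% and AGP-like module count.
* **Homology branch** — proteins hit by BLASTP against known AGP seeds
  (e-value <= 1e-3) pass under looser minima (GlycoIndex >= 0.13,
  PAST_P% >= 45); this branch deliberately ignores the signal-peptide
  call, since it exists to recover chimeric AGPs lacking one.

Proteins hit by BLAST are removed from the signal-peptide branch before
grouping, so no identifier can be emitted twice.  Surviving candidates are
purged of extensin/PRP-repeat artifacts and classified into subfamilies
(Pep, C, KC, HAE, FLA, PAG, XYLP, other_chimeric, NC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .glyco import VariableSet, compute_variables, scan_ext_modules
from .lysrich import detect_basic_regions
from .seqio import BlastHit, DomainHit, ProteinRecord, SignalPeptideCall

logger = logging.getLogger(__name__)

SP_BRANCH = "signal_peptide"
BLAST_BRANCH = "homology"

#: Case-insensitive substring -> subfamily mapping for conserved-domain
#: short names.  Editable via ScreenConfig.domain_vocabulary.
DEFAULT_DOMAIN_VOCABULARY: tuple[tuple[str, str], ...] = (
    ("fasciclin", "FLA"),
    ("fas1", "FLA"),
    ("plastocyanin", "PAG"),
    ("phytocyanin", "PAG"),
    ("cu_bind", "PAG"),
    ("nsltp", "XYLP"),
    ("ltp", "XYLP"),
    ("aai", "XYLP"),
    ("xylogen", "XYLP"),
)


@dataclass
class GroupThresholds:
    glyco_index_min: float
    past_p_min: float
    glyco_no_p_min: int = 0


@dataclass
class ScreenConfig:
    """All tunable thresholds of the screen (defaults per the method)."""

    d_cutoff: float = 0.34
    e_cutoff: float = 1e-3
    pep_len_min: int = 55
    pep_len_max_exclusive: int = 90
    past_t_split: float = 42.0
    group1: GroupThresholds = field(
        default_factory=lambda: GroupThresholds(0.15, 60.0)
    )
    group2: GroupThresholds = field(
        default_factory=lambda: GroupThresholds(0.15, 55.0, 5)
    )
    group3: GroupThresholds = field(
        default_factory=lambda: GroupThresholds(0.20, 60.0, 5)
    )
    blast_branch: GroupThresholds = field(
        default_factory=lambda: GroupThresholds(0.13, 45.0)
    )
    max_gap: int = 10
    min_modules: int = 3
    # extensin/PRP removal
    ext_min_motifs: int = 2
    ext_min_pro_run: int = 3  # Ser-Pro2 strings occur in genuine AGPs
    ext_max_module_frac: float = 0.5  # removed when frac inside motifs > this
    prp_patterns: tuple[str, ...] = ("PVKCYT", "PPVYK", "PPVEK")
    prp_min_repeats: int = 2
    prp_glyco_index_max: float = 0.20  # removed only below this
    # basic-region (KC) detection
    basic_min_len: int = 5
    basic_min_frac: float = 0.6
    # chimeric fallback: unknown domain must sit mostly outside AGP-like
    # regions to count as a chimeric domain
    domain_outside_min: int = 30
    domain_vocabulary: tuple[tuple[str, str], ...] = DEFAULT_DOMAIN_VOCABULARY

    def __post_init__(self):
        if not self.pep_len_min < self.pep_len_max_exclusive:
            raise ValueError("pep_len_min must be < pep_len_max_exclusive")
        for name in ("group1", "group2", "group3", "blast_branch"):
            g = getattr(self, name)
            if g.glyco_index_min < 0 or g.past_p_min < 0 or g.glyco_no_p_min < 0:
                raise ValueError(f"{name}: thresholds must be non-negative")

    def group_thresholds(self, group: int | str) -> GroupThresholds:
        if group == BLAST_BRANCH:
            return self.blast_branch
        return {1: self.group1, 2: self.group2, 3: self.group3}[group]


@dataclass
class Candidate:
    record: ProteinRecord
    variables: VariableSet
    branch: str
    group: int | None
    agp_like_sequence: str
    subfamily: str = "NC"
    domain_names: tuple[str, ...] = ()
    hae_flag: bool = False


@dataclass
class ScreenSummary:
    """Per-stage identifier bookkeeping for auditability."""

    n_input: int = 0
    sp_positive: set[str] = field(default_factory=set)
    blast_ids: set[str] = field(default_factory=set)
    sp_only: set[str] = field(default_factory=set)
    group_members: dict[int, set[str]] = field(default_factory=dict)
    group_passed: dict[int, set[str]] = field(default_factory=dict)
    blast_passed: set[str] = field(default_factory=set)
    removed_ext: set[str] = field(default_factory=set)
    removed_prp: set[str] = field(default_factory=set)
    final: set[str] = field(default_factory=set)

    def counts(self) -> dict[str, int]:
        out = {
            "input": self.n_input,
            "signal_peptide_positive": len(self.sp_positive),
            "blast_hits": len(self.blast_ids),
            "sp_only_after_dedupe": len(self.sp_only),
            "blast_passed": len(self.blast_passed),
            "removed_ext": len(self.removed_ext),
            "removed_prp": len(self.removed_prp),
            "final_candidates": len(self.final),
        }
        for g in (1, 2, 3):
            out[f"group{g}_members"] = len(self.group_members.get(g, ()))
            out[f"group{g}_passed"] = len(self.group_passed.get(g, ()))
        return out


def signal_peptide_gate(
    records: list[ProteinRecord],
    calls: dict[str, SignalPeptideCall],
) -> list[ProteinRecord]:
    """Keep records whose signal-peptide call exists and is positive."""
    missing = sum(1 for r in records if r.id not in calls)
    if missing:
        logger.warning(
            "%d records had no signal-peptide call and were dropped", missing
        )
    return [
        r
        for r in records
        if r.id in calls and calls[r.id].has_signal_peptide
    ]


def dedupe_branches(
    sp_set: set[str], blast_set: set[str]
) -> tuple[set[str], set[str]]:
    """Remove BLAST-hit ids from the signal-peptide set; BLAST passes through."""
    return sp_set - blast_set, set(blast_set)


def assign_group(variables: VariableSet, config: ScreenConfig) -> int | None:
    """Split signal-peptide-branch proteins into the three threshold groups.

    Group 1: AG-peptide length window; Group 2: long and PAST-rich;
    Group 3: long and PAST-poor.  Below the Group-1 lower bound -> None
    (excluded from this branch).
    """
    if variables.length_t < config.pep_len_min:
        return None
    if variables.length_t < config.pep_len_max_exclusive:
        return 1
    return 2 if variables.past_t_pct >= config.past_t_split else 3


def pass_thresholds(
    variables: VariableSet,
    group_or_branch: int | str,
    config: ScreenConfig,
) -> bool:
    """Apply the group/branch minima (inclusive, on unrounded values)."""
    if not variables.has_agp_like:
        return False
    t = config.group_thresholds(group_or_branch)
    return (
        variables.glyco_index >= t.glyco_index_min
        and variables.past_p_pct >= t.past_p_min
        and variables.glyco_no_p >= t.glyco_no_p_min
    )


def _ext_motifs(sequence: str, config: ScreenConfig):
    return [
        m
        for m in scan_ext_modules(sequence)
        if m.pro_run >= config.ext_min_pro_run
    ]


def _modules_inside_ext_motifs(candidate: Candidate, config: ScreenConfig) -> int:
    """Count region-forming glycomodules contained in extensin motifs."""
    motifs = _ext_motifs(candidate.record.sequence, config)
    spans = [(m.start, m.end) for m in motifs]
    inside = 0
    for region in candidate.variables.regions:
        for hit_start in _region_module_starts(candidate, region):
            if any(s <= hit_start and hit_start + 2 <= e for s, e in spans):
                inside += 1
    return inside


def _region_module_starts(candidate: Candidate, region) -> list[int]:
    from .glyco import scan_glycomodules

    return [
        h.start
        for h in scan_glycomodules(candidate.record.sequence)
        if region.start <= h.start and h.end <= region.end
    ]


def remove_ext_prp(
    candidates: list[Candidate], config: ScreenConfig
) -> tuple[list[Candidate], list[Candidate], list[Candidate]]:
    """Drop extensin- and PRP-repeat artifacts; flag surviving hybrids.

    EXT removal: >= ``ext_min_motifs`` Ser-Pro(>= ``ext_min_pro_run``)
    motifs AND more than
    ``ext_max_module_frac`` of the region-forming glycomodules lie inside
    those motifs (the AGP-like signal is an artifact of extensin repeats).
    PRP removal: >= ``prp_min_repeats`` occurrences of any configured PRP
    repeat AND GlycoIndex < ``prp_glyco_index_max``.  Candidates with
    enough motifs whose modules are mostly outside them survive with an
    AGP-extensin-hybrid (HAE) flag.
    """
    kept: list[Candidate] = []
    removed_ext: list[Candidate] = []
    removed_prp: list[Candidate] = []
    for cand in candidates:
        seq = cand.record.sequence
        n_motifs = len(_ext_motifs(seq, config))
        if n_motifs >= config.ext_min_motifs:
            glyco_no_p = cand.variables.glyco_no_p
            inside = _modules_inside_ext_motifs(cand, config)
            if glyco_no_p > 0 and inside / glyco_no_p > config.ext_max_module_frac:
                removed_ext.append(cand)
                continue
            cand = replace(cand, hae_flag=True)
        n_prp = sum(seq.count(p) for p in config.prp_patterns)
        if (
            n_prp >= config.prp_min_repeats
            and cand.variables.glyco_index < config.prp_glyco_index_max
        ):
            removed_prp.append(cand)
            continue
        kept.append(cand)
    return kept, removed_ext, removed_prp


def _map_domain_name(name: str, config: ScreenConfig) -> str | None:
    lowered = name.lower()
    for needle, subfamily in config.domain_vocabulary:
        if needle in lowered:
            return subfamily
    return None


def _domain_residues_outside_regions(hit: DomainHit, regions) -> int:
    """Residues of a 1-based inclusive domain interval not covered by regions."""
    start0, end0 = hit.start - 1, hit.end  # 0-based half-open
    covered = 0
    for r in regions:
        lo, hi = max(start0, r.start), min(end0, r.end)
        if hi > lo:
            covered += hi - lo
    return (end0 - start0) - covered


def classify_subfamily(
    candidate: Candidate,
    domains: list[DomainHit],
    config: ScreenConfig,
) -> str:
    """Assign one subfamily label (precedence: domain, length, KC, HAE, PAST).

    Recognized chimeric domain names map to FLA/PAG/XYLP; any other domain
    hit counts as ``other_chimeric`` only when >= ``domain_outside_min``
    of its residues fall outside AGP-like regions (a domain engulfed by the
    AGP-like sequence is not treated as a chimeric scaffold).
    """
    v = candidate.variables
    for hit in domains:
        mapped = _map_domain_name(hit.domain_name, config)
        if mapped is not None:
            return mapped
    for hit in domains:
        if (
            _domain_residues_outside_regions(hit, v.regions)
            >= config.domain_outside_min
        ):
            return "other_chimeric"
    if v.length_t < config.pep_len_max_exclusive:
        return "Pep"
    if _has_embedded_basic_region(candidate, config):
        return "KC"
    if candidate.hae_flag:
        return "HAE"
    if v.past_t_pct >= config.past_t_split:
        return "C"
    return "NC"


def _has_embedded_basic_region(candidate: Candidate, config: ScreenConfig) -> bool:
    """A basic-rich region lying within/between the AGP-like regions."""
    regions = candidate.variables.regions
    if not regions:
        return False
    span_start = min(r.start for r in regions)
    span_end = max(r.end for r in regions)
    basic = detect_basic_regions(
        candidate.record.sequence,
        min_len=config.basic_min_len,
        min_basic_frac=config.basic_min_frac,
    )
    return any(b.start >= span_start and b.end <= span_end for b in basic)


def run_screen(
    records: list[ProteinRecord],
    signalp_calls: dict[str, SignalPeptideCall],
    blast_hits: list[BlastHit],
    domain_hits: dict[str, list[DomainHit]] | None = None,
    config: ScreenConfig | None = None,
) -> tuple[list[Candidate], ScreenSummary]:
    """Execute the full integrated screen and return candidates + counts."""
    config = config or ScreenConfig()
    domain_hits = domain_hits or {}
    summary = ScreenSummary(n_input=len(records))

    variables = {
        r.id: compute_variables(
            r.sequence, max_gap=config.max_gap, min_modules=config.min_modules
        )
        for r in records
    }
    by_id = {r.id: r for r in records}

    # homology branch
    summary.blast_ids = {
        h.query_id for h in blast_hits if h.e_value <= config.e_cutoff
    }
    candidates: list[Candidate] = []
    for rid in sorted(summary.blast_ids):
        if rid not in by_id:
            continue
        v = variables[rid]
        if pass_thresholds(v, BLAST_BRANCH, config):
            summary.blast_passed.add(rid)
            candidates.append(
                Candidate(
                    record=by_id[rid],
                    variables=v,
                    branch=BLAST_BRANCH,
                    group=None,
                    agp_like_sequence=_rep(by_id[rid], v),
                )
            )

    # signal-peptide branch
    gated = signal_peptide_gate(records, signalp_calls)
    summary.sp_positive = {r.id for r in gated}
    sp_only, _ = dedupe_branches(summary.sp_positive, summary.blast_ids)
    summary.sp_only = sp_only
    for r in gated:
        if r.id not in sp_only:
            continue
        v = variables[r.id]
        group = assign_group(v, config)
        if group is None:
            continue
        summary.group_members.setdefault(group, set()).add(r.id)
        if pass_thresholds(v, group, config):
            summary.group_passed.setdefault(group, set()).add(r.id)
            candidates.append(
                Candidate(
                    record=r,
                    variables=v,
                    branch=SP_BRANCH,
                    group=group,
                    agp_like_sequence=_rep(r, v),
                )
            )

    kept, removed_ext, removed_prp = remove_ext_prp(candidates, config)
    summary.removed_ext = {c.record.id for c in removed_ext}
    summary.removed_prp = {c.record.id for c in removed_prp}

    for cand in kept:
        cand.subfamily = classify_subfamily(
            cand, domain_hits.get(cand.record.id, []), config
        )
        cand.domain_names = tuple(
            d.domain_name for d in domain_hits.get(cand.record.id, [])
        )
    summary.final = {c.record.id for c in kept}
    logger.info("screen summary: %s", summary.counts())
    return kept, summary


def _rep(record: ProteinRecord, variables: VariableSet) -> str:
    from .glyco import representative_sequence

    return representative_sequence(record.sequence, list(variables.regions))
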