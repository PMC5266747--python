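"""Arabinogalactan (AG) glycomodule scanning and the seven screening variables.

AGP protein backbones carry dipeptide "glycomodules" — Ala-Pro, Pro-Ala,
Ser-Pro, Pro-Ser, Thr-Pro, Pro-Thr — whose prolines are hydroxylated and then
decorated with arabinogalactan polysaccharides.  A stretch of sequence in
which at least three such modules occur, with no more than ten residues
between consecutive modules, is treated as an *AGP-like region*: the unit of
sequence that can plausibly be glycosylated.  This module locates modules,
extracts regions, and derives the seven per-protein screening variables
(whole-sequence length / PAST% / module count, AGP-like length / PAST% /
module count, and the glycomodule index).

Counting convention
-------------------
Modules are counted by a greedy, left-to-right, *non-overlapping* scan: at
each position, if the dipeptide starting there is a glycomodule and does not
overlap the previously accepted hit, it is accepted and the scan jumps past
it.  On the canonical AtAGP1 AGP-like sequence (82 residues) this yields 21
modules; an overlapping count would give 36.  Ties such as "APA" resolve in
favour of the leftmost module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

GLYCOMODULES = frozenset({"AP", "PA", "SP", "PS", "TP", "PT"})
PAST = frozenset("PAST")


@dataclass(frozen=True)
class GlycomoduleHit:
    """One accepted AG glycomodule; ``start`` is the 0-based first residue."""

    start: int
    module: str

    @property
    def end(self) -> int:
        """0-based exclusive end of the dipeptide."""
        return self.start + 2


@dataclass(frozen=True)
class AGPLikeRegion:
    """Maximal chain of >= ``min_modules`` glycomodules with bounded gaps.

    ``start``/``end`` form a 0-based half-open interval; the region begins
    and ends on a glycomodule.
    """

    start: int
    end: int
    module_count: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExtModuleHit:
    """An extensin-type Ser-Pro(2-4) motif; ``pro_run`` counts the prolines."""

    start: int
    pro_run: int

    @property
    def end(self) -> int:
        """End of the motif span (Ser plus the counted prolines)."""
        return self.start + 1 + self.pro_run


@dataclass
class VariableSet:
    """The seven screening variables for one protein.

    ``length_t``/``past_t_pct``/``glyco_no_t`` describe the whole sequence;
    ``length_p``/``past_p_pct``/``glyco_no_p`` the representative AGP-like
    sequence; ``glyco_index`` is glyco_no_p / length_p.  Values are stored
    unrounded; 2-decimal rounding happens only at report time.
    """

    length_t: int
    past_t_pct: float
    glyco_no_t: int
    length_p: int
    past_p_pct: float
    glyco_no_p: int
    glyco_index: float
    has_agp_like: bool = True
    regions: tuple[AGPLikeRegion, ...] = field(default=())

    FIELD_ORDER = (
        "length_t",
        "past_t_pct",
        "glyco_no_t",
        "length_p",
        "past_p_pct",
        "glyco_no_p",
        "glyco_index",
    )

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in self.FIELD_ORDER)


def round2(value: float) -> float:
    """Round to 2 decimals, half away from zero (report convention)."""
    return float(
        Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def fmt2(value: float) -> str:
    """Format with exactly 2 decimals under the report rounding rule."""
    return f"{round2(value):.2f}"


def scan_glycomodules(sequence: str) -> list[GlycomoduleHit]:
    """Greedy left-to-right non-overlapping scan for AG glycomodules."""
    hits: list[GlycomoduleHit] = []
    i = 0
    n = len(sequence)
    while i < n - 1:
        pair = sequence[i : i + 2]
        if pair in GLYCOMODULES:
            hits.append(GlycomoduleHit(i, pair))
            i += 2
        else:
            i += 1
    return hits


def extract_regions(
    hits: list[GlycomoduleHit],
    max_gap: int = 10,
    min_modules: int = 3,
) -> list[AGPLikeRegion]:
    """Chain sorted non-overlapping hits into maximal AGP-like regions.

    Consecutive hits stay in one chain while the number of residues strictly
    between them (``next.start - prev.end``) is <= ``max_gap``.  Maximal
    chains with at least ``min_modules`` modules become regions spanning
    from the first module's start to the last module's end.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    if min_modules < 1:
        raise ValueError(f"min_modules must be >= 1, got {min_modules}")
    regions: list[AGPLikeRegion] = []
    chain: list[GlycomoduleHit] = []
    for hit in hits:
        if chain and hit.start - chain[-1].end > max_gap:
            if len(chain) >= min_modules:
                regions.append(
                    AGPLikeRegion(chain[0].start, chain[-1].end, len(chain))
                )
            chain = []
        chain.append(hit)
    if len(chain) >= min_modules:
        regions.append(AGPLikeRegion(chain[0].start, chain[-1].end, len(chain)))
    return regions


def representative_sequence(sequence: str, regions: list[AGPLikeRegion]) -> str:
    """Join the AGP-like region substrings (ascending start, no separator)."""
    return "".join(
        sequence[r.start : r.end] for r in sorted(regions, key=lambda r: r.start)
    )


def past_percent(sequence: str) -> float:
    """Percent of residues that are P, A, S or T.

    Ambiguity codes count in the denominator but never in the numerator.
    """
    if not sequence:
        return 0.0
    n_past = sum(1 for c in sequence if c in PAST)
    return 100.0 * n_past / len(sequence)


def compute_variables(
    sequence: str,
    max_gap: int = 10,
    min_modules: int = 3,
) -> VariableSet:
    """Compute the seven screening variables for one (normalized) sequence."""
    if not sequence:
        raise ValueError("cannot compute variables of an empty sequence")
    hits = scan_glycomodules(sequence)
    regions = extract_regions(hits, max_gap=max_gap, min_modules=min_modules)
    rep = representative_sequence(sequence, regions)
    glyco_no_p = sum(r.module_count for r in regions)
    length_p = len(rep)
    return VariableSet(
        length_t=len(sequence),
        past_t_pct=past_percent(sequence),
        glyco_no_t=len(hits),
        length_p=length_p,
        past_p_pct=past_percent(rep),
        glyco_no_p=glyco_no_p,
        glyco_index=(glyco_no_p / length_p) if length_p else 0.0,
        has_agp_like=length_p > 0,
        regions=tuple(regions),
    )


def scan_ext_modules(sequence: str) -> list[ExtModuleHit]:
    """Find extensin-type Ser-Pro(2-4) motifs.

    Every Ser followed by a maximal run of >= 2 Pro yields one hit; runs
    longer than 4 are recorded with pro_run = 4 (one hit per Ser).
    """
    hits: list[ExtModuleHit] = []
    n = len(sequence)
    for i, c in enumerate(sequence):
        if c != "S":
            continue
        j = i + 1
        while j < n and sequence[j] == "P":
            j += 1
        run = j - i - 1
        if run >= 2:
            hits.append(ExtModuleHit(i, min(run, 4)))
    return hits
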