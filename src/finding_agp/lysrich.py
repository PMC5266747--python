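"""Detection and classification of short basic-residue-rich regions.

One subclass of classical AGPs carries a short region rich in basic
residues (Lys/His/Arg) that interrupts the PAST-rich backbone — the
"Lys-rich" classical AGPs, e.g. the tomato LeAGP1 region KGKVKGKKGKKHN.
The detector finds maximal windows of length >= ``min_len`` that start and
end on a basic residue and whose basic fraction is >= ``min_basic_frac``;
overlapping maximal windows are merged.  The classifier labels a region by
the plurality basic residue (exact two-way ties get a pair label,
three-way ties "mixed").
"""

from __future__ import annotations

from dataclasses import dataclass

BASIC = frozenset("KHR")


@dataclass(frozen=True)
class BasicRegion:
    """0-based half-open interval plus per-residue counts and label."""

    start: int
    end: int
    k_count: int
    h_count: int
    r_count: int
    other_count: int
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def basic_count(self) -> int:
        return self.k_count + self.h_count + self.r_count


def classify_basic_counts(k: int, h: int, r: int) -> str:
    """Plurality label over (Lys, His, Arg) counts, with tie pair labels."""
    top = max(k, h, r)
    leaders = [name for name, n in (("Lys", k), ("His", h), ("Arg", r)) if n == top]
    if len(leaders) == 1:
        return f"{leaders[0]}-rich"
    if len(leaders) == 2:
        return f"{leaders[0]}/{leaders[1]}-rich"
    return "mixed"


def classify_basic_region(region: BasicRegion) -> str:
    return classify_basic_counts(region.k_count, region.h_count, region.r_count)


def _make_region(sequence: str, start: int, end: int) -> BasicRegion:
    window = sequence[start:end]
    k = window.count("K")
    h = window.count("H")
    r = window.count("R")
    other = len(window) - k - h - r
    return BasicRegion(start, end, k, h, r, other, classify_basic_counts(k, h, r))


def detect_basic_regions(
    sequence: str,
    min_len: int = 5,
    min_basic_frac: float = 0.6,
) -> list[BasicRegion]:
    """Find maximal basic-residue-rich windows in a protein sequence.

    A candidate interval [i, j) qualifies when j - i >= min_len, both
    endpoints are basic residues, and the basic fraction is >=
    min_basic_frac.  Only maximal qualifying intervals are kept, and
    overlapping ones are merged.  Each kept window is then extended outward
    over flanking non-PAST residues while the basic fraction stays >=
    min_basic_frac: basic regions interrupt a PAST-rich backbone, so a
    trailing polar residue (e.g. the Asn closing LeAGP1's KGKVKGKKGKKHN)
    belongs to the interruption, while the PAST-rich context does not.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if not 0 < min_basic_frac <= 1:
        raise ValueError(
            f"min_basic_frac must be in (0, 1], got {min_basic_frac}"
        )
    n = len(sequence)
    basic_pos = [i for i, c in enumerate(sequence) if c in BASIC]
    if not basic_pos:
        return []
    # prefix sums of basic counts for O(1) window fraction queries
    prefix = [0] * (n + 1)
    for i, c in enumerate(sequence):
        prefix[i + 1] = prefix[i] + (1 if c in BASIC else 0)

    def frac_ok(i: int, j: int) -> bool:
        return prefix[j] - prefix[i] >= min_basic_frac * (j - i)

    qualifying: list[tuple[int, int]] = []
    for a_idx, i in enumerate(basic_pos):
        # widest qualifying window starting at this basic residue
        best_j = -1
        for j in reversed(basic_pos[a_idx:]):
            if j + 1 - i >= min_len and frac_ok(i, j + 1):
                best_j = j + 1
                break
        if best_j > 0:
            qualifying.append((i, best_j))
    # keep maximal intervals (drop those contained in another)
    maximal = [
        (s, e)
        for s, e in qualifying
        if not any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e)
            for s2, e2 in qualifying
        )
    ]
    maximal.sort()
    merged = _merge_if_qualifying(maximal, frac_ok)
    extended = [
        _extend_over_non_past(sequence, s, e, frac_ok) for s, e in merged
    ]
    final = _merge_if_qualifying(extended, frac_ok)
    return [_make_region(sequence, s, e) for s, e in final]


def _merge_if_qualifying(intervals, frac_ok):
    """Merge overlapping intervals, but only while the union keeps the
    required basic fraction; otherwise both overlapping windows are kept."""
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        if out and s < out[-1][1]:
            ms, me = out[-1][0], max(out[-1][1], e)
            if frac_ok(ms, me):
                out[-1] = (ms, me)
                continue
            if e <= out[-1][1]:  # contained: nothing new to keep
                continue
        out.append((s, e))
    return out


_PAST = frozenset("PAST")


def _extend_over_non_past(sequence, start, end, frac_ok):
    """Grow [start, end) across flanking non-PAST residues, fraction holding."""
    while start > 0 and sequence[start - 1] not in _PAST and frac_ok(start - 1, end):
        start -= 1
    while (
        end < len(sequence)
        and sequence[end] not in _PAST
        and frac_ok(start, end + 1)
    ):
        end += 1
    return start, end
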