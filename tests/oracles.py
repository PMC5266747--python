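"""Independent reference implementations used only to check the engine.

These deliberately avoid the engine's greedy scan.  The placement oracle
computes, by dynamic programming over all non-overlapping dipeptide
placements, the maximum-cardinality placement that is lexicographically
earliest in its start positions — the placement a left-to-right greedy
scan of unit-length-2 intervals provably produces.  A literal exhaustive
enumerator (exponential; short strings only) double-checks the DP.
"""

from __future__ import annotations

from itertools import combinations

MODULES = {"AP", "PA", "SP", "PS", "TP", "PT"}


def oracle_scan_starts(s: str) -> list[int]:
    """Lexicographically-earliest maximum non-overlapping placement (DP)."""
    n = len(s)
    is_mod = [s[i : i + 2] in MODULES for i in range(max(n - 1, 0))]
    best = [0] * (n + 2)
    for i in range(n - 2, -1, -1):
        take = (1 + best[i + 2]) if is_mod[i] else 0
        best[i] = max(best[i + 1], take)
    starts = []
    i = 0
    while i < n - 1:
        if is_mod[i] and 1 + best[i + 2] == best[i]:
            starts.append(i)
            i += 2
        else:
            i += 1
    return starts


def exhaustive_scan_starts(s: str) -> list[int]:
    """All-subsets enumeration; use only for short strings (len <= ~14)."""
    candidates = [i for i in range(len(s) - 1) if s[i : i + 2] in MODULES]
    best: list[int] | None = None
    for k in range(len(candidates), -1, -1):
        placements = [
            list(combo)
            for combo in combinations(candidates, k)
            if all(b - a >= 2 for a, b in zip(combo, combo[1:]))
        ]
        if placements:
            best = min(placements)
            break
    return best or []


def oracle_regions(starts: list[int], max_gap: int = 10, min_modules: int = 3):
    """Chain module starts under the gap rule; independent of the engine."""
    chains: list[list[int]] = []
    for start in starts:
        if chains and start - (chains[-1][-1] + 2) <= max_gap:
            chains[-1].append(start)
        else:
            chains.append([start])
    return [
        (chain[0], chain[-1] + 2, len(chain))
        for chain in chains
        if len(chain) >= min_modules
    ]
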