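"""Descriptive statistics over AGP-like sequences and screening variables.

Four tables: per-residue amino-acid composition, X-Pro dipeptide counts,
the 7x7 correlation matrix of the screening variables, and threshold
efficiency grids (candidate counts surviving each threshold value).

Note the X-Pro table is a *composition* statistic: it counts every
position where a non-Pro residue precedes a Pro, overlaps allowed, for all
19 X-Pro dipeptide types.  This deliberately differs from the screening
scan, which counts only the six AG glycomodules without overlap.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glyco import VariableSet

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def composition_table(sequences: list[str]) -> pd.DataFrame:
    """Amino-acid composition over a set of sequences.

    Columns: ``total_count`` (sum over sequences),
    ``n_sequences_containing``, ``mean_per_containing_sequence``
    (total / n_containing), ``percent_of_all_residues`` (total / all
    standard residues).  Rows sorted by total_count descending.
    """
    if not sequences:
        raise ValueError("composition_table requires at least one sequence")
    totals = {aa: 0 for aa in AMINO_ACIDS}
    containing = {aa: 0 for aa in AMINO_ACIDS}
    for seq in sequences:
        for aa in AMINO_ACIDS:
            n = seq.count(aa)
            totals[aa] += n
            if n:
                containing[aa] += 1
    grand_total = sum(totals.values())
    rows = []
    for aa in AMINO_ACIDS:
        n_cont = containing[aa]
        rows.append(
            {
                "amino_acid": THREE_LETTER[aa],
                "letter": aa,
                "total_count": totals[aa],
                "n_sequences_containing": n_cont,
                "mean_per_containing_sequence": (
                    totals[aa] / n_cont if n_cont else 0.0
                ),
                "percent_of_all_residues": (
                    100.0 * totals[aa] / grand_total if grand_total else 0.0
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["total_count", "letter"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def xpro_table(sequences: list[str]) -> pd.DataFrame:
    """Counts of X-Pro dipeptides (X any residue but Pro), overlaps allowed."""
    if not sequences:
        raise ValueError("xpro_table requires at least one sequence")
    xs = [aa for aa in AMINO_ACIDS if aa != "P"]
    totals = {x: 0 for x in xs}
    containing = {x: 0 for x in xs}
    for seq in sequences:
        found = {x: 0 for x in xs}
        for i in range(len(seq) - 1):
            if seq[i + 1] == "P" and seq[i] in totals:
                found[seq[i]] += 1
        for x, n in found.items():
            totals[x] += n
            if n:
                containing[x] += 1
    grand_total = sum(totals.values())
    rows = []
    for x in xs:
        n_cont = containing[x]
        rows.append(
            {
                "dipeptide": f"{x}P",
                "total_count": totals[x],
                "n_sequences_containing": n_cont,
                "mean_per_containing_sequence": (
                    totals[x] / n_cont if n_cont else 0.0
                ),
                "percent_of_all_xpro": (
                    100.0 * totals[x] / grand_total if grand_total else 0.0
                ),
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["total_count", "dipeptide"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def variables_frame(variable_sets: list[VariableSet]) -> pd.DataFrame:
    """Stack VariableSets into a DataFrame with the seven named columns."""
    return pd.DataFrame(
        [v.as_tuple() for v in variable_sets], columns=list(VariableSet.FIELD_ORDER)
    )


def correlation_matrix(
    variable_sets: list[VariableSet],
    method: str = "pearson",
    with_p_values: bool = False,
):
    """Pairwise correlation of the seven variables across proteins.

    Records without an AGP-like sequence (length_p = 0) are excluded with a
    logged count.  Returns the 7x7 correlation DataFrame, and optionally a
    matching two-tailed p-value DataFrame.
    """
    usable = [v for v in variable_sets if v.has_agp_like]
    dropped = len(variable_sets) - len(usable)
    if dropped:
        logger.info("correlation_matrix: excluded %d records without an "
                    "AGP-like sequence", dropped)
    if len(usable) < 3:
        raise ValueError("need at least 3 records with AGP-like sequences")
    df = variables_frame(usable)
    corr = df.corr(method=method)
    if not with_p_values:
        return corr
    cols = corr.columns
    pvals = pd.DataFrame(np.zeros_like(corr), index=cols, columns=cols)
    test = sps.pearsonr if method == "pearson" else sps.spearmanr
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if i == j:
                continue
            pvals.loc[a, b] = test(df[a], df[b]).pvalue
    return corr, pvals


def threshold_efficiency(
    variable_sets: list[VariableSet],
    groups: list[int | str] | None = None,
    glyco_index_thresholds: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25),
    past_p_thresholds: tuple[float, ...] = (45.0, 50.0, 55.0, 60.0),
) -> pd.DataFrame:
    """Counts of records surviving each threshold, one variable at a time.

    ``groups`` optionally assigns each record a group label; one row per
    group is produced (plus an ``all`` row when groups are omitted).  Along
    each threshold axis the counts are non-increasing by construction.
    """
    if groups is None:
        groups = ["all"] * len(variable_sets)
    if len(groups) != len(variable_sets):
        raise ValueError("groups and variable_sets must have equal length")
    frame = variables_frame(variable_sets)
    frame["group"] = groups
    rows = []
    for g, sub in frame.groupby("group", sort=True):
        row: dict[str, object] = {"group": g, "n": len(sub)}
        for t in glyco_index_thresholds:
            row[f"GlycoIndex>={t:g}"] = int((sub["glyco_index"] >= t).sum())
        for t in past_p_thresholds:
            row[f"PAST_P%>={t:g}"] = int((sub["past_p_pct"] >= t).sum())
        rows.append(row)
    return pd.DataFrame(rows)
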