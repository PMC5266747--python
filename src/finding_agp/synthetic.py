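"""Synthetic proteomes with planted AGPs, for end-to-end pipeline testing.

The generator plants protein constructs from every subfamily the screen
must handle — classical AGPs, AG-peptides, Lys-rich classical AGPs,
AGP-extensin hybrids, chimeric AGPs (fasciclin / phytocyanin / xylogen /
other domains), extensins, PRP-like repeats — plus three families of
negative controls that each defeat exactly one screening clause (gap
violations, module scarcity, composition failure) and compositionally
unbiased background proteins.  Matching annotation reports (signal-peptide
summary, BLAST hit table, domain hit table) and a ground-truth table are
produced alongside, so the full screen runs without any external predictor.

Signal peptides are emitted as *report rows*, not as realistic N-terminal
sequences: the harness exercises the pipeline's logic, not the predictors.
Sequence construction is verified against the scanning engine at build
time, and every truth record's expected outcome is computed by the
screening logic itself, then frozen.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .glyco import compute_variables, scan_glycomodules
from .screening import (
    BLAST_BRANCH,
    SP_BRANCH,
    Candidate,
    ScreenConfig,
    assign_group,
    classify_subfamily,
    pass_thresholds,
    remove_ext_prp,
)
from .seqio import DomainHit, ProteinRecord, SignalPeptideCall

MODULES = ("AP", "PA", "SP", "PS", "TP", "PT")
#: filler letters guaranteed never to seed a glycomodule (no P/A/S/T) nor a
#: basic-rich region (no K/H/R)
NEUTRAL = "GVLNEDQI"
PAST_FILLER = "AST"  # proline excluded: fillers must not create modules


def _filler(
    length: int,
    rng: random.Random,
    past_frac: float = 0.0,
    no_past_first: bool = False,
    no_past_last: bool = False,
) -> str:
    """Random gap filler; PAST letters appear at rate ``past_frac`` except
    in slots adjacent to a module proline (which must stay non-PAST)."""
    out = []
    for i in range(length):
        forced_neutral = (no_past_first and i == 0) or (
            no_past_last and i == length - 1
        )
        if not forced_neutral and rng.random() < past_frac:
            out.append(rng.choice(PAST_FILLER))
        else:
            out.append(rng.choice(NEUTRAL))
    return "".join(out)


def build_agp_core(
    target_modules: int,
    target_length: int,
    max_internal_gap: int,
    rng: random.Random,
    past_filler_frac: float = 0.0,
) -> str:
    """Build a string with exactly ``target_modules`` greedy-scan modules.

    The string starts and ends on a glycomodule, internal gaps are
    <= ``max_internal_gap``, and gap fillers avoid proline so no accidental
    module can arise.  Raises ``ValueError`` on infeasible targets.
    """
    m, length = target_modules, target_length
    if m < 1:
        raise ValueError("target_modules must be >= 1")
    slack = length - 2 * m
    if slack < 0:
        raise ValueError(
            f"infeasible: {m} modules need >= {2 * m} residues, got {length}"
        )
    n_gaps = m - 1
    if n_gaps == 0 and slack > 0:
        raise ValueError("a single module cannot carry internal gap slack")
    if n_gaps > 0 and slack > n_gaps * max_internal_gap:
        raise ValueError(
            f"infeasible: slack {slack} exceeds {n_gaps} gaps x "
            f"{max_internal_gap}"
        )
    gaps = [0] * n_gaps
    for _ in range(slack):
        candidates = [i for i, g in enumerate(gaps) if g < max_internal_gap]
        gaps[candidates[rng.randrange(len(candidates))]] += 1

    parts: list[str] = []
    prev = None
    for i in range(m):
        choices = list(MODULES)
        if prev == "SP" and (i == 0 or gaps[i - 1] == 0):
            # avoid S-P-P runs (extensin motifs) at zero-gap junctions
            choices = [c for c in choices if not c.startswith("P")]
        mod = rng.choice(choices)
        parts.append(mod)
        if i < n_gaps:
            parts.append(
                _filler(
                    gaps[i],
                    rng,
                    past_frac=past_filler_frac,
                    no_past_first=mod.endswith("P"),
                    no_past_last=True,  # conservatively neutral before next
                )
            )
        prev = mod
    core = "".join(parts)
    hits = scan_glycomodules(core)
    if len(hits) != m or len(core) != length:  # pragma: no cover - self-check
        raise AssertionError(
            f"core construction self-check failed: {len(hits)} modules, "
            f"length {len(core)} (wanted {m}, {length})"
        )
    return core


def build_background(length: int, past_bias: float, rng: random.Random) -> str:
    """I.i.d. residues with P/A/S/T at combined frequency ``past_bias``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= past_bias <= 1:
        raise ValueError("past_bias must be in [0, 1]")
    others = "CDEFGHIKLMNQRVWY"
    out = []
    for _ in range(length):
        if rng.random() < past_bias:
            out.append("PAST"[rng.randrange(4)])
        else:
            out.append(others[rng.randrange(len(others))])
    return "".join(out)


def _basic_region(length: int, rng: random.Random) -> str:
    """A Lys-heavy basic stretch with basic endpoints and fraction >= 0.6."""
    while True:
        letters = []
        for i in range(length):
            if i == 0 or i == length - 1:
                letters.append("K")
                continue
            u = rng.random()
            if u < 0.55:
                letters.append("K")
            elif u < 0.70:
                letters.append("H")
            elif u < 0.78:
                letters.append("R")
            else:
                letters.append(rng.choice("GVN"))
        s = "".join(letters)
        n_basic = sum(1 for c in s if c in "KHR")
        if n_basic >= 0.7 * length:  # margin above the 0.6 detector floor
            return s


@dataclass
class SynthConfig:
    """Counts and parameter ranges for one synthetic proteome.

    Defaults produce a 1000-protein proteome: 100 planted constructs, 30
    targeted negative controls, 870 background proteins.
    """

    seed: int = 0
    n_classical: int = 20
    n_pep: int = 15
    n_kc: int = 10
    n_hae: int = 10
    n_fla: int = 10
    n_pag: int = 10
    n_xylp: int = 10
    n_other_chimeric: int = 5
    n_ext: int = 5
    n_prp: int = 5
    n_neg_gap: int = 10
    n_neg_sparse: int = 10
    n_neg_lowpast: int = 10
    n_background: int = 870
    background_sp_rate: float = 0.5
    chimeric_no_sp_frac: float = 0.5
    background_past_bias: tuple[float, float] = (0.10, 0.25)
    basic_len_range: tuple[int, int] = (11, 22)  # > max_gap, splits regions
    max_gap: int = 10

    def __post_init__(self):
        for f in fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def total(self) -> int:
        return sum(
            getattr(self, f.name) for f in fields(self) if f.name.startswith("n_")
        )


@dataclass
class SyntheticProteome:
    records: list[ProteinRecord]
    truth: pd.DataFrame
    signalp_calls: dict[str, SignalPeptideCall]
    blast_rows: list[tuple]
    domain_rows: list[tuple]
    domain_hits: dict[str, list[DomainHit]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        from .seqio import write_fasta

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "proteome.fasta")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "signalp.txt", "w") as fh:
            fh.write("# SignalP-4.1 euk predictions (synthetic report)\n")
            fh.write(
                "# name\tCmax\tpos\tYmax\tpos\tSmax\tpos\tSmean\tD\t?"
                "\tDmaxcut\tNetworks-used\n"
            )
            for rec in self.records:
                call = self.signalp_calls[rec.id]
                d = call.d_score if call.d_score is not None else 0.0
                flag = "Y" if call.has_signal_peptide else "N"
                fh.write(
                    f"{rec.id}\t0.5\t20\t0.5\t20\t0.6\t15\t0.5\t{d:.3f}"
                    f"\t{flag}\t0.340\tSignalP-noTM\n"
                )
        with open(out / "blast.tsv", "w") as fh:
            for row in self.blast_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        with open(out / "domains.tsv", "w") as fh:
            fh.write("Query\tHit type\tShort name\tFrom\tTo\n")
            for row in self.domain_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# per-class construct builders: each returns (sequence, wants_sp, wants_blast,
# domain_info) where domain_info is None or (short_name, start1, end1)


def _classical(rng) -> str:
    m = rng.randint(25, 35)
    gi = rng.uniform(0.18, 0.28)
    length = min(int(m / gi), 2 * m + (m - 1) * 10)
    core = build_agp_core(m, length, 10, rng, past_filler_frac=0.85)
    return _filler(rng.randint(20, 25), rng) + core + _filler(
        rng.randint(15, 20), rng
    )


def _pep(rng) -> str:
    prefix = _filler(20, rng)
    core_len = rng.randint(35, 65)
    m = max(3, int(core_len * rng.uniform(0.20, 0.28)))
    core = build_agp_core(m, core_len, 10, rng, past_filler_frac=0.9)
    return prefix + core


def _kc_core(rng) -> str:
    m = rng.randint(10, 15)
    length = int(m / rng.uniform(0.18, 0.26))
    return build_agp_core(m, length, 10, rng, 0.85)


def _kc(rng, basic_len_range) -> str:
    core1 = _kc_core(rng)
    core2 = _kc_core(rng)
    basic = _basic_region(rng.randint(*basic_len_range), rng)
    return _filler(22, rng) + core1 + basic + core2 + _filler(16, rng)


def _hae(rng) -> str:
    core = build_agp_core(rng.randint(18, 24), rng.randint(80, 110), 10, rng, 0.85)
    motif = "S" + "P" * rng.randint(3, 4)
    spacer1 = _filler(rng.randint(13, 16), rng)
    spacer2 = _filler(rng.randint(13, 16), rng)
    return _filler(22, rng) + motif + spacer1 + core + spacer2 + motif


def _chimeric(rng, domain_name):
    prefix_len = 20
    stub_len = rng.randint(100, 150)
    stub = "".join(
        rng.choice("GKLVNEDQIRFWMHYC" if rng.random() > 0.25 else "AST")
        for _ in range(stub_len)
    )
    m = rng.randint(15, 20)
    gi = rng.uniform(0.20, 0.25)
    length = int(m / gi)
    core = build_agp_core(m, length, 10, rng, past_filler_frac=0.7)
    seq = _filler(prefix_len, rng) + stub + "G" + core + _filler(10, rng)
    domain = (domain_name, prefix_len + 1, prefix_len + stub_len)
    return seq, domain


def _ext(rng) -> str:
    n_units = rng.randint(9, 11)
    unit_gap = 1
    units = []
    for _ in range(n_units):
        units.append("S" + "P" * 4 + _filler(unit_gap, rng))
    return _filler(rng.randint(15, 20), rng) + "".join(units)


def _prp(rng) -> str:
    n_plain = rng.randint(5, 7)
    pieces = []
    plain_done = 0
    ins_done = 0
    while plain_done < n_plain or ins_done < 2:
        if ins_done < 2 and plain_done >= 2 * (ins_done + 1):
            pieces.append("SP" + "G" + "PVKCYT")
            ins_done += 1
        else:
            pieces.append("SP" + "".join(rng.choice("AAS") for _ in range(4)))
            plain_done += 1
    pieces.append("SP")
    return _filler(20, rng) + "".join(pieces)


def _neg_gap(rng) -> str:
    parts = []
    for i in range(6):
        parts.append(rng.choice(("AP", "SP", "TP")))
        if i < 5:
            parts.append(_filler(rng.randint(11, 15), rng))
    return _filler(20, rng) + "".join(parts) + _filler(20, rng)


def _neg_sparse(rng) -> str:
    core = build_agp_core(2, rng.randint(8, 14), 10, rng, 0.5)
    return _filler(40, rng, past_frac=0.3) + core + _filler(40, rng, past_frac=0.3)


def _neg_lowpast(rng) -> str:
    # high glycomodule index but zero PAST filler: PAST_P = 200 * GlycoIndex
    m = rng.randint(12, 18)
    length = int(m / rng.uniform(0.20, 0.24))
    core = build_agp_core(m, length, 10, rng, past_filler_frac=0.0)
    return _filler(20, rng) + core + _filler(20, rng)


_BLAST_SEEDS = {
    "fla": "seed_FLA_known",
    "pag": "seed_PAG_known",
    "xylp": "seed_XYLP_known",
    "other_chimeric": "seed_AGP_known",
}
_DOMAIN_NAMES = {
    "fla": "fasciclin domain",
    "pag": "Plastocyanin-like",
    "xylp": "nsLTP-like",
    "other_chimeric": "PKc_like",
}


def expected_outcome(
    record: ProteinRecord,
    has_sp: bool,
    has_blast: bool,
    domains: list[DomainHit],
    config: ScreenConfig,
) -> tuple[str, str]:
    """Mirror the screen for a single protein: (outcome, subfamily).

    Outcomes: ``pass`` (a final candidate), ``removed_ext``,
    ``removed_prp``, ``fail`` (gate/group/threshold failure).  The same
    screening primitives used by ``run_screen`` are applied, so the frozen
    truth is the engine's own verdict on the construct.
    """
    v = compute_variables(
        record.sequence, max_gap=config.max_gap, min_modules=config.min_modules
    )
    if has_blast:
        branch, group = BLAST_BRANCH, None
        passed = pass_thresholds(v, BLAST_BRANCH, config)
    elif has_sp:
        branch = SP_BRANCH
        group = assign_group(v, config)
        passed = group is not None and pass_thresholds(v, group, config)
    else:
        return "fail", ""
    if not passed:
        return "fail", ""
    from .glyco import representative_sequence

    cand = Candidate(
        record=record,
        variables=v,
        branch=branch,
        group=group,
        agp_like_sequence=representative_sequence(record.sequence, list(v.regions)),
    )
    kept, removed_ext, removed_prp = remove_ext_prp([cand], config)
    if removed_ext:
        return "removed_ext", ""
    if removed_prp:
        return "removed_prp", ""
    return "pass", classify_subfamily(kept[0], domains, config)


def generate_proteome(
    config: SynthConfig, screen_config: ScreenConfig | None = None
) -> SyntheticProteome:
    """Build the proteome, annotation reports and frozen ground truth."""
    screen_config = screen_config or ScreenConfig()
    rng = random.Random(config.seed)

    plan: list[tuple[str, int]] = [
        ("classical", config.n_classical),
        ("pep", config.n_pep),
        ("kc", config.n_kc),
        ("hae", config.n_hae),
        ("fla", config.n_fla),
        ("pag", config.n_pag),
        ("xylp", config.n_xylp),
        ("other_chimeric", config.n_other_chimeric),
        ("ext", config.n_ext),
        ("prp", config.n_prp),
        ("neg_gap", config.n_neg_gap),
        ("neg_sparse", config.n_neg_sparse),
        ("neg_lowpast", config.n_neg_lowpast),
        ("background", config.n_background),
    ]

    records: list[ProteinRecord] = []
    truth_rows: list[dict] = []
    signalp_calls: dict[str, SignalPeptideCall] = {}
    blast_rows: list[tuple] = []
    domain_rows: list[tuple] = []
    domain_hits: dict[str, list[DomainHit]] = {}

    for cls, count in plan:
        for i in range(count):
            pid = f"{cls}_{i:04d}"
            domain = None
            wants_blast = False
            if cls == "classical":
                seq, wants_sp = _classical(rng), True
            elif cls == "pep":
                seq, wants_sp = _pep(rng), True
            elif cls == "kc":
                seq, wants_sp = _kc(rng, config.basic_len_range), True
            elif cls == "hae":
                seq, wants_sp = _hae(rng), True
            elif cls in ("fla", "pag", "xylp", "other_chimeric"):
                seq, domain = _chimeric(rng, _DOMAIN_NAMES[cls])
                wants_blast = True
                wants_sp = rng.random() >= config.chimeric_no_sp_frac
            elif cls == "ext":
                seq, wants_sp = _ext(rng), True
            elif cls == "prp":
                seq, wants_sp = _prp(rng), True
            elif cls == "neg_gap":
                seq, wants_sp = _neg_gap(rng), True
            elif cls == "neg_sparse":
                seq, wants_sp = _neg_sparse(rng), True
            elif cls == "neg_lowpast":
                seq, wants_sp = _neg_lowpast(rng), True
            else:  # background
                bias = rng.choice(config.background_past_bias)
                seq = build_background(rng.randint(100, 400), bias, rng)
                wants_sp = rng.random() < config.background_sp_rate

            record = ProteinRecord(id=pid, sequence=seq)
            records.append(record)

            d_score = (
                round(rng.uniform(0.45, 0.85), 3)
                if wants_sp
                else round(rng.uniform(0.05, 0.30), 3)
            )
            signalp_calls[pid] = SignalPeptideCall(pid, wants_sp, d_score)

            hits: list[DomainHit] = []
            if domain is not None:
                name, d_start, d_end = domain
                hits = [DomainHit(pid, name, d_start, d_end)]
                domain_hits[pid] = hits
                domain_rows.append((f"Q#{len(domain_rows) + 1} - >{pid}",
                                    "specific", name, d_start, d_end))
            if wants_blast:
                blast_rows.append(
                    (pid, _BLAST_SEEDS[cls], 85.0, 120, 18, 0, 1, 120, 1, 120,
                     1e-20, 250.0)
                )

            outcome, subfamily = expected_outcome(
                record, wants_sp, wants_blast, hits, screen_config
            )
            v = compute_variables(seq, max_gap=screen_config.max_gap,
                                  min_modules=screen_config.min_modules)
            truth_rows.append(
                {
                    "id": pid,
                    "planted_class": cls,
                    "length_t": v.length_t,
                    "past_t_pct": round(v.past_t_pct, 4),
                    "glyco_no_p": v.glyco_no_p,
                    "glyco_index": round(v.glyco_index, 6),
                    "past_p_pct": round(v.past_p_pct, 4),
                    "has_signal_peptide": wants_sp,
                    "has_blast_hit": wants_blast,
                    "expected_outcome": outcome,
                    "expected_subfamily": subfamily,
                }
            )

    order = list(range(len(records)))
    rng.shuffle(order)
    records = [records[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return SyntheticProteome(
        records=records,
        truth=truth,
        signalp_calls=signalp_calls,
        blast_rows=blast_rows,
        domain_rows=domain_rows,
        domain_hits=domain_hits,
    )
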