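"""The two-branch screen: gates, groups, thresholds, removal, classification."""

import dataclasses

import pytest

from conftest import blast_hits_from_rows
from finding_agp.glyco import VariableSet, compute_variables
from finding_agp.screening import (
    Candidate,
    GroupThresholds,
    ScreenConfig,
    assign_group,
    classify_subfamily,
    dedupe_branches,
    pass_thresholds,
    remove_ext_prp,
    run_screen,
    signal_peptide_gate,
)
from finding_agp.seqio import DomainHit, ProteinRecord, SignalPeptideCall


def make_variables(**overrides):
    base = dict(
        length_t=120, past_t_pct=60.0, glyco_no_t=10, length_p=50,
        past_p_pct=70.0, glyco_no_p=10, glyco_index=0.2,
    )
    base.update(overrides)
    return VariableSet(**base)


def make_candidate(seq, **kwargs):
    v = compute_variables(seq)
    defaults = dict(
        record=ProteinRecord(id=kwargs.pop("pid", "x"), sequence=seq),
        variables=v,
        branch="signal_peptide",
        group=2,
        agp_like_sequence="",
    )
    defaults.update(kwargs)
    return Candidate(**defaults)


class TestGateAndDedupe:
    def test_gate_keeps_positive_calls_only(self, caplog):
        records = [ProteinRecord("p1", "AP"), ProteinRecord("p2", "AP"),
                   ProteinRecord("p3", "AP")]
        calls = {
            "p1": SignalPeptideCall("p1", True),
            "p2": SignalPeptideCall("p2", False),
        }
        with caplog.at_level("WARNING"):
            kept = signal_peptide_gate(records, calls)
        assert [r.id for r in kept] == ["p1"]
        assert "1 records" in caplog.text  # p3 had no call

    def test_gate_empty_input(self):
        assert signal_peptide_gate([], {}) == []

    def test_dedupe_set_difference(self):
        sp_only, blast = dedupe_branches({"a", "b", "c"}, {"b", "d"})
        assert sp_only == {"a", "c"}
        assert blast == {"b", "d"}

    def test_dedupe_disjoint_unchanged(self):
        sp_only, blast = dedupe_branches({"a"}, {"b"})
        assert sp_only == {"a"} and blast == {"b"}


class TestGroups:
    @pytest.mark.parametrize(
        "length_t,past_t,expected",
        [
            (60, 90.0, 1),
            (55, 10.0, 1),
            (89, 10.0, 1),
            (120, 50.0, 2),
            (90, 42.0, 2),
            (120, 30.0, 3),
            (90, 41.9, 3),
            (40, 90.0, None),
            (54, 90.0, None),
        ],
    )
    def test_group_assignment(self, length_t, past_t, expected):
        v = make_variables(length_t=length_t, past_t_pct=past_t)
        assert assign_group(v, ScreenConfig()) == expected


class TestThresholds:
    def test_group2_module_count_floor(self):
        config = ScreenConfig()
        v = make_variables(glyco_no_p=4)
        assert not pass_thresholds(v, 2, config)
        assert pass_thresholds(make_variables(glyco_no_p=5), 2, config)

    def test_homology_branch_boundaries_inclusive(self):
        config = ScreenConfig()
        v = make_variables(glyco_index=0.13, past_p_pct=45.0)
        assert pass_thresholds(v, "homology", config)

    @pytest.mark.parametrize("gi,ok", [(0.149, False), (0.15, True)])
    def test_group1_glyco_index_boundary(self, gi, ok):
        v = make_variables(glyco_index=gi, past_p_pct=80.0)
        assert pass_thresholds(v, 1, ScreenConfig()) is ok

    def test_no_agp_like_sequence_fails_everywhere(self):
        v = make_variables(length_p=0, glyco_no_p=0, glyco_index=0.0,
                           has_agp_like=False)
        config = ScreenConfig()
        assert not any(
            pass_thresholds(v, g, config) for g in (1, 2, 3, "homology")
        )

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(pep_len_min=90, pep_len_max_exclusive=90)
        with pytest.raises(ValueError):
            ScreenConfig(group1=GroupThresholds(-0.1, 60))


class TestRemoveExtPrp:
    def test_pure_extensin_repeats_removed(self):
        seq = "SPPPPG" * 6
        cand = make_candidate(seq)
        kept, removed_ext, removed_prp = remove_ext_prp([cand], ScreenConfig())
        assert not kept and not removed_prp
        assert [c.record.id for c in removed_ext] == ["x"]

    def test_atagp1_kept_without_hybrid_flag(self, atagp1):
        kept, removed_ext, removed_prp = remove_ext_prp(
            [make_candidate(atagp1)], ScreenConfig()
        )
        assert len(kept) == 1
        assert not kept[0].hae_flag

    def test_isolated_motifs_keep_candidate_with_hybrid_flag(self, atagp1):
        seq = "SPPP" + "G" * 14 + atagp1 + "G" * 14 + "SPPP"
        cand = make_candidate(seq)
        kept, removed_ext, removed_prp = remove_ext_prp([cand], ScreenConfig())
        assert len(kept) == 1 and kept[0].hae_flag

    def test_prp_repeats_with_low_index_removed(self):
        seq = "SPAASA" * 2 + "SPGPVKCYT" + "SPAASA" * 2 + "SPGPVKCYT" + "SP"
        cand = make_candidate(seq)
        assert cand.variables.glyco_index < 0.20
        kept, removed_ext, removed_prp = remove_ext_prp([cand], ScreenConfig())
        assert [c.record.id for c in removed_prp] == ["x"]

    def test_prp_repeats_with_high_index_kept(self, atagp1):
        seq = atagp1 + "GPVKCYTG" + "GPVKCYTG"
        cand = make_candidate(seq)
        assert cand.variables.glyco_index >= 0.20
        kept, *_ = remove_ext_prp([cand], ScreenConfig())
        assert len(kept) == 1


class TestClassify:
    def test_short_no_domain_is_pep(self):
        cand = make_candidate("SPAPSPAP" * 8)  # 64 residues
        assert classify_subfamily(cand, [], ScreenConfig()) == "Pep"

    def test_fasciclin_domain_maps_to_fla(self):
        seq = "G" * 100 + "SPAPSPAPSPAP"
        cand = make_candidate(seq, pid="p9")
        hit = DomainHit("p9", "fasciclin domain", 1, 100)
        assert classify_subfamily(cand, [hit], ScreenConfig()) == "FLA"

    @pytest.mark.parametrize(
        "name,label",
        [("Plastocyanin-like", "PAG"), ("nsLTP", "XYLP"), ("Cu_bind_like", "PAG")],
    )
    def test_domain_vocabulary(self, name, label):
        seq = "G" * 100 + "SPAPSPAPSPAP"
        cand = make_candidate(seq)
        hit = DomainHit("x", name, 1, 100)
        assert classify_subfamily(cand, [hit], ScreenConfig()) == label

    def test_unknown_domain_outside_regions_is_other_chimeric(self):
        seq = "G" * 100 + "SPAPSPAPSPAP"
        cand = make_candidate(seq)
        hit = DomainHit("x", "totally_new_domain", 1, 100)
        assert classify_subfamily(cand, [hit], ScreenConfig()) == "other_chimeric"

    def test_domain_engulfed_by_agp_like_region_ignored(self, atagp1):
        cand = make_candidate(atagp1)  # 82 residues, one region [0, 82)
        hit = DomainHit("x", "mystery", 10, 30)
        assert classify_subfamily(cand, [hit], ScreenConfig()) == "Pep"

    def test_basic_region_between_regions_is_kc(self, atagp1):
        seq = atagp1 + "KGKVKGKKGKKHN" + atagp1
        cand = make_candidate(seq)
        assert len(cand.variables.regions) == 2
        assert classify_subfamily(cand, [], ScreenConfig()) == "KC"

    def test_long_past_rich_is_classical(self, atagp1):
        seq = atagp1 + "G" * 12 + atagp1  # 176 residues, PAST-rich
        cand = make_candidate(seq)
        assert classify_subfamily(cand, [], ScreenConfig()) == "C"

    def test_hybrid_flag_wins_over_classical(self, atagp1):
        seq = atagp1 + "G" * 12 + atagp1
        cand = make_candidate(seq, hae_flag=True)
        assert classify_subfamily(cand, [], ScreenConfig()) == "HAE"


class TestRunScreen:
    def test_module_free_proteome_yields_nothing(self):
        records = [ProteinRecord(f"p{i}", "MKWVLLLG" * 10) for i in range(5)]
        calls = {r.id: SignalPeptideCall(r.id, True) for r in records}
        candidates, summary = run_screen(records, calls, [])
        assert candidates == []
        assert summary.counts()["final_candidates"] == 0

    def test_branch_independence(self, small_proteome):
        p = small_proteome
        hits = blast_hits_from_rows(p.blast_rows)
        with_blast, _ = run_screen(p.records, p.signalp_calls, hits, p.domain_hits)
        without_blast, _ = run_screen(p.records, p.signalp_calls, [], p.domain_hits)
        sp_with = {c.record.id for c in with_blast if c.branch == "signal_peptide"}
        sp_without = {
            c.record.id for c in without_blast if c.branch == "signal_peptide"
        }
        assert sp_with <= sp_without  # dedupe can only shrink the SP branch
        assert not any(c.branch == "homology" for c in without_blast)

    def test_branches_disjoint_and_thresholds_hold(self, small_proteome):
        p = small_proteome
        config = ScreenConfig()
        candidates, summary = run_screen(
            p.records, p.signalp_calls, blast_hits_from_rows(p.blast_rows),
            p.domain_hits, config,
        )
        sp_ids = {c.record.id for c in candidates if c.branch == "signal_peptide"}
        blast_ids = {c.record.id for c in candidates if c.branch == "homology"}
        assert not sp_ids & blast_ids
        for c in candidates:
            key = c.group if c.branch == "signal_peptide" else "homology"
            assert pass_thresholds(c.variables, key, config)
            assert c.subfamily in {
                "Pep", "C", "KC", "HAE", "FLA", "PAG", "XYLP",
                "other_chimeric", "NC",
            }

    def test_threshold_monotonicity_over_grid(self, small_proteome):
        p = small_proteome
        hits = blast_hits_from_rows(p.blast_rows)
        previous = None
        for gi_min in (0.10, 0.15, 0.20, 0.25):
            config = ScreenConfig()
            for name in ("group1", "group2", "group3", "blast_branch"):
                t = getattr(config, name)
                setattr(
                    config, name,
                    dataclasses.replace(t, glyco_index_min=gi_min),
                )
            candidates, _ = run_screen(
                p.records, p.signalp_calls, hits, p.domain_hits, config
            )
            if previous is not None:
                assert len(candidates) <= previous
            previous = len(candidates)
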