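"""Flexibility statistics, ddG triage, the filter chain and reports."""

import itertools
import math

import numpy as np
import pytest
from conftest import synthetic_sasa

from rfscreen.conservation import conservation_profile, parse_alignment
from rfscreen.geometry import shrake_rupley_sasa
from rfscreen.screen import (
    KCAL_TO_KJ,
    DdgRecord,
    DdgTable,
    ScreenConfig,
    aggregate_residue_ddg,
    ddg_filter,
    flexibility_stats,
    load_ddg_table,
    parse_report,
    rank_candidates,
    screen_report,
    select_candidates,
)
from rfscreen.ss_turns import assign_secondary_structure, detect_beta_turns
from rfscreen.structure import format_residue_key
from rfscreen.synthetic import build_ddg_table, build_peptide, build_screen_fixture


def _pipeline_inputs(fx):
    s = fx.structure
    ss = assign_secondary_structure(s)
    turns = detect_beta_turns(s)
    sasa = synthetic_sasa(s, fx.surface_flags)
    stats = flexibility_stats(s, ss, sasa, fx.catalytic)
    table = load_ddg_table(fx.ddg_text, structure=s)
    profile = conservation_profile(parse_alignment(fx.msa_text, "query"))
    config = ScreenConfig(
        catalytic=fx.catalytic, min_catalytic_distance=fx.min_catalytic_distance
    )
    return s, ss, turns, sasa, stats, table, profile, config


# ---------------------------------------------------------------------------
# flexibility statistics

def test_group_means_simple_arithmetic():
    s, _ = build_peptide([("strand", 6)], seed=0,
                         b_factor_profile=[10, 20, 30, 40, 50, 60])
    ss = assign_secondary_structure(s)
    keys = [r.key for r in s.residues]
    surface = {k: (i < 2) for i, k in enumerate(keys)}
    sasa = synthetic_sasa(s, surface)
    stats = flexibility_stats(s, ss, sasa, [keys[-1]], shell_radius=0.1)
    assert stats.surface_mean == pytest.approx(15.0)   # (10+20)/2
    assert stats.buried_mean == pytest.approx(45.0)    # (30+40+50+60)/4
    # interior strand residues: 20..50
    assert stats.class_means["sheet"] == pytest.approx(np.mean([20, 30, 40, 50]))
    assert math.isnan(stats.class_means["helix"])      # empty group is NaN, not 0


def test_group_means_match_brute_force_recount():
    fx = build_screen_fixture(seed=13)
    s, ss, turns, sasa, stats, *_ = _pipeline_inputs(fx)
    for cls in ("helix", "sheet", "loop"):
        members = [k for k in stats.per_residue if ss[k] == cls]
        if members:
            assert stats.class_means[cls] == pytest.approx(
                np.mean([stats.per_residue[k] for k in members])
            )
        else:
            assert math.isnan(stats.class_means[cls])
    surf = [stats.per_residue[k] for k in stats.per_residue if sasa.surface[k]]
    assert stats.surface_mean == pytest.approx(np.mean(surf))


def test_catalytic_shell_membership():
    s, _ = build_peptide([("strand", 8)], seed=1)
    keys = [r.key for r in s.residues]
    ss = assign_secondary_structure(s)
    sasa = synthetic_sasa(s, {k: True for k in keys})
    stats = flexibility_stats(s, ss, sasa, [keys[3]], shell_radius=5.0)
    # neighbours along the chain are within 5 A; far ends are not
    assert keys[2] in stats.shell_residues and keys[4] in stats.shell_residues
    assert keys[3] not in stats.shell_residues
    assert keys[0] not in stats.shell_residues


# ---------------------------------------------------------------------------
# ddG table + filter

def test_saturation_table_count_and_units():
    positions = [(("A", i, ""), "A") for i in range(1, 21)]
    text, _ = build_ddg_table(positions, set(), seed=0)
    table = load_ddg_table(text)
    assert len(table) == 380            # 20 positions x 19 substitutions
    assert len(table.positions()) == 20

    kcal = "position\twild\tmut\tddg\nA:1\tA\tG\t1.0\n"
    rec = load_ddg_table(kcal, units="kcal/mol").records[0]
    assert rec.ddg == pytest.approx(KCAL_TO_KJ)


def test_wild_type_mismatch_and_duplicates_rejected():
    s, _ = build_peptide([("strand", 4)], seed=0, sequence="GGGG")
    bad = "position\twild\tmut\tddg\nA:1\tA\tP\t-1.0\n"
    with pytest.raises(ValueError, match="wild-type mismatch"):
        load_ddg_table(bad, structure=s)
    dup = "position\twild\tmut\tddg\nA:1\tG\tP\t-1.0\nA:1\tG\tP\t-2.0\n"
    with pytest.raises(ValueError, match="duplicate"):
        load_ddg_table(dup)


def test_ddg_partition_with_planted_stable_set():
    """65 stable of 380, mirroring a saturation screen where 315 mutants
    exceed the -0.5 kJ/mol error margin."""
    positions = [(("A", i, ""), "A") for i in range(1, 21)]
    rng = np.random.default_rng(5)
    all_subs = [(k, m) for k, _ in positions for m in "CDEFGHIKLMNPQRSTVWY"]
    picked = rng.choice(len(all_subs), size=65, replace=False)
    stable_set = {all_subs[i] for i in picked}
    text, _ = build_ddg_table(positions, stable_set, seed=6)
    table = load_ddg_table(text)
    stable, rest = ddg_filter(table, threshold=-0.5)
    assert len(stable) == 65
    assert len(rest) == 315
    assert {(r.position, r.mut_aa) for r in stable} == stable_set


def test_ddg_threshold_boundary_inclusive():
    table = DdgTable([DdgRecord(("A", 1, ""), "A", "P", -0.5),
                      DdgRecord(("A", 1, ""), "A", "G", -0.4999)])
    stable, rest = ddg_filter(table)
    assert [r.mut_aa for r in stable] == ["P"]
    all_stable, none = ddg_filter(
        DdgTable([DdgRecord(("A", 1, ""), "A", "P", -0.1)]), threshold=0.0
    )
    assert len(all_stable) == 1 and not none


def test_residue_level_ddg_aggregation():
    table = DdgTable([
        DdgRecord(("A", 1, ""), "A", "P", -2.0),
        DdgRecord(("A", 1, ""), "A", "G", 4.0),
        DdgRecord(("A", 2, ""), "A", "P", 1.0),
    ])
    assert aggregate_residue_ddg(table, "min") == {("A", 1, ""): -2.0, ("A", 2, ""): 1.0}
    assert aggregate_residue_ddg(table, "mean")[("A", 1, "")] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# filter chain

def test_planted_pass_set_recovered():
    for seed in (0, 1, 2, 3, 4):
        fx = build_screen_fixture(seed)
        s, ss, turns, sasa, stats, table, profile, config = _pipeline_inputs(fx)
        cands = select_candidates(s, ss, turns, sasa, stats, table, profile, config)
        assert {(c.position, c.mut_aa) for c in cands} == fx.expected_pass
        assert all(c.passes for c in cands)


def test_filter_chain_order_independent():
    fx = build_screen_fixture(seed=8)
    s, ss, turns, sasa, stats, table, profile, config = _pipeline_inputs(fx)
    full = {(c.position, c.mut_aa)
            for c in select_candidates(s, ss, turns, sasa, stats, table, profile, config)}

    single_filter_configs = {
        "loop": dict(require_surface=False, require_turn=False,
                     min_catalytic_distance=None, ddg_threshold=None,
                     conservation_veto=None),
        "surface": dict(require_loop=False, require_turn=False,
                        min_catalytic_distance=None, ddg_threshold=None,
                        conservation_veto=None),
        "turn": dict(require_loop=False, require_surface=False,
                     min_catalytic_distance=None, ddg_threshold=None,
                     conservation_veto=None),
        "distance": dict(require_loop=False, require_surface=False,
                         require_turn=False, ddg_threshold=None,
                         conservation_veto=None),
        "ddg": dict(require_loop=False, require_surface=False, require_turn=False,
                    min_catalytic_distance=None, conservation_veto=None),
        "conservation": dict(require_loop=False, require_surface=False,
                             require_turn=False, min_catalytic_distance=None,
                             ddg_threshold=None),
    }
    sets = {}
    for name, kwargs in single_filter_configs.items():
        kwargs.setdefault("min_catalytic_distance", fx.min_catalytic_distance
                          if name == "distance" else None)
        cfg = ScreenConfig(catalytic=fx.catalytic, **kwargs)
        sets[name] = {(c.position, c.mut_aa)
                      for c in select_candidates(s, ss, turns, sasa, stats,
                                                 table, profile, cfg)}
    for order in itertools.islice(itertools.permutations(sets), 6):
        acc = set.intersection(*(sets[name] for name in order))
        assert acc == full


def test_control_distance_fails_default_cutoff():
    """A turn sitting ~10.5 A from the catalytic residues fails the 13 A
    distance filter that accepted sites must clear."""
    fx = build_screen_fixture(seed=2)
    s, ss, turns, sasa, stats, table, profile, config = _pipeline_inputs(fx)
    config.min_catalytic_distance = 13.0
    cands = select_candidates(s, ss, turns, sasa, stats, table, profile, config)
    for c in cands:
        assert c.mean_catalytic_distance >= 13.0
    near = [t for t in turns if np.mean([
        np.linalg.norm(s[q].ca.coords - s[c].ca.coords)
        for q in t.residues for c in config.catalytic]) < 13.0]
    near_keys = {k for t in near for k in t.residues}
    assert not any(c.position in near_keys and c.turn_index in
                   {t.index for t in near} for c in cands)


def test_all_filters_disabled_returns_everything_ranked():
    fx = build_screen_fixture(seed=9)
    s, ss, turns, sasa, stats, table, profile, _ = _pipeline_inputs(fx)
    cfg = ScreenConfig(
        catalytic=fx.catalytic, require_loop=False, require_surface=False,
        require_turn=False, min_catalytic_distance=None, ddg_threshold=None,
        conservation_veto=None,
    )
    cands = select_candidates(s, ss, turns, sasa, stats, table, profile, cfg)
    assert len(cands) == len(table)
    scores = [c.rank_score for c in cands]
    assert scores == sorted(scores, reverse=True)


def test_empty_catalytic_set_with_distance_filter_is_config_error():
    fx = build_screen_fixture(seed=1)
    s, ss, turns, sasa, stats, table, profile, _ = _pipeline_inputs(fx)
    cfg = ScreenConfig(catalytic=(), min_catalytic_distance=13.0)
    with pytest.raises(ValueError, match="catalytic"):
        select_candidates(s, ss, turns, sasa, stats, table, profile, cfg)


def test_rank_score_monotone_in_ddg_under_fixed_normalization():
    fx = build_screen_fixture(seed=4)
    s, ss, turns, sasa, stats, table, profile, config = _pipeline_inputs(fx)
    cands = select_candidates(s, ss, turns, sasa, stats, table, profile, config)
    if len(cands) < 2:
        pytest.skip("fixture passed fewer than 2 candidates")
    norms = {
        "b_factor": (20.0, 5.0),
        "neg_ddg": (1.0, 0.5),
        "catalytic_distance": (15.0, 4.0),
        "preference": (1.0, 0.5),
    }
    target = cands[0]
    before = rank_candidates(list(cands), norms=norms)
    score_before = next(c.rank_score for c in before if c is target)
    target.ddg += 1.0   # more destabilizing
    after = rank_candidates(list(cands), norms=norms)
    score_after = next(c.rank_score for c in after if c is target)
    assert score_after < score_before


def test_config_file_round_trip_and_unknown_key():
    text = (
        "catalytic = A:1,A:2\n"
        "min_catalytic_distance = 12.5\n"
        "ddg_threshold = -0.5\n"
        "require_surface = false\n"
        "# comment\n"
    )
    cfg = ScreenConfig.from_text(text)
    assert cfg.catalytic == (("A", 1, ""), ("A", 2, ""))
    assert cfg.min_catalytic_distance == 12.5
    assert cfg.require_surface is False
    with pytest.raises(ValueError, match="unknown key"):
        ScreenConfig.from_text("no_such_threshold = 3\n")
    with pytest.raises(ValueError, match="range"):
        ScreenConfig(conservation_veto=2.0)


# ---------------------------------------------------------------------------
# reports

def test_report_round_trip_and_determinism():
    fx = build_screen_fixture(seed=6)
    cands = select_candidates(*_pipeline_inputs(fx))
    tsv = screen_report(cands, "tsv")
    js = screen_report(cands, "json")
    assert tsv == screen_report(cands, "tsv")
    df_tsv = parse_report(tsv, "tsv")
    df_js = parse_report(js, "json")
    assert len(df_tsv) == len(cands) == len(df_js)
    for col in ("position", "mut", "rank"):
        assert list(df_tsv[col]) == list(df_js[col])
    assert list(df_tsv["rank"]) == list(range(1, len(cands) + 1))


def test_empty_report_has_header_only():
    tsv = screen_report([], "tsv")
    lines = tsv.strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("rank\t")
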