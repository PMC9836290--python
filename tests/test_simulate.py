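import dataclasses
import math

import numpy as np
import pytest

from tnscreen import (
    SimConfig,
    SimTruth,
    evaluate_recovery,
    internal_window,
    plant_truth,
    run_screen,
    simulate_annotation,
    simulate_experiment,
    simulate_library,
)
from tnscreen.pipeline import ScreenVerdict


SMALL = SimConfig(
    genome_length=60_000,
    n_genes=30,
    n_insertions=1_600,
    depth=100_000,
    bottleneck_cells=1_000_000,
    seed=11,
)


def _simulate(config, **plant_kwargs):
    genes, seq = simulate_annotation(config)
    truth = plant_truth(genes, config, **plant_kwargs)
    library = simulate_library(genes, config, truth=truth, sequence=seq)
    profiles, sheet = simulate_experiment(library, truth, config)
    return genes, truth, library, profiles, sheet


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_annotation_genes_are_sorted_and_non_overlapping():
    genes, _ = simulate_annotation(SMALL)
    assert len(genes) == SMALL.n_genes
    for a, b in zip(genes, genes[1:]):
        assert a.end < b.start
    assert genes[-1].end <= SMALL.genome_length


def test_annotation_zero_genes():
    cfg = dataclasses.replace(SMALL, n_genes=0)
    genes, _ = simulate_annotation(cfg)
    assert genes == []


def test_annotation_error_when_genes_cannot_fit():
    cfg = dataclasses.replace(SMALL, genome_length=10_000)
    with pytest.raises(ValueError, match="cannot fit"):
        simulate_annotation(cfg)


def test_annotation_deterministic_under_fixed_seed():
    assert simulate_annotation(SMALL) == simulate_annotation(SMALL)
    other = dataclasses.replace(SMALL, seed=12)
    assert simulate_annotation(other)[0] != simulate_annotation(SMALL)[0]


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def test_library_mean_spacing_matches_site_density():
    # 100_000 sites on a genome sized for one site per 37 bp
    cfg = SimConfig(
        genome_length=3_700_000, n_genes=10, n_insertions=100_000, seed=3
    )
    genes, _ = simulate_annotation(cfg)
    lib = simulate_library(genes, cfg)
    spacing = np.diff(lib.positions).mean()
    assert spacing == pytest.approx(37.0, rel=0.05)


def test_library_sites_are_distinct_and_in_range():
    genes, _ = simulate_annotation(SMALL)
    lib = simulate_library(genes, SMALL)
    assert len(np.unique(lib.positions)) == SMALL.n_insertions
    assert lib.positions.min() >= 1 and lib.positions.max() <= SMALL.genome_length


def test_library_essential_windows_carry_no_sites():
    genes, _ = simulate_annotation(SMALL)
    truth = plant_truth(genes, SMALL, n_protective=0, n_detrimental=0, n_essential=5)
    lib = simulate_library(genes, SMALL, truth=truth)
    for gene in genes:
        if truth.label[gene.gene_id] == "essential":
            ws, we = internal_window(gene)
            assert not np.any((lib.positions >= ws) & (lib.positions <= we))


def test_library_too_many_sites_is_error():
    cfg = dataclasses.replace(SMALL, n_insertions=70_000)
    genes, _ = simulate_annotation(cfg)
    with pytest.raises(ValueError, match="exceeds"):
        simulate_library(genes, cfg)


def test_library_ta_restricted_sites_fall_on_ta_dinucleotides():
    cfg = dataclasses.replace(SMALL, ta_restricted=True, n_insertions=500)
    genes, seq = simulate_annotation(cfg)
    lib = simulate_library(genes, cfg, sequence=seq)
    for pos in lib.positions[:50]:
        assert seq[pos - 1 : pos + 1] == "TA"


def test_library_reproducible_under_fixed_seed():
    genes, _ = simulate_annotation(SMALL)
    a = simulate_library(genes, SMALL)
    b = simulate_library(genes, SMALL)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.abundance, b.abundance)


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------

def test_experiment_total_reads_equal_depth():
    _, _, _, profiles, _ = _simulate(SMALL)
    for p in profiles:
        assert sum(p.counts.values()) == SMALL.depth


def test_experiment_zero_depth_gives_empty_profiles():
    cfg = dataclasses.replace(SMALL, depth=0)
    _, _, _, profiles, _ = _simulate(cfg)
    assert all(p.counts == {} for p in profiles)


def test_experiment_lethal_gene_has_zero_treated_reads():
    genes, seq = simulate_annotation(SMALL)
    truth = plant_truth(genes, SMALL, n_protective=0, n_detrimental=0, n_essential=0)
    victim = genes[5]
    truth.survival[victim.gene_id] = 0.0
    truth.label[victim.gene_id] = "protective"
    library = simulate_library(genes, SMALL, truth=truth, sequence=seq)
    profiles, sheet = simulate_experiment(library, truth, SMALL)
    for p, s in zip(profiles, sheet):
        reads = sum(
            c for (ctg, pos), c in p.counts.items()
            if victim.start <= pos <= victim.end
        )
        if s.condition == "treated":
            assert reads == 0


def test_experiment_sample_sheet_matches_configured_times():
    _, _, _, profiles, sheet = _simulate(SMALL)
    controls = sorted(s.time_h for s in sheet if s.condition == "control")
    treated = sorted(s.time_h for s in sheet if s.condition == "treated")
    assert controls == list(SMALL.control_times)
    assert treated == list(SMALL.treated_times)
    assert {p.sample_id for p in profiles} == {s.sample_id for s in sheet}


def test_experiment_bit_reproducible_end_to_end():
    out1 = _simulate(SMALL)
    out2 = _simulate(SMALL)
    assert [p.counts for p in out1[3]] == [p.counts for p in out2[3]]
    r1 = run_screen(out1[3], out1[0], out1[4])
    r2 = run_screen(out2[3], out2[0], out2[4])
    assert r1.table.equals(r2.table)


def test_neutral_effects_give_fold_changes_centered_at_zero():
    """All survival equal, growth 1, large depth: per-gene FCs concentrate
    near 0 (law of large numbers)."""
    cfg = dataclasses.replace(SMALL, depth=1_000_000, seed=21)
    genes, truth, _, profiles, sheet = _simulate(
        cfg, n_protective=0, n_detrimental=0, n_essential=0
    )
    result = run_screen(profiles, genes, sheet)
    finals = [
        s.final(4.0).log2_fc
        for s in result.fc_series.values()
        if not math.isnan(s.final(4.0).log2_fc)
    ]
    assert abs(float(np.mean(finals))) < 0.1


def test_stronger_planted_effects_give_larger_fold_changes():
    """Expected |FC| grows with the planted survival ratio."""
    mean_abs = []
    for factor in (2.0, 5.0, 10.0):
        cfg = dataclasses.replace(SMALL, seed=31)
        genes, seq = simulate_annotation(cfg)
        truth = plant_truth(
            genes, cfg, n_protective=0, n_detrimental=5, n_essential=0,
            detrimental_factor=factor,
        )
        lib = simulate_library(genes, cfg, truth=truth, sequence=seq)
        profiles, sheet = simulate_experiment(lib, truth, cfg)
        result = run_screen(profiles, genes, sheet)
        fcs = [
            result.fc_series[g].final(4.0).log2_fc
            for g in truth.genes_with_label("detrimental")
        ]
        mean_abs.append(float(np.mean([abs(f) for f in fcs if math.isfinite(f)])))
    assert mean_abs[0] < mean_abs[1] < mean_abs[2]


# ---------------------------------------------------------------------------
# truth round trip and recovery scoring
# ---------------------------------------------------------------------------

def test_truth_round_trip(tmp_path):
    genes, _ = simulate_annotation(SMALL)
    truth = plant_truth(genes, SMALL, n_protective=3, n_detrimental=3, n_essential=2)
    truth.to_tsv(tmp_path / "truth.tsv")
    back = SimTruth.from_tsv(tmp_path / "truth.tsv")
    assert back.label == truth.label
    assert back.survival == pytest.approx(truth.survival)
    assert back.baseline_survival == pytest.approx(truth.baseline_survival)


def _verdict(gene_id, verdict):
    hit = verdict in ("depleted_hit", "enriched_hit")
    return ScreenVerdict(gene_id, verdict, hit, hit, hit, hit)


def _toy_truth():
    return SimTruth(
        baseline_survival=0.1,
        survival={"g1": 0.01, "g2": 1.0, "g3": 0.1, "g4": 0.1},
        growth={g: 1.0 for g in ("g1", "g2", "g3", "g4")},
        label={"g1": "protective", "g2": "detrimental", "g3": "neutral", "g4": "neutral"},
    )


def test_recovery_perfect_verdicts():
    verdicts = {
        "g1": _verdict("g1", "depleted_hit"),
        "g2": _verdict("g2", "enriched_hit"),
        "g3": _verdict("g3", "neutral"),
        "g4": _verdict("g4", "excluded"),
    }
    s = evaluate_recovery(verdicts, _toy_truth())
    assert (s.sensitivity, s.specificity, s.sign_accuracy) == (1.0, 1.0, 1.0)


def test_recovery_all_neutral_has_zero_sensitivity():
    verdicts = {g: _verdict(g, "neutral") for g in ("g1", "g2", "g3", "g4")}
    s = evaluate_recovery(verdicts, _toy_truth())
    assert s.sensitivity == 0.0 and s.specificity == 1.0


def test_recovery_wrong_sign_is_error_not_true_positive():
    verdicts = {
        "g1": _verdict("g1", "depleted_hit"),
        "g2": _verdict("g2", "depleted_hit"),  # detrimental called depleted
        "g3": _verdict("g3", "neutral"),
        "g4": _verdict("g4", "neutral"),
    }
    s = evaluate_recovery(verdicts, _toy_truth())
    assert s.tp == 1 and s.sign_errors == 1
    assert s.sensitivity == 0.5
    assert s.sign_accuracy == 0.5


def test_recovery_universe_mismatch_is_error():
    verdicts = {"g1": _verdict("g1", "neutral")}
    with pytest.raises(ValueError):
        evaluate_recovery(verdicts, _toy_truth())
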