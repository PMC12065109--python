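"""ΔC computation, rule derivation, imputation and rule serialization."""

import random

import numpy as np
import pytest

from porerules import (
    DeltaRecord,
    DeltaTable,
    DerivationConfig,
    ModelEntry,
    ModificationScheme,
    Rule,
    RuleSet,
    compute_delta,
    derive_rules,
    detect_trained_kmers,
    enumerate_modified_kmers,
    expand_alphabet,
    forward_apply,
    gen_canonical_model,
    gen_ruleset,
    impute,
    max_residual_median,
    read_rules,
    summarize_by_position,
    write_rules,
)


@pytest.fixture
def fig_toy_rules(toy_scheme):
    """Center-position shift −4, A-at-1 shift −2, T-at-3 shift +1."""
    return RuleSet(
        scheme=toy_scheme,
        k=3,
        rules=[
            Rule(2, "position", -4.0, order=0),
            Rule(2, "pattern", -2.0, pattern_position=1, pattern_base="A", order=1),
            Rule(2, "pattern", 1.0, pattern_position=3, pattern_base="T", order=2),
        ],
    )


# ---------------------------------------------------------------------------
# compute_delta


def test_delta_is_modified_minus_canonical(toy_scheme, canonical3):
    modified = expand_alphabet(canonical3, toy_scheme)
    modified.entries["AMA"].level_mean = canonical3.level("ACA") - 7.0
    table = compute_delta(canonical3, modified, toy_scheme, {"AMA"})
    assert table.records[0].delta == pytest.approx(-7.0)
    assert table.records[0].mod_position == 2


def test_delta_zero_for_pure_expansion(cg_scheme, canonical6):
    modified = expand_alphabet(canonical6, cg_scheme)
    table = compute_delta(
        canonical6, modified, cg_scheme, enumerate_modified_kmers(6, cg_scheme, False)
    )
    assert len(table) == 1280
    assert all(rec.delta == 0.0 for rec in table.records)


def test_delta_skips_invalid_trained_kmers_with_warning(cg_scheme, canonical6, caplog):
    modified = expand_alphabet(canonical6, cg_scheme, include_incomplete=True, include_multi=True)
    trained = {"AAAMGA", "AAAAAM", "MGMGAA"}  # valid, incomplete-motif, multi-mod
    with caplog.at_level("WARNING"):
        table = compute_delta(canonical6, modified, cg_scheme, trained)
    assert [rec.kmer for rec in table.records] == ["AAAMGA"]
    assert sum("skipping" in r.message for r in caplog.records) == 2


def test_delta_missing_trained_kmer_raises(cg_scheme, canonical6):
    modified = expand_alphabet(canonical6, cg_scheme)
    with pytest.raises(KeyError, match="absent"):
        compute_delta(canonical6, modified, cg_scheme, {"MGMGMG"})


def test_delta_matches_forward_apply_oracle(cg_scheme, canonical6):
    rules = gen_ruleset(cg_scheme, 6, 8, seed=5)
    modified = forward_apply(canonical6, rules)
    trained = enumerate_modified_kmers(6, cg_scheme, False)
    table = compute_delta(canonical6, modified, cg_scheme, trained)
    for rec in table.records:
        expected = sum(r.shift for r in rules.rules if r.matches(rec.kmer, rec.mod_position))
        assert rec.delta == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# derive_rules


def _toy_table(toy_scheme):
    # Group median −4; residuals leave AMA=−3 and AMC=−1 as the A-at-1 members.
    return DeltaTable(
        scheme=toy_scheme,
        k=3,
        records=[
            DeltaRecord("AMA", 2, -7.0),
            DeltaRecord("AMC", 2, -5.0),
            DeltaRecord("CMG", 2, -4.0),
            DeltaRecord("CMA", 2, -4.0),
            DeltaRecord("CMC", 2, -4.0),
        ],
    )


def test_derivation_reproduces_worked_median_example(toy_scheme):
    """Median of the A-at-1 residuals (−1 + (−3))/2 = −2 becomes the rule."""
    rules = derive_rules(_toy_table(toy_scheme))
    assert rules.rules[0].kind == "position"
    assert rules.rules[0].shift == pytest.approx(-4.0)
    first_pattern = rules.rules[1]
    assert (first_pattern.pattern_position, first_pattern.pattern_base) == (1, "A")
    assert first_pattern.shift == pytest.approx(-2.0)


def test_constant_deltas_give_position_rules_only(cg_scheme):
    records = [
        DeltaRecord(km, km.index("M") + 1, 3.5)
        for km in sorted(enumerate_modified_kmers(6, cg_scheme, False))
    ]
    rules = derive_rules(DeltaTable(scheme=cg_scheme, k=6, records=records))
    assert len(rules.pattern_rules()) == 0
    assert [r.shift for r in rules.rules] == pytest.approx([3.5] * 5)


def test_derivation_recovers_synthetic_ruleset(cg_scheme, canonical6):
    config = DerivationConfig(r=0.01)
    truth = gen_ruleset(cg_scheme, 6, 12, seed=9)
    modified = forward_apply(canonical6, truth)
    table = compute_delta(
        canonical6, modified, cg_scheme, enumerate_modified_kmers(6, cg_scheme, False)
    )
    derived = derive_rules(table, config)
    truth_shifts = {
        (r.mod_position, r.kind, r.pattern_position, r.pattern_base): r.shift
        for r in truth.rules
    }
    derived_shifts: dict = {}
    for r in derived.rules:
        key = (r.mod_position, r.kind, r.pattern_position, r.pattern_base)
        derived_shifts[key] = derived_shifts.get(key, 0.0) + r.shift
    for key, shift in truth_shifts.items():
        assert derived_shifts.get(key, 0.0) == pytest.approx(shift, abs=config.r)


def test_termination_certificate(cg_scheme, canonical6):
    config = DerivationConfig(r=0.01)
    truth = gen_ruleset(cg_scheme, 6, 20, seed=2)
    modified = forward_apply(canonical6, truth)
    table = compute_delta(
        canonical6, modified, cg_scheme, enumerate_modified_kmers(6, cg_scheme, False)
    )
    derived = derive_rules(table, config)
    assert max_residual_median(table, derived, config) <= config.r


def test_derivation_is_order_invariant(toy_scheme):
    table = _toy_table(toy_scheme)
    shuffled = DeltaTable(
        scheme=toy_scheme,
        k=3,
        records=random.Random(4).sample(table.records, len(table.records)),
    )
    assert derive_rules(table) == derive_rules(shuffled)


def test_position_rule_shift_equivariance(toy_scheme):
    table = _toy_table(toy_scheme)
    shifted = DeltaTable(
        scheme=toy_scheme,
        k=3,
        records=[DeltaRecord(r.kmer, r.mod_position, r.delta + 2.25) for r in table.records],
    )
    base, moved = derive_rules(table), derive_rules(shifted)
    assert moved.rules[0].shift == pytest.approx(base.rules[0].shift + 2.25)
    assert [(r.pattern_position, r.pattern_base) for r in moved.pattern_rules()] == [
        (r.pattern_position, r.pattern_base) for r in base.pattern_rules()
    ]
    assert [r.shift for r in moved.pattern_rules()] == pytest.approx(
        [r.shift for r in base.pattern_rules()]
    )


def test_derivation_idempotent_on_reconstructed_table(cg_scheme, canonical6):
    config = DerivationConfig(r=0.01)
    truth = gen_ruleset(cg_scheme, 6, 10, seed=13)
    table = compute_delta(
        canonical6,
        forward_apply(canonical6, truth),
        cg_scheme,
        enumerate_modified_kmers(6, cg_scheme, False),
    )
    first = derive_rules(table, config)
    # rebuild the ΔC table from the derived rules and re-derive
    rebuilt = compute_delta(
        canonical6,
        forward_apply(canonical6, first),
        cg_scheme,
        {rec.kmer for rec in table.records},
    )
    second = derive_rules(rebuilt, config)
    for a, b in zip(first.rules, second.rules):
        assert (a.mod_position, a.kind, a.pattern_position, a.pattern_base) == (
            b.mod_position,
            b.kind,
            b.pattern_position,
            b.pattern_base,
        )
        assert b.shift == pytest.approx(a.shift, abs=config.r)


def test_empty_delta_table_rejected(cg_scheme):
    with pytest.raises(ValueError, match="empty"):
        derive_rules(DeltaTable(scheme=cg_scheme, k=6, records=[]))


# ---------------------------------------------------------------------------
# summarize_by_position


def test_position_summary_matches_position_rules(cg_scheme, canonical6):
    truth = gen_ruleset(cg_scheme, 6, 6, seed=21)
    table = compute_delta(
        canonical6,
        forward_apply(canonical6, truth),
        cg_scheme,
        enumerate_modified_kmers(6, cg_scheme, False),
    )
    summary = summarize_by_position(table)
    derived = derive_rules(table)
    for m, row in summary.items():
        assert row["median"] == pytest.approx(derived.position_rule(m).shift)
        assert row["count"] == 256


def test_position_summary_constant_table(toy_scheme):
    table = DeltaTable(
        scheme=toy_scheme,
        k=3,
        records=[DeltaRecord("AMA", 2, 1.5), DeltaRecord("GMG", 2, 1.5), DeltaRecord("MAA", 1, 1.5)],
    )
    summary = summarize_by_position(table)
    assert summary[1] == {"median": 1.5, "count": 1}
    assert summary[2] == {"median": 1.5, "count": 2}


# ---------------------------------------------------------------------------
# impute


def test_impute_worked_example(fig_toy_rules, canonical3):
    canonical3 = canonical3.copy()
    canonical3.entries["ACT"] = ModelEntry("ACT", 11.0, 2.0)
    full = impute(canonical3, fig_toy_rules, mode="full")
    assert full.level("AMT") == pytest.approx(6.0)  # 11 + (−4 − 2 + 1)


def test_impute_empty_rules_copies_canonical(cg_scheme, canonical6):
    rules = RuleSet(scheme=cg_scheme, k=6, rules=[])
    full = impute(canonical6, rules, mode="full")
    for km in full.modified_kmers():
        assert full.level(km) == canonical6.level(cg_scheme.canonicalize(km))


def test_impute_missing_partitions_trained_and_imputed(cg_scheme, canonical6):
    truth = gen_ruleset(cg_scheme, 6, 8, seed=31)
    trained_model = forward_apply(canonical6, truth)
    rng = np.random.default_rng(0)
    universe = sorted(enumerate_modified_kmers(6, cg_scheme, False))
    trained = {universe[i] for i in rng.choice(len(universe), size=300, replace=False)}
    # trained values perturbed so verbatim copying is observable
    for km in trained:
        trained_model.entries[km].level_mean += 0.123
    missing = impute(
        canonical6, truth, mode="missing", trained_model=trained_model, trained=trained
    )
    full = impute(canonical6, truth, mode="full")
    for km in universe:
        if km in trained:
            assert missing.entries[km].level_mean == trained_model.entries[km].level_mean
            assert missing.entries[km].level_stdv == trained_model.entries[km].level_stdv
        else:
            assert missing.entries[km].level_mean == full.entries[km].level_mean


def test_impute_equals_forward_apply(cg_scheme, canonical6):
    rules = gen_ruleset(cg_scheme, 6, 15, seed=8)
    full = impute(canonical6, rules, mode="full", include_multi=True)
    oracle = forward_apply(canonical6, rules, include_multi=True)
    assert set(full.entries) == set(oracle.entries)
    for km in full.entries:
        assert full.level(km) == pytest.approx(oracle.level(km), abs=1e-12)


def test_impute_multi_modification_sums_per_position(cg_scheme, canonical6):
    rules = gen_ruleset(cg_scheme, 6, 10, seed=17)
    full = impute(canonical6, rules, mode="full", include_multi=True)
    km = "MGMGMG"
    expected = canonical6.level("CGCGCG")
    for m in (1, 3, 5):
        expected += sum(r.shift for r in rules.rules if r.matches(km, m))
    assert full.level(km) == pytest.approx(expected)


def test_pattern_never_matches_modification_code(cg_scheme, canonical6):
    # A rule keyed on base C at position 3 must not fire for an M at position 3.
    rules = RuleSet(
        scheme=cg_scheme,
        k=6,
        rules=[
            Rule(1, "position", -1.0, order=0),
            Rule(3, "position", -2.0, order=1),
            Rule(1, "pattern", 5.0, pattern_position=3, pattern_base="C", order=2),
        ],
    )
    full = impute(canonical6, rules, mode="full", include_multi=True)
    # MGMGAA is modified at 1 and 3; position 3 holds M, not C
    assert full.level("MGMGAA") == pytest.approx(canonical6.level("CGCGAA") - 3.0)


def test_impute_stdv_from_canonical_counterpart(cg_scheme, canonical6):
    rules = gen_ruleset(cg_scheme, 6, 4, seed=3)
    full = impute(canonical6, rules, mode="full")
    for km in full.modified_kmers():
        assert full.entries[km].level_stdv == canonical6.entries[cg_scheme.canonicalize(km)].level_stdv


def test_impute_k_mismatch_rejected(cg_scheme, canonical3):
    rules = RuleSet(scheme=cg_scheme, k=6, rules=[])
    with pytest.raises(ValueError, match="incompatible"):
        impute(canonical3, rules)


def test_detect_trained_kmers_by_stdv_convention(cg_scheme, canonical6):
    expanded = expand_alphabet(canonical6, cg_scheme, stdv_increment=1.0)
    trained = {"AAAMGA", "TTTMGT", "MGAAAA"}
    for km in trained:
        expanded.entries[km].level_mean += 2.0
        expanded.entries[km].level_stdv = 2.2  # training overwrote the placeholder
    assert detect_trained_kmers(expanded, canonical6, cg_scheme) == trained


# ---------------------------------------------------------------------------
# rule serialization


def test_pattern_strings(cg_scheme):
    rule = Rule(4, "pattern", -4.10, pattern_position=3, pattern_base="T")
    assert rule.pattern_string(6, cg_scheme) == "NNTMGN"
    pos = Rule(1, "position", -0.85)
    assert pos.pattern_string(6, cg_scheme) == "MGNNNN"


def test_pattern_string_gpc(gc_scheme):
    # GpC: modified C preceded by G; mod at position 2 puts the G at 1
    rule = Rule(2, "pattern", 1.0, pattern_position=4, pattern_base="A")
    assert rule.pattern_string(6, gc_scheme) == "GMNANN"


def test_rules_roundtrip(tmp_path, cg_scheme):
    rules = gen_ruleset(cg_scheme, 6, 9, seed=77)
    p = tmp_path / "rules.tsv"
    write_rules(rules, p)
    back = read_rules(p)
    assert back == rules


def test_read_rules_rejects_malformed_pattern(tmp_path, cg_scheme):
    p = tmp_path / "rules.tsv"
    p.write_text("#k=6\n#scheme=CG:0:M\norder\tkind\tpattern\tshift\n0\tposition\tNNNNNN\t1.0\n")
    with pytest.raises(ValueError, match="malformed"):
        read_rules(p)
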