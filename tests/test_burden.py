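import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from var3d.burden import (
    ALL_GENES,
    AssociationTable,
    BurdenConfig,
    ContingencyTable,
    build_table,
    correct_p,
    dedupe_variants,
    derive_associations,
    fisher_two_sided,
    or_ci,
    relative_risk,
    results_to_frame,
    run_burden,
    sample_or,
)
from var3d.simulate import (
    DEFAULT_PREVALENCE,
    SimulationConfig,
    simulate_cohort,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided p: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed
    that of the observed table."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


# ---------------------------------------------------------------------------
# Component statistics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "table,expected",
    [
        ((10, 10, 10, 10), 1.0),
        ((5, 0, 0, 5), 2 / 252),  # enumeration over margins (5,5;5,5)
        ((2, 1, 1, 2), 1.0),  # all tables with margins (3,3;3,3) qualify
    ],
)
def test_fisher_known_values(table, expected):
    assert fisher_two_sided(ContingencyTable(*table)) == pytest.approx(expected)


def test_fisher_untestable_margin_errors():
    with pytest.raises(ValueError):
        fisher_two_sided(ContingencyTable(0, 0, 3, 4))


@given(st.tuples(*[st.integers(min_value=0, max_value=12)] * 4))
@settings(derandomize=True, max_examples=150)
def test_fisher_transposition_invariance(cells):
    """Swapping the pathogenic/population rows inverts the OR and leaves
    the two-sided p unchanged."""
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    tt = ContingencyTable(c, d, a, b)
    if not t.untestable:
        assert fisher_two_sided(t) == pytest.approx(fisher_two_sided(tt))
        or1, or2 = sample_or(t), sample_or(tt)
        if not math.isnan(or1) and 0 < or1 < math.inf:
            assert or2 == pytest.approx(1 / or1)


@pytest.mark.parametrize(
    "table,expected",
    [
        ((10, 10, 10, 10), 1.0),
        ((0, 7, 4, 9), 0.0),  # zero numerator cell -> exact 0
        ((5, 1, 1, 5), 25.0),
        ((3, 0, 2, 4), math.inf),
    ],
)
def test_sample_or(table, expected):
    assert sample_or(ContingencyTable(*table)) == expected


def test_sample_or_degenerate_nan():
    assert math.isnan(sample_or(ContingencyTable(0, 3, 0, 4)))


def test_or_ci_balanced_table_formula():
    lo, hi = or_ci(ContingencyTable(10, 10, 10, 10))
    z = stats.norm.ppf(0.975)
    assert lo == pytest.approx(math.exp(-z * math.sqrt(0.4)))
    assert hi == pytest.approx(math.exp(z * math.sqrt(0.4)))


def test_or_ci_symmetric_about_one_on_log_scale():
    lo, hi = or_ci(ContingencyTable(7, 3, 7, 3))
    assert math.log(lo) == pytest.approx(-math.log(hi))


def test_or_ci_zero_cell_uses_haldane_correction():
    t = ContingencyTable(5, 0, 2, 7)
    lo, hi = or_ci(t)
    corrected_or = (5.5 * 7.5) / (0.5 * 2.5)
    assert 0 < lo < corrected_or < hi < math.inf


@pytest.mark.parametrize(
    "p,m,q", [(1e-5, 1000, 0.01), (0.5, 1000, 1.0), (0.0, 1000, 0.0)]
)
def test_correct_p(p, m, q):
    assert correct_p(p, m) == pytest.approx(q)


@given(
    st.floats(min_value=0, max_value=1),
    st.floats(min_value=0, max_value=1),
    st.integers(min_value=1, max_value=10_000),
)
@settings(derandomize=True, max_examples=100)
def test_correct_p_monotone(p1, p2, m):
    if p1 > p2:
        p1, p2 = p2, p1
    assert correct_p(p1, m) <= correct_p(p2, m)
    assert correct_p(p1, m) >= p1


@pytest.mark.parametrize(
    "table,expected",
    [((10, 10, 10, 10), 1.0), ((8, 2, 2, 8), 4.0), ((0, 5, 3, 4), 0.0)],
)
def test_relative_risk(table, expected):
    assert relative_risk(ContingencyTable(*table)) == pytest.approx(expected)


def test_relative_risk_zero_denominator():
    assert math.isnan(relative_risk(ContingencyTable(0, 0, 3, 4)))


def test_rr_approximates_or_when_pathogenic_is_rare():
    """When pathogenic variants make up <=10% of the feature carriers
    and of the non-carriers, RR is within 25% of OR (the concordance the
    all-genes analysis reports)."""
    rng = np.random.default_rng(5)
    checked = 0
    while checked < 50:
        c, d = rng.integers(500, 2000, 2)
        a = rng.integers(1, c // 10)
        b = rng.integers(1, d // 10)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        or_, rr = sample_or(t), relative_risk(t)
        assert abs(rr - or_) / or_ <= 0.25
        checked += 1


# ---------------------------------------------------------------------------
# Tables from cohorts
# ---------------------------------------------------------------------------

def _toy_inputs():
    variants = pd.DataFrame(
        {
            "gene": ["G1"] * 6 + ["G2"] * 4,
            "protein": ["G1"] * 6 + ["G2"] * 4,
            "pos": [1, 2, 3, 4, 5, 6, 1, 2, 3, 4],
            "ref_aa": list("AAAAAAAAAA"),
            "alt_aa": list("VVVVVVVVVV"),
            "label": [
                "pathogenic", "pathogenic", "pathogenic",
                "population", "population", "population",
                "pathogenic", "benign", "population", "benign",
            ],
            "source": "t",
        }
    )
    features = pd.DataFrame(
        {
            "protein": ["G1"] * 6 + ["G2"] * 4,
            "pos": [1, 2, 3, 4, 5, 6, 1, 2, 3, 4],
            "resolved": 1,
            "f1": [1, 1, 0, 1, 0, 0, 1, 1, 0, 0],
        }
    )
    class_map = pd.DataFrame(
        {"gene": ["G1", "G1", "G2"], "class": ["kinase", "transporter", "kinase"]}
    )
    return variants, features, class_map


def test_build_table_direct_count():
    variants, features, class_map = _toy_inputs()
    t = build_table(
        variants[variants["gene"] == "G1"], features, "f1", ALL_GENES, class_map
    )
    assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)


def test_build_table_multiclass_gene_counts_in_both_groups():
    variants, features, class_map = _toy_inputs()
    kin = build_table(variants, features, "f1", "kinase", class_map)
    tra = build_table(variants, features, "f1", "transporter", class_map)
    # G1 belongs to both classes; its 6 qualifying variants appear in each
    assert kin.n == 8  # G1 (6) + G2 pathogenic/population (2)
    assert tra.n == 6


def test_build_table_excludes_benign_validation_variants():
    variants, features, class_map = _toy_inputs()
    t = build_table(variants, features, "f1", ALL_GENES, class_map)
    n_benign = (variants["label"] == "benign").sum()
    assert n_benign == 2
    assert t.n == len(variants) - n_benign


def test_dedupe_prefers_pathogenic_label():
    variants, _, _ = _toy_inputs()
    dup = pd.concat(
        [variants, variants.iloc[[3]].assign(label="pathogenic", source="other")],
        ignore_index=True,
    )
    deduped = dedupe_variants(dup)
    assert len(deduped) == len(variants)
    row = deduped[(deduped["gene"] == "G1") & (deduped["pos"] == 4)]
    assert row["label"].tolist() == ["pathogenic"]


# ---------------------------------------------------------------------------
# Cohort-level runs
# ---------------------------------------------------------------------------

def test_run_burden_recovers_planted_19_fold_association():
    """A disulfide-like feature planted at OR = 19 lands in the
    pathogenic association set of the all-genes group."""
    prev = dict(DEFAULT_PREVALENCE, bond_disulfide=0.05)
    config = SimulationConfig(
        seed=7,
        n_genes=80,
        protein_length_range=(100, 200),
        class_labels={"simulated": 1.0},
        feature_prevalence=prev,
        planted_log_or={"bond_disulfide": math.log(19.0)},
        n_variants_per_gene=250,
        n_validation_per_gene=0,
    )
    cohort = simulate_cohort(config)
    results = run_burden(
        cohort.discovery, cohort.residues, cohort.class_map,
        config=BurdenConfig(correction=1000),
    )
    assoc = derive_associations(results)
    assert "bond_disulfide" in assoc.pathogenic(ALL_GENES)
    row = next(
        r for r in results if r.group == ALL_GENES and r.feature == "bond_disulfide"
    )
    assert row.ci_low <= 19.0 <= row.ci_high


def test_run_burden_absent_feature_untestable(cohort):
    variants = cohort.discovery
    features = cohort.residues.copy()
    features["ss_helix_pi"] = 0
    results = run_burden(variants, features, cohort.class_map)
    for r in results:
        if r.feature == "ss_helix_pi":
            assert r.association == "none"
            assert math.isnan(r.p)


def test_results_frame_sorted_and_complete(cohort):
    results = run_burden(cohort.discovery, cohort.residues, cohort.class_map)
    df = results_to_frame(results)
    n_groups = cohort.class_map["class"].nunique() + 1
    assert len(df) == 40 * n_groups
    assert df[["group", "feature"]].apply(tuple, axis=1).is_monotonic_increasing


def test_association_sets_disjoint_and_roundtrip(tmp_path, cohort):
    results = run_burden(cohort.discovery, cohort.residues, cohort.class_map)
    assoc = derive_associations(results)
    for g in assoc.groups:
        assert not assoc.pathogenic(g) & assoc.population(g)
    path = tmp_path / "assoc.tsv"
    assoc.write(path)
    back = AssociationTable.read(path)
    for g in assoc.groups:
        if assoc.pathogenic(g) or assoc.population(g):
            assert back.pathogenic(g) == assoc.pathogenic(g)
            assert back.population(g) == assoc.population(g)


def test_association_swap_invariance(cohort):
    """Inverting feature presence inverts the OR and swaps the
    association label."""
    variants = cohort.discovery
    flipped = cohort.residues.copy()
    flipped["func_modular_domain"] = 1 - flipped["func_modular_domain"]
    res = run_burden(variants, cohort.residues, cohort.class_map,
                     config=BurdenConfig(correction=1000))
    res_f = run_burden(variants, flipped, cohort.class_map,
                       config=BurdenConfig(correction=1000))
    for r, rf in zip(res, res_f):
        if r.feature != "func_modular_domain" or math.isnan(r.p):
            continue
        assert rf.p == pytest.approx(r.p)
        swap = {"pathogenic": "population", "population": "pathogenic", "none": "none"}
        assert rf.association == swap[r.association]
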