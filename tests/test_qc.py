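"""QC stages: allele stats, HWE mid-p exact test, KING-robust kinship,
relatedness pruning and variant filters."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from giacall import (ContractError, EmptyOutputError, ReferencePanel,
                     WorkflowConfig, allele_stats, apply_variant_filters,
                     exclude_samples, hwe_exact_p, hwe_midp, king_robust,
                     kinship_matrix, prune_related, simulate_pair)

from conftest import make_matrix


# --- independent enumeration oracle (exact rational arithmetic) -----------

def hwe_midp_oracle(n_refhom: int, n_het: int, n_althom: int) -> float:
    """Full enumeration of heterozygote-count tables with exact Fractions."""
    n = n_refhom + n_het + n_althom
    rare = n_het + 2 * min(n_refhom, n_althom)
    weights = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hom_min = (rare - h) // 2
        hom_maj = n - h - hom_min
        weights[h] = Fraction(2 ** h * factorial(n),
                              factorial(hom_maj) * factorial(h)
                              * factorial(hom_min))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    midp = sum(p for p in probs.values() if p < obs) \
        + Fraction(1, 2) * sum(p for p in probs.values() if p == obs)
    return float(midp)


@pytest.mark.parametrize("table", [
    (5, 0, 0),        # monomorphic: single table, half weight
    (0, 2, 0),        # N=2, support {0, 2}
    (10, 10, 10),
    (0, 200, 0),
    (25, 3, 22),
    (1, 1, 48),
])
def test_hwe_midp_matches_enumeration_oracle(table):
    assert hwe_midp(*table) == pytest.approx(
        hwe_midp_oracle(*table), rel=1e-12)


def test_hwe_midp_monomorphic_is_half():
    assert hwe_midp(7, 0, 0) == 0.5
    assert hwe_midp(0, 0, 7) == 0.5


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_hwe_midp_property_sweep(n0, n1, n2):
    """Mid-p equals the exact-rational oracle for every table N <= 50 and
    is strictly below the plain exact p whenever >= 2 tables exist."""
    if n0 + n1 + n2 == 0 or n0 + n1 + n2 > 50:
        return
    midp = hwe_midp(n0, n1, n2)
    assert midp == pytest.approx(hwe_midp_oracle(n0, n1, n2), rel=1e-12)
    rare = n1 + 2 * min(n0, n2)
    n = n0 + n1 + n2
    n_tables = len(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))
    if n_tables >= 2:
        assert midp < hwe_exact_p(n0, n1, n2)


def test_hwe_contract_error():
    with pytest.raises(ContractError):
        hwe_midp(-1, 2, 3)


@pytest.mark.parametrize("dosages,exp_freq,exp_maf,exp_counts", [
    ([0, 0, 1, 2], 0.375, 0.375, (2, 1, 1)),
    ([0] * 100, 0.0, 0.0, (100, 0, 0)),
    ([2, 2, 2], 1.0, 0.0, (0, 0, 3)),
])
def test_allele_stats(dosages, exp_freq, exp_maf, exp_counts):
    m = make_matrix(np.array(dosages)[:, None])
    freq, maf, counts = allele_stats(m, 0)
    assert freq == pytest.approx(exp_freq)
    assert maf == pytest.approx(exp_maf)
    assert counts == exp_counts


# --- KING-robust ----------------------------------------------------------

def test_king_identity_and_symmetry():
    g = np.array([0, 1, 2, 1, 0, 1])
    est = king_robust(g, g)
    assert est.phi == 0.5
    h = np.array([1, 1, 0, 2, 0, 1])
    assert king_robust(g, h).phi == pytest.approx(king_robust(h, g).phi)


def test_king_undefined_without_heterozygotes():
    est = king_robust(np.zeros(50, dtype=int), np.full(50, 2))
    assert np.isnan(est.phi)


def test_king_length_mismatch():
    with pytest.raises(ContractError):
        king_robust(np.zeros(3), np.zeros(4))


@pytest.mark.parametrize("relationship,expected,tol", [
    ("duplicate", 0.5, 1e-12),
    ("parent_offspring", 0.25, 0.05),
    ("full_sib", 0.25, 0.05),
    ("unrelated", 0.0, 0.05),
])
def test_king_pedigree_recovery(relationship, expected, tol):
    """Simulated pairs at 5000 loci recover pedigree kinship."""
    rng = np.random.default_rng(123)
    f = rng.uniform(0.1, 0.9, size=5000)
    g1, g2 = simulate_pair(relationship, f, seed=99)
    assert king_robust(g1, g2).phi == pytest.approx(expected, abs=tol)


def test_kinship_matrix_matches_pairwise():
    rng = np.random.default_rng(5)
    d = rng.integers(0, 3, size=(6, 300))
    m = make_matrix(d)
    phi = kinship_matrix(m)
    for i in range(6):
        for j in range(6):
            expected = king_robust(d[i], d[j]).phi
            assert phi[i, j] == pytest.approx(expected, rel=1e-12)


# --- relatedness pruning --------------------------------------------------

def _panel_from(dosages, labels):
    m = make_matrix(np.asarray(dosages), sample_prefix="P")
    return ReferencePanel(genotypes=m,
                          labels={s: l for s, l in zip(m.samples, labels)})


def test_prune_removes_duplicate(cfg):
    rng = np.random.default_rng(17)
    f = rng.uniform(0.2, 0.8, 800)
    base = rng.binomial(2, f, size=(4, 800))
    dup = np.vstack([base, base[0]])  # P4 duplicates P0
    panel = _panel_from(dup, ["EUR", "EUR", "AFR", "AFR", "EUR"])
    pruned = prune_related(panel, cfg)
    assert pruned.genotypes.n_samples == 4
    assert ("P0" in pruned.genotypes.samples) ^ ("P4" in pruned.genotypes.samples)


def test_prune_unrelated_identity(cfg):
    rng = np.random.default_rng(18)
    f = rng.uniform(0.2, 0.8, 2000)
    dosages = rng.binomial(2, f, size=(5, 2000))
    panel = _panel_from(dosages, ["EUR", "EUR", "AFR", "AFR", "EUR"])
    pruned = prune_related(panel, cfg)
    assert pruned.genotypes.samples == panel.genotypes.samples


def test_prune_star_graph_removes_hub(cfg):
    """A star relatedness graph: a mosaic hub sample shares one third of
    its loci with each of three mutually unrelated donors (phi ~ 1/6 to
    each, donors ~ 0 to each other).  Removing the hub is the brute-force
    minimum removal on this 4-node graph, and greedy max-degree removal
    finds it, retaining all three donors."""
    rng = np.random.default_rng(19)
    n_loci = 6000
    f = rng.uniform(0.2, 0.8, n_loci)
    donors = rng.binomial(2, f, size=(3, n_loci))
    hub = np.empty(n_loci, dtype=int)
    for k in range(3):  # copy donor k's genotype on a third of the loci
        hub[k::3] = donors[k, k::3]
    rows = np.vstack([hub, donors, rng.binomial(2, f, size=(2, n_loci))])
    panel = _panel_from(rows, ["EUR"] * 4 + ["AFR", "AFR"])
    phi = kinship_matrix(panel.genotypes)
    assert all(phi[0, i] > cfg.king_threshold for i in (1, 2, 3))
    assert all(abs(phi[i, j]) < cfg.king_threshold
               for i, j in ((1, 2), (1, 3), (2, 3)))
    pruned = prune_related(panel, cfg)
    kept = pruned.genotypes.samples
    assert "P0" not in kept          # the hub goes
    assert {"P1", "P2", "P3"} <= set(kept)
    phi = kinship_matrix(pruned.genotypes)
    np.fill_diagonal(phi, np.nan)
    assert np.nanmax(phi) <= cfg.king_threshold


def test_prune_post_invariant(small_panel, cfg):
    panel, _, _ = small_panel
    pruned = prune_related(panel, cfg)
    phi = kinship_matrix(pruned.genotypes)
    np.fill_diagonal(phi, np.nan)
    assert np.nanmax(phi) <= cfg.king_threshold


# --- variant filters ------------------------------------------------------

def test_filters_remove_low_maf_and_all_het(cfg):
    """A 1-in-2000-allele singleton fails MAF; an all-heterozygote column
    at N=200 fails HWE; a balanced HWE column survives."""
    rng = np.random.default_rng(31)
    n = 1000
    singleton = np.zeros(n, dtype=int)
    singleton[0] = 1                       # maf 0.0005 <= 0.001
    all_het = np.ones(n, dtype=int)        # extreme heterozygote excess
    hwe_ok = rng.binomial(2, 0.3, n)
    m = make_matrix(np.stack([singleton, all_het, hwe_ok], axis=1))
    out = apply_variant_filters(m, cfg)
    assert [v.id for v in out.variants] == ["v2"]


def test_filters_idempotent_and_subset(small_panel, cfg):
    panel, _, _ = small_panel
    once = apply_variant_filters(panel.genotypes, cfg)
    assert set(v.key for v in once.variants) <= set(
        v.key for v in panel.genotypes.variants)
    twice = apply_variant_filters(once, cfg)
    assert twice.variants == once.variants


def test_filters_empty_output_error(cfg):
    m = make_matrix(np.zeros((50, 3), dtype=int))  # all monomorphic
    with pytest.raises(EmptyOutputError):
        apply_variant_filters(m, cfg)


# --- sample exclusion -----------------------------------------------------

def test_exclude_samples():
    rng = np.random.default_rng(7)
    panel = _panel_from(rng.integers(0, 3, (6, 50)),
                        ["EUR"] * 3 + ["AFR"] * 3)
    out = exclude_samples(panel, {"P0", "P5"})
    assert out.genotypes.samples == ["P1", "P2", "P3", "P4"]
    assert exclude_samples(panel, set()).genotypes.samples == \
        panel.genotypes.samples
    with pytest.warns(UserWarning, match="unknown ids"):
        out = exclude_samples(panel, {"P1", "NOPE"})
    assert "P1" not in out.genotypes.samples
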