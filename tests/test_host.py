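"""Sample filters, host groups, Fisher host-specific genes, UniFrac/Jaccard
distances and PERMANOVA."""

from io import StringIO
from itertools import combinations, permutations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from skbio import TreeNode

import gstprofiler as gp
from gstprofiler.classifier import AbundanceProfile
from gstprofiler.pangenome import GeneProfile


def _sample(sid, n_classified, n_hits, relative=None):
    rel = relative or {"1": 1.0}
    return gp.SampleRecord(
        sid,
        "pig",
        AbundanceProfile(sid, dict(rel), dict(rel), n_classified),
        GeneProfile(sid, frozenset({"clu_1"}), n_hits),
    )


def test_sample_filters_are_strict_less_than():
    kept = gp.filter_samples(
        [
            _sample("a", 19_999, 1000),     # too few classified reads
            _sample("b", 20_000, 500),      # exactly at both floors -> kept
            _sample("c", 10**6, 499),       # too few gene hits
            _sample("d", 50_000, 2000),
        ]
    )
    assert [s.sample_id for s in kept] == ["b", "d"]


def test_host_groups_require_more_than_five_samples():
    samples = [
        _sample(f"p{i}", 10**5, 10**3, {"16": 0.8, "1": 0.2}) for i in range(6)
    ] + [_sample(f"m{i}", 10**5, 10**3, {"9": 0.9, "1": 0.1}) for i in range(5)]
    groups = gp.assign_host_groups(samples)
    assert len(groups) == 1
    assert groups[0].dominant_gst == "16" and len(groups[0].members) == 6


def test_dominant_gst_tie_breaks_to_smallest_and_flags():
    s = _sample("t", 10**5, 10**3, {"2": 0.5, "1": 0.5})
    gst, tied = gp.dominant_gst(s.abundance)
    assert gst == "1" and tied
    groups = gp.assign_host_groups([s], min_size=0)
    assert groups[0].tie_flagged == ("t",)


def _presence(rows, samples, genes):
    return pd.DataFrame(rows, index=samples, columns=genes).astype(bool)


def _two_groups(n_in=8, n_out=12):
    g1 = gp.HostGroup("group_GST1", "1", tuple(f"i{k}" for k in range(n_in)))
    g2 = gp.HostGroup("group_GST2", "2", tuple(f"o{k}" for k in range(n_out)))
    return g1, g2


def test_fisher_ubiquitous_gene_not_specific():
    g1, g2 = _two_groups()
    pres = _presence(np.ones((20, 1)), list(g1.members) + list(g2.members), ["g"])
    calls = gp.fisher_host_specific(pres, [g1, g2])
    assert all(c.p_value == 1.0 and not c.specific for c in calls)


def test_fisher_perfect_split_exact_p():
    g1, g2 = _two_groups()
    rows = np.zeros((20, 1))
    rows[:8] = 1
    pres = _presence(rows, list(g1.members) + list(g2.members), ["g"])
    calls = gp.fisher_host_specific(pres, [g1, g2])
    c1 = next(c for c in calls if c.group_id == "group_GST1")
    assert c1.contingency == (8, 0, 0, 12)
    assert c1.p_value == pytest.approx(1 / comb(20, 8), rel=1e-9)
    assert c1.specific


def test_fisher_directionality_required():
    g1, g2 = _two_groups()
    rows = np.zeros((20, 1))
    rows[8:] = 1  # present only OUTSIDE group 1
    pres = _presence(rows, list(g1.members) + list(g2.members), ["g"])
    calls = gp.fisher_host_specific(pres, [g1, g2])
    c1 = next(c for c in calls if c.group_id == "group_GST1")
    assert c1.p_value < 0.01 and not c1.specific
    c2 = next(c for c in calls if c.group_id == "group_GST2")
    assert c2.specific


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    n, K, N = a + b, a + c, a + b + c + d
    rv = hypergeom(N, K, n)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(k) for k in range(max(0, n + K - N), min(n, K) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-7)
    )


def test_fisher_matches_enumeration_all_small_margins(rng):
    g1 = gp.HostGroup("group_GSTa", "a", tuple())
    for _ in range(150):
        n_in = int(rng.integers(2, 16))
        n_out = int(rng.integers(2, 16))
        a = int(rng.integers(0, n_in + 1))
        c = int(rng.integers(0, n_out + 1))
        samples = [f"i{k}" for k in range(n_in)] + [f"o{k}" for k in range(n_out)]
        rows = np.zeros((n_in + n_out, 1))
        rows[:a] = 1
        rows[n_in : n_in + c] = 1
        pres = _presence(rows, samples, ["g"])
        grp_in = gp.HostGroup("gin", "1", tuple(samples[:n_in]))
        grp_out = gp.HostGroup("gout", "2", tuple(samples[n_in:]))
        calls = gp.fisher_host_specific(pres, [grp_in, grp_out])
        call = next(x for x in calls if x.group_id == "gin")
        assert call.p_value == pytest.approx(
            _fisher_oracle(a, n_in - a, c, n_out - c), rel=1e-6, abs=1e-12
        )


def test_fisher_needs_two_groups():
    pres = _presence(np.ones((3, 1)), ["a", "b", "c"], ["g"])
    with pytest.raises(ValueError):
        gp.fisher_host_specific(pres, [gp.HostGroup("x", "1", ("a", "b", "c"))])


# -- distances ---------------------------------------------------------------


def test_weighted_unifrac_identity_and_two_leaf_closed_form():
    tree = TreeNode.read(StringIO("(A:1,B:1);"))
    assert gp.weighted_unifrac({"A": 0.4, "B": 0.6}, {"A": 0.4, "B": 0.6}, tree) == 0.0
    assert gp.weighted_unifrac({"A": 1.0}, {"B": 1.0}, tree) == pytest.approx(2.0)
    assert gp.weighted_unifrac({"A": 1.0}, {"B": 1.0}, tree, normalized=True) == pytest.approx(1.0)


def test_weighted_unifrac_metric_properties(rng):
    tree = TreeNode.read(StringIO("((1:1.0,2:2.0):1.5,(3:0.5,4:2.5):1.0);"))
    def rand_profile():
        x = rng.random(4)
        x /= x.sum()
        return dict(zip("1234", x))
    for _ in range(25):
        a, b, c = rand_profile(), rand_profile(), rand_profile()
        dab = gp.weighted_unifrac(a, b, tree)
        dba = gp.weighted_unifrac(b, a, tree)
        assert dab == pytest.approx(dba)
        assert dab >= 0
        assert dab <= gp.weighted_unifrac(a, c, tree) + gp.weighted_unifrac(c, b, tree) + 1e-12


def test_weighted_unifrac_missing_gst_raises():
    tree = TreeNode.read(StringIO("(A:1,B:1);"))
    with pytest.raises(ValueError, match="missing"):
        gp.weighted_unifrac({"Z": 1.0}, {"A": 1.0}, tree)


def test_jaccard_distances():
    assert gp.jaccard_distance({1, 2, 3}, {1, 2, 3}) == 0.0
    assert gp.jaccard_distance({1}, {2}) == 1.0
    assert gp.jaccard_distance({1, 2, 3}, {2, 3, 4}) == pytest.approx(0.5)
    assert gp.jaccard_distance(set(), set()) == 0.0
    a = GeneProfile("a", frozenset({"x"}), 1)
    b = GeneProfile("b", frozenset({"x", "y"}), 2)
    assert gp.jaccard_distance(a, b) == pytest.approx(0.5)


# -- PERMANOVA ---------------------------------------------------------------


def _gower_f_oracle(d, labels):
    """Pseudo-F via Gower-centered matrix traces (independent route)."""
    d = np.asarray(d, float)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (d**2) @ J
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    X = np.column_stack([(labels == g).astype(float) for g in groups])
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    a = len(groups)
    ss_among = np.trace(H @ G @ H)
    ss_resid = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H))
    return (ss_among / (a - 1)) / (ss_resid / (n - a))


def _rand_distance(rng, n, shift=0.0, split=None):
    x = rng.normal(size=(n, 3))
    if shift:
        x[split:] += shift
    return np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))


def test_pseudo_f_matches_gower_trace_oracle(rng):
    for n, split in [(6, 3), (9, 4), (12, 6)]:
        d = _rand_distance(rng, n)
        labels = ["a"] * split + ["b"] * (n - split)
        f, _ = gp.permanova(d, labels, n_perm=9, seed=0)
        assert f == pytest.approx(_gower_f_oracle(d, labels), rel=1e-9)


def test_permutation_p_matches_exhaustive_enumeration(rng):
    d = _rand_distance(rng, 6, shift=1.0, split=3)
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    f_obs, p = gp.permanova(d, labels, n_perm=4999, seed=5)
    d2 = d**2
    fs = [
        _gower_f_oracle(d, np.array(perm))
        for perm in set(permutations(labels.tolist()))
    ]
    p_exact = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
    assert p == pytest.approx(p_exact, abs=0.02)


def test_saturated_separation_gives_minimal_p(rng):
    # 8+8 design: the chance a sampled permutation reproduces the grouping
    # (which would tie F_obs) is ~2/12870 per draw, negligible here
    d = _rand_distance(rng, 16, shift=100.0, split=8)
    labels = ["a"] * 8 + ["b"] * 8
    f, p = gp.permanova(d, labels, n_perm=99, seed=0)
    assert p == pytest.approx(1 / 100)


def test_permanova_relabel_invariance(rng):
    d = _rand_distance(rng, 8)
    labels = ["x", "x", "y", "y", "x", "y", "x", "y"]
    f1, _ = gp.permanova(d, labels, n_perm=9, seed=0)
    order = np.array([3, 1, 0, 2, 7, 6, 5, 4])
    f2, _ = gp.permanova(d[np.ix_(order, order)], [labels[i] for i in order], n_perm=9, seed=0)
    assert f1 == pytest.approx(f2)


def test_permanova_rejects_degenerate_grouping(rng):
    d = _rand_distance(rng, 6)
    with pytest.raises(ValueError):
        gp.permanova(d, ["a"] * 6)
    with pytest.raises(ValueError):
        gp.permanova(d, ["a"] * 5 + ["b"])


def test_permanova_agrees_with_skbio(rng):
    from skbio import DistanceMatrix as SKDM
    from skbio.stats.distance import permanova as skperm

    d = _rand_distance(rng, 12, shift=1.2, split=6)
    labels = ["a"] * 6 + ["b"] * 6
    f, _ = gp.permanova(d, labels, n_perm=99, seed=0)
    res = skperm(SKDM(d, ids=[str(i) for i in range(12)]), labels, permutations=99)
    assert f == pytest.approx(res["test statistic"], rel=1e-9)


def test_pairwise_permanova_covers_all_group_pairs(rng):
    d = _rand_distance(rng, 9)
    labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    df = gp.permanova_pairwise(d, labels, n_perm=49, seed=0)
    assert sorted(map(tuple, df[["group_a", "group_b"]].values.tolist())) == [
        ("a", "b"), ("a", "c"), ("b", "c"),
    ]


def test_pcoa_coordinates_shape(rng):
    from gstprofiler.host import pcoa_coordinates

    d = _rand_distance(rng, 7)
    coords = pcoa_coordinates(d, [f"s{i}" for i in range(7)], n_axes=2)
    assert coords.shape == (7, 2)
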