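"""Host association: sample filters, host groups, host-specific genes,
and population-structure statistics.

Samples passing the depth filters are grouped by their dominant (most
abundant) GST; groups need more than five samples to survive. Gene
families enriched in one host group are detected with Fisher's exact test
at p < 0.01 plus a directionality requirement. Population structure is
compared with weighted UniFrac (GST abundance) and Jaccard (gene content)
distances under one-way PERMANOVA with label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from skbio import TreeNode

from .classifier import AbundanceProfile
from .pangenome import GeneProfile

MIN_CLASSIFIED_READS = 20_000
MIN_GENE_HITS = 500
MIN_GROUP_SIZE = 5          # groups must be strictly larger than this
FISHER_ALPHA = 0.01
DEFAULT_PERMUTATIONS = 9_999


@dataclass
class SampleRecord:
    sample_id: str
    host_species: str
    abundance: AbundanceProfile
    genes: GeneProfile

    def __post_init__(self):
        if self.abundance.sample_id != self.sample_id or self.genes.sample_id != self.sample_id:
            raise ValueError("profiles belong to a different sample")


@dataclass
class HostGroup:
    group_id: str
    dominant_gst: str
    members: tuple[str, ...]
    tie_flagged: tuple[str, ...] = ()


@dataclass
class HostSpecificCall:
    cluster_id: str
    group_id: str
    contingency: tuple[int, int, int, int]  # a=in/present b=in/absent c=out/present d=out/absent
    p_value: float
    specific: bool


def filter_samples(
    samples: list[SampleRecord],
    min_classified: int = MIN_CLASSIFIED_READS,
    min_gene_hits: int = MIN_GENE_HITS,
) -> list[SampleRecord]:
    """Drop samples with < min_classified classified reads or < min_gene_hits
    matched CDSs (both strict 'less than' removals)."""
    return [
        s
        for s in samples
        if s.abundance.n_classified >= min_classified and s.genes.n_hits >= min_gene_hits
    ]


def dominant_gst(profile: AbundanceProfile) -> tuple[str, bool]:
    """Most abundant GST; ties break to the smallest GST id and are flagged."""
    if not profile.relative:
        raise ValueError(f"empty abundance profile for {profile.sample_id}")
    best = max(profile.relative.values())
    tied = sorted((g for g, v in profile.relative.items() if v == best), key=_gst_key)
    return tied[0], len(tied) > 1


def _gst_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


def assign_host_groups(
    samples: list[SampleRecord], min_size: int = MIN_GROUP_SIZE
) -> list[HostGroup]:
    """Group samples by dominant GST; keep groups with more than ``min_size``
    members (strict)."""
    by_gst: dict[str, list[str]] = {}
    ties: dict[str, list[str]] = {}
    for s in samples:
        g, tied = dominant_gst(s.abundance)
        by_gst.setdefault(g, []).append(s.sample_id)
        if tied:
            ties.setdefault(g, []).append(s.sample_id)
    return [
        HostGroup(f"group_GST{g}", g, tuple(members), tuple(ties.get(g, ())))
        for g, members in sorted(by_gst.items(), key=lambda kv: _gst_key(kv[0]))
        if len(members) > min_size
    ]


def fisher_host_specific(
    gene_presence: pd.DataFrame,
    groups: list[HostGroup],
    alpha: float = FISHER_ALPHA,
    min_prevalence: int = 0,
    bh_correct: bool = False,
) -> list[HostSpecificCall]:
    """Per (gene, group) Fisher's exact test on presence in vs out of group.

    A gene is host-specific for a group when the two-sided p-value is below
    ``alpha`` and its in-group prevalence exceeds its out-group prevalence.
    ``min_prevalence`` optionally skips genes present in fewer samples
    overall; ``bh_correct`` applies Benjamini–Hochberg per group (off by
    default, matching the plain p < 0.01 rule).
    """
    if len(groups) < 2:
        raise ValueError("need at least two host groups")
    universe = [sid for g in groups for sid in g.members]
    presence = gene_presence.loc[universe].astype(bool)
    calls: list[HostSpecificCall] = []
    for grp in groups:
        inside = presence.loc[list(grp.members)]
        outside = presence.drop(index=list(grp.members))
        n_in, n_out = len(inside), len(outside)
        group_calls = []
        for gene in presence.columns:
            a = int(inside[gene].sum())
            c = int(outside[gene].sum())
            if a + c < min_prevalence:
                continue
            b, d = n_in - a, n_out - c
            if a + c == 0 or b + d == 0:
                p = 1.0
            else:
                p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            enriched = (a / n_in) > (c / n_out)
            group_calls.append(
                HostSpecificCall(gene, grp.group_id, (a, b, c, d), p, p < alpha and enriched)
            )
        if bh_correct and group_calls:
            order = np.argsort([c.p_value for c in group_calls])
            m = len(group_calls)
            q_prev = 1.0
            adjusted = [0.0] * m
            for rank_from_end, idx in enumerate(order[::-1]):
                rank = m - rank_from_end
                q_prev = min(q_prev, group_calls[idx].p_value * m / rank)
                adjusted[idx] = q_prev
            for i, call in enumerate(group_calls):
                a, b, c, d = call.contingency
                n_in2 = a + b
                n_out2 = c + d
                call.specific = adjusted[i] < alpha and (a / n_in2) > (c / n_out2)
        calls.extend(group_calls)
    return calls


def host_specific_frame(calls: list[HostSpecificCall]) -> pd.DataFrame:
    rows = [
        (c.cluster_id, c.group_id, *c.contingency, c.p_value, c.specific) for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "group", "a", "b", "c", "d", "p", "specific"]
    )


# ---------------------------------------------------------------------------
# distances


def weighted_unifrac(
    a: AbundanceProfile | dict[str, float],
    b: AbundanceProfile | dict[str, float],
    gst_tree: TreeNode,
    normalized: bool = False,
) -> float:
    """Weighted UniFrac between two GST abundance profiles.

    Sum over branches of branch_length * |A_b - B_b|, where A_b is the
    fraction of sample A descending through the branch. The tree's tips
    must be named by GST label (optionally "GST <label>"). The normalized
    variant divides by sum of branch_length * (A_b + B_b).
    """
    pa = a.relative if isinstance(a, AbundanceProfile) else a
    pb = b.relative if isinstance(b, AbundanceProfile) else b

    def tip_mass(profile, name: str) -> float:
        label = name.removeprefix("GST ").strip() if name else name
        return profile.get(label, profile.get(name, 0.0))

    known = {t.name.removeprefix("GST ").strip() for t in gst_tree.tips()}
    for profile in (pa, pb):
        missing = {g for g in profile if g not in known and f"GST {g}" not in known}
        if missing:
            raise ValueError(f"GSTs missing from tree: {sorted(missing)}")

    num = 0.0
    den = 0.0
    masses: dict[int, tuple[float, float]] = {}
    for node in gst_tree.postorder():
        if node.is_tip():
            ma, mb = tip_mass(pa, node.name), tip_mass(pb, node.name)
        else:
            ma = sum(masses[id(c)][0] for c in node.children)
            mb = sum(masses[id(c)][1] for c in node.children)
        masses[id(node)] = (ma, mb)
        length = node.length or 0.0
        if node.parent is not None and length:
            num += length * abs(ma - mb)
            den += length * (ma + mb)
    if normalized:
        return num / den if den else 0.0
    return num


def jaccard_distance(a: GeneProfile | set, b: GeneProfile | set) -> float:
    """1 - |A n B| / |A u B|; two empty sets are at distance 0."""
    sa = a.present if isinstance(a, GeneProfile) else frozenset(a)
    sb = b.present if isinstance(b, GeneProfile) else frozenset(b)
    union = sa | sb
    if not union:
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


def distance_matrix_from(profiles: list, metric, **kwargs) -> tuple[list[str], np.ndarray]:
    ids = [p.sample_id for p in profiles]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = metric(profiles[i], profiles[j], **kwargs)
    return ids, d


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and integer group labels."""
    n = d2.shape[0]
    groups = np.unique(labels)
    a = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    d: np.ndarray,
    labels,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> tuple[float, float]:
    """One-way PERMANOVA on a distance matrix.

    Returns (pseudo-F, p) with p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    under free label permutation with a fixed seed.
    """
    d = np.asarray(d, dtype=float)
    labels = np.asarray(pd.factorize(np.asarray(labels))[0])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        raise ValueError("each group needs at least two samples")
    d2 = d**2
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _pseudo_f(d2, rng.permutation(labels)) >= f_obs:
            hits += 1
    return f_obs, (1 + hits) / (1 + n_perm)


def permanova_pairwise(
    d: np.ndarray,
    labels,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA for every pair of groups (rows: group_a, group_b, F, p)."""
    labels = np.asarray(labels)
    d = np.asarray(d, dtype=float)
    rows = []
    for ga, gb in combinations(sorted(set(labels.tolist())), 2):
        mask = (labels == ga) | (labels == gb)
        f, p = permanova(d[np.ix_(mask, mask)], labels[mask], n_perm=n_perm, seed=seed)
        rows.append((ga, gb, f, p))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F", "p"])


def pcoa_coordinates(d: np.ndarray, ids: list[str], n_axes: int = 2) -> pd.DataFrame:
    """Classical MDS (PCoA) coordinates for ordination plots."""
    from skbio import DistanceMatrix as _DM
    from skbio.stats.ordination import pcoa as _pcoa

    res = _pcoa(_DM(np.asarray(d, dtype=float), ids=ids), number_of_dimensions=n_axes)
    out = res.samples.iloc[:, :n_axes].copy()
    out.index.name = "sample_id"
    return out
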