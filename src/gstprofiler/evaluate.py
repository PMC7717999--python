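"""Validation metrics against simulated ground truth.

Read-level precision counts assignments to the true GST or any of its
ancestors as correct, over all classified reads (unclassified reads are
excluded from the denominator; the classified fraction is reported
separately). Composition accuracy is the Pearson correlation between true
and estimated GST abundance; gene-profile accuracy is TPR and F1 of the
presence/absence calls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from scipy.stats import pearsonr

from .classifier import AbundanceProfile
from .pangenome import GeneProfile
from .taxonomy import TaxonomyTree


@dataclass
class EvaluationReport:
    precision: float | None = None
    classified_fraction: float | None = None
    pearson_r: float | None = None
    tpr: float | None = None
    f1: float | None = None
    per_sample: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def read_level_precision(
    assignments: dict[str, int | None],
    truth: dict[str, str],
    taxonomy: TaxonomyTree,
) -> float:
    """Fraction of classified reads assigned to the true GST or an ancestor."""
    leaves = taxonomy.gst_leaves
    correct = classified = 0
    for rid, node in assignments.items():
        if node is None:
            continue
        if rid not in truth:
            raise KeyError(f"read {rid} has no truth entry")
        true_leaf = leaves.get(f"GST {truth[rid]}", leaves.get(truth[rid]))
        if true_leaf is None:
            raise KeyError(f"true GST {truth[rid]} not in taxonomy")
        classified += 1
        if taxonomy.is_ancestor_or_self(node, true_leaf):
            correct += 1
    if classified == 0:
        raise ValueError("no classified reads")
    return correct / classified


def abundance_correlation(
    estimated: AbundanceProfile | dict[str, float],
    true_abundance: dict[str, float],
) -> float | None:
    """Pearson r between true and estimated abundance over the GST union.

    Returns None when either vector has zero variance (undefined r).
    """
    est = estimated.relative if isinstance(estimated, AbundanceProfile) else estimated
    universe = sorted(set(est) | set(true_abundance))
    if len(universe) < 2:
        return None
    x = [true_abundance.get(g, 0.0) for g in universe]
    y = [est.get(g, 0.0) for g in universe]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    return float(pearsonr(x, y)[0])


def gene_profile_tpr_f1(
    profile: GeneProfile | frozenset, true_content: frozenset[str] | set[str]
) -> tuple[float, float]:
    """TPR = TP/(TP+FN) and F1 = 2PR/(P+R) for presence/absence calls."""
    present = profile.present if isinstance(profile, GeneProfile) else frozenset(profile)
    truth = frozenset(true_content)
    if not truth:
        raise ValueError("empty truth gene content")
    tp = len(present & truth)
    fn = len(truth - present)
    fp = len(present - truth)
    tpr = tp / (tp + fn)
    if tp == 0:
        return tpr, 0.0
    precision = tp / (tp + fp)
    f1 = 2 * precision * tpr / (precision + tpr)
    return tpr, f1


def classified_fraction(assignments: dict[str, int | None]) -> float:
    if not assignments:
        raise ValueError("no assignments")
    return sum(v is not None for v in assignments.values()) / len(assignments)
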