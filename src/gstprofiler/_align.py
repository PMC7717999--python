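"""Pairwise identity and bidirectional-coverage computation.

Thin wrapper around edlib. The shorter sequence is aligned as an infix of
the longer one; identity is matches / alignment columns and coverage is
reported for both sequences (aligned span over full length), so a fragment
covering only part of a full-length gene fails the coverage test even at
100% identity.
"""

from __future__ import annotations

import re
from typing import NamedTuple

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class AlignmentStats(NamedTuple):
    identity: float   # matches / alignment columns, in [0, 1]
    cov_a: float      # aligned fraction of sequence a
    cov_b: float      # aligned fraction of sequence b


_ZERO = AlignmentStats(0.0, 0.0, 0.0)


def align_stats(a: str, b: str, max_dist_frac: float | None = None) -> AlignmentStats:
    """Align two nucleotide sequences and report identity and coverage.

    The shorter sequence is used as the (fully aligned) query against the
    longer target in infix mode. ``max_dist_frac`` bounds the edit distance
    as a fraction of the query length; alignments beyond the bound return
    zero identity (early abort for clearly unrelated pairs).
    """
    if not a or not b:
        return _ZERO
    swapped = len(a) > len(b)
    q, t = (b, a) if swapped else (a, b)
    k = -1 if max_dist_frac is None else max(1, int(max_dist_frac * len(q)))
    res = edlib.align(q, t, mode="HW", task="path", k=k)
    if res["editDistance"] < 0:
        return _ZERO
    matches = columns = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        columns += n
        if op == "=":
            matches += n
    start, end = res["locations"][0]
    span_t = end - start + 1
    cov_q = 1.0
    cov_t = span_t / len(t)
    identity = matches / columns if columns else 0.0
    if swapped:
        return AlignmentStats(identity, cov_t, cov_q)
    return AlignmentStats(identity, cov_q, cov_t)


def passes_thresholds(a: str, b: str, min_id: float, min_cov: float) -> bool:
    """True when the pair meets the identity and bidirectional coverage cutoffs."""
    # identity >= min_id bounds edit distance; 2x margin keeps the abort safe
    st = align_stats(a, b, max_dist_frac=2.0 * (1.0 - min_id) + 0.05)
    return st.identity >= min_id and st.cov_a >= min_cov and st.cov_b >= min_cov
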