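"""Reference-genome model: prioritization, core reference, SNV calling, distances.

The species reference is the concatenation of the type strain's core genes
(lexicographic family order, 1-based coordinates). Isolates are compared to
it gene by gene — the synthetic generator is substitution-only, so each
core-gene copy aligns to its reference copy positionally and SNV calling is
exact. Users with real data supply pre-computed variant tables instead
(TSV: genome_id, position, ref, alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd


class AssemblyLevel(str, Enum):
    COMPLETE = "complete"
    CHROMOSOME = "chromosome"
    OTHER = "other"


_LEVEL_RANK = {AssemblyLevel.COMPLETE: 0, AssemblyLevel.CHROMOSOME: 1, AssemblyLevel.OTHER: 2}


@dataclass(frozen=True)
class GenomeRecord:
    """An isolate genome with the metadata used for prioritization."""

    genome_id: str
    sequences: tuple[str, ...]
    assembly_level: AssemblyLevel
    n50: int
    host_source: str = "unknown"
    is_type_strain: bool = False

    def __post_init__(self):
        if self.n50 < 0:
            raise ValueError("n50 must be nonnegative")


@dataclass(frozen=True)
class CoreReference:
    """Concatenated core genes of the type strain, with per-gene offsets."""

    core_gene_ids: tuple[str, ...]
    sequence: str
    gene_offsets: tuple[int, ...]  # 1-based start of each gene in the concatenation

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_span(self, gene_id: str) -> tuple[int, int]:
        """1-based inclusive (start, end) of a core gene on the reference."""
        i = self.core_gene_ids.index(gene_id)
        start = self.gene_offsets[i]
        end = (self.gene_offsets[i + 1] - 1) if i + 1 < len(self.gene_offsets) else self.length
        return start, end


@dataclass
class SnvSet:
    """Substitutions of one genome relative to the core reference."""

    genome_id: str
    variants: dict[int, tuple[str, str]]  # position -> (ref_base, alt_base)
    missing_genes: frozenset[str] = frozenset()
    reference_id: str = "core"

    def __post_init__(self):
        for pos, (ref, alt) in self.variants.items():
            if ref == alt:
                raise ValueError(f"ref == alt at position {pos}")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, nonnegative integers, zero diagonal

    def __post_init__(self):
        self.d = np.asarray(self.d)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.array_equal(self.d, self.d.T) or np.diag(self.d).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self._idx = {g: i for i, g in enumerate(self.ids)}

    def get(self, a: str, b: str) -> int:
        return int(self.d[self._idx[a], self._idx[b]])

    def submax(self, genome_ids) -> int:
        """Maximum pairwise distance within a subset of genomes."""
        idx = [self._idx[g] for g in genome_ids]
        if len(idx) < 2:
            return 0
        return int(self.d[np.ix_(idx, idx)].max())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for g, row in zip(self.ids, self.d):
                fh.write(g + "  " + " ".join(str(int(x)) for x in row) + "\n")


# ---------------------------------------------------------------------------


def prioritize_genomes(genomes) -> list[str]:
    """Total priority order: assembly level, then descending N50, then id.

    Complete genomes outrank chromosome-level assemblies outrank the rest,
    regardless of N50; within a level larger N50 wins; ties break
    lexicographically by genome id for determinism.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("empty genome collection")
    key = lambda g: (_LEVEL_RANK[AssemblyLevel(g.assembly_level)], -g.n50, g.genome_id)
    return [g.genome_id for g in sorted(genomes, key=key)]


def build_core_reference(core_genes: dict[str, str]) -> CoreReference:
    """Concatenate the type strain's core genes into the species reference.

    Gene order is lexicographic by family id; offsets are 1-based.
    """
    if not core_genes:
        raise ValueError("empty core gene set")
    ids = tuple(sorted(core_genes))
    offsets, seqs, pos = [], [], 1
    for gid in ids:
        seq = core_genes[gid]
        if not seq:
            raise ValueError(f"empty core gene {gid}")
        offsets.append(pos)
        seqs.append(seq)
        pos += len(seq)
    return CoreReference(ids, "".join(seqs), tuple(offsets))


def call_snvs(genome_id: str, genome_core_genes: dict[str, str], reference: CoreReference) -> SnvSet:
    """Substitutions of a genome's core-gene copies against the reference.

    Each present core gene is compared positionally to its reference copy
    (generator output is indel-free, so copies are length-matched). Core
    genes absent from the genome contribute no variants and are flagged
    missing — absence is not a single-nucleotide variation.
    """
    variants: dict[int, tuple[str, str]] = {}
    missing = []
    for i, gid in enumerate(reference.core_gene_ids):
        start = reference.gene_offsets[i]
        end = (reference.gene_offsets[i + 1] - 1) if i + 1 < len(reference.gene_offsets) else reference.length
        ref_seq = reference.sequence[start - 1 : end]
        if gid not in genome_core_genes:
            missing.append(gid)
            continue
        gseq = genome_core_genes[gid]
        if len(gseq) != len(ref_seq):
            raise ValueError(f"core gene {gid} length mismatch for {genome_id} (indels unsupported)")
        a = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
        b = np.frombuffer(gseq.encode(), dtype=np.uint8)
        for off in np.nonzero(a != b)[0]:
            pos = start + int(off)
            variants[pos] = (chr(a[off]), chr(b[off]))
    return SnvSet(genome_id, variants, frozenset(missing))


def snv_distance(a: SnvSet, b: SnvSet, reference: CoreReference | None = None) -> int:
    """Number of positions at which the two genomes carry different alleles.

    A position counts once whether one genome varies from the reference or
    both vary to different alternate bases; positions where both carry the
    same alternate do not count. Positions inside a core gene missing from
    either genome are excluded entirely.
    """
    if a.reference_id != b.reference_id:
        raise ValueError("SNV sets called against different references")
    excluded_spans: list[tuple[int, int]] = []
    missing = a.missing_genes | b.missing_genes
    if missing:
        if reference is None:
            raise ValueError("reference required to exclude missing-gene positions")
        excluded_spans = [reference.gene_span(g) for g in missing]

    def excluded(pos: int) -> bool:
        return any(s <= pos <= e for s, e in excluded_spans)

    count = 0
    for pos in set(a.variants) | set(b.variants):
        if excluded_spans and excluded(pos):
            continue
        alt_a = a.variants.get(pos, (None, None))[1]
        alt_b = b.variants.get(pos, (None, None))[1]
        if alt_a != alt_b:
            count += 1
    return count


def distance_matrix(snv_sets: list[SnvSet], reference: CoreReference | None = None) -> DistanceMatrix:
    """All-against-all pairwise SNV distances."""
    ids = [s.genome_id for s in snv_sets]
    n = len(ids)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = snv_distance(snv_sets[i], snv_sets[j], reference)
    return DistanceMatrix(ids, d)


def read_snv_table(path) -> list[SnvSet]:
    """Read a variant table TSV (genome_id, position, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "ref": str, "alt": str})
    out = []
    for gid, grp in df.groupby("genome_id", sort=True):
        variants = {int(r.position): (r.ref, r.alt) for r in grp.itertuples(index=False)}
        out.append(SnvSet(str(gid), variants))
    return out


def write_snv_table(snv_sets: list[SnvSet], path) -> None:
    rows = [
        (s.genome_id, pos, ref, alt)
        for s in snv_sets
        for pos, (ref, alt) in sorted(s.variants.items())
    ]
    pd.DataFrame(rows, columns=["genome_id", "position", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )
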