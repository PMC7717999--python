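"""Synthetic strain communities with known ground truth.

Generates a clonal species: one ancestral genome of annotated genes, a set
of strain types (GSTs) separated by a controlled minimum SNV distance, and
strains within each GST separated by a controlled maximum. Gene content
varies by GST (accessory loss plus private novel gene gain), giving clean
truth for gene-profiling and host-specificity evaluation. Reads, pseudo-
contigs and multi-host cohorts are derived from these genomes.

Substitutions only — no indels — so SNV distance equals Hamming distance
on the aligned core genes and the SNV-calling oracle is exact. Mutations
are placed only inside core genes (the coordinates SNV distances are
defined on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
from skbio import TreeNode

from .reference import AssemblyLevel, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FASTQ_QUAL = "?"  # constant Q30; quality trimming is out of scope


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic strain community.

    ``within_gst_snv`` caps the pairwise SNV distance inside one GST;
    ``between_gst_snv`` floors the distance between strains of different
    GSTs. ``accessory_fraction`` is the fraction of ancestral gene families
    whose presence varies across GSTs.
    """

    seed: int = 0
    genome_length: int = 500_000
    n_genes: int = 400
    gene_length_range: tuple[int, int] = (600, 1500)
    n_gsts: int = 5
    strains_per_gst: int = 3
    within_gst_snv: int = 100
    between_gst_snv: int = 5000
    accessory_fraction: float = 0.15
    read_length: int = 150
    error_rate: float = 0.0
    novel_genes_per_gst: int = 2

    def __post_init__(self):
        if self.within_gst_snv >= self.between_gst_snv:
            raise ValueError("within_gst_snv must be < between_gst_snv")
        if not (0 <= self.error_rate < 0.05):
            raise ValueError("error_rate must be in [0, 0.05)")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.genome_length < self.n_genes * lo:
            raise ValueError("genome_length too small for n_genes genes")
        if min(self.n_gsts, self.strains_per_gst, self.n_genes) < 1:
            raise ValueError("counts must be positive")
        if self.novel_genes_per_gst < 1:
            raise ValueError("each GST must gain at least one private gene family")


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    read_origin: dict[str, str] = field(default_factory=dict)        # read id -> true GST label
    sample_abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    gene_content: dict[str, frozenset[str]] = field(default_factory=dict)
    host_label: dict[str, str] = field(default_factory=dict)         # sample id -> host group


@dataclass
class ReadSet:
    """Simulated reads plus their (separately kept) true origins."""

    reads: list[tuple[str, str]]                 # (read_id, sequence)
    origin: dict[str, str]                       # read_id -> source genome id
    abundances: dict[str, float]                 # genome id -> sampling fraction

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{_FASTQ_QUAL * len(seq)}\n")


@dataclass
class Sample:
    sample_id: str
    reads: ReadSet
    true_gst_abundance: dict[str, float]         # GST label -> true fraction
    host_label: str


@dataclass
class StrainCollection:
    """Output of :func:`simulate_strain_genomes`."""

    config: SimulationConfig
    records: list[GenomeRecord]
    sequences: dict[str, str]
    gene_intervals: dict[str, list[tuple[str, int, int]]]  # genome -> (family, start, end) 0-based half-open
    gene_content: dict[str, frozenset[str]]
    genome_gst: dict[str, str]                             # genome id -> GST label ("1".."n")
    type_strain_id: str
    tree: TreeNode
    mutation_log: dict[str, dict[int, tuple[str, str]]]    # 0-based ancestral coords -> (ref, alt)
    ancestral_core_genes: dict[str, str]
    ancestral_core_layout: list[tuple[str, int, int]]      # (family, start, end) on the ancestor
    core_families: list[str]

    @property
    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.records]

    def core_genes_of(self, genome_id: str) -> dict[str, str]:
        """The genome's copies of the core gene families, by family id."""
        seq = self.sequences[genome_id]
        return {
            fam: seq[a:b]
            for fam, a, b in self.gene_intervals[genome_id]
            if fam in self._core_set
        }

    @property
    def _core_set(self) -> frozenset[str]:
        return frozenset(self.core_families)

    def gst_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, t in self.genome_gst.items():
            out.setdefault(t, []).append(g)
        return out

    def mutations_on_reference(self, genome_id: str) -> dict[int, tuple[str, str]]:
        """The genome's planted substitutions in core-reference coordinates.

        The reference frame is the ancestral core genes concatenated in
        lexicographic family order with 1-based positions — the same frame
        ``build_core_reference(ancestral_core_genes)`` produces.
        """
        offsets: dict[str, int] = {}
        pos = 1
        for fam in sorted(self.ancestral_core_genes):
            offsets[fam] = pos
            pos += len(self.ancestral_core_genes[fam])
        out: dict[int, tuple[str, str]] = {}
        for anc_pos, (ref, alt) in self.mutation_log[genome_id].items():
            for fam, a, b in self.ancestral_core_layout:
                if a <= anc_pos < b:
                    out[offsets[fam] + (anc_pos - a)] = (ref, alt)
                    break
        return out


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _mutate(rng: np.random.Generator, base: int) -> int:
    choices = _BASES[_BASES != base]
    return int(choices[rng.integers(0, 3)])


def simulate_strain_genomes(config: SimulationConfig) -> StrainCollection:
    """Evolve a clonal strain community from a single ancestor.

    Each GST ancestor receives ``between_gst_snv`` substitutions at
    GST-private core positions (so any cross-GST pair differs at >=
    2 x between_gst_snv sites); each strain receives within_gst_snv // 2
    private substitutions (so any within-GST pair differs at <=
    within_gst_snv sites). Accessory families are retained per GST with
    probability 1/2 and every GST gains private novel gene families.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.gene_length_range

    # ancestral layout: genes with evenly distributed intergenic spacers
    fams = [f"fam{i:04d}" for i in range(cfg.n_genes)]
    gene_lens = rng.integers(lo, hi + 1, cfg.n_genes)
    spacer_total = cfg.genome_length - int(gene_lens.sum())
    if spacer_total < 0:
        raise ValueError("genome_length too small for drawn gene lengths")
    n_slots = cfg.n_genes + 1
    spacer = np.full(n_slots, spacer_total // n_slots)
    spacer[: spacer_total % n_slots] += 1

    anc = _random_seq(rng, cfg.genome_length)
    layout: list[tuple[str, int, int]] = []
    pos = int(spacer[0])
    for i, fam in enumerate(fams):
        layout.append((fam, pos, pos + int(gene_lens[i])))
        pos += int(gene_lens[i]) + int(spacer[i + 1])

    # accessory pool vs core families
    n_acc = int(round(cfg.accessory_fraction * cfg.n_genes))
    acc_idx = rng.choice(cfg.n_genes, n_acc, replace=False) if n_acc else np.empty(0, int)
    accessory = {fams[i] for i in acc_idx}
    core_families = sorted(set(fams) - accessory)

    # substitution positions: drawn without replacement from core genes only
    core_positions = np.concatenate(
        [np.arange(a, b) for fam, a, b in layout if fam not in accessory]
    )
    half_within = cfg.within_gst_snv // 2
    needed = cfg.n_gsts * (cfg.between_gst_snv + cfg.strains_per_gst * half_within)
    if needed > core_positions.size:
        raise ValueError(
            f"infeasible SNV budget: need {needed} distinct core positions, "
            f"have {core_positions.size}"
        )
    drawn = rng.choice(core_positions, needed, replace=False)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = drawn[cursor : cursor + n]
        cursor += n
        return out

    records, sequences, gene_intervals = [], {}, {}
    gene_content, genome_gst, mutation_log = {}, {}, {}
    tree_clades = []
    genome_idx = 0

    for g in range(1, cfg.n_gsts + 1):
        gst = str(g)
        gst_pos = take(cfg.between_gst_snv)
        gst_subs = {int(p): _mutate(rng, int(anc[p])) for p in gst_pos}
        retained_acc = {f for f in sorted(accessory) if rng.random() < 0.5}
        novel = {
            f"nov_g{g:02d}_{i}": "".join(map(chr, _random_seq(rng, int(rng.integers(lo, hi + 1)))))
            for i in range(cfg.novel_genes_per_gst)
        }
        present = set(core_families) | retained_acc | set(novel)
        strain_leaves = []

        for s in range(1, cfg.strains_per_gst + 1):
            gid = f"g{g:02d}s{s:02d}"
            priv_pos = take(half_within)
            priv_subs = {int(p): _mutate(rng, int(anc[p])) for p in priv_pos}
            seq = anc.copy()
            all_subs = {**gst_subs, **priv_subs}
            for p, alt in all_subs.items():
                seq[p] = alt

            # assemble the final genome: drop lost accessory genes, append novels
            parts, intervals, out_pos, prev_end = [], [], 0, 0
            for fam, a, b in layout:
                parts.append(seq[prev_end:a])
                out_pos += a - prev_end
                if fam in present:
                    parts.append(seq[a:b])
                    intervals.append((fam, out_pos, out_pos + (b - a)))
                    out_pos += b - a
                prev_end = b
            parts.append(seq[prev_end:])
            out_pos += len(seq) - prev_end
            final = "".join(p.tobytes().decode() for p in parts)
            for fam in sorted(novel):
                final += "ACGT" * 15  # 60 bp spacer before each gained gene
                intervals.append((fam, len(final), len(final) + len(novel[fam])))
                final += novel[fam]

            is_type = genome_idx == 0
            records.append(
                GenomeRecord(
                    genome_id=gid,
                    sequences=(final,),
                    assembly_level=(
                        AssemblyLevel.COMPLETE
                        if s == 1
                        else AssemblyLevel.CHROMOSOME if s == 2 else AssemblyLevel.OTHER
                    ),
                    n50=10_000_000 - genome_idx * 1000,
                    host_source=f"host{g}",
                    is_type_strain=is_type,
                )
            )
            sequences[gid] = final
            gene_intervals[gid] = intervals
            gene_content[gid] = frozenset(present)
            genome_gst[gid] = gst
            mutation_log[gid] = {
                p: (chr(anc[p]), chr(alt)) for p, alt in sorted(all_subs.items())
            }
            strain_leaves.append(f"{gid}:{len(priv_subs)}")
            genome_idx += 1

        if cfg.strains_per_gst == 1:
            gid = strain_leaves[0].split(":")[0]
            tree_clades.append(f"{gid}:{half_within + cfg.between_gst_snv}")
        else:
            tree_clades.append("(" + ",".join(strain_leaves) + f"):{cfg.between_gst_snv}")

    if cfg.n_gsts == 1 and cfg.strains_per_gst == 1:
        newick = tree_clades[0].split(":")[0] + ";"
    else:
        newick = "(" + ",".join(tree_clades) + ");"
    tree = TreeNode.read(StringIO(newick))

    type_id = records[0].genome_id
    ancestral_core = {}
    core_layout = []
    for fam, a, b in layout:
        if fam not in accessory:
            ancestral_core[fam] = anc[a:b].tobytes().decode()
            core_layout.append((fam, a, b))

    return StrainCollection(
        config=cfg,
        records=records,
        sequences=sequences,
        gene_intervals=gene_intervals,
        gene_content=gene_content,
        genome_gst=genome_gst,
        type_strain_id=type_id,
        tree=tree,
        mutation_log=mutation_log,
        ancestral_core_genes=ancestral_core,
        ancestral_core_layout=core_layout,
        core_families=core_families,
    )


# ---------------------------------------------------------------------------
# reads


def draw_abundances(ids: list[str], distribution: str, rng: np.random.Generator) -> dict[str, float]:
    """Normalized abundance vector from a log-normal or exponential draw."""
    if distribution == "lognormal":
        x = rng.lognormal(mean=0.0, sigma=1.0, size=len(ids))
    elif distribution == "exponential":
        x = rng.exponential(scale=1.0, size=len(ids))
    else:
        raise ValueError(f"unknown abundance distribution: {distribution!r}")
    x = x / x.sum()
    return dict(zip(ids, x.tolist()))


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def simulate_reads(
    sequences: dict[str, str],
    n_reads: int,
    *,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    abundances: dict[str, float] | None = None,
    distribution: str | None = None,
    paired: bool = False,
    insert_size: int = 350,
) -> ReadSet:
    """Draw reads from a set of genomes at given or drawn abundances.

    Start positions are uniform, strands random, substitution errors occur
    independently per base at ``error_rate``. Read ids encode nothing about
    the source genome; the truth is returned separately. ``paired`` only
    changes emission (two mates per fragment), not any downstream logic.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    ids = sorted(sequences)
    if abundances is None:
        if distribution is None:
            raise ValueError("provide abundances or a distribution name")
        abundances = draw_abundances(ids, distribution, rng)
    else:
        total = sum(abundances.values())
        abundances = {g: v / total for g, v in abundances.items()}
        ids = sorted(abundances)
    probs = np.array([abundances[g] for g in ids])
    n_frags = n_reads // 2 if paired else n_reads
    sources = rng.choice(len(ids), n_frags, p=probs)

    reads: list[tuple[str, str]] = []
    origin: dict[str, str] = {}

    def emit(rid: str, seq: str, gid: str) -> None:
        if error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
            for p in hit:
                arr[p] = _mutate(rng, int(arr[p]))
            seq = arr.tobytes().decode()
        reads.append((rid, seq))
        origin[rid] = gid

    for i, src in enumerate(sources):
        gid = ids[src]
        genome = sequences[gid]
        if paired:
            span = min(insert_size, len(genome))
            start = int(rng.integers(0, len(genome) - span + 1))
            frag = genome[start : start + span]
            fwd = frag[:read_length]
            rev = frag[-read_length:].translate(_RC)[::-1]
            if rng.random() < 0.5:
                fwd, rev = rev, fwd
            emit(f"r{i:07d}/1", fwd, gid)
            emit(f"r{i:07d}/2", rev, gid)
        else:
            if len(genome) < read_length:
                raise ValueError(f"genome {gid} shorter than read_length")
            start = int(rng.integers(0, len(genome) - read_length + 1))
            seq = genome[start : start + read_length]
            if rng.random() < 0.5:
                seq = seq.translate(_RC)[::-1]
            emit(f"r{i:07d}", seq, gid)

    return ReadSet(reads, origin, abundances)


# ---------------------------------------------------------------------------
# pseudo-assembly


def simulate_contigs(
    sequence: str,
    gene_intervals: list[tuple[str, int, int]],
    coverage: float,
    *,
    read_length: int = 150,
    seed: int = 0,
    min_contig: int = 500,
    min_cds: int = 100,
):
    """Pseudo-assembly by coverage gaps (Lander–Waterman model).

    Uniform read starts at the given fold coverage; maximal covered runs
    become contigs, contigs shorter than ``min_contig`` are dropped, and
    true gene intervals clipped to the surviving contigs yield the
    predicted CDS set (fragments shorter than ``min_cds`` are dropped).

    Returns ``(contigs, cds, cds_truth)`` where ``cds`` is a list of
    (cds_id, sequence) and ``cds_truth`` maps cds_id to the true family.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    G = len(sequence)
    if math.isinf(coverage):
        covered = [(0, G)]
    else:
        rng = np.random.default_rng(seed)
        n_reads = int(math.ceil(coverage * G / read_length))
        starts = np.sort(rng.integers(0, max(1, G - read_length + 1), n_reads))
        covered = []
        cur_a, cur_b = int(starts[0]), int(starts[0]) + read_length
        for s in starts[1:]:
            s = int(s)
            if s <= cur_b:
                cur_b = max(cur_b, s + read_length)
            else:
                covered.append((cur_a, min(cur_b, G)))
                cur_a, cur_b = s, s + read_length
        covered.append((cur_a, min(cur_b, G)))

    contigs = [(a, b, sequence[a:b]) for a, b in covered if b - a >= min_contig]

    cds: list[tuple[str, str]] = []
    cds_truth: dict[str, str] = {}
    k = 0
    for fam, ga, gb in gene_intervals:
        for ca, cb, _ in contigs:
            a, b = max(ga, ca), min(gb, cb)
            if b - a >= min_cds:
                cid = f"cds{k:05d}"
                cds.append((cid, sequence[a:b]))
                cds_truth[cid] = fam
                k += 1
    return [c[2] for c in contigs], cds, cds_truth


# ---------------------------------------------------------------------------
# cohorts


def simulate_sample(
    collection: StrainCollection,
    sample_id: str,
    n_reads: int,
    *,
    seed: int,
    n_sample_gsts: int = 5,
    distribution: str = "lognormal",
    dominant_gst: str | None = None,
    dominant_frac: float | None = None,
    error_rate: float | None = None,
) -> Sample:
    """One metagenomic sample over a random subset of GSTs.

    One strain per selected GST is sampled; abundances come from the named
    distribution. When ``dominant_gst`` is set, that GST receives
    ``dominant_frac`` (default drawn in [0.5, 0.9]) of the mass and the
    rest is split by the distribution over the other selected GSTs.
    """
    rng = np.random.default_rng(seed)
    members = collection.gst_members()
    all_gsts = sorted(members, key=int)
    n_pick = min(n_sample_gsts, len(all_gsts))
    if dominant_gst is not None:
        others = [g for g in all_gsts if g != dominant_gst]
        picked = [dominant_gst] + [
            others[i] for i in rng.choice(len(others), min(n_pick - 1, len(others)), replace=False)
        ]
    else:
        picked = [all_gsts[i] for i in rng.choice(len(all_gsts), n_pick, replace=False)]

    genomes = {g: members[g][int(rng.integers(0, len(members[g])))] for g in picked}
    ab = draw_abundances(picked, distribution, rng)
    if dominant_gst is not None:
        frac = dominant_frac if dominant_frac is not None else float(rng.uniform(0.5, 0.9))
        rest = {g: v for g, v in ab.items() if g != dominant_gst}
        scale = (1 - frac) / sum(rest.values()) if rest else 0.0
        ab = {dominant_gst: frac, **{g: v * scale for g, v in rest.items()}}

    genome_ab = {genomes[g]: ab[g] for g in picked}
    cfg = collection.config
    rs = simulate_reads(
        {gid: collection.sequences[gid] for gid in genome_ab},
        n_reads,
        read_length=cfg.read_length,
        error_rate=cfg.error_rate if error_rate is None else error_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
        abundances=genome_ab,
    )
    host = f"host{dominant_gst}" if dominant_gst is not None else "mixed"
    return Sample(sample_id, rs, ab, host)


def simulate_cohort(
    collection: StrainCollection,
    samples_per_gst: int,
    n_reads: int,
    *,
    seed: int,
    n_sample_gsts: int = 5,
    dominant_frac: float | None = 0.7,
) -> tuple[list[Sample], CohortTruth]:
    """Multi-host cohort: ``samples_per_gst`` samples dominated by each GST.

    Abundance distributions alternate log-normal / exponential across
    samples. Ground truth (read origins at GST level, sample abundances,
    gene content, host labels) is collected into a :class:`CohortTruth`.
    """
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    truth = CohortTruth(gene_content=dict(collection.gene_content))
    i = 0
    for gst in sorted(collection.gst_members(), key=int):
        for _ in range(samples_per_gst):
            sid = f"S{i:03d}"
            smp = simulate_sample(
                collection,
                sid,
                n_reads,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_sample_gsts=n_sample_gsts,
                distribution="lognormal" if i % 2 == 0 else "exponential",
                dominant_gst=gst,
                dominant_frac=dominant_frac,
            )
            samples.append(smp)
            truth.sample_abundance[sid] = dict(smp.true_gst_abundance)
            truth.host_label[sid] = smp.host_label
            for rid, gid in smp.reads.origin.items():
                truth.read_origin[f"{sid}:{rid}"] = collection.genome_gst[gid]
            i += 1
    return samples, truth
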