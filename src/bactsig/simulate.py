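"""Synthetic bacterial mutagenesis datasets with planted mutational signatures.

This module emulates the statistical structure of a reversion-assay
whole-genome-sequencing experiment: a bacterial genome with annotated genes,
groups of sequenced revertant clones whose single-nucleotide variants are
drawn from a mixture of planted trinucleotide signatures, an optional
transcriptional strand bias per signature, and an optional planted reversion
mutation inside a designated target gene. Every random draw is recorded in a
truth table so downstream catalog construction, signature extraction and
strand-bias detection can be validated against known ground truth.

The shipped default configuration mirrors a two-strain experiment:

* a wild-type strain with 48 clones in 5 treatment groups — 10 controls at a
  mean burden of 0.2 SNVs/clone, two taurine-conjugate-like groups (10 + 8
  clones) at 27 SNVs/clone, and two glycine-conjugate-like groups (10 + 10
  clones) at 14 SNVs/clone;
* an alkyltransferase-deficient strain (no O6-methylguanine repair) with 60
  clones whose glycine-conjugate groups carry ~44 SNVs/clone.

Two planted signatures are provided: a glycine-conjugate-like signature
concentrated on G[C>T]C / G[C>T]T (GCY) contexts with a 4:1 transcribed-strand
bias, and a taurine-conjugate-like signature concentrated on A[C>T]C,
C[C>T]T and T[C>T]G contexts with no strand bias.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .channels import (
    BASES,
    CHANNELS_96,
    CHANNEL_INDEX,
    CHANNEL_TO_CONTEXT,
    COMPLEMENT,
    encode_sequence,
    genome_context_table,
    parse_channel,
)
from .errors import ConfigurationError, SimulationError

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass(frozen=True)
class Genome:
    """A single chromosome: name plus uppercase sequence."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PlantedSignature:
    """A named probability distribution over the 96 SBS channels."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (96,):
            raise ConfigurationError(
                f"signature {self.name!r}: expected 96 channel probabilities, "
                f"got shape {p.shape}"
            )
        if (p < 0).any():
            raise ConfigurationError(f"signature {self.name!r}: negative probability")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigurationError(
                f"signature {self.name!r}: probabilities sum to {total:.6g}, not 1"
            )
        object.__setattr__(self, "probs", p / total)


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: clone count, mean mutation burden, and the
    mixing proportions over the planted signatures."""

    name: str
    n_clones: int
    mean_mutations: float
    exposures: tuple[float, ...]


@dataclass(frozen=True)
class PlantedMutation:
    """One planted SNV: 1-based position, forward-strand alleles, its
    pyrimidine-collapsed channel, the strand label at planting time
    (transcribed / untranscribed / intergenic / ambiguous), and the name of
    the signature (or 'reversion') that generated it."""

    pos: int
    ref: str
    alt: str
    channel: str
    strand_label: str
    signature: str


@dataclass(frozen=True)
class CloneTruth:
    clone_id: str
    group: str
    exposures: tuple[float, ...]
    mutations: tuple[PlantedMutation, ...]

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment.

    ``strand_bias_factors[i]`` is the odds ratio r with which genic mutations
    of signature i fall on the template (transcribed) vs coding
    (untranscribed) strand; r = 1 means no bias.
    """

    genome_length: int = 200_000
    gc_content: float = 0.52
    n_genes: int = 160
    gene_length: int = 1_000
    groups: tuple[GroupSpec, ...] = ()
    strand_bias_factors: tuple[float, ...] = (1.0,)
    plant_reversion: bool = False
    reversion_gene_index: int = 0
    reversion_positions: tuple[int, ...] = (205, 206)
    chrom: str = "simchr"
    seed: int = 0

    def validate(self, n_signatures: int | None = None) -> None:
        if self.genome_length < 1_000:
            raise ConfigurationError("genome_length must be >= 1000")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ConfigurationError("gc_content must lie in [0, 1]")
        if self.n_genes < 0 or self.gene_length < 0:
            raise ConfigurationError("gene counts and lengths must be >= 0")
        if self.n_genes * self.gene_length > self.genome_length:
            raise ConfigurationError(
                f"cannot pack {self.n_genes} genes of length {self.gene_length} "
                f"into a genome of {self.genome_length} bp"
            )
        if any(f < 0 for f in self.strand_bias_factors):
            raise ConfigurationError("strand_bias_factors must be >= 0")
        for g in self.groups:
            if g.n_clones < 0 or g.mean_mutations < 0:
                raise ConfigurationError(f"group {g.name!r}: counts must be >= 0")
            e = np.asarray(g.exposures, dtype=float)
            if (e < 0).any() or not np.isclose(e.sum(), 1.0, atol=1e-6):
                raise ConfigurationError(
                    f"group {g.name!r}: exposures must be non-negative and sum to 1"
                )
            if n_signatures is not None and len(g.exposures) != n_signatures:
                raise ConfigurationError(
                    f"group {g.name!r}: {len(g.exposures)} exposures for "
                    f"{n_signatures} signatures"
                )
        if n_signatures is not None and len(self.strand_bias_factors) != n_signatures:
            raise ConfigurationError(
                "strand_bias_factors length must equal the number of signatures"
            )


def _signature_from_peaks(
    name: str, peaks: Mapping[str, float], floor_mass: float = 0.04
) -> PlantedSignature:
    """Build a signature from named channel peaks plus a uniform floor."""
    p = np.full(96, floor_mass / 96.0)
    total_peaks = sum(peaks.values())
    for label, mass in peaks.items():
        p[CHANNEL_INDEX[label]] += (1.0 - floor_mass) * mass / total_peaks
    return PlantedSignature(name, p)


def default_signatures() -> list[PlantedSignature]:
    """The two shipped planted signatures.

    ``glycine-like``: C>T in GCY contexts (plus minor G[C>T]A/G and G[C>A]Y),
    emulating an O6-methylguanine-driven process. ``taurine-like``: C>T in
    ACC, CCT and TCG contexts.
    """
    b1 = _signature_from_peaks(
        "glycine-like",
        {
            "G[C>T]C": 0.33,
            "G[C>T]T": 0.33,
            "G[C>T]A": 0.12,
            "G[C>T]G": 0.12,
            "G[C>A]C": 0.03,
            "G[C>A]T": 0.03,
        },
    )
    b2 = _signature_from_peaks(
        "taurine-like",
        {
            "A[C>T]C": 0.30,
            "C[C>T]T": 0.30,
            "T[C>T]G": 0.30,
            "A[C>A]C": 0.02,
            "T[C>A]G": 0.02,
            "C[C>G]T": 0.02,
        },
    )
    return [b1, b2]


def default_config(strain: str = "TA1535", seed: int = 0) -> SimConfig:
    """Default experiment layout for the wild-type (``TA1535``-like, 48
    clones) or repair-deficient (``YG7108``-like, 60 clones) strain."""
    if strain == "TA1535":
        groups = (
            GroupSpec("control", 10, 0.2, (0.5, 0.5)),
            GroupSpec("NO-TCA", 10, 27.0, (0.1, 0.9)),
            GroupSpec("NO-TDCA", 8, 27.0, (0.1, 0.9)),
            GroupSpec("NO-GCA", 10, 14.0, (0.9, 0.1)),
            GroupSpec("NO-GDCA", 10, 14.0, (0.9, 0.1)),
        )
    elif strain == "YG7108":
        groups = (
            GroupSpec("control", 20, 0.2, (0.5, 0.5)),
            GroupSpec("NO-GCA", 28, 44.0, (0.9, 0.1)),
            GroupSpec("NO-GDCA", 12, 44.0, (0.9, 0.1)),
        )
    else:
        raise ConfigurationError(f"unknown strain {strain!r}")
    return SimConfig(groups=groups, strand_bias_factors=(4.0, 1.0), seed=seed)


# ---------------------------------------------------------------------------
# genome generation


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def generate_genome(config: SimConfig) -> tuple[Genome, pd.DataFrame]:
    """Generate an i.i.d. random genome and non-overlapping gene annotation.

    Bases are drawn independently with P(G) = P(C) = gc_content / 2. Genes
    are placed without overlap by distributing the leftover intergenic space
    uniformly at random among the n_genes + 1 gaps; strands are uniform.
    Returns the genome and a gene table with 1-based inclusive ``start`` /
    ``end`` and ``strand`` columns. Deterministic for a fixed config.
    """
    config.validate()
    rng = _rng(config.seed, 0xB10C, 1)
    p = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )
    codes = rng.choice(4, size=config.genome_length, p=p)
    seq = "".join(BASES[c] for c in codes)

    n, glen = config.n_genes, config.gene_length
    slack = config.genome_length - n * glen
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if n else []
    rows = []
    cursor = 0
    for i in range(n):
        cursor += gaps[i]
        start = cursor + 1  # 1-based
        end = cursor + glen
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"gene{i + 1:04d}", start, end, strand))
        cursor += glen
    genes = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])
    return Genome(config.chrom, seq), genes


def write_fasta(genome: Genome, path: str | Path) -> Path:
    path = Path(path)
    rec = SeqRecord(Seq(genome.seq), id=genome.name, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    return path


def write_gff3(genes: pd.DataFrame, genome: Genome, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome)}\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{genome.name}\tbactsig\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id};Name={row.gene_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# clone simulation


class _SiteIndex:
    """Per-context candidate mutation sites, split by strand label.

    For each of the 32 pyrimidine-collapsed contexts, stores the 0-based
    genome positions whose collapsed context matches, partitioned into
    transcribed (pyrimidine on the template strand of a gene), untranscribed
    (pyrimidine on the coding strand), and non-genic (intergenic or
    strand-ambiguous) pools. Terminal positions are excluded (context
    undefined).
    """

    def __init__(self, genome: Genome, genes: pd.DataFrame):
        code = encode_sequence(genome.seq)
        ctx, pyr_forward = genome_context_table(code)
        L = len(code)
        # gene occupancy codes: 0 none, 1 '+', 2 '-', 3 ambiguous
        occ = np.zeros(L, dtype=np.int8)
        for row in genes.itertuples(index=False):
            s, e = row.start - 1, row.end  # to 0-based half-open
            val = 1 if row.strand == "+" else 2
            seg = occ[s:e]
            seg[np.logical_and(seg != 0, seg != val)] = 3
            seg[seg == 0] = val
        genic = (occ == 1) | (occ == 2)
        gene_forward = occ == 1
        # transcribed <=> pyrimidine strand is opposite the gene (coding) strand
        transcribed = genic & (pyr_forward != gene_forward)
        untranscribed = genic & (pyr_forward == gene_forward)
        self.pools: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        for c in range(32):
            in_ctx = ctx == c
            self.pools.append(
                (
                    np.flatnonzero(in_ctx & transcribed),
                    np.flatnonzero(in_ctx & untranscribed),
                    np.flatnonzero(in_ctx & ~transcribed & ~untranscribed),
                )
            )
        self._occ = occ
        self._pyr_forward = pyr_forward
        self._code = code

    def context_site_count(self, ctx_idx: int) -> int:
        t, u, o = self.pools[ctx_idx]
        return len(t) + len(u) + len(o)

    def strand_label(self, pos0: int) -> str:
        occ = self._occ[pos0]
        if occ == 0:
            return "intergenic"
        if occ == 3:
            return "ambiguous"
        gene_forward = occ == 1
        if self._pyr_forward[pos0] != gene_forward:
            return "transcribed"
        return "untranscribed"


@dataclass
class SimulationResult:
    genome: Genome
    genes: pd.DataFrame
    signatures: list[PlantedSignature]
    config: SimConfig
    clones: list[CloneTruth]

    def channel_histogram(self) -> pd.DataFrame:
        """Truth-table catalog: clones x 96 channel counts."""
        counts = pd.DataFrame(
            0,
            index=[c.clone_id for c in self.clones],
            columns=list(CHANNELS_96),
            dtype=int,
        )
        for clone in self.clones:
            for m in clone.mutations:
                counts.loc[clone.clone_id, m.channel] += 1
        return counts

    def total_mutations(self) -> int:
        return sum(c.n_mutations for c in self.clones)


def simulate_clones(
    genome: Genome,
    genes: pd.DataFrame,
    signatures: Sequence[PlantedSignature],
    config: SimConfig,
) -> SimulationResult:
    """Plant signature-mixed mutations into clones and record the truth.

    Per clone the mutation count is Poisson(group mean); each mutation first
    draws its generating signature from the group's exposure vector, then its
    channel from that signature, then its position uniformly within the
    matching strand-label pool — genic placements choose the transcribed pool
    with odds ``strand_bias_factors[signature]`` against the untranscribed
    pool, genic vs non-genic placement follows the genomic share of matching
    sites. At most one mutation per clone per position (rejection
    resampling). Deterministic for a fixed config.
    """
    signatures = list(signatures)
    config.validate(n_signatures=len(signatures))
    index = _SiteIndex(genome, genes)

    # every channel reachable with positive probability must have >= 1 site
    active = np.zeros(96, dtype=bool)
    for g in config.groups:
        if g.n_clones == 0 or g.mean_mutations == 0:
            continue
        for sig, w in zip(signatures, g.exposures):
            if w > 0:
                active |= sig.probs > 0
    for ch in np.flatnonzero(active):
        if index.context_site_count(int(CHANNEL_TO_CONTEXT[ch])) == 0:
            raise SimulationError(
                f"channel {CHANNELS_96[ch]} has no matching trinucleotide "
                "context anywhere in the genome"
            )

    clones: list[CloneTruth] = []
    for gi, group in enumerate(config.groups):
        probs = [sig.probs for sig in signatures]
        for ci in range(group.n_clones):
            rng = _rng(config.seed, 0xC10E, gi, ci)
            n = int(rng.poisson(group.mean_mutations))
            used: set[int] = set()
            muts: list[PlantedMutation] = []
            for _ in range(n):
                mut = _draw_mutation(
                    rng, group, probs, signatures, config, index, used
                )
                used.add(mut.pos)
                muts.append(mut)
            if config.plant_reversion:
                rev = _plant_reversion(rng, genome, genes, config, index, used)
                if rev is not None:
                    used.add(rev.pos)
                    muts.append(rev)
            muts.sort(key=lambda m: m.pos)
            clones.append(
                CloneTruth(
                    clone_id=f"{group.name}_{ci + 1:02d}",
                    group=group.name,
                    exposures=tuple(group.exposures),
                    mutations=tuple(muts),
                )
            )
    return SimulationResult(genome, genes, signatures, config, clones)


def _draw_mutation(rng, group, probs, signatures, config, index, used):
    for _attempt in range(1000):
        si = int(rng.choice(len(probs), p=np.asarray(group.exposures)))
        ch = int(rng.choice(96, p=probs[si]))
        r = config.strand_bias_factors[si]
        pool_t, pool_u, pool_o = index.pools[int(CHANNEL_TO_CONTEXT[ch])]
        n_t, n_u, n_o = len(pool_t), len(pool_u), len(pool_o)
        n_genic = n_t + n_u
        total = n_genic + n_o
        if total == 0:
            raise SimulationError(
                f"channel {CHANNELS_96[ch]} has no matching context in the genome"
            )
        if n_genic and rng.random() < n_genic / total:
            if n_t == 0:
                pool = pool_u
            elif n_u == 0:
                pool = pool_t
            else:
                pool = pool_t if rng.random() < r / (1.0 + r) else pool_u
        else:
            pool = pool_o if n_o else (pool_t if n_t else pool_u)
        pos0 = int(pool[rng.integers(len(pool))])
        if pos0 in used:
            continue
        five, pyr_ref, pyr_alt, three = parse_channel(CHANNELS_96[ch])
        if index._pyr_forward[pos0]:
            ref, alt = pyr_ref, pyr_alt
        else:
            ref, alt = COMPLEMENT[pyr_ref], COMPLEMENT[pyr_alt]
        return PlantedMutation(
            pos=pos0 + 1,
            ref=ref,
            alt=alt,
            channel=CHANNELS_96[ch],
            strand_label=index.strand_label(pos0),
            signature=signatures[si].name,
        )
    raise SimulationError(
        "could not place a mutation after 1000 attempts; "
        "candidate sites exhausted for this clone"
    )


def _plant_reversion(rng, genome, genes, config, index, used):
    """One transition at a designated within-gene position (reversion target)."""
    if not 0 <= config.reversion_gene_index < len(genes):
        raise ConfigurationError("reversion_gene_index outside the gene table")
    gene = genes.iloc[config.reversion_gene_index]
    within = int(rng.choice(list(config.reversion_positions)))
    if within < 1 or within > gene.end - gene.start + 1:
        raise ConfigurationError(
            f"reversion position {within} outside gene of length "
            f"{gene.end - gene.start + 1}"
        )
    pos = gene.start + within - 1 if gene.strand == "+" else gene.end - within + 1
    pos0 = pos - 1
    if pos0 in used or pos0 <= 0 or pos0 >= len(genome) - 1:
        return None
    ref = genome.seq[pos0]
    alt = _TRANSITION[ref]
    from .channels import channel_of

    channel = channel_of(ref, alt, genome.seq[pos0 - 1], genome.seq[pos0 + 1])
    return PlantedMutation(
        pos=pos,
        ref=ref,
        alt=alt,
        channel=channel,
        strand_label=index.strand_label(pos0),
        signature="reversion",
    )


# ---------------------------------------------------------------------------
# writers


def write_clone_vcfs(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """One VCFv4.2 file per clone (FILTER=PASS, sorted by position)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    chrom = result.genome.name
    for clone in result.clones:
        path = outdir / f"{clone.clone_id}.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={chrom},length={len(result.genome)}>\n")
            fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
            fh.write(f"##source=bactsig-simulate\n##bactsig_clone={clone.clone_id}\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for m in clone.mutations:
                fh.write(
                    f"{chrom}\t{m.pos}\t.\t{m.ref}\t{m.alt}\t.\tPASS\t.\n"
                )
        paths[clone.clone_id] = path
    return paths


def write_truth_json(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "config": {
            **{
                k: v
                for k, v in dataclasses.asdict(result.config).items()
                if k != "groups"
            },
            "groups": [dataclasses.asdict(g) for g in result.config.groups],
        },
        "signatures": {s.name: s.probs.tolist() for s in result.signatures},
        "clones": [
            {
                "clone_id": c.clone_id,
                "group": c.group,
                "exposures": list(c.exposures),
                "n_mutations": c.n_mutations,
                "mutations": [dataclasses.asdict(m) for m in c.mutations],
            }
            for c in result.clones
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def make_cosmic_fixture(
    signatures: Sequence[PlantedSignature] | pd.DataFrame,
    path: str | Path,
    channel_order: Sequence[str] = CHANNELS_96,
) -> Path:
    """Write signatures as a COSMIC-style TSV (``Type`` column + one column
    per signature), round-trippable to 1e-6."""
    if isinstance(signatures, pd.DataFrame):
        df = signatures.copy()
        if list(df.index) != list(channel_order):
            df = df.reindex(list(channel_order))
    else:
        for s in signatures:
            if np.asarray(s.probs).shape != (96,):
                raise ConfigurationError(f"signature {s.name!r}: wrong vector length")
        df = pd.DataFrame(
            {s.name: s.probs for s in signatures}, index=list(channel_order)
        )
    if df.isna().any().any():
        raise ConfigurationError("signature table does not cover the channel order")
    df.index.name = "Type"
    path = Path(path)
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def make_geneset_fixture(
    n_sets: int,
    set_size: int,
    background_size: int,
    planted_overlap: int,
    seed: int,
    query_size: int = 300,
    planted_name: str = "PLANTED_SET",
) -> tuple[dict[str, list[str]], list[str], list[str]]:
    """Gene-set collection with exactly one set sharing ``planted_overlap``
    genes with the query; all other sets are uniform draws from the
    background (hypergeometric chance overlap).

    Returns ``(gene_sets, query_genes, background_genes)``.
    """
    if planted_overlap > set_size or planted_overlap > query_size:
        raise ConfigurationError(
            "planted_overlap cannot exceed the set size or the query size"
        )
    if set_size > background_size or query_size > background_size:
        raise ConfigurationError("background smaller than a set or the query")
    rng = _rng(seed, 0x6E9E)
    background = [f"G{i:05d}" for i in range(background_size)]
    query = list(rng.choice(background, size=query_size, replace=False))
    non_query = sorted(set(background) - set(query))
    planted = list(rng.choice(query, size=planted_overlap, replace=False)) + list(
        rng.choice(non_query, size=set_size - planted_overlap, replace=False)
    )
    gene_sets: dict[str, list[str]] = {planted_name: sorted(planted)}
    for i in range(n_sets - 1):
        members = rng.choice(background, size=set_size, replace=False)
        gene_sets[f"RANDOM_SET_{i + 1:03d}"] = sorted(members)
    return gene_sets, query, background


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write(name + "\tbactsig fixture\t" + "\t".join(genes) + "\n")
    return path


def write_gene_list(genes: Sequence[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(genes) + "\n")
    return path
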