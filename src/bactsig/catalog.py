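"""SNV ingestion and trinucleotide mutation catalogs.

Builds the 96-channel (pyrimidine-collapsed) and 192-channel (transcribed /
untranscribed) substitution catalogs from PASS-filtered VCF calls against a
reference genome, computes genome trinucleotide frequencies for signature
renormalization, and produces the strand-collapsed six-type mutation summary
and the reversion-target-site report.

Coordinates are 1-based inclusive throughout (VCF/GFF3 native); the circular
bacterial chromosome is treated as linear, so the two terminal positions have
no defined trinucleotide context.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

from .channels import (
    CHANNELS_96,
    CHANNEL_INDEX,
    CONTEXTS_32,
    PYRIMIDINES,
    SIX_TYPES,
    STRANDED_CHANNELS_192,
    channel_of,
    encode_sequence,
    genome_context_table,
    six_type_of,
)
from .errors import (
    ChannelAlignmentError,
    ClassificationError,
    ConfigurationError,
    FormatError,
    ReferenceMismatchError,
)
from .simulate import Genome

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SnvRecord:
    """One PASS single-nucleotide variant of one clone."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.ref == self.alt or self.ref not in _VALID or self.alt not in _VALID:
            raise FormatError(
                f"invalid SNV alleles {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise FormatError(f"position {self.pos} is not 1-based")


@dataclass
class CallSet:
    """All PASS calls of one sample: SNVs plus side tallies."""

    sample_id: str
    snvs: list[SnvRecord] = field(default_factory=list)
    n_insertions: int = 0
    n_deletions: int = 0
    n_non_pass: int = 0


@dataclass
class StrandedCatalog:
    """192-channel catalog plus the 96-channel side tally of genic-ambiguous
    and intergenic SNVs excluded from it."""

    counts: pd.DataFrame  # samples x 192
    excluded: pd.DataFrame  # samples x 96
    convention: str = "cosmic"

    def marginal_96(self) -> pd.DataFrame:
        """Collapse to 96 channels including the excluded side tally."""
        t = self.counts[[f"T:{c}" for c in CHANNELS_96]].to_numpy()
        u = self.counts[[f"U:{c}" for c in CHANNELS_96]].to_numpy()
        total = t + u + self.excluded.to_numpy()
        return pd.DataFrame(
            total, index=self.counts.index, columns=list(CHANNELS_96)
        )


# ---------------------------------------------------------------------------
# reference / annotation IO


def read_fasta(path: str | Path) -> Genome:
    """First record of a FASTA file as the reference chromosome."""
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            return Genome(rec.id, str(rec.seq).upper())
    raise FormatError(f"no sequences in {path}")


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> pd.DataFrame:
    """Gene features of a GFF3 file as a table with 1-based inclusive
    coordinates and strand."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                (
                    attrs.get("ID", f"feature{lineno}"),
                    int(parts[3]),
                    int(parts[4]),
                    parts[6],
                )
            )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])


class GeneIndex:
    """Interval lookup over gene annotations for strand classification."""

    def __init__(self, genes: pd.DataFrame):
        self._tree = IntervalTree()
        for row in genes.itertuples(index=False):
            # half-open on 1-based coordinates: [start, end + 1)
            self._tree[row.start : row.end + 1] = row.strand

    def strands_at(self, pos: int) -> set[str]:
        return {iv.data for iv in self._tree[pos]}


# ---------------------------------------------------------------------------
# VCF ingestion


def read_calls(path: str | Path, sample_id: str) -> CallSet:
    """All PASS calls of one VCF: single-base SNVs (multi-allelic records
    split per ALT allele) plus insertion/deletion tallies; non-PASS records
    are counted but dropped."""
    cs = CallSet(sample_id=sample_id)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            filters = list(rec.filter.keys())
            if filters != ["PASS"]:
                cs.n_non_pass += 1
                continue
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) == 1 and len(alt) == 1:
                    if ref in _VALID and alt in _VALID and ref != alt:
                        cs.snvs.append(
                            SnvRecord(sample_id, rec.chrom, rec.pos, ref, alt)
                        )
                elif len(alt) > len(ref):
                    cs.n_insertions += 1
                elif len(alt) < len(ref):
                    cs.n_deletions += 1
    return cs


def read_snvs(path: str | Path, sample_id: str) -> list[SnvRecord]:
    """PASS single-nucleotide variants of one VCF file."""
    return read_calls(path, sample_id).snvs


# ---------------------------------------------------------------------------
# classification


def trinucleotide_context(genome: Genome | str, snv: SnvRecord) -> str:
    """Pyrimidine-collapsed channel label (e.g. ``"A[C>T]G"``) of an SNV.

    If the reference base is a purine, the substitution and its flanks are
    reverse-complemented so the mutated base is a pyrimidine.
    """
    seq = genome.seq if isinstance(genome, Genome) else genome
    if snv.pos < 2 or snv.pos > len(seq) - 1:
        raise ClassificationError(
            f"{snv.chrom}:{snv.pos}: terminal position has no trinucleotide context"
        )
    ref_base = seq[snv.pos - 1]
    if ref_base != snv.ref:
        raise ReferenceMismatchError(
            f"{snv.chrom}:{snv.pos}: VCF REF {snv.ref} but reference has {ref_base}"
        )
    five = seq[snv.pos - 2]
    three = seq[snv.pos]
    if five not in _VALID or three not in _VALID:
        raise ClassificationError(
            f"{snv.chrom}:{snv.pos}: non-ACGT base in trinucleotide window"
        )
    return channel_of(snv.ref, snv.alt, five, three)


def classify_strand(
    snv: SnvRecord,
    annotation: GeneIndex | pd.DataFrame,
    convention: str = "cosmic",
) -> str:
    """Transcriptional strand label of an SNV.

    Under the default (COSMIC) convention a genic SNV is ``"transcribed"``
    when the pyrimidine of the mutated pair lies on the gene's template
    strand, ``"untranscribed"`` when on the coding strand;
    ``convention="inverted"`` swaps the two. SNVs inside genes on both
    strands are ``"ambiguous"``; outside genes, ``"intergenic"``.
    """
    if convention not in ("cosmic", "inverted"):
        raise ConfigurationError(f"unknown strand convention {convention!r}")
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    strands = index.strands_at(snv.pos)
    if not strands:
        return "intergenic"
    if len(strands) > 1:
        return "ambiguous"
    gene_strand = next(iter(strands))
    pyr_strand = "+" if snv.ref in PYRIMIDINES else "-"
    # template strand is the opposite of the gene (coding) strand
    transcribed = pyr_strand != gene_strand
    if convention == "inverted":
        transcribed = not transcribed
    return "transcribed" if transcribed else "untranscribed"


def build_catalog(
    snv_lists: Mapping[str, Sequence[SnvRecord]],
    genome: Genome,
    stranded: bool = False,
    annotation: GeneIndex | pd.DataFrame | None = None,
    convention: str = "cosmic",
) -> pd.DataFrame | StrandedCatalog:
    """Samples x channels count matrix in canonical COSMIC channel order.

    Unstranded: a samples x 96 DataFrame. Stranded: a
    :class:`StrandedCatalog` whose 192-channel matrix covers genic SNVs with
    an unambiguous strand; intergenic and ambiguous SNVs go to the 96-channel
    ``excluded`` side tally.
    """
    samples = list(snv_lists.keys())
    if not stranded:
        counts = np.zeros((len(samples), 96), dtype=int)
        for i, sid in enumerate(samples):
            for snv in snv_lists[sid]:
                try:
                    counts[i, CHANNEL_INDEX[trinucleotide_context(genome, snv)]] += 1
                except (ClassificationError, ReferenceMismatchError) as exc:
                    raise type(exc)(f"sample {sid}: {exc}") from exc
        return pd.DataFrame(counts, index=samples, columns=list(CHANNELS_96))
    if annotation is None:
        raise ConfigurationError("stranded catalogs require a gene annotation")
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    counts = np.zeros((len(samples), 192), dtype=int)
    excluded = np.zeros((len(samples), 96), dtype=int)
    for i, sid in enumerate(samples):
        for snv in snv_lists[sid]:
            try:
                ch = CHANNEL_INDEX[trinucleotide_context(genome, snv)]
            except (ClassificationError, ReferenceMismatchError) as exc:
                raise type(exc)(f"sample {sid}: {exc}") from exc
            label = classify_strand(snv, index, convention)
            if label == "transcribed":
                counts[i, ch] += 1
            elif label == "untranscribed":
                counts[i, 96 + ch] += 1
            else:
                excluded[i, ch] += 1
    return StrandedCatalog(
        counts=pd.DataFrame(counts, index=samples, columns=list(STRANDED_CHANNELS_192)),
        excluded=pd.DataFrame(excluded, index=samples, columns=list(CHANNELS_96)),
        convention=convention,
    )


def genome_trinucleotide_frequencies(genome: Genome | str) -> pd.Series:
    """Proportion of genome positions in each of the 32 pyrimidine-collapsed
    trinucleotide contexts (each context pooled with its reverse complement).

    Windows containing non-ACGT bases are skipped with a logged count.
    """
    seq = genome.seq if isinstance(genome, Genome) else genome
    if len(seq) < 3:
        raise ConfigurationError("genome shorter than one trinucleotide")
    ctx, _ = genome_context_table(encode_sequence(seq))
    interior = ctx[1:-1]
    n_skipped = int((interior < 0).sum())
    if n_skipped:
        logger.warning("skipped %d trinucleotide windows with non-ACGT bases", n_skipped)
    counts = np.bincount(interior[interior >= 0], minlength=32).astype(float)
    total = counts.sum()
    if total == 0:
        raise ConfigurationError("no classifiable trinucleotide windows in genome")
    return pd.Series(counts / total, index=list(CONTEXTS_32), name="frequency")


# ---------------------------------------------------------------------------
# summaries


def mutation_type_summary(
    vcf_paths_by_group: Mapping[str, Sequence[str | Path]],
) -> pd.DataFrame:
    """Six-type (strand-collapsed) mutation summary per treatment group.

    Rows: the six substitution types, Insertion, Deletion, Total. The total
    is the computed sum of the column.
    """
    rows = list(SIX_TYPES) + ["Insertion", "Deletion", "Total"]
    out = pd.DataFrame(0, index=rows, columns=list(vcf_paths_by_group.keys()))
    for group, paths in vcf_paths_by_group.items():
        for path in paths:
            cs = read_calls(path, sample_id=Path(path).stem)
            for snv in cs.snvs:
                out.loc[six_type_of(snv.ref, snv.alt), group] += 1
            out.loc["Insertion", group] += cs.n_insertions
            out.loc["Deletion", group] += cs.n_deletions
        out.loc["Total", group] = out.loc[rows[:-1], group].sum()
    return out


def gene_position(genome_pos: int, start: int, end: int, strand: str) -> int:
    """1-based position within a gene, in its reading orientation."""
    if strand == "+":
        return genome_pos - start + 1
    return end - genome_pos + 1


def target_site_report(
    snv_lists: Mapping[str, Sequence[SnvRecord]],
    gene_interval: tuple[int, int, str],
    within_gene_positions: Iterable[int] = (205, 206),
) -> pd.DataFrame:
    """Per-clone flags of SNVs at designated within-gene positions.

    ``gene_interval`` is (start, end, strand) of the target gene on the
    reference, 1-based inclusive; ``within_gene_positions`` are 1-based
    positions in the gene's reading orientation.
    """
    start, end, strand = gene_interval
    gene_len = end - start + 1
    positions = sorted(set(within_gene_positions))
    for p in positions:
        if p < 1 or p > gene_len:
            raise ConfigurationError(
                f"target position {p} outside gene of length {gene_len}"
            )
    rows = []
    for sid, snvs in snv_lists.items():
        for snv in snvs:
            if not start <= snv.pos <= end:
                continue
            gpos = gene_position(snv.pos, start, end, strand)
            if gpos in positions:
                rows.append(
                    (
                        sid,
                        snv.pos,
                        gpos,
                        snv.ref,
                        snv.alt,
                        six_type_of(snv.ref, snv.alt),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "clone_id",
            "genome_pos",
            "gene_pos",
            "ref",
            "alt",
            "substitution",
        ],
    )


# ---------------------------------------------------------------------------
# catalog TSV IO (COSMIC-style channels x samples layout)


def write_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> Path:
    """Write a samples x channels catalog as channels x samples TSV."""
    path = Path(path)
    out = catalog.T
    out.index.name = "Type"
    out.to_csv(path, sep="\t")
    return path


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    """Read a channels x samples TSV back into samples x channels form."""
    df = pd.read_csv(path, sep="\t", index_col=0).T
    cols = list(df.columns)
    if set(cols) == set(CHANNELS_96):
        df = df[list(CHANNELS_96)]
    elif set(cols) == set(STRANDED_CHANNELS_192):
        df = df[list(STRANDED_CHANNELS_192)]
    else:
        missing = sorted(set(CHANNELS_96) - set(cols))[:5]
        raise FormatError(
            f"{path}: not a 96- or 192-channel catalog (e.g. missing {missing})"
        )
    return df


def validate_channel_order(obj_channels: Sequence[str]) -> None:
    if list(obj_channels) != list(CHANNELS_96):
        raise ChannelAlignmentError("channel order does not match canonical order")
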