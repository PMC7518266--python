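"""Synthetic bacterial genomes with known ground truth.

The generator emulates the inputs of a real genome-wide scan — a FASTA
contig, a GFF3 CDS annotation, an operon-membership table — while
controlling every property the pipeline measures: codon usage, GC
content and length of intergenic regions, strand layout, operon
grouping, and optionally hairpins of tunable stability planted at a
chosen offset downstream of stop codons.  Because coding sequences are
drawn i.i.d. from a codon-usage model and intergenic sequence i.i.d.
from a base composition, an un-planted genome is itself a draw from the
codon-shuffle null: its expected dLFE is zero at every position, which
makes it the calibration standard for the landscape machinery.  Planted
hairpins provide positive ground truth for detector recovery tests.

All outputs are reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .genome_io import GeneModel, GenomeSequence, OperonRecord, revcomp

__all__ = [
    "SynthConfigError",
    "HairpinSpec",
    "SynthConfig",
    "SynthGenome",
    "design_hairpin",
    "make_genome",
    "make_library_reads",
    "ECOLI_LIKE_USAGE",
]


class SynthConfigError(ValueError):
    pass


def design_hairpin(stem_len: int, loop: str = "GAAA") -> str:
    """A perfect G:C-stem hairpin: ``stem_len`` Gs, the loop, ``stem_len`` Cs.

    Folding stability increases monotonically with stem length; a
    stem-12 hairpin folds well below -15 kcal/mol under Turner
    parameters.
    """
    if stem_len < 3:
        raise SynthConfigError("stem length must be >= 3")
    if len(loop) < 3:
        raise SynthConfigError("loop must be >= 3 nt")
    return "G" * stem_len + loop + "C" * stem_len


@dataclass(frozen=True)
class HairpinSpec:
    """Which genes get a planted hairpin and where it sits.

    ``offset`` is the position of the hairpin's 5' end on the
    stop-relative axis of its gene (0 = first nt after the stop).
    """

    fraction: float = 0.0
    stem_len: int = 12
    loop: str = "GAAA"
    offset: int = 5

    @property
    def length(self) -> int:
        return 2 * self.stem_len + len(self.loop)


@dataclass(frozen=True)
class SynthConfig:
    n_genes: int = 200
    gene_len_codons: tuple[int, int] = (60, 200)  # uniform, incl. start & stop codons
    codon_usage: Mapping[str, Mapping[str, float]] | None = None  # aa -> codon -> weight
    intergenic_gc: float = 0.25
    intergenic_range: tuple[int, int] = (20, 120)  # uniform inclusive
    fraction_opposite: float = 0.0
    operon_size_range: tuple[int, int] = (1, 4)
    hairpin: HairpinSpec = HairpinSpec()
    stop_codons: tuple[str, ...] = ("TAA", "TAG", "TGA")
    translation_table: int = 11
    flank: int = 160  # neutral sequence before the first and after the last gene
    contig_id: str = "synth_1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hairpin.fraction <= 1.0:
            raise SynthConfigError("hairpin fraction must be in [0,1]")
        if not 0.0 <= self.fraction_opposite <= 1.0:
            raise SynthConfigError("fraction_opposite must be in [0,1]")
        if not 0.0 <= self.intergenic_gc <= 1.0:
            raise SynthConfigError("intergenic GC must be in [0,1]")
        if self.gene_len_codons[0] < 15:
            raise SynthConfigError("genes must be at least 15 codons")


def _sense_families(table_id: int) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fam: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fam.setdefault(aa, []).append(codon)
    for aa in fam:
        fam[aa].sort()
    return fam


#: Approximate E. coli K-12 codon usage (relative weights within each
#: synonymous family), available as ``SynthConfig(codon_usage=ECOLI_LIKE_USAGE)``.
ECOLI_LIKE_USAGE: dict[str, dict[str, float]] = {
    "A": {"GCA": 21, "GCC": 27, "GCG": 36, "GCT": 16},
    "R": {"AGA": 4, "AGG": 2, "CGA": 6, "CGC": 40, "CGG": 10, "CGT": 38},
    "N": {"AAC": 55, "AAT": 45},
    "D": {"GAC": 37, "GAT": 63},
    "C": {"TGC": 56, "TGT": 44},
    "Q": {"CAA": 35, "CAG": 65},
    "E": {"GAA": 69, "GAG": 31},
    "G": {"GGA": 11, "GGC": 41, "GGG": 15, "GGT": 34},
    "H": {"CAC": 43, "CAT": 57},
    "I": {"ATA": 7, "ATC": 42, "ATT": 51},
    "L": {"CTA": 4, "CTC": 10, "CTG": 50, "CTT": 10, "TTA": 13, "TTG": 13},
    "K": {"AAA": 77, "AAG": 23},
    "M": {"ATG": 100},
    "F": {"TTC": 43, "TTT": 57},
    "P": {"CCA": 19, "CCC": 12, "CCG": 53, "CCT": 16},
    "S": {"AGC": 28, "AGT": 15, "TCA": 12, "TCC": 15, "TCG": 15, "TCT": 15},
    "T": {"ACA": 13, "ACC": 44, "ACG": 27, "ACT": 17},
    "W": {"TGG": 100},
    "Y": {"TAC": 43, "TAT": 57},
    "V": {"GTA": 15, "GTC": 22, "GTG": 37, "GTT": 26},
}


@dataclass
class SynthGenome:
    """In-memory result of :func:`make_genome`, with text-file export."""

    config: SynthConfig
    seed: int
    contigs: dict[str, GenomeSequence]
    genes: list[GeneModel]
    operons: list[OperonRecord]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fasta",
            "gff": outdir / "annotation.gff3",
            "operons": outdir / "operons.tsv",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["fasta"], "w") as fh:
            for contig in self.contigs.values():
                fh.write(f">{contig.contig_id}\n")
                for i in range(0, len(contig.residues), 70):
                    fh.write(contig.residues[i : i + 70] + "\n")
        with open(paths["gff"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                attrs = (
                    f"ID=cds_{g.gene_id};Parent={g.gene_id};gene_id={g.gene_id};"
                    f"transl_table={g.translation_table}"
                )
                fh.write(
                    "\t".join(
                        [
                            g.contig_id,
                            "rtscan_synth",
                            "CDS",
                            str(g.cds_start + 1),
                            str(g.cds_end),
                            ".",
                            g.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )
        with open(paths["operons"], "w") as fh:
            for op in self.operons:
                for i, gid in enumerate(op.ordered_gene_ids):
                    fh.write(f"{op.operon_id}\t{gid}\t{i}\n")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=length, p=probs)])


def _random_cds(
    rng: np.random.Generator,
    n_codons: int,
    families: dict[str, list[str]],
    usage: Mapping[str, Mapping[str, float]] | None,
    stop_codons: Sequence[str],
) -> str:
    aas = sorted(families)
    parts = ["ATG"]
    for _ in range(n_codons - 2):
        aa = aas[rng.integers(len(aas))]
        codons = families[aa]
        if usage is not None and aa in usage:
            weights = np.array([usage[aa].get(c, 0.0) for c in codons], dtype=float)
            probs = weights / weights.sum()
            parts.append(codons[rng.choice(len(codons), p=probs)])
        else:
            parts.append(codons[rng.integers(len(codons))])
    parts.append(stop_codons[rng.integers(len(stop_codons))])
    return "".join(parts)


def make_genome(config: SynthConfig, seed: int) -> SynthGenome:
    """Generate one genome, annotation, operon table and truth table.

    Genes are laid out left to right on a single contig separated by
    intergenic gaps drawn from ``intergenic_range``.  A gene selected
    for the opposite strand is reverse-complemented in place (distances
    are preserved); its stop-relative downstream region is then the gap
    on its left, and hairpins are planted in each gene's own sense
    downstream.  Planting replaces intergenic sequence, never inserts,
    so configured distances stay exact.  A hairpin that does not fit in
    its gap, or that would collide with a neighbouring gene's hairpin,
    raises :class:`SynthConfigError` naming the gene.
    """
    rng = np.random.default_rng(seed)
    cfg = config
    n = cfg.n_genes
    families = _sense_families(cfg.translation_table)
    hp = cfg.hairpin
    hairpin_seq = design_hairpin(hp.stem_len, hp.loop) if hp.fraction > 0 else ""

    lengths = rng.integers(cfg.gene_len_codons[0], cfg.gene_len_codons[1] + 1, size=n)
    gaps = rng.integers(cfg.intergenic_range[0], cfg.intergenic_range[1] + 1, size=n + 1)
    gaps[0] = max(cfg.flank, gaps[0])
    gaps[n] = max(cfg.flank, gaps[n])
    strands = np.where(rng.random(n) < cfg.fraction_opposite, "-", "+")
    n_planted = int(round(hp.fraction * n))
    planted = np.zeros(n, dtype=bool)
    planted[rng.permutation(n)[:n_planted]] = True

    gap_seqs = [list(_random_seq(rng, int(g), cfg.intergenic_gc)) for g in gaps]
    cds_sense = [
        _random_cds(rng, int(L), families, cfg.codon_usage, cfg.stop_codons)
        for L in lengths
    ]

    # hairpin placement bookkeeping: per gap, list of occupied (start, end) slices
    occupied: dict[int, list[tuple[int, int]]] = {}

    def claim(gap_idx: int, s: int, e: int, gene_id: str) -> None:
        gap = gap_seqs[gap_idx]
        if s < 0 or e > len(gap):
            raise SynthConfigError(
                f"gene {gene_id}: hairpin (offset {hp.offset}, {hp.length} nt) does not "
                f"fit in its {len(gap)} nt intergenic region"
            )
        for os_, oe in occupied.get(gap_idx, []):
            if s < oe and os_ < e:
                raise SynthConfigError(
                    f"gene {gene_id}: hairpin collides with a neighbouring gene's hairpin"
                )
        occupied.setdefault(gap_idx, []).append((s, e))

    for i in range(n):
        if not planted[i]:
            continue
        gid = f"g{i:04d}"
        if strands[i] == "+":
            claim(i + 1, hp.offset, hp.offset + hp.length, gid)
            gap_seqs[i + 1][hp.offset : hp.offset + hp.length] = list(hairpin_seq)
        else:
            L = len(gap_seqs[i])
            s, e = L - hp.offset - hp.length, L - hp.offset
            claim(i, s, e, gid)
            gap_seqs[i][s:e] = list(revcomp(hairpin_seq))

    # assemble the contig and gene models
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    for i in range(n):
        parts.append("".join(gap_seqs[i]))
        pos += len(gap_seqs[i])
        forward = cds_sense[i] if strands[i] == "+" else revcomp(cds_sense[i])
        parts.append(forward)
        genes.append(
            GeneModel(
                gene_id=f"g{i:04d}",
                contig_id=cfg.contig_id,
                strand=str(strands[i]),
                cds_start=pos,
                cds_end=pos + len(forward),
                translation_table=cfg.translation_table,
            )
        )
        pos += len(forward)
    parts.append("".join(gap_seqs[n]))
    contig = GenomeSequence(cfg.contig_id, "".join(parts))

    # operons: consecutive genes grouped into runs of random size
    operons: list[OperonRecord] = []
    i = 0
    while i < n:
        size = int(rng.integers(cfg.operon_size_range[0], cfg.operon_size_range[1] + 1))
        members = [g.gene_id for g in genes[i : i + size]]
        operons.append(OperonRecord(f"op{len(operons):04d}", members))
        i += size

    from .genome_io import operon_positions, pair_topology

    contigs = {cfg.contig_id: contig}
    topo = {t.gene_id: t for t in pair_topology(genes)}
    labels = operon_positions(operons, genes)
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "strand": [g.strand for g in genes],
            "hairpin_planted": planted,
            "stem_len": np.where(planted, hp.stem_len, 0),
            "target_offset": np.where(planted, hp.offset, np.nan),
            "intergenic_distance": [
                topo[g.gene_id].intergenic_distance for g in genes
            ],
            "same_strand": [topo[g.gene_id].same_strand for g in genes],
            "operon_position": [labels[g.gene_id] for g in genes],
        }
    )
    return SynthGenome(
        config=cfg, seed=seed, contigs=contigs, genes=genes, operons=operons, truth=truth
    )


def make_library_reads(
    n_reads: int,
    seed: int,
    n_bins: int = 4,
    gc_range: tuple[float, float] = (0.3, 0.7),
    mean_count: float = 5.0,
) -> list:
    """Random 24-nt library read tables spanning a range of fold stability.

    Bin ``b`` draws its variable regions at a GC content interpolated
    across ``gc_range`` — GC-rich bins fold more stably, emulating the
    spread of clone stabilities across expression bins.  Counts are
    geometric with the given mean (always >= 1).
    """
    from .library_ops import LibraryRead

    rng = np.random.default_rng(seed)
    gcs = np.linspace(gc_range[0], gc_range[1], n_bins)
    reads = []
    per_bin = [n_reads // n_bins] * n_bins
    for i in range(n_reads - sum(per_bin)):
        per_bin[i] += 1
    for b, (gc, m) in enumerate(zip(gcs, per_bin)):
        for _ in range(m):
            seq = _random_seq(rng, 24, float(gc))
            count = 1 + int(rng.geometric(min(1.0, 1.0 / mean_count)) - 1)
            reads.append(LibraryRead(seq, count, f"bin{b + 1}"))
    return reads
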