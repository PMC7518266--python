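"""Genome and annotation handling for stop-codon-centred analyses.

This module parses a genome (FASTA) plus its CDS annotation (GFF3),
applies the gene-inclusion filters used throughout the pipeline, and
provides strand-aware access to mRNA-sense sequence windows positioned
relative to the *end of the stop codon* of each gene.

Position convention (the "position axis")
-----------------------------------------
All downstream analyses index windows by the mRNA-sense offset ``p`` of
the window's 5'-most nucleotide relative to the first nucleotide after
the stop codon: ``p = 0`` is the nucleotide immediately 3' of the stop,
``p = -3`` is the first nucleotide of the stop codon itself, negative
positions lie inside the coding sequence.

Coordinates are 0-based half-open internally; GFF3 input (1-based
inclusive) is converted at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "GenePairTopology",
    "OperonRecord",
    "parse_genome",
    "qc_filter_genes",
    "gene_sense_seq",
    "sense_window",
    "pair_topology",
    "operon_positions",
    "read_operon_table",
    "read_abundance_table",
    "downstream_start_census",
    "start_probability_dp",
    "EFFICIENT_STARTS",
]

#: The three most used bacterial initiation codons.
EFFICIENT_STARTS = ("ATG", "GTG", "TTG")

_VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: an uppercase nucleotide string over {A,C,G,T,N}."""

    contig_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"contig {self.contig_id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A protein-coding gene as a single (possibly merged) CDS interval.

    ``cds_start``/``cds_end`` are 0-based half-open coordinates on the
    forward strand.  Bacterial CDSs are effectively single-part; the rare
    multi-part annotation is merged to its genomic span and flagged.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    cds_end: int
    translation_table: int = 11
    multi_part: bool = False

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.cds_end <= self.cds_start:
            raise ValueError(f"gene {self.gene_id}: empty or inverted CDS interval")

    @property
    def length(self) -> int:
        return self.cds_end - self.cds_start

    def stop_axis_origin(self) -> int:
        """Forward-strand coordinate of position-axis 0 (first nt after stop)."""
        return self.cds_end if self.strand == "+" else self.cds_start - 1


@dataclass
class GenePairTopology:
    """Relation of a gene to its mRNA-sense downstream neighbour.

    ``intergenic_distance`` is measured between the end of this CDS
    (including its stop codon) and the start of the next annotated CDS
    in this gene's transcription direction; it is negative when the two
    CDSs overlap, and undefined when no downstream gene exists.
    """

    gene_id: str
    next_gene_id: str | None
    intergenic_distance: int | None
    same_strand: bool | None
    downstream_exists: bool


@dataclass
class OperonRecord:
    operon_id: str
    ordered_gene_ids: list[str]

    def __post_init__(self) -> None:
        if not self.ordered_gene_ids:
            raise ValueError(f"operon {self.operon_id}: no genes")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _gene_id_of(feature: gffutils.Feature) -> str:
    for key in ("gene_id", "Parent", "ID", "locus_tag"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    raise ValueError(f"CDS feature at {feature.seqid}:{feature.start} has no usable id attribute")


def parse_genome(
    fasta_path: str | Path, gff_path: str | Path
) -> tuple[dict[str, GenomeSequence], list[GeneModel]]:
    """Read a FASTA genome and GFF3 CDS annotation into gene models.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  CDS features sharing a gene id are merged to one
    :class:`GeneModel` spanning all parts, flagged ``multi_part``.
    Genes are returned sorted by contig then start coordinate.
    """
    contigs: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        contigs[rec.id] = GenomeSequence(rec.id, str(rec.seq))

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    parts: dict[str, list[gffutils.Feature]] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS"):
        gid = _gene_id_of(feat)
        if gid not in parts:
            parts[gid] = []
            order.append(gid)
        parts[gid].append(feat)

    genes: list[GeneModel] = []
    for gid in order:
        feats = parts[gid]
        contig_id = feats[0].seqid
        if contig_id != feats[-1].seqid:
            raise ValueError(f"gene {gid}: CDS parts on different contigs")
        if contig_id not in contigs:
            raise ValueError(f"GFF refers to contig {contig_id!r} absent from the FASTA")
        start = min(f.start for f in feats) - 1  # to 0-based
        end = max(f.end for f in feats)
        contig = contigs[contig_id]
        if start < 0 or end > len(contig):
            raise ValueError(
                f"gene {gid}: CDS [{start},{end}) outside contig {contig_id} "
                f"of length {len(contig)}"
            )
        strand = feats[0].strand if feats[0].strand in _VALID_STRANDS else "+"
        table = 11
        for f in feats:
            if "transl_table" in f.attributes:
                table = int(f.attributes["transl_table"][0])
        genes.append(
            GeneModel(
                gene_id=gid,
                contig_id=contig_id,
                strand=strand,
                cds_start=start,
                cds_end=end,
                translation_table=table,
                multi_part=len(feats) > 1,
            )
        )
    genes.sort(key=lambda g: (g.contig_id, g.cds_start))
    return contigs, genes


def gene_sense_seq(gene: GeneModel, contigs: Mapping[str, GenomeSequence]) -> str:
    """mRNA-sense CDS sequence (reverse complement for minus-strand genes)."""
    raw = contigs[gene.contig_id].residues[gene.cds_start : gene.cds_end]
    return raw if gene.strand == "+" else revcomp(raw)


def qc_filter_genes(
    genes: Iterable[GeneModel],
    contigs: Mapping[str, GenomeSequence],
    min_length: int = 40,
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Apply the gene-inclusion filters used throughout the pipeline.

    A gene is retained only if its CDS is at least ``min_length`` nt, a
    multiple of 3, free of internal in-frame stop codons, and terminated
    by a stop codon of its translation table.  Returns the retained
    genes and an exclusion report of ``(gene_id, reason)`` rows with
    reasons in {"short", "not_multiple_of_3", "internal_stop",
    "no_terminal_stop"}.
    """
    kept: list[GeneModel] = []
    report: list[tuple[str, str]] = []
    for gene in genes:
        if gene.length < min_length:
            report.append((gene.gene_id, "short"))
            continue
        if gene.length % 3 != 0:
            report.append((gene.gene_id, "not_multiple_of_3"))
            continue
        stops = set(CodonTable.unambiguous_dna_by_id[gene.translation_table].stop_codons)
        sense = gene_sense_seq(gene, contigs)
        if sense[-3:] not in stops:
            report.append((gene.gene_id, "no_terminal_stop"))
            continue
        internal = any(sense[i : i + 3] in stops for i in range(0, gene.length - 3, 3))
        if internal:
            report.append((gene.gene_id, "internal_stop"))
            continue
        kept.append(gene)
    return kept, report


def sense_window(
    gene: GeneModel,
    contigs: Mapping[str, GenomeSequence],
    p: int,
    width: int,
) -> str | None:
    """``width`` nt of mRNA-sense sequence opening at axis position ``p``.

    The window's 5' end sits ``p`` nucleotides after the last nucleotide
    of the stop codon (``p`` may be negative, reaching into the CDS).
    Returns ``None`` when the window is not fully contained in the
    contig; truncated windows are never padded.
    """
    contig = contigs[gene.contig_id]
    if gene.strand == "+":
        s = gene.cds_end + p
        e = s + width
        if s < 0 or e > len(contig):
            return None
        return contig.residues[s:e]
    # minus strand: axis position p maps to forward coordinate cds_start-1-p
    e = gene.cds_start - p
    s = e - width
    if s < 0 or e > len(contig):
        return None
    return revcomp(contig.residues[s:e])


def _nested_gene_ids(genes: Sequence[GeneModel]) -> set[str]:
    """Genes whose span lies strictly inside another gene's span."""
    nested: set[str] = set()
    for g in genes:
        for h in genes:
            if h is g:
                continue
            if h.cds_start <= g.cds_start and g.cds_end <= h.cds_end and (
                h.cds_start < g.cds_start or g.cds_end < h.cds_end
            ):
                nested.add(g.gene_id)
                break
    return nested


def pair_topology(genes: Sequence[GeneModel]) -> list[GenePairTopology]:
    """Classify each gene against its mRNA-sense downstream neighbour.

    The neighbour is the nearest annotated CDS (either strand, nested
    genes excluded) beyond this gene's 3' end *in this gene's reading
    direction*: to the right on the forward strand, to the left on the
    reverse strand.  This keeps the classification invariant under
    reverse-complementing the genome.  Distances may be negative for
    overlapping CDS pairs.
    """
    out: list[GenePairTopology] = []
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig_genes in by_contig.values():
        contig_genes = sorted(contig_genes, key=lambda g: g.cds_start)
        nested = _nested_gene_ids(contig_genes)
        for g in contig_genes:
            if g.strand == "+":
                cands = [
                    h
                    for h in contig_genes
                    if h is not g and h.gene_id not in nested and h.cds_start > g.cds_start
                ]
                nxt = min(cands, key=lambda h: h.cds_start) if cands else None
                dist = None if nxt is None else nxt.cds_start - g.cds_end
            else:
                cands = [
                    h
                    for h in contig_genes
                    if h is not g and h.gene_id not in nested and h.cds_end < g.cds_end
                ]
                nxt = max(cands, key=lambda h: h.cds_end) if cands else None
                dist = None if nxt is None else g.cds_start - nxt.cds_end
            out.append(
                GenePairTopology(
                    gene_id=g.gene_id,
                    next_gene_id=None if nxt is None else nxt.gene_id,
                    intergenic_distance=dist,
                    same_strand=None if nxt is None else (nxt.strand == g.strand),
                    downstream_exists=nxt is not None,
                )
            )
    order = {g.gene_id: i for i, g in enumerate(genes)}
    out.sort(key=lambda t: order[t.gene_id])
    return out


def operon_positions(
    operons: Iterable[OperonRecord], genes: Iterable[GeneModel]
) -> dict[str, str]:
    """Label every gene as first/internal/last/monocistronic/unassigned."""
    labels = {g.gene_id: "unassigned" for g in genes}
    for op in operons:
        ids = op.ordered_gene_ids
        if len(ids) == 1:
            if ids[0] in labels:
                labels[ids[0]] = "monocistronic"
            continue
        for i, gid in enumerate(ids):
            if gid not in labels:
                continue
            if i == 0:
                labels[gid] = "first"
            elif i == len(ids) - 1:
                labels[gid] = "last"
            else:
                labels[gid] = "internal"
    return labels


def read_operon_table(path: str | Path) -> list[OperonRecord]:
    """Read ``operon_id<TAB>gene_id<TAB>position_index`` rows."""
    rows: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            op, gid, idx = line.split("\t")[:3]
            rows.setdefault(op, []).append((int(idx), gid))
    return [
        OperonRecord(op, [gid for _, gid in sorted(members)])
        for op, members in rows.items()
    ]


def read_abundance_table(path: str | Path) -> dict[str, float]:
    """Read ``gene_id<TAB>abundance`` rows."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, ab = line.split("\t")[:2]
            out[gid] = float(ab)
    return out


def downstream_start_census(
    gene: GeneModel,
    contigs: Mapping[str, GenomeSequence],
    L: int = 50,
    codons: Sequence[str] = EFFICIENT_STARTS,
) -> tuple[int, bool]:
    """Count start-codon trinucleotides in the ``L`` nt after the stop.

    Every occurrence at every offset (any reading frame) is counted,
    since a scanning ribosome can re-initiate in all frames.  When fewer
    than ``L`` nt remain on the contig the census runs over what is
    available and the result is flagged truncated.
    """
    contig = contigs[gene.contig_id]
    if gene.strand == "+":
        avail = min(L, len(contig) - gene.cds_end)
    else:
        avail = min(L, gene.cds_start)
    truncated = avail < L
    if avail < 3:
        return 0, truncated
    seq = sense_window(gene, contigs, 0, avail)
    assert seq is not None
    wanted = set(codons)
    count = sum(1 for i in range(avail - 2) if seq[i : i + 3] in wanted)
    return count, truncated


def start_probability_dp(L: int, base_composition: Mapping[str, float]) -> float:
    """Probability that an i.i.d. ``L``-mer contains ATG, GTG or TTG in any frame.

    Exact dynamic program over the 2-nucleotide suffix state: a hit
    occurs whenever a nucleotide from {A,G,T} is followed by TG at any
    offset.  Monotonically non-decreasing in ``L``.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    comp = {k.upper().replace("U", "T"): float(v) for k, v in base_composition.items()}
    total = sum(comp.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("base composition must sum to 1")
    if L < 3:
        return 0.0
    alphabet = "ACGT"
    probs = {b: comp.get(b, 0.0) for b in alphabet}
    # state: last two emitted nucleotides; value: P(no hit so far, suffix=state)
    states: dict[tuple[str, str], float] = {}
    for b1 in alphabet:
        for b2 in alphabet:
            states[(b1, b2)] = probs[b1] * probs[b2]
    for _ in range(L - 2):
        nxt: dict[tuple[str, str], float] = {k: 0.0 for k in states}
        for (a, b), pr in states.items():
            if pr == 0.0:
                continue
            for c in alphabet:
                if c == "G" and b == "T" and a in "AGT":
                    continue  # start codon completed: path leaves the no-hit set
                nxt[(b, c)] += pr * probs[c]
        states = nxt
    return 1.0 - sum(states.values())
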