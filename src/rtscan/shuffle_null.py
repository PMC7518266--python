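"""Composition-preserving genome randomization (the dLFE null model).

The null hypothesis is that only the amino-acid sequence and the
nucleotide/codon composition of a region are under selection.  Sampling
from it means:

* within each coding sequence, synonymous codons are randomly permuted
  among the positions coding for the same amino acid (translation and
  codon multiset are invariant);
* within each non-coding region, nucleotides are randomly permuted
  (nucleotide multiset is invariant);
* nucleotides covered by two or more CDS annotations, codons containing
  ambiguous bases (N), and terminal stop codons are left untouched.

Minus-strand CDSs are shuffled in mRNA sense (so synonymous families are
biologically defined) and written back reverse-complemented.  All
randomness is driven by a master seed plus a replicate index, so any
replicate can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .genome_io import GeneModel, GenomeSequence, revcomp

__all__ = [
    "RandomizedGenome",
    "shuffle_cds_codons",
    "shuffle_noncoding",
    "randomize_genome",
    "replicate_rng",
]


def replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    """Deterministic substream for one randomization replicate."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate_index)]))


def _codon_aa_map(translation_table: int) -> Mapping[str, str]:
    table = CodonTable.unambiguous_dna_by_id[translation_table]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def _permute_codons(
    codons: list[str],
    frozen: Sequence[bool],
    translation_table: int,
    rng: np.random.Generator,
) -> list[str]:
    aa_of = _codon_aa_map(translation_table)
    groups: dict[str, list[int]] = {}
    for i, codon in enumerate(codons):
        if frozen[i]:
            continue
        groups.setdefault(aa_of.get(codon, "X"), []).append(i)
    out = list(codons)
    for positions in groups.values():
        if len(positions) < 2:
            continue
        perm = rng.permutation(len(positions))
        for dst, src in zip(positions, perm):
            out[dst] = codons[positions[src]]
    return out


def shuffle_cds_codons(
    cds_seq: str,
    translation_table: int = 11,
    rng: np.random.Generator | None = None,
) -> str:
    """Permute synonymous codons of one mRNA-sense CDS.

    Codons containing ambiguous bases and a terminal stop codon are left
    in place.  Translation and the codon multiset are preserved exactly.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if rng is None:
        rng = np.random.default_rng()
    seq = cds_seq.upper()
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stops = set(CodonTable.unambiguous_dna_by_id[translation_table].stop_codons)
    frozen = [any(b not in "ACGT" for b in c) for c in codons]
    if codons and codons[-1] in stops:
        frozen[-1] = True
    return "".join(_permute_codons(codons, frozen, translation_table, rng))


def shuffle_noncoding(seq: str, rng: np.random.Generator | None = None) -> str:
    """Uniform random permutation of a non-coding region's nucleotides."""
    if rng is None:
        rng = np.random.default_rng()
    if len(seq) < 2:
        return seq
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(len(chars))])


@dataclass
class RandomizedGenome:
    """One composition-preserving randomization of a genome."""

    replicate_index: int
    seed: int
    contigs: dict[str, GenomeSequence]
    provenance: dict[str, str]

    def write_fasta(self, path) -> None:
        """Export the replicate as FASTA (debugging aid)."""
        with open(path, "w") as fh:
            for cid in sorted(self.contigs):
                fh.write(f">{cid} replicate={self.replicate_index} seed={self.seed}\n")
                res = self.contigs[cid].residues
                for i in range(0, len(res), 70):
                    fh.write(res[i : i + 70] + "\n")


def _coverage(
    length: int, intervals: Iterable[tuple[int, int]]
) -> np.ndarray:
    cov = np.zeros(length + 1, dtype=np.int32)
    for s, e in intervals:
        cov[s] += 1
        cov[e] -= 1
    return np.cumsum(cov[:-1])


def randomize_genome(
    contigs: Mapping[str, GenomeSequence],
    genes: Sequence[GeneModel],
    seed: int,
    replicate_index: int,
    frozen_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> RandomizedGenome:
    """Produce one randomized replicate of the whole genome.

    ``genes`` should be the QC-passed gene set: their CDSs are
    codon-permuted in mRNA sense; every position not covered by any CDS
    is nucleotide-permuted within its contiguous run.  Positions covered
    by more than one CDS are kept byte-identical to the native genome,
    as are any extra ``frozen_intervals`` (e.g. CDSs of QC-excluded
    genes, whose bases should be neither codon- nor UTR-permuted).
    """
    rng = replicate_rng(seed, replicate_index)
    out: dict[str, GenomeSequence] = {}
    provenance: dict[str, str] = {}
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)

    for contig_id in sorted(contigs):
        native = contigs[contig_id].residues
        arr = list(native)
        contig_genes = sorted(
            genes_by_contig.get(contig_id, []), key=lambda g: (g.cds_start, g.gene_id)
        )
        cds_intervals = [(g.cds_start, g.cds_end) for g in contig_genes]
        extra = list((frozen_intervals or {}).get(contig_id, []))
        cov = _coverage(len(native), cds_intervals)
        multi = cov >= 2
        blocked = multi.copy()  # positions a codon permutation may not touch
        for s, e in extra:
            blocked[s:e] = True

        for gene in contig_genes:
            sense = native[gene.cds_start : gene.cds_end]
            if gene.strand == "-":
                sense = revcomp(sense)
            codons = [sense[i : i + 3] for i in range(0, len(sense), 3)]
            n_codons = len(codons)

            def codon_positions(idx: int) -> range:
                if gene.strand == "+":
                    return range(gene.cds_start + 3 * idx, gene.cds_start + 3 * idx + 3)
                return range(gene.cds_end - 3 * idx - 3, gene.cds_end - 3 * idx)

            stops = set(
                CodonTable.unambiguous_dna_by_id[gene.translation_table].stop_codons
            )
            frozen = []
            for i, codon in enumerate(codons):
                froz = any(b not in "ACGT" for b in codon)
                froz = froz or any(blocked[p] for p in codon_positions(i))
                if i == n_codons - 1 and codon in stops:
                    froz = True
                frozen.append(froz)
            shuffled = _permute_codons(codons, frozen, gene.translation_table, rng)
            new_sense = "".join(shuffled)
            if gene.strand == "-":
                new_sense = revcomp(new_sense)
            for k, pos in enumerate(range(gene.cds_start, gene.cds_end)):
                if not multi[pos]:
                    arr[pos] = new_sense[k]

        # nucleotide-permute every maximal run of CDS-free positions
        free = cov == 0
        for s, e in extra:
            free[s:e] = False
        i = 0
        n = len(native)
        while i < n:
            if not free[i]:
                i += 1
                continue
            j = i
            while j < n and free[j]:
                j += 1
            arr[i:j] = list(shuffle_noncoding(native[i:j], rng))
            i = j
        out[contig_id] = GenomeSequence(contig_id, "".join(arr))
        provenance[contig_id] = "cds=codon_permuted;noncoding=nt_permuted;overlaps=frozen"
    return RandomizedGenome(
        replicate_index=replicate_index, seed=seed, contigs=out, provenance=provenance
    )
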