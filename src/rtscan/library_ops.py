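"""Synthetic-operon library calculations.

A sort-seq library places 24 random nucleotides in the inter-cistronic
region of a two-gene reporter operon, immediately after a fixed hexamer
that follows the proximal gene's UAG stop.  This module reproduces the
downstream computations on such read tables:

* read filtering (reject variable regions with an in-frame stop, keep
  only those with an in-frame efficient start codon);
* abundance-weighted mean clone-window dG_fold per expression bin, with
  a seeded bootstrap confidence interval;
* theoretical dG_fold distributions of random clone libraries under
  three sampling schemes, plus the closed-form acceptance probability
  of the in-frame filter.

The clone window is the 37-mer starting +9 nt from the first nucleotide
of the stop codon, which in the default plasmid context is exactly the
24-nt variable region plus the fixed 13-nt suffix AAGGGCGAGGAGC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fold_engine import EnergyEngine, clone_window_dg

__all__ = [
    "LibraryRead",
    "CloneContext",
    "VARIABLE_LEN",
    "LIB_SUFFIX",
    "STARTS",
    "STOPS",
    "filter_variable_reads",
    "read_library_table",
    "bin_weighted_dg",
    "filter_acceptance_probability",
    "simulate_library",
]

VARIABLE_LEN = 24
#: Fixed constant region immediately 3' of the variable region.
LIB_SUFFIX = "AAGGGCGAGGAGC"
STARTS = ("ATG", "GTG", "TTG")
STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class LibraryRead:
    variable_seq: str
    count: int
    bin_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")


@dataclass(frozen=True)
class CloneContext:
    """Fixed plasmid sequence around the variable region.

    ``upstream`` must end with the stop codon followed by the fixed
    spacer so that the clone window lands on variable + suffix; both
    flanks are configuration, not hard-coded biology.
    """

    upstream: str = "TGGCTCCGCTGCTGGTTCTGGCGAATAGACTAGT"
    downstream: str = LIB_SUFFIX + "TCTTTACTG"

    @property
    def stop_index(self) -> int:
        idx = self.upstream.rfind("TAG", 0, len(self.upstream) - 6)
        if idx < 0:
            raise ValueError("clone context upstream flank contains no TAG stop")
        return idx

    def embed(self, variable_seq: str) -> tuple[str, int]:
        return self.upstream + variable_seq.upper() + self.downstream, self.stop_index


def _in_frame_codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - 2, 3)]


def filter_variable_reads(
    reads: Iterable[LibraryRead],
    starts: Sequence[str] = STARTS,
    stops: Sequence[str] = STOPS,
) -> tuple[list[LibraryRead], list[tuple[LibraryRead, str]]]:
    """Partition reads into kept and (read, reason) rejects.

    A read is rejected if any in-frame codon of its variable region
    (offsets 0, 3, ..., 21; the frame of the downstream reporter ORF) is
    a stop codon, or if no in-frame codon is an efficient start codon.
    Filtering is idempotent: re-filtering kept reads changes nothing.
    """
    start_set, stop_set = set(starts), set(stops)
    kept: list[LibraryRead] = []
    rejected: list[tuple[LibraryRead, str]] = []
    for read in reads:
        seq = read.variable_seq.upper().replace("U", "T")
        if len(seq) != VARIABLE_LEN:
            rejected.append((read, "bad_length"))
            continue
        codons = _in_frame_codons(seq)
        if any(c in stop_set for c in codons):
            rejected.append((read, "internal_stop"))
            continue
        if not any(c in start_set for c in codons):
            rejected.append((read, "no_start"))
            continue
        kept.append(read)
    return kept, rejected


def read_library_table(path) -> list[LibraryRead]:
    """Read ``bin_id<TAB>variable_seq<TAB>count`` rows."""
    reads: list[LibraryRead] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            bin_id, seq, count = line.split("\t")[:3]
            reads.append(LibraryRead(seq, int(count), bin_id))
    return reads


def bin_weighted_dg(
    reads_in_bin: Sequence[LibraryRead],
    engine: EnergyEngine,
    ci_level: float = 0.99,
    n_boot: int = 10_000,
    seed: int = 0,
    context: CloneContext = CloneContext(),
    width: int = 37,
    offset: int = 9,
) -> tuple[float, float, float]:
    """Count-weighted mean clone dG_fold of a bin with a bootstrap CI.

    Each unique read is folded once in its fixed plasmid context; the
    mean is weighted by read count.  The confidence interval is a
    seeded percentile bootstrap resampling reads with probability
    proportional to count.
    """
    if not reads_in_bin:
        raise ValueError("empty bin")
    dgs = np.empty(len(reads_in_bin))
    counts = np.empty(len(reads_in_bin))
    for i, read in enumerate(reads_in_bin):
        full, stop_idx = context.embed(read.variable_seq)
        dgs[i] = clone_window_dg(engine, full, stop_idx, width=width, offset=offset)
        counts[i] = read.count
    total = counts.sum()
    mean = float(np.average(dgs, weights=counts))
    if len(reads_in_bin) == 1:
        return mean, mean, mean
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(int(total), counts / total, size=n_boot)
    boot_means = draws @ dgs / total
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    return mean, float(lo), float(hi)


def _codon_prob(codons: Sequence[str], composition: Mapping[str, float]) -> float:
    return sum(
        composition[c[0]] * composition[c[1]] * composition[c[2]] for c in codons
    )


def filter_acceptance_probability(
    n_codons: int,
    composition: Mapping[str, float] | None = None,
    starts: Sequence[str] = STARTS,
    stops: Sequence[str] = STOPS,
) -> float:
    """Exact probability a random sequence passes the in-frame filter.

    In-frame codons of an i.i.d. sequence are independent, so
    P(no stop and >= 1 start) = (1-ps)^k - (1-ps-pa)^k with ps, pa the
    per-codon stop/start probabilities and k the number of in-frame
    codons.
    """
    comp = composition or {b: 0.25 for b in "ACGT"}
    ps = _codon_prob(stops, comp)
    pa = _codon_prob(starts, comp)
    return (1.0 - ps) ** n_codons - (1.0 - ps - pa) ** n_codons


_SCHEMES = ("constrained37", "lib24plus13", "unconstrained")


def simulate_library(
    scheme: str,
    n: int,
    seed: int,
    engine: EnergyEngine,
    starts: Sequence[str] = STARTS,
    stops: Sequence[str] = STOPS,
) -> dict:
    """Theoretical dG_fold distribution of ``n`` random library clones.

    Draws ``n`` sequences of uniform nucleotide composition and applies
    the scheme's filter:

    * ``constrained37`` — 37-mers kept when an in-frame start codon is
      present and no in-frame stop codon occurs;
    * ``lib24plus13`` — 24-mers filtered the same way, then concatenated
      with the fixed suffix AAGGGCGAGGAGC (total 37 nt), mimicking the
      real library design;
    * ``unconstrained`` — unfiltered 37-mers.

    Returns the accepted sequences' energies plus summary statistics and
    the empirical acceptance rate.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {_SCHEMES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    length = 24 if scheme == "lib24plus13" else 37
    bases = np.array(list("ACGT"))
    draws = bases[rng.integers(0, 4, size=(n, length))]
    start_set, stop_set = set(starts), set(stops)

    seqs: list[str] = []
    for row in draws:
        s = "".join(row)
        if scheme != "unconstrained":
            codons = _in_frame_codons(s)
            if any(c in stop_set for c in codons):
                continue
            if not any(c in start_set for c in codons):
                continue
        seqs.append(s + LIB_SUFFIX if scheme == "lib24plus13" else s)
    dgs = np.array([engine.fold(s) for s in seqs])
    summary = {}
    if dgs.size:
        summary = {
            "mean": float(dgs.mean()),
            "q25": float(np.quantile(dgs, 0.25)),
            "median": float(np.quantile(dgs, 0.5)),
            "q75": float(np.quantile(dgs, 0.75)),
        }
    return {
        "scheme": scheme,
        "n_sampled": n,
        "n_accepted": len(seqs),
        "acceptance_rate": len(seqs) / n,
        "sequences": seqs,
        "dg": dgs,
        "summary": summary,
    }
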