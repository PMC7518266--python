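"""Minimum-free-energy folding of short RNA windows.

Two engines implement the same contract (``fold(seq) -> dG`` in
kcal/mol per window, deterministic, dG <= 0 with 0 meaning no paired
structure):

* :class:`ViennaEngine` — Turner-parameter MFE via the ViennaRNA Python
  bindings at default settings (37 C).  This is the production engine;
  all absolute energy thresholds in the RTS caller are calibrated
  against it.
* :class:`NussinovEngine` — a dependency-free dynamic-programming
  base-pair maximiser with fixed per-pair energies.  It satisfies the
  same contracts and keeps the pipeline importable where the ViennaRNA
  bindings are absent, but its absolute energies are not comparable to
  Turner-parameter values; results always record which engine produced
  them.

DNA input is transparently transcribed (T -> U).  Windows are folded in
isolation: flanking sequence outside a window can never change that
window's energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genome_io import GeneModel, GenomeSequence, sense_window

__all__ = [
    "EngineUnavailableError",
    "EnergyEngine",
    "ViennaEngine",
    "NussinovEngine",
    "get_engine",
    "mfe",
    "WindowedEnergySeries",
    "window_scan",
    "clone_window_dg",
]


class EngineUnavailableError(RuntimeError):
    """Raised when a requested folding engine cannot be constructed."""


class EnergyEngine:
    """Contract: deterministic ``fold(seq) -> dG <= 0`` for a fixed parameter set."""

    name: str = "abstract"
    parameter_set: str = ""

    _CACHE_MAX = 1 << 20

    def __init__(self) -> None:
        self._cache: dict[str, float] = {}

    def _fold_uncached(self, seq: str) -> float:
        raise NotImplementedError

    def fold(self, seq: str) -> float:
        if not seq:
            raise ValueError("cannot fold an empty sequence")
        rna = seq.upper().replace("T", "U")
        hit = self._cache.get(rna)
        if hit is not None:
            return hit
        dg = self._fold_uncached(rna)
        dg = min(dg, 0.0) + 0.0  # open chain is always available at 0
        if len(self._cache) < self._CACHE_MAX:
            self._cache[rna] = dg
        return dg


class ViennaEngine(EnergyEngine):
    """Turner-parameter MFE via the ViennaRNA bindings, default settings."""

    def __init__(self) -> None:
        super().__init__()
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - depends on environment
            raise EngineUnavailableError(
                "ViennaRNA Python bindings (module 'RNA') are not importable"
            ) from exc
        self._RNA = RNA
        self.name = "vienna"
        self.parameter_set = f"ViennaRNA {RNA.__version__} default"

    def _fold_uncached(self, seq: str) -> float:
        _, dg = self._RNA.fold(seq)
        return float(dg)


# Fixed per-pair energies (kcal/mol) for the fallback maximiser; chosen to
# rank pair types like nearest-neighbour stacks do (GC > AU > GU) without
# claiming Turner-scale accuracy.
_PAIR_ENERGY: Mapping[frozenset[str], float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}
_MIN_LOOP = 3


class NussinovEngine(EnergyEngine):
    """Base-pair maximisation with fixed pair energies and a 3-nt minimum loop."""

    def __init__(self) -> None:
        super().__init__()
        self.name = "fallback"
        self.parameter_set = "nussinov GC=-3 AU=-2 GU=-1 minloop=3"

    def _fold_uncached(self, seq: str) -> float:
        n = len(seq)
        pe = np.zeros((n, n))
        for i in range(n):
            for j in range(i + _MIN_LOOP + 1, n):
                pe[i, j] = _PAIR_ENERGY.get(frozenset(seq[i] + seq[j]), 0.0)
        E = np.zeros((n + 1, n + 1))
        for span in range(_MIN_LOOP + 1, n):
            for i in range(n - span):
                j = i + span
                best = E[i][j - 1 + 1]  # j unpaired; E indexed [i, j+1) half-open
                for k in range(i, j - _MIN_LOOP):
                    if pe[k, j] < 0.0:
                        cand = E[i][k] + pe[k, j] + E[k + 1][j]
                        if cand < best:
                            best = cand
                E[i][j + 1] = best
        return float(E[0][n])


def get_engine(name: str | None = None) -> EnergyEngine:
    """Construct an engine: 'vienna', 'fallback', or best-available (None)."""
    if name in (None, "auto"):
        try:
            return ViennaEngine()
        except EngineUnavailableError:
            return NussinovEngine()
    if name == "vienna":
        return ViennaEngine()
    if name == "fallback":
        return NussinovEngine()
    raise ValueError(f"unknown engine {name!r}")


def mfe(engine: EnergyEngine, seq: str) -> float:
    """MFE of ``seq`` in kcal/mol; T is treated as U, N folds unpaired."""
    return engine.fold(seq)


@dataclass
class WindowedEnergySeries:
    """Per-gene vector of window opening positions and native window energies."""

    gene_id: str
    width: int
    positions: np.ndarray  # strictly increasing opening positions (axis coords)
    dg: np.ndarray  # kcal/mol per window, elementwise <= 0
    engine: str

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.dg = np.asarray(self.dg, dtype=float)
        if self.positions.shape != self.dg.shape:
            raise ValueError("positions and dg must have identical shape")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.positions.tolist(), self.dg.tolist()))


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq)


def window_scan(
    engine: EnergyEngine,
    gene: GeneModel,
    contigs: Mapping[str, GenomeSequence],
    width: int = 40,
    p_min: int = -100,
    p_max: int = 100,
    max_n_fraction: float = 0.1,
) -> WindowedEnergySeries:
    """Fold every ``width``-nt window opening at positions ``p_min..p_max``.

    Windows that run off the contig, or in which more than
    ``max_n_fraction`` of bases are N, are omitted (never padded).
    """
    positions: list[int] = []
    dgs: list[float] = []
    for p in range(p_min, p_max + 1):
        seq = sense_window(gene, contigs, p, width)
        if seq is None or _n_fraction(seq) > max_n_fraction:
            continue
        positions.append(p)
        dgs.append(engine.fold(seq))
    return WindowedEnergySeries(
        gene_id=gene.gene_id,
        width=width,
        positions=np.array(positions, dtype=int),
        dg=np.array(dgs, dtype=float),
        engine=engine.name,
    )


def clone_window_dg(
    engine: EnergyEngine,
    operon_seq: str,
    stop_first_nt_index: int,
    width: int = 37,
    offset: int = 9,
) -> float:
    """dG_fold of the single clone window downstream of a UAG stop.

    The window starts ``offset`` nt after the *first* nucleotide of the
    stop codon (default +9, placing it just outside the footprint of a
    terminating ribosome) and spans ``width`` nt (default 37; sensible
    values lie in 30-50).
    """
    seq = operon_seq.upper().replace("U", "T")
    stop = seq[stop_first_nt_index : stop_first_nt_index + 3]
    if stop != "TAG":
        raise ValueError(f"expected a TAG/UAG stop at index {stop_first_nt_index}, found {stop!r}")
    s = stop_first_nt_index + offset
    e = s + width
    if e > len(seq):
        raise ValueError(
            f"clone window [{s},{e}) exceeds sequence length {len(seq)}"
        )
    return engine.fold(seq[s:e])
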