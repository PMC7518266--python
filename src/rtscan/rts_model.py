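"""Rule-based caller for ribosome termination structures (RTS).

A gene is deemed followed by an RTS when three conditions hold:

1. *Topology* — re-initiation is not expected to be useful: the next
   gene (in this gene's reading direction) is at least
   ``min_intergenic`` nt away, or lies on the opposite strand, or does
   not exist (contig-terminal genes are treated like opposite-strand
   neighbours).
2. *Run* — at least ``min_run`` consecutive windows opening within
   ``[open_min, open_max]`` have strictly negative dLFE (native folding
   stronger than the composition null).
3. *Depth* — within the selected run, the native window energy reaches
   ``dg_threshold`` (default -6 kcal/mol per 40-nt window) at least
   once.

When several qualifying runs exist the longest is selected, 5'-most on
ties; the depth condition is evaluated on that run only.  All default
parameter values are deliberately simple cutoffs; the call is robust to
moderate changes in each of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fold_engine import WindowedEnergySeries
from .genome_io import GenePairTopology
from .landscape import DlfeProfile

__all__ = ["RtsModelConfig", "RtsCall", "call_rts", "rts_fraction"]


@dataclass(frozen=True)
class RtsModelConfig:
    min_intergenic: int = 25
    open_min: int = -10
    open_max: int = 20
    min_run: int = 5
    dg_threshold: float = -6.0
    width: int = 40

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.open_max < self.open_min:
            raise ValueError("empty opening range")


@dataclass
class RtsCall:
    gene_id: str
    callable: bool
    present: bool
    cond_topology: bool
    cond_run: bool
    cond_depth: bool
    run_start: int | None = None
    run_end: int | None = None  # inclusive opening position of the run's last window
    min_native_dg_in_run: float | None = None
    reason: str | None = None


def _negative_runs(positions: np.ndarray, dlfe: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with dlfe < 0, as (start, end) inclusive."""
    runs: list[tuple[int, int]] = []
    start = None
    prev = None
    for p, v in zip(positions.tolist(), dlfe.tolist()):
        neg = v < 0.0
        if neg and start is not None and prev is not None and p == prev + 1:
            prev = p
            continue
        if start is not None and prev is not None:
            runs.append((start, prev))
            start = prev = None
        if neg:
            start = prev = p
    if start is not None and prev is not None:
        runs.append((start, prev))
    return runs


def call_rts(
    profile: DlfeProfile,
    native: WindowedEnergySeries,
    topology: GenePairTopology,
    config: RtsModelConfig = RtsModelConfig(),
) -> RtsCall:
    """Evaluate the three RTS conditions for one gene."""
    lo, hi = config.open_min, config.open_max
    wanted = set(range(lo, hi + 1))
    have_prof = set(profile.positions.tolist())
    have_nat = set(native.positions.tolist())
    if not wanted <= have_prof or not wanted <= have_nat:
        return RtsCall(
            gene_id=profile.gene_id,
            callable=False,
            present=False,
            cond_topology=False,
            cond_run=False,
            cond_depth=False,
            reason="missing_windows_in_open_range",
        )

    if not topology.downstream_exists:
        cond_topology = True
    else:
        assert topology.intergenic_distance is not None
        cond_topology = (
            (not topology.same_strand)
            or topology.intergenic_distance >= config.min_intergenic
        )

    mask = (profile.positions >= lo) & (profile.positions <= hi)
    positions = profile.positions[mask]
    dlfe = profile.dlfe[mask]
    runs = [r for r in _negative_runs(positions, dlfe) if r[1] - r[0] + 1 >= config.min_run]
    cond_run = bool(runs)

    run_start = run_end = None
    min_native = None
    cond_depth = False
    if runs:
        run_start, run_end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        nat_map = native.as_dict()
        min_native = min(nat_map[p] for p in range(run_start, run_end + 1))
        cond_depth = min_native <= config.dg_threshold

    present = cond_topology and cond_run and cond_depth
    return RtsCall(
        gene_id=profile.gene_id,
        callable=True,
        present=present,
        cond_topology=cond_topology,
        cond_run=cond_run,
        cond_depth=cond_depth,
        run_start=run_start,
        run_end=run_end,
        min_native_dg_in_run=min_native,
    )


def rts_fraction(calls: list[RtsCall]) -> tuple[float, int, int]:
    """Fraction of callable genes with an RTS, plus (n_present, n_callable)."""
    callable_calls = [c for c in calls if c.callable]
    if not callable_calls:
        raise ValueError("no callable genes")
    n_present = sum(c.present for c in callable_calls)
    return n_present / len(callable_calls), n_present, len(callable_calls)
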