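"""Local folding-energy bias (dLFE) profiles and landscapes.

For every gene, the native minimum free energy of each 40-nt window
around the stop codon is compared with the mean energy of the same
window extracted from R composition-preserving randomized genomes
(see :mod:`rtscan.shuffle_null`):

    dLFE(p) = dG_native(p) - (1/R) * sum_r dG_randomized_r(p)

Negative dLFE means the native sequence folds more stably than its
composition alone explains, i.e. direct selection for structure.
Per-gene profiles are aggregated into per-position landscapes (mean,
median, SD, quartiles), optionally stratified by any gene -> label map
(intergenic-distance class, strand class, operon position, abundance
quantile, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fold_engine import EnergyEngine, WindowedEnergySeries, window_scan
from .genome_io import GeneModel, GenomeSequence
from .shuffle_null import RandomizedGenome

__all__ = [
    "DlfeProfile",
    "gene_dlfe",
    "aggregate",
    "native_landscape",
    "localize_minimum",
    "shift_convention",
]


@dataclass
class DlfeProfile:
    """Per-gene dLFE values with the replicate energies behind them."""

    gene_id: str
    positions: np.ndarray  # opening positions on the stop-relative axis
    native_dg: np.ndarray
    rand_dg: np.ndarray  # shape (R, P)
    R: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.native_dg = np.asarray(self.native_dg, dtype=float)
        self.rand_dg = np.asarray(self.rand_dg, dtype=float)
        if self.rand_dg.shape != (self.R, len(self.positions)):
            raise ValueError("rand_dg must have shape (R, n_positions)")

    @property
    def dlfe(self) -> np.ndarray:
        return self.native_dg - self.rand_dg.mean(axis=0)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.positions.tolist(), self.dlfe.tolist()))


def gene_dlfe(
    gene: GeneModel,
    contigs: Mapping[str, GenomeSequence],
    randomized: Sequence[RandomizedGenome],
    engine: EnergyEngine,
    width: int = 40,
    p_min: int = -100,
    p_max: int = 100,
) -> DlfeProfile:
    """Compute one gene's dLFE profile against a set of randomized genomes.

    A position is reported only where the native window and the window
    in *every* replicate are available (pairwise-complete deletion).
    """
    if not randomized:
        raise ValueError("at least one randomized genome is required")
    native = window_scan(engine, gene, contigs, width=width, p_min=p_min, p_max=p_max)
    series = [
        window_scan(engine, gene, rg.contigs, width=width, p_min=p_min, p_max=p_max)
        for rg in randomized
    ]
    common = set(native.positions.tolist())
    for s in series:
        common &= set(s.positions.tolist())
    positions = np.array(sorted(common), dtype=int)
    nat_map = native.as_dict()
    native_dg = np.array([nat_map[p] for p in positions])
    rand_dg = np.empty((len(series), len(positions)))
    for r, s in enumerate(series):
        m = s.as_dict()
        rand_dg[r] = [m[p] for p in positions]
    return DlfeProfile(
        gene_id=gene.gene_id,
        positions=positions,
        native_dg=native_dg,
        rand_dg=rand_dg,
        R=len(series),
    )


def _summarize(df: pd.DataFrame) -> pd.DataFrame:
    grouped = df.groupby(["group", "position"])["value"]
    out = grouped.agg(
        n="size",
        mean="mean",
        median="median",
        sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
        q25=lambda v: v.quantile(0.25),
        q75=lambda v: v.quantile(0.75),
    ).reset_index()
    return out.sort_values(["group", "position"]).reset_index(drop=True)


def aggregate(
    profiles: Iterable[DlfeProfile],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-position landscape summary of dLFE profiles, per group.

    ``grouping`` maps gene_id -> label; genes missing from the map fall
    into group "all".  Returns a tidy frame with columns
    group, position, n, mean, median, sd, q25, q75.
    """
    rows = []
    for prof in profiles:
        label = "all" if grouping is None else grouping.get(prof.gene_id, "all")
        rows.append(
            pd.DataFrame(
                {
                    "group": label,
                    "position": prof.positions,
                    "value": prof.dlfe,
                }
            )
        )
    if not rows:
        raise ValueError("no profiles to aggregate")
    return _summarize(pd.concat(rows, ignore_index=True))


def native_landscape(
    series: Iterable[WindowedEnergySeries],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-position summary of native window energies (no null model)."""
    rows = []
    for s in series:
        label = "all" if grouping is None else grouping.get(s.gene_id, "all")
        rows.append(pd.DataFrame({"group": label, "position": s.positions, "value": s.dg}))
    if not rows:
        raise ValueError("no series to aggregate")
    return _summarize(pd.concat(rows, ignore_index=True))


def shift_convention(
    summary: pd.DataFrame, width: int = 40, to: str = "center"
) -> pd.DataFrame:
    """Relabel landscape positions between window conventions.

    The default convention indexes a window by its 5' *opening*
    position; some presentations index it by its *center* instead.  The
    switch only relabels the axis (center = opening + width//2); it
    never changes which windows are deep, so detection results are
    convention-independent.
    """
    if to not in ("center", "open"):
        raise ValueError("convention must be 'center' or 'open'")
    out = summary.copy()
    shift = width // 2 if to == "center" else -(width // 2)
    out["position"] = out["position"] + shift
    return out


def localize_minimum(
    summary: pd.DataFrame, group: str = "all", depth_fraction: float = 0.9
) -> dict:
    """Locate a structured element from a landscape's deep plateau.

    A structural element shorter than the folding window produces a
    *plateau* of deep windows rather than a single deep point: every
    window that fully contains the element is near-equally stable, so
    the raw argmin sits roughly where the window is centred on the
    element — offset from the element's 5' end by about
    ``(element_len - width) / 2``.  The element's 5' end itself is the
    3'-most opening position still inside the plateau (the last window
    that fully contains the element), which this function estimates as
    the largest position whose mean is at least ``depth_fraction`` of
    the way down to the global minimum.

    Returns a dict with ``argmin`` (raw deepest opening position),
    ``depth``, ``plateau_start``/``plateau_end`` (opening positions),
    and ``element_offset`` (= plateau_end, the recovered 5'-end
    position; None when the landscape has no negative minimum).
    """
    sub = summary[summary["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present in summary")
    imin = sub["mean"].idxmin()
    depth = float(sub.loc[imin, "mean"])
    argmin = int(sub.loc[imin, "position"])
    if depth >= 0:
        return {
            "argmin": argmin,
            "depth": depth,
            "plateau_start": None,
            "plateau_end": None,
            "element_offset": None,
        }
    deep = sub[sub["mean"] <= depth_fraction * depth]
    return {
        "argmin": argmin,
        "depth": depth,
        "plateau_start": int(deep["position"].min()),
        "plateau_end": int(deep["position"].max()),
        "element_offset": int(deep["position"].max()),
    }


def write_landscape_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False, float_format="%.4f")


def profiles_matrix(profiles: Iterable[DlfeProfile]) -> pd.DataFrame:
    """Genes x positions matrix of dLFE values (NaN where unavailable)."""
    return pd.DataFrame(
        {p.gene_id: pd.Series(p.dlfe, index=p.positions) for p in profiles}
    ).T.sort_index(axis=1)
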