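"""Joins between DMR tiles, expression, and nuclear-architecture data:
DEG filtering/intersection, quadrant-count-ratio concordance, LAD
redistribution with cross-cell-type conservation, DEG-to-LAD distances,
and nearest-neighbor proximity resampling."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, ORResult, _make_or_result, gene_body_track
from .intervals import (
    GenomicInterval,
    IntervalTrack,
    closest,
    intersect,
    merge_within,
    subtract,
)

__all__ = [
    "DEGRecord",
    "QCRResult",
    "LADRedistribution",
    "ProximityResult",
    "read_degs",
    "filter_degs",
    "filter_and_intersect_degs",
    "qcr",
    "direction_concordance",
    "lad_redistribute",
    "conserve_across_celltypes",
    "deg_lad_distance",
    "hotspot_proximity",
]

Site = Tuple[str, int]


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2_fc: float
    p_value: float
    fdr: float


@dataclass(frozen=True)
class QCRResult:
    """Quadrant counts over the signed (x, y) plane and their ratio.

    Quadrants: I = (+,+), II = (-,+), III = (-,-), IV = (+,-).
    qcr = (nI + nIII - nII - nIV) / n_total. Points on an axis are
    excluded from all counts and from n_total.
    """

    n_q1: int
    n_q2: int
    n_q3: int
    n_q4: int
    n_excluded: int = 0

    @property
    def n_total(self) -> int:
        return self.n_q1 + self.n_q2 + self.n_q3 + self.n_q4

    @property
    def qcr(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return (self.n_q1 + self.n_q3 - self.n_q2 - self.n_q4) / self.n_total


@dataclass
class LADRedistribution:
    """Gain/Loss/Maintenance-of-LAD interval tracks."""

    gol: IntervalTrack
    lol: IntervalTrack
    mol: IntervalTrack


@dataclass
class ProximityResult:
    """Nearest-neighbor distances for observed vs matched-random CpG sets."""

    observed_distances: np.ndarray
    background_distances: np.ndarray
    test: str  # {'wilcoxon_rank_sum', 'fisher_binned'}
    p_value: Optional[float]
    bin_edges: Optional[List[float]]
    bin_p_values: Optional[List[float]]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "test": self.test,
                "p_value": self.p_value,
                "bin_edges": self.bin_edges,
                "bin_p_values": self.bin_p_values,
                "seed": self.seed,
                "n_observed": int(len(self.observed_distances)),
                "n_background": int(len(self.background_distances)),
                "observed_median": float(np.median(self.observed_distances)),
                "background_median": float(np.median(self.background_distances)),
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# DEGs


def read_degs(
    path,
    gene_col: str = "gene",
    fc_col: str = "log2_fc",
    p_col: str = "p_value",
    fdr_col: str = "fdr",
) -> List[DEGRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in (gene_col, fc_col, p_col, fdr_col):
        if col not in df.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    return [
        DEGRecord(str(r[gene_col]), float(r[fc_col]), float(r[p_col]), float(r[fdr_col]))
        for _, r in df.iterrows()
    ]


def filter_degs(
    degs: Sequence[DEGRecord], fdr_max: Optional[float] = None, p_max: Optional[float] = None
) -> List[DEGRecord]:
    """Apply the source-specific filter: fdr <= 0.05 for the fibroblast set,
    p <= 0.05 for the cardiac set."""
    out = list(degs)
    if fdr_max is not None:
        out = [d for d in out if d.fdr <= fdr_max]
    if p_max is not None:
        out = [d for d in out if d.p_value <= p_max]
    return out


def filter_and_intersect_degs(
    fib: Sequence[DEGRecord], cardiac: Sequence[DEGRecord]
) -> Set[str]:
    """Genes present in both pre-filtered DEG lists (conserved DEGs)."""
    return {d.gene_id for d in fib} & {d.gene_id for d in cardiac}


# ---------------------------------------------------------------------------
# Quadrant count ratio


def qcr(points: Sequence[Tuple[float, float]]) -> QCRResult:
    """Quadrant count ratio of signed points; axis points are excluded."""
    if len(points) == 0:
        raise ValueError("qcr requires at least one point")
    n = [0, 0, 0, 0]
    excluded = 0
    for x, y in points:
        if x == 0 or y == 0:
            excluded += 1
        elif x > 0 and y > 0:
            n[0] += 1
        elif x < 0 and y > 0:
            n[1] += 1
        elif x < 0 and y < 0:
            n[2] += 1
        else:
            n[3] += 1
    return QCRResult(n[0], n[1], n[2], n[3], excluded)


def direction_concordance(
    tiles: Sequence,
    gene_assoc: Dict[object, Set[str]],
    degs: Sequence[DEGRecord],
) -> Tuple[pd.DataFrame, QCRResult, float]:
    """Pair each tile with its associated DEGs and compare directions.

    One point per (tile, gene) pair: (tile mean_diff, DEG log2_fc).
    Returns the pair table, the QCR, and the fraction of pairs in the
    inverse quadrants (+/- and -/+).
    """
    deg_by_id = {d.gene_id: d for d in degs}
    rows = []
    for t in tiles:
        for gene_id in sorted(gene_assoc.get(t, ())):
            d = deg_by_id.get(gene_id)
            if d is None:
                continue
            rows.append(
                {
                    "chrom": t.chrom,
                    "start": t.start,
                    "end": t.end,
                    "mean_diff": t.mean_diff,
                    "gene": gene_id,
                    "log2_fc": d.log2_fc,
                }
            )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_diff", "gene", "log2_fc"])
    if len(table) == 0:
        return table, QCRResult(0, 0, 0, 0), float("nan")
    result = qcr(list(zip(table["mean_diff"], table["log2_fc"])))
    frac_inverse = (
        (result.n_q2 + result.n_q4) / result.n_total if result.n_total else float("nan")
    )
    return table, result, frac_inverse


# ---------------------------------------------------------------------------
# LAD redistribution


def lad_redistribute(dcm_lads: IntervalTrack, ctrl_lads: IntervalTrack) -> LADRedistribution:
    """GoL = disease minus control; LoL = control minus disease;
    MoL = intersection of the two."""
    gol = subtract(dcm_lads, ctrl_lads)
    lol = subtract(ctrl_lads, dcm_lads)
    mol = intersect(dcm_lads, ctrl_lads)
    gol.name, lol.name, mol.name = "GoL", "LoL", "MoL"
    return LADRedistribution(gol, lol, mol)


def conserve_across_celltypes(
    redist: LADRedistribution, fib_lads: IntervalTrack
) -> LADRedistribution:
    """Keep GoL intervals with NO fibroblast-LAD overlap; keep LoL and MoL
    intervals WITH >= 1 bp fibroblast-LAD overlap."""

    def no_overlap(track: IntervalTrack) -> IntervalTrack:
        return IntervalTrack(
            [iv for iv in track if not fib_lads.any_overlap(iv.chrom, iv.start, iv.end)],
            name=track.name,
        )

    def with_overlap(track: IntervalTrack) -> IntervalTrack:
        return IntervalTrack(
            [iv for iv in track if fib_lads.any_overlap(iv.chrom, iv.start, iv.end)],
            name=track.name,
        )

    return LADRedistribution(
        gol=no_overlap(redist.gol),
        lol=with_overlap(redist.lol),
        mol=with_overlap(redist.mol),
    )


def deg_lad_distance(
    deg_genes: Sequence[GeneModel],
    redist: LADRedistribution,
    background_genes: Optional[Sequence[GeneModel]] = None,
    window: int = 2_000_000,
) -> Tuple[pd.DataFrame, Optional[ORResult]]:
    """Per-gene LAD category and nearest redistributed-LAD distance.

    Category is within_GoL/within_LoL/within_MoL when the gene body
    overlaps the corresponding track (checked in that order) else distal.
    Distance is the gap to the nearest interval over all three tracks.
    When ``background_genes`` is given, also returns a 2x2 OR comparing
    within-``window`` membership of the focal genes vs the background
    (genes not in the focal set).
    """
    all_lads = IntervalTrack(
        list(redist.gol) + list(redist.lol) + list(redist.mol), name="redistributed"
    )
    if len(all_lads) == 0:
        raise ValueError("empty LAD tracks")

    def gene_row(g: GeneModel) -> Dict[str, object]:
        if redist.gol.any_overlap(g.chrom, g.tx_start, g.tx_end):
            cat = "within_GoL"
        elif redist.lol.any_overlap(g.chrom, g.tx_start, g.tx_end):
            cat = "within_LoL"
        elif redist.mol.any_overlap(g.chrom, g.tx_start, g.tx_end):
            cat = "within_MoL"
        else:
            cat = "distal"
        body = IntervalTrack([GenomicInterval(g.chrom, g.tx_start, g.tx_end)])
        (_, _, dist), = closest(body, all_lads)
        return {"gene": g.gene_id, "category": cat, "distance": dist}

    table = pd.DataFrame([gene_row(g) for g in deg_genes])

    or_result = None
    if background_genes is not None:
        focal_ids = {g.gene_id for g in deg_genes}
        bg = [g for g in background_genes if g.gene_id not in focal_ids]
        bg_table = pd.DataFrame([gene_row(g) for g in bg]) if bg else pd.DataFrame(columns=["distance"])

        def within(t: pd.DataFrame) -> int:
            if len(t) == 0:
                return 0
            d = t["distance"]
            return int(((d >= 0) & (d <= window)).sum())

        a = within(table)
        b = len(table) - a
        c = within(bg_table)
        d = len(bg_table) - c
        or_result = _make_or_result(f"within_{window}bp_of_redistributed_LAD", a, b, c, d)
    return table, or_result


# ---------------------------------------------------------------------------
# Hotspot proximity


def _nearest_distances(query: Sequence[Site], targets: Sequence[Site]) -> np.ndarray:
    """Distance (bp) from each query site to the nearest target site.

    Sites on chromosomes absent from the target set are dropped.
    """
    by_chrom: Dict[str, List[int]] = {}
    for c, p in targets:
        by_chrom.setdefault(c, []).append(p)
    arrays = {c: np.array(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}
    out: List[int] = []
    for c, p in query:
        arr = arrays.get(c)
        if arr is None:
            continue
        i = int(np.searchsorted(arr, p))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                d = abs(int(arr[j]) - p)
                best = d if best is None else min(best, d)
        out.append(best)
    return np.array(out, dtype=np.int64)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small tie-free samples, else the
    tie-corrected normal approximation."""
    method = "exact" if (len(x) <= 50 and len(y) <= 50 and
                         len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def hotspot_proximity(
    query_cpgs: Sequence[Site],
    target_cpgs: Sequence[Site],
    target_background: Sequence[Site],
    mode: str = "density",
    bins: Optional[Sequence[float]] = None,
    seed: int = 0,
    n_draws: int = 1,
) -> ProximityResult:
    """Nearest-neighbor proximity of one CpG category to another, against a
    matched-size random background.

    observed = per query CpG, distance to the nearest target CpG.
    background = the same computation against ``|target_cpgs|`` sites drawn
    uniformly without replacement from ``target_background`` (seeded; with
    ``n_draws > 1`` the draws are concatenated).

    mode='density'  -> Wilcoxon rank-sum p on the two distance samples.
    mode='binned'   -> per distance bin, a 1-tailed (greater) Fisher's
                       exact test comparing observed vs background counts.
    """
    if mode not in ("density", "binned"):
        raise ValueError(f"unknown mode {mode!r}")
    query_cpgs = list(query_cpgs)
    target_cpgs = list(target_cpgs)
    target_background = list(target_background)
    if not query_cpgs or not target_cpgs:
        raise ValueError("query and target sets must be non-empty")
    if not set(target_cpgs) <= set(target_background):
        raise ValueError("target_cpgs must be a subset of target_background")
    if len(target_background) < len(target_cpgs):
        raise ValueError("background smaller than the target set")

    observed = _nearest_distances(query_cpgs, target_cpgs)

    rng = np.random.default_rng(seed)
    bg_parts = []
    ordered_bg = sorted(target_background)
    for _ in range(max(n_draws, 1)):
        idx = rng.choice(len(ordered_bg), size=len(target_cpgs), replace=False)
        sample = [ordered_bg[i] for i in idx]
        bg_parts.append(_nearest_distances(query_cpgs, sample))
    background = np.concatenate(bg_parts)

    if mode == "density":
        p = _rank_sum_p(observed, background)
        return ProximityResult(observed, background, "wilcoxon_rank_sum", p, None, None, seed)

    if bins is None:
        bins = [0, 1_000, 10_000, 100_000, 1_000_000, float("inf")]
    edges = list(bins)
    obs_counts, _ = np.histogram(observed, bins=edges)
    bg_counts, _ = np.histogram(background, bins=edges)
    n_obs, n_bg = len(observed), len(background)
    bin_ps = []
    for o, g in zip(obs_counts, bg_counts):
        _, p = stats.fisher_exact(
            [[int(o), int(n_obs - o)], [int(g), int(n_bg - g)]], alternative="greater"
        )
        bin_ps.append(float(p))
    return ProximityResult(
        observed, background, "fisher_binned", None,
        [float(e) for e in edges], bin_ps, seed,
    )
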