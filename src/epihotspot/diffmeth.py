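"""Differential methylation: DMCpG calling, DMR tiling, tile classification.

Sign convention: meth_diff = mean(patient percent) - mean(control percent);
negative means the patients are hypomethylated, positive hypermethylated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalTrack
from .methio import UnitedMatrix

__all__ = [
    "GroupDesign",
    "DMCpG",
    "DMRTile",
    "call_dmcpgs",
    "tile_dmrs",
    "classify_tiles",
    "classify_persistence",
    "tiles_to_track",
    "read_dmcpgs",
    "write_dmcpgs",
    "read_tiles",
    "write_tiles",
]


@dataclass(frozen=True)
class GroupDesign:
    """A two-group comparison: control sample ids vs patient sample ids."""

    label: str  # {'all', 'familyA', 'familyC'} by convention, free-form allowed
    control_ids: Tuple[str, ...]
    patient_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.control_ids or not self.patient_ids:
            raise ValueError("both groups must be non-empty")
        if set(self.control_ids) & set(self.patient_ids):
            raise ValueError("control and patient groups overlap")


@dataclass(frozen=True)
class DMCpG:
    """A CpG passing both the q-value and the effect-size cutoff."""

    chrom: str
    pos: int  # 1-based
    meth_diff: float  # percent points, patient - control
    p_value: float
    q_value: float


@dataclass(frozen=True)
class DMRTile:
    """A merged differential-methylation interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_dmcpgs: int
    mean_diff: float
    direction: str  # {'hyper', 'hypo'}
    category: str = "unclassified"  # {'shared','familyA_specific','familyC_specific','unclassified'}
    cell_type: str = "fibroblast"  # {'fibroblast', 'iPSC'}
    source: str = ""  # label of the run that produced the tile

    def __post_init__(self) -> None:
        if self.end - self.start < 100:
            raise ValueError(f"tile {self.chrom}:{self.start}-{self.end} shorter than 100 bp")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"invalid direction {self.direction!r}")
        if (self.mean_diff > 0) != (self.direction == "hyper"):
            raise ValueError("direction inconsistent with sign of mean_diff")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, name=self.category, score=self.mean_diff
        )


def _binom_ll(m: np.ndarray, u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel, with the 0*log(0) = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    mask = m > 0
    out[mask] += m[mask] * np.log(p[mask])
    mask = u > 0
    out[mask] += u[mask] * np.log(1.0 - p[mask])
    return out


def _lrt_pvalues(
    mp: np.ndarray, up: np.ndarray, mc: np.ndarray, uc: np.ndarray
) -> np.ndarray:
    """Likelihood-ratio test of a binomial GLM with a single group factor.

    With one binary covariate the group-wise MLE is the pooled group
    proportion, so the deviance difference has a closed form; the statistic
    is referred to chi-square with 1 df (the replicate-aware logistic
    regression test).
    """
    pp = mp / (mp + up)
    pc = mc / (mc + uc)
    pa = (mp + mc) / (mp + up + mc + uc)
    lrt = 2.0 * (
        _binom_ll(mp, up, pp)
        + _binom_ll(mc, uc, pc)
        - _binom_ll(mp + mc, up + uc, pa)
    )
    lrt = np.maximum(lrt, 0.0)
    return stats.chi2.sf(lrt, df=1)


def _fisher_pvalues(
    mp: np.ndarray, up: np.ndarray, mc: np.ndarray, uc: np.ndarray
) -> np.ndarray:
    pvals = np.empty(len(mp), dtype=float)
    for i in range(len(mp)):
        _, pvals[i] = stats.fisher_exact(
            [[mp[i], up[i]], [mc[i], uc[i]]], alternative="two-sided"
        )
    return pvals


def call_dmcpgs(
    matrix: UnitedMatrix,
    design: GroupDesign,
    diff_cutoff: float = 30.0,
    q_cutoff: float = 0.01,
    test: str = "lrt",
) -> List[DMCpG]:
    """Call differentially methylated CpGs between patients and controls.

    Per position, methylated/unmethylated counts are pooled within each
    group and tested (``test='lrt'``: binomial-GLM likelihood-ratio test,
    the replicated default; ``test='fisher'``: Fisher's exact on the pooled
    2x2, suited to 1-vs-1 designs). p-values are Benjamini-Hochberg
    corrected over all tested positions; records failing
    ``q <= q_cutoff`` or ``|meth_diff| >= diff_cutoff`` are dropped.
    """
    if test not in ("lrt", "fisher"):
        raise ValueError(f"unknown test {test!r}")
    for sid in design.control_ids + design.patient_ids:
        matrix.sample_index(sid)  # raises KeyError if absent
    if len(matrix.positions) == 0:
        return []
    jp = [matrix.sample_index(s) for s in design.patient_ids]
    jc = [matrix.sample_index(s) for s in design.control_ids]
    mp = matrix.n_meth[:, jp].sum(axis=1).astype(float)
    up = matrix.n_unmeth[:, jp].sum(axis=1).astype(float)
    mc = matrix.n_meth[:, jc].sum(axis=1).astype(float)
    uc = matrix.n_unmeth[:, jc].sum(axis=1).astype(float)
    if test == "lrt":
        pvals = _lrt_pvalues(mp, up, mc, uc)
    else:
        pvals = _fisher_pvalues(
            mp.astype(int), up.astype(int), mc.astype(int), uc.astype(int)
        )
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    pct = matrix.percent
    diff = pct[:, jp].mean(axis=1) - pct[:, jc].mean(axis=1)
    keep = (np.abs(diff) >= diff_cutoff) & (qvals <= q_cutoff)
    return [
        DMCpG(matrix.positions[i][0], matrix.positions[i][1],
              float(diff[i]), float(pvals[i]), float(qvals[i]))
        for i in np.nonzero(keep)[0]
    ]


def tile_dmrs(
    dmcpgs: Sequence[DMCpG],
    merge_gap: int = 500,
    min_size: int = 100,
    cell_type: str = "fibroblast",
    source: str = "",
) -> Tuple[List[DMRTile], int]:
    """Merge DMCpGs into DMR tiles.

    1. DMCpGs within ``merge_gap`` bp of each other on the same chromosome
       chain into one tile spanning the member sites (single linkage).
    2. Tiles whose members mix hyper and hypo signs are ambiguous and are
       removed (counted in the second return value).
    3. Tiles shorter than ``min_size`` are extended symmetrically to
       exactly ``min_size``: both sides grow by ceil(deficit/2), then one
       bp is trimmed from the right when the parity overshoots; the left
       edge is clipped at coordinate 0 with the remainder pushed right.
    4. ``mean_diff`` is the arithmetic mean of member diffs.
    """
    ordered = sorted(dmcpgs, key=lambda d: (d.chrom, d.pos))
    clusters: List[List[DMCpG]] = []
    for d in ordered:
        if (
            clusters
            and clusters[-1][-1].chrom == d.chrom
            and d.pos - clusters[-1][-1].pos <= merge_gap
        ):
            clusters[-1].append(d)
        else:
            clusters.append([d])

    tiles: List[DMRTile] = []
    n_ambiguous = 0
    for members in clusters:
        signs = {d.meth_diff > 0 for d in members}
        if len(signs) != 1:
            n_ambiguous += 1
            continue
        # span of member sites, 0-based half-open
        start = members[0].pos - 1
        end = members[-1].pos
        deficit = min_size - (end - start)
        if deficit > 0:
            grow = math.ceil(deficit / 2)
            start -= grow
            end += grow
            if end - start > min_size:
                end -= (end - start) - min_size
            if start < 0:
                end -= start  # push the clipped remainder to the right
                start = 0
        mean_diff = float(np.mean([d.meth_diff for d in members]))
        tiles.append(
            DMRTile(
                chrom=members[0].chrom,
                start=start,
                end=end,
                n_dmcpgs=len(members),
                mean_diff=mean_diff,
                direction="hyper" if mean_diff > 0 else "hypo",
                cell_type=cell_type,
                source=source,
            )
        )
    return tiles, n_ambiguous


def tiles_to_track(tiles: Iterable[DMRTile], name: str = "dmrs") -> IntervalTrack:
    return IntervalTrack([t.to_interval() for t in tiles], name=name)


def _overlap_bp(tile: DMRTile, others: IntervalTrack) -> int:
    return sum(
        min(tile.end, iv.end) - max(tile.start, iv.start)
        for iv in others.overlapping(tile.chrom, tile.start, tile.end)
    )


def classify_tiles(
    run_all: Sequence[DMRTile],
    run_A: Sequence[DMRTile],
    run_C: Sequence[DMRTile],
    matrix_A: UnitedMatrix,
    matrix_C: UnitedMatrix,
    min_overlap_bp: int = 1,
) -> List[DMRTile]:
    """Label tiles as shared or family-specific.

    A tile is eligible only if its span contains at least one united
    position in BOTH family matrices. Membership "found in" a run means
    >= ``min_overlap_bp`` bp of overlap with any tile of that run. A tile
    found in exactly one family run (with or without the all-samples run)
    is family-specific; found in both family runs, in all three, or only
    in the all-samples run, it is shared. Ineligible tiles are dropped.
    """
    cell_types = {t.cell_type for t in (*run_all, *run_A, *run_C)}
    if len(cell_types) > 1:
        raise ValueError(f"tile sets mix cell types: {sorted(cell_types)}")
    track_all = tiles_to_track(run_all)
    track_A = tiles_to_track(run_A)
    track_C = tiles_to_track(run_C)

    out: List[DMRTile] = []
    for tile in (*run_all, *run_A, *run_C):
        if matrix_A.positions_in(tile.chrom, tile.start, tile.end) == 0:
            continue
        if matrix_C.positions_in(tile.chrom, tile.start, tile.end) == 0:
            continue
        in_all = _overlap_bp(tile, track_all) >= min_overlap_bp
        in_a = _overlap_bp(tile, track_A) >= min_overlap_bp
        in_c = _overlap_bp(tile, track_C) >= min_overlap_bp
        if in_a and not in_c:
            category = "familyA_specific"
        elif in_c and not in_a:
            category = "familyC_specific"
        elif in_a and in_c:
            category = "shared"
        elif in_all:
            category = "shared"
        else:  # pragma: no cover - every tile overlaps its own run
            category = "unclassified"
        out.append(replace(tile, category=category))
    return out


_STATE_NONE = "none"


def classify_persistence(
    fib_tiles: Sequence[DMRTile],
    ipsc_tiles: Sequence[DMRTile],
    fib_matrix: UnitedMatrix,
    ipsc_matrix: UnitedMatrix,
) -> Dict[DMRTile, str]:
    """Label each eligible tile by its (fibroblast, iPSC) methylation states.

    The state in each cell type is 'hyper', 'hypo', or 'none' (no
    overlapping tile in that cell type's run); classes are the 8 ordered
    pairs excluding (none, none), written ``"<fib>-><ipsc>"``. Eligibility
    requires united CpG data in both cell types.
    """
    fib_track = tiles_to_track(fib_tiles)
    ipsc_track = tiles_to_track(ipsc_tiles)
    fib_dir = {(t.chrom, t.start, t.end): t.direction for t in fib_tiles}
    ipsc_dir = {(t.chrom, t.start, t.end): t.direction for t in ipsc_tiles}

    def state_in(tile: DMRTile, track: IntervalTrack, dirs: Dict) -> str:
        hits = track.overlapping(tile.chrom, tile.start, tile.end)
        if not hits:
            return _STATE_NONE
        best = max(
            hits, key=lambda iv: min(tile.end, iv.end) - max(tile.start, iv.start)
        )
        return dirs[(best.chrom, best.start, best.end)]

    result: Dict[DMRTile, str] = {}
    for tile in (*fib_tiles, *ipsc_tiles):
        if fib_matrix.positions_in(tile.chrom, tile.start, tile.end) == 0:
            continue
        if ipsc_matrix.positions_in(tile.chrom, tile.start, tile.end) == 0:
            continue
        fs = state_in(tile, fib_track, fib_dir)
        is_ = state_in(tile, ipsc_track, ipsc_dir)
        if fs == _STATE_NONE and is_ == _STATE_NONE:  # pragma: no cover
            continue
        result[tile] = f"{fs}->{is_}"
    return result


# ---------------------------------------------------------------------------
# Serialization


def write_dmcpgs(dmcpgs: Sequence[DMCpG], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tmeth_diff\tp_value\tq_value\n")
        for d in dmcpgs:
            fh.write(
                f"{d.chrom}\t{d.pos}\t{d.meth_diff:.6g}\t{d.p_value:.6g}\t{d.q_value:.6g}\n"
            )


def read_dmcpgs(path) -> List[DMCpG]:
    out: List[DMCpG] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: missing DMCpG header")
        for line in fh:
            chrom, pos, diff, p, q = line.rstrip("\n").split("\t")
            out.append(DMCpG(chrom, int(pos), float(diff), float(p), float(q)))
    return out


_TILE_HEADER = "chrom\tstart\tend\tcategory\tmean_diff\tdirection\tn_dmcpgs\tcell_type\tsource"


def write_tiles(tiles: Sequence[DMRTile], path) -> None:
    """BED6+ style tile table (name = category, score = mean_diff)."""
    with open(path, "w") as fh:
        fh.write("#" + _TILE_HEADER + "\n")
        for t in tiles:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.category}\t{t.mean_diff:.6g}"
                f"\t{t.direction}\t{t.n_dmcpgs}\t{t.cell_type}\t{t.source}\n"
            )


def read_tiles(path) -> List[DMRTile]:
    out: List[DMRTile] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(
                DMRTile(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), category=f[3],
                    mean_diff=float(f[4]), direction=f[5], n_dmcpgs=int(f[6]),
                    cell_type=f[7], source=f[8] if len(f) > 8 else "",
                )
            )
    return out
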