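"""Feature annotation and enrichment: promoters, feature assignment,
odds-ratio tables with Fisher tests, TSS-distance bins, and the
basal-plus-extension gene association rule."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalTrack

__all__ = [
    "GeneModel",
    "ORResult",
    "read_gene_models",
    "write_gene_models",
    "define_promoters",
    "gene_body_track",
    "exon_track",
    "assign_feature",
    "assign_features",
    "odds_ratio",
    "tss_distance_bins",
    "great_associate",
    "write_or_results",
]

Site = Tuple[str, int]  # (chrom, 1-based pos)


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS, body span and exon structure (1-based tss;
    tx_start/tx_end 0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid span")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start site."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True)
class ORResult:
    """A 2x2 enrichment outcome.

    a = query sites inside the context, b = query sites outside,
    c = background-minus-query sites inside, d = those outside.
    """

    context: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: Optional[float]
    log_or: Optional[float]  # log10
    p_value: float
    degenerate: bool = False

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


# ---------------------------------------------------------------------------
# Gene model I/O

_GENE_COLS = ["gene_id", "chrom", "strand", "tx_start", "tx_end", "exons"]


def read_gene_models(path) -> List[GeneModel]:
    """Read a gene model TSV: gene_id, chrom, strand, tx_start, tx_end,
    exons (semicolon-separated start-end pairs, 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(_GENE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        exons: Tuple[Tuple[int, int], ...] = ()
        raw = getattr(row, "exons", "")
        if isinstance(raw, str) and raw and raw != ".":
            exons = tuple(
                (int(p.split("-")[0]), int(p.split("-")[1])) for p in raw.split(";")
            )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                exons=exons,
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for g in genes:
            exons = ";".join(f"{s}-{e}" for s, e in g.exons) or "."
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{exons}\n"
            )


# ---------------------------------------------------------------------------
# Feature tracks


def define_promoters(genes: Sequence[GeneModel], upstream: int = 2000) -> IntervalTrack:
    """Strand-aware promoter intervals of ``upstream`` bp ending at the TSS;
    clipped at coordinate 0."""
    intervals = []
    for g in genes:
        if g.strand == "+":
            start, end = max(g.tx_start - upstream, 0), g.tx_start
        else:
            start, end = g.tx_end, g.tx_end + upstream
        if end > start:
            intervals.append(GenomicInterval(g.chrom, start, end, name=g.gene_id))
    return IntervalTrack(intervals, name="promoters")


def gene_body_track(genes: Sequence[GeneModel]) -> IntervalTrack:
    return IntervalTrack(
        [GenomicInterval(g.chrom, g.tx_start, g.tx_end, name=g.gene_id) for g in genes],
        name="gene_bodies",
    )


def exon_track(genes: Sequence[GeneModel]) -> IntervalTrack:
    intervals = [
        GenomicInterval(g.chrom, s, e, name=g.gene_id)
        for g in genes
        for s, e in g.exons
    ]
    return IntervalTrack(intervals, name="exons")


def assign_feature(
    site: Site,
    promoters: IntervalTrack,
    exons: IntervalTrack,
    gene_bodies: IntervalTrack,
) -> str:
    """Assign one of {promoter, exon, intron, intergenic} to a site under
    the precedence promoter > exon > intron > intergenic."""
    chrom, pos = site
    start0 = pos - 1
    if promoters.any_overlap(chrom, start0, start0 + 1):
        return "promoter"
    if exons.any_overlap(chrom, start0, start0 + 1):
        return "exon"
    if gene_bodies.any_overlap(chrom, start0, start0 + 1):
        return "intron"
    return "intergenic"


def assign_features(
    sites: Iterable[Site], genes: Sequence[GeneModel], upstream: int = 2000
) -> Dict[Site, str]:
    promoters = define_promoters(genes, upstream)
    exons = exon_track(genes)
    bodies = gene_body_track(genes)
    return {s: assign_feature(s, promoters, exons, bodies) for s in sites}


# ---------------------------------------------------------------------------
# Odds-ratio enrichment


def _sites_in_track(sites: Set[Site], track: IntervalTrack) -> Set[Site]:
    hits = set()
    for chrom, pos in sites:
        if track.any_overlap(chrom, pos - 1, pos):
            hits.add((chrom, pos))
    return hits


def odds_ratio(
    dm_cpgs: Set[Site], background: Set[Site], context: IntervalTrack,
    label: Optional[str] = None,
) -> ORResult:
    """2x2 enrichment of query CpGs in a context track vs background.

    c and d are counted over background MINUS the query set. OR =
    (a/c)/(b/d); a zero margin flags the result degenerate (no continuity
    correction). p is two-sided Fisher's exact.
    """
    if not dm_cpgs <= background:
        raise ValueError("dm_cpgs must be a subset of background")
    rest = background - dm_cpgs
    in_ctx_dm = _sites_in_track(dm_cpgs, context)
    in_ctx_rest = _sites_in_track(rest, context)
    a = len(in_ctx_dm)
    b = len(dm_cpgs) - a
    c = len(in_ctx_rest)
    d = len(rest) - c
    return _make_or_result(label or context.name, a, b, c, d)


def _make_or_result(context: str, a: int, b: int, c: int, d: int) -> ORResult:
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b > 0 and c > 0 and d > 0:
        orv = (a / c) / (b / d)
        log_or = math.log10(orv) if orv > 0 else None
        degenerate = orv == 0
    else:
        orv, log_or, degenerate = None, None, True
    return ORResult(context, a, b, c, d, orv, log_or, float(p), degenerate)


def _nearest_tss_signed_distance(
    site: Site, tss_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]]
) -> Optional[int]:
    """Signed bp distance from the site to the nearest TSS: positive
    downstream of the gene, negative upstream, per the gene's strand."""
    chrom, pos = site
    entry = tss_by_chrom.get(chrom)
    if entry is None:
        return None
    tss_coords, strand_is_minus = entry
    x = pos - 1
    i = int(np.argmin(np.abs(tss_coords - x)))
    raw = x - int(tss_coords[i])
    return -raw if strand_is_minus[i] else raw


def tss_distance_bins(
    dm_cpgs: Set[Site],
    background: Set[Site],
    genes: Sequence[GeneModel],
    bin_edges_kb: Sequence[float] = (0, 1, 5, 10, 50),
) -> List[ORResult]:
    """One OR per signed TSS-distance bin.

    Distance is to the nearest TSS over all genes, signed by that gene's
    orientation (negative = upstream). Downstream bins are half-open
    [lo, hi); upstream bins are (-hi, -lo], with distance exactly 0
    counted in the first downstream bin.
    """
    if not genes:
        raise ValueError("empty gene set")
    edges = [int(e * 1000) for e in bin_edges_kb]
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if not dm_cpgs <= background:
        raise ValueError("dm_cpgs must be a subset of background")

    by_chrom: Dict[str, List[Tuple[int, bool]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand == "-"))
    tss_by_chrom = {
        c: (
            np.array([t for t, _ in v], dtype=np.int64),
            np.array([m for _, m in v], dtype=bool),
        )
        for c, v in by_chrom.items()
    }

    def bin_of(d: Optional[int]) -> Optional[str]:
        if d is None:
            return None
        if d >= 0:
            for lo, hi in zip(edges, edges[1:]):
                if lo <= d < hi:
                    return f"+[{lo},{hi})"
        else:
            for lo, hi in zip(edges, edges[1:]):
                if -hi < d <= -lo and d != 0:
                    return f"-({lo},{hi}]"
        return None

    dm_bins: Dict[Site, Optional[str]] = {
        s: bin_of(_nearest_tss_signed_distance(s, tss_by_chrom)) for s in dm_cpgs
    }
    rest = background - dm_cpgs
    rest_bins: Dict[Site, Optional[str]] = {
        s: bin_of(_nearest_tss_signed_distance(s, tss_by_chrom)) for s in rest
    }

    results = []
    labels = [f"-({lo},{hi}]" for lo, hi in zip(edges, edges[1:])][::-1] + [
        f"+[{lo},{hi})" for lo, hi in zip(edges, edges[1:])
    ]
    for label in labels:
        a = sum(1 for v in dm_bins.values() if v == label)
        b = len(dm_cpgs) - a
        c = sum(1 for v in rest_bins.values() if v == label)
        d = len(rest) - c
        results.append(_make_or_result(f"tss{label}", a, b, c, d))
    return results


# ---------------------------------------------------------------------------
# Basal-plus-extension gene association


def regulatory_domains(
    genes: Sequence[GeneModel],
    proximal_up: int = 5000,
    proximal_down: int = 1000,
    distal_max: int = 1_000_000,
    genome: Optional[Dict[str, int]] = None,
) -> Dict[str, Tuple[int, int]]:
    """Per-gene regulatory domain (0-based half-open span).

    The basal domain runs ``proximal_up`` bp upstream to ``proximal_down``
    bp downstream of the TSS (strand-aware). Each side extends to the
    nearest neighboring basal-domain boundary or ``distal_max`` from the
    basal edge, whichever is closer, but never shrinks below the basal
    domain itself. Clipped at 0 and at the chromosome length if known.
    """
    basal: Dict[str, Tuple[int, int]] = {}
    for g in genes:
        if g.strand == "+":
            s = g.tss - proximal_up
            e = g.tss + proximal_down
        else:
            s = g.tss - proximal_down + 1
            e = g.tss + proximal_up + 1
        basal[g.gene_id] = (max(s, 0), e)

    domains: Dict[str, Tuple[int, int]] = {}
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        chrom_len = genome.get(chrom) if genome else None
        for g in gs:
            bs, be = basal[g.gene_id]
            left = bs - distal_max
            right = be + distal_max
            for other in gs:
                if other.gene_id == g.gene_id:
                    continue
                obs, obe = basal[other.gene_id]
                if obe <= bs:
                    left = max(left, obe)
                if obs >= be:
                    right = min(right, obs)
            left = min(max(left, 0), bs)
            right = max(right, be)
            if chrom_len is not None:
                right = min(right, chrom_len)
                right = max(right, be)
            domains[g.gene_id] = (left, right)
    return domains


def great_associate(
    tiles: Sequence,
    genes: Sequence[GeneModel],
    proximal_up: int = 5000,
    proximal_down: int = 1000,
    distal_max: int = 1_000_000,
    genome: Optional[Dict[str, int]] = None,
) -> Dict[object, Set[str]]:
    """Map each tile (anything with chrom/start/end) to the genes whose
    regulatory domain it overlaps by >= 1 bp."""
    domains = regulatory_domains(genes, proximal_up, proximal_down, distal_max, genome)
    dom_track = IntervalTrack(
        [
            GenomicInterval(g.chrom, s, e, name=g.gene_id)
            for g in genes
            for s, e in [domains[g.gene_id]]
        ],
        name="regulatory_domains",
    )
    out: Dict[object, Set[str]] = {}
    for t in tiles:
        hits = dom_track.overlapping(t.chrom, t.start, t.end)
        out[t] = {iv.name for iv in hits}
    return out


def write_or_results(results: Sequence[ORResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("context\ta\tb\tc\td\todds_ratio\tlog10_or\tp_value\tdegenerate\n")
        for r in results:
            orv = format(r.odds_ratio, ".6g") if r.odds_ratio is not None else "NA"
            lov = format(r.log_or, ".6g") if r.log_or is not None else "NA"
            fh.write(
                f"{r.context}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{orv}\t{lov}"
                f"\t{r.p_value:.6g}\t{int(r.degenerate)}\n"
            )
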