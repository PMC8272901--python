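"""Seeded synthetic fixture generator.

Produces multi-sample CpG methylomes for two families (controls +
patients) with planted shared and family-specific differential regions of
known location, sign, and effect size, plus matching gene models,
chromatin tracks, LAD tracks, and DEG tables consistent with the planted
structure. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gene_models
from .intervals import GenomicInterval, IntervalTrack, write_bed
from .methio import CpGCall, SampleMethylome, UnitedMatrix, write_calls

__all__ = [
    "PlantedDMR",
    "SimulationConfig",
    "plant_dmrs",
    "simulate_methylomes",
    "simulate_united_matrix",
    "simulate_companions",
    "write_fixture",
]


@dataclass(frozen=True)
class PlantedDMR:
    chrom: str
    start: int  # 0-based half-open
    end: int
    family: str  # {'A', 'C', 'shared'}
    delta: float  # percent points, signed (patient - control)

    def __post_init__(self) -> None:
        if self.family not in ("A", "C", "shared"):
            raise ValueError(f"invalid planted family {self.family!r}")
        if not -100 <= self.delta <= 100 or self.delta == 0:
            raise ValueError("delta must be nonzero and within +/-100")


@dataclass
class SimulationConfig:
    genome: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_cpgs: int = 50_000
    families: Dict[str, Dict[str, int]] = field(
        default_factory=lambda: {
            "A": {"n_controls": 2, "n_patients": 3},
            "C": {"n_controls": 2, "n_patients": 2},
        }
    )
    coverage_mean: float = 30.0
    baseline_beta: Tuple[float, float] = (0.4, 0.4)
    family_offset_sd: float = 0.015  # per-family per-site baseline jitter
    island_fraction: float = 0.5  # fraction of CpGs placed in clustered islands
    planted_dmrs: List[PlantedDMR] = field(default_factory=list)
    deg_rho: float = 0.65  # P(DEG sign opposite to overlapping DMR sign)
    n_genes_per_mb: int = 10
    seed: int = 0


def plant_dmrs(
    genome: Dict[str, int],
    n_family_a: int,
    n_family_c: int,
    n_shared: int,
    delta: float = 40.0,
    span: int = 1000,
    rng: Optional[np.random.Generator] = None,
    min_gap: int = 5000,
) -> List[PlantedDMR]:
    """Place disjoint planted intervals across the genome, alternating sign."""
    rng = rng if rng is not None else np.random.default_rng(0)
    chroms = sorted(genome)
    labels = ["A"] * n_family_a + ["C"] * n_family_c + ["shared"] * n_shared
    n = len(labels)
    placed: List[Tuple[str, int, int]] = []
    # deterministic grid placement with jitter keeps spans disjoint
    per_chrom = -(-n // len(chroms))
    spots: List[Tuple[str, int]] = []
    for chrom in chroms:
        length = genome[chrom]
        usable = length - 2 * (span + min_gap)
        step = usable // max(per_chrom, 1)
        if step < span + min_gap:
            raise ValueError("genome too small for requested planted intervals")
        for i in range(per_chrom):
            start = span + min_gap + i * step + int(rng.integers(0, max(step - span - min_gap, 1)))
            spots.append((chrom, start))
    order = rng.permutation(len(labels))
    out = []
    for k, idx in enumerate(order):
        chrom, start = spots[k]
        sign = 1.0 if k % 2 == 0 else -1.0
        out.append(PlantedDMR(chrom, start, start + span, labels[idx], sign * delta))
    return sorted(out, key=lambda d: (d.chrom, d.start))


def _sample_ids(cfg: SimulationConfig) -> List[Tuple[str, str, str]]:
    """(sample_id, family, status) triples in deterministic order."""
    out = []
    for fam in sorted(cfg.families):
        spec = cfg.families[fam]
        for i in range(spec["n_controls"]):
            out.append((f"{fam}_C{i + 1}", fam, "control"))
        for i in range(spec["n_patients"]):
            out.append((f"{fam}_P{i + 1}", fam, "patient"))
    return out


def _place_cpgs(cfg: SimulationConfig, rng: np.random.Generator) -> List[Tuple[str, int]]:
    """Non-uniform CpG placement: uniform background plus Gamma-spaced
    clustered islands, with CpGs guaranteed inside every planted span."""
    positions: Dict[str, set] = {c: set() for c in cfg.genome}
    # guaranteed coverage of planted spans: one CpG every ~25 bp
    n_planted = 0
    for dmr in cfg.planted_dmrs:
        step = 25
        for pos0 in range(dmr.start + 5, dmr.end - 5, step):
            p = pos0 + int(rng.integers(0, 10))
            positions[dmr.chrom].add(min(p, dmr.end - 2))
            n_planted += 1
    remaining = max(cfg.n_cpgs - n_planted, 0)
    n_island = int(remaining * cfg.island_fraction)
    n_uniform = remaining - n_island
    chroms = sorted(cfg.genome)
    total_len = sum(cfg.genome.values())
    # uniform background
    for chrom in chroms:
        k = int(round(n_uniform * cfg.genome[chrom] / total_len))
        pts = rng.integers(2, cfg.genome[chrom] - 2, size=k)
        positions[chrom].update(int(p) for p in pts)
    # clustered islands: island anchors uniform, members Gamma-spaced
    n_islands = max(n_island // 60, 1)
    for _ in range(n_islands):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        anchor = int(rng.integers(10_000, cfg.genome[chrom] - 10_000))
        gaps = rng.gamma(shape=1.2, scale=25.0, size=60).astype(np.int64) + 2
        pos = anchor + np.cumsum(gaps)
        positions[chrom].update(int(p) for p in pos if p < cfg.genome[chrom] - 2)
    sites: List[Tuple[str, int]] = []
    for chrom in chroms:
        ordered = sorted(positions[chrom])
        # enforce >= 2 bp spacing so CpG dinucleotides never collide
        kept: List[int] = []
        for p in ordered:
            if not kept or p - kept[-1] >= 2:
                kept.append(p)
        sites.extend((chrom, p) for p in kept)
    return sites


def _baseline_rates(
    cfg: SimulationConfig, sites: Sequence[Tuple[str, int]], rng: np.random.Generator
) -> np.ndarray:
    """Bimodal per-site methylation rates; inside planted spans the rate is
    drawn so the shifted patient rate stays within [0.02, 0.98]."""
    a, b = cfg.baseline_beta
    rates = rng.beta(a, b, size=len(sites))
    rates = np.clip(rates, 0.02, 0.98)
    span_of_site = _planted_lookup(cfg, sites)
    for i, dmr in enumerate(span_of_site):
        if dmr is None:
            continue
        shift = dmr.delta / 100.0
        lo, hi = 0.02, 0.98
        if shift > 0:
            hi = 0.98 - shift
        else:
            lo = 0.02 - shift
        if lo >= hi:
            raise ValueError(f"planted delta {dmr.delta} leaves no feasible baseline rate")
        rates[i] = lo + (hi - lo) * rng.random()
    return rates


def _planted_lookup(
    cfg: SimulationConfig, sites: Sequence[Tuple[str, int]]
) -> List[Optional[PlantedDMR]]:
    by_chrom: Dict[str, List[PlantedDMR]] = {}
    for d in cfg.planted_dmrs:
        by_chrom.setdefault(d.chrom, []).append(d)
    for v in by_chrom.values():
        v.sort(key=lambda d: d.start)
    out: List[Optional[PlantedDMR]] = []
    for chrom, pos in sites:
        hit = None
        for d in by_chrom.get(chrom, ()):
            if d.start <= pos - 1 < d.end:
                hit = d
                break
        out.append(hit)
    return out


def _effective_rates(
    cfg: SimulationConfig,
    sites: Sequence[Tuple[str, int]],
    base: np.ndarray,
    rng: np.random.Generator,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Per (family, status) methylation rate vectors."""
    span_of_site = _planted_lookup(cfg, sites)
    shifts: Dict[str, np.ndarray] = {}
    for fam in sorted(cfg.families):
        shift = np.zeros(len(sites))
        for i, d in enumerate(span_of_site):
            if d is not None and (d.family == fam or d.family == "shared"):
                shift[i] = d.delta / 100.0
        shifts[fam] = shift
    out: Dict[Tuple[str, str], np.ndarray] = {}
    for fam in sorted(cfg.families):
        offset = rng.normal(0.0, cfg.family_offset_sd, size=len(sites))
        fam_base = np.clip(base + offset, 0.005, 0.995)
        out[(fam, "control")] = fam_base
        out[(fam, "patient")] = np.clip(fam_base + shifts[fam], 0.005, 0.995)
    return out


def simulate_methylomes(
    cfg: SimulationConfig,
) -> Tuple[List[SampleMethylome], pd.DataFrame]:
    """Generate stranded per-sample CpG call sets and the planted-truth table.

    Per site and sample, total coverage ~ Poisson(coverage_mean) (min 1)
    is split binomially between the two strands of the CpG dinucleotide;
    methylated counts are Binomial(coverage, rate), with patient rates of
    the targeted family shifted by delta/100 inside planted spans.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _place_cpgs(cfg, rng)
    base = _baseline_rates(cfg, sites, rng)
    rates = _effective_rates(cfg, sites, base, rng)

    methylomes: List[SampleMethylome] = []
    for sample_id, fam, status in _sample_ids(cfg):
        rate = rates[(fam, status)]
        cov = np.maximum(rng.poisson(cfg.coverage_mean, size=len(sites)), 1)
        cov_plus = rng.binomial(cov, 0.5)
        cov_minus = cov - cov_plus
        meth_plus = rng.binomial(cov_plus, rate)
        meth_minus = rng.binomial(cov_minus, rate)
        calls: List[CpGCall] = []
        for i, (chrom, pos) in enumerate(sites):
            if cov_plus[i] > 0:
                calls.append(
                    CpGCall(chrom, pos, "+", int(meth_plus[i]), int(cov_plus[i] - meth_plus[i]))
                )
            if cov_minus[i] > 0:
                calls.append(
                    CpGCall(chrom, pos + 1, "-", int(meth_minus[i]), int(cov_minus[i] - meth_minus[i]))
                )
        methylomes.append(SampleMethylome(sample_id, calls, family=fam, status=status))

    truth = pd.DataFrame(
        [
            {"chrom": d.chrom, "start": d.start, "end": d.end,
             "family": d.family, "delta": d.delta}
            for d in cfg.planted_dmrs
        ],
        columns=["chrom", "start", "end", "family", "delta"],
    )
    return methylomes, truth


def simulate_united_matrix(
    cfg: SimulationConfig,
) -> Tuple[UnitedMatrix, pd.DataFrame]:
    """Fast path: the united count matrix directly, skipping per-strand call
    objects and the destrand/unite machinery. Counts follow the same model
    with site-level coverage (already destranded)."""
    rng = np.random.default_rng(cfg.seed)
    sites = _place_cpgs(cfg, rng)
    base = _baseline_rates(cfg, sites, rng)
    rates = _effective_rates(cfg, sites, base, rng)
    ids = _sample_ids(cfg)
    n_meth = np.zeros((len(sites), len(ids)), dtype=np.int64)
    n_unmeth = np.zeros_like(n_meth)
    for j, (_, fam, status) in enumerate(ids):
        rate = rates[(fam, status)]
        cov = np.maximum(rng.poisson(cfg.coverage_mean, size=len(sites)), 5)
        m = rng.binomial(cov, rate)
        n_meth[:, j] = m
        n_unmeth[:, j] = cov - m
    truth = pd.DataFrame(
        [
            {"chrom": d.chrom, "start": d.start, "end": d.end,
             "family": d.family, "delta": d.delta}
            for d in cfg.planted_dmrs
        ],
        columns=["chrom", "start", "end", "family", "delta"],
    )
    matrix = UnitedMatrix(
        positions=list(sites),
        sample_ids=[sid for sid, _, _ in ids],
        n_meth=n_meth,
        n_unmeth=n_unmeth,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Companion fixtures


def simulate_companions(
    cfg: SimulationConfig, truth: pd.DataFrame
) -> Dict[str, object]:
    """Gene models, chromatin tracks, LAD tracks and DEG tables consistent
    with the planted differential regions.

    * a fraction of planted spans sit inside synthetic enhancer-state
      segments so enrichment is detectable;
    * DCM/control/fibroblast LAD tracks place planted-DMR genes mostly
      within 2 Mb of a GoL;
    * DEG log2 fold change is signed opposite to the overlapping planted
      delta with probability ``deg_rho``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    chroms = sorted(cfg.genome)

    genes: List[GeneModel] = []
    gidx = 0
    for chrom in chroms:
        length = cfg.genome[chrom]
        n_genes = max(cfg.n_genes_per_mb * length // 1_000_000, 1)
        step = length // (n_genes + 1)
        for i in range(n_genes):
            gidx += 1
            tx_start = (i + 1) * step
            tx_len = int(rng.integers(5_000, 30_000))
            tx_end = min(tx_start + tx_len, length - 1)
            strand = "+" if gidx % 2 == 1 else "-"
            n_ex = int(rng.integers(2, 5))
            ex_bounds = np.sort(rng.integers(tx_start, tx_end, size=2 * n_ex))
            exons = tuple(
                (int(ex_bounds[2 * k]), int(ex_bounds[2 * k + 1]))
                for k in range(n_ex)
                if ex_bounds[2 * k] < ex_bounds[2 * k + 1]
            )
            genes.append(GeneModel(f"GENE{gidx:04d}", chrom, strand, tx_start, tx_end, exons))

    planted = [
        PlantedDMR(r.chrom, int(r.start), int(r.end), r.family, float(r.delta))
        for r in truth.itertuples(index=False)
    ]

    # enhancer-state segments: ~60% of planted spans (padded) + decoys
    enh: List[GenomicInterval] = []
    for d in planted:
        if rng.random() < 0.6:
            enh.append(GenomicInterval(d.chrom, max(d.start - 200, 0), d.end + 200, name="EnhA"))
    for _ in range(max(len(enh), 5)):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, cfg.genome[chrom] - 2_000))
        enh.append(GenomicInterval(chrom, s, s + int(rng.integers(500, 2_000)), name="EnhA"))
    enhancer_track = IntervalTrack(enh, name="enhancer_state")

    histone: List[GenomicInterval] = []
    for _ in range(40):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, cfg.genome[chrom] - 5_000))
        histone.append(GenomicInterval(chrom, s, s + int(rng.integers(1_000, 5_000)), name="H3K4me1"))
    histone_track = IntervalTrack(histone, name="histone_peaks")

    # gene/planted association: gene body or 2 kb promoter overlaps a span
    assoc: Dict[str, PlantedDMR] = {}
    for g in genes:
        lo, hi = g.tx_start - 2_000, g.tx_end + 2_000
        for d in planted:
            if d.chrom == g.chrom and d.start < hi and lo < d.end:
                assoc[g.gene_id] = d
                break

    # LAD tracks: GoL blocks near associated genes; control LADs elsewhere
    dcm, ctrl, fib = [], [], []
    assoc_genes = [g for g in genes if g.gene_id in assoc]
    for g in assoc_genes[:: max(len(assoc_genes) // 20, 1)]:
        center = (g.tx_start + g.tx_end) // 2 + int(rng.integers(-500_000, 500_000))
        s = max(center - 100_000, 0)
        e = min(center + 100_000, cfg.genome[g.chrom])
        if e > s:
            dcm.append(GenomicInterval(g.chrom, s, e))  # becomes GoL (no ctrl overlap)
    for chrom in chroms:
        length = cfg.genome[chrom]
        for _ in range(4):
            s = int(rng.integers(0, length - 300_000))
            e = s + int(rng.integers(100_000, 300_000))
            ctrl.append(GenomicInterval(chrom, s, e))
            if rng.random() < 0.5:
                dcm.append(GenomicInterval(chrom, s, e))  # MoL
            fib.append(GenomicInterval(chrom, s, e))  # fibroblast LAD over ctrl LADs
    dcm_track = IntervalTrack(dcm, name="dcm_lads")
    ctrl_track = IntervalTrack(ctrl, name="ctrl_lads")
    fib_track = IntervalTrack(fib, name="fib_lads")

    # DEG tables: associated genes are DEGs with sign anti-linked to delta
    fib_rows, cardiac_rows = [], []
    for g in genes:
        d = assoc.get(g.gene_id)
        if d is not None:
            sign = -np.sign(d.delta) if rng.random() < cfg.deg_rho else np.sign(d.delta)
            fc = float(sign * (0.5 + rng.gamma(2.0, 0.5)))
            p = float(10 ** rng.uniform(-8, -3))
            fdr = min(p * 5, 0.049)
        else:
            fc = float(rng.normal(0, 0.3))
            p = float(rng.uniform(0.05, 1.0))
            fdr = min(p * 2, 1.0)
        fib_rows.append({"gene": g.gene_id, "log2_fc": fc, "p_value": p, "fdr": fdr})
        # cardiac table: conserved for most associated genes
        if d is not None and rng.random() < 0.8:
            cardiac_rows.append(
                {"gene": g.gene_id, "log2_fc": fc * float(rng.uniform(0.5, 1.5)),
                 "p_value": p, "fdr": fdr}
            )
        elif d is None and rng.random() < 0.2:
            cardiac_rows.append(
                {"gene": g.gene_id, "log2_fc": float(rng.normal(0, 0.5)),
                 "p_value": float(rng.uniform(0.0, 1.0)), "fdr": 1.0}
            )
    return {
        "genes": genes,
        "enhancer_track": enhancer_track,
        "histone_track": histone_track,
        "dcm_lads": dcm_track,
        "ctrl_lads": ctrl_track,
        "fib_lads": fib_track,
        "fib_degs": pd.DataFrame(fib_rows),
        "cardiac_degs": pd.DataFrame(cardiac_rows),
    }


def write_fixture(cfg: SimulationConfig, outdir) -> Dict[str, str]:
    """Write the complete fixture tree; returns a name -> path map."""
    outdir = Path(outdir)
    for sub in ("coverage", "tracks", "lads", "degs", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    methylomes, truth = simulate_methylomes(cfg)
    companions = simulate_companions(cfg, truth)

    paths: Dict[str, str] = {}
    sheet_rows = []
    for m in methylomes:
        p = outdir / "coverage" / f"{m.sample_id}.cov.tsv"
        write_calls(m, p)
        sheet_rows.append(
            {"sample_id": m.sample_id, "family": m.family, "status": m.status,
             "path": str(p.relative_to(outdir))}  # portable fixture tree
        )
    sheet = outdir / "samples.tsv"
    pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
    paths["sample_sheet"] = str(sheet)

    genes_path = outdir / "genes.tsv"
    write_gene_models(companions["genes"], genes_path)
    paths["genes"] = str(genes_path)

    sizes = outdir / "genome.sizes"
    with open(sizes, "w") as fh:
        for chrom in sorted(cfg.genome):
            fh.write(f"{chrom}\t{cfg.genome[chrom]}\n")
    paths["genome"] = str(sizes)

    for key, sub in [
        ("enhancer_track", "tracks/enhancer_state.bed"),
        ("histone_track", "tracks/histone_peaks.bed"),
        ("dcm_lads", "lads/dcm_lads.bed"),
        ("ctrl_lads", "lads/ctrl_lads.bed"),
        ("fib_lads", "lads/fib_lads.bed"),
    ]:
        p = outdir / sub
        write_bed(companions[key], p)
        paths[key] = str(p)

    for key, sub in [("fib_degs", "degs/fibroblast.tsv"), ("cardiac_degs", "degs/cardiac.tsv")]:
        p = outdir / sub
        companions[key].to_csv(p, sep="\t", index=False)
        paths[key] = str(p)

    tpath = outdir / "truth" / "planted_dmrs.tsv"
    truth.to_csv(tpath, sep="\t", index=False)
    paths["truth"] = str(tpath)
    return paths
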