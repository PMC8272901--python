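"""CpG methylation-call I/O: parsing, coverage filtering, destranding, unite.

Positions are 1-based (the cytosine of the CpG on the + strand after
destranding), matching the Bismark coverage convention. Conversion to
0-based interval coordinates happens wherever calls are turned into
genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CpGCall",
    "SampleMethylome",
    "UnitedMatrix",
    "read_calls",
    "write_calls",
    "destrand",
    "filter_coverage",
    "unite",
    "read_sample_sheet",
]


@dataclass(frozen=True)
class CpGCall:
    """A single cytosine call: counts of methylated/unmethylated reads."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+', '-' or '.' once destranded
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(f"negative counts at {self.chrom}:{self.pos}")
        if self.n_meth + self.n_unmeth < 1:
            raise ValueError(f"zero coverage at {self.chrom}:{self.pos}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def percent(self) -> float:
        return 100.0 * self.n_meth / self.coverage


@dataclass
class SampleMethylome:
    """One sample's CpG calls, keyed by (chrom, pos)."""

    sample_id: str
    calls: List[CpGCall]
    family: str = "none"  # {'A', 'C', 'none'}
    status: str = "control"  # {'patient', 'control'}
    destranded: bool = False

    def __len__(self) -> int:
        return len(self.calls)

    def positions(self) -> set:
        return {(c.chrom, c.pos) for c in self.calls}

    def by_position(self) -> Dict[Tuple[str, int], CpGCall]:
        return {(c.chrom, c.pos): c for c in self.calls}


@dataclass
class UnitedMatrix:
    """Shared-position count matrix across samples (complete-case).

    ``n_meth``/``n_unmeth`` are (n_positions, n_samples) integer arrays
    aligned with ``positions`` (sorted (chrom, pos) tuples) and
    ``sample_ids``.
    """

    positions: List[Tuple[str, int]]
    sample_ids: List[str]
    n_meth: np.ndarray
    n_unmeth: np.ndarray
    min_coverage: int = 5

    def __post_init__(self) -> None:
        np_, ns = len(self.positions), len(self.sample_ids)
        if self.n_meth.shape != (np_, ns) or self.n_unmeth.shape != (np_, ns):
            raise ValueError("count array shape mismatch")

    @property
    def coverage(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def percent(self) -> np.ndarray:
        cov = self.coverage
        return 100.0 * self.n_meth / cov

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"sample {sample_id!r} not in matrix") from exc

    def _pos_index(self) -> Dict[str, np.ndarray]:
        cached = getattr(self, "_pos_index_cache", None)
        if cached is None:
            by_chrom: Dict[str, List[int]] = {}
            for c, p in self.positions:
                by_chrom.setdefault(c, []).append(p)
            cached = {c: np.array(sorted(ps), dtype=np.int64) for c, ps in by_chrom.items()}
            object.__setattr__(self, "_pos_index_cache", cached)
        return cached

    def positions_in(self, chrom: str, start0: int, end0: int) -> int:
        """Count united positions with 0-based coordinate in [start0, end0)."""
        arr = self._pos_index().get(chrom)
        if arr is None:
            return 0
        # 1-based pos p occupies 0-based coordinate p-1
        lo = int(np.searchsorted(arr, start0 + 1, side="left"))
        hi = int(np.searchsorted(arr, end0, side="right"))
        return max(hi - lo, 0)

    def to_frame(self) -> pd.DataFrame:
        chroms = [c for c, _ in self.positions]
        poss = [p for _, p in self.positions]
        data: Dict[str, object] = {"chrom": chroms, "pos": poss}
        for j, sid in enumerate(self.sample_ids):
            data[f"{sid}.n_meth"] = self.n_meth[:, j]
            data[f"{sid}.n_unmeth"] = self.n_unmeth[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, min_coverage: int = 5) -> "UnitedMatrix":
        sample_ids = [
            c[: -len(".n_meth")] for c in df.columns if c.endswith(".n_meth")
        ]
        positions = list(zip(df["chrom"].astype(str), df["pos"].astype(int)))
        n_meth = np.column_stack(
            [df[f"{s}.n_meth"].to_numpy(dtype=np.int64) for s in sample_ids]
        )
        n_unmeth = np.column_stack(
            [df[f"{s}.n_unmeth"].to_numpy(dtype=np.int64) for s in sample_ids]
        )
        return cls(positions, sample_ids, n_meth, n_unmeth, min_coverage)


# ---------------------------------------------------------------------------
# I/O

_COV_COLS = 6  # chrom, start(1-based), end, percent, n_meth, n_unmeth


def read_calls(
    path,
    sample_id: Optional[str] = None,
    family: str = "none",
    status: str = "control",
) -> SampleMethylome:
    """Read a Bismark-style coverage file.

    Two dialects are accepted:

    * 6 columns: chrom, pos(1-based), end, percent, n_meth, n_unmeth —
      strand-less; every call is treated as '+' (already destranded data).
    * 7 columns: the same six plus an explicit strand column ('+'/'-').

    Malformed lines raise ``ValueError`` naming the line number.
    """
    calls: List[CpGCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _COV_COLS:
                raise ValueError(f"{path}:{lineno}: expected >=6 columns")
            chrom = fields[0]
            try:
                pos = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            strand = fields[6] if len(fields) > 6 else "+"
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                calls.append(CpGCall(chrom, pos, strand, n_meth, n_unmeth))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    sid = sample_id if sample_id is not None else str(path)
    return SampleMethylome(sid, calls, family=family, status=status)


def write_calls(m: SampleMethylome, path) -> None:
    """Write calls in the coverage dialect (7 columns when stranded)."""
    stranded = any(c.strand in ("+", "-") for c in m.calls)
    ordered = sorted(m.calls, key=lambda c: (c.chrom, c.pos, c.strand))
    with open(path, "w") as fh:
        for c in ordered:
            row = [
                c.chrom,
                str(c.pos),
                str(c.pos),
                format(c.percent, ".6g"),
                str(c.n_meth),
                str(c.n_unmeth),
            ]
            if stranded:
                row.append(c.strand)
            fh.write("\t".join(row) + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet TSV: sample_id, family, status, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "family", "status", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return df


# ---------------------------------------------------------------------------
# Transformations


def destrand(m: SampleMethylome) -> SampleMethylome:
    """Merge the two strand-symmetric calls of each CpG dinucleotide.

    A '-' strand call at position p+1 is count-summed into the '+' strand
    call at p; orphan '-' calls are repositioned to their '+' strand
    coordinate. Output carries one record per CpG site with strand '.'.
    """
    merged: Dict[Tuple[str, int], List[int]] = {}
    seen_plus: set = set()
    for c in m.calls:
        if c.strand == "+":
            key = (c.chrom, c.pos)
            if key in seen_plus:
                raise ValueError(f"duplicate + strand call at {c.chrom}:{c.pos}")
            seen_plus.add(key)
        elif c.strand == "-":
            key = (c.chrom, c.pos - 1)
            if c.pos < 2:
                raise ValueError(f"- strand call at {c.chrom}:{c.pos} has no + mate position")
        else:
            raise ValueError(f"call at {c.chrom}:{c.pos} lacks strand; already destranded?")
        acc = merged.setdefault(key, [0, 0])
        acc[0] += c.n_meth
        acc[1] += c.n_unmeth
    calls = [
        CpGCall(chrom, pos, ".", nm, nu)
        for (chrom, pos), (nm, nu) in sorted(merged.items())
    ]
    return SampleMethylome(
        m.sample_id, calls, family=m.family, status=m.status, destranded=True
    )


def filter_coverage(m: SampleMethylome, min_cov: int = 5) -> SampleMethylome:
    """Keep only sites with coverage >= ``min_cov``."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    calls = [c for c in m.calls if c.coverage >= min_cov]
    return SampleMethylome(
        m.sample_id, calls, family=m.family, status=m.status, destranded=m.destranded
    )


def unite(methylomes: Sequence[SampleMethylome], min_cov: int = 5) -> UnitedMatrix:
    """Intersect site sets across samples into a complete-case matrix.

    Every retained position is covered >= ``min_cov`` in every sample; the
    per-sample coverage filter is (re-)applied here so callers cannot
    accidentally skip it.
    """
    if len(methylomes) < 2:
        raise ValueError("unite requires at least 2 samples")
    ids = [m.sample_id for m in methylomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    filtered = [filter_coverage(m, min_cov) for m in methylomes]
    common = set(filtered[0].positions())
    for m in filtered[1:]:
        common &= m.positions()
    positions = sorted(common)
    index = {key: i for i, key in enumerate(positions)}
    n_meth = np.zeros((len(positions), len(ids)), dtype=np.int64)
    n_unmeth = np.zeros_like(n_meth)
    for j, m in enumerate(filtered):
        for c in m.calls:
            i = index.get((c.chrom, c.pos))
            if i is not None:
                n_meth[i, j] = c.n_meth
                n_unmeth[i, j] = c.n_unmeth
    return UnitedMatrix(positions, ids, n_meth, n_unmeth, min_coverage=min_cov)
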