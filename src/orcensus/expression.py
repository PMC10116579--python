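"""Spatial expression statistics for receptor-expressing neurons.

Input is a table of labeled olfactory sensory neurons (OSNs), one row per
cell, with the lamella the cell sits on (primary or secondary), its
distance from the lamellar apex, and the apex-to-base length of the parent
primary lamella (positions on secondary lamellae are projections onto the
primary lamella). The module computes the per-gene summaries used to
compare receptors — labeling density per mm of lamellar length,
primary/secondary proportions, normalized radial positions and their ECDFs
— and the two significance tests: Welch's two-sided unpaired t-test and
the two-sample Kolmogorov-Smirnov test with exact small-sample p-values.

Orientation convention: normalized position 0 is the lamellar apex, 1 the
base at the connective capsule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledCell:
    section_id: str
    lamella_id: str
    lamella_type: str  # "primary" | "secondary"
    distance_from_apex: float  # um
    parent_lamella_length: float  # um
    receptor_id: str

    def __post_init__(self) -> None:
        if self.lamella_type not in ("primary", "secondary"):
            raise ValueError(f"bad lamella_type {self.lamella_type!r}")
        if not (0 <= self.distance_from_apex <= self.parent_lamella_length):
            raise ValueError("distance_from_apex outside [0, lamella length]")


@dataclass(frozen=True)
class LamellaMeasurement:
    lamella_id: str
    measured_length: float  # mm
    section_id: str = ""

    def __post_init__(self) -> None:
        if self.measured_length <= 0:
            raise ValueError("lamella length must be > 0")


@dataclass
class ExpressionSummary:
    receptor_id: str
    density_mean: float  # cells / mm
    density_sem: float
    n_cells: int
    pct_primary: float
    pct_secondary: float
    total_length_mm: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_kind: str
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# Positions and summaries
# ---------------------------------------------------------------------------


def normalized_position(cell: LabeledCell) -> float:
    """Distance from the apex divided by total lamellar length (0=apex)."""
    if cell.parent_lamella_length <= 0:
        raise ValueError("zero-length lamella")
    return cell.distance_from_apex / cell.parent_lamella_length


def summarize_expression(
    cells: Sequence[LabeledCell],
    lamellae: Sequence[LamellaMeasurement],
    receptor_id: Optional[str] = None,
) -> ExpressionSummary:
    """Density and primary/secondary proportions for one receptor gene.

    Density is the mean over surveyed lamellae of cells-per-mm (the lamella
    is the unit of replication for the SEM); lamellae with no labeled cell
    count as zero. Proportions are percentages of the total cell count.
    """
    if not lamellae:
        raise ValueError("empty lamella list")
    known = {l.lamella_id for l in lamellae}
    for c in cells:
        if c.lamella_id not in known:
            raise ValueError(f"cell references unknown lamella {c.lamella_id!r}")
    if receptor_id is None:
        rids = {c.receptor_id for c in cells}
        receptor_id = rids.pop() if len(rids) == 1 else "all"
    per = {l.lamella_id: 0 for l in lamellae}
    n_primary = 0
    for c in cells:
        per[c.lamella_id] += 1
        if c.lamella_type == "primary":
            n_primary += 1
    dens = np.array([per[l.lamella_id] / l.measured_length for l in lamellae])
    sem = float(np.std(dens, ddof=1) / np.sqrt(len(dens))) if len(dens) > 1 else 0.0
    n = len(cells)
    pct_primary = 100.0 * n_primary / n if n else float("nan")
    return ExpressionSummary(
        receptor_id=receptor_id,
        density_mean=float(dens.mean()),
        density_sem=sem,
        n_cells=n,
        pct_primary=pct_primary,
        pct_secondary=100.0 - pct_primary if n else float("nan"),
        total_length_mm=float(sum(l.measured_length for l in lamellae)),
    )


def summary_table(
    cells: Sequence[LabeledCell], lamellae: Sequence[LamellaMeasurement]
) -> pd.DataFrame:
    """Per-receptor summary table (one row per receptor gene)."""
    rows = []
    for rid in sorted({c.receptor_id for c in cells}):
        s = summarize_expression([c for c in cells if c.receptor_id == rid], lamellae, rid)
        rows.append(
            {
                "receptor_id": s.receptor_id,
                "density_mean": s.density_mean,
                "density_sem": s.density_sem,
                "n_cells": s.n_cells,
                "pct_primary": s.pct_primary,
                "pct_secondary": s.pct_secondary,
                "total_length_mm": s.total_length_mm,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ECDF
# ---------------------------------------------------------------------------


class Ecdf:
    """Right-continuous empirical CDF with tied values accumulated."""

    def __init__(self, values: Sequence[float]):
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError("empty sample")
        support, counts = np.unique(v, return_counts=True)
        self.support = support
        self.fractions = np.cumsum(counts) / v.size
        self.n = v.size

    def __call__(self, x) -> np.ndarray:
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        out = np.where(idx > 0, self.fractions[np.maximum(idx - 1, 0)], 0.0)
        return out if out.shape else float(out)


def ecdf(values: Sequence[float]) -> Ecdf:
    return Ecdf(values)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def t_test_two_sample(
    x: Sequence[float], y: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-sided unpaired t-test (Welch by default, Student optional)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two observations per sample")
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate: no within-group variability
        stat, p = (0.0, 1.0) if x.mean() == y.mean() else (float("inf"), 0.0)
    else:
        stat, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
        stat, p = float(stat), float(p)
    kind = "t_two_sided_unpaired" if variant == "welch" else "t_two_sided_unpaired_student"
    return TestResult(stat, p, kind, len(x), len(y))


def _ks_statistic_numerator(x: np.ndarray, y: np.ndarray) -> int:
    """sup|F_x - F_y| as an exact integer numerator over n1*n2."""
    n1, n2 = len(x), len(y)
    pooled = np.unique(np.concatenate([x, y]))
    cx = np.searchsorted(np.sort(x), pooled, side="right")
    cy = np.searchsorted(np.sort(y), pooled, side="right")
    return int(np.max(np.abs(cx * n2 - cy * n1)))


def _ks_exact_pvalue(x: np.ndarray, y: np.ndarray, d_num: int) -> float:
    """Exact permutation p-value P(D* >= D_obs) by lattice-path counting.

    Counts the arrangements of pooled ranks whose deviation |i*n2 - j*n1|
    stays strictly below ``d_num`` at every distinct pooled value (ties are
    handled by group convolution); the complement over C(n1+n2, n1) is the
    exact two-sided permutation p-value.
    """
    n1, n2 = len(x), len(y)
    pooled, _, counts = np.unique(
        np.concatenate([x, y]), return_inverse=True, return_counts=True
    )
    xc = np.searchsorted(np.sort(x), pooled, side="right")
    xg = np.diff(np.concatenate([[0], xc]))  # x count per group
    yg = counts - xg
    ways = np.zeros(n1 + 1)
    ways[0] = 1.0
    used_x = 0
    used_tot = 0
    for g in range(len(counts)):
        s = int(counts[g])
        sx_max = int(xg[g] + yg[g])
        # distribute the s tied observations: k of them are x's
        kernel = np.array([special.comb(s, k, exact=True) for k in range(s + 1)], dtype=float)
        ways = np.convolve(ways, kernel)[: n1 + 1]
        used_tot += s
        # checkpoint after the group: i x's used, j = used_tot - i
        i = np.arange(n1 + 1)
        j = used_tot - i
        bad = (j < 0) | (j > n2) | (np.abs(i * n2 - j * n1) >= d_num)
        ways[bad[: len(ways)]] = 0.0
    total = float(special.comb(n1 + n2, n1, exact=True))
    return float(min(1.0, max(0.0, 1.0 - ways[n1] / total)))


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], exact_max_product: int = 10_000
) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``D = sup|F_x - F_y|`` over the pooled support. The p-value is exact
    (permutation of pooled ranks, lattice-path counting) when
    ``n1*n2 <= exact_max_product``, otherwise the asymptotic Kolmogorov
    distribution is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    d_num = _ks_statistic_numerator(x, y)
    d = d_num / (n1 * n2)
    if d_num == 0:
        p = 1.0
    elif n1 * n2 <= exact_max_product:
        p = _ks_exact_pvalue(x, y, d_num)
    else:
        en = np.sqrt(n1 * n2 / (n1 + n2))
        p = float(min(1.0, max(0.0, special.kolmogorov(en * d))))
    return TestResult(float(d), p, "ks_two_sample", n1, n2)


def ks_bruteforce(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Literal enumeration of all C(n1+n2, n1) pooled-rank arrangements.

    Exponential-time reference used to validate :func:`ks_two_sample` on
    tiny samples.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    d_obs = _ks_statistic_numerator(x, y)
    pooled = np.sort(np.concatenate([x, y]))
    hits = 0
    total = 0
    for pick in itertools.combinations(range(n1 + n2), n1):
        xs = pooled[list(pick)]
        ys = pooled[[i for i in range(n1 + n2) if i not in pick]]
        total += 1
        if _ks_statistic_numerator(xs, ys) >= d_obs:
            hits += 1
    return TestResult(d_obs / (n1 * n2), hits / total, "ks_two_sample", n1, n2)


# ---------------------------------------------------------------------------
# Pairwise test matrix (Table-1B-style)
# ---------------------------------------------------------------------------


def pairwise_test_matrix(
    cells: Sequence[LabeledCell],
    lamellae: Sequence[LamellaMeasurement],
    variant: str = "welch",
) -> pd.DataFrame:
    """Receptor x receptor p-value matrix.

    Upper triangle: t-test on per-lamella primary-fraction indicator
    replaced by the per-cell primary/secondary comparison via two-sample
    proportions is ill-posed with cells as replicates, so the comparison
    follows the per-lamella replicate convention: upper triangle compares
    primary-cell fractions per lamella, lower triangle per-lamella
    densities.
    """
    rids = sorted({c.receptor_id for c in cells})
    lam_ids = [l.lamella_id for l in lamellae]
    per_density: Dict[str, np.ndarray] = {}
    per_primary: Dict[str, np.ndarray] = {}
    for rid in rids:
        counts = {lid: 0 for lid in lam_ids}
        prim = {lid: 0 for lid in lam_ids}
        for c in cells:
            if c.receptor_id != rid:
                continue
            counts[c.lamella_id] += 1
            if c.lamella_type == "primary":
                prim[c.lamella_id] += 1
        per_density[rid] = np.array(
            [counts[l.lamella_id] / l.measured_length for l in lamellae]
        )
        per_primary[rid] = np.array(
            [prim[lid] / counts[lid] for lid in lam_ids if counts[lid] > 0]
        )
    mat = pd.DataFrame(np.nan, index=rids, columns=rids)
    for i, a in enumerate(rids):
        for j, b in enumerate(rids):
            if i < j:
                mat.loc[a, b] = t_test_two_sample(
                    per_primary[a], per_primary[b], variant
                ).p_value
            elif i > j:
                mat.loc[a, b] = t_test_two_sample(
                    per_density[a], per_density[b], variant
                ).p_value
    return mat


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

CELL_COLUMNS = [
    "section_id",
    "lamella_id",
    "lamella_type",
    "distance_from_apex_um",
    "lamella_length_um",
    "receptor_id",
]


def cells_to_frame(cells: Sequence[LabeledCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "section_id": c.section_id,
                "lamella_id": c.lamella_id,
                "lamella_type": c.lamella_type,
                "distance_from_apex_um": c.distance_from_apex,
                "lamella_length_um": c.parent_lamella_length,
                "receptor_id": c.receptor_id,
            }
            for c in cells
        ],
        columns=CELL_COLUMNS,
    )


def frame_to_cells(df: pd.DataFrame) -> List[LabeledCell]:
    return [
        LabeledCell(
            section_id=str(r.section_id),
            lamella_id=str(r.lamella_id),
            lamella_type=str(r.lamella_type),
            distance_from_apex=float(r.distance_from_apex_um),
            parent_lamella_length=float(r.lamella_length_um),
            receptor_id=str(r.receptor_id),
        )
        for r in df.itertuples()
    ]


def read_cells_tsv(path) -> List[LabeledCell]:
    return frame_to_cells(pd.read_csv(path, sep="\t"))


def read_lamellae_tsv(path) -> List[LamellaMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        LamellaMeasurement(
            lamella_id=str(r.lamella_id),
            measured_length=float(r.length_mm),
            section_id=str(getattr(r, "section_id", "")),
        )
        for r in df.itertuples()
    ]
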