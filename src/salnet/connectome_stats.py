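"""Edge-level connection-strength statistics and the network edge filter.

For every region pair and hemisphere the per-subject tract counts reduce to:
the number of subjects showing the connection, the mean count over those
subjects ("when present"), and the mean over the whole cohort ("across all
brains", i.e. mean_present * n_present / N). The laterality index is
(right - left) / (right + left) over the across-all-brains means; hemispheric
counts are compared with an uncorrected two-sided Wilcoxon rank-sum test.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "HemiStats", "EdgeStats", "NetworkModel",
    "CLUSTER_INSULAR_OPERCULAR", "CLUSTER_MIDDLE_CINGULATE", "CLUSTER_DLPFC",
    "FIBER_FAT", "FIBER_U", "FIBER_OTHER",
    "mean_present", "mean_all", "laterality_index", "rank_sum_p",
    "classify_edge", "build_network", "aggregate_counts", "round_half_up",
]

CLUSTER_INSULAR_OPERCULAR = "insular_opercular"
CLUSTER_MIDDLE_CINGULATE = "middle_cingulate"
CLUSTER_DLPFC = "dlpfc"
_KNOWN_CLUSTERS = {CLUSTER_INSULAR_OPERCULAR, CLUSTER_MIDDLE_CINGULATE, CLUSTER_DLPFC}

FIBER_FAT = "FAT"
FIBER_U = "U_fiber"
FIBER_OTHER = "Other"

_EXACT_RANKSUM_MAX_N = 12


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, matching the report formatting convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class HemiStats:
    n_present: int
    mean_present: float | None  # undefined when n_present = 0
    mean_all: float


@dataclass
class EdgeStats:
    pair: tuple[str, str]
    fiber_type: str
    left: HemiStats
    right: HemiStats
    li: float | None
    p: float | None


@dataclass
class NetworkModel:
    regions: dict[str, str]  # region -> cluster
    edges: list[EdgeStats]
    min_edge_strength: float = 10.0

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for r, c in self.regions.items():
            g.add_node(r, cluster=c)
        for e in self.edges:
            g.add_edge(*e.pair, fiber_type=e.fiber_type,
                       left_mean_all=e.left.mean_all, right_mean_all=e.right.mean_all,
                       li=float("nan") if e.li is None else e.li)
        return g

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            rows.append({
                "region_a": e.pair[0], "region_b": e.pair[1], "fiber_type": e.fiber_type,
                "left_n": e.left.n_present,
                "left_mean_present": _fmt(e.left.mean_present),
                "left_mean_all": round_half_up(e.left.mean_all),
                "right_n": e.right.n_present,
                "right_mean_present": _fmt(e.right.mean_present),
                "right_mean_all": round_half_up(e.right.mean_all),
                "li": _fmt(e.li), "p": _fmt(e.p),
            })
        return pd.DataFrame(rows)


def _fmt(v):
    # undefined quantities render as the dash the source table uses
    return "-" if v is None else round_half_up(v)


def mean_present(counts) -> tuple[int, float | None]:
    """(number of subjects with the connection, mean count over those subjects)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 1:
        raise ValueError("empty cohort")
    present = counts > 0
    n = int(present.sum())
    return n, (float(counts[present].mean()) if n else None)


def mean_all(mean_present_value: float | None, n_present: int, n_total: int) -> float:
    """Cohort-wide mean count: mean_present * n_present / N (0 when absent)."""
    if n_total == 0:
        raise ValueError("N must be positive")
    if not 0 <= n_present <= n_total:
        raise ValueError("n_present out of range")
    if n_present == 0:
        return 0.0
    return float(mean_present_value) * n_present / n_total


def laterality_index(left_mean_all: float, right_mean_all: float) -> float | None:
    """(R - L) / (R + L); None when both hemispheres are zero."""
    if left_mean_all < 0 or right_mean_all < 0:
        raise ValueError("tract averages must be non-negative")
    total = left_mean_all + right_mean_all
    if total == 0:
        return None
    return (right_mean_all - left_mean_all) / total


def _ranksum_exact(x: np.ndarray, y: np.ndarray) -> float:
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks handle ties
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(ranks)
    dev = abs(w_obs - mu)
    hits = total = 0
    for comb in itertools.combinations(range(len(ranks)), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


def _ranksum_normal(x: np.ndarray, y: np.ndarray) -> float:
    combined = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(combined)
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, t = np.unique(combined, return_counts=True)
    tie_term = ((t ** 3 - t).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        logger.warning("rank-sum on fully tied samples; p = 1.0")
        return 1.0
    z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
    return float(2.0 * sps.norm.sf(abs(z)))


def rank_sum_p(left_counts, right_counts) -> float:
    """Two-sided Wilcoxon rank-sum p, uncorrected for multiplicity.

    Exact enumeration of rank splits for combined n <= 12, normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(left_counts, dtype=float)
    y = np.asarray(right_counts, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        logger.warning("rank-sum on fully tied samples; p = 1.0")
        return 1.0
    if x.size + y.size <= _EXACT_RANKSUM_MAX_N:
        return _ranksum_exact(x, y)
    return _ranksum_normal(x, y)


def classify_edge(pair: tuple[str, str], cluster_map: dict[str, str]) -> str:
    """Cluster-rule fiber taxonomy.

    Insular-opercular <-> middle-cingulate pairs are FAT, within-cluster pairs
    are U-fibers, and any pair touching the DLPFC cluster is Other.
    """
    clusters = []
    for r in pair:
        if r not in cluster_map:
            raise ValueError(f"region {r!r} has no cluster assignment")
        c = cluster_map[r]
        if c not in _KNOWN_CLUSTERS:
            raise ValueError(f"unknown cluster {c!r} for region {r!r}")
        clusters.append(c)
    a, b = clusters
    if CLUSTER_DLPFC in (a, b):
        return FIBER_OTHER
    if a == b:
        return FIBER_U
    return FIBER_FAT


def aggregate_counts(counts_frame: pd.DataFrame, cluster_map: dict[str, str],
                     n_subjects: int) -> list[EdgeStats]:
    """Reduce a per-subject counts table to EdgeStats per region pair.

    ``counts_frame`` columns: subject, region_a, region_b, hemisphere, count.
    Pairs never observed in any subject get zero-count vectors.
    """
    subjects = sorted(counts_frame["subject"].unique())
    if len(subjects) > n_subjects:
        raise ValueError("more subjects in table than cohort size N")
    regions = sorted(cluster_map)
    lut: dict[tuple, dict] = {}
    for row in counts_frame.itertuples(index=False):
        a, b = sorted((row.region_a, row.region_b))
        lut.setdefault((a, b, row.hemisphere), {})[row.subject] = int(row.count)

    out = []
    for a, b in itertools.combinations(regions, 2):
        hemi = {}
        counts = {}
        for h in ("L", "R"):
            per = lut.get((a, b, h), {})
            vec = np.array([per.get(s, 0) for s in subjects] +
                           [0] * (n_subjects - len(subjects)), dtype=float)
            n, mp = mean_present(vec)
            hemi[h] = HemiStats(n_present=n, mean_present=mp,
                                mean_all=mean_all(mp, n, n_subjects))
            counts[h] = vec
        li = laterality_index(hemi["L"].mean_all, hemi["R"].mean_all)
        p = rank_sum_p(counts["L"], counts["R"]) if li is not None else None
        out.append(EdgeStats(pair=(a, b), fiber_type=classify_edge((a, b), cluster_map),
                             left=hemi["L"], right=hemi["R"], li=li, p=p))
    return out


def build_network(edge_stats: list[EdgeStats], cluster_map: dict[str, str],
                  min_edge_strength: float = 10.0) -> NetworkModel:
    """Retain edges whose across-all-brains mean reaches the threshold in
    at least one hemisphere."""
    if min_edge_strength < 0:
        raise ValueError("min_edge_strength must be >= 0")
    kept = [e for e in edge_stats
            if e.left.mean_all >= min_edge_strength or e.right.mean_all >= min_edge_strength]
    return NetworkModel(regions=dict(cluster_map), edges=kept,
                        min_edge_strength=min_edge_strength)
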