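"""RIL linkage-map construction.

From a genotype-call matrix (markers x RILs, internal codes A/B/H/U with A =
parent-1 homozygote) the pipeline selects parent-polymorphic markers, removes
markers with distorted 1:1 segregation (chi-squared, P < 0.01), collapses
duplicate markers into bins, estimates pairwise recombination fractions with
the selfed-RIL correction r = R / (2(1-R)) (observed R = 2r/(1+2r)), groups
markers by transitive closure over r <= 0.35 and LOD >= 6, orders each group
by greedy seriation plus a window-4 ripple minimising the sum of adjacent
recombination fractions, and converts adjacent-pair r to cM with the Kosambi
mapping function d = 25 ln((1+2r)/(1-2r)).
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .models import GeneticMap, LinkageGroup, PairwiseLinkage

R_CAP = 0.4999


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM, for 0 <= r < 0.5."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Meiotic r for a Kosambi distance: r = tanh(d/50) / 2."""
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(d_cm / 50.0)


def ril_observed_fraction(r: float) -> float:
    """Observed recombinant fraction in selfed RILs: R = 2r / (1 + 2r)."""
    return 2 * r / (1 + 2 * r)


def ril_corrected_r(big_r: float) -> float:
    """Invert R = 2r/(1+2r): r = R / (2(1-R)), capped just below 0.5."""
    if big_r >= 1.0:
        return R_CAP
    return min(big_r / (2 * (1 - big_r)), R_CAP)


def select_parent_polymorphic(
    calls: pd.DataFrame, parent1: str, parent2: str
) -> pd.DataFrame:
    """Keep markers whose parents are called, homozygous and different.

    Returns the progeny matrix (parent columns dropped) recoded so that 'A'
    is the parent-1 allele at every marker.
    """
    p1 = calls[parent1]
    p2 = calls[parent2]
    keep = p1.isin(["A", "B"]) & p2.isin(["A", "B"]) & (p1 != p2)
    sub = calls.loc[keep].drop(columns=[parent1, parent2])
    flip = p1.loc[keep] == "B"
    if flip.any():
        sub = sub.copy()
        swapped = sub.loc[flip].replace({"A": "B", "B": "A"})
        sub.loc[flip] = swapped
    return sub


def segregation_chi2(n_a: int, n_b: int) -> tuple[float, float]:
    """Chi-squared test of 1:1 segregation: chi2 = (nA-nB)^2/(nA+nB), 1 df."""
    total = n_a + n_b
    if total <= 0:
        raise ValueError("no informative calls")
    chi2 = (n_a - n_b) ** 2 / total
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def filter_segregation(calls: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Remove markers whose A:B counts deviate from 1:1 at p < alpha."""
    keep = []
    for marker, row in calls.iterrows():
        n_a = int((row == "A").sum())
        n_b = int((row == "B").sum())
        if n_a + n_b == 0:
            continue
        _, p = segregation_chi2(n_a, n_b)
        if p >= alpha:
            keep.append(marker)
    return calls.loc[keep]


def _encode(calls: pd.DataFrame) -> np.ndarray:
    """A -> +1, B -> -1, H/U -> 0 (het and missing are non-informative)."""
    arr = np.zeros(calls.shape, dtype=np.int8)
    vals = calls.to_numpy()
    arr[vals == "A"] = 1
    arr[vals == "B"] = -1
    return arr


def bin_duplicates(
    calls: pd.DataFrame, min_joint_coverage: float = 0.5
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Collapse duplicate markers to one representative per bin.

    Two markers are duplicates when their calls agree on every jointly
    non-missing RIL and their joint coverage is at least
    ``min_joint_coverage``.  Bins are the connected components of this
    relation; the representative is the first marker in input order (input
    order follows genome position in this pipeline).
    """
    vals = calls.to_numpy()
    n_markers, n_samples = vals.shape
    codes = np.zeros(vals.shape, dtype=np.int8)
    codes[vals == "A"] = 1
    codes[vals == "B"] = 2
    codes[vals == "H"] = 3
    called = codes > 0

    rows, cols = [], []
    for i in range(n_markers):
        for j in range(i + 1, n_markers):
            joint = called[i] & called[j]
            nj = int(joint.sum())
            if nj / n_samples < min_joint_coverage:
                continue
            if np.array_equal(codes[i][joint], codes[j][joint]):
                rows.append(i)
                cols.append(j)
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_markers, n_markers)
    )
    n_comp, labels = connected_components(adj, directed=False)
    bin_map: dict[str, list[str]] = {}
    reps: list[str] = []
    names = list(calls.index)
    for comp in range(n_comp):
        members = [names[i] for i in np.flatnonzero(labels == comp)]
        rep = members[0]
        reps.append(rep)
        bin_map[rep] = members
    reps = [m for m in names if m in set(bin_map)]
    return calls.loc[reps], bin_map


def pairwise_lod(big_r: float, n: int) -> float:
    """Two-point LOD for linkage vs independence at observed fraction R.

    LOD = n [R log10 R + (1-R) log10(1-R) + log10 2], with 0 log 0 = 0;
    set to 0 for R >= 0.5 (no support for linkage in repulsion).
    """
    if n <= 0:
        raise ValueError("need at least one informative pair")
    if big_r >= 0.5:
        return 0.0
    terms = math.log10(2.0)
    if big_r > 0:
        terms += big_r * math.log10(big_r)
    if big_r < 1:
        terms += (1 - big_r) * math.log10(1 - big_r)
    return n * terms


def estimate_rf_ril(
    calls_i: Sequence[str], calls_j: Sequence[str], names: tuple[str, str] = ("i", "j")
) -> PairwiseLinkage:
    """Two-point linkage between two markers in a RIL population.

    Only RILs homozygous at both markers are informative; het and missing
    calls are excluded.
    """
    pairs = [
        (a, b)
        for a, b in zip(calls_i, calls_j)
        if a in ("A", "B") and b in ("A", "B")
    ]
    n = len(pairs)
    if n == 0:
        raise ValueError("no jointly informative RILs")
    rec = sum(1 for a, b in pairs if a != b)
    big_r = rec / n
    return PairwiseLinkage(
        marker_i=names[0],
        marker_j=names[1],
        n_informative=n,
        big_r=big_r,
        r=ril_corrected_r(big_r),
        lod=pairwise_lod(big_r, n),
    )


def pairwise_matrices(
    calls: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised all-pairs (R, corrected r, LOD) matrices.

    Entries with no jointly informative RILs hold R = nan, r = R_CAP and
    LOD = 0.
    """
    x = _encode(calls).astype(np.float64)
    info = np.abs(x)
    n_inf = info @ info.T
    dot = x @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        big_r = (n_inf - dot) / (2 * n_inf)
    big_r[n_inf == 0] = np.nan

    r = np.full_like(big_r, R_CAP)
    ok = ~np.isnan(big_r)
    rr = big_r[ok]
    r[ok] = np.minimum(rr / (2 * np.maximum(1 - rr, 1e-12)), R_CAP)

    lod = np.zeros_like(big_r)
    linked = ok & (big_r < 0.5)
    rl = big_r[linked]
    with np.errstate(invalid="ignore", divide="ignore"):
        term = np.where(rl > 0, rl * np.log10(np.maximum(rl, 1e-300)), 0.0) + (
            1 - rl
        ) * np.log10(np.maximum(1 - rl, 1e-300)) + math.log10(2.0)
    lod[linked] = n_inf[linked] * term
    return big_r, r, lod


def group_markers(
    r: np.ndarray,
    lod: np.ndarray,
    names: Sequence[str],
    rf_max: float = 0.35,
    lod_min: float = 6.0,
) -> list[list[str]]:
    """Single-linkage transitive closure over pairs with r <= rf_max and
    LOD >= lod_min.  Groups are returned largest-first, ties by first marker."""
    adj = (r <= rf_max) & (lod >= lod_min)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        groups.append([names[i] for i in idx])
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _sarf(order: Sequence[int], r: np.ndarray) -> float:
    return float(sum(r[a, b] for a, b in zip(order, order[1:])))


def order_markers(
    member_idx: Sequence[int],
    r: np.ndarray,
    genome_rank: Sequence[int] | None = None,
    ripple_window: int = 4,
) -> list[int]:
    """Order a linkage group minimising the sum of adjacent rf (SARF).

    Greedy nearest-neighbour seriation from every start, keeping the best,
    then ripple: exhaustive permutation of every sliding window, repeated to
    convergence.  For groups no larger than the ripple window this is exact.
    The output is oriented so the marker with the smallest genome rank is
    nearest position 0 (falls back to index order when ranks are not given).
    """
    members = list(member_idx)
    k = len(members)
    if k <= 1:
        return members
    sub = r[np.ix_(members, members)]

    best_order: list[int] | None = None
    best_cost = math.inf
    for start in range(k):
        left = set(range(k)) - {start}
        path = [start]
        while left:
            cur = path[-1]
            nxt = min(left, key=lambda j: sub[cur, j])
            path.append(nxt)
            left.remove(nxt)
        cost = _sarf(path, sub)
        if cost < best_cost:
            best_cost = cost
            best_order = path
    order = list(best_order)  # type: ignore[arg-type]

    w = min(ripple_window, k)
    improved = True
    while improved:
        improved = False
        for s in range(0, k - w + 1):
            window = order[s : s + w]
            base = order[:s]
            tail = order[s + w :]
            for perm in itertools.permutations(window):
                trial = base + list(perm) + tail
                if _sarf(trial, sub) < _sarf(order, sub) - 1e-12:
                    order = trial
                    improved = True

    ranks = list(genome_rank) if genome_rank is not None else members
    rank_of = {local: ranks[local] for local in range(k)}
    if rank_of[order[0]] > rank_of[order[-1]]:
        order = order[::-1]
    return [members[i] for i in order]


def build_map(
    calls: pd.DataFrame,
    rf_max: float = 0.35,
    lod_min: float = 6.0,
    min_group_size: int = 2,
    seg_alpha: float = 0.01,
    group_prefix: str = "LG",
) -> tuple[GeneticMap, dict[str, list[str]]]:
    """Full map construction from a parent-recoded progeny call matrix.

    Applies segregation filtering, duplicate binning, grouping, ordering and
    Kosambi distances.  Groups smaller than ``min_group_size`` are dropped
    (unlinked singletons).  Returns the map and the duplicate-bin map.
    """
    kept = filter_segregation(calls, alpha=seg_alpha)
    binned, bin_map = bin_duplicates(kept)
    names = list(binned.index)
    _, r, lod = pairwise_matrices(binned)
    groups = group_markers(r, lod, names, rf_max=rf_max, lod_min=lod_min)
    name_to_idx = {m: i for i, m in enumerate(names)}
    genome_rank = {m: i for i, m in enumerate(calls.index)}

    lg_list = []
    gi = 0
    for members in groups:
        if len(members) < min_group_size:
            continue
        gi += 1
        idx = [name_to_idx[m] for m in members]
        ordered_idx = order_markers(
            idx, r, genome_rank=[genome_rank[names[i]] for i in idx]
        )
        ordered = [names[i] for i in ordered_idx]
        pos = [0.0]
        for a, b in zip(ordered_idx, ordered_idx[1:]):
            pos.append(pos[-1] + kosambi_cm(min(r[a, b], R_CAP)))
        lg_list.append(
            LinkageGroup(
                name=f"{group_prefix}{gi:02d}", markers=ordered, positions_cm=pos
            )
        )
    return GeneticMap(groups=lg_list), bin_map


def summarize_group_stats(
    names: Sequence[str],
    counts: Sequence[int],
    lengths_cm: Sequence[float],
) -> dict:
    """Per-group and total map statistics from marker counts and lengths.

    Returns counts, lengths, densities (markers/cM; None where length is 0),
    totals, per-group averages and the overall density.
    """
    if not (len(names) == len(counts) == len(lengths_cm)):
        raise ValueError("names, counts and lengths must align")
    densities = [
        (c / l if l > 0 else None) for c, l in zip(counts, lengths_cm)
    ]
    total_markers = int(sum(counts))
    total_length = float(sum(lengths_cm))
    n_groups = len(names)
    return {
        "groups": list(names),
        "counts": [int(c) for c in counts],
        "lengths_cm": [float(x) for x in lengths_cm],
        "densities": densities,
        "total_markers": total_markers,
        "total_length_cm": total_length,
        "mean_markers_per_group": total_markers / n_groups if n_groups else 0.0,
        "mean_length_cm": total_length / n_groups if n_groups else 0.0,
        "overall_density": (
            total_markers / total_length if total_length > 0 else None
        ),
    }


def map_summary(gmap: GeneticMap) -> dict:
    """Summary statistics of a constructed genetic map."""
    return summarize_group_stats(
        [g.name for g in gmap.groups],
        [g.n_markers for g in gmap.groups],
        [g.length_cm for g in gmap.groups],
    )
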