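"""Inclusive composite interval mapping, additive model (ICIM-ADD).

The procedure for a RIL population:

1. stepwise forward-backward linear regression of the phenotype on all
   markers (coded +1 / -1 for the two homozygotes, 0 for het/missing) with
   entry/exit F-test probabilities p_in = 0.001, p_out = 0.002 picks cofactor
   markers;
2. for each scanned interval the phenotype is adjusted by subtracting the
   fitted effects of every selected cofactor EXCEPT the interval's two
   flanking markers;
3. the genome is walked at a 1-cM step; at each position the expected QTL
   genotype is interpolated from the flanking markers (no-double-crossover
   convention) and regressed on the adjusted phenotype, giving
   LOD = (n/2) log10(RSS0/RSS1), the additive effect (regression slope on
   the +/-1 coding) and PVE = 100 (1 - RSS1/RSS0);
4. the genome-wide LOD threshold is the 100(1-alpha) percentile of the
   maximum LOD over phenotype permutations (1000 permutations, alpha 0.05,
   seeded);
5. peaks above threshold become QTLs with a 1-LOD support interval; peaks
   within 5 cM merge into the higher one;
6. across environments a QTL is robust when PVE > 10 (strict), stable when
   the same trait maps within 10 cM in two or more locations, consistent
   when in two or more years.
"""

from __future__ import annotations

import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneticMap, QtlResult, ScanProfile

CODE_VALUE = {"A": 1.0, "B": -1.0, "H": 0.0, "U": 0.0}


def code_genotypes(calls: pd.DataFrame) -> pd.DataFrame:
    """Markers x RILs call matrix to the +/-1 additive coding (H/U -> 0)."""
    return calls.apply(lambda col: col.map(CODE_VALUE)).astype(float)


def _ols_rss(y: np.ndarray, x_mat: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of y on [1, x_mat]; returns coefficients (incl. intercept) and RSS."""
    n = len(y)
    design = np.column_stack([np.ones(n), x_mat]) if x_mat.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def stepwise_select(
    x: pd.DataFrame,
    y: np.ndarray,
    p_in: float = 0.001,
    p_out: float = 0.002,
    max_steps: int = 50,
) -> tuple[list[str], dict[str, float]]:
    """Forward-backward stepwise regression on +/-1-coded markers.

    ``x`` is samples x markers.  Entry uses the partial F-test at p_in, exit
    at p_out.  Collinear candidates (no residual variance after projection on
    the current model) never enter, so of two duplicate markers exactly one
    can be selected.  Returns selected marker names and their coefficients
    from the final joint fit (intercept under key "(intercept)").
    """
    n, m = x.shape
    cols = list(x.columns)
    xv = x.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        return [], {"(intercept)": float(y.mean()) if n else 0.0}

    selected: list[int] = []
    for _ in range(max_steps):
        x_sel = xv[:, selected]
        _, rss_cur = _ols_rss(y, x_sel)
        design = np.column_stack([np.ones(n), x_sel])
        q, _ = np.linalg.qr(design)
        resid_y = y - q @ (q.T @ y)
        resid_x = xv - q @ (q.T @ xv)
        ss_x = np.einsum("ij,ij->j", resid_x, resid_x)
        dof = n - len(selected) - 2
        if dof <= 0:
            break
        with np.errstate(invalid="ignore", divide="ignore"):
            extra = (resid_x.T @ resid_y) ** 2 / ss_x
        extra[ss_x < 1e-8 * n] = 0.0
        for j in selected:
            extra[j] = 0.0
        rss_new = rss_cur - extra
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat = extra / (rss_new / dof)
        f_stat[~np.isfinite(f_stat)] = 0.0
        p_vals = stats.f.sf(f_stat, 1, dof)
        best = int(np.argmin(p_vals))
        if p_vals[best] >= p_in or extra[best] <= 0:
            break
        selected.append(best)

        # backward elimination
        while len(selected) > 1:
            x_sel = xv[:, selected]
            _, rss_full = _ols_rss(y, x_sel)
            dof_b = n - len(selected) - 1
            worst_p, worst_k = -1.0, -1
            for k in range(len(selected)):
                rest = [s for idx, s in enumerate(selected) if idx != k]
                _, rss_drop = _ols_rss(y, xv[:, rest])
                f_k = (rss_drop - rss_full) / (rss_full / dof_b)
                p_k = float(stats.f.sf(max(f_k, 0.0), 1, dof_b))
                if p_k > worst_p:
                    worst_p, worst_k = p_k, k
            if worst_p > p_out:
                del selected[worst_k]
            else:
                break

    names = [cols[j] for j in selected]
    beta, _ = _ols_rss(y, xv[:, selected])
    coefs = {"(intercept)": float(beta[0])}
    for name, b in zip(names, beta[1:]):
        coefs[name] = float(b)
    return names, coefs


def adjust_phenotype(
    y: np.ndarray,
    x: pd.DataFrame,
    selected: Sequence[str],
    coefs: dict[str, float],
    exclude: Sequence[str] = (),
) -> np.ndarray:
    """Subtract fitted cofactor effects, keeping the excluded (flanking) ones."""
    y_adj = np.asarray(y, dtype=float).copy()
    excl = set(exclude)
    for name in selected:
        if name in excl:
            continue
        y_adj -= coefs[name] * x[name].to_numpy(dtype=float)
    return y_adj


def _group_positions(length: float, step: float) -> np.ndarray:
    pos = np.arange(0.0, length + 1e-9, step)
    if pos.size == 0 or pos[-1] < length - 1e-9:
        pos = np.append(pos, length)
    return pos


def _interp_coding(
    xg: np.ndarray, marker_pos: np.ndarray, scan_pos: np.ndarray
) -> np.ndarray:
    """Expected QTL coding at scan positions from flanking markers.

    ``xg`` is samples x markers for one ordered group.  Linear interpolation
    between the flanking marker codings (the no-double-crossover expected
    genotype); at a marker position this is the marker coding itself.
    """
    out = np.empty((xg.shape[0], scan_pos.size))
    for k, p in enumerate(scan_pos):
        j = int(np.searchsorted(marker_pos, p, side="right"))
        if j <= 0:
            out[:, k] = xg[:, 0]
        elif j >= marker_pos.size:
            out[:, k] = xg[:, -1]
        else:
            left, right = marker_pos[j - 1], marker_pos[j]
            if right - left <= 1e-12:
                out[:, k] = xg[:, j - 1]
            else:
                w = (p - left) / (right - left)
                out[:, k] = (1 - w) * xg[:, j - 1] + w * xg[:, j]
    return out


def _regress_position(y: np.ndarray, xq: np.ndarray) -> tuple[float, float, float]:
    """LOD, additive effect and PVE of y ~ xq with intercept."""
    n = len(y)
    yc = y - y.mean()
    xc = xq - xq.mean()
    rss0 = float(yc @ yc)
    ssx = float(xc @ xc)
    if rss0 <= 0:
        raise ValueError("zero residual variance in phenotype")
    if ssx <= 1e-12:
        return 0.0, 0.0, 0.0
    slope = float(xc @ yc) / ssx
    rss1 = rss0 - slope**2 * ssx
    rss1 = max(rss1, 1e-300)
    lod = (n / 2.0) * math.log10(rss0 / rss1)
    pve = 100.0 * (1.0 - rss1 / rss0)
    return lod, slope, pve


def interval_scan(
    y: np.ndarray,
    gmap: GeneticMap,
    calls: pd.DataFrame,
    selected: Sequence[str] = (),
    coefs: dict[str, float] | None = None,
    step: float = 1.0,
    trait: str = "trait",
    location: str = "loc",
    year: str = "year",
) -> ScanProfile:
    """Walk the map at ``step`` cM computing LOD / additive effect / PVE.

    For every scanned position the phenotype is first adjusted for all
    selected cofactors except the two markers flanking the position's
    interval.
    """
    coefs = coefs or {}
    x = code_genotypes(calls).T  # samples x markers
    sel_set = set(selected)

    groups, positions, lods, adds, pves = [], [], [], [], []
    for lg in gmap.groups:
        marker_pos = np.asarray(lg.positions_cm)
        xg = x[lg.markers].to_numpy()
        scan_pos = _group_positions(lg.length_cm, step)
        xq = _interp_coding(xg, marker_pos, scan_pos)
        for k, p in enumerate(scan_pos):
            j = int(np.searchsorted(marker_pos, p, side="right"))
            lo = max(j - 1, 0)
            hi = min(j, len(lg.markers) - 1)
            flanks = {lg.markers[lo], lg.markers[hi]} & sel_set
            y_adj = adjust_phenotype(y, x, selected, coefs, exclude=flanks)
            lod, a, pve = _regress_position(y_adj, xq[:, k])
            groups.append(lg.name)
            positions.append(float(p))
            lods.append(lod)
            adds.append(a)
            pves.append(pve)
    return ScanProfile(
        trait=trait,
        location=location,
        year=year,
        groups=groups,
        positions_cm=positions,
        lod=lods,
        additive=adds,
        pve=pves,
    )


def icim_scan(
    y: np.ndarray,
    gmap: GeneticMap,
    calls: pd.DataFrame,
    p_in: float = 0.001,
    p_out: float = 0.002,
    step: float = 1.0,
    **meta: str,
) -> ScanProfile:
    """Stepwise cofactor selection followed by the cofactor-adjusted scan."""
    x = code_genotypes(calls).T
    selected, coefs = stepwise_select(x, y, p_in=p_in, p_out=p_out)
    return interval_scan(
        y, gmap, calls, selected=selected, coefs=coefs, step=step, **meta
    )


def _max_lod_batch(
    gmap: GeneticMap, calls: pd.DataFrame, ys: np.ndarray, step: float
) -> np.ndarray:
    """Genome-wide max LOD for many phenotype columns, no cofactors.

    ``ys`` is samples x n_phenotypes.  Used for the plain-interval-mapping
    fast path of the permutation test.
    """
    x = code_genotypes(calls).T
    n = ys.shape[0]
    yc = ys - ys.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", yc, yc)
    max_lod = np.zeros(ys.shape[1])
    for lg in gmap.groups:
        marker_pos = np.asarray(lg.positions_cm)
        xg = x[lg.markers].to_numpy()
        scan_pos = _group_positions(lg.length_cm, step)
        xq = _interp_coding(xg, marker_pos, scan_pos)
        xc = xq - xq.mean(axis=0)
        ssx = np.einsum("ij,ij->j", xc, xc)
        cross = xc.T @ yc  # positions x phenotypes
        with np.errstate(invalid="ignore", divide="ignore"):
            rss1 = rss0[None, :] - cross**2 / np.maximum(ssx, 1e-12)[:, None]
        rss1 = np.maximum(rss1, 1e-300)
        lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
        lod[ssx <= 1e-12, :] = 0.0
        max_lod = np.maximum(max_lod, lod.max(axis=0))
    return max_lod


def permutation_threshold(
    y: np.ndarray,
    gmap: GeneticMap,
    calls: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    p_in: float = 0.001,
    p_out: float = 0.002,
    step: float = 1.0,
) -> float:
    """Genome-wide LOD threshold from phenotype permutations.

    Each permutation reruns the full ICIM procedure (stepwise selection plus
    adjusted scan); permutations where the stepwise pass selects no cofactor
    reduce to plain interval mapping and are evaluated on a vectorised fast
    path.  The threshold is the 100(1-alpha) percentile of the per-
    permutation genome-wide maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = code_genotypes(calls).T

    plain_cols = []
    maxima = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y[perm]
        selected, coefs = stepwise_select(x, yp, p_in=p_in, p_out=p_out)
        if not selected:
            plain_cols.append(yp)
        else:
            prof = interval_scan(
                yp, gmap, calls, selected=selected, coefs=coefs, step=step
            )
            maxima.append(max(prof.lod))
    if plain_cols:
        batch = _max_lod_batch(gmap, calls, np.column_stack(plain_cols), step)
        maxima.extend(batch.tolist())
    return float(np.quantile(np.asarray(maxima), 1.0 - alpha))


def call_qtls(
    profile: ScanProfile,
    threshold: float,
    merge_cm: float = 5.0,
    support_drop: float = 1.0,
) -> list[QtlResult]:
    """Local LOD maxima above threshold, with 1-LOD support intervals.

    Peaks on the same group closer than ``merge_cm`` collapse into the
    higher peak.
    """
    results: list[QtlResult] = []
    df = pd.DataFrame(
        {
            "group": profile.groups,
            "pos": profile.positions_cm,
            "lod": profile.lod,
            "add": profile.additive,
            "pve": profile.pve,
        }
    )
    for group, sub in df.groupby("group", sort=False):
        sub = sub.reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        k = len(lod)
        peaks = [
            i
            for i in range(k)
            if lod[i] >= threshold
            and (i == 0 or lod[i] >= lod[i - 1])
            and (i == k - 1 or lod[i] >= lod[i + 1])
        ]
        # merge nearby peaks into the higher one
        peaks.sort(key=lambda i: -lod[i])
        kept: list[int] = []
        for i in peaks:
            if all(
                abs(sub["pos"][i] - sub["pos"][j]) > merge_cm for j in kept
            ):
                kept.append(i)
        for i in sorted(kept):
            lo = i
            while lo > 0 and lod[lo - 1] > lod[i] - support_drop:
                lo -= 1
            hi = i
            while hi < k - 1 and lod[hi + 1] > lod[i] - support_drop:
                hi += 1
            results.append(
                QtlResult(
                    trait=profile.trait,
                    location=profile.location,
                    year=profile.year,
                    group=group,
                    peak_cm=float(sub["pos"][i]),
                    interval_cm=(float(sub["pos"][lo]), float(sub["pos"][hi])),
                    lod=float(lod[i]),
                    additive=float(sub["add"][i]),
                    pve=float(sub["pve"][i]),
                )
            )
    return results


def categorize_qtls(
    results: Sequence[QtlResult],
    robust_pve: float = 10.0,
    co_window_cm: float = 10.0,
) -> list[QtlResult]:
    """Flag robust / stable / consistent QTLs across environments.

    Robust: PVE strictly above ``robust_pve`` percent.  Stable: the same
    trait maps to peaks within ``co_window_cm`` on the same group in at
    least two distinct locations.  Consistent: likewise in at least two
    distinct years.
    """
    results = list(results)
    for q in results:
        q.robust = q.pve > robust_pve
        q.stable = False
        q.consistent = False
    for i, a in enumerate(results):
        for b in results[i + 1 :]:
            if (
                a.trait == b.trait
                and a.group == b.group
                and abs(a.peak_cm - b.peak_cm) <= co_window_cm
            ):
                if a.location != b.location:
                    a.stable = b.stable = True
                if a.year != b.year:
                    a.consistent = b.consistent = True
    return results
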