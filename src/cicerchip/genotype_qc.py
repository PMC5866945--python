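"""Axiom-style genotype quality control.

Sample-level filters (dish QC, call rate) and per-SNP cluster-geometry
metrics with category assignment.  A SNP's genotype clusters are summarised
as mean/SD of the contrast axis (x, allele ratio) and size axis (y, signal
intensity); from these the pipeline computes

* FLD  - Fisher's linear discriminant: separation of the heterozygote
  cluster from the nearest homozygote cluster in contrast space, in pooled-SD
  units;
* HetSO - heterozygote strength offset: vertical (size-axis) offset of the
  het cluster mean from the chord joining the two homozygote cluster means;
* HomRO - homozygote ratio offset: signed contrast-axis distance of the
  homozygote cluster(s) from zero, positive on the expected side (AA
  positive, BB negative).

Default cutoffs follow the vendor's diploid defaults: call rate >= 97%,
FLD >= 3.6, HetSO >= -0.1, HetSO-OTV >= -0.3, HomRO >= 0.6 (one cluster) /
>= 0.3 (two or three clusters).  The FLD/HetSO/HomRO formulas are stated
explicitly above because the upstream tool does not publish them; every
cutoff is configurable.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass, field

from .models import SNP_CATEGORIES, ClusterSummary, SampleQc, SnpQcMetrics

HOM_LABELS = ("AA", "BB")


@dataclass
class QcThresholds:
    dqc_min: float = 0.82
    sample_cr_min: float = 0.97
    snp_cr_min: float = 0.97
    fld_min: float = 3.6
    hom_fld_min: float = 6.5
    het_so_min: float = -0.1
    het_so_otv_min: float = -0.3
    hom_ro_1_min: float = 0.6   # single-cluster (monomorphic) cutoff
    hom_ro_2_min: float = 0.3   # two/three-cluster cutoff
    minor_hom_min: int = 2
    var_x_max: float = 0.25
    var_y_max: float = 0.25
    otv_cluster_fraction: float = 0.05
    # Upstream allele-caller metadata, recorded only (calls are taken as given)
    inbred_penalty: int = 12


def filter_samples(
    samples: Sequence[SampleQc],
    dqc_min: float = 0.82,
    cr_min: float = 0.97,
) -> tuple[list[SampleQc], dict[str, list[str]]]:
    """Two-stage sample QC: DQC < dqc_min first, then call rate < cr_min.

    Equality retains (the thresholds are strict "below" removals).  Returns
    the retained samples and a removal log keyed by stage.
    """
    log: dict[str, list[str]] = {"dqc": [], "call_rate": []}
    dqc_pass = []
    for s in samples:
        if s.dqc < dqc_min:
            log["dqc"].append(s.sample_id)
        else:
            dqc_pass.append(s)
    retained = []
    for s in dqc_pass:
        if s.call_rate < cr_min:
            log["call_rate"].append(s.sample_id)
        else:
            retained.append(s)
    return retained, log


def _by_genotype(clusters: Sequence[ClusterSummary]) -> dict[str, ClusterSummary]:
    out: dict[str, ClusterSummary] = {}
    for c in clusters:
        if c.genotype in out:
            raise ValueError(f"duplicate cluster for genotype {c.genotype}")
        out[c.genotype] = c
    return out


def _pooled_sd(clusters: Sequence[ClusterSummary]) -> float:
    return math.sqrt(sum(c.sd_x**2 for c in clusters) / len(clusters))


def compute_fld(clusters: Sequence[ClusterSummary]) -> float:
    """FLD: min over homozygote clusters of |x_het - x_hom| / pooled SD.

    Pooled SD is the root mean within-cluster contrast variance over the
    present genotype clusters.  Requires a het cluster and at least one
    homozygote cluster; use :func:`compute_hom_fld` for het-free SNPs.
    """
    by = _by_genotype(clusters)
    if "AB" not in by:
        raise ValueError("no heterozygote cluster; FLD not applicable")
    homs = [by[g] for g in HOM_LABELS if g in by]
    if not homs:
        raise ValueError("need at least one homozygote cluster")
    present = [by[g] for g in ("AA", "AB", "BB") if g in by]
    sd = _pooled_sd(present)
    if sd == 0:
        raise ValueError("zero pooled SD")
    return min(abs(by["AB"].mean_x - h.mean_x) for h in homs) / sd


def compute_hom_fld(clusters: Sequence[ClusterSummary]) -> float:
    """Homozygote FLD: |x_AA - x_BB| / pooled SD for two-hom-cluster SNPs."""
    by = _by_genotype(clusters)
    if not all(g in by for g in HOM_LABELS):
        raise ValueError("need both homozygote clusters")
    present = [by[g] for g in ("AA", "AB", "BB") if g in by]
    sd = _pooled_sd(present)
    if sd == 0:
        raise ValueError("zero pooled SD")
    return abs(by["AA"].mean_x - by["BB"].mean_x) / sd


def compute_het_so(clusters: Sequence[ClusterSummary]) -> float:
    """HetSO: size-axis offset of the het mean from the homozygote chord.

    With homozygote cluster means (x1, y1), (x2, y2) and het mean (xh, yh),
    HetSO = yh - [y1 + (xh - x1) * (y2 - y1) / (x2 - x1)].
    """
    by = _by_genotype(clusters)
    if not all(g in by for g in ("AA", "AB", "BB")):
        raise ValueError("HetSO requires all three genotype clusters")
    a, h, b = by["AA"], by["AB"], by["BB"]
    if a.mean_x == b.mean_x:
        raise ValueError("degenerate chord: homozygote contrasts equal")
    chord_y = a.mean_y + (h.mean_x - a.mean_x) * (b.mean_y - a.mean_y) / (
        b.mean_x - a.mean_x
    )
    return h.mean_y - chord_y


def compute_hom_ro(clusters: Sequence[ClusterSummary]) -> float:
    """HomRO: signed min over homozygote clusters of distance from x = 0.

    AA is expected at positive contrast and BB at negative contrast; a
    cluster on its expected side contributes a positive value, a cluster on
    the wrong side a negative one.
    """
    by = _by_genotype(clusters)
    vals = []
    if "AA" in by:
        vals.append(by["AA"].mean_x)
    if "BB" in by:
        vals.append(-by["BB"].mean_x)
    if not vals:
        raise ValueError("need at least one homozygote cluster")
    return min(vals)


def compute_snp_metrics(
    snp_id: str,
    calls: Sequence[str],
    clusters: Sequence[ClusterSummary],
    thresholds: QcThresholds | None = None,
) -> SnpQcMetrics:
    """Assemble per-SNP QC metrics from calls and cluster summaries.

    ``calls`` use the internal {A, B, H, U} alphabet.  The OTV flag is set
    when an extra low-size ("OTV") cluster holds at least
    ``otv_cluster_fraction`` of the samples and HetSO is computable.
    """
    th = thresholds or QcThresholds()
    n = len(calls)
    n_called = sum(1 for c in calls if c != "U")
    call_rate = n_called / n if n else 0.0

    geno_clusters = [c for c in clusters if c.genotype in ("AA", "AB", "BB")]
    by = _by_genotype(geno_clusters)
    n_clusters = len(by)
    total_in_clusters = sum(c.n for c in clusters)

    fld = hom_fld = het_so = hom_ro = None
    if "AB" in by and any(g in by for g in HOM_LABELS):
        try:
            fld = compute_fld(geno_clusters)
        except ValueError:
            fld = None
    if all(g in by for g in HOM_LABELS):
        try:
            hom_fld = compute_hom_fld(geno_clusters)
        except ValueError:
            hom_fld = None
    if n_clusters == 3:
        try:
            het_so = compute_het_so(geno_clusters)
        except ValueError:
            het_so = None
    if any(g in by for g in HOM_LABELS):
        hom_ro = compute_hom_ro(geno_clusters)

    n_a = sum(1 for c in calls if c == "A")
    n_b = sum(1 for c in calls if c == "B")
    minor_hom = min(n_a, n_b)

    otv = [c for c in clusters if c.genotype == "OTV"]
    otv_flag = bool(
        otv
        and total_in_clusters > 0
        and sum(c.n for c in otv) / total_in_clusters >= th.otv_cluster_fraction
    )

    return SnpQcMetrics(
        snp_id=snp_id,
        call_rate=call_rate,
        n_clusters=n_clusters,
        fld=fld,
        hom_fld=hom_fld,
        het_so=het_so,
        hom_ro=hom_ro,
        var_x={g: by[g].sd_x**2 for g in by},
        var_y={g: by[g].sd_y**2 for g in by},
        minor_hom_count=minor_hom,
        otv_flag=otv_flag,
    )


def _variance_class(m: SnpQcMetrics, th: QcThresholds) -> str | None:
    for g in ("AA", "BB"):
        if m.var_x.get(g, 0.0) > th.var_x_max:
            return f"{g}varianceX"
        if m.var_y.get(g, 0.0) > th.var_y_max:
            return f"{g}varianceY"
    return None


def classify_snp(m: SnpQcMetrics, thresholds: QcThresholds | None = None) -> str:
    """Assign a SNP to exactly one quality category.

    Decision order: call rate, OTV, then the cluster-count-specific pass
    gates (monomorphic, no-minor-hom, hom-hom, polymorphic), then the AA/BB
    variance classes, else Other.
    """
    th = thresholds or QcThresholds()
    if m.n_clusters not in (1, 2, 3):
        raise ValueError(f"inconsistent metrics: n_clusters={m.n_clusters}")
    if m.n_clusters == 3 and (m.fld is None or m.het_so is None):
        raise ValueError("3-cluster SNP without FLD/HetSO metrics")

    if m.call_rate < th.snp_cr_min:
        return "CallRateBelowThreshold"
    if m.otv_flag and m.het_so is not None and m.het_so < th.het_so_otv_min:
        return "OTV"

    variance_fail = _variance_class(m, th)

    if m.n_clusters == 1:
        if (
            m.hom_ro is not None
            and m.hom_ro >= th.hom_ro_1_min
            and variance_fail is None
        ):
            return "MonoHighResolution"
    elif m.n_clusters == 2 and m.fld is not None:
        # one homozygote cluster plus the heterozygote cluster
        if (
            m.fld >= th.fld_min
            and m.hom_ro is not None
            and m.hom_ro >= th.hom_ro_2_min
            and variance_fail is None
        ):
            return "NoMinorHom"
    elif m.n_clusters == 2 and m.hom_fld is not None:
        if (
            m.hom_fld >= th.hom_fld_min
            and m.hom_ro is not None
            and m.hom_ro >= th.hom_ro_2_min
            and variance_fail is None
        ):
            return "HomHomResolution"
    elif m.n_clusters == 3:
        if (
            m.fld >= th.fld_min
            and m.het_so >= th.het_so_min
            and m.hom_ro is not None
            and m.hom_ro >= th.hom_ro_2_min
            and m.minor_hom_count >= th.minor_hom_min
            and variance_fail is None
        ):
            return "PolyHighResolution"

    if variance_fail is not None:
        return variance_fail
    return "Other"


def qc_summary(categories: Sequence[str], total: int | None = None) -> dict:
    """Counts and percentages per category, plus the polymorphic-usable count.

    ``total`` defaults to the number of classified SNPs; pass the array size
    to express percentages of the full array.
    """
    counts = {cat: 0 for cat in SNP_CATEGORIES}
    for c in categories:
        if c not in counts:
            raise ValueError(f"unknown category {c!r}")
        counts[c] += 1
    denom = total if total is not None else len(categories)
    pct = {
        cat: (100.0 * n / denom if denom else 0.0) for cat, n in counts.items()
    }
    return {
        "counts": counts,
        "percentages": pct,
        "total": denom,
        "polymorphic_usable": counts["PolyHighResolution"],
    }
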