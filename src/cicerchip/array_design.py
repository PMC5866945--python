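"""Candidate-SNP selection for array probe design.

Implements the probe-design pipeline used for high-density SNP genotyping
arrays: a flanking-uniqueness rule (no other SNP within 35 bp on either
side), seven sequential quality filters (SSR-free window, indel-free window,
biallelic, minor allele frequency, GC content, no ambiguity codes, site
quality), deduplication, probe-window extraction, and genomic-region /
coding-effect annotation, with a per-filter attrition report.

A probe candidate is the 71-mer reference window centred on the SNP
(35 bp flank each side).  All threshold comparisons are inclusive on the
passing side: MAF >= 0.05, 0.40 <= GC <= 0.70, QUAL >= 30, score >= 0.3.
"""

from __future__ import annotations

from collections import OrderedDict
from collections.abc import Callable, Iterable, Sequence

from Bio.Seq import Seq

from .models import (
    DesignReport,
    Gene,
    ProbeCandidate,
    SsrTract,
    SyntheticGenome,
    VariantRecord,
)

FLANK = 35
WINDOW = 2 * FLANK + 1

#: Minimum copy number per motif length for a perfect tandem repeat to count
#: as an SSR (MISA-convention defaults).
SSR_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

DEFAULT_THRESHOLDS = {
    "maf_min": 0.05,
    "gc_min": 0.40,
    "gc_max": 0.70,
    "qual_min": 30.0,
    "score_min": 0.3,
}

#: Sequential filter order as applied (flanking-uniqueness rule first, then
#: the seven quality filters).
FILTER_ORDER = (
    "isolated",
    "no_ssr",
    "no_indel",
    "biallelic",
    "maf_ok",
    "gc_ok",
    "no_ambiguity",
    "qual_ok",
)

START_CODONS = frozenset({"ATG", "CTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def filter_isolated(
    variants: Sequence[VariantRecord], window: int = FLANK
) -> list[VariantRecord]:
    """Keep SNPs with no other SNP within ``window`` bp on either side.

    Both members of a too-close pair are removed.  Input must be sorted by
    (chrom, pos); an unsorted input raises ``ValueError``.
    """
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos)")
    keep: list[VariantRecord] = []
    n = len(variants)
    for i, v in enumerate(variants):
        crowded = False
        for j in (i - 1, i + 1):
            if 0 <= j < n and variants[j].chrom == v.chrom:
                if abs(variants[j].pos - v.pos) <= window:
                    crowded = True
        if not crowded:
            keep.append(v)
    return keep


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def detect_ssr(
    sequence: str, min_copies: dict[int, int] | None = None
) -> list[SsrTract]:
    """Find perfect tandem repeats (SSRs) with motif length 1-6.

    A tract is a maximal run of complete copies of a primitive motif meeting
    the per-motif-length minimum copy number.  Non-ACGT characters terminate
    tracts.  Coordinates returned are 1-based inclusive; ``chrom`` is left
    empty (caller context).
    """
    if min_copies is None:
        min_copies = SSR_MIN_COPIES
    seq = sequence.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    tracts: list[SsrTract] = []
    for m, need in sorted(min_copies.items()):
        for i in range(0, n - m + 1):
            if not all(valid[i : i + m]):
                continue
            motif = seq[i : i + m]
            if not _is_primitive(motif):
                continue
            # left-maximality: skip if the run extends one base to the left
            if i >= 1 and valid[i - 1] and seq[i - 1] == seq[i + m - 1]:
                continue
            j = i + m
            while j < n and valid[j] and seq[j] == seq[j - m]:
                j += 1
            copies = (j - i) // m
            if copies >= need:
                tracts.append(
                    SsrTract(chrom="", start=i + 1, end=i + copies * m, motif=motif)
                )
    tracts.sort(key=lambda t: (t.start, len(t.motif)))
    return tracts


def compute_gc_fraction(window: str) -> float:
    """(#G + #C) / length of the window."""
    if not window:
        raise ValueError("empty window")
    w = window.upper()
    return (w.count("G") + w.count("C")) / len(w)


def compute_maf(allele_counts: Sequence[int]) -> float:
    """Minor allele frequency from observed allele counts (REF-first order).

    For biallelic counts this is min(p, 1-p); for multiallelic sites the
    frequency of the second most common allele is returned.
    """
    total = sum(allele_counts)
    if total == 0:
        raise ValueError("no observed alleles")
    if len(allele_counts) < 2:
        raise ValueError("need counts for at least two alleles")
    ordered = sorted(allele_counts, reverse=True)
    return ordered[1] / total


def has_ambiguity(window: str) -> bool:
    """True iff any character outside {A,C,G,T} (IUPAC ambiguity incl. N)."""
    return any(c not in "ACGT" for c in window.upper())


def extract_window(genome: SyntheticGenome, chrom: str, pos: int) -> str | None:
    """The 71-mer reference window centred on ``pos``; None if flank too short."""
    seq = genome.sequence(chrom)
    if pos - FLANK < 1 or pos + FLANK > len(seq):
        return None
    return seq[pos - FLANK - 1 : pos + FLANK]


def deduplicate_candidates(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """One record per (chrom, pos): highest QUAL wins, ties by lowest alt.

    Output preserves the first-seen order of the surviving positions.
    """
    best: OrderedDict[tuple[str, int], VariantRecord] = OrderedDict()
    for v in variants:
        key = (v.chrom, v.pos)
        cur = best.get(key)
        if cur is None:
            best[key] = v
        elif v.qual > cur.qual or (v.qual == cur.qual and v.alts < cur.alts):
            best[key] = v
    return list(best.values())


def annotate_region(variant: VariantRecord, genes: Sequence[Gene]) -> str:
    """Classify a position as coding, intronic, or intergenic.

    Coding iff inside a CDS exon; intronic iff inside a gene span but not in
    any of its exons; otherwise intergenic (UTRs are not annotated as a
    separate class and fall into intergenic unless in CDS).
    """
    in_gene = False
    for g in genes:
        if g.chrom != variant.chrom or not g.contains(variant.pos):
            continue
        if g.in_exon(variant.pos):
            return "coding"
        in_gene = True
    return "intronic" if in_gene else "intergenic"


def _splice_label(pos: int, gene: Gene) -> str | None:
    """Splice donor/acceptor if pos lies in the 2-bp intronic dinucleotide."""
    for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
        intron_lo, intron_hi = e1 + 1, s2 - 1
        if intron_hi < intron_lo:
            continue
        near_low = pos in (intron_lo, intron_lo + 1)
        near_high = pos in (intron_hi - 1, intron_hi)
        if gene.strand == "+":
            if near_low:
                return "splice_site_donor"
            if near_high:
                return "splice_site_acceptor"
        else:
            if near_high:
                return "splice_site_donor"
            if near_low:
                return "splice_site_acceptor"
    return None


def classify_coding_effect(
    variant: VariantRecord, gene: Gene, chrom_seq: str
) -> str:
    """Coding / splice effect of a SNP within a transcript.

    Splice labels take precedence inside the 2-bp intronic dinucleotide;
    otherwise the affected codon is reconstructed strand-aware from the CDS
    and translated with the standard genetic code.
    """
    pos = variant.pos
    label = _splice_label(pos, gene)
    if label is not None:
        return label
    if not gene.in_exon(pos):
        raise ValueError("variant lies neither in CDS nor in a splice site")
    cds = "".join(chrom_seq[s - 1 : e] for s, e in gene.exons)
    offsets = []  # CDS offset of pos in genome (+) orientation
    off = 0
    for s, e in gene.exons:
        if s <= pos <= e:
            offsets.append(off + (pos - s))
        off += e - s + 1
    idx = offsets[0]
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        idx = len(cds) - 1 - idx
    if len(cds) % 3 != 0:
        raise ValueError("transcript CDS length is not a multiple of 3")
    alt = variant.alts[0]
    alt_base = alt if gene.strand == "+" else str(Seq(alt).complement())
    codon_i = idx // 3
    ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
    within = idx % 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_i == 0:
        if alt_codon in START_CODONS:
            return "synonymous_start"
        return "start_lost"
    if ref_codon in STOP_CODONS:
        return "synonymous_stop" if alt_codon in STOP_CODONS else "stop_lost"
    if alt_codon in STOP_CODONS:
        return "stop_gained"
    return "synonymous_coding" if ref_aa == alt_aa else "nonsynonymous_coding"


def score_hook(
    candidates: Sequence[ProbeCandidate],
    scorer: Callable[[ProbeCandidate], float] | None = None,
    threshold: float = DEFAULT_THRESHOLDS["score_min"],
) -> list[ProbeCandidate]:
    """Apply an external probe-conversion scorer and keep score >= threshold.

    The default scorer returns 1.0 for every candidate (no-op), standing in
    for the proprietary array-vendor conversion model.
    """
    if scorer is None:
        scorer = lambda c: 1.0  # noqa: E731
    kept = []
    for c in candidates:
        s = scorer(c)
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"scorer returned {s!r}, outside [0, 1]")
        c.score = s
        if s >= threshold:
            kept.append(c)
    return kept


def apply_design_filters(
    variants: Sequence[VariantRecord],
    genome: SyntheticGenome,
    genes: Sequence[Gene] | None = None,
    thresholds: dict | None = None,
    ssr_min_copies: dict[int, int] | None = None,
) -> tuple[list[ProbeCandidate], DesignReport]:
    """Run the full probe-design filter cascade over a variant panel.

    SNP records are the candidates; indel records in the panel are used only
    as context for the indel-proximity filter.  Filters are applied
    sequentially in ``FILTER_ORDER`` after deduplication; a SNP too close to
    a chromosome end to extract the 71-mer window is removed with reason
    "edge".  Survivors carry all flags true and genomic-region / coding-
    effect annotation when gene models are given.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    genes = list(genes or [])

    snps = [v for v in variants if v.is_snp]
    indels = [v for v in variants if v.is_indel]
    input_count = len(snps)

    removed: dict[str, int] = {"duplicate": 0, "edge": 0}
    removed.update({name: 0 for name in FILTER_ORDER})

    unique = deduplicate_candidates(snps)
    removed["duplicate"] = len(snps) - len(unique)
    unique.sort(key=lambda v: (v.chrom, v.pos))

    isolated = filter_isolated(unique)
    removed["isolated"] = len(unique) - len(isolated)

    indel_pos: dict[str, list[int]] = {}
    for ind in indels:
        span = max(len(ind.ref), *(len(a) for a in ind.alts))
        indel_pos.setdefault(ind.chrom, []).extend(
            range(ind.pos, ind.pos + span)
        )

    candidates: list[ProbeCandidate] = []
    for v in isolated:
        win = extract_window(genome, v.chrom, v.pos)
        if win is None:
            removed["edge"] += 1
            continue
        flags = {
            "no_ssr": not detect_ssr(win, ssr_min_copies),
            "no_indel": not any(
                v.pos - FLANK <= p <= v.pos + FLANK
                for p in indel_pos.get(v.chrom, [])
            ),
            "biallelic": v.is_biallelic,
            "maf_ok": compute_maf(v.allele_counts) >= th["maf_min"],
            "gc_ok": th["gc_min"] <= compute_gc_fraction(win) <= th["gc_max"],
            "no_ambiguity": not has_ambiguity(win),
            "qual_ok": v.qual >= th["qual_min"],
        }
        failed = None
        for name in FILTER_ORDER[1:]:
            if not flags[name]:
                failed = name
                break
        if failed is not None:
            removed[failed] += 1
            continue
        flags["isolated"] = True
        cand = ProbeCandidate(
            variant=v,
            window=win,
            gc_fraction=compute_gc_fraction(win),
            flags=flags,
        )
        cand.region = annotate_region(v, genes)
        if cand.region == "coding":
            for g in genes:
                if g.chrom == v.chrom and g.in_exon(v.pos):
                    cand.effect = classify_coding_effect(
                        v, g, genome.sequence(v.chrom)
                    )
                    break
        candidates.append(cand)

    region_counts: dict[str, int] = {}
    effect_counts: dict[str, int] = {}
    for c in candidates:
        if c.region:
            region_counts[c.region] = region_counts.get(c.region, 0) + 1
        if c.effect:
            effect_counts[c.effect] = effect_counts.get(c.effect, 0) + 1

    report = DesignReport(
        input_count=input_count,
        removed=removed,
        survivor_count=len(candidates),
        region_counts=region_counts,
        effect_counts=effect_counts,
    )
    report.check_conservation()
    return candidates, report
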