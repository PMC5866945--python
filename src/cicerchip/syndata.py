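"""Synthetic inputs with known ground truth for every pipeline stage.

The study whose computation this package re-implements rests on unpublished
resequencing, array-intensity and phenotyping data; this module emulates
them at desk scale so each downstream stage has a parameter-recovery test:

* a small multi-chromosome genome with planted protein-coding genes and SSR
  tracts (FASTA + GFF3 via :mod:`cicerchip.io_files`);
* a variant panel with SNPs, indels, triallelic sites, per-site quality
  scores and allele counts over the accession panel, including planted
  "filter-killer" variants that each violate exactly one design filter;
* RIL populations derived from two founders under a known true map, with
  marker-to-marker recombination at the selfed-RIL observed rate
  R = 2r/(1+2r) per interval (independent intervals, no interference);
* phenotypes with planted additive QTLs at stated heritabilities;
* genotype-cluster signal summaries with controllable separation plus
  off-target-variant contamination, and per-sample dish-QC values.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage_map import kosambi_inverse, ril_observed_fraction
from .models import ClusterSummary, Gene, SampleQc, SsrTract, SyntheticGenome
from .qtl_icim import _interp_coding, code_genotypes

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# true map / QTL specifications


@dataclass(frozen=True)
class TrueMapSpec:
    """Ground-truth genetic map: per-group marker cM positions.

    Adjacent meiotic recombination fractions follow from the Kosambi inverse
    of the position differences.
    """

    groups: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        for name, markers in self.groups.items():
            pos = [p for _, p in markers]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(f"positions not strictly increasing in {name}")
            for r in self.adjacent_r(name):
                if not 0.0 <= r < 0.5:
                    raise ValueError("adjacent rf outside [0, 0.5)")

    def adjacent_r(self, group: str) -> list[float]:
        pos = [p for _, p in self.groups[group]]
        return [kosambi_inverse(b - a) for a, b in zip(pos, pos[1:])]

    def marker_names(self) -> list[str]:
        return [m for g in self.groups.values() for m, _ in g]

    @classmethod
    def regular(
        cls,
        n_groups: int = 8,
        markers_per_group: int = 12,
        spacing_cm: float = 5.0,
        prefix: str = "M",
    ) -> "TrueMapSpec":
        groups = {}
        for g in range(1, n_groups + 1):
            name = f"G{g:02d}"
            groups[name] = [
                (f"{prefix}{g:02d}_{k:03d}", k * spacing_cm)
                for k in range(markers_per_group)
            ]
        return cls(groups)


@dataclass(frozen=True)
class Environment:
    location: str
    year: str
    shift: float = 0.0


@dataclass(frozen=True)
class QtlSpec:
    """Planted additive QTLs per trait, residual SD, and environments."""

    traits: dict[str, list[tuple[str, float, float]]]  # (group, cM, effect a)
    sigma: float
    environments: tuple[Environment, ...] = (Environment("L1", "2016"),)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("residual SD must be positive")
        for trait, qtls in self.traits.items():
            ss = sum(a * a for _, _, a in qtls)
            h2 = ss / (ss + self.sigma**2)
            if not 0.0 <= h2 < 1.0:
                raise ValueError(f"implied heritability {h2} out of range for {trait}")


# ---------------------------------------------------------------------------
# reference genome


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, size=3))
        if c not in STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


_SSR_MOTIFS = ("A", "AT", "AAG", "AGAT", "AACGT", "AACGTC")
_SSR_COPIES = {1: 12, 2: 8, 3: 6, 4: 6, 5: 6, 6: 6}


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_reference(
    seed: int,
    n_chrom: int = 8,
    chrom_length: int = 200_000,
    gene_count: int = 40,
    ssr_count: int = 20,
    gc_target: float = 0.5,
) -> SyntheticGenome:
    """Generate a genome with planted genes and SSR tracts.

    Genes have three CDS exons (no UTR exons) on random strands; SSR tracts
    use rotating motifs of length 1-6 with copy numbers above the detection
    thresholds, and their flanks are set to break the repeat periodicity so
    each planted tract is exactly recoverable.  Raises ``ValueError`` when
    the requested features cannot be packed into the genome.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 1000:
        raise ValueError("chromosome length must be >= 1000")
    rng = np.random.default_rng(seed)

    exon_lens = (120, 90, 60)
    intron_len = 80
    gene_span = sum(exon_lens) + 2 * intron_len
    ssr_span_max = 36
    per_chrom_genes = -(-gene_count // n_chrom)
    per_chrom_ssrs = -(-ssr_count // n_chrom)
    needed = per_chrom_genes * (gene_span + 100) + per_chrom_ssrs * (
        ssr_span_max + 100
    )
    if needed > chrom_length - 200:
        raise ValueError(
            f"cannot pack {gene_count} genes and {ssr_count} SSRs into "
            f"{n_chrom} x {chrom_length} bp"
        )

    chromosomes: dict[str, np.ndarray] = {
        f"chr{i + 1}": _random_seq(rng, chrom_length, gc_target)
        for i in range(n_chrom)
    }
    chrom_names = list(chromosomes)
    genes: list[Gene] = []
    ssrs: list[SsrTract] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def _claim(chrom: str, span: int) -> int:
        """Random non-overlapping 1-based start for a feature of ``span`` bp."""
        for _ in range(200):
            start = int(rng.integers(100, chrom_length - span - 100))
            if all(
                start + span < s or start > e for s, e in occupied[chrom]
            ):
                occupied[chrom].append((start, start + span))
                return start
        raise ValueError("infeasible packing: could not place feature")

    for gi in range(gene_count):
        chrom = chrom_names[gi % n_chrom]
        start = _claim(chrom, gene_span)
        strand = "+" if rng.random() < 0.5 else "-"
        cds = _random_cds(rng, sum(exon_lens) // 3)
        genome_cds = cds if strand == "+" else _revcomp(cds)
        exons = []
        cursor = start
        offset = 0
        for el in exon_lens:
            exons.append((cursor, cursor + el - 1))
            seq = chromosomes[chrom]
            seq[cursor - 1 : cursor + el - 1] = list(genome_cds[offset : offset + el])
            offset += el
            cursor += el + intron_len
        # canonical GT..AG intron dinucleotides (strand-aware)
        seq = chromosomes[chrom]
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if strand == "+":
                seq[e1], seq[e1 + 1] = "G", "T"
                seq[s2 - 3], seq[s2 - 2] = "A", "G"
            else:
                seq[e1], seq[e1 + 1] = "C", "T"
                seq[s2 - 3], seq[s2 - 2] = "A", "C"
        genes.append(
            Gene(name=f"gene{gi + 1:04d}", chrom=chrom, strand=strand,
                 exons=tuple(exons))
        )

    for si in range(ssr_count):
        chrom = chrom_names[si % n_chrom]
        motif = _SSR_MOTIFS[si % len(_SSR_MOTIFS)]
        copies = _SSR_COPIES[len(motif)]
        tract = motif * copies
        start = _claim(chrom, len(tract) + 2)
        seq = chromosomes[chrom]
        seq[start - 1 : start - 1 + len(tract)] = list(tract)
        # break periodicity at both flanks so the tract is exactly maximal
        left_break = "C" if tract[len(motif) - 1] != "C" else "G"
        right_break = "C" if tract[-len(motif)] != "C" else "G"
        seq[start - 2] = left_break
        seq[start - 1 + len(tract)] = right_break
        ssrs.append(
            SsrTract(chrom=chrom, start=start, end=start + len(tract) - 1,
                     motif=motif)
        )

    return SyntheticGenome(
        chromosomes={c: "".join(s) for c, s in chromosomes.items()},
        genes=genes,
        ssr_tracts=ssrs,
    )


# ---------------------------------------------------------------------------
# variant panel


@dataclass
class PlantedVariant:
    kind: str
    chrom: str
    pos: int
    note: str = ""


@dataclass
class PanelTruth:
    """Ground truth for the simulated variant panel."""

    planted: list[PlantedVariant] = field(default_factory=list)

    def positions(self, kind: str) -> list[tuple[str, int]]:
        return [(p.chrom, p.pos) for p in self.planted if p.kind == kind]


def _alt_base(rng: np.random.Generator, ref: str, exclude: set[str] = frozenset()) -> str:
    choices = [b for b in "ACGT" if b != ref and b not in exclude]
    return str(rng.choice(choices))


def _default_qual(rng: np.random.Generator, size: int) -> np.ndarray:
    return np.maximum(rng.gamma(4.0, 15.0, size=size), 1.0)


def simulate_panel(
    genome: SyntheticGenome,
    n_accessions: int = 429,
    snp_rate: float = 1e-3,
    indel_rate: float = 5e-5,
    maf_alpha_beta: tuple[float, float] = (0.8, 0.8),
    qual_distribution=None,
    seed: int = 0,
    plant_killers: bool = True,
):
    """Simulate a variant panel (VCF-shaped records) over the genome.

    Returns ``(variants, truth)``.  Alt-allele frequencies are drawn from a
    Beta(alpha, beta) to give a realistic MAF spectrum; allele counts are
    binomial over 2 x n_accessions alleles.  When ``plant_killers`` is true
    a set of variants is planted, one violating each design filter (too
    close pair, SSR in window, indel in window, triallelic, MAF < 0.05,
    GC outside 40-70%, ambiguity code in window, QUAL 29).  Planting the
    ambiguity killer edits one flanking base of that site to 'N' in the
    genome object passed in (the single place the genome departs from pure
    A/C/G/T); the edit is recorded in the returned truth.
    """
    if not (0 < snp_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in (0, 1)")
    if n_accessions < 2:
        raise ValueError("need at least two accessions")
    from .models import VariantRecord  # local import keeps module load light

    rng = np.random.default_rng(seed)
    two_n = 2 * n_accessions
    a, b = maf_alpha_beta
    truth = PanelTruth()
    variants: list[VariantRecord] = []
    reserved: dict[str, set[int]] = {c: set() for c in genome.chromosomes}

    def _counts(maf: float | None = None) -> tuple[int, int]:
        if maf is None:
            p = float(rng.beta(a, b))
        else:
            p = maf
        alt = int(rng.binomial(two_n, p)) if maf is None else int(round(maf * two_n))
        alt = min(max(alt, 0), two_n)
        return two_n - alt, alt

    def _snp(chrom: str, pos: int, qual: float | None = None,
             maf: float | None = 0.3, n_alts: int = 1) -> VariantRecord:
        ref = genome.sequence(chrom)[pos - 1]
        alts = []
        for _ in range(n_alts):
            alts.append(_alt_base(rng, ref, exclude=set(alts)))
        if qual is None:
            qual = float(_default_qual(rng, 1)[0])
        if n_alts == 1:
            ref_c, alt_c = _counts(maf)
            counts = (ref_c, alt_c)
        else:
            ref_c, alt_c = _counts(maf)
            second = max(alt_c // 3, 1)
            counts = (ref_c, alt_c - second, second)
        return VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
            allele_counts=counts,
        )

    if plant_killers:
        from .array_design import detect_ssr

        chrom = next(iter(genome.chromosomes))
        seq = genome.sequence(chrom)
        base = 10_000
        slots = iter(range(base, base + 40_000, 2_000))

        def _clean_pos(start: int) -> int:
            """First position >= start whose 71-mer window passes GC and SSR."""
            for cand in range(start, len(seq) - 100):
                win = seq[cand - 36 : cand + 35]
                gc = (win.count("G") + win.count("C")) / 71
                if 0.45 <= gc <= 0.65 and not detect_ssr(win):
                    return cand
            raise ValueError("no clean window found for planted variant")

        p1 = _clean_pos(next(slots))
        variants.append(_snp(chrom, p1, qual=50.0))
        variants.append(_snp(chrom, p1 + 20, qual=50.0))
        truth.planted.append(PlantedVariant("isolation_pair", chrom, p1))
        truth.planted.append(PlantedVariant("isolation_pair", chrom, p1 + 20))
        reserved[chrom].update(range(p1 - 40, p1 + 60))

        tract = next(
            (t for t in genome.ssr_tracts
             if t.chrom == chrom and (t.end - t.start + 1) <= 28),
            None,
        )
        if tract is not None:
            pos = tract.end + 5
            variants.append(_snp(chrom, pos, qual=50.0))
            truth.planted.append(PlantedVariant("ssr", chrom, pos))
            reserved[chrom].update(range(tract.start - 40, pos + 40))

        p_ind = _clean_pos(next(slots))
        variants.append(_snp(chrom, p_ind, qual=50.0))
        ref_span = seq[p_ind + 9 : p_ind + 12]
        variants.append(
            VariantRecord(chrom=chrom, pos=p_ind + 10, ref=ref_span,
                          alts=(ref_span[0],), qual=45.0,
                          allele_counts=_counts(0.3))
        )
        truth.planted.append(PlantedVariant("indel", chrom, p_ind))
        reserved[chrom].update(range(p_ind - 40, p_ind + 60))

        p_tri = _clean_pos(next(slots))
        variants.append(_snp(chrom, p_tri, qual=50.0, n_alts=2))
        truth.planted.append(PlantedVariant("triallelic", chrom, p_tri))
        reserved[chrom].update(range(p_tri - 40, p_tri + 40))

        p_maf = _clean_pos(next(slots))
        variants.append(_snp(chrom, p_maf, qual=50.0, maf=0.02))
        truth.planted.append(PlantedVariant("low_maf", chrom, p_maf))
        reserved[chrom].update(range(p_maf - 40, p_maf + 40))

        p_gc = None
        for cand in range(base + 50_000, len(seq) - 100):
            win = seq[cand - 36 : cand + 35]
            gc = (win.count("G") + win.count("C")) / 71
            if gc < 0.40 or gc > 0.70:
                if not detect_ssr(win):
                    p_gc = cand
                    break
        if p_gc is not None:
            variants.append(_snp(chrom, p_gc, qual=50.0))
            truth.planted.append(PlantedVariant("bad_gc", chrom, p_gc))
            reserved[chrom].update(range(p_gc - 40, p_gc + 40))

        p_amb = _clean_pos(next(slots))
        variants.append(_snp(chrom, p_amb, qual=50.0))
        s = genome.chromosomes[chrom]
        genome.chromosomes[chrom] = s[: p_amb + 4] + "N" + s[p_amb + 5 :]
        truth.planted.append(
            PlantedVariant("ambiguity", chrom, p_amb,
                           note=f"N edited into genome at {p_amb + 5}")
        )
        reserved[chrom].update(range(p_amb - 40, p_amb + 40))

        p_q = _clean_pos(next(slots))
        variants.append(_snp(chrom, p_q, qual=29.0))
        truth.planted.append(PlantedVariant("low_qual", chrom, p_q))
        reserved[chrom].update(range(p_q - 40, p_q + 40))

    for chrom, seq in genome.chromosomes.items():
        length = len(seq)
        n_snp = int(rng.binomial(length, snp_rate))
        pos = rng.choice(np.arange(100, length - 100), size=n_snp, replace=False)
        pos = np.sort(pos)
        quals = (
            _default_qual(rng, n_snp)
            if qual_distribution is None
            else np.asarray([qual_distribution(rng) for _ in range(n_snp)])
        )
        for p, q in zip(pos, quals):
            p = int(p)
            if p in reserved[chrom] or seq[p - 1] == "N":
                continue
            variants.append(_snp(chrom, p, qual=float(q), maf=None))
        n_ind = int(rng.binomial(length, indel_rate))
        ipos = np.sort(
            rng.choice(np.arange(100, length - 100), size=n_ind, replace=False)
        )
        for p in ipos:
            p = int(p)
            if p in reserved[chrom] or "N" in seq[p - 1 : p + 3]:
                continue
            ref = seq[p - 1 : p + 2]
            variants.append(
                VariantRecord(chrom=chrom, pos=p, ref=ref, alts=(ref[0],),
                              qual=float(_default_qual(rng, 1)[0]),
                              allele_counts=_counts(None))
            )

    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants, truth


# ---------------------------------------------------------------------------
# RIL genotypes


def simulate_ril(
    true_map: TrueMapSpec,
    n_ril: int,
    founder_labels: tuple[str, str] = ("P1", "P2"),
    residual_het_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a selfed-RIL genotype matrix under a known true map.

    Rows are markers, columns are the two founders then the RILs; calls use
    the internal {A, B, H, U} alphabet with A = founder-1 allele.  Adjacent
    markers recombine independently at the RIL-observed rate R = 2r/(1+2r)
    for the map's meiotic r (F-infinity selfed RILs: fully homozygous except
    for an optional residual heterozygosity rate).
    """
    if n_ril < 10:
        raise ValueError("n_ril must be >= 10")
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for group, markers in true_map.groups.items():
        big_r = [ril_observed_fraction(r) for r in true_map.adjacent_r(group)]
        k = len(markers)
        geno = np.empty((k, n_ril), dtype=np.int8)
        geno[0] = rng.random(n_ril) < 0.5
        for i, R in enumerate(big_r, start=1):
            flip = rng.random(n_ril) < R
            geno[i] = geno[i - 1] ^ flip
        for (marker, _pos), g in zip(markers, geno):
            rows.append(g)
            index.append(marker)
    arr = np.array(rows, dtype=np.int8)
    calls = np.where(arr == 0, "A", "B").astype(object)
    if residual_het_rate > 0:
        calls[rng.random(calls.shape) < residual_het_rate] = "H"
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = "U"
    ril_cols = [f"RIL{i + 1:04d}" for i in range(n_ril)]
    df = pd.DataFrame(calls, index=index, columns=ril_cols)
    p1, p2 = founder_labels
    df.insert(0, p1, "A")
    df.insert(1, p2, "B")
    return df


# ---------------------------------------------------------------------------
# phenotypes


def qtl_genotype_values(
    genotypes: pd.DataFrame,
    true_map: TrueMapSpec,
    group: str,
    cm: float,
) -> np.ndarray:
    """Expected +/-1 QTL genotype at a cM position from flanking markers."""
    markers = [m for m, _ in true_map.groups[group]]
    pos = np.array([p for _, p in true_map.groups[group]])
    if not pos[0] <= cm <= pos[-1]:
        raise ValueError(f"QTL position {cm} cM outside group {group}")
    sub = genotypes.loc[markers]
    xg = code_genotypes(sub).T.to_numpy()  # samples x markers
    return _interp_coding(xg, pos, np.array([cm]))[:, 0]


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    qtl_spec: QtlSpec,
    true_map: TrueMapSpec,
    seed: int = 0,
    sample_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-environment phenotypes: y = sum(a_k x_k) + env shift + N(0, s^2).

    Returns a long table with columns sample, trait, environment, location,
    year, value.  ``sample_columns`` restricts to the progeny (defaults to
    every column of ``genotypes``).
    """
    rng = np.random.default_rng(seed)
    cols = sample_columns if sample_columns is not None else list(genotypes.columns)
    sub = genotypes[cols]
    n = len(cols)
    records = []
    for trait, qtls in qtl_spec.traits.items():
        genetic = np.zeros(n)
        for group, cm, a in qtls:
            genetic += a * qtl_genotype_values(sub, true_map, group, cm)
        for env in qtl_spec.environments:
            y = genetic + env.shift + rng.normal(0.0, qtl_spec.sigma, size=n)
            env_name = f"{env.location}_{env.year}"
            for s, v in zip(cols, y):
                records.append(
                    (s, trait, env_name, env.location, env.year, float(v))
                )
    return pd.DataFrame(
        records,
        columns=["sample", "trait", "environment", "location", "year", "value"],
    )


# ---------------------------------------------------------------------------
# cluster signals


def add_monomorphic_markers(
    genotypes: pd.DataFrame, n: int, seed: int = 0, prefix: str = "MONO"
) -> pd.DataFrame:
    """Append monomorphic marker rows (all samples the same homozygote)."""
    rng = np.random.default_rng(seed)
    rows = {}
    for i in range(n):
        allele = "A" if rng.random() < 0.5 else "B"
        rows[f"{prefix}{i + 1:04d}"] = [allele] * genotypes.shape[1]
    extra = pd.DataFrame.from_dict(
        rows, orient="index", columns=genotypes.columns
    )
    return pd.concat([genotypes, extra])


def simulate_cluster_signals(
    genotypes: pd.DataFrame,
    separation: float = 10.0,
    size_offset_het: float = 0.0,
    otv_fraction: float = 0.0,
    dqc_low_fraction: float = 0.0,
    sigma_x: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, list[ClusterSummary]], list[SampleQc], list[str]]:
    """Per-SNP genotype-cluster summaries and per-sample DQC values.

    Cluster contrast centres sit at +/- separation * sigma_x (AA / BB) and 0
    (AB), so ``separation`` is the constructed |mean_AA - mean_AB| / SD.
    A fraction ``otv_fraction`` of polymorphic markers is contaminated by an
    off-target variant: a low-size extra cluster holding ~10% of samples
    plus a het-like cluster well below the homozygote chord.  Returns
    (clusters by marker, per-sample QC with DQC and call rate, list of
    OTV-planted marker ids).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    if not 0.0 <= otv_fraction < 1.0:
        raise ValueError("otv_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    centers_x = {"AA": separation * sigma_x, "AB": 0.0, "BB": -separation * sigma_x}
    label_of = {"A": "AA", "H": "AB", "B": "BB"}
    n_samples = genotypes.shape[1]

    vals_by_marker = {m: genotypes.loc[m].to_numpy() for m in genotypes.index}
    poly = [
        m for m, v in vals_by_marker.items()
        if (v == "A").any() and (v == "B").any()
    ]
    n_otv_markers = int(round(otv_fraction * len(poly)))
    otv_set = set(
        rng.choice(poly, size=n_otv_markers, replace=False)
    ) if n_otv_markers else set()

    clusters: dict[str, list[ClusterSummary]] = {}
    otv_markers: list[str] = []
    for marker, row in genotypes.iterrows():
        vals = vals_by_marker[marker]
        counts = {
            g: int((vals == code).sum())
            for code, g in label_of.items()
            if (vals == code).any()
        }
        make_otv = marker in otv_set
        out = []
        if make_otv:
            n_otv = max(int(round(0.1 * n_samples)), int(0.05 * n_samples) + 1)
            n_het = max(counts.get("AB", 0), max(2, int(0.05 * n_samples)))
            counts = dict(counts)
            counts["AB"] = n_het
            donor = "AA" if counts["AA"] >= counts["BB"] else "BB"
            counts[donor] = max(counts[donor] - n_otv, 1)
            otv_markers.append(str(marker))
        for g, n_g in counts.items():
            mx = centers_x[g] + rng.normal(0, sigma_x / math.sqrt(max(n_g, 1)))
            my = 1.0 + (size_offset_het if g == "AB" else 0.0)
            if make_otv and g == "AB":
                my -= 0.5  # sunken het-like cluster: HetSO below -0.3
            out.append(
                ClusterSummary(
                    genotype=g, n=n_g, mean_x=mx,
                    sd_x=sigma_x * rng.uniform(0.9, 1.1),
                    mean_y=my + rng.normal(0, 0.01),
                    sd_y=0.1 * rng.uniform(0.9, 1.1),
                )
            )
        if make_otv:
            out.append(
                ClusterSummary(
                    genotype="OTV", n=n_otv, mean_x=rng.normal(0, sigma_x),
                    sd_x=sigma_x, mean_y=0.3, sd_y=0.05,
                )
            )
        clusters[str(marker)] = out

    samples = []
    for col in genotypes.columns:
        if rng.random() < dqc_low_fraction:
            dqc = float(rng.uniform(0.5, 0.8199))
        else:
            dqc = float(min(rng.beta(60, 3), 0.9999))
        cr = float((genotypes[col] != "U").mean())
        samples.append(SampleQc(sample_id=str(col), dqc=dqc, call_rate=cr))
    return clusters, samples, otv_markers
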