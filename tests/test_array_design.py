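"""Probe-design filters: oracles, closed vocabularies and the filter cascade."""

import numpy as np
import pytest

from cicerchip.array_design import (
    FILTER_ORDER,
    SSR_MIN_COPIES,
    _is_primitive,
    annotate_region,
    apply_design_filters,
    classify_coding_effect,
    compute_gc_fraction,
    compute_maf,
    deduplicate_candidates,
    detect_ssr,
    extract_window,
    filter_isolated,
    has_ambiguity,
    score_hook,
)
from cicerchip.models import Gene, ProbeCandidate, SyntheticGenome, VariantRecord


def snp(chrom, pos, ref="A", alt="G", qual=50.0, counts=(600, 258), alts=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref,
        alts=alts if alts is not None else (alt,),
        qual=qual,
        allele_counts=counts if alts is None else (500, 258, 100),
    )


# ---------------------------------------------------------------------------
# flanking-uniqueness (isolation) rule


class TestFilterIsolated:
    def test_single_snp_kept(self):
        v = [snp("c1", 500)]
        assert filter_isolated(v) == v

    def test_close_pair_both_removed(self):
        v = [snp("c1", 100), snp("c1", 120)]
        assert filter_isolated(v) == []

    def test_36bp_gap_survives(self):
        v = [snp("c1", 100), snp("c1", 136)]
        assert filter_isolated(v) == v

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            filter_isolated([snp("c1", 200), snp("c1", 100)])

    def test_chromosome_boundary_not_crossed(self):
        v = [snp("c1", 100), snp("c2", 110)]
        assert filter_isolated(v) == v

    def test_agrees_with_all_pairs_oracle(self, rng):
        """Sorted-scan result equals the O(n^2) all-pairs check, 100 instances."""
        for _ in range(100):
            n = int(rng.integers(2, 300))
            pos = np.sort(rng.choice(np.arange(1, 5000), size=n, replace=False))
            chroms = np.sort(rng.choice(["c1", "c2"], size=n))
            variants = [snp(c, int(p)) for c, p in zip(chroms, pos)]
            variants.sort(key=lambda v: (v.chrom, v.pos))
            got = {(v.chrom, v.pos) for v in filter_isolated(variants)}
            expect = set()
            for i, a in enumerate(variants):
                if not any(
                    j != i
                    and b.chrom == a.chrom
                    and abs(b.pos - a.pos) <= 35
                    for j, b in enumerate(variants)
                ):
                    expect.add((a.chrom, a.pos))
            assert got == expect


# ---------------------------------------------------------------------------
# SSR detection


def brute_force_ssr(seq, min_copies=SSR_MIN_COPIES):
    """Exhaustive enumeration over every motif length, start and phase."""
    found = set()
    n = len(seq)
    for m, need in min_copies.items():
        for i in range(n - m + 1):
            motif = seq[i : i + m]
            if not _is_primitive(motif) or any(c not in "ACGT" for c in motif):
                continue
            k = 1
            while seq[i : i + (k + 1) * m] == motif * (k + 1):
                k += 1
            if k < need:
                continue
            if i >= 1 and seq[i - 1] == seq[i + m - 1]:
                continue  # run extends left: not maximal
            found.add((i + 1, i + k * m, motif))
    return found


class TestDetectSsr:
    def test_mononucleotide_run(self):
        tracts = detect_ssr("AAAAAAAAAA")
        assert [(t.start, t.end, t.motif) for t in tracts] == [(1, 10, "A")]

    def test_dinucleotide_run(self):
        tracts = detect_ssr("ATATATATATAT")
        assert [(t.start, t.end, t.motif) for t in tracts] == [(1, 12, "AT")]

    def test_below_threshold_ignored(self):
        assert detect_ssr("AAAAAAAAA") == []  # 9 < 10 copies

    def test_ambiguity_terminates_tract(self):
        assert detect_ssr("AAAAANAAAAA") == []

    def test_agrees_with_exhaustive_oracle(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            got = {(t.start, t.end, t.motif) for t in detect_ssr(seq)}
            assert got == brute_force_ssr(seq)

    def test_planted_repeats_found_in_random_context(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        planted = seq[:50] + "C" + "AT" * 8 + "C" + seq[50:]
        assert any(t.motif in ("AT", "TA") for t in detect_ssr(planted))


# ---------------------------------------------------------------------------
# window-level checks


class TestWindowChecks:
    def test_gc_all_gc(self):
        assert compute_gc_fraction("GGCC") == 1.0

    def test_gc_all_at(self):
        assert compute_gc_fraction("ATAT") == 0.0

    def test_gc_empty_errors(self):
        with pytest.raises(ValueError):
            compute_gc_fraction("")

    def test_gc_matches_character_count(self, rng):
        w = "".join(rng.choice(list("ACGT"), size=71))
        direct = sum(1 for c in w if c in "GC") / 71
        assert compute_gc_fraction(w) == pytest.approx(direct)

    def test_maf_symmetric(self):
        assert compute_maf((429, 429)) == pytest.approx(0.5)

    def test_maf_boundary_passes_at_0_05(self):
        maf = compute_maf((858 - 43, 43))
        assert maf == pytest.approx(43 / 858)
        assert maf >= 0.05

    def test_maf_just_below_boundary(self):
        assert compute_maf((858 - 42, 42)) < 0.05

    def test_maf_no_alleles_errors(self):
        with pytest.raises(ValueError):
            compute_maf((0, 0))

    @pytest.mark.parametrize(
        "window,expected",
        [("ACGT", False), ("ACNGT", True), ("ACRGT", True), ("acgt", False)],
    )
    def test_ambiguity(self, window, expected):
        assert has_ambiguity(window) is expected


# ---------------------------------------------------------------------------
# region / effect annotation


def _chrom_with_gene(strand="+"):
    """A 600-bp chromosome carrying one two-exon gene with a known CDS.

    Exon 1 (101-160) + exon 2 (241-270) give a 90-base CDS;
    CDS = ATG GCT TGG ... TAA with codon 2 = GCT (Ala) and codon 3 = TGG (Trp).
    """
    filler = ("ACGGTCTAGCATCGATCCGATAGCTACCGT" * 30)[:600]
    cds = "ATG" + "GCT" + "TGG" + "GAC" * 25 + "TAA" * 3
    cds = cds[:87] + "TAA"
    assert len(cds) == 90
    seq = list(filler)
    if strand == "+":
        exon1, exon2 = cds[:60], cds[60:]
    else:
        rc = cds.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        exon1, exon2 = rc[:60], rc[60:]
    seq[100:160] = list(exon1)
    seq[240:270] = list(exon2)
    if strand == "+":
        seq[160], seq[161] = "G", "T"  # donor
        seq[238], seq[239] = "A", "G"  # acceptor
    else:
        seq[160], seq[161] = "C", "T"
        seq[238], seq[239] = "A", "C"
    gene = Gene(name="g1", chrom="c1", strand=strand,
                exons=((101, 160), (241, 270)))
    return "".join(seq), gene


class TestAnnotateRegion:
    def test_outside_genes_is_intergenic(self):
        _, gene = _chrom_with_gene()
        assert annotate_region(snp("c1", 50), [gene]) == "intergenic"

    def test_inside_cds_is_coding(self):
        _, gene = _chrom_with_gene()
        assert annotate_region(snp("c1", 110), [gene]) == "coding"

    def test_between_exons_is_intronic(self):
        _, gene = _chrom_with_gene()
        assert annotate_region(snp("c1", 200), [gene]) == "intronic"


class TestCodingEffect:
    def test_synonymous(self):
        seq, gene = _chrom_with_gene()
        # codon 2 GCT (positions 104-106): T->C at 106 gives GCC, still Ala
        v = snp("c1", 106, ref="T", alt="C")
        assert classify_coding_effect(v, gene, seq) == "synonymous_coding"

    def test_nonsynonymous(self):
        seq, gene = _chrom_with_gene()
        # GCT -> GTT (Ala -> Val) at codon 2 position 2
        v = snp("c1", 105, ref="C", alt="T")
        assert classify_coding_effect(v, gene, seq) == "nonsynonymous_coding"

    def test_stop_gained(self):
        seq, gene = _chrom_with_gene()
        # codon 3 TGG (107-109): G->A at 109 gives TGA
        v = snp("c1", 109, ref="G", alt="A")
        assert classify_coding_effect(v, gene, seq) == "stop_gained"

    def test_start_lost(self):
        seq, gene = _chrom_with_gene()
        v = snp("c1", 103, ref="G", alt="A")  # ATG -> ATA
        assert classify_coding_effect(v, gene, seq) == "start_lost"

    def test_synonymous_start(self):
        seq, gene = _chrom_with_gene()
        v = snp("c1", 101, ref="A", alt="C")  # ATG -> CTG, alternative start
        assert classify_coding_effect(v, gene, seq) == "synonymous_start"

    def test_stop_lost_and_synonymous_stop(self):
        seq, gene = _chrom_with_gene()
        # last codon TAA at CDS 88-90 = exon2 positions 268-270
        v = snp("c1", 270, ref="A", alt="G")  # TAA -> TAG, still stop
        assert classify_coding_effect(v, gene, seq) == "synonymous_stop"
        v = snp("c1", 269, ref="A", alt="C")  # TAA -> TCA, stop lost
        assert classify_coding_effect(v, gene, seq) == "stop_lost"

    def test_splice_donor_and_acceptor(self):
        seq, gene = _chrom_with_gene()
        v = snp("c1", 161, ref="G", alt="A")  # first intron base (GT)
        assert classify_coding_effect(v, gene, seq) == "splice_site_donor"
        v = snp("c1", 240, ref="G", alt="C")  # last intron base (AG)
        assert classify_coding_effect(v, gene, seq) == "splice_site_acceptor"

    def test_minus_strand_synonymous(self):
        seq, gene = _chrom_with_gene(strand="-")
        # transcript codon 2 GCT third base (transcript base 6) maps to
        # genome position 265 (exon2 holds CDS bases 61-90 of the revcomp)
        v = snp("c1", 265, ref=seq[264], alt="G")
        assert classify_coding_effect(v, gene, seq) == "synonymous_coding"

    def test_frame_error_detected(self):
        seq, _ = _chrom_with_gene()
        broken = Gene(name="g2", chrom="c1", strand="+", exons=((101, 161),))
        v = snp("c1", 110, ref=seq[109], alt="T" if seq[109] != "T" else "C")
        with pytest.raises(ValueError, match="multiple of 3"):
            classify_coding_effect(v, broken, seq)


# ---------------------------------------------------------------------------
# deduplication and the scoring hook


class TestDeduplicate:
    def test_highest_quality_kept(self):
        a, b = snp("c1", 100, qual=40.0), snp("c1", 100, qual=30.0, alt="T")
        assert deduplicate_candidates([b, a]) == [a]

    def test_tie_broken_by_lowest_alt(self):
        a, b = snp("c1", 100, alt="C"), snp("c1", 100, alt="T")
        assert deduplicate_candidates([b, a]) == [a]

    def test_no_duplicates_identity(self):
        v = [snp("c1", 100), snp("c1", 200)]
        assert deduplicate_candidates(v) == v

    def test_agrees_with_grouping_oracle(self, rng):
        variants = [
            snp("c1", int(rng.integers(1, 30)),
                alt=str(rng.choice(["C", "G", "T"])),
                qual=float(rng.integers(10, 60)))
            for _ in range(200)
        ]
        got = deduplicate_candidates(variants)
        by_pos = {}
        for v in variants:
            by_pos.setdefault((v.chrom, v.pos), []).append(v)
        expect = {
            key: min(grp, key=lambda v: (-v.qual, v.alts))
            for key, grp in by_pos.items()
        }
        assert {(v.chrom, v.pos): v for v in got} == expect


class TestScoreHook:
    def _candidates(self, n=3):
        genome = SyntheticGenome(chromosomes={"c1": "ACGGTCTAGCATCGATCCGATAGCTACCGT" * 10})
        out = []
        for i in range(n):
            pos = 100 + 40 * i
            win = extract_window(genome, "c1", pos)
            v = VariantRecord(chrom="c1", pos=pos, ref=win[35],
                              alts=("T" if win[35] != "T" else "C",),
                              qual=50.0, allele_counts=(600, 258))
            out.append(ProbeCandidate(variant=v, window=win,
                                      gc_fraction=compute_gc_fraction(win),
                                      flags={}))
        return out

    def test_default_scorer_is_identity(self):
        c = self._candidates()
        assert score_hook(c) == c

    def test_constant_zero_scorer_empties(self):
        assert score_hook(self._candidates(), scorer=lambda c: 0.0) == []

    def test_threshold_inclusive(self):
        c = self._candidates(3)
        scores = iter([0.29, 0.30, 0.31])
        kept = score_hook(c, scorer=lambda _: next(scores))
        assert len(kept) == 2

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            score_hook(self._candidates(1), scorer=lambda c: 1.5)


# ---------------------------------------------------------------------------
# full cascade


def _fixture_panel():
    """Ten hand-built SNPs: seven violate exactly one quality filter each.

    The chromosome is a repeat of a 30-mer with 50% GC and no SSR; windows
    are then locally doctored per violation.
    """
    unit = "ACGGTCTAGCATCGATCCGATAGCTACCGT"  # 15 G/C of 30
    seq = list(unit * 200)  # 6000 bp

    def place(i):
        return 300 + 400 * i  # >= 71 bp apart, isolated

    seq[place(0) - 20 : place(0) - 4] = list("C" + "AT" * 7 + "G")  # SSR violator
    # GC violator: push the window above 70% GC with an aperiodic G/C-rich patch
    rng = np.random.default_rng(5)
    while True:
        patch = "".join(rng.choice(list("GCAT"), size=40, p=[0.44, 0.44, 0.06, 0.06]))
        trial = seq.copy()
        trial[place(4) - 30 : place(4) + 10] = list(patch)
        win = "".join(trial[place(4) - 36 : place(4) + 35])
        if compute_gc_fraction(win) > 0.70 and not detect_ssr(win):
            seq = trial
            break
    seq[place(5) + 5] = "N"  # ambiguity violator
    genome = SyntheticGenome(chromosomes={"c1": "".join(seq)})
    g = genome.sequence("c1")

    def mk(i, **kw):
        pos = place(i)
        ref = g[pos - 1]
        alt = "T" if ref != "T" else "C"
        kw.setdefault("qual", 50.0)
        kw.setdefault("counts", (600, 258))
        return snp("c1", pos, ref=ref, alt=alt, **kw)

    variants = [
        mk(0),                                   # removed: SSR in window
        mk(1),                                   # removed: indel in window
        mk(2, alts=("C", "T")),                  # removed: triallelic
        mk(3, counts=(846, 12)),                 # removed: MAF < 0.05
        mk(4),                                   # removed: GC out of range
        mk(5),                                   # removed: ambiguity in window
        mk(6, qual=29.0),                        # removed: QUAL < 30
        mk(7), mk(8), mk(9),                     # survivors
    ]
    indel = VariantRecord(
        chrom="c1", pos=place(1) + 10, ref=g[place(1) + 9 : place(1) + 12],
        alts=(g[place(1) + 9],), qual=50.0, allele_counts=(600, 258),
    )
    variants.append(indel)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return genome, variants


class TestApplyDesignFilters:
    def test_seven_single_violators_give_unit_removal_vector(self):
        genome, variants = _fixture_panel()
        cands, rep = apply_design_filters(variants, genome)
        assert rep.input_count == 10
        assert rep.survivor_count == 3
        seven = [rep.removed[f] for f in FILTER_ORDER[1:]]
        assert seven == [1, 1, 1, 1, 1, 1, 1]
        assert rep.removed["isolated"] == 0

    def test_empty_input(self):
        genome, _ = _fixture_panel()
        cands, rep = apply_design_filters([], genome)
        assert cands == [] and rep.input_count == 0 and rep.survivor_count == 0

    def test_all_passing_identity(self):
        genome, variants = _fixture_panel()
        clean = [v for v in variants if v.pos in (3100, 3500, 3900)]
        cands, rep = apply_design_filters(clean, genome)
        assert rep.survivor_count == len(clean)
        assert all(n == 0 for n in rep.removed.values())

    def test_edge_variant_recorded_not_crashed(self):
        genome, _ = _fixture_panel()
        v = snp("c1", 10, ref=genome.sequence("c1")[9],
                alt="T" if genome.sequence("c1")[9] != "T" else "C")
        _, rep = apply_design_filters([v], genome)
        assert rep.removed["edge"] == 1

    def test_report_conservation_random_panels(self, rng):
        genome, variants = _fixture_panel()
        for _ in range(10):
            sub = [v for v in variants if rng.random() < 0.7]
            sub.sort(key=lambda v: (v.chrom, v.pos))
            _, rep = apply_design_filters(sub, genome)
            rep.check_conservation()

    def test_survivor_set_invariant_to_filter_order(self):
        """Survivors = variants passing every filter, however ordered."""
        genome, variants = _fixture_panel()
        cands, _ = apply_design_filters(variants, genome)
        survivors = {(c.variant.chrom, c.variant.pos) for c in cands}
        snps = sorted((v for v in variants if v.is_snp),
                      key=lambda v: (v.chrom, v.pos))
        iso = {(v.chrom, v.pos) for v in filter_isolated(snps)}
        indels = [v for v in variants if v.is_indel]
        expect = set()
        for v in snps:
            win = extract_window(genome, v.chrom, v.pos)
            if win is None or (v.chrom, v.pos) not in iso:
                continue
            checks = [
                not detect_ssr(win),
                not any(d.chrom == v.chrom and abs(d.pos - v.pos) <= 37
                        for d in indels),
                v.is_biallelic,
                compute_maf(v.allele_counts) >= 0.05,
                0.40 <= compute_gc_fraction(win) <= 0.70,
                not has_ambiguity(win),
                v.qual >= 30.0,
            ]
            if all(checks):
                expect.add((v.chrom, v.pos))
        assert survivors == expect
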