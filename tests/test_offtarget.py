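"""Alignment correctness against independent oracles; variant adjudication logic."""

from functools import lru_cache

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from cas9kit import errors, genome_scan as gs, offtarget_analysis as ot
from cas9kit import synthetic_data as sd

from conftest import CDT1_N209S_GUIDE

MATCH, MISMATCH = 2, -1
OPEN, EXT = ot.GAP_OPEN, ot.GAP_EXTEND


def oracle_global_score(a, b, open_=OPEN, ext=EXT):
    """Top-down recursive optimal global score (independent of the iterative DP)."""

    @lru_cache(maxsize=None)
    def f(i, j, state):
        if i == len(a) and j == len(b):
            return 0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            best = max(best, s + f(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, -(ext if state == "X" else open_) + f(i + 1, j, "X"))
        if j < len(b):
            best = max(best, -(ext if state == "Y" else open_) + f(i, j + 1, "Y"))
        return best

    return f(0, 0, "M")


def enumerate_all_alignments(a, b):
    """Every gapped alignment of a and b as (aligned_a, aligned_b) pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for ra, rb in enumerate_all_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)
    if a:
        for ra, rb in enumerate_all_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_all_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)


def score_alignment(aligned_a, aligned_b, open_=OPEN, ext=EXT):
    """Score a gapped alignment with run-aware affine gap costs."""
    score, in_gap_a, in_gap_b = 0, False, False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-":
            score -= ext if in_gap_a else open_
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= ext if in_gap_b else open_
            in_gap_b, in_gap_a = True, False
        else:
            score += MATCH if x == y else MISMATCH
            in_gap_a = in_gap_b = False
    return score


def biopython_aligner(mode):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = -OPEN
    aligner.extend_gap_score = -EXT
    return aligner


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestGlobalAlign:
    def test_self_alignment_is_all_matches(self, guide):
        r = ot.global_align(guide, guide)
        assert (r.score, r.matches, r.mismatches, r.gaps) == (40, 20, 0, 0)

    def test_five_substitutions(self, guide):
        target = list(guide)
        for i in (0, 4, 9, 14, 19):
            target[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[target[i]]
        r = ot.global_align(guide, "".join(target))
        assert (r.score, r.matches) == (25, 15)

    def test_printed_guide_vs_edited_protospacer(self):
        r = ot.global_align(CDT1_N209S_GUIDE, "TGCACTGGCTTCTACAGCTG")
        assert (r.matches, r.mismatches, r.score) == (19, 1, 37)

    def test_matches_recursive_oracle_on_1000_random_short_pairs(self, rng):
        for _ in range(1000):
            a = random_seq(rng, rng.integers(1, 9))
            b = random_seq(rng, rng.integers(1, 9))
            assert ot.global_align(a, b).score == oracle_global_score(a, b)

    def test_matches_exhaustive_enumeration_on_tiny_pairs(self, rng):
        for _ in range(25):
            a = random_seq(rng, rng.integers(1, 5))
            b = random_seq(rng, rng.integers(1, 5))
            best = max(
                score_alignment(ra, rb) for ra, rb in enumerate_all_alignments(a, b)
            )
            assert ot.global_align(a, b).score == best

    def test_matches_biopython_on_random_20mers(self, rng):
        aligner = biopython_aligner("global")
        for _ in range(200):
            a, b = random_seq(rng, 20), random_seq(rng, 20)
            assert ot.global_align(a, b).score == int(aligner.score(a, b))

    def test_reported_alignment_is_consistent_with_its_score(self, rng):
        for _ in range(200):
            a, b = random_seq(rng, 20), random_seq(rng, 20)
            r = ot.global_align(a, b)
            assert score_alignment(r.aligned_guide, r.aligned_target) == r.score
            assert r.aligned_guide.replace("-", "") == a
            assert r.aligned_target.replace("-", "") == b

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_gapless_score_identity(self, seed):
        # for gapless 20-vs-20 alignments, matches + mismatches = 20, so
        # score = 2m - (20 - m) = 3m - 20
        rng = np.random.default_rng(seed)
        guide = random_seq(rng, 20)
        k = int(rng.integers(0, 21))
        decoy = sd.make_decoy_protospacer(guide, k, rng)
        r = ot.global_align(guide, decoy)
        if r.gaps == 0:
            assert r.score == 3 * r.matches - 20

    def test_alphabet_rejected(self):
        with pytest.raises(errors.AlphabetError):
            ot.global_align("ACGTN" * 4, "ACGT" * 5)


class TestLocalAlign:
    def test_batch_agrees_with_biopython(self, rng):
        aligner = biopython_aligner("local")
        guide = random_seq(rng, 20)
        targets = [random_seq(rng, 20) for _ in range(300)]
        got = ot.local_align_scores(guide, targets)
        expected = [int(aligner.score(guide, t)) for t in targets]
        assert list(got) == expected

    def test_perfect_match_scores_40(self, guide):
        assert ot.local_align_score(guide, guide) == 40


class TestPlausibility:
    @pytest.mark.parametrize("k", list(range(21)))
    def test_match_threshold_boundary(self, guide, k, rng):
        decoy = sd.make_decoy_protospacer(guide, k, rng)
        res = ot.global_align(guide, decoy)
        assert ot.classify_plausible(res) is (k >= 12)

    def test_twelve_is_plausible_eleven_is_not(self, guide, rng):
        r12 = ot.global_align(guide, sd.make_decoy_protospacer(guide, 12, rng))
        r11 = ot.global_align(guide, sd.make_decoy_protospacer(guide, 11, rng))
        assert ot.classify_plausible(r12) and not ot.classify_plausible(r11)


class TestEmpiricalNull:
    def _background(self, guide, scores_above, total=10, rng=None):
        # plant `scores_above` targets that align better than a fixed candidate
        targets = []
        for i in range(total):
            k = 18 if i < scores_above else 5
            targets.append(sd.make_decoy_protospacer(guide, k, rng))
        return gs.BackgroundTargetSet(tuple(targets), total, seed=0)

    def test_direct_count_over_planted_background(self, guide, rng):
        bg = self._background(guide, scores_above=3, rng=rng)
        candidate_score = ot.local_align_score(
            guide, sd.make_decoy_protospacer(guide, 12, rng)
        )
        scores = ot.local_align_scores(guide, bg.targets)
        expected = float((scores > candidate_score).mean())
        assert ot.empirical_better_match_probability(guide, candidate_score, bg) == expected
        assert expected == 0.3

    def test_perfect_candidate_has_p_zero(self, guide, rng):
        bg = self._background(guide, scores_above=5, rng=rng)
        assert ot.empirical_better_match_probability(guide, 40, bg) == 0.0

    def test_hopeless_candidate_has_p_one(self, guide, rng):
        bg = self._background(guide, scores_above=10, rng=rng)
        assert ot.empirical_better_match_probability(guide, -100, bg) == 1.0

    def test_monotone_in_candidate_score(self, guide, rng):
        targets = tuple(
            sd.make_decoy_protospacer(guide, int(k), rng)
            for k in rng.integers(0, 21, size=200)
        )
        bg = gs.BackgroundTargetSet(targets, 200, seed=0)
        ps = [
            ot.empirical_better_match_probability(guide, s, bg) for s in range(-5, 45)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_background_rejected(self, guide):
        with pytest.raises(errors.ParameterError):
            ot.empirical_better_match_probability(
                guide, 10, gs.BackgroundTargetSet((), 0, seed=0)
            )


class TestVariants:
    def test_vcf_round_trip_and_classes(self, offtarget_scene, tmp_path):
        genome, records = offtarget_scene["genome"], offtarget_scene["records"]
        path = tmp_path / "v.vcf"
        sd.write_vcf(records, genome, path)
        variants = ot.read_variants(path, genome=genome)
        assert len(variants) == len(records)
        classes = sorted(v.var_class for v in variants)
        assert classes == sorted(
            ot.classify_variant(r[2], r[3]) for r in records
        )

    def test_multiallelic_rows_split(self, tmp_path):
        genome = gs.as_genome({"chr01": "ACGT" * 100})
        path = tmp_path / "multi.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr01,length=400>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chr01\t10\t.\tC\tA,T\t100\tPASS\t.\n")
        variants = ot.read_variants(path, genome=genome)
        assert [v.alt_allele for v in variants] == ["A", "T"]
        assert all(v.var_class == "SNP" for v in variants)

    def test_unknown_contig_rejected(self, tmp_path):
        genome = gs.as_genome({"chr01": "ACGT" * 100})
        path = tmp_path / "bad.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=chrX,length=400>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            fh.write("chrX\t10\t.\tC\tA\t100\tPASS\t.\n")
        with pytest.raises(errors.ConsistencyError):
            ot.read_variants(path, genome=genome)

    def test_twenty_one_planted_rows(self, guide, tmp_path):
        specs = [(3 + (i % 5), ("SNP", "MNP", "INDEL")[i % 3], 6 + (i % 9)) for i in range(21)]
        plants = sd.plan_decoy_plants(guide, specs, 10_000, seed=21, spacing=300)
        genome, gtruth = sd.make_genome(lengths=(10_000,), planted=plants, seed=21)
        records, _ = sd.make_variants(
            genome, specs, guide, seed=21, planted_sites=gtruth.planted_sites
        )
        path = tmp_path / "v21.vcf"
        sd.write_vcf(records, genome, path)
        assert len(ot.read_variants(path)) == 21


class TestCandidateWindows:
    def test_planted_positive_within_window(self, guide):
        genome, truth = sd.make_genome(
            lengths=(2_000,), planted=[(guide, 1_000, "+")], seed=6
        )
        contig, pam_start, _, _ = truth.planted_sites[0]
        ref = genome[contig].residues[pam_start + 5]
        alt = "C" if ref != "C" else "G"
        variant = ot.VariantRecord(contig, pam_start + 6, ref, alt)
        sites = ot.candidate_sites_near_variant(genome, variant)
        assert any(s.pam_start == pam_start for s in sites)

    def test_distant_variant_yields_no_planted_site(self, guide):
        genome, truth = sd.make_genome(
            lengths=(2_000,), planted=[(guide, 1_000, "+")], seed=6
        )
        contig, pam_start, _, _ = truth.planted_sites[0]
        variant = ot.VariantRecord(contig, pam_start + 101, "A", "C")
        sites = ot.candidate_sites_near_variant(genome, variant)
        assert all(s.pam_start != pam_start for s in sites)

    def test_overlapping_pam_cluster_all_returned(self):
        # AGGGG gives PAMs at three consecutive anchors (AGG, GGG, GGG)
        seq = "ACGT" * 10 + "A" * 21 + "GGGG" + "ACGT" * 10
        genome = gs.as_genome({"c": seq})
        sites = gs.scan_pam_sites(genome, strand_mode="forward")
        pos = 40 + 21  # first G
        variant = ot.VariantRecord("c", pos - 3, seq[pos - 4], "T" if seq[pos - 4] != "T" else "A")
        got = ot.candidate_sites_near_variant(genome, variant, sites=sites)
        win = gs.window_around(pos - 4, 30, len(seq), anchor_width=1)
        expected = [s for s in sites if win.contains_interval(*s.pam_interval)]
        assert got == expected and len(got) >= 3


class TestAdjudicate:
    def test_planted_truth_recovered(self, guide, offtarget_scene):
        genome = offtarget_scene["genome"]
        variants = [
            ot.VariantRecord(c, p, r, a)
            for c, p, r, a in offtarget_scene["records"]
        ]
        report, summary = ot.adjudicate(
            genome, {"g": guide}, variants, n_background=2_000, seed=11
        )
        truth = {key: k for key, _, k in offtarget_scene["offtargets"]}
        for key, k in truth.items():
            rows = report[report["variant"] == key]
            assert bool(rows["plausible"].any()) is (k >= 12)
        # only planted decoys reach the threshold on this dataset
        plausible = report[report["plausible"]]
        planted_pams = {pam for _, pam, k in offtarget_scene["offtargets"] if k >= 12}
        assert set(plausible["pam_start"]) == planted_pams
        assert summary["any_plausible_offtarget"]

    def test_variant_without_adjacent_pam_reported(self, guide):
        # all-A contig has no GG/CC at all
        genome = gs.as_genome({"c": "A" * 500 + "A" * 21 + "TGG" + "A" * 500})
        variants = [ot.VariantRecord("c", 100, "A", "C")]
        report, summary = ot.adjudicate(genome, {"g": guide}, variants, n_background=10, seed=0)
        assert (report["note"] == "no adjacent PAM").all()
        assert summary["n_no_adjacent_pam"] == 1

    def test_report_is_deterministic(self, guide, offtarget_scene, tmp_path):
        genome = offtarget_scene["genome"]
        variants = [
            ot.VariantRecord(c, p, r, a) for c, p, r, a in offtarget_scene["records"]
        ]
        outputs = []
        for run in range(2):
            report, summary = ot.adjudicate(
                genome, {"g": guide}, variants, n_background=500, seed=7
            )
            path = tmp_path / f"report{run}.tsv"
            ot.write_report(report, summary, path)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]
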