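"""Demultiplexing, MPAF tallying/classification, chimera screening,
grey-zone resolution, allele naming, genotype calls and replicates."""

import numpy as np
import pandas as pd
import pytest

from bearmhc import genotyping as gt
from bearmhc.genotyping import (Amplicon, CLASS_I_THRESHOLDS,
                                ClassificationThresholds, DRB_THRESHOLDS,
                                classify_variants, demultiplex,
                                detect_chimeras, name_alleles,
                                replicate_concordance, resolve_grey_zone,
                                tally_variants)
from bearmhc.simdata import AlleleSequence, revcomp

PF, PR = "GCTCCCACTCCCTGAGGTAT", "CCACGCTCTGGTTGTAGTA"


def tag_map(rows):
    return pd.DataFrame(rows, columns=["amplicon_id", "tag", "individual",
                                       "marker", "template", "replicate"])


def amp(aid, counts, individual="i1", template="gDNA", replicate=1):
    return Amplicon(aid, individual, "U", replicate, template,
                    dict(counts))


class TestDemultiplex:
    TM = tag_map([("a1", "AAAAAA", "i1", "U", "gDNA", 1),
                  ("a2", "CCCTTT", "i2", "U", "gDNA", 1)])

    def test_exact_read_assigned_and_trimmed(self):
        insert = "ACGT" * 12
        read = ("r1", "AAAAAA" + PF + insert + revcomp(PR))
        amps, stats = demultiplex([read], self.TM, PF, PR)
        a1 = next(a for a in amps if a.amplicon_id == "a1")
        assert a1.variant_counts == {insert: 1}
        assert stats.n_assigned == 1

    def test_one_mismatch_in_tag_unassigned(self):
        insert = "ACGT" * 12
        read = ("r1", "AAATAA" + PF + insert + revcomp(PR))
        amps, stats = demultiplex([read], self.TM, PF, PR)
        assert stats.n_assigned == 0 and stats.n_bad_tag == 1
        assert all(not a.variant_counts for a in amps)

    def test_missing_primer_dropped(self):
        read = ("r1", "AAAAAA" + "T" * len(PF) + "ACGT" * 12 + revcomp(PR))
        _, stats = demultiplex([read], self.TM, PF, PR)
        assert stats.n_bad_primer == 1 and stats.n_assigned == 0

    def test_duplicate_or_close_tags_rejected(self):
        tm = tag_map([("a1", "AAAAAA", "i1", "U", "gDNA", 1),
                      ("a2", "AAAAAA", "i2", "U", "gDNA", 1)])
        with pytest.raises(ValueError):
            demultiplex([("r", "A" * 60)], tm, PF, PR)
        tm2 = tag_map([("a1", "AAAAAA", "i1", "U", "gDNA", 1),
                       ("a2", "AAAATT", "i2", "U", "gDNA", 1)])
        with pytest.raises(ValueError):
            demultiplex([("r", "A" * 60)], tm2, PF, PR)

    def test_empty_read_collection_fails(self):
        with pytest.raises(ValueError):
            demultiplex([], self.TM, PF, PR)

    def test_zero_error_simulation_fully_assigned(self, zero_error_ds,
                                                  zero_error_amplicons):
        amps, stats = zero_error_amplicons
        assert stats.n_assigned == stats.n_reads == len(zero_error_ds.reads)
        # every read lands in its true amplicon
        by_id = {a.amplicon_id: a for a in amps}
        truth_counts = {}
        for r in zero_error_ds.reads:
            truth_counts[r.amplicon_id] = truth_counts.get(r.amplicon_id, 0) + 1
        for aid, n in truth_counts.items():
            assert by_id[aid].total_reads == n


class TestTally:
    def test_hand_tally_mpaf(self):
        a = amp("A", {"v1": 60, "v2": 30, "v3": 10})
        b = amp("B", {"v1": 50, "v3": 50}, individual="i2")
        recs = {v.sequence: v for v in tally_variants([a, b])}
        assert recs["v1"].mpaf == pytest.approx(0.60)
        assert recs["v3"].mpaf == pytest.approx(0.50)
        assert recs["v2"].mpaf == pytest.approx(0.30)
        assert recs["v1"].n_amplicons == 2
        assert recs["v1"].per_amplicon_frequency["B"] == pytest.approx(0.5)

    def test_single_variant_mpaf_one(self):
        recs = tally_variants([amp("A", {"v": 7})])
        assert recs[0].mpaf == 1.0 and recs[0].n_amplicons == 1

    def test_cdna_excluded_from_mpaf_by_default(self):
        a = amp("A", {"v1": 10, "v2": 90})
        c = amp("C", {"v1": 100}, template="cDNA")
        recs = {v.sequence: v for v in tally_variants([a, c])}
        assert recs["v1"].mpaf == pytest.approx(0.10)
        assert "C" in recs["v1"].per_amplicon_frequency

    def test_mpaf_invariant_to_amplicon_and_read_order(self):
        amps = [amp("A", {"v1": 60, "v2": 40}),
                amp("B", {"v2": 10, "v1": 90}, individual="i2")]
        r1 = {v.sequence: v.mpaf for v in tally_variants(amps)}
        r2 = {v.sequence: v.mpaf for v in tally_variants(amps[::-1])}
        assert r1 == r2


class TestClassify:
    def rec(self, mpaf, reads=100, seq="ACGT"):
        return gt.VariantRecord(seq, {"A": mpaf}, mpaf, 1, reads)

    @pytest.mark.parametrize("mpaf,expected", [
        (0.12, gt.TRUE_ALLELE),   # above the DRB acceptance threshold
        (0.05, gt.ARTIFACT),      # inside the 3-10% interval
        (1.00, gt.TRUE_ALLELE),
        (0.01, gt.ARTIFACT),
    ])
    def test_drb_operating_point(self, mpaf, expected):
        v = classify_variants([self.rec(mpaf)], DRB_THRESHOLDS)[0]
        assert v.classification == expected

    @pytest.mark.parametrize("mpaf,expected", [
        (0.02, gt.GREY_ZONE),     # inside the 1.53-2.86% grey zone
        (0.029, gt.TRUE_ALLELE),
        (0.01, gt.ARTIFACT),
        (1.00, gt.TRUE_ALLELE),
    ])
    def test_class_i_operating_point(self, mpaf, expected):
        v = classify_variants([self.rec(mpaf)], CLASS_I_THRESHOLDS)[0]
        assert v.classification == expected

    def test_sorted_descending_with_deterministic_ties(self):
        vs = [self.rec(0.5, reads=100, seq="CCC"),
              self.rec(0.5, reads=900, seq="AAA"),
              self.rec(0.9, reads=10, seq="TTT"),
              self.rec(0.5, reads=100, seq="AAG")]
        out = classify_variants(vs, CLASS_I_THRESHOLDS)
        assert [v.sequence for v in out] == ["TTT", "AAA", "AAG", "CCC"]

    def test_classification_monotone_in_mpaf(self):
        rank = {gt.ARTIFACT: 0, gt.GREY_ZONE: 1, gt.TRUE_ALLELE: 2}
        for thr in (CLASS_I_THRESHOLDS, DRB_THRESHOLDS):
            grid = np.linspace(1e-4, 1.0, 400)
            ranks = [rank[thr.classify(m)] for m in grid]
            assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            ClassificationThresholds(0.05, 0.03, (0.04, 0.04))


class TestChimeras:
    def make_trio(self):
        v1 = "AAAA" + "C" * 8
        v2 = "GGGG" + "T" * 8
        vc = v1[:6] + v2[6:]  # crossover inside
        return v1, v2, vc

    def test_constructed_recombinant_flagged_with_parents(self):
        v1, v2, vc = self.make_trio()
        amps = [amp("A", {v1: 60, v2: 35, vc: 5}),
                amp("B", {v1: 70, v2: 25, vc: 5}, individual="i2")]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        flagged = detect_chimeras(variants, amps)
        assert [v.sequence for v in flagged] == [vc]
        flag = flagged[0].chimera_flag
        assert {flag.parent1, flag.parent2} == {v1, v2}
        lo, hi = flag.crossover
        k = lo  # any breakpoint in the reported interval reconstructs vc
        assert flag.parent1[:k] + flag.parent2[k:] == vc
        assert flag.parent1[:hi] + flag.parent2[hi:] == vc

    def test_not_flagged_when_parent_missing_in_one_amplicon(self):
        v1, v2, vc = self.make_trio()
        amps = [amp("A", {v1: 60, v2: 35, vc: 5}),
                amp("B", {v1: 95, vc: 5}, individual="i2")]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        assert detect_chimeras(variants, amps) == []

    def test_not_flagged_when_parent_not_more_frequent(self):
        v1, v2, vc = self.make_trio()
        amps = [amp("A", {v1: 60, v2: 5, vc: 35})]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        assert detect_chimeras(variants, amps) == []

    def test_simulated_chimeras_flagged_at_depth_500(self, paperlike_ds,
                                                     paperlike_amplicons,
                                                     paperlike_validation):
        ds = paperlike_ds
        cfg = ds.config
        true_seqs = {a.sequence for a in ds.truth.alleles}
        exact = set()
        for r in ds.reads:
            if r.is_exact_chimera:
                ins = r.sequence[cfg.tag_length + len(cfg.primer_f):
                                 len(r.sequence) - len(cfg.primer_r)]
                if ins not in true_seqs:
                    exact.add(ins)
        flagged = {v.sequence for v in paperlike_validation.variants
                   if v.chimera_flag}
        assert len(exact) > 100
        assert len(exact & flagged) / len(exact) >= 0.9

    def test_every_flag_reconstructs_the_variant(self, paperlike_validation):
        flagged = [v for v in paperlike_validation.variants if v.chimera_flag]
        assert flagged
        for v in flagged:
            f = v.chimera_flag
            for k in (f.crossover[0], f.crossover[1]):
                assert f.parent1[:k] + f.parent2[k:] == v.sequence


class TestGreyZone:
    def grey_setup(self, extra_amp=None):
        v1 = "AAAA" + "C" * 8
        v2 = "GGGG" + "T" * 8
        vg = v1[:6] + v2[6:]
        amps = [amp("A", {v1: 500, v2: 480, vg: 20}),
                amp("B", {v1: 500, v2: 490, vg: 10}, individual="i2")]
        if extra_amp:
            amps.append(extra_amp)
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        return v1, v2, vg, amps, variants

    def test_grey_chimera_becomes_artifact(self):
        v1, v2, vg, amps, variants = self.grey_setup()
        detect_chimeras(variants, amps)
        by_seq = {v.sequence: v for v in variants}
        assert by_seq[vg].classification == gt.GREY_ZONE
        variants, review = resolve_grey_zone(variants, amps)
        assert by_seq[vg].classification == gt.ARTIFACT
        assert review.rule.tolist() == ["chimera"]

    def test_one_off_shadow_becomes_artifact(self):
        v1 = "A" * 12
        shadow = "A" * 11 + "C"
        amps = [amp("A", {v1: 980, shadow: 20})]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        variants, review = resolve_grey_zone(variants, amps)
        by_seq = {v.sequence: v for v in variants}
        assert by_seq[shadow].classification == gt.ARTIFACT
        assert review.rule.tolist() == ["one_off_shadow"]

    def test_replicate_confirmation_becomes_true_allele(self):
        vg = "C" * 6 + "G" * 6
        v1 = "A" * 12
        amps = [amp("A", {v1: 980, vg: 20}, individual="i1", replicate=1),
                amp("B", {v1: 975, vg: 25}, individual="i1", replicate=2)]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        variants, review = resolve_grey_zone(variants, amps)
        by_seq = {v.sequence: v for v in variants}
        assert by_seq[vg].classification == gt.TRUE_ALLELE
        assert review.rule.tolist() == ["replicate_confirmed"]

    def test_unresolved_stays_grey_and_reported(self):
        vg = "C" * 6 + "G" * 6
        v1 = "A" * 12
        amps = [amp("A", {v1: 980, vg: 20})]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        variants, review = resolve_grey_zone(variants, amps)
        by_seq = {v.sequence: v for v in variants}
        assert by_seq[vg].classification == gt.GREY_ZONE
        assert review.rule.tolist() == ["unresolved"]

    def test_decision_file_overrides_and_validates(self):
        vg = "C" * 6 + "G" * 6
        v1 = "A" * 12
        amps = [amp("A", {v1: 980, vg: 20})]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        variants, _ = resolve_grey_zone(variants, amps,
                                        decisions={vg: gt.TRUE_ALLELE})
        by_seq = {v.sequence: v for v in variants}
        assert by_seq[vg].classification == gt.TRUE_ALLELE
        with pytest.raises(ValueError):
            resolve_grey_zone(variants, amps, decisions={"NOPE": gt.ARTIFACT})


class TestNaming:
    def test_names_by_individual_abundance_then_reads(self):
        v_common = "A" * 12
        v_rare_heavy = "C" * 12
        v_rare_light = "G" * 12
        amps = [amp("A", {v_common: 500, v_rare_heavy: 450},
                    individual="i1"),
                amp("B", {v_common: 500, v_rare_light: 50},
                    individual="i2")]
        variants = classify_variants(tally_variants(amps), CLASS_I_THRESHOLDS)
        alleles = name_alleles(variants, amps, "U", "Urar")
        named = {a.sequence: a.name for a in alleles}
        assert named[v_common] == "Urar-U*01"
        assert named[v_rare_heavy] == "Urar-U*02"  # tie on 1 ind, more reads
        assert named[v_rare_light] == "Urar-U*03"

    def test_sixteen_variants_named_bijectively(self):
        import itertools as it
        seqs = ["".join(p) * 6 for p in it.product("ACGT", repeat=2)]
        amps = [amp("A", {s: 100 + i for i, s in enumerate(seqs)})]
        variants = classify_variants(tally_variants(amps), DRB_THRESHOLDS)
        # all at MPAF such that some are artifacts; force all true for naming
        for v in variants:
            v.classification = gt.TRUE_ALLELE
        alleles = name_alleles(variants, amps, "DRB", "Urar")
        names = [a.name for a in alleles]
        assert len(set(names)) == 16
        assert names[0] == "Urar-DRB*01" and names[-1] == "Urar-DRB*16"


class TestGenotypeCalls:
    def test_zero_error_calls_equal_truth(self, zero_error_ds,
                                          zero_error_validation):
        ds = zero_error_ds
        res = zero_error_validation
        name_of = {a.sequence: a.name for a in res.alleles}
        truth_name = {a.sequence: a.name for a in ds.truth.alleles}
        # validated set equals sampled truth set
        sampled = set().union(*ds.truth.genotypes.values())
        sampled_seqs = {a.sequence for a in ds.truth.alleles
                        if a.name in sampled}
        assert set(name_of) == sampled_seqs
        # per-individual allele sets match truth exactly
        seq_by_called = {a.name: a.sequence for a in res.alleles}
        for ind in res.genotypes.individuals:
            called = {truth_name[seq_by_called[n]]
                      for n in res.genotypes.allele_set(ind)}
            assert called == set(ds.truth.genotypes[ind])

    def test_cdna_only_variant_not_in_gdna_table(self):
        allele = AlleleSequence("Urar-U*01", "U", "A" * 12)
        amps = [amp("A", {"A" * 12: 10}, template="cDNA"),
                amp("B", {"C" * 12: 10}, template="gDNA")]
        table = gt.call_genotypes(amps, [allele])
        assert table.presence.loc["i1", "Urar-U*01"] == 0

    def test_paperlike_counts_in_expected_band(self, paperlike_validation):
        counts = paperlike_validation.genotypes.allele_counts()
        assert counts.min() >= 5 and counts.max() <= 11


class TestReplicates:
    def test_perfect_concordance_bound(self):
        calls = {}
        # 10 individuals, 38 calls total, identical replicates
        sizes = [4, 4, 4, 4, 4, 4, 4, 4, 3, 3]
        for i, k in enumerate(sizes):
            s = frozenset(f"al{j}" for j in range(k))
            calls[(f"i{i}", 1)] = s
            calls[(f"i{i}", 2)] = s
        rep = replicate_concordance(calls)
        assert rep["total_calls"] == 38
        assert rep["discordance_rate"] == 0.0
        assert rep["max_error_bound"] == pytest.approx(1 / 38)

    def test_one_discordant_of_fifty(self):
        calls = {}
        for i in range(10):
            s = frozenset(f"al{j}" for j in range(5))
            calls[(f"i{i}", 1)] = s
            calls[(f"i{i}", 2)] = (s - {"al0"}) if i == 0 else s
        rep = replicate_concordance(calls)
        assert rep["total_calls"] == 50
        assert rep["discordance_rate"] == pytest.approx(0.02)

    def test_zero_error_simulation_concordant(self, zero_error_amplicons,
                                              zero_error_validation):
        amps, _ = zero_error_amplicons
        calls = gt.call_genotypes_by_replicate(
            amps, zero_error_validation.alleles)
        rep = replicate_concordance(calls)
        assert rep["discordance_rate"] == 0.0

    def test_no_replicates_is_error(self):
        with pytest.raises(ValueError):
            replicate_concordance({("i1", 1): frozenset({"a"})})
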