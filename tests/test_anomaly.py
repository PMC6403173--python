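import numpy as np
import pytest

from proteoclust.anomaly import (check_synteny_pair, detect_fragment_pairs,
                                 detect_merged, detect_mislabeled,
                                 detect_missing_members, detect_truncated,
                                 infer_label_map)
from proteoclust.simulate import (SimulationConfig, generate_ancestral_family,
                                  generate_pan_proteome)

from conftest import ZERO_RATES, make_proteome, make_record


def _cluster_of_lengths(lengths, organism="org1"):
    recs = [make_record(seq_id=f"s{i}", organism_id=organism, start=1 + 5000 * i,
                        sequence="M" * L)
            for i, L in enumerate(lengths)]
    return make_proteome(recs), [r.seq_id for r in recs]


def _truth_assignment(truth):
    return {sid: int(f[3:]) for sid, f in truth.family_of().items()}


class TestDetectTruncated:
    def test_flags_much_shorter_members(self):
        prot, mem = _cluster_of_lengths([546, 546, 546, 546, 292, 385])
        found = detect_truncated(mem, prot)
        flagged = {f.seq_ids[0] for f in found}
        assert flagged == {"s4", "s5"}
        # ranked by deviation: 292 before 385
        assert found[0].seq_ids == ("s4",)
        assert found[0].evidence == {"length": 292, "median": 546.0}

    def test_median_member_not_flagged(self):
        prot, mem = _cluster_of_lengths([546, 546, 546])
        assert detect_truncated(mem, prot) == []

    def test_overlong_members_flagged(self):
        prot, mem = _cluster_of_lengths([500, 500, 500, 700])
        found = detect_truncated(mem, prot)
        assert [f.seq_ids[0] for f in found] == ["s3"]

    def test_small_cluster_rejected(self):
        prot, mem = _cluster_of_lengths([100, 100])
        with pytest.raises(ValueError):
            detect_truncated(mem, prot)


class TestDetectFragmentPairs:
    def _fragmented_setup(self):
        # family cluster of four full-length members plus one organism whose
        # gene is split 385 + 161 with a 50 bp gap
        recs = [make_record(seq_id=f"full{i}", organism_id=f"org{i}",
                            sequence="M" * 546, start=1000)
                for i in range(4)]
        p1 = make_record(seq_id="frag_p1", organism_id="orgX",
                         sequence="M" * 385, start=1000)
        p2 = make_record(seq_id="frag_p2", organism_id="orgX",
                         sequence="M" * 161, start=p1.end + 51)
        prot = make_proteome(recs + [p1, p2])
        assignment = {r.seq_id: 0 for r in recs}
        assignment.update({"frag_p1": 0, "frag_p2": 5})
        return prot, assignment

    def test_flags_adjacent_pair_summing_to_median(self):
        prot, assignment = self._fragmented_setup()
        found = detect_fragment_pairs(prot, assignment)
        assert len(found) == 1
        f = found[0]
        assert f.seq_ids == ("frag_p1", "frag_p2")
        assert f.evidence["combined"] == 546
        assert abs(f.evidence["combined"] - f.evidence["median"]) <= \
            0.10 * f.evidence["median"]

    def test_adjacent_unrelated_genes_not_flagged(self):
        # two neighbouring genes whose sum is far from any cluster median
        recs = [make_record(seq_id=f"full{i}", organism_id=f"org{i}",
                            sequence="M" * 546, start=1000)
                for i in range(3)]
        a = make_record(seq_id="genA", organism_id="orgX", sequence="M" * 546,
                        start=1000)
        b = make_record(seq_id="genB", organism_id="orgX", sequence="M" * 500,
                        start=a.end + 100)
        prot = make_proteome(recs + [a, b])
        assignment = {r.seq_id: 0 for r in recs}
        assignment.update({"genA": 0, "genB": 1})
        assert detect_fragment_pairs(prot, assignment) == []

    def test_recall_on_seeded_corruptions(self):
        """>= 95% of simulated frameshift fragmentations are recovered."""
        cfg = SimulationConfig(n_organisms=40, n_families=5,
                               paralog_probability=0.0, plasmid_probability=0.0,
                               corruption_rates={**ZERO_RATES, "fragment": 0.15},
                               rng_seed=17)
        prot, truth = generate_pan_proteome(cfg)
        frag = truth.records[truth.records["corruption"] == "fragment"]
        events = {sid.rsplit("_p", 1)[0] for sid in frag["seq_id"]}
        assert len(events) >= 25
        found = detect_fragment_pairs(prot, _truth_assignment(truth))
        hits = {f.seq_ids[0].rsplit("_p", 1)[0] for f in found
                if f.seq_ids[0].endswith("_p1")}
        recall = len(events & hits) / len(events)
        assert recall >= 0.95

    def test_no_false_positives_on_clean_proteome(self, clean_sim):
        prot, truth = clean_sim
        assert detect_fragment_pairs(prot, _truth_assignment(truth)) == []


class TestDetectMerged:
    def test_synthetic_merge_flagged_with_both_halves(self):
        cfg = SimulationConfig(n_organisms=8, n_families=2,
                               family_length_range=(150, 250),
                               paralog_probability=0.0, plasmid_probability=0.0,
                               corruption_rates=dict(ZERO_RATES), rng_seed=23)
        prot, truth = generate_pan_proteome(cfg)
        assignment = _truth_assignment(truth)
        fam = truth.family_of()
        a_mem = sorted(s for s, f in fam.items() if f == "fam00")
        b_mem = sorted(s for s, f in fam.items() if f == "fam01")
        # fuse org00's two family members into one chimeric record
        ra = prot.records[a_mem[0]]
        rb = prot.records[b_mem[0]]
        merged = make_record(seq_id="merged", organism_id="org00",
                             sequence=ra.sequence + rb.sequence, start=900_000)
        prot.records["merged"] = merged
        assignment["merged"] = 99
        found = detect_merged(a_mem, b_mem, prot, assignment)
        assert [f.seq_ids for f in found] == [("merged",)]
        ev = found[0].evidence
        assert ev["cover_a"] >= 0.8 * ev["median_a"]
        assert ev["cover_b"] >= 0.8 * ev["median_b"]

    def test_normal_length_member_not_flagged(self):
        cfg = SimulationConfig(n_organisms=6, n_families=2,
                               family_length_range=(150, 250),
                               paralog_probability=0.0,
                               corruption_rates=dict(ZERO_RATES), rng_seed=29)
        prot, truth = generate_pan_proteome(cfg)
        assignment = _truth_assignment(truth)
        fam = truth.family_of()
        a_mem = sorted(s for s, f in fam.items() if f == "fam00")
        b_mem = sorted(s for s, f in fam.items() if f == "fam01")
        assert detect_merged(a_mem, b_mem, prot, assignment) == []


class TestDetectMissingMembers:
    def test_universal_cluster_no_findings(self, clean_sim):
        prot, truth = clean_sim
        fam = truth.family_of()
        members = [s for s, f in fam.items() if f == "fam00"]
        assert detect_missing_members(members, prot) == []

    def test_two_dropped_organisms_reported(self, clean_sim):
        prot, truth = clean_sim
        fam = truth.family_of()
        members = [s for s, f in fam.items() if f == "fam00"
                   and prot.records[s].organism_id not in ("org03", "org07")]
        found = detect_missing_members(members, prot)
        assert [f.organism_id for f in found] == ["org03", "org07"]

    def test_below_representation_gate_silent(self, clean_sim):
        prot, truth = clean_sim
        fam = truth.family_of()
        members = [s for s, f in fam.items() if f == "fam00"
                   and prot.records[s].organism_id < "org10"]
        assert detect_missing_members(members, prot) == []


class TestDetectMislabeled:
    def _prot(self):
        recs = [make_record(seq_id=f"g{i}", annotation="GroEL",
                            organism_id=f"o{i}") for i in range(4)]
        recs.append(make_record(seq_id="imposter", organism_id="oX",
                                annotation="chaperonin GroEL"))
        recs.append(make_record(seq_id="pol", organism_id="oY",
                                annotation="DNA polymerase I"))
        prot = make_proteome(recs)
        assignment = {f"g{i}": 0 for i in range(4)}
        assignment.update({"imposter": 7, "pol": 3})
        return prot, assignment

    def test_record_outside_home_cluster_flagged(self):
        prot, assignment = self._prot()
        label_map = infer_label_map(["GroEL"], assignment, prot)
        assert label_map == {"GroEL": 0}
        found = detect_mislabeled(assignment, prot, label_map)
        assert [f.seq_ids[0] for f in found] == ["imposter"]

    def test_all_matches_at_home_no_findings(self):
        prot, assignment = self._prot()
        found = detect_mislabeled(assignment, prot, {"polymerase": 3})
        assert found == []

    def test_pattern_without_majority_skipped_with_warning(self):
        prot, assignment = self._prot()
        assignment = dict(assignment)
        assignment.update({"g0": 0, "g1": 0, "g2": 1, "g3": 1})
        with pytest.warns(UserWarning, match="majority"):
            label_map = infer_label_map(["GroEL$"], assignment, prot)
        assert label_map == {}

    def test_precision_recall_on_seeded_relabels(self):
        """Planted wrong-label events are recovered with precision and
        recall >= 0.9 when clusters equal the true families."""
        cfg = SimulationConfig(n_organisms=30, n_families=8,
                               paralog_probability=0.0,
                               corruption_rates={**ZERO_RATES, "relabel": 0.3},
                               rng_seed=31)
        prot, truth = generate_pan_proteome(cfg)
        assignment = _truth_assignment(truth)
        planted = {s for s, c in truth.corruption_of().items() if c == "relabel"}
        assert len(planted) >= 50
        patterns = [rf"\bfam{f:02d}\b" for f in range(8)]
        label_map = infer_label_map(patterns, assignment, prot)
        found = {f.seq_ids[0] for f in detect_mislabeled(assignment, prot, label_map)}
        tp = len(found & planted)
        assert tp / max(len(found), 1) >= 0.9   # precision
        assert tp / len(planted) >= 0.9         # recall


class TestSynteny:
    def test_adjacent_same_strand_conserved(self):
        a = make_record(seq_id="a", start=1000, end=1300)
        b = make_record(seq_id="b", start=1400, end=3000)
        prot = make_proteome([a, b])
        assert check_synteny_pair(prot, ["a"], ["b"]) == {"org1": "conserved"}

    def test_opposite_strand_broken(self):
        a = make_record(seq_id="a", start=1000, end=1300)
        b = make_record(seq_id="b", start=1400, end=3000, strand="-")
        prot = make_proteome([a, b])
        assert check_synteny_pair(prot, ["a"], ["b"]) == {"org1": "broken"}

    def test_minus_strand_upstream_is_genomically_after(self):
        # on the minus strand A upstream of B means A lies 3' (to the right)
        a = make_record(seq_id="a", start=1400, end=3000, strand="-")
        b = make_record(seq_id="b", start=1000, end=1300, strand="-")
        prot = make_proteome([a, b])
        assert check_synteny_pair(prot, ["a"], ["b"]) == {"org1": "conserved"}
        assert check_synteny_pair(prot, ["b"], ["a"]) == {"org1": "broken"}

    def test_missing_member_absent(self):
        a = make_record(seq_id="a")
        prot = make_proteome([a])
        assert check_synteny_pair(prot, ["a"], []) == {"org1": "absent"}

    def test_clean_simulation_pair_fully_conserved(self):
        cfg = SimulationConfig(n_organisms=12, n_families=5,
                               paralog_probability=0.0, plasmid_probability=0.0,
                               corruption_rates=dict(ZERO_RATES), rng_seed=41)
        prot, truth = generate_pan_proteome(cfg)
        fam = truth.family_of()
        members = {f: sorted(s for s, ff in fam.items() if ff == f)
                   for f in {v for v in fam.values()}}
        # find an adjacent family pair transcribed on the same (+) strand
        pair = None
        for f in range(4):
            a, b = f"fam{f:02d}", f"fam{f + 1:02d}"
            if (prot.records[members[a][0]].strand == "+" and
                    prot.records[members[b][0]].strand == "+"):
                pair = (a, b)
                break
        assert pair is not None
        report = check_synteny_pair(prot, members[pair[0]], members[pair[1]])
        assert set(report.values()) == {"conserved"}


def test_detectors_silent_on_clean_proteomes():
    """Zero false positives across every detector on corruption-free
    synthetic proteomes over multiple seeds."""
    for seed in range(202, 208):
        cfg = SimulationConfig(n_organisms=10, n_families=4,
                               family_length_range=(120, 240),
                               paralog_probability=0.0,
                               corruption_rates=dict(ZERO_RATES), rng_seed=seed)
        prot, truth = generate_pan_proteome(cfg)
        assignment = _truth_assignment(truth)
        fam = truth.family_of()
        clusters = {f: sorted(s for s, ff in fam.items() if ff == f)
                    for f in set(fam.values())}
        assert detect_fragment_pairs(prot, assignment) == []
        patterns = [rf"\bfam{f:02d}\b" for f in range(4)]
        label_map = infer_label_map(patterns, assignment, prot)
        assert detect_mislabeled(assignment, prot, label_map) == []
        for mem in clusters.values():
            assert detect_truncated(mem, prot, 0.9, 1.1) == []
            assert detect_missing_members(mem, prot) == []
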