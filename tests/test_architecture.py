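"""Architecture calls, six-group rules, core extraction, Sfth filter."""

import itertools
import random

import pytest

from lhr.architecture import (ClassifierParams, call_architecture,
                              classify_dataset, classify_family,
                              extract_helicase_core, filter_sfth,
                              tabulate_paralog_counts)
from lhr.records import (PF_DOMAIN4, PF_DUF1998, PF_HTH42, PF_INTEIN,
                         PF_RECA1, PF_RECA2, ProfileHit, ProteinRecord)


def _protein(pid="p1", seq=None, taxon="Archaea", length=600):
    return ProteinRecord(pid, "S00", "A00", taxon, seq or "A" * length)


def _hit(pid, profile, e=1e-30, start=1, end=100, plen=100, cov=1.0):
    return ProfileHit(pid, profile, e, 100.0, start, end, plen, cov)


def core_hits(pid, s1=1, e1=140, s2=160, e2=300):
    return [_hit(pid, PF_RECA1, start=s1, end=e1, plen=e1 - s1 + 1),
            _hit(pid, PF_RECA2, start=s2, end=e2, plen=e2 - s2 + 1)]


class TestCallArchitecture:
    def test_core_with_intact_domain4(self):
        p = _protein()
        hits = core_hits("p1") + [_hit("p1", PF_DOMAIN4, start=320, end=430,
                                       plen=120, cov=0.9)]
        call = call_architecture(p, hits)
        assert call.has_core and call.domain4_status == "intact"

    def test_single_core_domain_is_not_core(self):
        p = _protein()
        call = call_architecture(p, [_hit("p1", PF_RECA1)])
        assert not call.has_core
        assert call.domain4_status == "absent"

    def test_low_coverage_domain4_is_deteriorated(self):
        p = _protein()
        hits = core_hits("p1") + [_hit("p1", PF_DOMAIN4, start=320, end=350,
                                       plen=120, cov=0.30)]
        assert call_architecture(p, hits).domain4_status == "deteriorated"

    def test_domain4_above_report_floor_is_absent(self):
        p = _protein()
        hits = core_hits("p1") + [_hit("p1", PF_DOMAIN4, e=0.5, start=320,
                                       end=430, plen=120, cov=0.9)]
        assert call_architecture(p, hits).domain4_status == "absent"

    def test_cys_rich_window_after_domain4(self):
        seq = "A" * 430 + "CCACCAACC" + "A" * 100
        p = _protein(seq=seq)
        hits = core_hits("p1") + [_hit("p1", PF_DOMAIN4, start=320, end=430,
                                       plen=120, cov=0.9)]
        assert call_architecture(p, hits).has_cys_rich_cterm

    def test_cys_outside_window_not_counted(self):
        seq = "A" * 430 + "A" * 120 + "CCCCCC" + "A" * 10
        p = _protein(seq=seq)
        hits = core_hits("p1") + [_hit("p1", PF_DOMAIN4, start=320, end=430,
                                       plen=120, cov=0.9)]
        assert not call_architecture(p, hits).has_cys_rich_cterm

    def test_intein_inside_core_flagged(self):
        p = _protein()
        hits = core_hits("p1") + [_hit("p1", PF_INTEIN, start=50, end=90,
                                       plen=40, cov=1.0)]
        assert call_architecture(p, hits).intein_inserted

    def test_foreign_hits_rejected(self):
        with pytest.raises(ValueError):
            call_architecture(_protein("p1"), [_hit("p2", PF_RECA1)])

    def test_matches_threshold_rule_oracle_on_random_tables(self):
        rng = random.Random(13)
        params = ClassifierParams()
        for _ in range(50):
            pid = "px"
            hits = []
            if rng.random() < 0.8:
                hits += core_hits(pid)
            d4_cov = rng.choice([None, 0.2, 0.3, 0.49, 0.5, 0.9])
            d4_e = rng.choice([1e-30, 1e-2])
            if d4_cov is not None:
                span = max(1, int(120 * d4_cov))
                hits.append(_hit(pid, PF_DOMAIN4, e=d4_e, start=320,
                                 end=319 + span, plen=120, cov=d4_cov))
            if rng.random() < 0.4:
                hits.append(_hit(pid, PF_HTH42, start=460, end=520, plen=60))
            call = call_architecture(_protein(pid), hits, params)
            # independent re-derivation
            passing = [h for h in hits if h.profile_id == PF_DOMAIN4
                       and h.e_value <= 1e-3]
            if not passing:
                want = "absent"
            elif max(h.coverage for h in passing) >= 0.5:
                want = "intact"
            else:
                want = "deteriorated"
            assert call.domain4_status == want
            assert call.has_core == (
                any(h.profile_id == PF_RECA1 for h in hits) and
                any(h.profile_id == PF_RECA2 for h in hits))
            assert call.has_hth42 == any(h.profile_id == PF_HTH42
                                         for h in hits)


class TestClassifyFamily:
    def _call(self, core=True, d4="intact", hth=False, cys=False):
        from lhr.architecture import ArchitectureCall
        return ArchitectureCall("p", core, d4, hth, cys, False)

    @pytest.mark.parametrize("taxon,d4,hth,cys,label", [
        ("Archaea", "intact", False, True, "aLhr1"),
        ("Asgard", "intact", False, True, "aLhr1"),
        ("Archaea", "intact", False, False, "aLhr2"),
        ("Archaea", "intact", True, False, "aLhr2"),   # HTH tolerated
        ("Archaea", "deteriorated", False, False, "aLhr3"),
        ("Bacteria", "intact", True, False, "bLhr-HTH"),
        ("Bacteria", "intact", False, False, "bLhr"),
        ("Bacteria", "absent", False, False, "Lhr-like"),
        ("Archaea", "absent", False, False, "Lhr-like"),
    ])
    def test_rule_table(self, taxon, d4, hth, cys, label):
        a = classify_family(self._call(d4=d4, hth=hth, cys=cys), taxon)
        assert a.label == label

    def test_no_core_is_unclassified(self):
        a = classify_family(self._call(core=False), "Archaea")
        assert a.label == "unclassified"

    def test_total_function_over_flag_space(self):
        taxa = ("Archaea", "Bacteria", "Asgard")
        statuses = ("intact", "deteriorated", "absent")
        for core, d4, hth, cys, taxon in itertools.product(
                (True, False), statuses, (True, False), (True, False), taxa):
            a = classify_family(self._call(core, d4, hth, cys), taxon)
            assert a.label in {"aLhr1", "aLhr2", "aLhr3", "bLhr", "bLhr-HTH",
                               "Lhr-like", "unclassified"}
            if a.label != "unclassified":
                assert a.evidence.has_core

    def test_planted_labels_recovered_exactly(self, planted_dataset):
        assignments = classify_dataset(planted_dataset.proteins,
                                       planted_dataset.profile_hits)
        for a in assignments:
            assert a.label == planted_dataset.truth_labels[a.protein_id]


class TestExtractCore:
    def test_disjoint_intervals_concatenated(self):
        p = _protein(length=400)
        hits = core_hits("p1", 10, 100, 150, 300)
        assert len(extract_helicase_core(p, hits)) == 91 + 151

    def test_overlapping_intervals_merged(self):
        p = _protein(length=400)
        hits = core_hits("p1", 10, 100, 90, 200)
        assert len(extract_helicase_core(p, hits)) == 191

    def test_missing_core_hit_rejected(self):
        with pytest.raises(ValueError):
            extract_helicase_core(_protein(), [_hit("p1", PF_RECA1)])

    def test_content_matches_coordinates(self):
        seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(400))
        p = _protein(seq=seq)
        hits = core_hits("p1", 11, 40, 61, 90)
        assert extract_helicase_core(p, hits) == seq[10:40] + seq[60:90]

    def test_cores_align_better_than_full_sequences(self, planted_dataset):
        # within one family, extracted cores keep the conserved region only
        from lhr.pairwise import align_local
        by_protein = {}
        for h in planted_dataset.profile_hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        fam0 = [p for p in planted_dataset.proteins
                if planted_dataset.truth_clusters[p.protein_id] == 0][:3]
        for p in fam0:
            core = extract_helicase_core(p, by_protein[p.protein_id])
            assert 0 < len(core) < p.length


class TestSfthFilter:
    def _with(self, pid, profiles):
        return [_hit(pid, pr) for pr in profiles]

    def test_counts_complete_architectures(self):
        hits, prots = [], []
        for i in range(5):
            pid = f"sfth{i}"
            prots.append(_protein(pid))
            hits += self._with(pid, (PF_RECA1, PF_DUF1998, PF_RECA2))
        for i in range(5):
            pid = f"lhr{i}"
            prots.append(_protein(pid))
            hits += self._with(pid, (PF_RECA1, PF_RECA2, PF_DOMAIN4))
        kept = filter_sfth(prots, hits)
        assert kept == {f"sfth{i}" for i in range(5)}

    def test_missing_duf1998_excluded(self):
        p = _protein("x")
        hits = self._with("x", (PF_RECA1, PF_RECA2))
        assert filter_sfth([p], hits) == set()


class TestParalogCounts:
    def test_matches_direct_group_by(self, planted_dataset):
        assignments = classify_dataset(planted_dataset.proteins,
                                       planted_dataset.profile_hits)
        genome_of = {p.protein_id: p.genome_id
                     for p in planted_dataset.proteins}
        table = tabulate_paralog_counts(assignments, genome_of)
        # independent tally
        import collections
        tally = collections.Counter(
            (genome_of[a.protein_id], a.label) for a in assignments
            if a.label != "unclassified")
        for (genome, label), count in tally.items():
            assert table.loc[genome, label] == count
        assert int(table.values.sum()) == sum(tally.values())

    def test_genome_without_classified_proteins_zero_row(self):
        genome_of = {"p1": "G1"}
        table = tabulate_paralog_counts([], genome_of)
        assert int(table.loc["G1"].sum()) == 0
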