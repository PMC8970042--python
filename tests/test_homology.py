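"""Assignment rules, reference classifier, four-step orchestration."""

import collections

import numpy as np
import pytest

from synfam.align import SearchHit
from synfam.homology import (Assignment, AssignmentRule, RELAXED_GROUP_RULE,
                             STRICT_SUBGROUP_RULE, ReferenceHomologyClassifier,
                             apply_assignment_rule, apply_group_rule,
                             build_reference_dataset, classify_new_species,
                             parse_reference_fasta)
from synfam.records import ConfigError, DataError, ProteinRecord
from synfam.simulate import mutate_sequence

from conftest import random_protein


def hit(identity=70.0, align_len=200, evalue=1e-20, subject="ref1",
        bitscore=300.0):
    return SearchHit("q", subject, identity, align_len, bitscore, evalue)


def query(length=200):
    return ProteinRecord("q", "sp", "A" * length)


class TestRuleBoundaries:
    @pytest.mark.parametrize("rule, identity, evalue, alen, qlen, ok", [
        # strict rule: identity boundary at exactly 60
        (STRICT_SUBGROUP_RULE, 60.0, 1e-10, 130, 200, True),
        (STRICT_SUBGROUP_RULE, 59.9, 1e-10, 130, 200, False),
        # coverage branch: >= 60% of the query length
        (STRICT_SUBGROUP_RULE, 65.0, 1e-10, 120, 200, True),   # 0.600
        (STRICT_SUBGROUP_RULE, 65.0, 1e-10, 119, 200, False),  # 0.595
        # absolute-length branch: >= 150 aa rescues long queries
        (STRICT_SUBGROUP_RULE, 70.0, 1e-20, 150, 400, True),
        (STRICT_SUBGROUP_RULE, 70.0, 1e-20, 149, 400, False),
        # e-value boundary
        (STRICT_SUBGROUP_RULE, 70.0, 1e-5, 200, 200, True),
        (STRICT_SUBGROUP_RULE, 70.0, 2e-5, 200, 200, False),
        # relaxed group rule
        (RELAXED_GROUP_RULE, 40.0, 1e-8, 150, 300, True),
        (RELAXED_GROUP_RULE, 39.9, 1e-8, 150, 300, False),
        (RELAXED_GROUP_RULE, 45.0, 1e-8, 100, 300, True),   # 100-aa branch
        (RELAXED_GROUP_RULE, 45.0, 1e-8, 99, 300, False),
        (RELAXED_GROUP_RULE, 45.0, 1e-8, 120, 300, True),   # 0.40 coverage
    ])
    def test_threshold_boundaries(self, rule, identity, evalue, alen, qlen, ok):
        assert rule.satisfied_by(hit(identity, alen, evalue), qlen) is ok

    def test_relaxing_a_threshold_never_unassigns(self):
        """Rule monotonicity: any hit satisfying the strict rule also
        satisfies every relaxation of it."""
        rng = np.random.default_rng(20)
        relaxed = AssignmentRule(50.0, 1e-3, 0.5, 120)
        for _ in range(200):
            h = hit(identity=float(rng.uniform(30, 100)),
                    align_len=int(rng.integers(50, 400)),
                    evalue=float(10 ** rng.uniform(-30, -3)))
            qlen = int(rng.integers(100, 600))
            if STRICT_SUBGROUP_RULE.satisfied_by(h, qlen):
                assert relaxed.satisfied_by(h, qlen)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            AssignmentRule(0.0, 1e-5, 0.6, 150)


class TestApplyRule:
    def test_best_qualifying_hit_wins(self):
        hits = [hit(59.0, 300, 1e-30, "refA", bitscore=500),
                hit(80.0, 300, 1e-30, "refB", bitscore=400),
                hit(90.0, 300, 1e-30, "refC", bitscore=300)]
        a = apply_assignment_rule(query(300), hits, STRICT_SUBGROUP_RULE,
                                  {"refA": "IA", "refB": "IIB", "refC": "IIC"})
        assert a.label == "IIB"  # refA fails the rule, refB outranks refC

    def test_no_qualifying_hit_gives_none(self):
        hits = [hit(59.9, 300, 1e-30)]
        assert apply_assignment_rule(query(300), hits, STRICT_SUBGROUP_RULE,
                                     {"ref1": "IA"}) is None

    def test_unlabeled_subject_skipped_with_warning(self):
        hits = [hit(80, 300, 1e-30, "mystery", bitscore=500),
                hit(80, 300, 1e-30, "refB", bitscore=400)]
        with pytest.warns(UserWarning, match="mystery"):
            a = apply_assignment_rule(query(300), hits, STRICT_SUBGROUP_RULE,
                                      {"refB": "IIB"})
        assert a.label == "IIB"

    def test_group_rule_labels_at_group_level(self):
        a = apply_group_rule(query(300), [hit(45, 150, 1e-8)],
                             RELAXED_GROUP_RULE, {"ref1": "II"})
        assert a.level == "group_only" and a.label == "II"

    def test_assignment_level_invariants(self):
        with pytest.raises(DataError):
            Assignment("g", "subgroup", None, "step1_cluster")
        with pytest.raises(DataError):
            Assignment("g", "bogus", "IA", None)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(21)
    refs, labels = [], []
    for sg in ("IA", "IIB"):
        anc = random_protein(rng, 400)
        for i in range(4):
            refs.append(ProteinRecord(f"{sg}_r{i}", "spR",
                                      mutate_sequence(anc, 0.13, rng)))
            labels.append(sg)
    return refs, labels


class TestReferenceClassifier:

    def test_self_classification_returns_own_label(self, reference):
        refs, labels = reference
        clf = ReferenceHomologyClassifier().fit(refs, labels)
        assert clf.predict(refs) == labels
        for r in refs:
            top = clf.search(r)[0]
            assert top.subject_id == r.gene_id and top.pct_identity == 100.0

    def test_derived_queries_recover_source_labels(self, reference):
        rng = np.random.default_rng(22)
        refs, labels = reference
        clf = ReferenceHomologyClassifier().fit(refs, labels)
        queries = [ProteinRecord(f"q{i}", "spQ",
                                 mutate_sequence(r.sequence, 0.1, rng))
                   for i, r in enumerate(refs)]
        assert clf.predict(queries) == labels

    def test_random_query_is_unassigned(self, reference):
        refs, labels = reference
        clf = ReferenceHomologyClassifier().fit(refs, labels)
        rng = np.random.default_rng(23)
        assert clf.predict([ProteinRecord("r", "spQ",
                                          random_protein(rng, 400))]) == [None]

    def test_sklearn_estimator_contract(self, reference):
        from sklearn.base import clone
        refs, labels = reference
        est = ReferenceHomologyClassifier(k=3)
        cloned = clone(est)
        assert cloned.get_params()["k"] == 3
        est.fit(refs, labels)
        assert est.classes_ == ["IA", "IIB"]
        with pytest.raises(ConfigError):
            ReferenceHomologyClassifier().fit([], [])


class TestFourStep:
    def test_every_gene_has_exactly_one_assignment(self, small_dataset,
                                                   small_result):
        records = {r.gene_id for r in small_dataset.records}
        assert set(small_result.assignments) == records

    def test_step_bookkeeping_identity(self, small_result):
        by_level = collections.Counter(
            a.level for a in small_result.assignments.values())
        by_step = collections.Counter(
            a.step for a in small_result.assignments.values()
            if a.level == "subgroup")
        assert sum(by_step.values()) == by_level["subgroup"]
        assert (by_level["subgroup"] + by_level["group_only"]
                + by_level["unclassified"] + by_level["non_family"]
                ) == len(small_result.assignments)

    def test_truncated_fragment_recovered_at_step2(self, small_dataset,
                                                   small_result):
        truncs = [g for g, kind in small_dataset.truth.degenerates.items()
                  if kind == "truncation"]
        assert truncs
        for g in truncs:
            a = small_result.assignments[g]
            assert a.level == "subgroup" and a.step == "step2_homology"

    def test_decoys_end_as_non_family(self, small_dataset, small_result):
        for g in small_dataset.truth.decoys:
            assert small_result.assignments[g].level == "non_family"

    def test_audit_is_deterministic(self, small_dataset, small_config,
                                    small_result):
        from synfam.pipeline import inputs_from_dataset, run_full_pipeline
        again = run_full_pipeline(inputs_from_dataset(small_dataset),
                                  small_config)
        assert again.audit.equals(small_result.audit)
        assert again.assignments == small_result.assignments


class TestReferenceDataset:
    def test_export_format_and_roundtrip(self, tmp_path, small_dataset,
                                         small_result):
        path = tmp_path / "reference.faa"
        records = {r.gene_id: r for r in small_dataset.records}
        kept = build_reference_dataset(small_result.assignments, records,
                                       small_result.architectures, path=path)
        assert kept
        lines = path.read_text().splitlines()
        headers = [l for l in lines if l.startswith(">")]
        assert all(h.count("|") == 4 for h in headers)
        parsed = parse_reference_fasta(path)
        assert len(parsed) == len(kept)
        for (rec, label, step), (orig, olabel, ostep) in zip(parsed, kept):
            assert (rec.gene_id, rec.sequence, label, step) == \
                (orig.gene_id, orig.sequence, olabel, ostep)

    def test_length_350_is_excluded_from_reference(self):
        rec = ProteinRecord("short", "sp", "A" * 350)
        a = {"short": Assignment("short", "subgroup", "IA", "step1_cluster")}
        assert build_reference_dataset(a, {"short": rec}) == []
        rec2 = ProteinRecord("ok", "sp", "A" * 351)
        a2 = {"ok": Assignment("ok", "subgroup", "IA", "step1_cluster")}
        assert len(build_reference_dataset(a2, {"ok": rec2})) == 1


class TestClassifyNewSpecies:
    def test_planted_new_species_recovery(self, tmp_path, small_dataset,
                                          small_result):
        """A synthetic new species derived from the classified reference
        at ~75% identity recovers every planted label."""
        rng = np.random.default_rng(24)
        records = {r.gene_id: r for r in small_dataset.records}
        path = tmp_path / "reference.faa"
        build_reference_dataset(small_result.assignments, records,
                                small_result.architectures, path=path)
        reference = parse_reference_fasta(path)
        picks = [t for t in reference][::4][:12]
        queries = [ProteinRecord(f"new{i:02d}", "NewSp",
                                 mutate_sequence(rec.sequence, 0.13, rng))
                   for i, (rec, _l, _s) in enumerate(picks)]
        out = classify_new_species(queries, path)
        for q, (_rec, label, _step) in zip(queries, picks):
            assert out[q.gene_id].level == "subgroup"
            assert out[q.gene_id].label == label

    def test_random_protein_stays_unclassified(self, tmp_path, small_dataset,
                                               small_result):
        rng = np.random.default_rng(25)
        records = {r.gene_id: r for r in small_dataset.records}
        path = tmp_path / "reference.faa"
        build_reference_dataset(small_result.assignments, records,
                                small_result.architectures, path=path)
        out = classify_new_species(
            [ProteinRecord("junk", "NewSp", random_protein(rng, 400))], path,
            relaxed_rule=RELAXED_GROUP_RULE)
        assert out["junk"].level == "unclassified"

    def test_empty_reference_is_config_error(self, tmp_path):
        path = tmp_path / "empty.faa"
        path.write_text("")
        with pytest.raises(ConfigError):
            classify_new_species([query()], path)
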