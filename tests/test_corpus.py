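"""Corpus data model: serialization round-trips, patient-level splitting,
class distributions."""

import json

import pytest

import radresponse as rr
from radresponse.corpus import (
    CorpusFormatError,
    CorpusIntegrityError,
    largest_remainder,
)

from conftest import make_record


class TestResponseLabel:
    def test_code_name_bijection_is_fixed(self):
        assert [l.name for l in rr.ResponseLabel] == ["NED", "PR", "SD", "PD"]
        assert [int(l) for l in rr.ResponseLabel] == [0, 1, 2, 3]

    @pytest.mark.parametrize("value,expected", [
        ("ned", rr.ResponseLabel.NED), ("Pd", rr.ResponseLabel.PD),
        (1, rr.ResponseLabel.PR), ("2", rr.ResponseLabel.SD),
    ])
    def test_parse_accepts_names_and_codes(self, value, expected):
        assert rr.ResponseLabel.parse(value) == expected

    def test_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            rr.ResponseLabel.parse("complete response")


class TestRecordsAndCorpus:
    def test_empty_conclusion_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_record("   \t  ")

    def test_duplicate_report_ids_rejected(self):
        recs = [make_record("Stable disease.", rid="R1"),
                make_record("Stable disease.", rid="R1", pid="P2")]
        with pytest.raises(CorpusIntegrityError, match="duplicate"):
            rr.Corpus(recs)

    def test_patient_spanning_two_splits_rejected(self):
        a = make_record("Stable.", rid="R1", pid="P1").with_split("train")
        b = make_record("Stable.", rid="R2", pid="P1").with_split("test")
        with pytest.raises(CorpusIntegrityError, match="spans"):
            rr.Corpus([a, b])


class TestSerialization:
    def test_round_trip_identity(self, tmp_path, small_corpus):
        sub = rr.Corpus(small_corpus.records[:10])
        path = tmp_path / "c.jsonl"
        rr.write_corpus(sub, path)
        back = rr.read_corpus(path)
        assert len(back) == 10
        assert all(a == b for a, b in zip(sub, back))

    def test_empty_corpus_round_trip(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        rr.write_corpus(rr.Corpus([]), path)
        assert len(rr.read_corpus(path)) == 0

    def test_missing_field_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        good = {"report_id": "R1", "patient_id": "P1",
                "conclusion_text": "Stable.", "label": "SD"}
        bad = {k: v for k, v in good.items() if k != "label"}
        bad["report_id"] = "R2"
        path.write_text(json.dumps(good) + "\n" + json.dumps(bad) + "\n")
        with pytest.raises(CorpusFormatError, match="line 2.*label"):
            rr.read_corpus(path)

    def test_integer_label_codes_accepted_on_read(self, tmp_path):
        path = tmp_path / "codes.jsonl"
        path.write_text(json.dumps({
            "report_id": "R1", "patient_id": "P1",
            "conclusion_text": "Stable.", "label": 3}) + "\n")
        assert rr.read_corpus(path)[0].label == rr.ResponseLabel.PD


class TestSplitByPatient:
    def test_exact_apportionment_10_patients(self):
        recs = [make_record("Stable disease.", rid=f"R{i}", pid=f"P{i % 10}")
                for i in range(30)]
        out = rr.split_by_patient(rr.Corpus(recs), rr.SplitSpec(seed=0))
        per_split = {s: {r.patient_id for r in out if r.split == s}
                     for s in ("train", "dev", "test")}
        assert (len(per_split["train"]), len(per_split["dev"]),
                len(per_split["test"])) == (8, 1, 1)

    def test_deterministic_given_seed(self, small_corpus):
        a = rr.split_by_patient(small_corpus, rr.SplitSpec(seed=5))
        b = rr.split_by_patient(small_corpus, rr.SplitSpec(seed=5))
        assert [r.split for r in a] == [r.split for r in b]

    def test_patient_disjointness_and_counts_at_1000(self):
        recs = [make_record("Stable disease.", rid=f"R{i}", pid=f"P{i // 2}")
                for i in range(2000)]
        out = rr.split_by_patient(rr.Corpus(recs), rr.SplitSpec(seed=3))
        patients = {s: {r.patient_id for r in out if r.split == s}
                    for s in ("train", "dev", "test")}
        assert (len(patients["train"]), len(patients["dev"]),
                len(patients["test"])) == (800, 100, 100)
        assert not (patients["train"] & patients["dev"])
        assert not (patients["train"] & patients["test"])
        assert not (patients["dev"] & patients["test"])

    def test_too_few_patients_rejected(self):
        recs = [make_record("Stable.", rid="R1", pid="P1"),
                make_record("Stable.", rid="R2", pid="P2")]
        with pytest.raises(ValueError, match="patients"):
            rr.split_by_patient(rr.Corpus(recs), rr.SplitSpec())

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            rr.SplitSpec(fractions=(0.8, 0.1, 0.2))


class TestLargestRemainder:
    @pytest.mark.parametrize("total,fracs,expected", [
        (10, (0.8, 0.1, 0.1), [8, 1, 1]),
        (100, (0.39, 0.11, 0.14, 0.36), [39, 11, 14, 36]),
        (25, (0.8, 0.1, 0.1), [20, 3, 2]),  # remainder tie -> lower index
        (7, (0.5, 0.5), [4, 3]),
    ])
    def test_apportionment(self, total, fracs, expected):
        counts = largest_remainder(total, fracs)
        assert counts == expected
        assert sum(counts) == total


class TestClassDistribution:
    def test_reported_class_percentages(self):
        """Distribution computed from the study's printed per-class counts."""
        counts = {rr.ResponseLabel.NED: 4133, rr.ResponseLabel.PR: 1204,
                  rr.ResponseLabel.SD: 1531, rr.ResponseLabel.PD: 3734}
        recs, i = [], 0
        for label, n in counts.items():
            for _ in range(n):
                recs.append(make_record("Stable disease.", label=label,
                                        rid=f"R{i}", pid=f"P{i}"))
                i += 1
        dist = rr.class_distribution(rr.Corpus(recs))
        total = dist[dist.split == "total"].set_index("label")
        assert total.loc["NED", "percent"] == 39.0
        assert total.loc["PR", "percent"] == 11.4
        assert total.loc["SD", "percent"] == 14.4
        assert total.loc["PD", "percent"] == 35.2

    def test_uniform_four_records(self):
        recs = [make_record("Stable disease.", label=l, rid=f"R{i}", pid=f"P{i}")
                for i, l in enumerate(rr.ResponseLabel)]
        dist = rr.class_distribution(rr.Corpus(recs))
        assert (dist[dist.split == "total"].percent == 25.0).all()

    def test_percentages_sum_to_100(self, split_corpus):
        dist = rr.class_distribution(split_corpus)
        sums = dist.groupby("split").percent.sum()
        assert ((sums - 100.0).abs() <= 0.2).all()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            rr.class_distribution(rr.Corpus([]))
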