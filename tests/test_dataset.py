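import io
import itertools

import pytest

from dihedralkd.dataset import (
    PairRecord,
    dedupe_pairs,
    generate_nonbinding,
    load_pairs,
    random_subsets,
    save_pairs,
    split_seen_unseen,
)


def seqs(prefix, n, length=9):
    base = "ACDEFGHIKLMNPQRSTVWY"
    return [(prefix + base * 2)[:length] + base[i % 20] for i in range(n)]


class TestGenerateNonbinding:
    def test_zero_requested_is_empty(self):
        assert generate_nonbinding(["ACD"], ["EFG"], 0) == []

    def test_counts_uniqueness_and_exclusion(self):
        cdr3bs = seqs("C", 10)
        peptides = seqs("P", 20)
        exclude = set(itertools.islice(itertools.product(cdr3bs, peptides), 5))
        out = generate_nonbinding(cdr3bs, peptides, 100, exclude=exclude, seed=3)
        pairs = [(r.cdr3b, r.peptide) for r in out]
        assert len(out) == 100
        assert len(set(pairs)) == 100
        assert not set(pairs) & exclude
        assert all(r.label == 0 for r in out)
        universe = set(itertools.product(cdr3bs, peptides))
        assert set(pairs) <= universe

    def test_deterministic_under_seed(self):
        cdr3bs, peptides = seqs("C", 8), seqs("P", 9)
        a = generate_nonbinding(cdr3bs, peptides, 30, seed=11)
        b = generate_nonbinding(cdr3bs, peptides, 30, seed=11)
        assert [(r.cdr3b, r.peptide) for r in a] == [(r.cdr3b, r.peptide) for r in b]

    def test_insufficient_combinations(self):
        with pytest.raises(ValueError, match="insufficient unique combinations"):
            generate_nonbinding(seqs("C", 2), seqs("P", 2), 5)


class TestSeenUnseen:
    def test_peptide_in_training_with_other_cdr3b_is_seen(self):
        train = [PairRecord("AAAAAAAA", "PEPTIDEA", 1)]
        test = [PairRecord("CCCCCCCC", "PEPTIDEA", 0)]
        assert split_seen_unseen(test, train)[0].stratum == "seen"

    def test_empty_training_set_makes_everything_unseen(self):
        test = [PairRecord("CCCCCCCC", f"PEPTIDE{c}", 1) for c in "AWY"]
        assert all(r.stratum == "unseen" for r in split_seen_unseen(test, []))

    def test_constructed_split_counts_recovered(self):
        seen_peps = seqs("S", 30)
        unseen_peps = seqs("U", 70)
        train = [PairRecord("AAAAAAAA", p, 1) for p in seen_peps]
        test = [PairRecord("CCCCCCCC", p, 0) for p in seen_peps + unseen_peps]
        out = split_seen_unseen(test, train)
        assert sum(r.stratum == "seen" for r in out) == 30
        assert sum(r.stratum == "unseen" for r in out) == 70

    def test_idempotent_and_cdr3b_blind(self):
        train = [PairRecord("AAAAAAAA", "PEPTIDEA", 0)]  # label irrelevant too
        test = [PairRecord("AAAAAAAA", "PEPTIDEB", 1)]  # same cdr3b, new peptide
        once = split_seen_unseen(test, train)
        twice = split_seen_unseen(once, train)
        assert once == twice
        assert once[0].stratum == "unseen"


class TestRandomSubsets:
    def test_even_partition(self):
        data = [PairRecord("AAAAAAAA", p, 1) for p in seqs("P", 100)]
        parts = random_subsets(data, 10, seed=0)
        assert len(parts) == 10
        assert all(len(p) == 10 for p in parts)

    def test_union_is_input_and_disjoint(self):
        data = [PairRecord("AAAAAAAA", p, i % 2) for i, p in enumerate(seqs("P", 23))]
        parts = random_subsets(data, 4, seed=5)
        flat = [r for p in parts for r in p]
        assert sorted(r.peptide for r in flat) == sorted(r.peptide for r in data)
        sizes = sorted(len(p) for p in parts)
        assert sizes[-1] - sizes[0] <= 1

    def test_deterministic_and_error(self):
        data = [PairRecord("AAAAAAAA", p, 1) for p in seqs("P", 12)]
        assert random_subsets(data, 3, seed=2) == random_subsets(data, 3, seed=2)
        with pytest.raises(ValueError, match="more subsets than records"):
            random_subsets(data, 13)


class TestCsvIO:
    def test_round_trip_and_invalid_sequence_dropped(self):
        csv = io.StringIO(
            "cdr3b,peptide,label,source_tag,extra\n"
            "CASSLGTDTQYF,GILGFVFTL,1,vdj,x\n"
            "CASS123,GILGFVFTL,1,vdj,x\n"          # invalid characters
            "CASRRGDTEAFF,NLVPMVATV,0,,y\n"
        )
        records = load_pairs(csv)
        assert len(records) == 2
        assert records[0].source_tag == "vdj"
        buf = io.StringIO()
        save_pairs(records, buf)
        buf.seek(0)
        again = load_pairs(buf)
        assert [(r.cdr3b, r.peptide, r.label) for r in again] == [
            (r.cdr3b, r.peptide, r.label) for r in records
        ]


def test_dedupe_conflict_resolves_to_binding():
    records = [
        PairRecord("CASSLGTDTQYF", "GILGFVFTL", 0),
        PairRecord("CASSLGTDTQYF", "GILGFVFTL", 1),
        PairRecord("CASRRGDTEAFF", "NLVPMVATV", 0),
        PairRecord("CASRRGDTEAFF", "NLVPMVATV", 0),
    ]
    out = {(r.cdr3b, r.peptide): r.label for r in dedupe_pairs(records)}
    assert len(out) == 2
    assert out[("CASSLGTDTQYF", "GILGFVFTL")] == 1
    assert out[("CASRRGDTEAFF", "NLVPMVATV")] == 0


def test_pair_record_validation():
    with pytest.raises(ValueError):
        PairRecord("CASS", "PEP", 2)
    with pytest.raises(ValueError):
        PairRecord("", "PEP", 1)
    with pytest.raises(ValueError):
        PairRecord("A" * 20, "PEP", 1)
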