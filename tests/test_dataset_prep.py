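"""Dataset construction: windows, negatives, dedup, balance, split, merge."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import random_protein
from dephoslearn import dataset_prep as dp
from dephoslearn.records import (
    ProteinRecord,
    SiteAnnotation,
    SiteDataset,
    ValidationError,
    WindowExample,
)


def brute_force_windows(proteins, sites, window_size):
    """Independent enumerator: every site whose flank fits yields one window."""
    flank = (window_size - 1) // 2
    by_id = {p.id: p for p in proteins}
    out = []
    for s in sites:
        seq = by_id[s.protein_id].sequence
        if s.position - flank >= 1 and s.position + flank <= len(seq):
            out.append((s.protein_id, s.position,
                        seq[s.position - flank - 1 : s.position + flank]))
    return out


class TestLoadFasta:
    def test_round_trip_parses_all_entries(self, fasta_file, tiny_proteins):
        records = dp.load_fasta(fasta_file)
        assert len(records) == len(tiny_proteins)
        assert {r.id for r in records} == {p.id for p in tiny_proteins}
        for got, want in zip(sorted(records, key=lambda r: r.id),
                             sorted(tiny_proteins, key=lambda r: r.id)):
            assert got.sequence == want.sequence

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert dp.load_fasta(path) == []

    def test_lowercase_sequences_are_uppercased(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">P1\nacDefGHik\n")
        (record,) = dp.load_fasta(path)
        assert record.sequence == "ACDEFGHIK"

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">P1\nACDEF\n>P1\nGHIKL\n")
        with pytest.raises(ValidationError, match="duplicate"):
            dp.load_fasta(path)


class TestLoadSiteTable:
    def test_valid_rows_accepted(self, fasta_file, sites_file):
        proteins = dp.load_fasta(fasta_file)
        sites = dp.load_site_table(sites_file, proteins)
        assert len(sites) == 3
        assert all(s.label == "positive" for s in sites)

    def test_residue_mismatch_rejected_in_strict_mode(self, tmp_path, tiny_proteins):
        path = tmp_path / "bad.tsv"
        bad = SiteAnnotation("P1", 1, "S", "positive", "synthetic")  # P1[1] is A
        dp.write_site_table([bad], path)
        with pytest.raises(ValidationError, match="annotated S"):
            dp.load_site_table(path, tiny_proteins, strict=True)

    def test_permissive_mode_drops_only_invalid_rows(self, tmp_path, rng):
        proteins = [random_protein(rng, f"P{i}", 60) for i in range(10)]
        rows, n_bad = [], 0
        for i, p in enumerate(proteins * 10):
            pos = int(rng.integers(1, len(p) + 1))
            residue = p.residue(pos)
            if residue not in "STY":
                continue
            rows.append(SiteAnnotation(p.id, pos, residue, "positive", "synthetic"))
        assert len(rows) >= 10
        path = tmp_path / "mixed.tsv"
        dp.write_site_table(rows, path)
        # corrupt 3 rows with a wrong residue annotation
        lines = path.read_text().splitlines()
        for i in (1, 3, 5):
            parts = lines[i].split("\t")
            parts[2] = {"S": "T", "T": "Y", "Y": "S"}[parts[2]]
            seq = next(p for p in proteins if p.id == parts[0]).sequence
            if seq[int(parts[1]) - 1] == parts[2]:
                parts[2] = "W"  # still wrong, and W is never annotatable
            lines[i] = "\t".join(parts)
            n_bad += 1
        path.write_text("\n".join(lines) + "\n")
        accepted = dp.load_site_table(path, proteins, strict=False)
        assert len(accepted) == len(rows) - n_bad
        with pytest.raises(ValidationError):
            dp.load_site_table(path, proteins, strict=True)

    def test_unknown_protein_rejected(self, tmp_path, tiny_proteins):
        path = tmp_path / "unknown.tsv"
        dp.write_site_table(
            [SiteAnnotation("NOPE", 3, "S", "positive", "synthetic")], path)
        with pytest.raises(ValidationError, match="unknown protein"):
            dp.load_site_table(path, tiny_proteins)


class TestExtractWindows:
    def test_full_length_window_is_whole_protein(self):
        protein = ProteinRecord("P", "A" * 16 + "S" + "A" * 16)
        site = SiteAnnotation("P", 17, "S", "positive")
        ds, report = dp.extract_windows([protein], [site], 33)
        assert len(ds) == 1
        assert ds.examples[0].window == protein.sequence
        assert report.total_dropped == 0

    def test_site_too_close_to_terminus_is_dropped(self, rng):
        protein = random_protein(rng, "P", 40)
        seq = protein.sequence[:15] + "S" + protein.sequence[16:]
        protein = ProteinRecord("P", seq)
        site = SiteAnnotation("P", 16, "S", "positive")
        ds, report = dp.extract_windows([protein], [site], 33)
        assert len(ds) == 0
        assert report.dropped_left == 1

    def test_flank_arithmetic_on_length_60(self):
        seq = list("A" * 60)
        for pos in (17, 20, 50):
            seq[pos - 1] = "S"
        protein = ProteinRecord("P", "".join(seq))
        sites = [SiteAnnotation("P", p, "S", "positive") for p in (17, 20, 50)]
        ds, report = dp.extract_windows([protein], sites, 33)
        # brute force: windows exist iff p-16 >= 1 and p+16 <= 60
        expected = [p for p in (17, 20, 50) if p - 16 >= 1 and p + 16 <= 60]
        assert [e.position for e in ds] == expected
        assert report.dropped_right == 1

    def test_even_window_size_rejected(self, tiny_proteins, tiny_sites):
        with pytest.raises(ValidationError, match="odd"):
            dp.extract_windows(tiny_proteins, tiny_sites, 32)

    @pytest.mark.parametrize("window_size", [11, 21, 33])
    def test_matches_brute_force_on_random_proteins(self, rng, window_size):
        """Window-extraction equivalence against an independent enumerator."""
        proteins, sites = [], []
        for i in range(200):
            p = random_protein(rng, f"P{i}", int(rng.integers(5, 80)))
            proteins.append(p)
            for pos0, aa in enumerate(p.sequence):
                if aa in "STY" and rng.random() < 0.4:
                    sites.append(
                        SiteAnnotation(p.id, pos0 + 1, aa, "positive"))
        ds, report = dp.extract_windows(proteins, sites, window_size, "ST")
        expected = brute_force_windows(proteins, sites, window_size)
        got = [(e.protein_id, e.position, e.window) for e in ds]
        assert got == expected
        assert len(ds) + report.total_dropped == len(sites)


class TestGenerateNegatives:
    def test_no_remaining_in_class_residues_gives_no_negatives(self):
        protein = ProteinRecord("P", "AASAA")
        positives = [SiteAnnotation("P", 3, "S", "positive")]
        assert dp.generate_negative_sites([protein], positives, "ST") == []

    def test_set_difference_count(self, rng):
        """Negatives = all in-class residues minus the positives."""
        protein = random_protein(rng, "P", 100)
        st_positions = [i + 1 for i, aa in enumerate(protein.sequence)
                        if aa in "ST"]
        assert len(st_positions) >= 3
        positives = [
            SiteAnnotation("P", p, protein.residue(p), "positive")
            for p in st_positions[:2]
        ]
        negatives = dp.generate_negative_sites([protein], positives, "ST")
        assert len(negatives) == len(st_positions) - 2
        assert {n.position for n in negatives} == set(st_positions[2:])

    def test_y_class_on_protein_without_y(self):
        protein = ProteinRecord("P", "ASTASTAST")
        positives = [SiteAnnotation("P", 2, "S", "positive")]
        assert dp.generate_negative_sites([protein], positives, "Y") == []


def make_dataset(entries, residue_class="ST", window_size=5, stage="raw"):
    examples = [
        WindowExample(window=w, center_residue=w[len(w) // 2], label=label,
                      protein_id=pid, position=pos)
        for (w, label, pid, pos) in entries
    ]
    return SiteDataset(examples=examples, residue_class=residue_class,
                       window_size=window_size, stage=stage)


class TestDeduplicate:
    def test_unique_windows_unchanged(self):
        ds = make_dataset([("AASAA", "positive", "P1", 3),
                           ("CCTCC", "negative", "P2", 3)])
        out, report = dp.deduplicate(ds)
        assert len(out) == 2
        assert report.within_label_duplicates == 0

    def test_within_label_duplicate_collapses_to_first(self):
        ds = make_dataset([("AASAA", "positive", "P2", 9),
                           ("AASAA", "positive", "P1", 3),
                           ("CCTCC", "negative", "P3", 3)])
        out, report = dp.deduplicate(ds)
        assert len(out) == 2
        survivor = next(e for e in out if e.label == "positive")
        assert (survivor.protein_id, survivor.position) == ("P1", 3)
        assert report.within_label_duplicates == 1

    def test_cross_label_conflict_removes_both(self):
        ds = make_dataset([("AASAA", "positive", "P1", 3),
                           ("AASAA", "negative", "P2", 7),
                           ("CCTCC", "negative", "P3", 3)])
        out, report = dp.deduplicate(ds)
        assert [e.window for e in out] == ["CCTCC"]
        assert report.cross_label_conflicts == 2

    def test_label_conservation(self, rng):
        """Dedup never invents examples: every output key exists in input."""
        entries = []
        for i in range(50):
            w = "".join(rng.choice(list("ACDS"), size=4))
            w = w[:2] + "S" + w[2:]
            label = "positive" if rng.random() < 0.5 else "negative"
            entries.append((w, label, f"P{rng.integers(5)}", int(rng.integers(1, 9))))
        ds = make_dataset([(w, l, p, pos) for (w, l, p, pos) in entries])
        out, _ = dp.deduplicate(ds)
        input_keys = {(e.protein_id, e.position) for e in ds}
        assert all((e.protein_id, e.position) in input_keys for e in out)


class TestBalanceAndSplit:
    @staticmethod
    def _unbalanced(n_pos, n_neg, rng):
        entries = []
        for i in range(n_pos):
            w = "".join(rng.choice(list("ACDEF"), size=4))
            entries.append((w[:2] + "S" + w[2:], "positive", f"A{i}", 3))
        for i in range(n_neg):
            w = "".join(rng.choice(list("GHIKL"), size=4))
            entries.append((w[:2] + "T" + w[2:], "negative", f"B{i}", 3))
        return make_dataset(entries, stage="deduplicated")

    @pytest.mark.parametrize("n_pos,n_neg", [(10, 30), (30, 10), (10, 10)])
    def test_majority_downsampled_to_minority(self, rng, n_pos, n_neg):
        ds = self._unbalanced(n_pos, n_neg, rng)
        out = dp.balance_undersample(ds, seed=1)
        m = min(n_pos, n_neg)
        assert out.count("positive") == out.count("negative") == m
        assert out.stage == "balanced"
        # minority examples are untouched
        minority_label = "positive" if n_pos <= n_neg else "negative"
        assert set(e.protein_id for e in out.by_label(minority_label)) == set(
            e.protein_id for e in ds.by_label(minority_label))

    def test_seed_determinism_and_sensitivity(self, rng):
        ds = self._unbalanced(50, 200, rng)
        ref = dp.balance_undersample(ds, seed=7)
        again = dp.balance_undersample(ds, seed=7)
        assert [e.protein_id for e in ref] == [e.protein_id for e in again]
        differs = any(
            [e.protein_id for e in dp.balance_undersample(ds, seed=s)]
            != [e.protein_id for e in ref]
            for s in range(10)
        )
        assert differs, "10 distinct seeds all produced the same selection"

    def test_empty_class_raises(self, rng):
        entries = [("AASAA", "positive", "P1", 3)]
        ds = make_dataset(entries, stage="deduplicated")
        with pytest.raises(ValidationError, match="empty"):
            dp.balance_undersample(ds, seed=0)

    def test_split_counts_80_20(self, rng):
        ds = dp.balance_undersample(self._unbalanced(100, 100, rng), seed=0)
        train, test = dp.split_train_test(ds, 0.8, seed=0)
        assert train.count("positive") == train.count("negative") == 80
        assert test.count("positive") == test.count("negative") == 20

    def test_split_is_disjoint_and_exhaustive(self, rng):
        ds = dp.balance_undersample(self._unbalanced(37, 41, rng), seed=0)
        train, test = dp.split_train_test(ds, 0.8, seed=3)
        key = lambda e: (e.protein_id, e.position, e.label)
        train_keys = {key(e) for e in train}
        test_keys = {key(e) for e in test}
        assert not (train_keys & test_keys)
        assert train_keys | test_keys == {key(e) for e in ds}

    def test_split_fraction_half_on_two_plus_two(self, rng):
        ds = self._unbalanced(2, 2, rng)
        train, test = dp.split_train_test(ds, 0.5, seed=0)
        assert train.count("positive") == train.count("negative") == 1
        assert test.count("positive") == test.count("negative") == 1


class TestShrinkWindow:
    def test_one_step_removes_exactly_the_ends(self, rng):
        p = random_protein(rng, "P", 50)
        seq = p.sequence[:24] + "S" + p.sequence[25:]
        proteins = [ProteinRecord("P", seq)]
        sites = [SiteAnnotation("P", 25, "S", "positive")]
        ds33, _ = dp.extract_windows(proteins, sites, 33)
        ds31, _ = dp.shrink_window(ds33, 31)
        assert ds31.examples[0].window == ds33.examples[0].window[1:-1]

    def test_identity_when_target_equals_current(self, rng):
        ds = TestBalanceAndSplit._unbalanced(5, 5, rng)
        out, report = dp.shrink_window(ds, 5)
        assert [e.window for e in out] == [e.window for e in ds]

    def test_center_preserved_across_the_size_ladder(self, rng):
        proteins = [random_protein(rng, f"P{i}", 64) for i in range(20)]
        sites = []
        for p in proteins:
            for pos0, aa in enumerate(p.sequence):
                if aa in "ST" and 17 <= pos0 + 1 <= len(p) - 16:
                    sites.append(SiteAnnotation(p.id, pos0 + 1, aa, "positive"))
        ds, _ = dp.extract_windows(proteins, sites, 33, "ST")
        current = ds
        for size in (33, 31, 29, 27, 25, 23):
            current, _ = dp.shrink_window(current, size)
            assert all(
                e.window[size // 2] == e.center_residue for e in current)

    def test_target_larger_than_current_rejected(self, rng):
        ds = TestBalanceAndSplit._unbalanced(5, 5, rng)
        with pytest.raises(ValidationError, match="exceeds"):
            dp.shrink_window(ds, 7)


class TestMergeAndStats:
    def test_disjoint_merge_is_union(self, rng):
        a = TestBalanceAndSplit._unbalanced(3, 2, rng)
        b_entries = [
            ("CCSCC", "positive", "C0", 3),
            ("DDSDD", "positive", "C1", 3),
            ("EETEE", "positive", "C2", 3),
            ("FFTFF", "positive", "C3", 3),
            ("GGSGG", "negative", "D0", 3),
        ]
        b = make_dataset(b_entries)
        merged, _ = dp.merge_datasets(a, b)
        assert len(merged) == len(a) + len(b)

    def test_shared_pair_merged_once(self):
        a = make_dataset([("AASAA", "positive", "P1", 3),
                          ("CCTCC", "negative", "P2", 3)])
        b = make_dataset([("AASAA", "positive", "P9", 5),
                          ("GGSGG", "negative", "P3", 3)])
        merged, report = dp.merge_datasets(a, b)
        assert len(merged) == 3
        assert report.within_label_duplicates == 1

    def test_merge_size_mismatch_rejected(self):
        a = make_dataset([("AASAA", "positive", "P1", 3)])
        b = make_dataset([("AAASAAA", "positive", "P2", 4)], window_size=7)
        with pytest.raises(ValidationError, match="window size"):
            dp.merge_datasets(a, b)

    def test_stats_counts_and_empty(self):
        ds = make_dataset([("AASAA", "positive", "P1", 3),
                           ("CCTCC", "negative", "P2", 3)])
        stats = dp.dataset_stats(ds)
        assert (stats.positives, stats.negatives, stats.total) == (1, 1, 2)
        empty = dp.dataset_stats(make_dataset([]))
        assert (empty.positives, empty.negatives, empty.total) == (0, 0, 0)

    def test_fold_ratio_two_decimals(self):
        assert dp.fold_ratio(949, 292) == 3.25
        assert dp.fold_ratio(1, 3) == 0.33


class TestPreparePipeline:
    def test_end_to_end_invariants(self, rng):
        proteins = [random_protein(rng, f"P{i}", 80) for i in range(30)]
        positives = []
        for p in proteins:
            for pos0, aa in enumerate(p.sequence):
                if aa in "ST" and rng.random() < 0.25:
                    positives.append(
                        SiteAnnotation(p.id, pos0 + 1, aa, "positive"))
        result = dp.prepare_dataset(proteins, positives, "ST", 21, seed=5)
        balanced = result["balanced"]
        assert balanced.count("positive") == balanced.count("negative")
        windows = [e.window for e in balanced]
        labels = {}
        for e in balanced:
            assert labels.setdefault(e.window, e.label) == e.label
        assert all(len(w) == 21 for w in windows)
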