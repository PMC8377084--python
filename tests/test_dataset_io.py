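"""Ingestion, normalization and filtering of activity tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_dataset, random_spacers
from guidescape.dataset_io import (
    MINMAX,
    RAW,
    SIGN_INVERTED,
    DegenerateScaleWarning,
    collapse_base_edit,
    filter_valid_targets,
    invert_activity,
    load_dataset,
    minmax_scale,
    remove_redundant,
    write_dataset,
)
from guidescape.errors import (
    EmptyDatasetError,
    FormatError,
    InputError,
    SizeError,
    StateError,
)


def _write_tsv(path, rows, header="spacer\tpam_context\tactivity"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))


class TestLoad:
    def test_valid_file_roundtrip(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_tsv(
            p,
            [
                "ACGTACGTACGTACGTACGT\tAGGT\t1.5",
                "TTTTACGTACGTACGTACGA\tCGG\t-0.2",
                "GGGGACGTACGTACGTACGC\tTGGA\t0.0",
            ],
        )
        d = load_dataset(p)
        assert len(d) == 3 and d.scale_state == RAW
        assert d.meta["n_rejected"] == 0
        out = tmp_path / "out.tsv"
        write_dataset(d, out)
        d2 = load_dataset(out)
        pd.testing.assert_frame_equal(d.df, d2.df)

    def test_malformed_rows_rejected_with_count(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_tsv(
            p,
            [
                "ACGTACGTACGTACGTACG\tAGGT\t1.0",  # 19 nt
                "ACGTACGTACGTACGTACGT\tAGGT\t1.0",
                "ACGTACGTACGTACGTACGN\tAGGT\t1.0",  # N in spacer
                "ACGTACGTACGTACGTACGA\tAGGTC\t1.0",  # 5-nt pam
                "ACGTACGTACGTACGTACGC\tAGGT\tnot_a_number",
            ],
        )
        d = load_dataset(p)
        assert len(d) == 1
        assert d.meta["n_rejected"] == 4

    def test_lowercase_folded(self, tmp_path):
        p = tmp_path / "d.tsv"
        _write_tsv(p, ["acgtacgtacgtacgtacgt\taggt\t1.0"])
        d = load_dataset(p)
        assert d.df.loc[0, "spacer"] == "ACGTACGTACGTACGTACGT"

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("spacer\tactivity\nACGTACGTACGTACGTACGT\t1.0\n")
        with pytest.raises(FormatError):
            load_dataset(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("")
        with pytest.raises(EmptyDatasetError):
            load_dataset(p)
        p.write_text("spacer\tpam_context\tactivity\n")
        with pytest.raises(EmptyDatasetError):
            load_dataset(p)

    def test_duplicate_guide_ids_error(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "guide_id\tspacer\tpam_context\tactivity\n"
            "g1\tACGTACGTACGTACGTACGT\tAGGT\t1.0\n"
            "g1\tACGTACGTACGTACGTACGA\tAGGT\t2.0\n"
        )
        with pytest.raises(FormatError):
            load_dataset(p)

    def test_extra_numeric_columns_become_features(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "spacer\tpam_context\tactivity\tfold_energy\tnote\n"
            "ACGTACGTACGTACGTACGT\tAGGT\t1.0\t-3.2\thello\n"
            "ACGTACGTACGTACGTACGA\tAGGT\t2.0\t-1.1\tworld\n"
        )
        d = load_dataset(p)
        assert d.feature_columns == ("fold_energy",)
        rec = next(d.records())
        assert rec.features["fold_energy"] == -3.2


class TestInvert:
    def test_negates_activities(self):
        d = make_dataset(["A" * 20] * 3, [-2.0, 0.0, 5.0])
        # distinct guide ids come from make_dataset
        inv = invert_activity(d)
        assert list(inv.activities) == [2.0, 0.0, -5.0]
        assert inv.scale_state == SIGN_INVERTED
        assert list(inv.df["guide_id"]) == list(d.df["guide_id"])

    def test_involution(self):
        d = make_dataset(["A" * 20] * 3, [1.0, -4.0, 2.5])
        back = invert_activity(invert_activity(d))
        assert np.array_equal(back.activities, d.activities)
        assert back.scale_state == RAW

    def test_inversion_flips_pearson(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        d = make_dataset(["A" * 20] * 50, a)
        r = stats.pearsonr(a, invert_activity(d).activities).statistic
        assert r == pytest.approx(-1.0)

    def test_minmax_state_rejected(self):
        d = make_dataset(["A" * 20] * 3, [0.0, 0.5, 1.0], scale_state=MINMAX)
        with pytest.raises(StateError):
            invert_activity(d)


class TestMinmax:
    def test_basic_examples(self):
        d = minmax_scale(make_dataset(["A" * 20] * 3, [2.0, 5.0, 8.0]))
        assert list(d.activities) == [0.0, 0.5, 1.0]
        assert d.scale_state == MINMAX
        d2 = minmax_scale(make_dataset(["A" * 20] * 2, [0.0, 1.0]))
        assert list(d2.activities) == [0.0, 1.0]

    def test_degenerate_all_equal_warns_and_zeroes(self):
        d = make_dataset(["A" * 20] * 4, [3.0] * 4)
        with pytest.warns(DegenerateScaleWarning):
            out = minmax_scale(d)
        assert (out.activities == 0.0).all()

    def test_too_small(self):
        with pytest.raises(SizeError):
            minmax_scale(make_dataset(["A" * 20], [1.0]))

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=200, unique=True
        )
    )
    def test_preserves_rank_order(self, acts):
        d = minmax_scale(make_dataset(["A" * 20] * len(acts), acts))
        # monotone map: sorting by input sorts the output (ties may appear
        # only through float rounding of near-equal inputs)
        assert (np.diff(d.activities[np.argsort(acts)]) >= 0).all()
        assert d.activities.min() == 0.0 and d.activities.max() == 1.0

    def test_rank_permutation_identical_on_random_draw(self):
        rng = np.random.default_rng(2)
        acts = rng.normal(size=1000)
        d = minmax_scale(make_dataset(["A" * 20] * 1000, acts))
        assert np.array_equal(np.argsort(acts, kind="stable"),
                              np.argsort(d.activities, kind="stable"))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        d = minmax_scale(make_dataset(["A" * 20] * 100, rng.normal(size=100)))
        again = minmax_scale(d)
        np.testing.assert_allclose(again.activities, d.activities, atol=1e-15)


REVCOMP = str.maketrans("ACGT", "TGCA")


def _rc(s):
    return s.translate(REVCOMP)[::-1]


def _brute_force_hit(genome_seqs, spacer):
    """Independent oracle: scan every position of both strands."""
    for seq in genome_seqs:
        for s in (seq, _rc(seq)):
            for i in range(len(s) - 22):
                if s[i : i + 20] == spacer and s[i + 21 : i + 23] == "GG":
                    return True
    return False


class TestTargetFilter:
    def test_forward_match_retained(self, tmp_path):
        spacer = "ACGTACGTACGTACGTACGT"
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\nAAAA{spacer}TGGAAA\n")
        d = make_dataset([spacer], [1.0], pam_contexts=["TGG"])
        assert len(filter_valid_targets(d, fa)) == 1

    def test_reverse_complement_match_retained(self, tmp_path):
        spacer = "ACGTACGTACGTACGTACGT"
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\nTT{_rc(spacer + 'CGG')}TT\n")
        d = make_dataset([spacer], [1.0], pam_contexts=["CGG"])
        assert len(filter_valid_targets(d, fa)) == 1

    def test_no_pam_in_genome_removed(self, tmp_path):
        spacer = "ACGTACGTACGTACGTACGT"
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\nAAAA{spacer}TCCAAA\n")  # TCC, not NGG
        d = make_dataset([spacer], [1.0], pam_contexts=["TGG"])
        out = filter_valid_targets(d, fa)
        assert len(out) == 0 and out.meta["n_removed_no_target"] == 1

    def test_non_ngg_context_removed(self, tmp_path):
        spacer = "ACGTACGTACGTACGTACGT"
        fa = tmp_path / "g.fa"
        fa.write_text(f">chr1\nAAAA{spacer}TGGAAA\n")
        d = make_dataset([spacer], [1.0], pam_contexts=["TAG"])
        assert len(filter_valid_targets(d, fa)) == 0

    def test_matches_exhaustive_scan_oracle(self, tmp_path):
        rng = np.random.default_rng(42)
        genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\n" + genome + "\n")
        # mix of random spacers and spacers planted from the genome
        spacers = random_spacers(rng, 30)
        for _ in range(20):
            i = int(rng.integers(0, len(genome) - 23))
            spacers.append(genome[i : i + 20])
        d = make_dataset(spacers, np.arange(len(spacers), dtype=float),
                         pam_contexts=["AGG"] * len(spacers))
        kept = set(filter_valid_targets(d, fa).df["spacer"])
        expected = {s for s in spacers if _brute_force_hit([genome], s)}
        assert kept == expected

    def test_wrapping_and_case_invariance(self, tmp_path):
        spacer = "ACGTACGTACGTACGTACGT"
        body = f"AAAA{spacer}TGGAAA"
        fa1 = tmp_path / "flat.fa"
        fa1.write_text(f">c\n{body}\n")
        fa2 = tmp_path / "wrapped.fa"
        fa2.write_text(">c\n" + "\n".join(body[i : i + 7].lower() for i in range(0, len(body), 7)) + "\n")
        d = make_dataset([spacer], [1.0], pam_contexts=["TGG"])
        assert len(filter_valid_targets(d, fa1)) == len(filter_valid_targets(d, fa2)) == 1

    def test_ambiguity_codes_never_match(self, tmp_path):
        spacer = "ACGTACGTACGTACGTACGT"
        fa = tmp_path / "g.fa"
        fa.write_text(f">c\nAAAA{spacer[:-1]}NTGGAAA\n")
        d = make_dataset([spacer], [1.0], pam_contexts=["TGG"])
        assert len(filter_valid_targets(d, fa)) == 0

    def test_unreadable_fasta(self, tmp_path):
        d = make_dataset(["A" * 20], [1.0])
        with pytest.raises(OSError):
            filter_valid_targets(d, tmp_path / "missing.fa")


class TestRedundancy:
    def test_disjoint_unchanged(self):
        rng = np.random.default_rng(3)
        d = make_dataset(random_spacers(rng, 10), np.arange(10.0), dataset_id="d")
        ref = make_dataset(random_spacers(rng, 10), np.arange(10.0), dataset_id="r")
        assert len(remove_redundant(d, ref)) == 10

    def test_subset_empties(self):
        rng = np.random.default_rng(4)
        spacers = random_spacers(rng, 5)
        d = make_dataset(spacers, np.arange(5.0), dataset_id="d")
        ref = make_dataset(spacers + random_spacers(rng, 5), np.arange(10.0),
                           dataset_id="r")
        assert len(remove_redundant(d, ref)) == 0

    def test_planted_overlap_count(self):
        rng = np.random.default_rng(5)
        d_spacers = random_spacers(rng, 100)
        ref_spacers = random_spacers(rng, 60) + d_spacers[:17]
        d = make_dataset(d_spacers, np.arange(100.0), dataset_id="d")
        ref = make_dataset(ref_spacers, np.arange(77.0), dataset_id="r")
        out = remove_redundant(d, ref)
        # set-intersection oracle
        expected = 100 - len(set(d_spacers) - set(ref_spacers))
        assert out.meta["n_removed_redundant"] == expected == 17

    def test_self_and_empty_reference(self):
        rng = np.random.default_rng(6)
        spacers = random_spacers(rng, 8)
        d = make_dataset(spacers, np.arange(8.0), dataset_id="d")
        assert len(remove_redundant(d, d)) == 0
        empty = make_dataset([], [], dataset_id="e")
        assert len(remove_redundant(d, empty)) == 8


class TestCollapseBaseEdit:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(
            rows, columns=["guide_id", "position", "edit_frequency", "spacer",
                           "pam_context"]
        )

    def test_sums_per_guide(self):
        sp = "ACGTACGTACGTACGTACGT"
        t = self._table(
            [("g1", 3, 0.2, sp, "AGGT"), ("g1", 5, 0.1, sp, "AGGT"),
             ("g2", 3, 0.0, sp[::-1], "CGGT"), ("g2", 7, 0.0, sp[::-1], "CGGT")]
        )
        d = collapse_base_edit(t)
        acts = dict(zip(d.df["guide_id"], d.activities))
        assert acts["g1"] == pytest.approx(0.3)
        assert acts["g2"] == 0.0

    def test_matches_naive_accumulation(self):
        rng = np.random.default_rng(7)
        spacers = random_spacers(rng, 200)
        rows = []
        for i, sp in enumerate(spacers):
            for pos in range(1, 21):
                rows.append((f"g{i}", pos, float(rng.random()), sp, "AGGT"))
        t = self._table(rows)
        d = collapse_base_edit(t)
        # naive loop oracle
        expected = {}
        for gid, _, f, *_ in rows:
            expected[gid] = expected.get(gid, 0.0) + f
        for gid, act in zip(d.df["guide_id"], d.activities):
            assert act == pytest.approx(expected[gid])

    def test_duplicate_guide_position_rejected(self):
        sp = "A" * 20
        t = self._table([("g1", 3, 0.2, sp, "AGGT"), ("g1", 3, 0.1, sp, "AGGT")])
        with pytest.raises(InputError):
            collapse_base_edit(t)

    def test_negative_frequency_rejected(self):
        t = self._table([("g1", 3, -0.2, "A" * 20, "AGGT")])
        with pytest.raises(InputError):
            collapse_base_edit(t)
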