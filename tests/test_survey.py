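"""Ortholog survey: name filtering, alignment coordinates, composition,
isoelectric points, PCA and clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hetchrom as hc
from hetchrom.errors import (
    DegenerateInputError,
    MissingAccessionError,
    ParseError,
    RangeError,
)
from hetchrom.survey import CANONICAL_AA, AlignedSet, ProteinRecord, make_extension

# EMBOSS pKa constants, restated independently for the charge oracle
_ORACLE_PKA = {
    "nterm": 8.6, "cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}


def oracle_net_charge(seq: str, pH: float) -> float:
    """Independent sum-over-groups Henderson-Hasselbalch charge."""
    z = 1 / (1 + 10 ** (pH - _ORACLE_PKA["nterm"]))
    z -= 1 / (1 + 10 ** (_ORACLE_PKA["cterm"] - pH))
    for ch in seq.upper():
        if ch in "RKH":
            z += 1 / (1 + 10 ** (pH - _ORACLE_PKA[ch]))
        elif ch in "DECY":
            z -= 1 / (1 + 10 ** (_ORACLE_PKA[ch] - pH))
    return z


def oracle_grid_pi(seq: str, step: float = 1e-4) -> float:
    """Dense grid scan for the pH of minimal |Z| (vectorized)."""
    ph = np.arange(0.0, 14.0 + step, step)
    z = 1 / (1 + 10 ** (ph - _ORACLE_PKA["nterm"]))
    z = z - 1 / (1 + 10 ** (_ORACLE_PKA["cterm"] - ph))
    for ch in seq.upper():
        if ch in "RKH":
            z = z + 1 / (1 + 10 ** (ph - _ORACLE_PKA[ch]))
        elif ch in "DECY":
            z = z - 1 / (1 + 10 ** (_ORACLE_PKA[ch] - ph))
    return float(ph[np.argmin(np.abs(z))])


def _rec(name, acc="A1", seq="MRK"):
    return ProteinRecord(acc, name, "org", seq)


class TestNameFilter:
    def test_kept_and_excluded_examples(self):
        kept = hc.filter_by_name(
            [
                _rec("Histone-lysine N-methyltransferase SUV39H2"),
                _rec("PR domain zinc finger protein (PRDM2)"),
            ],
            "histone",
            ["prdm", "setmar"],
        )
        assert [r.protein_name for r in kept] == [
            "Histone-lysine N-methyltransferase SUV39H2"
        ]

    def test_fixture_of_ten_names_keeps_five(self):
        names = [
            "Histone methyltransferase A",
            "Histone methyltransferase B",
            "histone-lysine transferase C",
            "HISTONE writer D",
            "Histone reader E",
            "Histone SETMAR fusion F",  # has the include token but excluded
            "kinase G",
            "phosphatase H",
            "PRDM9 protein I",
            "transporter J",
        ]
        kept = hc.filter_by_name([_rec(n) for n in names], "histone", ["prdm", "setmar"])
        assert len(kept) == 5
        # order preserved
        assert [r.protein_name for r in kept] == names[:5]

    def test_empty_tokens_rejected(self):
        with pytest.raises(ValueError):
            hc.filter_by_name([], "", ["x"])


class TestAlignmentCoordinates:
    def test_gapless_reference_is_identity(self):
        aln = AlignedSet.from_rows([("R", "A" * 100)])
        assert hc.reference_column(aln, "R", 81) == 81

    def test_leading_gaps_offset(self):
        aln = AlignedSet.from_rows([("R", "-----AAAA")])
        assert hc.reference_column(aln, "R", 1) == 6

    def test_beyond_length_and_missing_accession(self):
        aln = AlignedSet.from_rows([("R", "AA--A")])
        with pytest.raises(RangeError):
            hc.reference_column(aln, "R", 4)
        with pytest.raises(MissingAccessionError):
            hc.reference_column(aln, "nope", 1)

    @given(st.lists(st.booleans(), min_size=1, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_column_matches_prefix_count_oracle(self, pattern):
        # brute-force oracle: returned column holds exactly the k-th residue
        row = "".join("A" if keep else "-" for keep in pattern)
        if "A" not in row:
            return
        aln = AlignedSet.from_rows([("R", row)])
        n_res = row.count("A")
        prev = 0
        for k in range(1, n_res + 1):
            col = hc.reference_column(aln, "R", k)
            assert row[: col].count("A") == k and row[col - 1] == "A"
            assert col > prev  # strictly increasing in residue index
            prev = col

    def test_extends_beyond(self):
        aln = AlignedSet.from_rows([("a", "---XYZ"), ("b", "--WXYZ"), ("r", "---ABC")])
        start = hc.reference_column(aln, "r", 1)  # column 4
        assert not hc.extends_beyond(aln, "a", start)
        assert hc.extends_beyond(aln, "b", start)

    def test_truncate_extension(self):
        aln = AlignedSet.from_rows([("a", "KR-ST"), ("b", "---ST")])
        assert hc.truncate_extension(aln, "a", 3) == "KR"
        assert hc.truncate_extension(aln, "b", 3) == ""

    def test_truncation_round_trip(self, planted_family):
        # prefix + suffix re-ungapped equals the original sequence
        records, aln, _ = planted_family
        seqs = {r.accession: r.sequence for r in records}
        for acc, row in aln.records:
            for col in (1, 40, aln.column_count):
                prefix = hc.truncate_extension(aln, acc, col)
                suffix = row[col:].replace("-", "")
                assert prefix + suffix == seqs[acc]


class TestComposition:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("RRRR", {"R": 1.0}),
            ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
            ("RKRKX", {"R": 0.5, "K": 0.5}),  # ambiguity code excluded
        ],
    )
    def test_fractions(self, seq, expected):
        comp = hc.aa_composition(seq)
        for i, aa in enumerate(CANONICAL_AA):
            assert comp[i] == pytest.approx(expected.get(aa, 0.0), abs=1e-12)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_canonical_residues_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            hc.aa_composition("XXBZ")

    def test_illegal_letters_rejected(self):
        with pytest.raises(ParseError):
            hc.aa_composition("AC1E")

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(CANONICAL_AA), 60))
        shuffled = "".join(rng.permutation(list(seq)))
        assert np.allclose(hc.aa_composition(seq), hc.aa_composition(shuffled))


class TestCharge:
    def test_limit_signs(self):
        for seq in ("GGG", "RRKK", "DDEE"):
            assert hc.net_charge(seq, 0.0) > 0
            assert hc.net_charge(seq, 14.0) < 0

    def test_termini_symmetry_midpoint(self):
        # no ionizable side chains: Z = 0 exactly at the termini pKa midpoint
        assert hc.net_charge("GGG", (8.6 + 3.6) / 2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            seq = "".join(rng.choice(list(CANONICAL_AA), 10))
            ph = float(rng.uniform(0, 14))
            assert hc.net_charge(seq, ph) == pytest.approx(
                oracle_net_charge(seq, ph), abs=1e-9
            )

    def test_strictly_decreasing_in_ph(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list(CANONICAL_AA), 12))
            ph = np.linspace(0, 14, 57)
            z = np.array([hc.net_charge(seq, p) for p in ph])
            assert np.all(np.diff(z) < 0)

    def test_unknown_scale_is_config_error(self):
        with pytest.raises(hc.errors.ConfigError):
            hc.net_charge("GGG", 7.0, pka_set="NOPE")


class TestIsoelectricPoint:
    def test_glycine_tripeptide_midpoint(self):
        assert hc.isoelectric_point("GGG") == pytest.approx(6.10, abs=0.005)

    def test_consistent_with_independent_pka_scale(self):
        # Biopython's IsoelectricPoint uses the Bjellqvist constants, a
        # different published scale; roots should land close but not equal
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = "".join(rng.choice(list(CANONICAL_AA), 20))
            assert hc.isoelectric_point(seq) == pytest.approx(
                IsoelectricPoint(seq).pi(), abs=1.2
            )

    def test_bisection_agrees_with_grid_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            seq = "".join(rng.choice(list(CANONICAL_AA), int(rng.integers(5, 30))))
            assert abs(hc.isoelectric_point(seq) - oracle_grid_pi(seq)) <= 0.01

    def test_filters(self):
        exts = [make_extension(str(i), s) for i, s in enumerate(
            ["R" * 5, "R" * 20, "R" * 21, "R" * 81]
        )]
        assert [e.length for e in hc.length_filter(exts)] == [21, 81]
        basic = make_extension("b", "R" * 30)
        acidic = make_extension("a", "D" * 30)
        assert hc.pi_filter([basic, acidic]) == [basic]
        # inclusive threshold boundary
        assert hc.pi_filter([basic], threshold=basic.pI) == [basic]
        assert hc.pi_filter([basic], threshold=basic.pI + 0.01) == []


class TestPca:
    def test_identical_rows_zero_scores(self):
        X = np.tile(hc.aa_composition("ARNDC"), (5, 1))
        res = hc.pca_composition(X)
        assert np.allclose(res.scores, 0.0, atol=1e-12)

    def test_rank_one_data(self):
        rng = np.random.default_rng(1)
        base = rng.random(20)
        coef = rng.random(6)
        X = base + np.outer(coef, rng.random(20))
        res = hc.pca_composition(X)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_conservation_orthonormality_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.random((50, 20))
        res = hc.pca_composition(X)
        centered = X - X.mean(axis=0)
        assert res.scores.var(axis=0, ddof=1).sum() == pytest.approx(
            centered.var(axis=0, ddof=1).sum()
        )
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.allclose(res.scores @ res.loadings.T, centered, atol=1e-8)
        evf = res.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12) and evf.sum() <= 1 + 1e-9

    def test_too_few_rows(self):
        with pytest.raises(DegenerateInputError):
            hc.pca_composition(np.zeros((2, 20)))


class TestClustering:
    def test_separated_blobs_labeled_by_reference(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(5, 0.1, (6, 2))])
        pca = hc.pca_composition(
            np.hstack([X, np.zeros((12, 18))]), [f"d{i}" for i in range(12)]
        )
        out = hc.cluster_domains(pca, "d0", seed=0)
        assert out.cluster_labels[:6] == ("similar",) * 6
        assert out.cluster_labels[6:] == ("distinct",) * 6

    def test_identical_points_all_similar(self):
        pca = hc.pca_composition(np.ones((4, 20)) * 0.05, list("abcd"))
        out = hc.cluster_domains(pca, "a", seed=0)
        assert set(out.cluster_labels) == {"similar"}

    def test_missing_reference(self):
        pca = hc.pca_composition(np.eye(4, 20) / 4, list("abcd"))
        with pytest.raises(MissingAccessionError):
            hc.cluster_domains(pca, "zz")


class TestSurveyPipeline:
    def test_counts_match_planted_truth(self, survey_result, planted_family):
        _, _, truth = planted_family
        counts = survey_result.counts.set_index("stage")["count"]
        assert counts["input"] == len(truth)
        assert counts["extended"] == int(truth.has_extension.sum())
        assert counts["long_extension"] == int(truth.is_long.sum())
        assert counts["basic_pi"] == int(truth.is_basic.sum())

    def test_extension_sequences_equal_planted(self, survey_result, planted_family):
        _, _, truth = planted_family
        planted = truth.set_index("accession")["ext_sequence"]
        for ext in survey_result.extensions:
            assert ext.sequence == planted[ext.accession]

    def test_percentages_are_hand_arithmetic(self, survey_result):
        c = survey_result.counts
        assert c["percent_of_input"].iloc[1] == pytest.approx(
            100.0 * c["count"].iloc[1] / c["count"].iloc[0]
        )

    def test_empty_input_all_zero(self, planted_family):
        _, aln, _ = planted_family
        res = hc.run_survey([], aln, ("SYN-REF1", 1), ("SYN-REF2", 81))
        assert res.counts["count"].tolist() == [0, 0, 0, 0]

    def test_output_table_columns(self, survey_result):
        table = survey_result.table()
        assert {"accession", "length", "pI", "PC1", "PC2", "cluster_label"} <= set(
            table.columns
        )
        assert len(table) == 5
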