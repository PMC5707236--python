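"""Genotype statistics, haplotype phasing and risk-group assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from genconn.genotypes import (
    BiallelicCounts,
    GenotypeError,
    allele_frequencies,
    assign_risk_groups,
    em_phase_two_markers,
    genotype_counts,
    hwe_chisq_test,
    hwe_report,
    parse_genotype_table,
    read_genotype_table,
    round_half_away,
)


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "counts, expected_a",
        [
            ((31, 57, 32), (2 * 31 + 57) / 240),  # L at 5-HTTLPR, reported as 0.50
            ((10, 0, 0), 1.0),                    # monomorphic
            ((56, 51, 11), 163 / 236),            # A at rs165599, ~0.69
        ],
    )
    def test_direct_count_arithmetic(self, counts, expected_a):
        fa, fb = allele_frequencies(BiallelicCounts(*counts))
        assert fa == pytest.approx(expected_a, abs=1e-12)
        assert fa + fb == 1.0

    def test_cohort_values_round_to_reported(self):
        for counts, reported in [((31, 57, 32), 0.50), ((34, 57, 28), 0.53), ((56, 51, 11), 0.69)]:
            fa, _ = allele_frequencies(BiallelicCounts(*counts))
            assert round_half_away(fa) == reported

    def test_zero_total_rejected(self):
        with pytest.raises(GenotypeError):
            BiallelicCounts(0, 0, 0)


class TestHWE:
    @pytest.mark.parametrize(
        "counts, p_2dp",
        [((31, 57, 32), 0.58), ((34, 57, 28), 0.67), ((56, 51, 11), 0.90)],
    )
    def test_cohort_p_values(self, counts, p_2dp):
        _, p = hwe_chisq_test(BiallelicCounts(*counts))
        assert round_half_away(p) == p_2dp

    def test_exact_equilibrium(self):
        stat, p = hwe_chisq_test(BiallelicCounts(25, 50, 25))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(GenotypeError):
            hwe_chisq_test(BiallelicCounts(10, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(
        n_aa=st.integers(0, 200), n_ab=st.integers(0, 200), n_bb=st.integers(0, 200)
    )
    def test_statistic_matches_brute_force(self, n_aa, n_ab, n_bb):
        """The statistic equals sum (obs-exp)^2/exp from expected HWE counts."""
        if n_aa + n_ab + n_bb == 0:
            return
        counts = BiallelicCounts(n_aa, n_ab, n_bb)
        fa, fb = allele_frequencies(counts)
        if fa == 0 or fb == 0:
            return
        n = counts.n
        exp = [n * fa**2, 2 * n * fa * fb, n * fb**2]
        obs = [n_aa, n_ab, n_bb]
        expected_stat = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        stat, _ = hwe_chisq_test(counts)
        assert stat == pytest.approx(expected_stat, rel=1e-12)


class TestParsing:
    def test_dialects_and_missing(self, cohort_geno_table):
        t = cohort_geno_table
        assert t.loc[1, "httlpr"] == "L/S"        # "s/l" normalized, unordered
        assert t.loc[4, "httlpr"] == "L/S"        # La/Lg collapse to L/S
        assert t.loc[5, "httlpr"] is None         # NA
        assert t.loc[3, "rs4680"] == "Met/Val"    # A/G maps to Met/Val
        assert t.loc[6, "rs4680"] is None         # empty string
        assert t.loc[3, "rs165599"] == "A/G"      # unordered g/a

    def test_duplicate_ids_rejected(self):
        raw = pd.DataFrame(
            {"subject_id": ["a", "a"], "httlpr": ["S/S", "L/L"],
             "rs4680": ["Met/Met", "Met/Met"], "rs165599": ["A/A", "A/A"]}
        )
        with pytest.raises(GenotypeError):
            parse_genotype_table(raw)

    def test_tsv_round_trip(self, cohort_geno_table, tmp_path):
        path = tmp_path / "geno.tsv"
        cohort_geno_table.fillna("NA").to_csv(path, sep="\t", index=False)
        back = read_genotype_table(path)
        pd.testing.assert_frame_equal(back, cohort_geno_table)

    def test_counts_drop_missing(self, cohort_geno_table):
        counts = genotype_counts(cohort_geno_table, "httlpr")
        assert counts.n == 7  # one missing of 8


class TestPhasing:
    @staticmethod
    def _table(rows):
        return parse_genotype_table(
            pd.DataFrame(
                {
                    "subject_id": [f"s{i}" for i in range(len(rows))],
                    "httlpr": ["L/L"] * len(rows),
                    "rs4680": [r[0] for r in rows],
                    "rs165599": [r[1] for r in rows],
                }
            )
        )

    def test_unambiguous_cohort_fully_assigned(self):
        table = self._table([("Met/Met", "A/A")] * 10)
        res = em_phase_two_markers(table)
        assert res.frequencies[0] == pytest.approx(1.0, abs=1e-9)  # Met-A
        assert (res.per_subject["posterior"] == 1.0).all()
        assert res.per_subject["assigned"].notna().all()

    def test_all_double_heterozygotes_stay_missing(self):
        """Symmetric likelihood: both phase configurations equally likely,
        so no posterior exceeds 0.80 and every phase is set missing."""
        table = self._table([("Val/Met", "A/G")] * 20)
        res = em_phase_two_markers(table)
        assert res.per_subject["posterior"].to_numpy() == pytest.approx(0.5)
        assert res.per_subject["assigned"].isna().all()

    def test_em_matches_direct_likelihood_maximizer(self):
        rows = [("Val/Val", "G/G")] * 40 + [("Met/Met", "A/A")] * 40 + [("Val/Met", "A/G")] * 20
        res = em_phase_two_markers(self._table(rows))
        dose_counts = {(0, 0): 40, (2, 2): 40, (1, 1): 20}
        direct = oracles.maximize_haplotype_likelihood(dose_counts)
        # compare achieved likelihoods and frequencies
        ll_em = oracles.haplotype_loglik(res.frequencies, dose_counts)
        ll_direct = oracles.haplotype_loglik(direct, dose_counts)
        assert ll_em >= ll_direct - 1e-6
        assert np.allclose(np.sort(res.frequencies), np.sort(direct), atol=1e-4)

    def test_loglik_nondecreasing_and_frequencies_simplex(self):
        rng = np.random.default_rng(0)
        g4680 = ["Met/Met", "Val/Met", "Val/Val"]
        g165599 = ["A/A", "A/G", "G/G"]
        rows = [(g4680[rng.integers(3)], g165599[rng.integers(3)]) for _ in range(60)]
        res = em_phase_two_markers(self._table(rows))
        trace = np.array(res.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.frequencies >= 0)

    def test_no_double_heterozygotes_equals_counting(self):
        rows = [("Met/Met", "A/G")] * 6 + [("Val/Met", "A/A")] * 4 + [("Val/Val", "G/G")] * 2
        res = em_phase_two_markers(self._table(rows))
        # phase is determined: count haplotypes directly (24 chromosomes)
        expected = {
            "Met-A": (6 + 4) / 24,
            "Met-G": 6 / 24,
            "Val-A": 4 / 24,
            "Val-G": (2 * 2) / 24,
        }
        freq = dict(zip(res.haplotype_names, res.frequencies))
        for name, value in expected.items():
            assert freq[name] == pytest.approx(value, abs=1e-8)

    def test_no_usable_subjects_rejected(self):
        table = self._table([("NA", "A/A"), ("Met/Met", "NA")])
        with pytest.raises(GenotypeError):
            em_phase_two_markers(table)


class TestRiskGroups:
    def test_mapping(self, cohort_geno_table):
        groups = assign_risk_groups(cohort_geno_table)
        assert groups.loc[1, "httlpr_group"] == "S-carrier"      # S/L
        assert groups.loc[3, "httlpr_group"] == "L-homozygote"   # L/L
        assert groups.loc[5, "httlpr_group"] is None
        assert groups.loc[0, "comt_group"] == "risk"             # Met/Met + A/A
        assert groups.loc[1, "comt_group"] == "non-risk"         # Val/Met + A/G
        assert groups.loc[2, "comt_group"] == "risk"             # Val/Val
        assert groups.loc[7, "comt_group"] == "risk"             # Val/Val, rs165599 missing

    def test_missing_at_deciding_marker(self):
        raw = pd.DataFrame(
            {"subject_id": ["a"], "httlpr": ["L/L"], "rs4680": ["NA"], "rs165599": ["A/G"]}
        )
        groups = assign_risk_groups(parse_genotype_table(raw))
        # rs165599 is non-risk but rs4680 could still be Val/Val: undecidable
        assert groups.loc[0, "comt_group"] is None

    def test_partition_exhaustive_and_exclusive(self):
        """Every fully genotyped subject gets exactly one group per marker set."""
        g4680 = ["Met/Met", "Val/Met", "Val/Val"]
        g165599 = ["A/A", "A/G", "G/G"]
        rows = [(a, b) for a in g4680 for b in g165599]
        raw = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(rows))],
                "httlpr": ["S/S"] * len(rows),
                "rs4680": [r[0] for r in rows],
                "rs165599": [r[1] for r in rows],
            }
        )
        groups = assign_risk_groups(parse_genotype_table(raw))
        assert set(groups["comt_group"]) == {"risk", "non-risk"}
        n_risk = (groups["comt_group"] == "risk").sum()
        # risk iff Val/Val or A/A: 3 + 3 - 1 overlapping cell
        assert n_risk == 5 and (groups["comt_group"] == "non-risk").sum() == 4


def test_hwe_report_reproduces_cohort_table():
    """The report on the printed genotype counts reproduces the published
    2-dp allele frequencies and HWE p-values."""
    rows = []
    for marker, (aa, ab, bb) in [
        ("httlpr", (31, 57, 32)), ("rs4680", (34, 57, 28)), ("rs165599", (56, 51, 11))
    ]:
        first, second = {"httlpr": ("L", "S"), "rs4680": ("Met", "Val"), "rs165599": ("A", "G")}[marker]
        geno = (
            [f"{first}/{first}"] * aa + [f"{first}/{second}"] * ab + [f"{second}/{second}"] * bb
        )
        rows.append(geno)
    n = max(len(r) for r in rows)
    table = parse_genotype_table(
        pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "httlpr": rows[0] + ["NA"] * (n - len(rows[0])),
                "rs4680": rows[1] + ["NA"] * (n - len(rows[1])),
                "rs165599": rows[2] + ["NA"] * (n - len(rows[2])),
            }
        )
    )
    report = hwe_report(table).set_index("marker")
    assert report.loc["httlpr", "hwe_p_2dp"] == 0.58
    assert report.loc["rs4680", "hwe_p_2dp"] == 0.67
    assert report.loc["rs165599", "hwe_p_2dp"] == 0.90
    assert report.loc["httlpr", "freq_a_2dp"] == 0.50
    assert report.loc["rs4680", "freq_a_2dp"] == 0.53
    assert report.loc["rs165599", "freq_a_2dp"] == 0.69
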