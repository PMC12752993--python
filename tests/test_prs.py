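"""Weight-table construction, allele alignment, scoring, relative scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polyclust import DataError
from polyclust.ld import DosageMatrix
from polyclust.prs import (
    PRSResult,
    WeightTable,
    align_alleles,
    build_weight_table,
    load_freq_table,
    relative_score,
    score_individuals,
)
from polyclust.sumstats import StudyStats


def _study(ids, beta, se=None, effect="A", other="G", p=None):
    n = len(ids)
    return StudyStats(
        "st",
        pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": "1",
                "pos": range(1, n + 1),
                "effect_allele": effect if isinstance(effect, list) else [effect] * n,
                "other_allele": other if isinstance(other, list) else [other] * n,
                "beta": beta,
                "se": se if se is not None else [1.0] * n,
                "p": p if p is not None else [np.nan] * n,
            }
        ),
    )


def _freqs(rows):
    return pd.DataFrame(rows, columns=["snp_id", "allele", "freq"])


def _weights(rows) -> WeightTable:
    t = pd.DataFrame(
        rows, columns=["snp_id", "effect_allele", "other_allele", "weight", "ref_freq"]
    ).set_index("snp_id")
    return WeightTable(cluster_label=1, table=t)


def _geno(data, counted) -> DosageMatrix:
    df = pd.DataFrame(data, dtype=float)
    df.index = [f"i{k}" for k in range(len(df))]
    return DosageMatrix(dose=df, counted_allele=pd.Series(counted))


class TestBuildWeightTable:
    def test_weight_is_signed_z(self):
        study = _study(["rs1"], beta=[0.8], se=[0.4])
        wt = build_weight_table(["rs1"], study, _freqs([("rs1", "A", 0.3), ("rs1", "G", 0.7)]))
        assert wt.table.loc["rs1", "weight"] == pytest.approx(2.0)
        assert wt.table.loc["rs1", "effect_allele"] == "A"

    def test_minor_allele_rule_flips_to_minor(self):
        study = _study(["rs1"], beta=[2.0])
        freqs = _freqs([("rs1", "A", 0.7), ("rs1", "G", 0.3)])
        wt = build_weight_table(["rs1"], study, freqs, minor_allele_rule=True)
        assert wt.table.loc["rs1", "effect_allele"] == "G"
        assert wt.table.loc["rs1", "weight"] == pytest.approx(-2.0)
        assert wt.table.loc["rs1", "ref_freq"] == pytest.approx(0.3)

    def test_minor_allele_rule_keeps_minor_effect(self):
        study = _study(["rs1"], beta=[2.0])
        freqs = _freqs([("rs1", "A", 0.3), ("rs1", "G", 0.7)])
        wt = build_weight_table(["rs1"], study, freqs, minor_allele_rule=True)
        assert wt.table.loc["rs1", "effect_allele"] == "A"
        assert wt.table.loc["rs1", "weight"] == pytest.approx(2.0)

    def test_directionless_study_raises(self):
        study = _study(["rs1"], beta=[np.nan], se=[np.nan], p=[0.01])
        with pytest.raises(DataError):
            build_weight_table(["rs1"], study, _freqs([("rs1", "A", 0.5)]))

    def test_snp_without_frequency_dropped(self):
        study = _study(["rs1", "rs2"], beta=[1.0, 2.0])
        wt = build_weight_table(
            ["rs1", "rs2"], study, _freqs([("rs1", "A", 0.4), ("rs1", "G", 0.6)])
        )
        assert list(wt.table.index) == ["rs1"]

    def test_two_column_freq_dialect(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("snp_id\tfreq\nrs1\t0.25\n")
        freqs = load_freq_table(path)
        study = _study(["rs1"], beta=[1.0])
        wt = build_weight_table(["rs1"], study, freqs)
        assert wt.table.loc["rs1", "ref_freq"] == pytest.approx(0.25)


class TestAlignAlleles:
    def test_counted_effect_unchanged(self):
        wt = _weights([("rs1", "A", "G", 2.0, 0.3)])
        geno = _geno({"rs1": [0, 1]}, {"rs1": "A"})
        out = align_alleles(wt, geno)
        assert out.table.loc["rs1", "weight"] == pytest.approx(2.0)

    def test_counted_other_flips_weight_and_freq(self):
        wt = _weights([("rs1", "A", "G", 2.0, 0.3)])
        geno = _geno({"rs1": [0, 1]}, {"rs1": "G"})
        out = align_alleles(wt, geno)
        assert out.table.loc["rs1", "weight"] == pytest.approx(-2.0)
        assert out.table.loc["rs1", "ref_freq"] == pytest.approx(0.7)

    def test_mismatched_allele_dropped(self):
        wt = _weights([("rs1", "A", "G", 2.0, 0.3), ("rs2", "C", "T", 1.0, 0.5)])
        geno = _geno({"rs1": [0], "rs2": [1]}, {"rs1": "T", "rs2": "C"})
        out = align_alleles(wt, geno)
        assert list(out.table.index) == ["rs2"]


class TestScoreIndividuals:
    def test_dose_equal_to_expectation_scores_zero(self):
        wt = _weights([("rs1", "A", "G", 1.0, 0.5)])
        geno = _geno({"rs1": [1.0]}, {"rs1": "A"})
        res = score_individuals(wt, geno)
        assert res.table["score"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_two_snp_score(self):
        # (1*(2-0.5) + 2*(0-1)) / 2 = -0.25
        wt = _weights([("rs1", "A", "G", 1.0, 0.25), ("rs2", "C", "T", 2.0, 0.5)])
        geno = _geno({"rs1": [2.0], "rs2": [0.0]}, {"rs1": "A", "rs2": "C"})
        assert score_individuals(wt, geno).table["score"].iloc[0] == pytest.approx(-0.25)

    def test_exclusion_above_ten_percent_missing(self):
        ids = [f"rs{i}" for i in range(20)]
        wt = _weights([(s, "A", "G", 1.0, 0.5) for s in ids])
        row_bad = {s: (np.nan if i < 3 else 1.0) for i, s in enumerate(ids)}  # 15% missing
        row_ok = {s: (np.nan if i < 2 else 1.0) for i, s in enumerate(ids)}  # 10% missing
        geno = DosageMatrix(
            dose=pd.DataFrame([row_bad, row_ok], index=["bad", "ok"]),
            counted_allele=pd.Series({s: "A" for s in ids}),
        )
        res = score_individuals(wt, geno)
        assert bool(res.table.loc["bad", "excluded"]) is True
        assert np.isnan(res.table.loc["bad", "score"])
        assert bool(res.table.loc["ok", "excluded"]) is False

    def test_missing_dose_contributes_exactly_zero(self):
        wt = _weights([("rs1", "A", "G", 3.0, 0.4), ("rs2", "C", "T", 2.0, 0.3)])
        geno_missing = _geno({"rs1": [np.nan], "rs2": [2.0]}, {"rs1": "A", "rs2": "C"})
        geno_imputed = _geno({"rs1": [0.8], "rs2": [2.0]}, {"rs1": "A", "rs2": "C"})  # 2f = 0.8
        a = score_individuals(wt, geno_missing, max_missing=0.6).table["score"].iloc[0]
        b = score_individuals(wt, geno_imputed, max_missing=0.6).table["score"].iloc[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_flip_consistency(self):
        """Negating a weight while replacing g by 2-g and f by 1-f leaves
        every score unchanged."""
        rng = np.random.default_rng(12)
        ids = [f"rs{i}" for i in range(8)]
        w = rng.normal(size=8)
        f = rng.uniform(0.1, 0.9, 8)
        g = rng.uniform(0, 2, size=(5, 8))
        wt1 = _weights([(s, "A", "G", w[i], f[i]) for i, s in enumerate(ids)])
        geno1 = DosageMatrix(
            dose=pd.DataFrame(g, columns=ids, index=[f"i{k}" for k in range(5)]),
            counted_allele=pd.Series({s: "A" for s in ids}),
        )
        wt2 = _weights([(s, "G", "A", -w[i], 1 - f[i]) for i, s in enumerate(ids)])
        geno2 = DosageMatrix(
            dose=pd.DataFrame(2 - g, columns=ids, index=[f"i{k}" for k in range(5)]),
            counted_allele=pd.Series({s: "G" for s in ids}),
        )
        s1 = score_individuals(wt1, geno1).table["score"]
        s2 = score_individuals(wt2, geno2).table["score"]
        assert np.allclose(s1, s2)

    def test_linearity_over_disjoint_subsets(self):
        rng = np.random.default_rng(21)
        ids = [f"rs{i}" for i in range(10)]
        w = rng.normal(size=10)
        f = rng.uniform(0.1, 0.9, 10)
        g = rng.integers(0, 3, size=(4, 10)).astype(float)
        geno = DosageMatrix(
            dose=pd.DataFrame(g, columns=ids, index=[f"i{k}" for k in range(4)]),
            counted_allele=pd.Series({s: "A" for s in ids}),
        )
        rows = [(s, "A", "G", w[i], f[i]) for i, s in enumerate(ids)]
        full = score_individuals(_weights(rows), geno).table["score"]
        part1 = score_individuals(_weights(rows[:6]), geno).table["score"]
        part2 = score_individuals(_weights(rows[6:]), geno).table["score"]
        assert np.allclose(full, (6 * part1 + 4 * part2) / 10)

    def test_centering_under_hwe(self):
        """Scores of genotypes drawn at HWE with the reference frequencies
        have mean near zero (n = 2,000 Monte-Carlo)."""
        rng = np.random.default_rng(17)
        n, m = 2000, 40
        ids = [f"rs{i}" for i in range(m)]
        f = rng.uniform(0.1, 0.9, m)
        w = rng.normal(size=m)
        g = (rng.random((n, m)) < f).astype(float) + (rng.random((n, m)) < f).astype(float)
        geno = DosageMatrix(
            dose=pd.DataFrame(g, columns=ids, index=[f"i{k}" for k in range(n)]),
            counted_allele=pd.Series({s: "A" for s in ids}),
        )
        res = score_individuals(_weights([(s, "A", "G", w[i], f[i]) for i, s in enumerate(ids)]), geno)
        scores = res.table["score"]
        se = scores.std() / np.sqrt(n)
        assert abs(scores.mean()) < 3 * se

    def test_empty_weight_table_raises(self):
        geno = _geno({"rs1": [1.0]}, {"rs1": "A"})
        with pytest.raises(DataError):
            score_individuals(_weights([]), geno)


class TestRelativeScore:
    @staticmethod
    def _result(scores, excluded=None):
        idx = list(scores)
        excluded = excluded or []
        t = pd.DataFrame(
            {
                "score": [np.nan if s in excluded else scores[s] for s in idx],
                "missing_frac": 0.0,
                "excluded": [s in excluded for s in idx],
            },
            index=idx,
        )
        return PRSResult(cluster_label=0, table=t)

    def test_difference(self):
        d = relative_score(self._result({"a": 0.4, "b": 1.0}), self._result({"a": -0.1, "b": 1.0}))
        assert d["a"] == pytest.approx(0.5)
        assert d["b"] == pytest.approx(0.0)

    def test_excluded_sample_absent(self):
        d = relative_score(
            self._result({"a": 0.4, "b": 0.2}, excluded=["b"]), self._result({"a": 0.1, "b": 0.2})
        )
        assert list(d.index) == ["a"]

    def test_empty_overlap_raises(self):
        with pytest.raises(DataError):
            relative_score(self._result({"a": 1.0}), self._result({"b": 1.0}))
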