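"""Peptide filtering, LOD imputation, substitution fractions, shift test,
moderated t with permutation FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trnaswitch.proteome import (
    PeptideQuantTable,
    filter_valid,
    impute_lod,
    moderated_t_s0,
    permutation_fdr,
    ratio_vs_control,
    read_peptide_table,
    substitution_fraction,
    thr_shift,
)
from trnaswitch.simulate import gen_peptide_table


def _tiny_table(values, groups=("A", "A", "A", "B", "B", "B")):
    samples = [f"s{i}" for i in range(len(groups))]
    vals = pd.DataFrame(values, columns=samples)
    meta = pd.DataFrame({
        "sequence": ["PEPTIDER"] * len(vals),
        "protein": ["P1"] * len(vals),
        "variant_class": ["base"] * len(vals),
        "site": [-1] * len(vals),
    }, index=vals.index)
    return PeptideQuantTable(
        values=vals, meta=meta, groups=pd.Series(list(groups), index=samples))


class TestFilterValid:
    def test_three_valid_in_one_group_kept(self):
        nan = float("nan")
        t = _tiny_table([[20.0, 21.0, 22.0, nan, nan, nan]])
        kept, removed = filter_valid(t, min_valid=3)
        assert len(kept.values) == 1 and removed == 0

    def test_two_valid_everywhere_removed(self):
        nan = float("nan")
        t = _tiny_table([[20.0, 21.0, nan, 20.0, 21.0, nan]])
        kept, removed = filter_valid(t, min_valid=3)
        assert len(kept.values) == 0 and removed == 1

    def test_surviving_set_matches_counting_oracle(self):
        table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=300,
                                     missing_rate=0.25, seed=7)
        kept, removed = filter_valid(table)
        oracle = set()
        for idx in table.values.index:
            for strain in ("A", "B"):
                cols = table.samples_of(strain)
                n_valid = table.values.loc[idx, cols].notna().sum()
                if n_valid >= 3:
                    oracle.add(idx)
                    break
        assert set(kept.values.index) == oracle
        assert removed == len(table.values) - len(oracle)


class TestImputeLod:
    def test_no_missing_is_noop(self):
        t = _tiny_table([[20.0, 21.0, 22.0, 20.0, 21.0, 22.0],
                         [25.0, 25.0, 25.0, 25.0, 25.0, 25.0]])
        out = impute_lod(t, seed=0)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_draws_concentrate_at_downshifted_mean(self):
        # one sample with observed mean 20, sd 1; 10,000 missing cells
        rng = np.random.default_rng(4)
        obs = rng.normal(20.0, 1.0, size=10_000)
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        samples = ["s0"]
        vals = pd.DataFrame({"s0": col})
        meta = pd.DataFrame({
            "sequence": ["PEPT"] * len(col), "protein": ["P"] * len(col),
            "variant_class": ["base"] * len(col), "site": [-1] * len(col),
        })
        t = PeptideQuantTable(vals, meta, pd.Series(["A"], index=samples))
        out = impute_lod(t, downshift=1.8, width=0.3, seed=9)
        imputed = out.values["s0"].iloc[10_000:]
        sd = np.std(obs, ddof=1)
        assert imputed.mean() == pytest.approx(np.mean(obs) - 1.8 * sd,
                                               abs=0.1)
        assert imputed.std() == pytest.approx(0.3 * sd, abs=0.05)

    def test_deterministic_under_seed(self):
        table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=200,
                                     missing_rate=0.2, seed=3)
        kept, _ = filter_valid(table)
        a = impute_lod(kept, seed=11).values
        b = impute_lod(kept, seed=11).values
        pd.testing.assert_frame_equal(a, b)


class TestSubstitutionFraction:
    def test_no_substituted_rows_gives_zero(self):
        table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=100,
                                     missing_rate=0.0, seed=5)
        assert substitution_fraction(table, "A", "T>K") == 0.0

    def test_recovers_planted_rates_and_ratio(self):
        # ~20,000 Thr-containing base observations per strain
        table, truth = gen_peptide_table(
            strains=("control", "mutant"), n_replicates=3, n_peptides=13334,
            substitution_rates={"control": 0.001, "mutant": 0.01},
            missing_rate=0.0, seed=6)
        for strain, planted in (("control", 0.001), ("mutant", 0.01)):
            f = substitution_fraction(table, strain, "T>K")
            n = 20_000
            ci = 3 * math.sqrt(planted * (1 - planted) / n)
            assert abs(f - planted) <= ci + 1e-4
        ratio = ratio_vs_control(table, "mutant", "control", "T>K")
        assert ratio == pytest.approx(10.0, rel=0.15)

    def test_equal_rates_give_unit_ratio(self):
        table, _ = gen_peptide_table(
            strains=("control", "twin"), n_peptides=2000,
            substitution_rates={"control": 0.005, "twin": 0.005},
            missing_rate=0.0, seed=8)
        assert ratio_vs_control(table, "twin", "control", "T>M") == \
            pytest.approx(1.0, rel=0.05)

    def test_count_mode_invariant_to_intensity_rescaling(self):
        table, _ = gen_peptide_table(
            strains=("control", "mutant"), n_peptides=1000,
            substitution_rates={"control": 0.01, "mutant": 0.01},
            missing_rate=0.0, seed=9)
        before = substitution_fraction(table, "mutant", "T>K", mode="count")
        rescaled = PeptideQuantTable(
            values=table.values + 3.0,   # x8 on the linear scale
            meta=table.meta, groups=table.groups)
        after = substitution_fraction(rescaled, "mutant", "T>K", mode="count")
        assert before == after
        # intensity mode shifts accordingly but stays a valid fraction
        fi = substitution_fraction(rescaled, "mutant", "T>K",
                                   mode="intensity")
        assert 0 < fi < 1


class TestThrShift:
    def test_subset_equals_all(self):
        v = np.random.default_rng(0).normal(size=50)
        r = thr_shift(v, v, n_permutations=100, seed=0)
        assert r.median_shift == 0.0
        assert r.ks_statistic == 0.0

    def test_null_shift_near_zero(self):
        rng = np.random.default_rng(1)
        allv = rng.normal(size=500)
        sub = allv[rng.choice(500, 100, replace=False)]
        r = thr_shift(allv, sub, n_permutations=500, seed=2)
        assert abs(r.median_shift) < 0.3
        assert r.p_value > 0.001

    def test_recovers_planted_downshift(self):
        # subset kept at 2% of all peptides so the reference median is
        # essentially unshifted by the planted subset itself
        rng = np.random.default_rng(2)
        rest = rng.normal(0.0, 0.4, size=245_000)
        sub = rng.normal(-0.5, 0.4, size=5000)
        allv = np.concatenate([sub, rest])
        r = thr_shift(allv, sub, n_permutations=200, seed=3)
        assert r.median_shift == pytest.approx(-0.5, abs=0.05)
        assert r.p_value < 0.01

    def test_p_uniform_under_null(self):
        rng = np.random.default_rng(7)
        ps = []
        for i in range(400):
            allv = rng.normal(size=150)
            sub = allv[rng.choice(150, 40, replace=False)]
            ps.append(thr_shift(allv, sub, n_permutations=499,
                                seed=i).p_value)
        d, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            thr_shift([1.0, 2.0], [], n_permutations=10, seed=0)


class TestModeratedT:
    def test_s0_zero_is_ordinary_t(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        t_mod = moderated_t_s0(a, b, s0=0.0)
        t_ref = stats.ttest_ind(a, b).statistic
        assert t_mod == pytest.approx(t_ref, rel=1e-12)

    def test_s0_damps_statistic(self):
        a = [10.0, 10.01, 9.99]
        b = [12.0, 12.01, 11.99]
        assert abs(moderated_t_s0(a, b, s0=1.0)) < \
            abs(moderated_t_s0(a, b, s0=0.0))

    def test_degenerate_variance_needs_s0(self):
        with pytest.raises(ZeroDivisionError):
            moderated_t_s0([1.0, 1.0], [2.0, 2.0], s0=0.0)
        assert moderated_t_s0([1.0, 1.0], [2.0, 2.0], s0=1.0) == -1.0


class TestPermutationFdr:
    def test_q_values_match_exhaustive_enumeration_oracle(self):
        """3v3 toy: all 20 label assignments enumerable by brute force."""
        rng = np.random.default_rng(10)
        data = pd.DataFrame(rng.normal(size=(30, 6)),
                            columns=[f"s{i}" for i in range(6)])
        data.iloc[:3, :3] += 3.0   # three strong rows
        a_cols = ["s0", "s1", "s2"]
        b_cols = ["s3", "s4", "s5"]
        res = permutation_fdr(data, a_cols, b_cols, s0=1.0)

        # independent oracle: plain loops, direct definitions
        def t_row(vals, a_idx):
            a = [vals[i] for i in a_idx]
            b = [vals[i] for i in range(6) if i not in a_idx]
            ma, mb = sum(a) / 3, sum(b) / 3
            va = sum((x - ma) ** 2 for x in a) / 2
            vb = sum((x - mb) ** 2 for x in b) / 2
            se = math.sqrt((va + vb) / 2 * (2 / 3))
            return (ma - mb) / (se + 1.0)

        rows = data.to_numpy()
        t_obs = [t_row(r, (0, 1, 2)) for r in rows]
        perms = list(itertools.combinations(range(6), 3))
        null = [[abs(t_row(r, p)) for r in rows] for p in perms]
        q_oracle = []
        for ti in t_obs:
            cut = abs(ti)
            fps = sorted(sum(v >= cut for v in perm_ts) for perm_ts in null)
            med = (fps[9] + fps[10]) / 2
            pos = sum(abs(t) >= cut for t in t_obs)
            q_oracle.append(min(med / pos, 1.0))
        # suffix-minimize over descending |t| (q = min FDR over cutoffs
        # that still include the row)
        order = sorted(range(len(t_obs)), key=lambda i: -abs(t_obs[i]))
        q_mon = [0.0] * len(t_obs)
        running = math.inf
        for i in reversed(order):
            running = min(running, q_oracle[i])
            q_mon[i] = running
        got = {int(r.feature_id): r.q_value for r in res}
        for i in range(len(t_obs)):
            assert got[i] == pytest.approx(q_mon[i], abs=1e-12)

    def test_q_monotone_in_t_ranking(self):
        table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=200,
                                     missing_rate=0.0, seed=12)
        res = permutation_fdr(table.values, table.samples_of("A"),
                              table.samples_of("B"), s0=1.0)
        ordered = sorted(res, key=lambda r: -abs(r.t_moderated))
        qs = [r.q_value for r in ordered]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_null_flag_rate_bounded(self):
        rates = []
        for seed in range(5):
            table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=400,
                                         missing_rate=0.0, seed=500 + seed)
            res = permutation_fdr(table.values, table.samples_of("A"),
                                  table.samples_of("B"), s0=1.0)
            rates.append(np.mean([r.significant for r in res]))
        assert np.mean(rates) <= 0.05 + 0.02

    def test_planted_effects_sensitivity_and_fdr(self):
        sens, fdrs = [], []
        for seed in range(20):
            table, truth = gen_peptide_table(
                strains=("control", "host"), n_peptides=500,
                missing_rate=0.0, n_differential=25,
                differential_strain="host", differential_effect=1.2,
                seed=1000 + seed)
            res = permutation_fdr(table.values, table.samples_of("host"),
                                  table.samples_of("control"), s0=1.0)
            sig = {int(r.feature_id) for r in res if r.significant}
            planted = set(truth.differential_rows)
            sens.append(len(sig & planted) / len(planted))
            fdrs.append(len(sig - planted) / max(len(sig), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdrs) <= 0.1

    def test_pipeline_deterministic_under_seed(self):
        table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=300,
                                     missing_rate=0.1, seed=13)

        def run():
            kept, _ = filter_valid(table)
            imp = impute_lod(kept, seed=21)
            return permutation_fdr(imp.values, imp.samples_of("A"),
                                   imp.samples_of("B"), s0=1.0, seed=21)

        assert run() == run()


class TestTableIO:
    def test_tsv_round_trip(self, tmp_path):
        table, _ = gen_peptide_table(strains=("A", "B"), n_peptides=50,
                                     missing_rate=0.1, seed=14)
        tpath = tmp_path / "peptides.tsv"
        gpath = tmp_path / "groups.tsv"
        pd.concat([table.meta, table.values], axis=1).to_csv(
            tpath, sep="\t", index=False)
        with open(gpath, "w") as fh:
            fh.write("sample\tstrain\n")
            for sample, strain in table.groups.items():
                fh.write(f"{sample}\t{strain}\n")
        back = read_peptide_table(tpath, gpath)
        assert list(back.values.columns) == list(table.values.columns)
        assert np.allclose(back.values.to_numpy(), table.values.to_numpy(),
                           equal_nan=True)
        assert (back.groups == table.groups).all()
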