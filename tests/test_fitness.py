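"""Tests of strain/gene fitness estimation, normalization and QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import survfit as sf
from survfit.fitness import normalize, strain_weight

from conftest import make_count_table


class TestStrainLogRatio:
    @pytest.mark.parametrize("ref,out,psi,expected", [
        (100, 100, 0.1, 0.0),
        (50, 200, 1e-9, 2.0),          # psi -> 0: exact ratio 4
        (0, 7, 1.0, 3.0),              # log2(8/1)
    ])
    def test_known_values(self, ref, out, psi, expected):
        assert sf.strain_log_ratio(ref, out, psi) == pytest.approx(expected, abs=1e-7)

    @given(a=st.integers(min_value=0, max_value=10**6),
           psi=st.floats(min_value=1e-6, max_value=10.0))
    def test_equal_counts_give_zero(self, a, psi):
        assert sf.strain_log_ratio(a, a, psi) == 0.0

    def test_monotone_in_counts(self):
        assert sf.strain_log_ratio(10, 21, 0.1) > sf.strain_log_ratio(10, 20, 0.1)
        assert sf.strain_log_ratio(11, 20, 0.1) < sf.strain_log_ratio(10, 20, 0.1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sf.strain_log_ratio(-1, 5, 0.1)
        with pytest.raises(ValueError):
            sf.strain_log_ratio(5, 5, 0.0)


class TestGeneFitness:
    @pytest.mark.parametrize("f,w,expected", [
        ([1, 3], [1, 1], 2.0),
        ([0, 4], [3, 1], 1.0),
        ([-2.5], [7.0], -2.5),
    ])
    def test_weighted_average(self, f, w, expected):
        assert sf.gene_fitness(f, w) == pytest.approx(expected)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_to_weight_rescaling(self, scale):
        f = [0.5, -1.5, 2.0]
        w = [1.0, 2.0, 0.5]
        base = sf.gene_fitness(f, w)
        assert sf.gene_fitness(f, [x * scale for x in w]) == pytest.approx(base)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            sf.gene_fitness([1.0, 2.0], [0.0, 0.0])


class TestAggregateReference:
    def test_sums_match_brute_force(self, null_experiment):
        _, table = null_experiment
        ref = sf.aggregate_reference(table)
        # independent oracle: explicit per-strain python summation
        ref_ids = [s for s in table.samples.index
                   if table.samples.loc[s, "role"] == "reference"]
        for bc in table.counts.index[:25]:
            assert ref[bc] == sum(int(table.counts.loc[bc, s]) for s in ref_ids)

    def test_single_reference_is_identity(self):
        table = make_count_table(
            strains=[{"barcode": "b1", "gene_id": "g1", "scaffold": "chr",
                      "position_fraction": 0.5}],
            counts={"r1": [9], "o1": [3]},
            samples=[
                {"sample_id": "r1", "role": "reference", "condition_axis": "",
                 "condition_value": np.nan, "replicate": 1},
                {"sample_id": "o1", "role": "outgrowth", "condition_axis": "time_h",
                 "condition_value": 1.0, "replicate": 1},
            ],
        )
        assert sf.aggregate_reference(table)["b1"] == 9


class TestNormalize:
    def test_median_centering(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0, 5.0]},
                            index=[f"g{i}" for i in range(5)])
        scaff = pd.Series("chr", index=vals.index)
        out = normalize(vals, scaff)
        np.testing.assert_allclose(out["s1"], [-2, -1, 0, 1, 2])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame({"s1": rng.normal(size=11), "s2": rng.normal(size=11)},
                            index=[f"g{i}" for i in range(11)])
        scaff = pd.Series(["chr"] * 6 + ["p1"] * 5, index=vals.index)
        once = normalize(vals, scaff)
        twice = normalize(once, scaff)
        pd.testing.assert_frame_equal(once, twice)

    def test_per_scope_median_is_zero_after_centering(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame({"s1": rng.normal(0.4, 1, 20)},
                            index=[f"g{i}" for i in range(20)])
        vals.iloc[10:, 0] += -0.6  # second scaffold shifted
        scaff = pd.Series(["chr"] * 10 + ["p1"] * 10, index=vals.index)
        out = normalize(vals, scaff)
        for s in ("chr", "p1"):
            assert out.loc[scaff == s, "s1"].median() == pytest.approx(0.0, abs=1e-12)

    def test_small_scope_falls_back_to_global_with_warning(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 100.0]},
                            index=[f"g{i}" for i in range(7)])
        scaff = pd.Series(["chr"] * 6 + ["tiny"], index=vals.index)
        with pytest.warns(UserWarning, match="tiny"):
            out = normalize(vals, scaff)
        # the lone gene was centered on the global median (4.0), not its own
        assert out.loc["g6", "s1"] == pytest.approx(96.0)


class TestQCFilter:
    def _table(self):
        rng = np.random.default_rng(3)
        strains, ref1, ref2, out = [], [], [], []
        for i in range(20):
            strains.append({
                "barcode": f"b{i:02d}",
                "gene_id": f"g{i % 5}",
                "scaffold": "chr",
                "position_fraction": 0.05 if i in (0, 7) else 0.5,
            })
            ref1.append(1 if i in (1, 8) else int(rng.integers(10, 50)))
            ref2.append(0 if i in (1, 8) else int(rng.integers(10, 50)))
            out.append(int(rng.integers(0, 50)))
        return make_count_table(
            strains=strains,
            counts={"r1": ref1, "r2": ref2, "o1": out},
            samples=[
                {"sample_id": "r1", "role": "reference", "condition_axis": "",
                 "condition_value": np.nan, "replicate": 1},
                {"sample_id": "r2", "role": "reference", "condition_axis": "",
                 "condition_value": np.nan, "replicate": 2},
                {"sample_id": "o1", "role": "outgrowth", "condition_axis": "time_h",
                 "condition_value": 1.0, "replicate": 1},
            ],
        )

    def test_reason_codes(self):
        table = self._table()
        report = sf.qc_filter(table)
        excl = report.strain_exclusions.set_index("barcode")["reason"]
        assert excl["b00"] == "non_central_insertion"
        assert excl["b01"] == "low_reference_count"

    def test_included_set_matches_rule_by_rule_oracle(self):
        table = self._table()
        config = sf.FitnessConfig(min_reference_reads_per_strain=3,
                                  min_reference_reads_per_gene=30)
        report = sf.qc_filter(table, config)

        # independent oracle: apply the three rules strain by strain
        ref = {bc: int(table.counts.loc[bc, "r1"] + table.counts.loc[bc, "r2"])
               for bc in table.counts.index}
        included = set()
        for bc, row in table.strains.iterrows():
            if not (0.1 <= row["position_fraction"] <= 0.9):
                continue
            if ref[bc] < 3:
                continue
            included.add(bc)
        gene_reads = {}
        for bc in included:
            g = table.strains.loc[bc, "gene_id"]
            gene_reads[g] = gene_reads.get(g, 0) + ref[bc]
        genes = {g for g, r in gene_reads.items() if r >= 30}

        assert set(report.included_strains) == included
        assert set(report.included_genes) == genes


class TestFitnessPipeline:
    def test_order_invariance(self, null_experiment):
        _, table = null_experiment
        gft = sf.fitness_pipeline(table)
        perm = np.random.default_rng(0).permutation(len(table.counts))
        shuffled = sf.CountTable(
            strains=table.strains.iloc[perm],
            counts=table.counts.iloc[perm],
            samples=table.samples,
        )
        gft2 = sf.fitness_pipeline(shuffled)
        pd.testing.assert_frame_equal(
            gft.fitness.sort_index(), gft2.fitness.sort_index()
        )

    def test_null_data_fitness_concentrated_near_zero(self, null_experiment):
        _, table = null_experiment
        gft = sf.fitness_pipeline(table)
        frac_small = (gft.fitness.abs() < 0.3).to_numpy().mean()
        assert frac_small >= 0.95

    def test_planted_effect_recovered(self, small_library):
        genes = sorted(small_library["gene_id"].unique())
        effects = sf.EffectModel.constant(genes, {genes[3]: -2.0})
        seq = sf.SequencingModel(depth=1_000_000, replicates=3, reference_samples=6)
        table = sf.simulate_survival_experiment(
            small_library, effects, [1.0], seq, seed=13
        )
        gft = sf.fitness_pipeline(table)
        assert -2.4 <= gft.fitness.loc[genes[3]].iloc[0] <= -1.6

    def test_no_outgrowth_samples_rejected(self):
        table = make_count_table(
            strains=[{"barcode": "b1", "gene_id": "g1", "scaffold": "chr",
                      "position_fraction": 0.5}],
            counts={"r1": [9]},
            samples=[{"sample_id": "r1", "role": "reference", "condition_axis": "",
                      "condition_value": np.nan, "replicate": 1}],
        )
        with pytest.raises(ValueError):
            sf.fitness_pipeline(table)


class TestStrainWeight:
    def test_downweights_low_counts(self):
        assert strain_weight(1000, 1000) > strain_weight(1000, 3)
        assert strain_weight(3, 1000) == pytest.approx(strain_weight(1000, 3))

    def test_known_value(self):
        # w = 1 / (1/(1+ref) + 1/(1+out))
        assert strain_weight(9, 4) == pytest.approx(1 / (1 / 10 + 1 / 5))
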