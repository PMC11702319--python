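import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fjordapcs.geochem import (GeochemTable, StandardizationModel,
                               destandardize, impute_below_lod, read_table,
                               read_written_table, standardize, write_table)
from fjordapcs.synthetic import SyntheticConfig, generate


class TestReadTable:
    def test_flags_and_shapes(self, small_csv):
        csv, schema = small_csv
        table = read_table(csv, schema)
        assert table.n == 5 and table.p == 3
        assert table.flags.loc["PN_25", "NO3"] == "below_lod"
        assert np.isnan(table.values.loc["PN_25", "NO3"])
        assert table.flags.loc["F_6", "dFe"] == "missing"
        assert table.flags.loc["PN_3", "salinity"] == "measured"
        assert table.parameters["dFe"].unit == "ng/L"

    def test_study_size_round_trip(self, synthetic_study, tmp_path):
        """A survey-footprint table (14 fjord + 3 river rows, 18 parameters)
        survives a write/read round trip with values, flags and units."""
        table, _ = synthetic_study
        assert table.n == 17 and table.p == 18
        assert (table.observations["sample_type"] == "fjord").sum() == 14
        write_table(table, tmp_path / "t.csv")
        back = read_written_table(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back.values, table.values)
        pd.testing.assert_frame_equal(back.flags, table.flags)
        assert back.parameters["dMn"].unit == table.parameters["dMn"].unit

    def test_empty_file_rejected(self, tmp_path, small_csv):
        _, schema = small_csv
        empty = tmp_path / "empty.csv"
        empty.write_text("ID,Station,Depth,Type,sal,no3,fe\n")
        with pytest.raises(ValueError, match="no observations"):
            read_table(empty, schema)

    def test_duplicate_sample_id_rejected(self, tmp_path, small_csv):
        _, schema = small_csv
        bad = tmp_path / "dup.csv"
        bad.write_text(
            "ID,Station,Depth,Type,sal,no3,fe\n"
            "A,PN,3,fjord,32.5,2.1,150\nA,PN,25,fjord,34.2,1.0,80\n")
        with pytest.raises(ValueError, match="duplicate sample_id"):
            read_table(bad, schema)

    def test_unmapped_column_rejected(self, small_csv):
        csv, schema = small_csv
        schema = {**schema, "parameters": {
            "dZn": {"column": "zn_missing"}}}
        with pytest.raises(ValueError, match="zn_missing"):
            read_table(csv, schema)

    def test_negative_concentration_named(self, tmp_path, small_csv):
        _, schema = small_csv
        bad = tmp_path / "neg.csv"
        bad.write_text(
            "ID,Station,Depth,Type,sal,no3,fe\n"
            "A,PN,3,fjord,32.5,-2.1,150\n")
        with pytest.raises(ValueError, match="NO3.*'A'"):
            read_table(bad, schema)


class TestImputation:
    def _censored_table(self, lod=1.0):
        cfg = SyntheticConfig.study(lod_quantile=0.25)
        table, _ = generate(cfg)
        return table

    def test_determinism_and_measured_untouched(self):
        table = self._censored_table()
        a = impute_below_lod(table, seed=7)
        b = impute_below_lod(table, seed=7)
        assert a.values.equals(b.values)
        measured = table.flags == "measured"
        assert ((a.values == table.values) | ~measured).all().all()
        censored = table.flags == "below_lod"
        assert censored.any().any()
        assert ((a.flags == "imputed") | ~censored).all().all()

    def test_zero_lod_gives_zero(self, small_csv):
        csv, schema = small_csv
        schema["parameters"]["NO3"]["lod"] = 0.0
        table = read_table(csv, schema)
        out = impute_below_lod(table, seed=1)
        assert out.values.loc["PN_25", "NO3"] == 0.0

    def test_missing_lod_rejected(self, small_csv):
        csv, schema = small_csv
        del schema["parameters"]["NO3"]["lod"]
        table = read_table(csv, schema)
        with pytest.raises(ValueError, match="no LOD"):
            impute_below_lod(table, seed=1)

    def test_uniform_distribution_oracle(self):
        """10,000 draws on [0, 1) should average ~0.5 (uniform oracle)."""
        n = 10_000
        obs = pd.DataFrame({"station": "X", "depth_m": np.arange(n, dtype=float),
                            "sample_type": "fjord"},
                           index=pd.Index([f"s{i}" for i in range(n)],
                                          name="sample_id"))
        vals = pd.DataFrame({"c": np.full(n, np.nan)}, index=obs.index)
        flags = pd.DataFrame({"c": ["below_lod"] * n}, index=obs.index)
        from fjordapcs.geochem import ParameterMeta
        table = GeochemTable(obs, vals, flags,
                             {"c": ParameterMeta("c", lod=1.0)})
        out = impute_below_lod(table, seed=3)
        assert 0.48 <= out.values["c"].mean() <= 0.52

    def test_lod_scaling_property(self):
        """Scaling the LOD by c scales the draws by c (same seed)."""
        table = self._censored_table()
        scaled = GeochemTable(
            table.observations.copy(), table.values.copy(),
            table.flags.copy(),
            {k: type(v)(v.name, v.unit,
                        None if v.lod is None else 3.0 * v.lod, v.loq, v.kind)
             for k, v in table.parameters.items()},
        )
        a = impute_below_lod(table, seed=11)
        b = impute_below_lod(scaled, seed=11)
        cens = table.flags == "below_lod"
        ratio = (b.values[cens] / a.values[cens]).stack()
        assert np.allclose(ratio, 3.0)


class TestStandardization:
    def test_hand_case(self):
        obs = pd.DataFrame({"station": "X", "depth_m": [1.0, 2, 3],
                            "sample_type": "fjord"},
                           index=pd.Index(list("abc"), name="sample_id"))
        vals = pd.DataFrame({"c": [1.0, 2.0, 3.0]}, index=obs.index)
        flags = pd.DataFrame({"c": ["measured"] * 3}, index=obs.index)
        from fjordapcs.geochem import ParameterMeta
        table = GeochemTable(obs, vals, flags, {"c": ParameterMeta("c")})
        z, model = standardize(table)
        assert np.allclose(z["c"], [-1, 0, 1])
        assert model.mean["c"] == 2.0 and model.sd["c"] == 1.0

    def test_columns_centered(self, fitted_default):
        z = fitted_default["z"]
        assert (z.mean().abs() < 1e-12).all()
        assert np.allclose(z.std(ddof=1), 1.0)

    def test_round_trip_identity(self, fitted_default):
        z, std = fitted_default["z"], fitted_default["std"]
        raw = fitted_default["fjord"].values
        back = destandardize(z, std)
        assert np.allclose(back, raw[z.columns], rtol=1e-10)
        z2, _ = standardize(fitted_default["fjord"], list(z.columns))
        assert np.allclose(z2, z)

    def test_constant_column_named(self):
        obs = pd.DataFrame({"station": "X", "depth_m": [1.0, 2, 3],
                            "sample_type": "fjord"},
                           index=pd.Index(list("abc"), name="sample_id"))
        vals = pd.DataFrame({"flat": [5.0, 5.0, 5.0]}, index=obs.index)
        flags = pd.DataFrame({"flat": ["measured"] * 3}, index=obs.index)
        from fjordapcs.geochem import ParameterMeta
        table = GeochemTable(obs, vals, flags, {"flat": ParameterMeta("flat")})
        with pytest.raises(ValueError, match="flat"):
            standardize(table)

    def test_unimputed_censoring_rejected(self, small_csv):
        csv, schema = small_csv
        table = read_table(csv, schema)
        with pytest.raises(ValueError, match="impute first"):
            standardize(table, ["NO3"])

    def test_destandardize_cases(self):
        model = StandardizationModel(mean=pd.Series({"x": 10.0}),
                                     sd=pd.Series({"x": 3.0}))
        assert destandardize(np.array([[2.0]]), model).iloc[0, 0] == 16.0
        assert destandardize(np.zeros((4, 1)), model)["x"].eq(10.0).all()
        with pytest.raises(ValueError, match="mismatch"):
            destandardize(np.zeros((2, 3)), model)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_destandardize_standardize_identity(self, seed):
        rng = np.random.default_rng(seed)
        model = StandardizationModel(
            mean=pd.Series(rng.normal(0, 100, 4), index=list("wxyz")),
            sd=pd.Series(rng.uniform(0.1, 50, 4), index=list("wxyz")))
        z = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("wxyz"))
        back = (destandardize(z, model) - model.mean) / model.sd
        assert np.allclose(back, z, rtol=1e-10, atol=1e-10)
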