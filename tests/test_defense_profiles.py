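"""Titer, EOP and log10-protection computation with censoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abikit.defense_profiles import (
    EOP,
    SpotCount,
    Titer,
    eop,
    eop_table,
    protection,
    protection_matrix,
    protection_table,
    read_spot_table,
    titer,
)


def _spot(d, plaques, lawn=False, phage="phi", system="abi", rep=1):
    return SpotCount(phage, system, rep, d, None if lawn else plaques, lawn=lawn)


class TestTiter:
    def test_arithmetic_from_definition(self):
        t = titer([_spot(-6, 23)])
        assert t.value == pytest.approx(23 / (0.0025 * 1e-6))
        assert t.value == pytest.approx(9.2e9)
        assert not t.censored

    def test_most_dilute_countable_spot_used(self):
        # consistent series: 230 at 1e-5, 23 at 1e-6 -> same titer either way
        t = titer([_spot(-5, 230), _spot(-6, 23)])
        assert t.value == pytest.approx(23 / (0.0025 * 1e-6))

    def test_all_zero_censored_at_half_plaque(self):
        spots = [_spot(d, 0) for d in range(0, -8, -1)]
        t = titer(spots)
        assert t.censored
        assert t.value == pytest.approx(0.5 / 0.0025)  # 200 PFU/ml

    def test_out_of_window_counts_used_as_fallback(self):
        t = titer([_spot(0, 2)])
        assert not t.censored
        assert t.value == pytest.approx(2 / 0.0025)

    def test_lawn_spots_skipped(self):
        t = titer([_spot(0, None, lawn=True), _spot(-3, 150)])
        assert t.value == pytest.approx(150 / (0.0025 * 1e-3))

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            titer([_spot(-1, 10), _spot(-1, 10, phage="other")])


class TestEOP:
    def test_simple_division(self):
        assert eop(Titer(1e4), Titer(1e7)).value == pytest.approx(1e-3)

    def test_equal_titers_give_one(self):
        assert eop(Titer(5e8), Titer(5e8)).value == 1.0

    def test_censored_numerator_propagates(self):
        e = eop(Titer(200, censored=True), Titer(1e7))
        assert e.censored and e.value == pytest.approx(2e-5)

    def test_censored_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            eop(Titer(1e4), Titer(200, censored=True))


class TestProtection:
    def test_arithmetic_mean_then_log(self):
        p = protection([EOP(0.1), EOP(0.01), EOP(0.01)])
        assert p.value == pytest.approx(-math.log10(0.04), abs=1e-12)
        assert p.value == pytest.approx(1.398, abs=1e-3)

    def test_eop_one_gives_zero(self):
        assert protection([EOP(1.0)] * 3).value == 0.0

    @given(st.floats(1e-9, 1.0), st.integers(0, 9))
    @settings(max_examples=50, derandomize=True)
    def test_log_law_exact_shift(self, base, k):
        eops = [EOP(base)] * 3
        scaled = [EOP(base * 10.0**-k)] * 3
        assert protection(scaled).value == pytest.approx(
            protection(eops).value + k, abs=1e-9
        )

    def test_strictly_decreasing_in_mean_eop(self):
        assert protection([EOP(0.01)]).value > protection([EOP(0.1)]).value

    def test_censored_replicate_flags_lower_bound(self):
        p = protection([EOP(1e-5, censored=True), EOP(2e-5)])
        assert p.censored

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            protection([])

    def test_geometric_mean_option(self):
        p = protection([EOP(0.1), EOP(0.001)], geometric=True)
        assert p.value == pytest.approx(2.0, abs=1e-12)


class TestTablesAndMatrix:
    def _spots(self):
        spots = []
        for system, count in (("empty_vector", 100), ("abi", 100)):
            for rep in (1, 2):
                spots.append(_spot(-4, count, system=system, rep=rep))
        return spots

    def test_eop_table_matches_vector_by_replicate(self):
        table = eop_table(self._spots())
        assert set(table["system"]) == {"abi"}
        assert table["eop"].tolist() == [1.0, 1.0]

    def test_missing_control_errors(self):
        with pytest.raises(ValueError, match="control"):
            eop_table([_spot(-4, 100, system="abi")])

    def test_protection_matrix_ordered_by_leaves_with_nan_for_untested(self):
        table = eop_table(self._spots())
        prot = protection_table(table)
        mat = protection_matrix(prot, ["other", "phi"], systems=["abi", "untested"])
        assert list(mat.index) == ["other", "phi"]
        assert mat.loc["phi", "abi"] == 0.0
        assert np.isnan(mat.loc["phi", "untested"])
        assert np.isnan(mat.loc["other", "abi"])

    def test_single_cell_matrix(self):
        import pandas as pd

        prot = pd.DataFrame(
            [("phi", "abi", 3.0, False)],
            columns=["phage_id", "system", "protection", "censored"],
        )
        mat = protection_matrix(prot, ["phi"])
        assert mat.shape == (1, 1) and mat.iloc[0, 0] == 3.0

    def test_heatmap_renders_image(self, tmp_path):
        from abikit.defense_profiles import plot_protection_heatmap
        import pandas as pd

        mat = pd.DataFrame([[0.0, 3.0], [6.0, np.nan]],
                           index=["p1", "p2"], columns=["abiA", "abiK"])
        out = tmp_path / "heat.png"
        plot_protection_heatmap(mat, out)
        assert out.stat().st_size > 0

    def test_spot_table_round_trip(self, tmp_path):
        from abikit.synthetic_data import AssaySimSpec, gen_plaque_table, write_plaque_table

        spec = AssaySimSpec(protection={("phi", "abi"): 2.0}, seed=3)
        spots, _ = gen_plaque_table(spec)
        write_plaque_table(spots, {}, tmp_path)
        again = read_spot_table(tmp_path / "spots.tsv")
        assert again == spots


class TestSpotCountValidation:
    def test_positive_dilution_rejected(self):
        with pytest.raises(ValueError):
            SpotCount("p", "s", 1, 1, 10)

    def test_lawn_xor_count(self):
        with pytest.raises(ValueError):
            SpotCount("p", "s", 1, 0, 5, lawn=True)
        with pytest.raises(ValueError):
            SpotCount("p", "s", 1, 0, None, lawn=False)
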