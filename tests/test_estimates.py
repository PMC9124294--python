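"""Estimate-table parsing, validation and the built-in fixture."""

import io
import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatherdss import (
    EstimateFormatError,
    EstimateTable,
    EstimateValidationError,
    HEATHER_MANIFEST,
    VariableEstimate,
    builtin_table1,
    parse_estimate_table,
    write_estimate_table,
)


class TestBuiltinTable:
    def test_has_all_printed_rows(self, table1):
        assert len(table1) == 32
        assert table1.names == HEATHER_MANIFEST

    @pytest.mark.parametrize(
        "name, distribution, lower, upper",
        [
            ("initial_investment_S", "posnorm", 18_000, 100_000),
            ("chance_high_risk", "tnorm", 40, 60),
            ("labor_costs_S", "posnorm", 500, 5_000),
            ("plant_value_of_A1_quality", "posnorm", 0.6, 0.9),
            ("n_years", "const", 10, 10),
            ("production_area", "const", 8, 8),
        ],
    )
    def test_printed_values(self, table1, name, distribution, lower, upper):
        est = table1[name]
        assert (est.distribution, est.lower, est.upper) == (distribution, lower, upper)

    def test_passes_completeness_validation(self, table1):
        table1.validate_complete()

    def test_strategy_suffix_partition(self, table1):
        shared = set(table1.shared_names())
        per_strategy = {c: set(table1.strategy_names(c)) for c in "BIS"}
        assert "discount_rate" in shared
        assert "labor_costs_S" in per_strategy["S"]
        assert len(shared) + sum(map(len, per_strategy.values())) == len(table1)

    def test_degenerate_posnorm_coerced_to_constant(self, table1, caplog):
        # post_processing_costs_I is printed as a posnorm with bounds 0, 0:
        # a zero-width CI is a point mass.
        assert table1["post_processing_costs_I"].is_constant
        with caplog.at_level(logging.WARNING, logger="heatherdss.estimates"):
            EstimateTable([VariableEstimate("x", "€", "posnorm", 3.0, 3.0)])
        assert "coerced" in caplog.text


class TestVariableEstimateInvariants:
    def test_ordered_bounds_enforced(self):
        with pytest.raises(EstimateValidationError, match="bad_var"):
            VariableEstimate("bad_var", "€", "posnorm", 200, 100)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(EstimateValidationError, match="lognorm"):
            VariableEstimate("x", "€", "lognorm", 1, 2)

    def test_percent_bounds_confined(self):
        with pytest.raises(EstimateValidationError):
            VariableEstimate("p", "%", "tnorm", 50, 120)

    def test_posnorm_lower_nonnegative(self):
        with pytest.raises(EstimateValidationError):
            VariableEstimate("x", "€", "posnorm", -1, 2)

    def test_const_requires_equal_bounds(self):
        with pytest.raises(EstimateValidationError):
            VariableEstimate("x", "€", "const", 1, 2)

    def test_duplicate_names_rejected(self):
        est = VariableEstimate("x", "€", "posnorm", 1, 2)
        with pytest.raises(EstimateValidationError, match="duplicate"):
            EstimateTable([est, est])


class TestParsing:
    def test_parses_table1_style_rows(self):
        csv = (
            "variable,unit,distribution,lower,upper,description\n"
            "labor_costs_S,€,posnorm,500,\"5,000\",sensor labor\n"
            "n_years,years,const,10,10,horizon\n"
        )
        table = parse_estimate_table(io.StringIO(csv))
        est = table["labor_costs_S"]
        assert (est.distribution, est.lower, est.upper) == ("posnorm", 500.0, 5000.0)
        assert table["n_years"].lower == 10.0

    def test_missing_column_is_format_error(self):
        csv = "variable,lower,upper\nx,1,2\n"
        with pytest.raises(EstimateFormatError, match="distribution"):
            parse_estimate_table(io.StringIO(csv))

    def test_unordered_bounds_name_the_variable(self):
        csv = "variable,unit,distribution,lower,upper\nbad_one,€,posnorm,200,100\n"
        with pytest.raises(EstimateValidationError, match="bad_one"):
            parse_estimate_table(io.StringIO(csv))

    def test_decimal_comma_rejected(self):
        csv = "variable,unit,distribution,lower,upper\nx,€,posnorm,\"3,5\",10\n"
        with pytest.raises(EstimateFormatError, match="comma"):
            parse_estimate_table(io.StringIO(csv))

    def test_extra_variables_allowed_but_completeness_checked(self, table1):
        buf = io.StringIO()
        write_estimate_table(table1, buf)
        buf.seek(0, 2)
        buf.write("something_else,€,posnorm,1,2,extra\n")
        buf.seek(0)
        table = parse_estimate_table(buf)
        table.validate_complete()
        assert "something_else" in table

    def test_missing_model_variable_reported(self, table1):
        subset = EstimateTable(
            est for name, est in table1.items() if name != "labor_costs_S"
        )
        with pytest.raises(EstimateValidationError, match="labor_costs_S"):
            subset.validate_complete()


class TestRoundTrip:
    def test_builtin_round_trips(self, table1, tmp_path):
        path = tmp_path / "table1.csv"
        write_estimate_table(table1, path)
        assert parse_estimate_table(path) == table1

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_estimate_table(EstimateTable([]), path)
        assert path.read_text(encoding="utf-8").strip() == (
            "variable,unit,distribution,lower,upper,description"
        )
        assert len(parse_estimate_table(path)) == 0

    def test_unicode_description_preserved(self, tmp_path):
        est = VariableEstimate("x", "€", "posnorm", 1, 2, "Bewässerung — 10 µl")
        path = tmp_path / "t.csv"
        write_estimate_table(EstimateTable([est]), path)
        assert parse_estimate_table(path)["x"].description == "Bewässerung — 10 µl"

    @given(
        tables=st.dictionaries(
            st.from_regex(r"[a-z][a-z0-9_]{0,15}", fullmatch=True),
            st.tuples(
                st.sampled_from(["€", "%", "digit", "years", "ha"]),
                st.sampled_from(["posnorm", "tnorm", "const"]),
                st.floats(min_value=0.0, max_value=99.0),
                st.floats(min_value=0.001, max_value=1.0),
                st.text(
                    alphabet=st.characters(
                        codec="utf-8", exclude_categories=("C",), exclude_characters=",\"'\r\n"
                    ),
                    max_size=20,
                ),
            ),
            max_size=8,
        )
    )
    def test_write_parse_identity(self, tables):
        """parse(write(t)) reproduces any valid table field-for-field."""
        estimates = []
        for name, (unit, dist, lower, frac, desc) in tables.items():
            upper = lower if dist == "const" else lower + frac * (99.9 - lower)
            if dist != "const" and upper == lower:
                upper = lower + 0.5
            if unit == "%":
                upper = min(upper, 100.0)
                if dist != "const" and upper <= lower:
                    continue
            estimates.append(
                VariableEstimate(name, unit, dist, lower, upper, desc.strip())
            )
        table = EstimateTable(estimates, coerce_degenerate=False)
        buf = io.StringIO()
        write_estimate_table(table, buf)
        buf.seek(0)
        assert parse_estimate_table(buf) == table
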