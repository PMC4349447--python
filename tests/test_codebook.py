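"""Codebook, standardization, degenerate-variable and partner-encoding tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exwas.codebook import (
    Codebook,
    DOMAINS,
    DegenerateVariableError,
    ExposomeMatrix,
    ExposureVariable,
    apply_coding_directions,
    drop_degenerate,
    encode_partner_variables,
    standardize,
)


def _matrix(values: dict, partner: dict | None = None, status=None) -> ExposomeMatrix:
    data = pd.DataFrame(values, dtype=float)
    partner = partner or {}
    variables = [
        ExposureVariable(
            name=c,
            domain=DOMAINS[0],
            reporter="partner" if partner.get(c) else "mother",
            var_type="continuous",
            feasible_range=(0.0, 10.0) if partner.get(c) else (float("nan"), float("nan")),
        )
        for c in data.columns
    ]
    if status is None:
        status = pd.Series(0, index=data.index)
    return ExposomeMatrix(data=data, codebook=Codebook.from_variables(variables), partner_status=status)


# -- standardization ---------------------------------------------------------


def test_standardize_rescales_to_unit_variance_and_records_scale(rng):
    m = _matrix({"a": 2.5 * rng.standard_normal(200), "b": rng.standard_normal(200)})
    out, record = standardize(m)
    assert np.isclose(out.data["a"].std(ddof=1), 1.0)
    assert np.isclose(record["a"], m.data["a"].std(ddof=1))
    # raw-scale slope recovery: B_raw = B_std / SD
    y = 3.0 * m.data["a"] + rng.standard_normal(200)
    b_raw = np.polyfit(m.data["a"], y, 1)[0]
    b_std = np.polyfit(out.data["a"], y, 1)[0]
    assert np.isclose(b_raw, b_std / record["a"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
def test_standardize_idempotent(scale, shift):
    vals = shift + scale * np.linspace(-1, 1, 50)
    m = _matrix({"a": vals})
    once, _ = standardize(m)
    twice, rec2 = standardize(once)
    assert np.allclose(once.data["a"], twice.data["a"], atol=1e-10)
    assert np.isclose(rec2["a"], 1.0, atol=1e-10)


def test_standardize_frozen_record_reused():
    m = _matrix({"a": np.arange(10.0)})
    _, rec = standardize(m)
    m2 = _matrix({"a": 2 * np.arange(10.0)})
    out, _ = standardize(m2, scale_record=rec)
    assert np.isclose(out.data["a"].std(ddof=1), 2.0)  # scaled by the frozen SD, not its own


def test_standardize_degenerate_column_raises_with_direction():
    m = _matrix({"a": np.ones(20)})
    with pytest.raises(DegenerateVariableError, match="drop_degenerate"):
        standardize(m)


# -- degenerate removal ------------------------------------------------------


def test_drop_degenerate_rules():
    n = 12
    outcome = pd.Series([np.nan] * 4 + [1.0] * 8)
    m = _matrix(
        {
            "all_zero": np.zeros(n),
            "varies_only_when_outcome_missing": [0, 1, 0, 1] + [0] * 8,
            "two_valued_in_sample": [0] * 6 + [1] * 6,
        }
    )
    kept, dropped = drop_degenerate(m, outcome)
    assert sorted(dropped) == ["all_zero", "varies_only_when_outcome_missing"]
    assert kept.codebook.names == ["two_valued_in_sample"]


def test_drop_degenerate_never_drops_varying_variable(rng):
    m = _matrix({f"v{i}": rng.standard_normal(30) for i in range(5)})
    outcome = pd.Series(rng.standard_normal(30))
    kept, dropped = drop_degenerate(m, outcome)
    assert dropped == []
    assert kept.n_variables == 5


# -- partner encoding --------------------------------------------------------


def _partner_matrix(rng, n=60):
    status = pd.Series([1] * 10 + [0] * (n - 10))
    vals = {
        "mine": rng.standard_normal(n),
        "theirs": rng.standard_normal(n),
    }
    m = _matrix(vals, partner={"theirs": True}, status=status)
    m.data.loc[status == 1, "theirs"] = np.nan  # partner answers absent
    return m, status


def test_encode_partner_fills_and_masks(rng):
    m, status = _partner_matrix(rng)
    enc = encode_partner_variables(m, fill_value=0.0)
    assert (enc.data.loc[status == 1, "theirs"] == 0.0).all()
    assert enc.convention_mask.loc[status == 1, "theirs"].all()
    assert not enc.convention_mask["mine"].any()
    # original untouched
    assert m.data.loc[status == 1, "theirs"].isna().all()


def test_encode_partner_noop_without_partnerless(rng):
    m = _matrix({"a": rng.standard_normal(20)}, partner={"a": True})
    enc = encode_partner_variables(m, fill_value=0.0)
    pd.testing.assert_frame_equal(enc.data, m.data)
    assert not enc.convention_mask.any().any()


def test_encode_partner_warns_outside_feasible_range(rng):
    m, _ = _partner_matrix(rng)
    with pytest.warns(UserWarning, match="outside feasible range"):
        encode_partner_variables(m, fill_value=99.0)


def test_partner_fill_value_invariance(rng):
    """Fill 0 vs 5: identical non-status coefficients and fitted values."""
    from exwas.select import fit_linear

    m, status = _partner_matrix(rng, n=120)
    y = pd.Series(
        1.5 * m.data["mine"] + 0.8 * m.data["theirs"].fillna(0) + rng.standard_normal(120)
    )
    results = {}
    for fill in (0.0, 5.0):  # both inside the declared feasible range
        enc = encode_partner_variables(m, fill_value=fill)
        fit = fit_linear(enc, y, ["mine", "theirs"])
        frame = enc.data[["mine", "theirs"]].copy()
        frame["partner_status"] = enc.partner_status.astype(float)
        results[fill] = (fit.coef[["mine", "theirs"]].to_numpy(), fit.predict(frame).to_numpy())
        assert "partner_status" in fit.forced
    assert np.allclose(results[0.0][0], results[5.0][0], atol=1e-10)
    assert np.allclose(results[0.0][1], results[5.0][1], atol=1e-10)


# -- codebook i/o and directions --------------------------------------------


def test_codebook_tsv_roundtrip(tmp_path):
    cb = Codebook.from_variables(
        [
            ExposureVariable("a", DOMAINS[1], "mother", "ordinal", 1, (0, 4)),
            ExposureVariable("b", DOMAINS[9], "partner", "binary", -1, (0, 1)),
        ]
    )
    path = tmp_path / "codebook.tsv"
    cb.to_tsv(path)
    back = Codebook.read_tsv(path)
    pd.testing.assert_frame_equal(back.table, cb.table)
    assert back.partner_variables == ["b"]


def test_codebook_rejects_unknown_domain():
    with pytest.raises(ValueError, match="domain"):
        ExposureVariable("a", "astrology")


def test_apply_coding_directions_flips_negative_columns(rng):
    vals = rng.standard_normal(30)
    data = pd.DataFrame({"a": vals})
    cb = Codebook.from_variables([ExposureVariable("a", DOMAINS[0], direction=-1)])
    m = ExposomeMatrix(data=data, codebook=cb, partner_status=pd.Series(0, index=data.index))
    out = apply_coding_directions(m)
    assert np.allclose(out.data["a"], -vals)
    assert (out.codebook.table["direction"] == 1).all()
    # idempotent after reset
    again = apply_coding_directions(out)
    assert np.allclose(again.data["a"], -vals)
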