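import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cmcqspr.dataset import (
    DescriptorTable,
    FormatError,
    assemble_design,
    drop_uninformative_descriptors,
    read_dataset,
    train_test_split,
    write_dataset,
)
from cmcqspr.synthetic import SyntheticSpec, generate_dataset
from conftest import make_dataset

CSV_3ROW = """compound_id,T_K,pH,Seq_ppm,log10_CMC,D1,D2
a,298.15,7.0,100.0,0.5,1.2,0.0
b,310.0,7.5,0.0,1.0,-0.3,1.1
c,320.0,8.0,5000.0,-0.2,0.7,2.2
"""


def test_read_well_formed_csv(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(CSV_3ROW)
    data = read_dataset(p)
    assert data.n == 3
    assert data.descriptors.descriptor_names == ["D1", "D2"]
    assert data.records[0].T == 298.15


def test_read_missing_column_names_it(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(CSV_3ROW.replace("pH", "PH"))
    with pytest.raises(FormatError, match="pH"):
        read_dataset(p)


def test_read_non_numeric_cell_located(tmp_path):
    p = tmp_path / "d.csv"
    p.write_text(CSV_3ROW.replace("-0.3", "oops"))
    with pytest.raises(FormatError, match="D1"):
        read_dataset(p)


def test_write_read_round_trip(tmp_path):
    data = make_dataset(n=5, p=4, seed=3)
    p = tmp_path / "rt.csv"
    write_dataset(data, p)
    back = read_dataset(p)
    assert [r.compound_id for r in back.records] == [r.compound_id for r in data.records]
    np.testing.assert_allclose(back.descriptors.values, data.descriptors.values)
    np.testing.assert_allclose([r.log_cmc for r in back.records],
                               [r.log_cmc for r in data.records])


def test_drop_constant_column():
    table = DescriptorTable(
        ["a", "b", "c"], [f"D{j}" for j in range(5)],
        np.column_stack([np.arange(3.0)] * 4 + [np.full(3, 7.0)]),
    )
    out, removed = drop_uninformative_descriptors(table)
    assert removed == ["D4"]
    assert len(out.descriptor_names) == 4


def test_drop_identity_when_all_vary():
    table = DescriptorTable(["a", "b", "c"], ["D0", "D1"],
                            np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 4.0]]))
    out, removed = drop_uninformative_descriptors(table, tol=0.0)
    assert removed == [] and out.descriptor_names == ["D0", "D1"]


def test_drop_near_constant_depends_on_tol():
    col = np.array([1.0, 1.0, 1.0 + 1e-9])
    table = DescriptorTable(["a", "b", "c"], ["near", "varies"],
                            np.column_stack([col, np.arange(3.0)]))
    kept, _ = drop_uninformative_descriptors(table, tol=1e-12)
    assert "near" not in [] and "near" in kept.descriptor_names
    dropped, removed = drop_uninformative_descriptors(table, tol=1e-6)
    assert removed == ["near"]


def test_drop_idempotent():
    table = DescriptorTable(
        ["a", "b", "c"], ["D0", "D1", "D2"],
        np.column_stack([np.arange(3.0), np.full(3, 2.0), np.arange(3.0) ** 2]),
    )
    once, _ = drop_uninformative_descriptors(table)
    twice, removed = drop_uninformative_descriptors(once)
    assert removed == []
    np.testing.assert_array_equal(once.values, twice.values)


def test_drop_all_constant_is_degenerate():
    table = DescriptorTable(["a", "b"], ["D0"], np.array([[1.0], [1.0]]))
    with pytest.raises(ValueError, match="degenerate"):
        drop_uninformative_descriptors(table)


def test_split_488_matches_printed_partition():
    data, _ = generate_dataset(SyntheticSpec(n_compounds=488, n_descriptors=5,
                                             planted_subset=(0, 1, 2, 3, 4), seed=0))
    split = train_test_split(data, 0.1, seed=11)
    assert len(split.train_indices) == 440
    assert len(split.test_indices) == 48


def test_split_floor_rule_and_determinism():
    data = make_dataset(n=10)
    s1 = train_test_split(data, 0.1, seed=5)
    s2 = train_test_split(data, 0.1, seed=5)
    assert len(s1.test_indices) == 1 and len(s1.train_indices) == 9
    assert s1 == s2


@settings(derandomize=True, max_examples=40)
@given(st.integers(5, 60), st.floats(0.05, 0.45), st.integers(0, 10**6))
def test_split_partition_property(n, frac, seed):
    data = make_dataset(n=n)
    n_test = int(np.floor(frac * n))
    if n_test < 1:
        return
    s = train_test_split(data, frac, seed)
    assert len(s.test_indices) == n_test
    assert set(s.train_indices) | set(s.test_indices) == set(range(n))
    assert set(s.train_indices) & set(s.test_indices) == set()


def test_split_csv_serialization(small_dataset):
    s = train_test_split(small_dataset, 0.2, seed=0)
    text = s.to_csv()
    assert text.startswith("index,role")
    assert text.count("test") == len(s.test_indices)


def test_assemble_design_temperature_column(small_dataset):
    X, y = assemble_design(small_dataset, ["T"])
    assert X.shape == (6, 1)
    np.testing.assert_allclose(X[:, 0], [300.0 + i for i in range(6)])


def test_assemble_design_unknown_name(small_dataset):
    with pytest.raises(KeyError, match="Dxx"):
        assemble_design(small_dataset, ["Dxx"])


def test_assemble_design_order_matches_request(small_dataset):
    X, _ = assemble_design(small_dataset, ["D1", "T", "D0"])
    X2, _ = assemble_design(small_dataset, ["D0", "T", "D1"])
    np.testing.assert_allclose(X[:, 0], X2[:, 2])
    np.testing.assert_allclose(X[:, 1], X2[:, 1])
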