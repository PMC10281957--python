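"""Sample-level feature extraction: abundance, central tendency,
percent-positive, and binned distribution distances."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linprog

import cytoverbs as cv
from cytoverbs.errors import (
    MissingColumnError,
    MissingReferenceError,
    ParameterError,
)

from conftest import make_table


def clustered_table(rows):
    """rows: list of (sample_id, cluster, m1, m2)."""
    df = pd.DataFrame(rows, columns=["sample_id", ".cluster", "m1", "m2"])
    return cv.CytoTable(df, panel=cv.Panel.from_columns(["m1", "m2"]))


def test_abundance_hand_counts():
    t = clustered_table(
        [("s1", "A", 0, 0)] * 3 + [("s1", "B", 0, 0)]
        + [("s2", "A", 0, 0)] * 2 + [("s2", "B", 0, 0)] * 2
    )
    out = cv.extract_abundance(t)
    row1 = out.set_index("sample_id").loc["s1"]
    assert row1["abundance@A"] == 0.75 and row1["abundance@B"] == 0.25
    row2 = out.set_index("sample_id").loc["s2"]
    assert row2["abundance@A"] == 0.5 and row2["abundance@B"] == 0.5


def test_abundance_unobserved_cluster_is_exact_zero():
    t = clustered_table([("s1", "A", 0, 0), ("s2", "A", 0, 0), ("s2", "B", 0, 0)])
    out = cv.extract_abundance(t).set_index("sample_id")
    assert out.loc["s1", "abundance@B"] == 0.0
    assert out.loc["s1", "abundance@A"] == 1.0


def test_abundance_requires_cluster_column(two_channel_table):
    t = cv.bind_samples([two_channel_table], ["s1"])
    with pytest.raises(MissingColumnError):
        cv.extract_abundance(t)


def test_abundance_rows_sum_to_one(small_cohort):
    _, tables, meta, _ = small_cohort
    t = cv.bind_samples(tables, meta["sample_id"].tolist())
    t = t.rename(columns={".true_cluster": ".cluster"})
    out = cv.extract_abundance(t)
    sums = out.filter(like="abundance@").sum(axis=1)
    assert np.abs(sums - 1.0).max() < 1e-12


def test_central_tendency_median_mean_and_missing():
    t = clustered_table(
        [("s1", "A", 1.0, 1.0), ("s1", "A", 2.0, 2.0), ("s1", "A", 3.0, 4.0),
         ("s2", "A", 5.0, 5.0), ("s2", "B", 9.0, 9.0)]
    )
    med = cv.extract_central_tendency(t, ["m1"], stat="median").set_index("sample_id")
    assert med.loc["s1", "ct@A@m1"] == 2.0
    assert np.isnan(med.loc["s1", "ct@B@m1"])  # missing, not 0
    mean = cv.extract_central_tendency(t, ["m2"], stat="mean").set_index("sample_id")
    assert mean.loc["s1", "ct@A@m2"] == pytest.approx(7.0 / 3)
    with pytest.raises(ParameterError):
        cv.extract_central_tendency(t, ["m1"], stat="mode")


def test_threshold_fraction_strictly_above():
    t = clustered_table(
        [("s1", "A", 0.1, 0.0), ("s1", "A", 0.9, 0.0), ("s1", "A", 1.5, 0.0)]
    )
    out = cv.extract_threshold(t, ["m1"], threshold=1.0).set_index("sample_id")
    assert out.loc["s1", "pos@A@m1"] == pytest.approx(1 / 3)
    zero = cv.extract_threshold(t, ["m1"], threshold=10.0).set_index("sample_id")
    assert zero.loc["s1", "pos@A@m1"] == 0.0


def test_default_positivity_threshold_value():
    assert cv.extract.DEFAULT_POS_THRESHOLD == pytest.approx(
        1.4436354751788103, abs=1e-12
    )  # asinh(2)


# -- distances -------------------------------------------------------------

def _transport_oracle(p, q, centers):
    """Brute-force optimal transport LP between binned distributions."""
    n = len(p)
    cost = np.abs(centers[:, None] - centers[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row sums = p
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # col sums = q
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.concatenate([p, q]),
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


@pytest.mark.parametrize("seed", range(5))
def test_emd_matches_transport_lp(seed):
    """Binned EMD equals a brute-force optimal-transport LP solution."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, 200)
    b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 200)
    bins = 20  # LP stays small; same binning path as production
    from cytoverbs.extract import _binned_pair

    p, q, spacing = _binned_pair(a, b, bins)
    lo = min(a.min(), b.min())
    centers = lo + spacing * np.arange(bins)
    assert cv.binned_emd(a, b, bins) == pytest.approx(
        _transport_oracle(p, q, centers), abs=1e-9
    )


def test_emd_point_masses_and_identity():
    assert cv.binned_emd(np.zeros(5), np.full(8, 3.0)) == pytest.approx(3.0, abs=0)
    x = np.random.default_rng(0).normal(size=100)
    assert cv.binned_emd(x, x) == 0.0
    assert cv.binned_jsd(x, x) == 0.0


def test_emd_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(7)
    for _ in range(5):
        a, b, c = (rng.normal(rng.uniform(-1, 1), 1, 150) for _ in range(3))
        # shared support: bin on the pooled range of all three
        lo = min(a.min(), b.min(), c.min())
        hi = max(a.max(), b.max(), c.max())
        anchor = np.array([lo, hi])
        ab = cv.binned_emd(np.r_[a, anchor], np.r_[b, anchor])
        ba = cv.binned_emd(np.r_[b, anchor], np.r_[a, anchor])
        ac = cv.binned_emd(np.r_[a, anchor], np.r_[c, anchor])
        cb = cv.binned_emd(np.r_[c, anchor], np.r_[b, anchor])
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab <= ac + cb + 1e-9


def test_jsd_bounded_by_ln2():
    a = np.zeros(50)
    b = np.full(50, 5.0)
    assert cv.binned_jsd(a, b) == pytest.approx(np.log(2), abs=1e-12)


def stim_table():
    rows = []
    rng = np.random.default_rng(3)
    for s in ("s1", "s2"):
        for cond, shift in (("basal", 0.0), ("stim", 2.0)):
            for _ in range(40):
                rows.append((s, "A", cond, rng.normal(shift, 0.3),
                             rng.normal(0, 0.3)))
    df = pd.DataFrame(rows, columns=["sample_id", ".cluster", "condition",
                                     "m1", "m2"])
    return cv.CytoTable(df, panel=cv.Panel.from_columns(["m1", "m2"]))


def test_extract_distance_stimulation_response():
    t = stim_table()
    out = cv.extract_distance(t, "condition", "basal").set_index("sample_id")
    assert out["emd@A@m1@stim"].between(1.5, 2.5).all()  # shift ~2
    assert (out["emd@A@m2@stim"] < 0.5).all()  # no shift
    jsd = cv.extract_distance(t, "condition", "basal", method="jsd")
    assert ((jsd.filter(like="jsd@") >= 0)
            & (jsd.filter(like="jsd@") <= np.log(2) + 1e-12)).all().all()


def test_extract_distance_missing_basal():
    t = stim_table()
    df = pd.DataFrame(t)
    df = df[~((df["sample_id"] == "s2") & (df["condition"] == "basal"))]
    t2 = cv.CytoTable(df.reset_index(drop=True), panel=t.panel)
    with pytest.raises(MissingReferenceError):
        cv.extract_distance(t2, "condition", "basal")


# -- combined --------------------------------------------------------------

def make_cohort_table(n_samples=8, n_clusters=10, n_markers=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = n_samples * 60
    df = pd.DataFrame(
        rng.normal(size=(rows, n_markers)),
        columns=[f"m{i}" for i in range(n_markers)],
    )
    df.insert(0, "sample_id", np.repeat([f"s{i}" for i in range(n_samples)], 60))
    df[".cluster"] = rng.choice([str(c + 1) for c in range(n_clusters)], rows)
    df["arm"] = np.repeat(["A", "B"], rows // 2)
    return cv.CytoTable(df, panel=cv.Panel.from_columns(
        [f"m{i}" for i in range(n_markers)]))


def test_extract_features_dimensional_formula():
    """8 samples, 10 clusters, 5 markers: abundance + ct(median) gives
    8 rows x (10 + 50) feature columns."""
    t = make_cohort_table()
    out = cv.extract_features(t, ["abundance", ("ct", {"stat": "median"})])
    assert len(out) == 8
    feats = [c for c in out.columns if c.startswith(("abundance@", "ct@"))]
    assert len(feats) == 60
    assert "arm" in out.columns  # sample-level metadata carried along


def test_extract_features_composition_identity():
    t = make_cohort_table()
    only = cv.extract_features(t, ["abundance"])
    direct = cv.extract_abundance(t)
    pd.testing.assert_frame_equal(
        only[direct.columns], direct, check_dtype=False
    )


def test_extract_features_dedup_and_empty():
    t = make_cohort_table()
    with pytest.warns(UserWarning, match="duplicate"):
        out = cv.extract_features(t, ["abundance", "abundance"])
    assert len([c for c in out.columns if c.startswith("abundance@")]) == 10
    with pytest.raises(ParameterError):
        cv.extract_features(t, [])


def test_features_invariant_to_cell_order():
    t = make_cohort_table()
    shuffled = cv.CytoTable(
        pd.DataFrame(t).sample(frac=1.0, random_state=1).reset_index(drop=True),
        panel=t.panel,
    )
    a = cv.extract_features(t, ["abundance", ("ct", {"stat": "median"})])
    b = cv.extract_features(shuffled, ["abundance", ("ct", {"stat": "median"})])
    a = a.set_index("sample_id").sort_index()
    b = b.set_index("sample_id").sort_index()
    pd.testing.assert_frame_equal(a, b[a.columns], check_dtype=False)
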