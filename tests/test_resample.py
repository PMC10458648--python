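"""Native SMOTE family: geometry, brute-force oracles, count contracts."""

import numpy as np
import pytest

from lodgetex.resample import (
    METHODS,
    ResamplePlan,
    apply_resample,
    enn_edit,
    smote,
    tomek_links,
)
from lodgetex.synth import FeatureTable


def _table(X, y, prov=None):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        feature_names=[f"f{i}" for i in range(X.shape[1])],
        X=X,
        y=np.asarray(y),
        provenance=np.asarray(prov) if prov is not None else np.full(len(y), "original"),
    )


# -- SMOTE core -------------------------------------------------------------

def test_smote_two_point_segment_geometry():
    t = _table([[0, 0], [1, 1], [9, 9]], ["SL", "SL", "NL"])
    out = smote(t, "SL", n_new=5, k=1, seed=0)
    new = out.X[out.provenance == "synthetic"]
    assert len(new) == 5
    # every synthetic point lies on the segment (0,0)-(1,1): coords equal, in [0,1]
    assert np.allclose(new[:, 0], new[:, 1])
    assert ((new >= 0) & (new <= 1)).all()
    assert (out.y[out.provenance == "synthetic"] == "SL").all()


def test_smote_zero_new_is_identity():
    t = _table([[0, 0], [1, 1]], ["SL", "SL"])
    assert smote(t, "SL", 0, seed=0) is t


def test_smote_singleton_class_errors_with_name():
    t = _table([[0, 0], [1, 1]], ["SL", "NL"])
    with pytest.raises(ValueError, match="SL"):
        smote(t, "SL", 3, seed=0)


def test_smote_synthetics_are_convex_combinations():
    """Solve for lambda per synthetic row: each must be x + lam (y - x) for
    two real minority rows with lam in [0, 1]."""
    rng = np.random.default_rng(5)
    Xmin = rng.normal(size=(8, 3))
    Xmaj = rng.normal(size=(20, 3)) + 6
    t = _table(np.vstack([Xmin, Xmaj]), ["SL"] * 8 + ["NL"] * 20)
    out = smote(t, "SL", 30, k=3, seed=1)
    for row in out.X[out.provenance == "synthetic"]:
        found = False
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                d = Xmin[j] - Xmin[i]
                num = row - Xmin[i]
                with np.errstate(divide="ignore", invalid="ignore"):
                    lams = num / d
                lam = lams[np.isfinite(lams)]
                if len(lam) and np.allclose(lam, lam[0], atol=1e-9):
                    if -1e-12 <= lam[0] <= 1 + 1e-12 and np.allclose(
                        row, Xmin[i] + lam[0] * d, atol=1e-9
                    ):
                        found = True
        assert found


# -- Tomek links ------------------------------------------------------------

def test_tomek_link_1d_example():
    t = _table([[0.0], [0.4], [5.0], [6.0]], ["SL", "NL", "NL", "NL"])
    assert tomek_links(t) == [(0, 1)]


def test_tomek_no_links_for_separated_classes():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(10, 0.1, (10, 2))])
    t = _table(X, ["NL"] * 10 + ["SL"] * 10)
    assert tomek_links(t) == []


def test_tomek_duplicate_point_tie_break():
    """A point duplicated in both classes: ties go to the lowest index and
    the link is reported once."""
    t = _table([[1.0], [1.0], [5.0], [9.0]], ["NL", "SL", "NL", "NL"])
    links = tomek_links(t)
    assert links == [(0, 1)]


def test_tomek_matches_brute_force_enumeration():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(16, 2))
    y = np.array(["NL"] * 10 + ["SL"] * 6)
    t = _table(X, y)
    # brute force: mutual nearest neighbours with opposite labels
    d = ((X[:, None] - X[None, :]) ** 2).sum(-1)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    expected = sorted(
        (a, int(nn[a]))
        for a in range(16)
        if int(nn[int(nn[a])]) == a and y[a] != y[nn[a]] and a < nn[a]
    )
    assert tomek_links(t) == expected


# -- ENN --------------------------------------------------------------------

def test_enn_marks_isolated_wrong_class_point():
    X = np.vstack([[0.0, 0.0], np.random.default_rng(0).normal(0, 0.3, (10, 2))])
    t = _table(X, ["SL"] + ["NL"] * 10)
    assert 0 in enn_edit(t, k=3)


def test_enn_pure_single_class_marks_nothing():
    t = _table(np.arange(10)[:, None], ["NL"] * 10)
    assert len(enn_edit(t, k=3)) == 0


def test_enn_matches_exhaustive_vote_oracle():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(12, 2))
    y = np.array(["NL"] * 5 + ["ML"] * 4 + ["SL"] * 3)
    t = _table(X, y)
    k = 3
    d = ((X[:, None] - X[None, :]) ** 2).sum(-1)
    np.fill_diagonal(d, np.inf)
    expected = []
    for i in range(12):
        nn = np.argsort(d[i], kind="stable")[:k]
        labels, counts = np.unique(y[nn], return_counts=True)
        winners = labels[counts == counts.max()]
        if len(winners) == 1 and winners[0] != y[i]:
            expected.append(i)
    assert list(enn_edit(t, k=k)) == expected


def test_enn_vote_tie_keeps_sample():
    # k=2, neighbours vote NL/ML 1-1: no clear disagreement, sample kept
    t = _table([[0.1], [0.15], [0.2]], ["NL", "SL", "ML"])
    assert 1 not in enn_edit(t, k=2)


# -- composite plans --------------------------------------------------------

@pytest.fixture(scope="module")
def imbalanced_table():
    from lodgetex import synth

    means, covs = synth.gaussian_table_spec(12, separation=2.0)
    return synth.generate_feature_table(
        {"NL": 964, "ML": 206, "HL": 85, "SL": 11}, means, covs, seed=1
    )


def test_equalizing_plans_balance_counts(imbalanced_table):
    """SMOTE-Tomek / Borderline / SMOTE-NC equalize all classes to the
    majority count (SMOTE-Tomek then removes majority link members)."""
    for method in ("borderline_smote", "smote_nc"):
        out = apply_resample(imbalanced_table, ResamplePlan(method, seed=1))
        assert set(out.class_counts().values()) == {964}, method
    out = apply_resample(imbalanced_table, ResamplePlan("smote_tomek", seed=1))
    counts = out.class_counts()
    assert counts["ML"] == counts["HL"] == counts["SL"] == 964
    assert counts["NL"] <= 964  # only majority members of links removed


def test_adasyn_approximately_equalizes(imbalanced_table):
    out = apply_resample(imbalanced_table, ResamplePlan("adasyn", seed=1))
    counts = out.class_counts()
    for c, v in counts.items():
        assert abs(v - 964) <= 0.02 * 964, counts


def test_smote_enn_does_not_equalize_and_reduces_majority(imbalanced_table):
    out = apply_resample(imbalanced_table, ResamplePlan("smote_enn", seed=1))
    counts = out.class_counts()
    assert len(set(counts.values())) > 1
    assert counts["NL"] < 964


def test_synthetics_in_class_convex_hull(imbalanced_table):
    """Interpolated points stay within the bounding box (hence hull-side
    bounds per coordinate) of their class's real points."""
    out = apply_resample(imbalanced_table, ResamplePlan("borderline_smote", seed=1))
    for cls in ("ML", "HL", "SL"):
        real = imbalanced_table.X[imbalanced_table.y == cls]
        syn = out.X[(out.y == cls) & (out.provenance == "synthetic")]
        assert (syn >= real.min(axis=0) - 1e-9).all()
        assert (syn <= real.max(axis=0) + 1e-9).all()


def test_smote_nc_reduces_to_smote_without_nominals(gaussian_table):
    t = gaussian_table()
    a = apply_resample(t, ResamplePlan("smote_nc", seed=3))
    b = apply_resample(t, ResamplePlan("smote_tomek", seed=3))
    # same seed, same neighbour structure: smote_nc equals the SMOTE stage
    # of smote_tomek before link removal on this well-separated table
    assert a.n >= b.n
    syn_a = a.X[a.provenance == "synthetic"]
    syn_b = b.X[b.provenance == "synthetic"]
    assert np.allclose(syn_a, syn_b)


def test_smote_nc_nominal_columns_take_neighbour_mode():
    rng = np.random.default_rng(0)
    X = np.hstack([rng.normal(size=(10, 2)), np.ones((10, 1))])
    X[:5, 2] = 0.0
    t = _table(np.vstack([X, rng.normal(5, 1, (30, 2)) @ np.eye(2, 3) + [0, 0, 1]]),
               ["SL"] * 10 + ["NL"] * 30)
    out = apply_resample(t, ResamplePlan("smote_nc", seed=0, nominal_columns=(2,)))
    syn = out.X[(out.provenance == "synthetic") & (out.y == "SL")]
    assert np.isin(syn[:, 2], (0.0, 1.0)).all()  # nominal stays categorical


def test_unknown_method_rejected(gaussian_table):
    with pytest.raises(ValueError):
        ResamplePlan("oversample_everything")


def test_provenance_flags_preserved(imbalanced_table):
    out = apply_resample(imbalanced_table, ResamplePlan("adasyn", seed=1))
    n_orig = (out.provenance == "original").sum()
    assert n_orig == imbalanced_table.n  # originals never dropped by ADASYN
    assert set(np.unique(out.provenance)) == {"original", "synthetic"}
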