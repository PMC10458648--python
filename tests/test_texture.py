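"""GLCM construction and the 14 Haralick features against independent oracles."""

from fractions import Fraction

import numpy as np
import pytest

from lodgetex import texture
from lodgetex.texture import (
    FEATURE_NAMES,
    DegenerateGLCMError,
    GLCMatrix,
    GLCMParams,
    average_glcms,
    compute_glcm,
    extract_plot_features,
    haralick_features,
    quantize,
)

TOY = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [0, 2, 2, 2], [2, 2, 3, 3]])


def naive_haralick(P: np.ndarray) -> dict[str, float]:
    """Independent triple-loop implementation of the 14 statistics straight
    from their defining sums (base-2 logs, 0 log 0 = 0, 0-based levels)."""
    ng = P.shape[0]
    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i][j] for i in range(ng)) for j in range(ng)]
    psum = [0.0] * (2 * ng - 1)
    pdiff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            psum[i + j] += P[i][j]
            pdiff[abs(i - j)] += P[i][j]

    def log2(x):
        return np.log2(x)

    asm = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
    contrast = sum(k * k * pdiff[k] for k in range(ng))
    mux = sum(i * px[i] for i in range(ng))
    muy = sum(j * py[j] for j in range(ng))
    sx = np.sqrt(sum((i - mux) ** 2 * px[i] for i in range(ng)))
    sy = np.sqrt(sum((j - muy) ** 2 * py[j] for j in range(ng)))
    corr = (
        (sum(i * j * P[i][j] for i in range(ng) for j in range(ng)) - mux * muy)
        / (sx * sy)
        if sx * sy > 0
        else 0.0
    )
    variance = sum((i - mux) ** 2 * P[i][j] for i in range(ng) for j in range(ng))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    sum_avg = sum(k * psum[k] for k in range(2 * ng - 1))
    sum_ent = -sum(p * log2(p) for p in psum if p > 0)
    sum_var = sum((k - sum_ent) ** 2 * psum[k] for k in range(2 * ng - 1))
    entropy = -sum(
        P[i][j] * log2(P[i][j]) for i in range(ng) for j in range(ng) if P[i][j] > 0
    )
    dmean = sum(k * pdiff[k] for k in range(ng))
    dvar = sum(k * k * pdiff[k] for k in range(ng)) - dmean**2
    dent = -sum(p * log2(p) for p in pdiff if p > 0)
    hx = -sum(p * log2(p) for p in px if p > 0)
    hy = -sum(p * log2(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i][j] * log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    info1 = (entropy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    info2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - entropy))))
    keep = [i for i in range(ng) if px[i] > 0 and py[i] > 0]
    Q = np.zeros((len(keep), len(keep)))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            Q[a, b] = sum(
                P[i][k] * P[j][k] / (px[i] * py[k]) for k in keep if py[k] > 0
            )
    if len(keep) < 2:
        mcc = 0.0
    else:
        eig = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        mcc = np.sqrt(min(max(eig[1], 0.0), 1.0))
    return dict(
        zip(
            FEATURE_NAMES,
            (asm, contrast, corr, variance, idm, sum_avg, sum_var, sum_ent,
             entropy, dvar, dent, info1, info2, mcc),
        )
    )


@pytest.mark.parametrize(
    "value,levels,expected", [(255, 8, 7), (0, 4, 0), (128, 8, 4), (15, 16, 0), (16, 16, 1)]
)
def test_quantize_equal_width(value, levels, expected):
    assert quantize(np.array([[value]], dtype=np.uint8), levels)[0, 0] == expected


def test_quantize_rejects_bad_levels():
    with pytest.raises(ValueError):
        quantize(np.zeros((2, 2), np.uint8), 7)


def test_toy_glcm_hand_enumeration():
    """12 horizontal adjacent pairs, doubled by symmetry -> 24 ordered counts."""
    g = compute_glcm(TOY, distance=1, angle=0, symmetric=True)
    assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
    counts = g.P * 24
    assert counts[0, 0] == pytest.approx(4)
    assert counts[2, 2] == pytest.approx(6)
    assert counts[0, 1] == pytest.approx(2)
    assert counts[1, 0] == pytest.approx(2)
    assert np.array_equal(g.P, g.P.T)


def test_toy_features_exact_fractions():
    """ASM and contrast of the toy GLCM in exact rational arithmetic."""
    g = compute_glcm(TOY, distance=1, angle=0)
    fv = haralick_features(g)
    counts = np.rint(g.P * 24).astype(int)
    asm_exact = sum(Fraction(int(c), 24) ** 2 for c in counts.ravel())
    assert asm_exact == Fraction(84, 576)
    assert fv["angular_second_moment"] == pytest.approx(float(asm_exact), abs=1e-12)
    contrast_exact = sum(
        Fraction(int(counts[i, j]), 24) * (i - j) ** 2
        for i in range(4)
        for j in range(4)
    )
    assert contrast_exact == Fraction(14, 24)
    assert fv["contrast"] == pytest.approx(float(contrast_exact), abs=1e-12)


def test_constant_image_degeneracies():
    """Single-cell mass: ASM=1, contrast=0, entropy=0, IDM=1, correlation
    flagged degenerate and reported as 0."""
    img = np.full((8, 8), 3, dtype=np.uint8)
    g = compute_glcm(img, angle=0, levels=4)
    assert g.P.sum() == pytest.approx(1.0)
    fv = haralick_features(g)
    assert fv["angular_second_moment"] == pytest.approx(1.0)
    assert fv["contrast"] == pytest.approx(0.0)
    assert fv["entropy"] == pytest.approx(0.0)
    assert fv["inverse_difference_moment"] == pytest.approx(1.0)
    assert fv["correlation"] == 0.0
    assert fv.degenerate


def test_masked_glcm_counts_only_inside_pairs():
    mask = np.ones_like(TOY, dtype=bool)
    mask[:, 2:] = False  # keep two left columns only
    g = compute_glcm(TOY, mask=mask, distance=1, angle=0)
    # remaining horizontal pairs: rows 0,1 give (0,0); rows 2,3 give (0,2),(2,2)
    total = 8  # 4 unordered pairs doubled by symmetry
    assert g.P[0, 0] == pytest.approx(4 / total)
    assert g.P[0, 2] == pytest.approx(1 / total)
    assert g.P[2, 2] == pytest.approx(2 / total)


def test_degenerate_glcm_raises():
    mask = np.zeros((4, 4), bool)
    mask[:, 0] = True  # no horizontal pair has both pixels inside
    with pytest.raises(DegenerateGLCMError):
        compute_glcm(TOY, mask=mask, distance=1, angle=0)


def test_average_glcms_identity_and_linearity():
    g = compute_glcm(TOY, angle=0)
    assert np.allclose(average_glcms([g]).P, g.P)
    assert np.allclose(average_glcms([g, g]).P, g.P)
    a = GLCMatrix(np.array([[1.0, 0], [0, 0]]), levels=4 // 2)  # 2 levels
    b = GLCMatrix(np.array([[0, 0], [0, 1.0]]), levels=2)
    avg = average_glcms([a, b])
    assert avg.P[0, 0] == pytest.approx(0.5)
    assert avg.P[1, 1] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        average_glcms([g, a])


def test_haralick_matches_naive_oracle():
    """All 14 features equal an independent triple-loop oracle to 1e-10 on
    random masked images."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        mask = rng.random((24, 24)) > 0.2
        q = quantize(img, 8)
        g = average_glcms(
            [compute_glcm(q, mask=mask, angle=a, levels=8) for a in (0, 45, 90, 135)]
        )
        fv = haralick_features(g)
        expected = naive_haralick(g.P)
        for name in FEATURE_NAMES:
            assert fv[name] == pytest.approx(expected[name], abs=1e-10), name


def test_haralick_matches_skimage_on_shared_subset():
    """ASM, contrast, correlation and IDM (homogeneity) agree with the
    scikit-image reference on unmasked images to 1e-6."""
    from skimage.feature import graycomatrix, graycoprops

    rng = np.random.default_rng(7)
    img = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
    q = quantize(img, 16)
    g = compute_glcm(q, angle=0, levels=16)
    sk = graycomatrix(q, [1], [0], levels=16, symmetric=True, normed=True)
    assert np.allclose(g.P, sk[:, :, 0, 0], atol=1e-12)
    assert haralick_features(g)["angular_second_moment"] == pytest.approx(
        graycoprops(sk, "ASM")[0, 0], abs=1e-6
    )
    assert haralick_features(g)["contrast"] == pytest.approx(
        graycoprops(sk, "contrast")[0, 0], abs=1e-6
    )
    assert haralick_features(g)["correlation"] == pytest.approx(
        graycoprops(sk, "correlation")[0, 0], abs=1e-6
    )
    assert haralick_features(g)["inverse_difference_moment"] == pytest.approx(
        graycoprops(sk, "homogeneity")[0, 0], abs=1e-6
    )


def test_glcm_invariants_random_images():
    """Normalization, symmetry, marginal sums; ASM <= 1; contrast = 0 iff
    all mass on the diagonal."""
    rng = np.random.default_rng(3)
    for _ in range(10):
        img = rng.integers(0, 4, size=(10, 10)).astype(np.uint8) * 64
        q = quantize(img, 4)
        g = compute_glcm(q, angle=rng.choice([0, 45, 90, 135]))
        assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(g.P, g.P.T)
        assert g.px.sum() == pytest.approx(1.0, abs=1e-12)
        assert g.p_sum.sum() == pytest.approx(1.0, abs=1e-12)
        assert g.p_diff.sum() == pytest.approx(1.0, abs=1e-12)
        fv = haralick_features(g)
        assert 0 < fv["angular_second_moment"] <= 1
        assert fv["contrast"] >= 0
        off_diag = g.P.sum() - np.trace(g.P)
        assert (fv["contrast"] == 0) == (off_diag == pytest.approx(0.0, abs=1e-15))
        assert -1 <= fv["correlation"] <= 1 + 1e-12
        assert 0 <= fv["info_measure_II"] <= 1
        assert 0 <= fv["max_correlation_coefficient"] <= 1


def test_feature_vector_invariant_to_transposition():
    """Transposing the image while averaging {0,90} and {45,135} leaves the
    averaged-GLCM features unchanged."""
    rng = np.random.default_rng(11)
    img = rng.integers(0, 256, size=(20, 28)).astype(np.uint8)
    q = quantize(img, 8)
    qT = q.T
    def feats(im):
        g = average_glcms(
            [compute_glcm(im, angle=a, levels=8) for a in (0, 45, 90, 135)]
        )
        return haralick_features(g).as_array()
    assert np.allclose(feats(q), feats(qT), atol=1e-10)


def test_extract_plot_features_shapes_and_skip():
    from lodgetex.texture import extract_feature_table

    rng = np.random.default_rng(0)
    roi = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    empty = np.zeros((32, 32), bool)
    table = extract_feature_table(
        [("a", roi, None, "NL"), ("b", roi, empty, "SL"), ("c", roi, None, "ML")]
    )
    assert table.n == 2  # plot "b" skipped: degenerate GLCM
    assert table.m == 14
    assert list(table.ids) == ["a", "c"]
    fv = extract_plot_features(roi, params=GLCMParams())
    assert fv.as_array().shape == (14,)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    a=st.integers(0, 255),
    b=st.integers(0, 255),
    ng=st.sampled_from([4, 8, 16, 32, 64]),
)
def test_quantize_bounded_and_monotone(a, b, ng):
    qa = int(quantize(np.array([[a]], np.uint8), ng)[0, 0])
    qb = int(quantize(np.array([[b]], np.uint8), ng)[0, 0])
    assert 0 <= qa < ng
    if a <= b:
        assert qa <= qb
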