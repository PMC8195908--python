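import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from resit import (
    EEGRecording,
    NeighborInterpolator,
    ResitInterpolator,
    SphericalSplineInterpolator,
    ni_interpolate,
    rereference,
    resit_interpolate,
    rest_standardize,
    spline_g,
    ssi_build,
    ssi_interpolate,
)


def avg_rec(montage, t=40, seed=0, bads=()):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((montage.n_channels, t))
    data -= data.mean(axis=0)
    rec = EEGRecording(data, list(montage.labels), 500.0, "average")
    return rec.mark_bad(bads) if bads else rec


# ---------------------------------------------------------------------------
# rereference


def test_rereference_average_zero_means(montage62):
    rec = avg_rec(montage62, seed=1).copy(data=np.random.default_rng(1).standard_normal((62, 10)),
                                          reference="average")
    out = rereference(rec, "average")
    assert np.abs(out.data.mean(axis=0)).max() < 1e-12
    assert out.reference == "average"


def test_rereference_point(montage62):
    rec = avg_rec(montage62, seed=2)
    out = rereference(rec, "point:Cz")
    i = out.index("Cz")
    assert np.all(out.data[i] == 0.0)
    j = out.index("Oz")
    assert np.allclose(out.data[j], rec.data[j] - rec.data[rec.index("Cz")])


def test_rereference_average_uses_good_channels_only(montage62):
    rec = avg_rec(montage62, seed=3, bads=["Cz", "Pz"])
    out = rereference(rec, "average")
    good = ~out.bad_mask
    assert np.abs(out.data[good].mean(axis=0)).max() < 1e-12


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1), st.floats(0.1, 1000.0))
def test_rereference_average_idempotent_and_scale_free(seed, scale):
    rng = np.random.default_rng(seed)
    data = scale * rng.standard_normal((6, 9))
    rec = EEGRecording(data, list("abcdef"), 100.0, "average")
    once = rereference(rec, "average")
    twice = rereference(once, "average")
    assert np.allclose(once.data, twice.data, atol=1e-12 * scale)
    assert np.abs(once.data.mean(axis=0)).max() <= 1e-12 * scale


def test_rereference_errors(montage62):
    rec = avg_rec(montage62, bads=["Cz"])
    with pytest.raises(ValueError, match="marked bad"):
        rereference(rec, "point:Cz")
    with pytest.raises(ValueError, match="not in recording"):
        rereference(rec, "point:nope")
    with pytest.raises(ValueError, match="target"):
        rereference(rec, "infinity")


# ---------------------------------------------------------------------------
# neighbor interpolation


def test_ni_matches_brute_force(montage62):
    bads = ["Cz", "T7", "Fp1", "PO8"]
    rec = avg_rec(montage62, seed=4, bads=bads)
    out = ni_interpolate(rec, montage62)
    ang = montage62.angular_distances()
    good = np.flatnonzero(~rec.bad_mask)
    for b in bads:
        bi = montage62.index(b)
        order = sorted(good, key=lambda i: (ang[bi, i], montage62.labels[i]))[:4]
        expect = rec.data[order].mean(axis=0)
        assert np.allclose(out.data[bi], expect, rtol=1e-12)
    # good channels untouched, bad mask cleared
    assert np.array_equal(out.data[good], rec.data[good])
    assert out.n_bad == 0


def test_ni_weights_structure(montage62):
    est = NeighborInterpolator(montage=montage62, bad_channels=["Cz"], n_neighbors=4).fit()
    W = est.weights_
    bi = montage62.index("Cz")
    assert np.isclose(W[bi].sum(), 1.0)
    assert np.count_nonzero(W[bi]) == 4
    assert np.allclose(W[bi][W[bi] != 0], 0.25)
    others = np.delete(np.arange(62), bi)
    assert np.array_equal(W[others][:, others], np.eye(61))


def test_ni_too_few_good_channels(montage62):
    bad = list(montage62.labels[:59])
    with pytest.raises(ValueError, match="good channels"):
        NeighborInterpolator(montage=montage62, bad_channels=bad, n_neighbors=4).fit()


# ---------------------------------------------------------------------------
# spherical splines


def test_spline_g_at_one_matches_series_sum():
    n = np.arange(1, 51, dtype=float)
    expect = np.sum((2 * n + 1) / (n * (n + 1)) ** 4) / (4 * np.pi)
    assert spline_g(1.0) == pytest.approx(expect, rel=1e-12)


def test_spline_g_hand_sum_at_zero():
    # 7 terms, P_n(0) = 0 for odd n; P_2(0) = -1/2, P_4(0) = 3/8, P_6(0) = -5/16
    expect = (
        (5 / 6**4) * (-0.5) + (9 / 20**4) * (3 / 8) + (13 / 42**4) * (-5 / 16)
    ) / (4 * np.pi)
    assert spline_g(0.0, order_m=4, n_legendre=7) == pytest.approx(expect, rel=1e-12)


def test_ssi_recovers_spline_generated_data(montage62):
    rng = np.random.default_rng(11)
    bads = ["C3", "Fpz", "P8", "TP9", "AF4"]
    bad_mask = np.array([l in bads for l in montage62.labels])
    good = np.flatnonzero(~bad_mask)
    # generate data lying exactly in the spline model span over the good sites
    C = rng.standard_normal((len(good), 8))
    C -= C.mean(axis=0)
    c0 = rng.standard_normal(8)
    cosang = np.clip(montage62.positions @ montage62.positions[good].T, -1, 1)
    V = spline_g(cosang) @ C + c0  # (62, 8)
    rec = EEGRecording(V, list(montage62.labels), 500.0, "average",
                       bad_mask=bad_mask)
    out = ssi_interpolate(rec, montage62)
    for b in bads:
        i = montage62.index(b)
        err = np.abs(out.data[i] - V[i]).max() / np.abs(V[i]).max()
        assert err < 1e-6


def test_ssi_coefficients_zero_sum(montage62):
    est = SphericalSplineInterpolator(montage=montage62, bad_channels=["Cz", "P3"]).fit()
    rng = np.random.default_rng(5)
    Vg = rng.standard_normal((len(est.good_idx_), 7))
    C, c0 = est.solve_coefficients(Vg)
    assert np.abs(C.sum(axis=0)).max() < 1e-8
    # the spline reproduces the good-channel data exactly
    recon = est.spline_system_.g_good @ C + c0
    assert np.allclose(recon, Vg, atol=1e-8)


def test_ssi_good_channels_unchanged(montage62):
    rec = avg_rec(montage62, seed=6, bads=["Fz", "Oz"])
    out = ssi_interpolate(rec, montage62)
    good = ~rec.bad_mask
    assert np.array_equal(out.data[good], rec.data[good])


def test_ssi_coincident_electrodes_rejected():
    from resit import ElectrodeMontage

    pos = np.array([[0, 0, 1.0], [0, 0, 1.0 - 1e-15], [1.0, 0, 0], [0, 1.0, 0]])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    m = ElectrodeMontage(["a", "b", "c", "d"], pos)
    with pytest.raises(ValueError, match="coincident"):
        SphericalSplineInterpolator(montage=m, bad_channels=None).fit()


def test_ssi_build_accepts_mask_or_labels(montage62):
    mask = np.zeros(62, dtype=bool)
    mask[montage62.index("Cz")] = True
    s1 = ssi_build(montage62, ["Cz"])
    s2 = ssi_build(montage62, mask)
    assert np.array_equal(s1.g_bad, s2.g_bad)
    assert s1.bad_labels == s2.bad_labels == ["Cz"]


# ---------------------------------------------------------------------------
# RESIT


def test_resit_zero_in_zero_out(montage62, leadfield):
    rec = EEGRecording(np.zeros((62, 9)), list(montage62.labels), 500.0, "average",
                       bad_mask=np.arange(62) < 3)
    out = resit_interpolate(rec, leadfield)
    assert np.all(out.data == 0.0)
    assert out.reference == "infinity"
    assert out.n_bad == 0


def test_resit_rest_equivalence_k0(montage62, leadfield):
    rec = avg_rec(montage62, seed=7)
    a = resit_interpolate(rec, leadfield)
    b = rest_standardize(rec, leadfield)
    assert np.array_equal(a.data, b.data)


def test_rest_requires_clean_recording(montage62, leadfield):
    rec = avg_rec(montage62, seed=7, bads=["Cz"])
    with pytest.raises(ValueError, match="no bad channels"):
        rest_standardize(rec, leadfield)


def test_resit_k0_avg_projection_consistency(montage62, leadfield):
    rec = avg_rec(montage62, seed=8)
    out = rereference(resit_interpolate(rec, leadfield), "average")
    assert np.abs(out.data.mean(axis=0)).max() < 1e-12


def test_resit_point_reference_input(montage62, leadfield):
    rec = avg_rec(montage62, seed=9, bads=["T7"])
    recp = rereference(rec, "point:Cz")
    out = resit_interpolate(recp, leadfield)
    # reconstructing from the point-referenced data must agree with the
    # average-referenced path: both estimate the same infinity-referenced
    # potentials from the same observable (reference-invariant) signal
    out_avg = resit_interpolate(rec, leadfield)
    assert np.allclose(out.data, out_avg.data, rtol=1e-6, atol=1e-9)


def test_resit_transform_accepts_good_only_columns(montage62, leadfield):
    rec = avg_rec(montage62, seed=10, bads=["Cz", "Pz"])
    est = ResitInterpolator(leadfield=leadfield, bad_channels=["Cz", "Pz"]).fit()
    full = est.transform(rec.data.T)
    good_only = est.transform(rec.data[~rec.bad_mask].T)
    assert np.array_equal(full, good_only)
    with pytest.raises(ValueError, match="channels, expected"):
        est.transform(rec.data[:10].T)


def test_resit_sources_forward_consistency(montage62, leadfield):
    rec = avg_rec(montage62, seed=12, bads=["Cz"])
    est = ResitInterpolator(leadfield=leadfield, bad_channels=["Cz"]).fit()
    S = est.estimate_sources(rec.data.T)
    V = est.transform(rec.data.T).T
    assert np.allclose(V, leadfield.matrix @ S, rtol=1e-9, atol=1e-12)


def test_resit_error_cases(montage62, leadfield):
    with pytest.raises(ValueError, match="all channels are bad"):
        ResitInterpolator(leadfield=leadfield, bad_channels=list(montage62.labels)).fit()
    with pytest.raises(ValueError, match="N-1"):
        ResitInterpolator(
            leadfield=leadfield, bad_channels=list(montage62.labels[1:])
        ).fit()
    rec_inf = EEGRecording(np.zeros((62, 4)), list(montage62.labels), 500.0, "infinity")
    with pytest.raises(ValueError, match="declare"):
        resit_interpolate(rec_inf, leadfield)
    rec = avg_rec(montage62, seed=1)
    with pytest.raises(ValueError, match="match the recording"):
        resit_interpolate(rec.copy(labels=[l + "_x" for l in rec.labels]), leadfield)
    with pytest.raises(ValueError, match="point reference"):
        ResitInterpolator(leadfield=leadfield, bad_channels=["Cz"],
                          input_reference="point:Cz").fit()


def test_resit_rank_logged(leadfield):
    est = ResitInterpolator(leadfield=leadfield, bad_channels=["Cz", "T8"]).fit()
    # average reference removes exactly one degree of freedom
    assert est.rank_ == 62 - 2 - 1


# ---------------------------------------------------------------------------
# shared properties


@pytest.mark.parametrize("method", ["ni", "ssi", "resit"])
def test_interpolators_are_linear(method, montage62, leadfield):
    bads = ["Cz", "F3", "PO8"]
    rng = np.random.default_rng(13)
    X = rng.standard_normal((62, 15))
    Y = rng.standard_normal((62, 15))
    X -= X.mean(axis=0)
    Y -= Y.mean(axis=0)
    a, b = 2.5, -1.25

    def run(data):
        rec = EEGRecording(data, list(montage62.labels), 500.0, "average",
                           bad_mask=np.array([l in bads for l in montage62.labels]))
        if method == "ni":
            return ni_interpolate(rec, montage62).data
        if method == "ssi":
            return ssi_interpolate(rec, montage62).data
        return resit_interpolate(rec, leadfield).data

    lhs = run(a * X + b * Y)
    rhs = a * run(X) + b * run(Y)
    scale = np.abs(rhs).max()
    assert np.abs(lhs - rhs).max() <= 1e-9 * scale


@pytest.mark.parametrize(
    "factory",
    [
        lambda m, lf: NeighborInterpolator(montage=m, bad_channels=["Cz"], n_neighbors=5),
        lambda m, lf: SphericalSplineInterpolator(montage=m, bad_channels=["Cz"], order=3),
        lambda m, lf: ResitInterpolator(leadfield=lf, bad_channels=["Cz"], pinv_rtol=1e-6),
    ],
)
def test_sklearn_estimator_api(factory, montage62, leadfield):
    est = factory(montage62, leadfield)
    params = est.get_params()
    assert "bad_channels" in params
    cloned = clone(est)
    assert cloned.get_params().keys() == params.keys()
    est.set_params(bad_channels=["Pz"])
    assert est.get_params()["bad_channels"] == ["Pz"]
    fitted = factory(montage62, leadfield).fit()
    assert hasattr(fitted, "n_features_in_")
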