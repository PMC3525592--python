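import numpy as np
import pytest

from tractkit.grid import VolumeGrid
from tractkit.gradients import GradientScheme
from tractkit import recon
from tractkit.phantom import default_scheme, make_phantom, straight_bundle_spec
from tractkit.recon import (
    InsufficientSchemeError,
    OdfField,
    eap_p0,
    extract_maxima,
    fa_from_eigenvalues,
    fit_tensor,
    odf_descriptors,
    tensor_scalars,
    tensor_to_odf,
)
from tractkit.sphere import make_sphere


def forward_dwi(tensors, scheme, s0=1000.0):
    """Noiseless single-tensor forward model on a flat voxel list."""
    tensors = np.asarray(tensors)
    n = len(tensors)
    sig = np.empty((n, scheme.n_volumes))
    for i, D in enumerate(tensors):
        att = np.exp(-scheme.bvals * np.einsum("ij,jk,ik->i", scheme.bvecs, D, scheme.bvecs))
        sig[i] = s0 * att
    side = int(np.ceil(n ** (1 / 3)))
    vol = np.full((side, side, side, scheme.n_volumes), s0)
    flat = vol.reshape(-1, scheme.n_volumes)
    flat[:n] = sig
    dwi = VolumeGrid(flat.reshape(side, side, side, -1), np.eye(4))
    mask = np.zeros((side, side, side), bool)
    mask.reshape(-1)[:n] = True
    return dwi, VolumeGrid(mask.astype(np.uint8), np.eye(4))


def random_spd_tensors(n, rng):
    """Random positive-definite diffusion tensors with physiological scale."""
    evals = rng.uniform(0.1e-3, 2.5e-3, size=(n, 3))
    out = np.empty((n, 3, 3))
    for i in range(n):
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        out[i] = q @ np.diag(evals[i]) @ q.T
    return out


class TestFitTensor:
    def test_recovers_known_diagonal_tensor(self, scheme30):
        D = np.diag([1.7e-3, 0.3e-3, 0.2e-3])
        dwi, mask = forward_dwi([D], scheme30)
        tf = fit_tensor(dwi, scheme30, mask)
        got = tf.tensors()[0, 0, 0]
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_isotropic_tensor_eigenvalues(self, scheme30):
        d = 0.9e-3
        dwi, mask = forward_dwi([d * np.eye(3)], scheme30)
        tf = fit_tensor(dwi, scheme30, mask)
        evals, _ = tf.eigensystem()
        np.testing.assert_allclose(evals[0, 0, 0], [d, d, d], atol=1e-9)

    def test_forward_model_inversion_on_random_tensors(self, scheme30):
        """Noiseless fit inverts the forward model to <= 1e-9 per coefficient."""
        rng = np.random.default_rng(42)
        tensors = random_spd_tensors(64, rng)
        dwi, mask = forward_dwi(tensors, scheme30)
        tf = fit_tensor(dwi, scheme30, mask)
        got = tf.tensors().reshape(-1, 3, 3)[: len(tensors)]
        assert np.abs(got - tensors).max() <= 1e-9

    def test_five_directions_insufficient(self):
        scheme = GradientScheme(
            [0] + [1000] * 5,
            np.vstack([np.zeros(3), np.eye(3), [[1, 1, 0], [0, 1, 1]]]),
        )
        dwi, mask = forward_dwi([np.eye(3) * 1e-3], scheme)
        with pytest.raises(InsufficientSchemeError):
            fit_tensor(dwi, scheme, mask)

    def test_rank_deficient_directions_insufficient(self):
        # 6 in-plane directions cannot constrain the z components
        ang = np.linspace(0, np.pi, 6, endpoint=False)
        vecs = np.vstack([np.zeros(3), np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])])
        scheme = GradientScheme([0] + [1000] * 6, vecs)
        dwi, mask = forward_dwi([np.eye(3) * 1e-3], scheme)
        with pytest.raises(InsufficientSchemeError):
            fit_tensor(dwi, scheme, mask)

    def test_empty_mask_rejected(self, scheme30):
        dwi, mask = forward_dwi([np.eye(3) * 1e-3], scheme30)
        empty = VolumeGrid(np.zeros_like(mask.data), mask.affine)
        with pytest.raises(ValueError, match="empty"):
            fit_tensor(dwi, scheme30, empty)

    def test_nonpositive_signal_marks_voxel_invalid(self, scheme30):
        dwi, mask = forward_dwi([np.eye(3) * 1e-3, np.eye(3) * 1e-3], scheme30)
        dwi.data[0, 0, 1, 5] = 0.0
        tf = fit_tensor(dwi, scheme30, mask)
        assert tf.valid[0, 0, 0]
        assert not tf.valid.reshape(-1)[1]


class TestTensorScalars:
    @pytest.mark.parametrize(
        "evals,fa,adc",
        [
            ((1e-3, 1e-3, 1e-3), 0.0, 1e-3),
            ((1.0, 0.0, 0.0), 1.0, 1 / 3),
            ((1.7e-3, 0.3e-3, 0.2e-3), 0.8359, 7.333e-4),
        ],
        ids=["isotropic", "stick", "prolate"],
    )
    def test_closed_forms(self, evals, fa, adc):
        assert abs(fa_from_eigenvalues(*evals) - fa) < 1e-4
        assert abs(np.mean(evals) - adc) < 1e-7

    def test_maps_match_eigenvalue_formula(self, scheme30):
        rng = np.random.default_rng(3)
        tensors = random_spd_tensors(20, rng)
        dwi, mask = forward_dwi(tensors, scheme30)
        tf = fit_tensor(dwi, scheme30, mask)
        maps = tensor_scalars(tf)
        fa = maps["FA"].data.reshape(-1)[:20]
        adc = maps["ADC"].data.reshape(-1)[:20]
        for i, D in enumerate(tensors):
            ev = np.sort(np.linalg.eigvalsh(D))[::-1]
            assert abs(fa[i] - fa_from_eigenvalues(*ev)) < 1e-6
            assert abs(adc[i] - ev.mean()) < 1e-9
        assert np.all((fa >= 0) & (fa <= 1))
        assert np.all(adc >= 0)

    def test_zero_tensor_fa_is_zero(self):
        tf = recon.TensorField(
            np.zeros((1, 1, 1, 6)), np.ones((1, 1, 1), bool),
            VolumeGrid(np.zeros((1, 1, 1)), np.eye(4)),
        )
        maps = tensor_scalars(tf)
        assert maps["FA"].data[0, 0, 0] == 0.0


def make_odf(psi_rows, sphere=None):
    sphere = sphere or make_sphere(freq=2)
    psi = np.asarray(psi_rows, dtype=float).reshape(1, 1, -1, sphere.n)
    valid = np.ones(psi.shape[:3], bool)
    return OdfField(sphere, psi, valid, VolumeGrid(np.zeros(psi.shape[:3]), np.eye(4)))


class TestOdfDescriptors:
    def test_constant_odf_gfa_zero(self, small_sphere):
        odf = make_odf([np.ones(small_sphere.n)], small_sphere)
        maps = odf_descriptors(odf)
        assert maps["GFA"].data.flat[0] == 0.0
        assert maps["skewness"].data.flat[0] == 0.0
        assert maps["kurtosis"].data.flat[0] == 0.0

    def test_single_sample_delta_gfa_one(self, small_sphere):
        psi = np.zeros(small_sphere.n)
        psi[5] = 1.0
        odf = make_odf([psi], small_sphere)
        assert abs(odf_descriptors(odf)["GFA"].data.flat[0] - 1.0) < 1e-12

    def test_one_lobe_gfa_exceeds_two_lobe_of_equal_mass(self, small_sphere):
        """Concentrating the same ODF mass in one lobe raises the amplitude
        dispersion; verified against direct evaluation of the formula."""
        n = small_sphere.n
        one = np.zeros(n)
        one[0] = 2.0
        two = np.zeros(n)
        two[0] = 1.0
        two[small_sphere.antipode[0]] = 1.0

        def gfa(psi):
            dev = psi - psi.mean()
            return np.sqrt(n * (dev**2).sum() / ((n - 1) * (psi**2).sum()))

        maps_one = odf_descriptors(make_odf([one], small_sphere))
        maps_two = odf_descriptors(make_odf([two], small_sphere))
        g1, g2 = maps_one["GFA"].data.flat[0], maps_two["GFA"].data.flat[0]
        assert g1 >= g2
        assert abs(g1 - gfa(one)) < 1e-12 and abs(g2 - gfa(two)) < 1e-12

    def test_moments_match_numpy_on_random_amplitudes(self, small_sphere):
        rng = np.random.default_rng(7)
        psi = rng.random(small_sphere.n)
        maps = odf_descriptors(make_odf([psi], small_sphere))
        dev = psi - psi.mean()
        sd = dev.std()
        assert abs(maps["skewness"].data.flat[0] - (dev**3).mean() / sd**3) < 1e-12
        assert abs(maps["kurtosis"].data.flat[0] - ((dev**4).mean() / sd**4 - 3)) < 1e-12


class TestEapP0:
    def test_no_attenuation_gives_one(self, scheme30):
        dwi, mask = forward_dwi([np.zeros((3, 3)) + 1e-12 * np.eye(3)], scheme30)
        dwi.data[..., :] = 1000.0
        p0 = eap_p0(dwi, scheme30, mask)
        np.testing.assert_allclose(p0.data[0, 0, 0], 1.0)

    def test_isotropic_closed_form(self, scheme30):
        d = 0.7e-3
        dwi, mask = forward_dwi([d * np.eye(3)], scheme30)
        p0 = eap_p0(dwi, scheme30, mask)
        bv = scheme30.bvals[~scheme30.b0_mask]
        np.testing.assert_allclose(p0.data[0, 0, 0], np.exp(-bv * d).mean(), atol=1e-12)

    def test_monotone_decreasing_in_diffusivity(self, scheme30):
        ds = [0.3e-3, 0.7e-3, 1.5e-3, 2.5e-3]
        dwi, mask = forward_dwi([d * np.eye(3) for d in ds], scheme30)
        p0 = eap_p0(dwi, scheme30, mask).data.reshape(-1)[: len(ds)]
        assert np.all(np.diff(p0) < 0)


class TestTensorToOdf:
    def test_isotropic_gives_constant(self, scheme30):
        dwi, mask = forward_dwi([1e-3 * np.eye(3)], scheme30)
        odf = tensor_to_odf(fit_tensor(dwi, scheme30, mask))
        psi = odf.amplitudes[0, 0, 0]
        np.testing.assert_allclose(psi, psi[0], atol=1e-6)

    def test_argmax_at_principal_axis(self, scheme30):
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        dwi, mask = forward_dwi([D], scheme30)
        odf = tensor_to_odf(fit_tensor(dwi, scheme30, mask))
        best = odf.sphere.vertices[np.argmax(odf.amplitudes[0, 0, 0])]
        step = np.degrees(np.arccos(np.clip(abs(best @ [1, 0, 0]), 0, 1)))
        assert step < 7.0  # within one sphere sampling step of +/-x

    def test_antipodal_symmetry(self, scheme30):
        rng = np.random.default_rng(11)
        dwi, mask = forward_dwi(random_spd_tensors(4, rng), scheme30)
        odf = tensor_to_odf(fit_tensor(dwi, scheme30, mask))
        anti = odf.sphere.antipode
        np.testing.assert_allclose(
            odf.amplitudes[..., anti], odf.amplitudes, atol=1e-12
        )


def brute_force_orientation_maxima(psi, sphere, rel_threshold):
    """Independent enumeration of the published maximum definition: strictly
    greater than every neighbour, plateau ties broken by lowest index,
    antipodal twins collapsed, floor at rel_threshold * peak."""
    peak = psi.max()
    if peak <= 0 or np.all(psi == psi[0]):
        return set()
    wins = []
    for i in range(sphere.n):
        ok = psi[i] >= rel_threshold * peak
        for j in sphere.neighbours[i]:
            if psi[j] > psi[i] or (psi[j] == psi[i] and j < i):
                ok = False
                break
        if ok:
            wins.append(i)
    out = set()
    for i in wins:
        a = int(sphere.antipode[i])
        out.add(min(i, a) if a in wins else i)
    return out


class TestExtractMaxima:
    @pytest.mark.parametrize("freq", [2, 3], ids=["42-samples", "92-samples"])
    def test_matches_brute_force_enumeration(self, freq):
        sphere = make_sphere(freq=freq)
        rng = np.random.default_rng(13)
        rows = []
        for _ in range(20):
            # smooth random ODF: mixture of random quadratic lobes
            psi = np.zeros(sphere.n)
            for _k in range(rng.integers(1, 4)):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                psi += rng.uniform(0.3, 1.0) * (sphere.vertices @ v) ** 2
            rows.append(psi / psi.max())
        odf = make_odf(rows, sphere)
        got = extract_maxima(odf, rel_threshold=0.1, min_separation_deg=1.0,
                             max_directions=16, refine=False)
        for k, psi in enumerate(rows):
            expect = brute_force_orientation_maxima(np.asarray(psi), sphere, 0.1)
            dirs = got.directions[0, 0, k]
            found = {
                int(np.argmax(np.abs(sphere.vertices @ d))) for d in dirs[~np.isnan(dirs[:, 0])]
            }
            canon = {min(i, int(sphere.antipode[i])) for i in found}
            expect_canon = {min(i, int(sphere.antipode[i])) for i in expect}
            assert canon == expect_canon

    def test_single_tensor_gives_one_maximum_near_e1(self, scheme30):
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        dwi, mask = forward_dwi([D], scheme30)
        dirs = extract_maxima(tensor_to_odf(fit_tensor(dwi, scheme30, mask)))
        d = dirs.voxel_directions((0, 0, 0))
        assert len(d) == 1
        assert np.degrees(np.arccos(abs(np.clip(d[0] @ [1, 0, 0], -1, 1)))) < 7.0

    def test_constant_odf_yields_no_directions(self, small_sphere):
        odf = make_odf([np.ones(small_sphere.n)], small_sphere)
        dirs = extract_maxima(odf)
        assert len(dirs.voxel_directions((0, 0, 0))) == 0

    def test_min_separation_enforced(self, straight_directions):
        df = straight_directions
        sep = np.cos(np.radians(25.0))
        for ijk in np.argwhere(df.n_directions() >= 2)[:20]:
            d = df.voxel_directions(ijk)
            for i in range(len(d)):
                for j in range(i + 1, len(d)):
                    assert abs(d[i] @ d[j]) < sep + 1e-9

    def test_max_directions_cap(self, small_sphere):
        rng = np.random.default_rng(17)
        psi = rng.random(small_sphere.n)
        psi = np.maximum(psi, psi[small_sphere.antipode])  # antipodal symmetry
        odf = make_odf([psi], small_sphere)
        dirs = extract_maxima(odf, rel_threshold=0.0, min_separation_deg=1.0, max_directions=2)
        assert len(dirs.voxel_directions((0, 0, 0))) <= 2


def test_fa_error_under_rician_noise(scheme30):
    """Median in-bundle FA error stays within 0.05 at sigma = 2% of S0."""
    spec = straight_bundle_spec(noise_sigma=0.02 * 1000.0, rng_seed=99)
    dwi, wm, _, truth = make_phantom(spec, scheme30)
    tf = fit_tensor(dwi, scheme30, wm)
    fa = tensor_scalars(tf)["FA"].data
    b = spec.bundles[0]
    ev = np.array([b.lambda_par, b.lambda_perp, b.lambda_perp])
    fa_true = fa_from_eigenvalues(*ev)
    errs = [abs(fa[tuple(v)] - fa_true) for v in truth.bundle_voxels[0] if np.isfinite(fa[tuple(v)])]
    assert np.median(errs) <= 0.05
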