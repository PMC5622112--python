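"""Feature extraction: registry contract, shape/granularity/intensity oracles,
and exact GLCM/Haralick verification against brute-force computation."""

import math

import numpy as np
import pytest
from scipy import ndimage

from conftest import make_disk
from morphoscreen import PhenotypeParams, extract_features, render_cell_image
from morphoscreen.features import (
    CATEGORY_SLICES,
    FEATURE_NAMES,
    FEATURE_REGISTRY,
    N_FEATURES,
    category_of,
    cooccurrence,
    geometry_features,
    granularity_features,
    haralick_from_glcm,
    intensity_features,
    quantize,
    shape_features,
    texture_features,
    zernike_magnitudes,
)
from morphoscreen.synthetic import AcquisitionParams
from morphoscreen.types import CellImage


class TestRegistry:
    def test_counts_and_index_ranges(self):
        assert len(FEATURE_REGISTRY) == 548
        cats = [e.category for e in FEATURE_REGISTRY]
        assert cats[0:43] == ["geometry"] * 43
        assert cats[43:53] == ["granularity"] * 10
        assert cats[53:96] == ["intensity"] * 43
        assert cats[96:548] == ["texture"] * 452
        assert [e.index for e in FEATURE_REGISTRY] == list(range(1, 549))

    def test_names_unique_and_category_lookup(self):
        assert len(set(FEATURE_NAMES)) == 548
        assert category_of(1) == "geometry"
        assert category_of(44) == "granularity"
        assert category_of(54) == "intensity"
        assert category_of(97) == "texture"
        assert category_of(548) == "texture"
        with pytest.raises(ValueError):
            category_of(549)


class TestGeometry:
    def test_disk_area_eccentricity_form_factor(self):
        mask, _ = make_disk(radius=20)
        f = shape_features(mask)
        named = dict(zip(FEATURE_NAMES[:13], f))
        assert named["geometry_area"] == pytest.approx(math.pi * 400, rel=0.02)
        assert named["geometry_eccentricity"] <= 0.05
        assert named["geometry_form_factor"] == pytest.approx(1.0, rel=0.05)

    def test_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[0:80, 0:80]
        mask = ((yy - 40) / 12) ** 2 + ((xx - 40) / 24) ** 2 <= 1.0
        f = dict(zip(FEATURE_NAMES[:13], shape_features(mask)))
        ratio = f["geometry_major_axis_length"] / f["geometry_minor_axis_length"]
        assert ratio == pytest.approx(2.0, rel=0.03)

    def test_linear_scaling(self):
        small, _ = make_disk(radius=10, size=40)
        large, _ = make_disk(radius=20, size=64)
        fs = dict(zip(FEATURE_NAMES[:13], shape_features(small)))
        fl = dict(zip(FEATURE_NAMES[:13], shape_features(large)))
        assert fl["geometry_area"] / fs["geometry_area"] == pytest.approx(4.0, rel=0.05)
        assert fl["geometry_perimeter"] / fs["geometry_perimeter"] == pytest.approx(
            2.0, rel=0.05
        )

    def test_disk_zernike_rotational_symmetry(self):
        mask, _ = make_disk(radius=20)
        from morphoscreen.features.registry import ZERNIKE_ORDERS

        z = zernike_magnitudes(mask)
        for (n, m), v in zip(ZERNIKE_ORDERS, z):
            if m > 0:
                assert v < 0.02, f"Z_{n}{m} = {v}"

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            geometry_features(np.zeros((8, 8), dtype=bool))


class TestGranularity:
    def test_constant_cell_all_zero(self):
        mask, img = make_disk(radius=15, value=0.7)
        assert np.allclose(granularity_features(img, mask), 0.0)

    def test_grain_size_localized(self):
        """Bright grains of radius 3 disappear at opening radius 4, so the
        spectrum mass lands in scale bins 3 +/- 1."""
        from skimage.morphology import disk

        img = np.zeros((64, 64))
        g = disk(3).astype(float)
        for r, c in [(10, 10), (10, 40), (40, 10), (40, 40), (25, 25)]:
            img[r : r + 7, c : c + 7] = np.maximum(img[r : r + 7, c : c + 7], g)
        mask = np.ones_like(img, dtype=bool)
        spec = granularity_features(img, mask)
        assert spec[1:5].sum() >= 0.8  # bins 2..5 (1-based scales 2..5)
        assert spec.sum() <= 1.0 + 1e-9

    def test_spectrum_bounds(self, rendered_cell):
        spec = granularity_features(rendered_cell.pixels, rendered_cell.mask)
        assert (spec >= 0).all()
        assert spec.sum() <= 1.0 + 1e-9

    def test_zero_intensity_rejected(self):
        mask, _ = make_disk(radius=5, size=16)
        with pytest.raises(ValueError, match="zero total intensity"):
            granularity_features(np.zeros((16, 16)), mask)

    def test_monotone_in_texture_grain(self, model):
        """Coarser generator texture shifts the spectrum to larger scales
        (positive Spearman correlation over synthetic cells)."""
        from scipy.stats import spearmanr

        clean = AcquisitionParams(noise_sd=0.0)
        grains, centers = [], []
        rng = np.random.default_rng(0)
        for i in range(200):
            grain = float(rng.uniform(0.6, 3.5))
            phen = PhenotypeParams(texture_grain=grain, intensity_sd=0.12)
            cell = render_cell_image(phen, clean, seed=3000 + i)
            spec = granularity_features(cell.pixels, cell.mask)
            scales = np.arange(1, 11)
            if spec.sum() == 0:
                continue
            centers.append((scales * spec).sum() / spec.sum())
            grains.append(grain)
        rho, _ = spearmanr(grains, centers)
        assert rho > 0


class TestIntensity:
    def test_constant_image(self):
        mask, _ = make_disk(radius=10, size=32)
        f = dict(
            zip(FEATURE_NAMES[53:96], intensity_features(np.full((32, 32), 0.5), mask))
        )
        assert f["intensity_mean"] == 0.5
        assert f["intensity_median"] == 0.5
        assert f["intensity_std"] == 0.0
        assert f["intensity_mad"] == 0.0
        assert f["intensity_mass_displacement"] == 0.0

    def test_ramp_integrated_exact(self):
        mask, _ = make_disk(radius=10, size=32)
        img = np.tile(np.linspace(0, 1, 32), (32, 1))
        f = intensity_features(img, mask)
        assert f[0] == img[mask].sum()  # direct-summation oracle

    def test_centered_spot_small_mass_displacement(self):
        mask, _ = make_disk(radius=12, size=32)
        yy, xx = np.mgrid[0:32, 0:32]
        img = np.exp(-(((yy - 15.5) ** 2 + (xx - 15.5) ** 2) / 30.0))
        f = dict(zip(FEATURE_NAMES[53:96], intensity_features(img, mask)))
        assert f["intensity_mass_displacement"] <= 0.5

    def test_output_length(self, rendered_cell):
        assert intensity_features(rendered_cell.pixels, rendered_cell.mask).shape == (
            43,
        )


def _brute_force_glcm(q, offset, levels=8):
    """Independent double-loop co-occurrence count (symmetric, normalized)."""
    dr, dc = offset
    h, w = q.shape
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] >= 0 and q[r2, c2] >= 0:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    total = counts.sum()
    return counts / total if total else counts


def _brute_force_haralick(P):
    """Independent scalar-loop implementation of the 13 statistics."""
    L = P.shape[0]
    eps = 0.0
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))
    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def H(p):
        return -sum(v * math.log2(v) for v in np.ravel(p) if v > 0)

    asm = float((P ** 2).sum())
    contrast = sum(k ** 2 * p_diff[k] for k in range(L))
    corr = (
        (sum(i * j * P[i, j] for i in range(L) for j in range(L)) - mu_x * mu_y)
        / (sd_x * sd_y)
        if sd_x > 0 and sd_y > 0
        else 0.0
    )
    var = sum((i - mu_x) ** 2 * P[i, j] for i in range(L) for j in range(L))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    savg = sum(k * p_sum[k] for k in range(2 * L - 1))
    svar = sum((k - savg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sent = H(p_sum)
    ent = H(P)
    dmean = sum(k * p_diff[k] for k in range(L))
    dvar = sum((k - dmean) ** 2 * p_diff[k] for k in range(L))
    dent = H(p_diff)
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if P[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if px[i] * py[j] > 0
    )
    hx, hy = H(px), H(py)
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - ent))))
    return np.array(
        [asm, contrast, corr, var, idm, savg, svar, sent, ent, dvar, dent, imc1, imc2]
    )


class TestTexture:
    def test_constant_image_degenerate_stats(self):
        mask, _ = make_disk(radius=12, size=32)
        f = texture_features(np.full((32, 32), 0.4), mask)
        named = dict(zip(FEATURE_NAMES[96:548], f))
        for d in (1, 2, 3, 4, 5, 6, 8, 10):
            for a in (0, 45, 90, 135):
                assert named[f"texture_haralick_contrast_d{d}_a{a}"] == 0.0
                assert named[f"texture_haralick_asm_d{d}_a{a}"] == 1.0

    @pytest.mark.parametrize("offset", [(0, 1), (-1, 1), (-2, 0), (3, -3)])
    def test_glcm_matches_brute_force(self, offset):
        rng = np.random.default_rng(hash(offset) % 2**31)
        img = rng.random((8, 8))
        mask = rng.random((8, 8)) > 0.2
        mask[2:6, 2:6] = True
        q = quantize(img, mask)
        P_fast = cooccurrence(q, offset)
        P_slow = _brute_force_glcm(q, offset)
        assert np.allclose(P_fast, P_slow, atol=1e-12)

    def test_haralick_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            img = rng.random((8, 8))
            mask = np.ones((8, 8), dtype=bool)
            P = cooccurrence(quantize(img, mask), (0, 1))
            assert np.allclose(
                haralick_from_glcm(P), _brute_force_haralick(P), atol=1e-10
            )

    def test_checkerboard_has_higher_contrast_than_blur(self):
        checker = np.indices((32, 32)).sum(axis=0) % 2 * 1.0
        blurred = ndimage.gaussian_filter(
            np.random.default_rng(1).random((32, 32)), 2.0
        )
        mask = np.ones((32, 32), dtype=bool)
        idx = FEATURE_NAMES[96:548].index("texture_haralick_contrast_d1_a0")
        c_checker = texture_features(checker, mask)[idx]
        c_blur = texture_features(blurred, mask)[idx]
        assert c_checker > c_blur

    def test_output_length(self, rendered_cell):
        assert texture_features(rendered_cell.pixels, rendered_cell.mask).shape == (
            452,
        )

    def test_tiny_mask_sentinel_not_error(self):
        """A mask too small for the largest offsets yields sentinel zeros."""
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:34, 30:34] = True
        rng = np.random.default_rng(2)
        f = texture_features(rng.random((64, 64)), mask)
        assert np.isfinite(f).all()


class TestExtract:
    def test_length_and_category_slices(self, rendered_cell):
        fv = extract_features(rendered_cell)
        assert fv.values.shape == (N_FEATURES,)
        assert np.isfinite(fv.values).all()
        widths = {k: s.stop - s.start for k, s in CATEGORY_SLICES.items()}
        assert widths == {
            "geometry": 43,
            "granularity": 10,
            "intensity": 43,
            "texture": 452,
        }

    def test_deterministic(self, rendered_cell):
        a = extract_features(rendered_cell).values
        b = extract_features(rendered_cell).values
        assert np.array_equal(a, b)

    def test_rotation_invariance_of_area_granularity_quantiles(self, rendered_cell):
        rotated = CellImage(
            pixels=np.rot90(rendered_cell.pixels).copy(),
            mask=np.rot90(rendered_cell.mask).copy(),
        )
        a = extract_features(rendered_cell).values
        b = extract_features(rotated).values
        names = FEATURE_NAMES
        for name in (
            "geometry_area",
            "intensity_median",
            "intensity_lower_quartile",
            "intensity_upper_quartile",
        ):
            i = names.index(name)
            assert b[i] == pytest.approx(a[i], rel=0.01)
        sl = CATEGORY_SLICES["granularity"]
        assert np.allclose(a[sl], b[sl], atol=0.01)
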