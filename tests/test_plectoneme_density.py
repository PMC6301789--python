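import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from plectopin.directional_stiffness import (
    directional_persistence_length,
    summed_covariance,
)
from plectopin.fixtures import GC_CURVED_UNIT, FixtureSpec, make_fixture
from plectopin.helix_geometry import curvature_profile, ground_state_path
from plectopin.loop_energetics import total_energy
from plectopin.plectoneme_density import (
    density_profile,
    energy_grid,
    gaussian_smooth,
    min_sequence_length,
)

from conftest import random_dna


# --------------------------------------------------------------------------
# slow, direct re-implementation of W_tot (shares no code with production)
# --------------------------------------------------------------------------

def naive_w_tot(seq, params, tension_pn=3.0, ceiling=1e4):
    geometry = params.geometry
    cov = params.stiffness
    rise = params.rise
    frames = [np.eye(3)]
    for a, b in zip(seq[:-1], seq[1:]):
        tilt, roll, twist = geometry[a + b]
        frames.append(frames[-1] @ Rotation.from_euler(
            "XYZ", [twist, roll, tilt]).as_matrix())
    pos = [np.zeros(3)]
    for f in frames[1:]:
        pos.append(pos[-1] + rise * f[:, 0])
    pos = np.array(pos)

    def tangent(i):
        chord = pos[i + 5] - pos[i - 5]
        return chord / np.linalg.norm(chord)

    n = len(seq)
    c_work = rise * tension_pn / (0.334 * 12.16)
    out = np.full(n, np.nan)
    for i in range(65, n - 65):
        total = 0.0
        for n_loop in range(40, 121, 8):
            half = n_loop // 2
            t0, t1 = tangent(i - half), tangent(i + half)
            theta = math.degrees(math.acos(np.clip(t0 @ t1, -1, 1)))
            delta = t1 - t0
            frame = frames[i]
            phi_b = math.atan2(delta @ frame[:, 2], delta @ frame[:, 1])
            # covariance sum co-rotated to the center frame
            steps = [seq[k : k + 2] for k in range(i - half, i - half + n_loop)]
            twists = [geometry[s][2] for s in steps]
            sigma = np.zeros((2, 2))
            for k, s in enumerate(steps):
                psi = sum(twists[:k]) - sum(twists[: half])
                c, sn = math.cos(psi), math.sin(psi)
                rot = np.array([[c, -sn], [sn, c]])
                sigma += rot @ cov[s] @ rot.T
            for k in range(8):
                phi = phi_b + k * math.pi / 4
                u = np.array([math.cos(-phi), math.sin(-phi)])
                var = max(u @ sigma @ u, rise * n_loop / ceiling)
                a_nm = rise * n_loop / var
                deficit = (1 + (theta / 240) ** 2
                           - 2 * (theta / 240) * math.cos(phi - phi_b))
                e_bend = (2 / 3) ** 2 * 2 * math.pi ** 2 * a_nm / (
                    rise * n_loop) * deficit
                total += math.exp(-(c_work * n_loop + e_bend))
        out[i] = total
    return out


def test_w_tot_matches_independent_oracle(default_params):
    seq = random_dna(180, 17)
    prod = density_profile(seq, params=default_params)
    oracle = naive_w_tot(seq, default_params)
    m = prod.defined_mask
    assert m.sum() == 180 - 130
    assert np.allclose(prod.w_tot[m], oracle[m], rtol=1e-9)


def test_oracle_equivalence_on_null_geometry(null_params):
    seq = random_dna(160, 23)
    prod = density_profile(seq, params=null_params)
    oracle = naive_w_tot(seq, null_params)
    m = prod.defined_mask
    assert np.allclose(prod.w_tot[m], oracle[m], rtol=1e-9)


# --------------------------------------------------------------------------
# energy grid
# --------------------------------------------------------------------------

def test_grid_shape_and_weights(default_params):
    grid = energy_grid(random_dna(300, 1), 150, params=default_params)
    assert grid.e_total.shape == (11, 8)
    assert np.all(grid.weights > 0)
    assert np.allclose(grid.weights, np.exp(-grid.e_total))
    assert grid.loop_sizes.tolist() == list(range(40, 121, 8))


def test_null_geometry_grid_is_direction_independent(null_params):
    grid = energy_grid("ACGT" * 80, 160, params=null_params)
    assert np.allclose(grid.theta, 0.0, atol=1e-9)
    for row in grid.e_total:
        assert np.allclose(row, row[0], atol=1e-9)


def test_grid_cell_matches_chained_component_calls(default_params):
    seq = random_dna(300, 9)
    center = 150
    grid = energy_grid(seq, center, params=default_params)
    j, k = 4, 3  # loop size 72, direction phi_B + 135 deg
    n_loop = int(grid.loop_sizes[j])
    path = ground_state_path(seq, default_params)
    curv = curvature_profile(path, n_loop)
    sigma = summed_covariance(seq, center, n_loop, default_params)
    phi = curv.phi_b[center] + k * math.pi / 4
    a_nm = directional_persistence_length(sigma, n_loop, -phi,
                                          default_params.rise)
    expected = total_energy(n_loop, 3.0, a_nm, curv.theta[center], phi,
                            curv.phi_b[center])
    assert grid.e_total[j, k] == pytest.approx(expected, rel=1e-9)


# --------------------------------------------------------------------------
# density profiles
# --------------------------------------------------------------------------

def test_homopolymer_stretch_gives_uniform_density(null_params):
    prof = density_profile("A" * 1000, params=null_params)
    m = prof.defined_mask
    assert np.allclose(prof.density[m], 1.0, atol=1e-9)
    assert np.isnan(prof.density[:65]).all()
    assert np.isnan(prof.density[-65:]).all()


def test_density_mean_is_one(default_params, random_20kb):
    prof = density_profile(random_20kb, params=default_params)
    assert np.nanmean(prof.density[prof.defined_mask]) == pytest.approx(
        1.0, abs=1e-9
    )
    assert np.isfinite(prof.free_energy[prof.defined_mask]).all()


def test_too_short_sequence_reports_minimum_length(default_params):
    with pytest.raises(ValueError, match=str(min_sequence_length())):
        density_profile("ACGT" * 30, params=default_params)


def test_insert_peak_translates_with_the_insert(default_params):
    insert = GC_CURVED_UNIT
    peaks = []
    for pos in (2000, 2600):
        seq = make_fixture(
            FixtureSpec(kind="insert_in_backbone", length=5000, insert=insert,
                        insert_position=pos, seed=5)
        )
        prof = density_profile(seq, params=default_params)
        peaks.append(int(np.nanargmax(prof.density)))
    shift = peaks[1] - peaks[0]
    assert abs(shift - 600) <= 40  # within grid support of the insert


def test_peak_area_grows_with_insert_length(default_params):
    # concatenating more curved units increases the pinning weight
    areas = []
    for n_units in (1, 2, 4):
        seq = make_fixture(
            FixtureSpec(kind="insert_in_backbone", length=6000,
                        insert=GC_CURVED_UNIT * n_units, insert_position=3000,
                        seed=5)
        )
        prof = density_profile(seq, params=default_params)
        w = prof.w_tot[prof.defined_mask]
        baseline = np.median(w)  # backbone-dominated level
        areas.append((np.clip(w - baseline, 0, None) / baseline).sum())
    assert areas[0] < areas[1] < areas[2]


def test_gc_rich_curved_beats_gc_matched_flat(default_params):
    curved = make_fixture(
        FixtureSpec(kind="insert_in_backbone", length=8000,
                    insert=GC_CURVED_UNIT * 8, insert_position=3700, seed=5)
    )
    flat_insert = make_fixture(
        FixtureSpec(kind="flat_random", length=600, seed=13, gc_fraction=0.59)
    )
    flat = make_fixture(
        FixtureSpec(kind="insert_in_backbone", length=8000,
                    insert=flat_insert, insert_position=3700, seed=5)
    )
    d_curved = density_profile(curved, params=default_params)
    d_flat = density_profile(flat, params=default_params)
    assert np.nanmax(d_curved.density) >= 1.2 * np.nanmax(d_flat.density)


# --------------------------------------------------------------------------
# smoothing
# --------------------------------------------------------------------------

def test_impulse_response_is_gaussian_of_expected_width():
    n = 12001
    x = np.zeros(n)
    x[n // 2] = 1.0
    sm = gaussian_smooth(x, fwhm=1600)
    sigma = 1600 / math.sqrt(8 * math.log(2))
    assert sigma == pytest.approx(679.45, abs=0.05)
    ref = np.exp(-0.5 * ((np.arange(n) - n // 2) / sigma) ** 2)
    ref /= ref.sum()
    assert np.allclose(sm, ref, atol=1e-6)


def test_constant_profile_is_unchanged_by_smoothing():
    x = np.full(5000, 3.7)
    assert np.allclose(gaussian_smooth(x, 1600), 3.7, atol=1e-9)


def test_smoothing_preserves_the_mean(default_params, random_20kb):
    prof = density_profile(random_20kb, params=default_params)
    sm = prof.smoothed(1600)
    m = prof.defined_mask
    assert np.nanmean(sm.smoothed_density[m]) == pytest.approx(
        np.nanmean(prof.density[m]), abs=1e-6
    )
    # circular smoothing wraps and preserves the mean too
    circ = density_profile(random_20kb[:4000], params=default_params,
                           circular=True)
    smc = gaussian_smooth(circ.density, 800, circular=True)
    assert smc.mean() == pytest.approx(circ.density.mean(), abs=1e-9)
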