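"""Micro-CT analysis chain: edges, filling, tracing, diameters, binning."""

import numpy as np
import pytest
from scipy import ndimage

from bpdph.microct import (
    BinaryVolume,
    DiameterHistogram,
    FilamentNetwork,
    FilamentSegment,
    Volume3D,
    bin_vessels,
    detect_large_vessel_edges,
    estimate_diameters,
    fill_large_vessels,
    normalize_to_reference,
    run_microct_pipeline,
    threshold_small_vessels,
    trace_filaments,
)
from bpdph.phantoms import ConditionProfile, generate_vascular_volume

from conftest import make_tube_volume


# --------------------------------------------------------------------- edges


def dense_dog_oracle(img2d, sigma, ratio=1.6):
    """Direct convolution with explicitly built Gaussian kernels."""

    def kernel(s):
        half = int(np.ceil(4 * s))
        x = np.arange(-half, half + 1)
        g = np.exp(-(x**2) / (2 * s * s))
        g /= g.sum()
        return np.outer(g, g)

    k = kernel(sigma)
    k2 = kernel(ratio * sigma)
    pad = max(k.shape[0], k2.shape[0]) // 2
    p = np.pad(img2d, pad)
    out = np.zeros_like(img2d, float)
    out2 = np.zeros_like(img2d, float)
    for i in range(img2d.shape[0]):
        for j in range(img2d.shape[1]):
            win = p[i + pad - k.shape[0] // 2 : i + pad + k.shape[0] // 2 + 1,
                    j + pad - k.shape[0] // 2 : j + pad + k.shape[0] // 2 + 1]
            out[i, j] = (win * k).sum()
            win2 = p[i + pad - k2.shape[0] // 2 : i + pad + k2.shape[0] // 2 + 1,
                     j + pad - k2.shape[0] // 2 : j + pad + k2.shape[0] // 2 + 1]
            out2[i, j] = (win2 * k2).sum()
    return out - out2


def test_all_zero_volume_gives_empty_mask():
    vol = Volume3D(np.zeros((4, 32, 32)))
    mask = detect_large_vessel_edges(vol)
    assert not mask.mask.any()


def test_dog_impulse_response_matches_dense_convolution():
    """A single bright voxel probes the first band-pass stage directly."""
    img = np.zeros((21, 21))
    img[10, 10] = 100.0
    oracle = dense_dog_oracle(img, 2.0)
    smooth = ndimage.gaussian_filter(img, 2.0) - ndimage.gaussian_filter(img, 3.2)
    # implementation and oracle agree away from the truncation boundary
    np.testing.assert_allclose(smooth[5:16, 5:16], oracle[5:16, 5:16], atol=1e-3)


def test_edges_of_wide_cylinder_form_annulus():
    """A radius-10 cylinder responds at its wall, not its interior."""
    zz = 6
    img = np.zeros((zz, 64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2
    img[:, disk] = 200.0
    mask = detect_large_vessel_edges(Volume3D(img)).mask
    r = np.hypot(yy - 32, xx - 32)
    plane = mask[zz // 2]
    wall_band = plane[(r >= 4) & (r <= 10)]     # response sits just inside the wall
    interior = plane[r < 3]
    outside = plane[r > 13]
    assert wall_band.mean() > 0.5         # wall detected
    assert interior.mean() < 0.3          # interior mostly empty (edge, not fill)
    assert outside.mean() < 0.05


def test_invalid_scales_rejected():
    vol = Volume3D(np.zeros((2, 16, 16)))
    with pytest.raises(ValueError):
        detect_large_vessel_edges(vol, r1=5, r2=2)


# --------------------------------------------------------------------- fill


def border_flood_fill_oracle(plane):
    """Fill = complement of the background reachable from the border."""
    inv = ~plane
    labels, _ = ndimage.label(inv)
    border_labels = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    border_labels.discard(0)
    outside = np.isin(labels, sorted(border_labels))
    return plane | (inv & ~outside)


def annulus_plane(gap=0):
    plane = np.zeros((32, 32), bool)
    yy, xx = np.mgrid[0:32, 0:32]
    r = np.hypot(yy - 16, xx - 16)
    plane[(r >= 8) & (r <= 10)] = True
    if gap:
        plane[16 - gap // 2 : 16 + (gap + 1) // 2, 24:] = False
    return plane


def test_fill_idempotent_on_solid_disk():
    yy, xx = np.mgrid[0:32, 0:32]
    disk = (np.hypot(yy - 16, xx - 16) <= 9)[None]
    out = fill_large_vessels(BinaryVolume(disk), max_gap=3)
    np.testing.assert_array_equal(out.mask, disk)


def test_fill_closed_annulus_matches_flood_fill_oracle():
    plane = annulus_plane()
    out = fill_large_vessels(BinaryVolume(plane[None]), max_gap=3).mask[0]
    oracle = border_flood_fill_oracle(plane)
    # the filled region contains the oracle disk; skeleton closing may
    # add a few voxels but never removes any
    assert np.all(oracle <= out | plane)
    assert out.sum() >= oracle.sum() * 0.98


def test_fill_bridges_gap_only_within_max_gap():
    gapped = annulus_plane(gap=2)
    filled = fill_large_vessels(BinaryVolume(gapped[None]), max_gap=6).mask[0]
    unfilled = fill_large_vessels(BinaryVolume(gapped[None]), max_gap=1).mask[0]
    assert filled.sum() > gapped.sum() + 50      # interior filled
    assert unfilled.sum() <= gapped.sum() + 10   # nothing enclosed
    with pytest.raises(ValueError):
        fill_large_vessels(BinaryVolume(gapped[None]), max_gap=0)


# --------------------------------------------------------------------- trace


def test_empty_inputs_give_empty_network():
    vol = Volume3D(np.zeros((16, 16, 16)))
    net = trace_filaments(BinaryVolume(np.zeros((16, 16, 16), bool)), vol)
    assert len(net) == 0


def test_single_tube_traced_once_with_correct_length(single_tube):
    vol, gt = single_tube
    net, _ = run_microct_pipeline(vol)
    assert len(net) == 1
    seg = net.segments[0]
    true_len = np.linalg.norm(gt.segments[0].end - gt.segments[0].start)
    assert seg.length_voxels == pytest.approx(true_len, abs=4.0)


def test_y_bifurcation_topology():
    """A parent tube with two diverging children: 3 segments, 1 junction."""
    from bpdph._geom import render_capsule

    canvas = np.zeros((64, 64, 64), float)
    j = np.array([32.0, 32.0, 30.0])
    render_capsule(canvas, [32, 32, 6], j, 1.6, amplitude=200, supersample=4)
    render_capsule(canvas, j, [18.0, 32.0, 52.0], 1.3, amplitude=200, supersample=4)
    render_capsule(canvas, j, [46.0, 32.0, 52.0], 1.3, amplitude=200, supersample=4)
    vol = Volume3D(20.0 + canvas)
    net = trace_filaments(
        BinaryVolume(np.zeros(canvas.shape, bool)), vol
    )
    assert len(net.segments) == 3
    assert net.n_branch_points >= 1


# ------------------------------------------------------------------ diameter


@pytest.mark.parametrize("radius_vox", [1.0, 2.0, 3.0])
def test_tube_diameter_within_one_voxel(radius_vox):
    vol, _ = make_tube_volume(radius_vox)
    net, _ = run_microct_pipeline(vol)
    assert len(net) == 1
    d_vox = net.segments[0].diameter_um / 6.0
    assert abs(d_vox - 2 * radius_vox) <= 1.0


def test_one_voxel_line_reads_one_voxel_size():
    """A 1-voxel-wide line at 6 um pitch must measure 6 um by the EDT rule."""
    mask = np.zeros((32, 32, 32), bool)
    mask[16, 16, 4:28] = True
    net = FilamentNetwork(
        [FilamentSegment(points=np.argwhere(mask).astype(float), vessel_class="small")],
        voxel_size=6.0,
    )
    out = estimate_diameters(
        net, BinaryVolume(np.zeros_like(mask)), BinaryVolume(mask), original=None
    )
    assert out.segments[0].diameter_um == pytest.approx(6.0)


def test_cone_median_gives_mid_tube_diameter():
    """Linearly tapering tube: the median rule lands at the mid radius."""
    from bpdph._geom import render_capsule

    canvas = np.zeros((40, 40, 72), float)
    render_capsule(canvas, [20, 20, 6], [20, 20, 66], 1.0, 4.0, amplitude=200, supersample=3)
    mask = canvas > 100
    pts = np.array([[20.0, 20.0, z] for z in range(8, 64)])
    net = FilamentNetwork([FilamentSegment(points=pts, vessel_class="small")], voxel_size=6.0)
    out = estimate_diameters(
        net, BinaryVolume(np.zeros_like(mask)), BinaryVolume(mask), original=None
    )
    # mid-tube radius is 2.5 voxels -> 30 um diameter (+-1 voxel)
    assert out.segments[0].diameter_um == pytest.approx(30.0, abs=6.0)


def test_segment_outside_masks_excluded():
    pts = np.array([[5.0, 5.0, z] for z in range(5, 15)])
    net = FilamentNetwork([FilamentSegment(points=pts, vessel_class="small")], voxel_size=6.0)
    empty = BinaryVolume(np.zeros((20, 20, 20), bool))
    out = estimate_diameters(net, empty, empty)
    assert len(out) == 0


# ------------------------------------------------------------------- binning


def make_network(diameters):
    segs = [
        FilamentSegment(
            points=np.array([[1.0, 1, 1], [1, 1, 5]]), vessel_class="small", diameter_um=d
        )
        for d in diameters
    ]
    return FilamentNetwork(segs, voxel_size=6.0)


def test_binning_discards_below_cutoff():
    hist = bin_vessels(make_network([3.5, 4.2, 5.5]), [4, 5, 6, 7])
    assert hist.counts.tolist() == [1, 1, 0]
    assert hist.n_discarded_small == 1
    assert hist.percent_of_total[:2].tolist() == [50.0, 50.0]


def test_empty_network_flagged():
    hist = bin_vessels(make_network([]), [4, 5, 6])
    assert hist.total == 0
    assert not hist.percent_defined
    assert np.all(np.isnan(hist.percent_of_total))


def test_count_conservation_and_exact_membership(rng):
    diameters = rng.uniform(2.0, 35.0, 100)
    edges = [4.0, 5, 6, 7, 10, 15, 20, 30]
    hist = bin_vessels(make_network(diameters), edges)
    expected, _ = np.histogram(diameters, bins=edges)
    assert hist.counts.tolist() == expected.tolist()
    assert hist.total + hist.n_discarded_small + hist.n_above_range == 100
    assert hist.percent_of_total.sum() == pytest.approx(100.0)


def test_first_edge_must_be_cutoff():
    with pytest.raises(ValueError):
        bin_vessels(make_network([5.0]), [5, 6, 7])


def test_monotonicity_adding_a_vessel():
    base = make_network([4.5, 6.5, 12.0])
    more = make_network([4.5, 6.5, 12.0, 8.0])
    h1 = bin_vessels(base)
    h2 = bin_vessels(more)
    assert np.all(h2.counts >= h1.counts)


# ------------------------------------------------------------- normalization


def histogram(counts, specimen, group):
    counts = np.asarray(counts)
    return DiameterHistogram(
        bin_edges=np.array([4.0, 5, 6, 7]),
        counts=counts,
        percent_of_total=100 * counts / counts.sum(),
        specimen_id=specimen,
        group=group,
    )


def test_reference_self_normalization_identity():
    hists = [histogram([10, 5, 5], "a1", "ref"), histogram([10, 5, 5], "a2", "ref")]
    out, summary = normalize_to_reference(hists, "ref")
    for h in out:
        np.testing.assert_allclose(h.normalized, h.percent_of_total)


def test_group_with_half_total_scales_by_half():
    hists = [
        histogram([10, 6, 4], "a1", "ref"),
        histogram([5, 3, 2], "b1", "b"),
    ]
    out, _ = normalize_to_reference(hists, "ref")
    b = next(h for h in out if h.group == "b")
    np.testing.assert_allclose(b.normalized, b.percent_of_total * 0.5)


def test_missing_reference_group_rejected():
    with pytest.raises(ValueError):
        normalize_to_reference([histogram([1, 1, 1], "x", "g")], "absent")


# ------------------------------------------------------------- end-to-end


def test_pipeline_counts_recover_ground_truth_within_tolerance():
    """Noise-free multi-bin phantom: total vessel recovery within 10%."""
    p = ConditionProfile("mix", [4, 5, 6, 7, 10, 15, 20, 30], [6, 5, 4, 5, 3, 2, 1])
    vol, gt = generate_vascular_volume(
        p, shape=(96, 96, 96), seed=21, poisson_counts=False, noise_sd=0.0
    )
    net, hist = run_microct_pipeline(vol)
    n_true = len(gt.segments)
    assert abs(len(net) - n_true) <= max(2, 0.1 * n_true)
    # diameter bias below one voxel on average
    det = np.sort(net.diameters_um())
    true = np.sort(gt.diameters_um())
    k = min(len(det), len(true))
    assert np.abs(np.median(det[:k] - true[:k])) <= 6.0
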