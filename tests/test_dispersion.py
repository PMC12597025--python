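"""PCoA with imaginary axes, spatial medians, and group dispersion."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from gutdrift.community import CountTable, bray_curtis
from gutdrift.dispersion import (
    _weiszfeld,
    bias_adjust,
    distance_to_median,
    group_dispersion,
    pcoa,
    spatial_median,
    sqrt_transform,
)
from tests.conftest import random_count_table


def euclidean_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestSqrtTransform:
    def test_elementwise_sqrt_with_fixed_points(self):
        dm = DistanceMatrix([[0, 0.25], [0.25, 0]], ids=["a", "b"])
        out = sqrt_transform(dm)
        assert out[("a", "b")] == pytest.approx(0.5)
        dm1 = DistanceMatrix([[0, 1.0], [1.0, 0]], ids=["a", "b"])
        assert sqrt_transform(dm1)[("a", "b")] == pytest.approx(1.0)

    def test_does_not_worsen_negative_eigenvalues(self, rng):
        """The sqrt transform makes Bray-Curtis more Euclidean-embeddable."""
        for _ in range(20):
            t = random_count_table(rng, n_samples=7)
            dm = bray_curtis(t)
            before = int((pcoa(dm).eigenvalues < -1e-10).sum())
            after = int((pcoa(sqrt_transform(dm)).eigenvalues < -1e-10).sum())
            assert after <= before


class TestPcoa:
    def test_two_samples_split_symmetrically(self):
        dm = DistanceMatrix([[0, 0.8], [0.8, 0]], ids=["a", "b"])
        res = pcoa(dm)
        assert res.real.shape[1] == 1
        np.testing.assert_allclose(np.sort(res.real[:, 0]), [-0.4, 0.4], atol=1e-12)

    def test_collinear_points_give_single_axis(self):
        d = np.array([[0, 3, 4], [3, 0, 1], [4, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert res.real.shape[1] == 1
        assert res.imag.shape[1] == 0
        axis = res.real[:, 0]
        rebuilt = np.abs(axis[:, None] - axis[None, :])
        np.testing.assert_allclose(rebuilt, d, atol=1e-8)

    def test_non_euclidean_input_keeps_reconstruction_identity(self):
        # count table whose Bray-Curtis matrix has a negative eigenvalue
        t = CountTable(
            pd.DataFrame(
                [
                    [4, 0, 0, 1],
                    [0, 6, 5, 6],
                    [2, 6, 7, 3],
                    [4, 9, 8, 9],
                    [3, 6, 9, 6],
                ],
                index=list("abcde"),
                columns=list("wxyz"),
            )
        )
        dm = bray_curtis(t)
        res = pcoa(dm)
        assert (res.eigenvalues < -1e-10).any()
        np.testing.assert_allclose(
            res.reconstructed_sq_dissimilarity(), dm.data**2, atol=1e-6
        )

    def test_eigenvalue_sum_matches_gower_trace(self, rng):
        t = random_count_table(rng)
        dm = bray_curtis(t)
        d = dm.data
        a = -0.5 * d**2
        g = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        res = pcoa(dm)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g), abs=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(Exception):
            DistanceMatrix([[0, 1], [2, 0]], ids=["a", "b"])


class TestSpatialMedian:
    def test_unit_square_median_at_center(self):
        dm = euclidean_dm(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        res = pcoa(dm)
        med_real, med_imag = spatial_median(res)
        d = [
            distance_to_median((res.real[i], res.imag[i]), (med_real, med_imag))
            for i in range(4)
        ]
        np.testing.assert_allclose(d, np.full(4, np.sqrt(2) / 2), atol=1e-8)

    def test_single_point_returns_itself(self):
        pts = np.array([[2.0, 3.0]])
        np.testing.assert_allclose(_weiszfeld(pts), [2, 3])

    def test_two_points_return_midpoint(self):
        pts = np.array([[0.0, 0.0], [2.0, 4.0]])
        np.testing.assert_allclose(_weiszfeld(pts), [1, 2])

    def test_matches_grid_search_oracle(self, rng):
        """Weiszfeld objective within 1e-4 of a fine-grid geometric median."""

        def objective(y, pts):
            return np.linalg.norm(pts - y, axis=1).sum()

        for _ in range(5):
            pts = rng.random((5, 2))
            med = _weiszfeld(pts)
            lo, hi = pts.min() - 0.05, pts.max() + 0.05
            grid = np.linspace(lo, hi, 201)
            xx, yy = np.meshgrid(grid, grid)
            cand = np.column_stack([xx.ravel(), yy.ravel()])
            dists = np.linalg.norm(
                pts[None, :, :] - cand[:, None, :], axis=2
            ).sum(axis=1)
            assert objective(med, pts) <= dists.min() + 1e-4


class TestDistanceToMedian:
    def test_plain_euclidean_without_imaginary_axes(self):
        z = distance_to_median(
            (np.array([1.0, 0.0]), np.zeros(0)), (np.array([0.0, 0.0]), np.zeros(0))
        )
        assert z == pytest.approx(1.0)

    def test_subtractive_metric(self):
        z = distance_to_median(
            (np.array([0.5]), np.array([0.3])), (np.array([0.0]), np.array([0.0]))
        )
        assert z == pytest.approx(0.4)

    def test_clamps_to_zero_when_imaginary_dominates(self):
        z = distance_to_median(
            (np.array([0.3]), np.array([0.3])), (np.array([0.0]), np.array([0.0]))
        )
        assert z == 0.0

    def test_axis_mismatch_errors(self):
        with pytest.raises(ValueError, match="axis structure"):
            distance_to_median(
                (np.array([1.0]), np.zeros(0)), (np.array([1.0, 2.0]), np.zeros(0))
            )


class TestBiasAdjust:
    def test_formula_and_limits(self):
        assert bias_adjust(np.array([0.5]), 2)[0] == pytest.approx(0.70711, abs=1e-5)
        assert bias_adjust(np.array([0.5]), 1000)[0] == pytest.approx(0.5, abs=1e-3)
        assert bias_adjust(np.array([0.0]), 7)[0] == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            bias_adjust(np.array([0.5]), 1)


class TestGroupDispersion:
    def test_identical_samples_give_zero_beta(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        out = group_dispersion(dm, {"a": "g", "b": "g"}, sqrt_dist=False, bias=False)
        assert out.results["g"].beta == 0

    def test_unit_square_betas(self):
        dm = euclidean_dm(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        groups = {i: "g" for i in dm.ids}
        plain = group_dispersion(dm, groups, sqrt_dist=False, bias=False)
        assert plain.results["g"].beta == pytest.approx(np.sqrt(2) / 2, abs=1e-8)
        adj = group_dispersion(dm, groups, sqrt_dist=False, bias=True)
        assert adj.results["g"].beta == pytest.approx(
            np.sqrt(2) / 2 * np.sqrt(4 / 3), abs=1e-8
        )

    def test_matches_direct_geometry_for_euclidean_clouds(self, rng):
        """Ordination route equals dispersion in original coordinates."""
        for _ in range(5):
            pts = rng.random((9, 3))
            labels = ["g1"] * 4 + ["g2"] * 5
            dm = euclidean_dm(pts)
            out = group_dispersion(
                dm, dict(zip(dm.ids, labels)), sqrt_dist=False, bias=False
            )
            for g, idx in (("g1", range(4)), ("g2", range(4, 9))):
                sub = pts[list(idx)]
                med = _weiszfeld(sub)
                direct = np.linalg.norm(sub - med, axis=1).mean()
                assert out.results[g].beta == pytest.approx(direct, abs=1e-6)

    def test_distances_scale_linearly_with_dissimilarity(self, rng):
        t = random_count_table(rng, n_samples=6)
        dm = bray_curtis(t)
        scaled = DistanceMatrix(dm.data * 0.37, ids=dm.ids)
        groups = {i: "g" for i in dm.ids}
        a = group_dispersion(dm, groups, sqrt_dist=False, bias=False)
        b = group_dispersion(scaled, groups, sqrt_dist=False, bias=False)
        np.testing.assert_allclose(
            b.results["g"].distances, a.results["g"].distances * 0.37, atol=1e-8
        )

    def test_invariant_to_sample_order_and_label_renaming(self, rng):
        t = random_count_table(rng, n_samples=6)
        dm = bray_curtis(t)
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        out1 = group_dispersion(dm, groups)
        perm = [3, 0, 5, 1, 4, 2]
        dm2 = DistanceMatrix(
            dm.data[np.ix_(perm, perm)], ids=[dm.ids[i] for i in perm]
        )
        renamed = {k: v.lower() for k, v in groups.items()}
        out2 = group_dispersion(dm2, renamed)
        for g in ("A", "B"):
            assert out2.results[g.lower()].beta == pytest.approx(
                out1.results[g].beta, abs=1e-10
            )

    def test_singleton_group_skipped_with_warning(self):
        dm = euclidean_dm(np.array([[0, 0], [1, 0], [0, 1]], float))
        out = group_dispersion(
            dm, {"s0": "g", "s1": "g", "s2": "lonely"}, sqrt_dist=False
        )
        assert "lonely" in out.skipped
        assert "lonely" not in out.results


class TestVeganCrossCheck:
    def test_agrees_with_vegan_betadisper(self, tmp_path, rng):
        """Independent oracle: vegan's betadisper with spatial medians,
        sqrt-transformed Bray-Curtis, and the n/(n-1) bias adjustment."""
        X = rng.integers(0, 50, (10, 5)).astype(float) + rng.random((10, 5))
        ids = [f"s{i}" for i in range(10)]
        labels = ["g1"] * 5 + ["g2"] * 5
        np.savetxt(tmp_path / "X.tsv", X, delimiter="\t")
        (tmp_path / "grp.txt").write_text("\n".join(labels) + "\n")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            X <- as.matrix(read.table(args[1], sep='\t'))
            grp <- factor(readLines(args[2]))
            bd <- betadisper(vegdist(X, method='bray'), grp, type='median',
                             bias.adjust=TRUE, sqrt.dist=TRUE)
            cat(sprintf('%.10f', tapply(bd$distances, grp, mean)), sep='\n')
            """
        )
        (tmp_path / "check.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "check.R"), str(tmp_path / "X.tsv"),
             str(tmp_path / "grp.txt")],
            capture_output=True,
            text=True,
            check=True,
        )
        vegan_betas = [float(x) for x in out.stdout.split()]
        t = CountTable(pd.DataFrame(X, index=ids, columns=list("ABCDE")))
        disp = group_dispersion(
            bray_curtis(t), dict(zip(ids, labels)), sqrt_dist=True, bias=True
        )
        ours = [disp.results["g1"].beta, disp.results["g2"].beta]
        np.testing.assert_allclose(ours, vegan_betas, atol=1e-6)
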