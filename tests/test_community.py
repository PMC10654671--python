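import shutil
import subprocess

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from methanocycle.abundance import AbundanceProfile, aggregate_by_rank, site_profiles
from methanocycle.community import DissimilarityMatrix, bray_curtis, nmds
from methanocycle.tables_io import TableValidationError


def profile(site, **entries):
    return AbundanceProfile(site_id=site, rank="family", entries=entries)


def bc_oracle(x, y):
    """Independent elementwise Bray-Curtis."""
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


class TestBrayCurtis:
    def test_identical_profiles_have_zero_distance(self):
        d = bray_curtis([profile("a", F1=60, F2=40), profile("b", F1=60, F2=40)])
        assert d.values[0, 1] == 0

    def test_disjoint_supports_are_maximally_dissimilar(self):
        d = bray_curtis([profile("a", F1=100), profile("b", F2=100)])
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_closed_form_half(self):
        d = bray_curtis([profile("a", F1=100, F2=0), profile("b", F1=50, F2=50)])
        assert d.values[0, 1] == pytest.approx(0.5)

    def test_matches_elementwise_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2)
        taxa = [f"F{i}" for i in range(12)]
        profiles = []
        raw = []
        for s in range(6):
            x = rng.random(12) * 10
            raw.append(x)
            profiles.append(profile(f"s{s}", **dict(zip(taxa, x))))
        d = bray_curtis(profiles)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        for i in range(6):
            for j in range(6):
                assert d.values[i, j] == pytest.approx(bc_oracle(raw[i], raw[j]))

    def test_two_all_zero_profiles_rejected(self):
        with pytest.raises(TableValidationError):
            bray_curtis([profile("a", F1=0), profile("b", F1=0), profile("c", F1=5)])

    def test_union_feature_space_fills_absent_taxa_with_zero(self):
        d = bray_curtis([profile("a", F1=50, F2=50), profile("b", F1=50, F3=50)])
        assert d.values[0, 1] == pytest.approx(0.5)


def unit_square_matrix():
    pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    return DissimilarityMatrix(ids=list("abcd"), values=squareform(pdist(pts)))


class TestNmds:
    def test_exactly_embeddable_distances_reach_near_zero_stress(self):
        result = nmds(unit_square_matrix(), k=2, n_restarts=20, seed=0, tol=1e-14, max_iter=2000)
        assert result.stress < 1e-6

    def test_same_seed_gives_identical_coordinates(self):
        a = nmds(unit_square_matrix(), k=2, n_restarts=5, seed=42)
        b = nmds(unit_square_matrix(), k=2, n_restarts=5, seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_coordinates_centered(self):
        result = nmds(unit_square_matrix(), k=2, n_restarts=3, seed=1)
        assert np.allclose(result.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_stress_non_increasing_within_restart(self):
        d = _random_distance_matrix(seed=5, n=9)
        result = nmds(d, k=2, n_restarts=4, seed=7)
        trace = result.stress_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_best_of_restarts_optimality(self):
        d = _random_distance_matrix(seed=6, n=9)
        result = nmds(d, k=2, n_restarts=8, seed=3)
        assert result.stress == min(result.restart_stresses)

    def test_invariant_under_monotone_transform_of_dissimilarities(self):
        d = _random_distance_matrix(seed=8, n=8)
        squared = DissimilarityMatrix(ids=d.ids, values=d.values**2)
        a = nmds(d, k=2, n_restarts=5, seed=9)
        b = nmds(squared, k=2, n_restarts=5, seed=9)
        assert a.stress == pytest.approx(b.stress, abs=1e-12)
        assert np.allclose(a.coordinates, b.coordinates)

    def test_asymmetric_matrix_rejected(self):
        bad = unit_square_matrix()
        bad.values[0, 1] += 0.2
        with pytest.raises(TableValidationError):
            nmds(bad, k=2)


def _random_distance_matrix(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.random((n, 5)) * 10
    return DissimilarityMatrix(
        ids=[f"s{i}" for i in range(n)],
        values=squareform(pdist(x, metric="braycurtis")),
    )


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_stress_agrees_with_vegan_metaMDS(tmp_path):
    """Independent oracle: the vegan package's NMDS on the same matrix."""
    d = _random_distance_matrix(seed=0, n=7)
    ours = nmds(d, k=2, n_restarts=20, seed=3)
    mat_path = tmp_path / "dmat.tsv"
    np.savetxt(mat_path, d.values, delimiter="\t")
    script = tmp_path / "nmds.R"
    script.write_text(
        "suppressMessages(library(vegan))\n"
        f'd <- as.dist(as.matrix(read.table("{mat_path}", sep="\\t")))\n'
        "set.seed(1)\n"
        "m <- metaMDS(d, k=2, trace=0)\n"
        'cat(m$stress, "\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    vegan_stress = float(out.stdout.strip().split()[-1])
    assert ours.stress == pytest.approx(vegan_stress, abs=0.01)


def test_family_profiles_separate_site_groups(study_bundle):
    """Old-pool and new-pool sites should split along the first axis."""
    profiles = [
        aggregate_by_rank(p, study_bundle.taxonomy, "family")
        for p in site_profiles(study_bundle.coverage).values()
    ]
    result = nmds(bray_curtis(sorted(profiles, key=lambda p: p.site_id)), k=2, n_restarts=10, seed=2)
    coords = dict(zip(result.ids, result.coordinates[:, 0]))
    older = {"A", "B", "C", "D1"}
    old_vals = [v for s, v in coords.items() if s in older]
    new_vals = [v for s, v in coords.items() if s not in older]
    assert max(old_vals) < min(new_vals) or min(old_vals) > max(new_vals)
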