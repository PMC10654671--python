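import numpy as np
import pytest

from methanocycle.simulate import (
    SimulationConfig,
    SiteSpec,
    class_recovery_probability,
    default_config,
    degrade,
    expected_recovery,
    generate,
    measure_recovery,
    synthetic_study_reports,
)
from methanocycle.tables_io import validate_pathways


def test_same_seed_gives_byte_identical_tables(tmp_path):
    cfg = default_config(seed=5, n_sites=2, n_mags=40)
    for name in ("one", "two"):
        generate(cfg).write(tmp_path / name)
    for f in (tmp_path / "one").iterdir():
        assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()


def test_noise_free_labels_fully_recovered(small_bundle):
    overall, per_class = measure_recovery(small_bundle)
    assert overall == 1.0
    assert all(v == 1.0 for v in per_class.values())


def test_single_mag_site_has_total_abundance():
    from methanocycle.abundance import site_profiles

    cfg = SimulationConfig(seed=1, sites=(SiteSpec("solo", 1, guild_counts={"strict": 1}),))
    bundle = generate(cfg)
    profiles = site_profiles(bundle.coverage)
    assert list(profiles["solo"].entries.values()) == [100.0]


def test_generated_tables_pass_validation(small_bundle):
    validate_pathways(small_bundle.pathways)
    assert (small_bundle.annotations["scaffold_length"] >= 0).all()
    assert (small_bundle.coverage["coverage"] >= 0).all()
    assert not small_bundle.coverage.duplicated(["mag_id", "scaffold_id"]).any()
    # scaffold lengths respect the 2.5 kbp assembly inclusion floor
    assert (small_bundle.annotations["scaffold_length"] >= 2500).all()


def test_infeasible_guild_mix_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        SiteSpec("s", 5, guild_counts={"strict": 10}).counts()


class TestDegrade:
    def test_zero_noise_is_identity(self, small_bundle):
        out = degrade(small_bundle, 0.0, seed=3)
        assert out.annotations.equals(small_bundle.annotations)

    def test_full_drop_turns_high_hydro_mags_into_excluded(self, small_bundle):
        from methanocycle.methanogens import classify_methanogens

        out = degrade(small_bundle, 1.0, seed=3)
        assert out.annotations.empty
        calls = classify_methanogens(out.annotations, out.pathways, out.taxonomy)
        truth = small_bundle.truth
        # every non-ANME MAG planted with a >=75% hydro pathway now lacks mcr
        high_hydro = set(
            truth[truth["guild"].isin(["strict", "acetoclastic", "broad", "mcr_lacking"])]["mag_id"]
        )
        got = dict(zip(calls["mag_id"], calls["label"]))
        assert {m: got.get(m) for m in high_hydro} == {m: "EXCLUDED_NO_MCR" for m in high_hydro}

    def test_recovery_monotone_non_increasing_in_noise(self):
        cfg = default_config(seed=21, n_sites=1, n_mags=120)
        bundle = generate(cfg)
        means = []
        for noise in (0.0, 0.1, 0.3, 0.6):
            rates = [
                measure_recovery(degrade(bundle, noise, seed=50 + s))[0] for s in range(5)
            ]
            means.append(float(np.mean(rates)))
        for a, b in zip(means, means[1:]):
            assert b <= a + 0.02  # Monte-Carlo slack


class TestAnalyticRecovery:
    def test_enumeration_matches_hand_derived_closed_forms(self):
        p = 0.05
        closed_forms = {
            "strict": 1 - p**3,
            "acetoclastic": (1 - p**2) * (1 - p),
            "methylotrophic": (1 - p) ** 2,
            "methylthiol": (1 - p) ** 2,
            "broad": (1 - p) ** 2 * (1 - p**2),
            "mcr_lacking": 1.0,
            "anme": 1.0,
            "methanotroph_pmo": 1 - p,
            "methanotroph_mmo": 1 - p,
            "methanotroph_both": (1 - p) ** 2,
            "acetogen_I": (1 - p) ** 2,
            "acetogen_II": (1 - p) ** 2,
            "acetogen_III": 1.0,
            "acetogen_IV": (1 - p) ** 2,
            "background": 1.0,
        }
        for guild, expected in closed_forms.items():
            assert class_recovery_probability(guild, p) == pytest.approx(expected, abs=1e-12)

    def test_expected_recovery_is_planted_weighted_mean(self):
        cfg = default_config(seed=1, n_sites=1, n_mags=100)
        assert expected_recovery(cfg, 0.0) == 1.0
        assert 0.9 < expected_recovery(cfg, 0.05) < 1.0


class TestSyntheticStudyReports:
    def test_planted_occurrence_counts_round_trip(self):
        from methanocycle.occurrence import load_synonym_map, occurrence_counts, presence_matrix

        reports = synthetic_study_reports(seed=4)
        matrix = presence_matrix(reports, load_synonym_map())
        assert matrix.shape[1] == 20  # discarded studies never become columns
        counts = dict(
            zip(*(occurrence_counts(matrix)[c] for c in ("family", "count")))
        )
        assert counts["Methanosarcinaceae"] == 17
        assert counts["Methanotrichaceae"] == 15

    def test_deterministic_under_seed(self):
        a = synthetic_study_reports(seed=9)
        b = synthetic_study_reports(seed=9)
        assert a.equals(b)
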