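from fractions import Fraction

import pytest

from methanocycle.methanogens import (
    MethanogenFeatures,
    audit_rule_overlap,
    classify_guild,
    classify_methanogens,
    identify_putative_methanogens,
)
from methanocycle.tables_io import RuleThresholds


def feats(**kw) -> MethanogenFeatures:
    kw.setdefault("mag_id", "m")
    if "methyl_substrates" in kw:
        kw["methyl_substrates"] = frozenset(kw["methyl_substrates"])
    return MethanogenFeatures(**kw)


class TestIdentification:
    def part(self, f):
        return identify_putative_methanogens([f], RuleThresholds()).get(f.mag_id)

    def test_mcrA_alone_is_candidate(self):
        assert self.part(feats(has_mcrA=True, hydro=Fraction(2, 8))) == "candidate"

    def test_high_hydro_with_mcrB_is_candidate(self):
        assert self.part(feats(has_mcrB=True, hydro=Fraction(6, 8))) == "candidate"

    def test_high_hydro_without_any_mcr_is_excluded(self):
        assert self.part(feats(hydro=Fraction(7, 8))) == "EXCLUDED_NO_MCR"

    def test_anme_family_rerouted_regardless_of_machinery(self):
        f = feats(has_mcrA=True, hydro=Fraction(7, 8), family="Methanoperedenaceae")
        assert self.part(f) == "REROUTED_ANME"

    def test_six_of_eight_meets_the_75_percent_bar(self):
        # the 6/8-steps equivalence forces an inclusive threshold
        assert self.part(feats(has_mcrG=True, hydro=Fraction(6, 8))) == "candidate"

    def test_low_hydro_no_mcr_is_not_a_methanogen(self):
        assert self.part(feats(hydro=Fraction(2, 8))) is None


class TestGuildRules:
    @pytest.mark.parametrize(
        "kw,label",
        [
            (dict(has_mcrA=True, hydro=Fraction(7, 8)), "STRICT_HYDROGENOTROPH"),
            (
                dict(has_mcrA=True, hydro=Fraction(7, 8), codh_acs=Fraction(2, 2), has_acs=True),
                "ACETOCLASTIC",
            ),
            (
                dict(has_mcrA=True, hydro=Fraction(3, 8), methyl_substrates={"methanol"}),
                "METHYLOTROPHIC",
            ),
            (
                dict(
                    has_mcrA=True,
                    hydro=Fraction(8, 8),
                    codh_acs=Fraction(2, 2),
                    has_acs=True,
                    methyl_substrates={"methanol", "trimethylamine"},
                ),
                "BROAD_SUBSTRATE",
            ),
            # CODH/ACS at 1/2 is not "> 50%": not acetoclastic, not strict either
            (
                dict(has_mcrA=True, hydro=Fraction(7, 8), codh_acs=Fraction(1, 2), has_acs=True),
                "UNRESOLVED_METHANOGEN",
            ),
        ],
    )
    def test_rule_forced_labels(self, kw, label):
        assert classify_guild(feats(**kw)).label == label

    def test_methylthiol_homolog_flags_methylotroph(self):
        call = classify_guild(feats(has_mcrA=True, hydro=Fraction(2, 8), has_mtsA=True))
        assert call.label == "METHYLOTROPHIC"
        assert call.methylthiol_flag
        assert "methylthiol_transferase" in call.evidence

    def test_regular_methyl_substrate_does_not_flag_methylthiol(self):
        call = classify_guild(
            feats(has_mcrA=True, hydro=Fraction(2, 8), methyl_substrates={"methanol"})
        )
        assert call.label == "METHYLOTROPHIC"
        assert not call.methylthiol_flag

    def test_acetate_activation_via_kinase_pair(self):
        f = feats(
            has_mcrB=True,
            hydro=Fraction(7, 8),
            codh_acs=Fraction(2, 2),
            has_ack_and_acyltx=True,
        )
        assert classify_guild(f).label == "ACETOCLASTIC"

    def test_idempotent_and_deterministic(self):
        f = feats(has_mcrA=True, hydro=Fraction(7, 8))
        first = classify_guild(f)
        second = classify_guild(f)
        assert (first.label, first.evidence) == (second.label, second.evidence)


class TestRuleOverlapAudit:
    def test_only_two_rule_pairs_can_fire_together(self):
        overlap = audit_rule_overlap()
        assert set(overlap) == {
            frozenset({"BROAD_SUBSTRATE", "ACETOCLASTIC"}),
            frozenset({"METHYLOTROPHIC", "STRICT_HYDROGENOTROPH"}),
        }

    def test_overlap_cell_counts_stable(self):
        overlap = audit_rule_overlap()
        # frozen from combinatorics: broad implies the acetoclastic predicate
        # (1 mcrA x 16 other-mcr x 3 hydro x 1 codh x 3 acetate x 15 methyl x 4
        # mts/mta = 8640); methylotroph/strict co-fire needs mcrA, codh absent,
        # hydro < 1/2, no acetate, any methyl evidence (16 x 4 x 1 x 1 x 63 = 4032)
        assert overlap[frozenset({"BROAD_SUBSTRATE", "ACETOCLASTIC"})] == 8640
        assert overlap[frozenset({"METHYLOTROPHIC", "STRICT_HYDROGENOTROPH"})] == 4032


def test_planted_labels_recovered_on_tables(small_bundle):
    calls = classify_methanogens(
        small_bundle.annotations, small_bundle.pathways, small_bundle.taxonomy
    )
    got = dict(zip(calls["mag_id"], calls["label"]))
    truth = small_bundle.truth
    expected = {
        row.mag_id: row.methanogen_label for row in truth.itertuples() if row.methanogen_label
    }
    assert expected == {m: got[m] for m in expected}
    # nothing else was called
    assert set(got) == set(expected)
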