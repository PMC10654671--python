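"""Methanogen identification and guild classification.

A MAG is a putative methanogen candidate when it carries *mcrA*, or when its
hydrogenotrophic-methanogenesis pathway is at least 75 % complete and it
carries any other gene of the *mcr* operon (*mcrBCDG*). MAGs with a
near-complete hydrogenotrophic pathway but no *mcr* gene at all are flagged
and excluded (they plausibly run the pathway in reverse or for carbon
fixation). MAGs in the ANME family *Methanoperedenaceae* are rerouted to the
methanotroph analysis regardless of their methanogenesis machinery.

Candidates receive exactly one of four guild labels, first match wins:

1. broad-substrate — *mcrA*, acetate activation, CODH/ACS > 50 %,
   hydrogenotrophic >= 75 %, and at least one methylamine/methanol
   methyltransferase: the generalist profile.
2. methylotrophic — *mcrA* plus a methyl-substrate transferase (or a
   methylthiol transferase, *mtsA*/*mtaA*), with no CODH/ACS step present and
   a hydrogenotrophic pathway below 50 %, so only methylated substrates can
   feed methane production.
3. acetoclastic — an *mcr* gene, acetate activation, CODH/ACS > 50 % and
   hydrogenotrophic >= 75 % (CO from acetyl-CoA dismutation is oxidized to
   CO2 and reduced through the hydrogenotrophic pathway).
4. strictly hydrogenotrophic — candidate machinery with no CODH/ACS step and
   no acetate activation: CO2 + H2 is the only route to methane.

Candidates matching none of these keep an UNRESOLVED label with the
partially-fired predicates as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

import pandas as pd

from .tables_io import (
    DEFAULT_PATHWAY_STEPS,
    RuleThresholds,
    pathway_fractions,
)

ANME_FAMILY = "Methanoperedenaceae"

METHYL_GENE_SUBSTRATE = {
    "mtaB": "methanol",
    "mttB": "trimethylamine",
    "mtbB": "dimethylamine",
    "mtmB": "methylamine",
}

LABELS = (
    "STRICT_HYDROGENOTROPH",
    "ACETOCLASTIC",
    "METHYLOTROPHIC",
    "BROAD_SUBSTRATE",
    "UNRESOLVED_METHANOGEN",
    "EXCLUDED_NO_MCR",
    "REROUTED_ANME",
)


@dataclass(frozen=True)
class MethanogenFeatures:
    """Deterministic per-MAG evidence for the methanogen rules."""

    mag_id: str
    has_mcrA: bool = False
    has_mcrB: bool = False
    has_mcrC: bool = False
    has_mcrD: bool = False
    has_mcrG: bool = False
    hydro: Fraction = Fraction(0, 8)
    codh_acs: Fraction = Fraction(0, 2)
    has_acs: bool = False
    has_ack_and_acyltx: bool = False
    methyl_substrates: frozenset[str] = frozenset()
    has_mtsA: bool = False
    has_mtaA: bool = False
    family: str = ""

    @property
    def any_mcr_bcdg(self) -> bool:
        return self.has_mcrB or self.has_mcrC or self.has_mcrD or self.has_mcrG

    @property
    def any_mcr(self) -> bool:
        return self.has_mcrA or self.any_mcr_bcdg

    @property
    def acetate_activation(self) -> bool:
        return self.has_acs or self.has_ack_and_acyltx


@dataclass
class GuildCall:
    mag_id: str
    label: str
    methylthiol_flag: bool = False
    evidence: list[str] = field(default_factory=list)


def build_features(
    annotations: pd.DataFrame,
    pathways: pd.DataFrame,
    taxonomy: pd.DataFrame,
) -> list[MethanogenFeatures]:
    """Derive one feature record per MAG from the three input tables."""
    mag_ids = sorted(
        set(annotations["mag_id"]) | set(pathways["mag_id"]) | set(taxonomy["mag_id"])
    )
    genes = {
        str(m): frozenset(sub["gene_symbol"])
        for m, sub in annotations.groupby("mag_id")
    }
    fractions = pathway_fractions(pathways, mag_ids)
    family = dict(zip(taxonomy["mag_id"], taxonomy["family"].fillna("")))
    out = []
    for mag in mag_ids:
        g = genes.get(mag, frozenset())
        f = fractions.get(mag, {})
        hydro = f.get(
            "HYDROGENOTROPHIC_METHANOGENESIS",
            Fraction(0, DEFAULT_PATHWAY_STEPS["HYDROGENOTROPHIC_METHANOGENESIS"]),
        )
        codh = f.get("CODH_ACS", Fraction(0, DEFAULT_PATHWAY_STEPS["CODH_ACS"]))
        out.append(
            MethanogenFeatures(
                mag_id=mag,
                has_mcrA="mcrA" in g,
                has_mcrB="mcrB" in g,
                has_mcrC="mcrC" in g,
                has_mcrD="mcrD" in g,
                has_mcrG="mcrG" in g,
                hydro=hydro,
                codh_acs=codh,
                has_acs="acs" in g,
                has_ack_and_acyltx="ack" in g and ("act" in g or "pta" in g),
                methyl_substrates=frozenset(
                    sub for gene, sub in METHYL_GENE_SUBSTRATE.items() if gene in g
                ),
                has_mtsA="mtsA" in g,
                has_mtaA="mtaA" in g,
                family=str(family.get(mag, "") or ""),
            )
        )
    return out


def identify_putative_methanogens(
    features: list[MethanogenFeatures], thresholds: RuleThresholds | None = None
) -> dict[str, str]:
    """Partition MAGs into candidate / EXCLUDED_NO_MCR / REROUTED_ANME.

    MAGs matching none of the three outcomes are not methanogens and are
    absent from the returned mapping.
    """
    thresholds = thresholds or RuleThresholds()
    out: dict[str, str] = {}
    for f in features:
        if f.family == ANME_FAMILY:
            out[f.mag_id] = "REROUTED_ANME"
        elif f.has_mcrA or (f.hydro >= thresholds.hydro_min and f.any_mcr_bcdg):
            out[f.mag_id] = "candidate"
        elif f.hydro >= thresholds.hydro_min and not f.any_mcr:
            out[f.mag_id] = "EXCLUDED_NO_MCR"
    return out


def classify_guild(
    f: MethanogenFeatures, thresholds: RuleThresholds | None = None
) -> GuildCall:
    """Assign one guild label to a candidate; first matching rule wins."""
    t = thresholds or RuleThresholds()
    methyl_evidence = bool(f.methyl_substrates) or f.has_mtsA or f.has_mtaA
    methylthiol_only = (f.has_mtsA or f.has_mtaA) and not f.methyl_substrates

    if (
        f.has_mcrA
        and f.acetate_activation
        and f.codh_acs > t.codh_acs_min
        and f.hydro >= t.hydro_min
        and len(f.methyl_substrates) >= 1
    ):
        return GuildCall(
            f.mag_id,
            "BROAD_SUBSTRATE",
            evidence=[
                "mcrA",
                "acetate_activation",
                "codh_acs_gt_min",
                "hydro_ge_min",
                "methyl_substrates",
            ],
        )
    if (
        f.has_mcrA
        and methyl_evidence
        and f.codh_acs == 0
        and f.hydro < t.hydro_low_max
    ):
        ev = ["mcrA", "codh_acs_absent", "hydro_low"]
        ev.insert(1, "methylthiol_transferase" if methylthiol_only else "methyl_substrates")
        return GuildCall(
            f.mag_id, "METHYLOTROPHIC", methylthiol_flag=methylthiol_only, evidence=ev
        )
    if (
        f.any_mcr
        and f.acetate_activation
        and f.codh_acs > t.codh_acs_min
        and f.hydro >= t.hydro_min
    ):
        return GuildCall(
            f.mag_id,
            "ACETOCLASTIC",
            evidence=["mcr_gene", "acetate_activation", "codh_acs_gt_min", "hydro_ge_min"],
        )
    if (
        (f.has_mcrA or (f.hydro >= t.hydro_min and f.any_mcr_bcdg))
        and f.codh_acs == 0
        and not f.acetate_activation
    ):
        return GuildCall(
            f.mag_id,
            "STRICT_HYDROGENOTROPH",
            evidence=["mcr_gene", "codh_acs_absent", "no_acetate_activation"],
        )
    partial = []
    if f.any_mcr:
        partial.append("mcr_gene")
    if f.acetate_activation:
        partial.append("acetate_activation")
    if methyl_evidence:
        partial.append("methyl_evidence")
    if f.hydro >= t.hydro_min:
        partial.append("hydro_ge_min")
    if f.codh_acs > 0:
        partial.append("codh_acs_present")
    return GuildCall(f.mag_id, "UNRESOLVED_METHANOGEN", evidence=partial or ["none"])


def classify_methanogens(
    annotations: pd.DataFrame,
    pathways: pd.DataFrame,
    taxonomy: pd.DataFrame,
    thresholds: RuleThresholds | None = None,
) -> pd.DataFrame:
    """Full methanogen stage: identification then guild assignment.

    Returns one row per MAG that is a candidate, excluded, or rerouted, with
    columns mag_id, label, methylthiol_flag, evidence (semicolon list).
    """
    thresholds = thresholds or RuleThresholds()
    features = build_features(annotations, pathways, taxonomy)
    by_mag = {f.mag_id: f for f in features}
    partition = identify_putative_methanogens(features, thresholds)
    rows = []
    for mag_id in sorted(partition):
        status = partition[mag_id]
        if status == "candidate":
            call = classify_guild(by_mag[mag_id], thresholds)
        elif status == "EXCLUDED_NO_MCR":
            call = GuildCall(mag_id, "EXCLUDED_NO_MCR", evidence=["hydro_ge_min", "no_mcr_gene"])
        else:
            call = GuildCall(mag_id, "REROUTED_ANME", evidence=["family_methanoperedenaceae"])
        rows.append(
            (call.mag_id, call.label, call.methylthiol_flag, ";".join(call.evidence))
        )
    return pd.DataFrame(rows, columns=["mag_id", "label", "methylthiol_flag", "evidence"])


# ---------------------------------------------------------------------------
# rule-overlap audit


def _rule_predicates(f: MethanogenFeatures, t: RuleThresholds) -> dict[str, bool]:
    methyl_evidence = bool(f.methyl_substrates) or f.has_mtsA or f.has_mtaA
    return {
        "BROAD_SUBSTRATE": (
            f.has_mcrA
            and f.acetate_activation
            and f.codh_acs > t.codh_acs_min
            and f.hydro >= t.hydro_min
            and len(f.methyl_substrates) >= 1
        ),
        "METHYLOTROPHIC": (
            f.has_mcrA and methyl_evidence and f.codh_acs == 0 and f.hydro < t.hydro_low_max
        ),
        "ACETOCLASTIC": (
            f.any_mcr
            and f.acetate_activation
            and f.codh_acs > t.codh_acs_min
            and f.hydro >= t.hydro_min
        ),
        "STRICT_HYDROGENOTROPH": (
            (f.has_mcrA or (f.hydro >= t.hydro_min and f.any_mcr_bcdg))
            and f.codh_acs == 0
            and not f.acetate_activation
        ),
    }


def enumerate_feature_grid() -> list[MethanogenFeatures]:
    """Every cell of the boolean/step-count methanogen feature grid.

    5 mcr booleans x hydro 0..8 x CODH/ACS 0..2 x 2 acetate booleans x
    4 methyl-substrate booleans x mtsA/mtaA: 221,184 cells.
    """
    cells = []
    substrates = tuple(METHYL_GENE_SUBSTRATE.values())
    for mcr_bits in product((False, True), repeat=5):
        for hydro_steps in range(9):
            for codh_steps in range(3):
                for acs_bit, ackacyl_bit in product((False, True), repeat=2):
                    for methyl_bits in product((False, True), repeat=4):
                        for mtsA_bit, mtaA_bit in product((False, True), repeat=2):
                            cells.append(
                                MethanogenFeatures(
                                    mag_id="grid",
                                    has_mcrA=mcr_bits[0],
                                    has_mcrB=mcr_bits[1],
                                    has_mcrC=mcr_bits[2],
                                    has_mcrD=mcr_bits[3],
                                    has_mcrG=mcr_bits[4],
                                    hydro=Fraction(hydro_steps, 8),
                                    codh_acs=Fraction(codh_steps, 2),
                                    has_acs=acs_bit,
                                    has_ack_and_acyltx=ackacyl_bit,
                                    methyl_substrates=frozenset(
                                        s for s, b in zip(substrates, methyl_bits) if b
                                    ),
                                    has_mtsA=mtsA_bit,
                                    has_mtaA=mtaA_bit,
                                )
                            )
    return cells


def audit_rule_overlap(
    thresholds: RuleThresholds | None = None,
) -> dict[frozenset[str], int]:
    """Which rule pairs can fire together, and on how many grid cells.

    The first-match precedence only matters on these overlap cells; the audit
    makes the affected set explicit so it can be asserted stable.
    """
    t = thresholds or RuleThresholds()
    overlap: dict[frozenset[str], int] = {}
    for f in enumerate_feature_grid():
        fired = frozenset(k for k, v in _rule_predicates(f, t).items() if v)
        if len(fired) > 1:
            overlap[fired] = overlap.get(fired, 0) + 1
    return overlap
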