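"""Acetate-production categories.

Four overlapping categories capture routes to acetate:

* I  — methyl branch: Wood-Ljungdahl >= 6/7 steps plus phosphotransacetylase
  and acetate kinase.
* II — carbonyl branch: complete (2/2) CODH/ACS plus phosphotransacetylase
  and acetate kinase.
* III — WL >= 6/7 but lacking the pta/ack pair: flagged for curation.
* IV — pta + ack alone: acetate from acetyl-CoA without the WL or CODH/ACS
  proton-reducing steps.

All matching categories are reported; the primary label is the most specific
by the order I > II > IV (III is exclusive of I/II/IV by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product

import pandas as pd

from .tables_io import DEFAULT_PATHWAY_STEPS, RuleThresholds, pathway_fractions

CATEGORIES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class AcetogenFeatures:
    mag_id: str
    wl: Fraction = Fraction(0, 7)
    codh_acs: Fraction = Fraction(0, 2)
    has_pta: bool = False
    has_ack: bool = False


def build_features(
    annotations: pd.DataFrame, pathways: pd.DataFrame
) -> list[AcetogenFeatures]:
    mag_ids = sorted(set(annotations["mag_id"]) | set(pathways["mag_id"]))
    genes = {
        str(m): set(sub["gene_symbol"]) for m, sub in annotations.groupby("mag_id")
    }
    fractions = pathway_fractions(pathways, mag_ids)
    out = []
    for mag in mag_ids:
        g = genes.get(mag, set())
        f = fractions.get(mag, {})
        out.append(
            AcetogenFeatures(
                mag_id=mag,
                wl=f.get("WOOD_LJUNGDAHL", Fraction(0, DEFAULT_PATHWAY_STEPS["WOOD_LJUNGDAHL"])),
                codh_acs=f.get("CODH_ACS", Fraction(0, DEFAULT_PATHWAY_STEPS["CODH_ACS"])),
                has_pta="pta" in g,
                has_ack="ack" in g,
            )
        )
    return out


def classify_acetogen(
    f: AcetogenFeatures, thresholds: RuleThresholds | None = None
) -> tuple[set[str], str | None]:
    """All matching categories plus the deterministic primary label."""
    t = thresholds or RuleThresholds()
    pta_ack = f.has_pta and f.has_ack
    cats = set()
    if f.wl >= t.wl_min and pta_ack:
        cats.add("I")
    if f.codh_acs == 1 and pta_ack:
        cats.add("II")
    if f.wl >= t.wl_min and not pta_ack:
        cats.add("III")
    if pta_ack:
        cats.add("IV")
    primary = next((c for c in ("I", "II", "IV", "III") if c in cats), None)
    return cats, primary


def classify_acetogens(
    annotations: pd.DataFrame,
    pathways: pd.DataFrame,
    thresholds: RuleThresholds | None = None,
) -> pd.DataFrame:
    """Category table for every MAG with at least one matching category."""
    rows = []
    for f in build_features(annotations, pathways):
        cats, primary = classify_acetogen(f, thresholds)
        if cats:
            rows.append((f.mag_id, ",".join(sorted(cats)), primary))
    return pd.DataFrame(rows, columns=["mag_id", "categories", "primary"])


def enumerate_feature_grid() -> list[AcetogenFeatures]:
    """Full WL-steps x CODH-steps x pta x ack grid (96 cells)."""
    return [
        AcetogenFeatures(
            mag_id="grid",
            wl=Fraction(wl, 7),
            codh_acs=Fraction(codh, 2),
            has_pta=pta,
            has_ack=ack,
        )
        for wl in range(8)
        for codh in range(3)
        for pta, ack in product((False, True), repeat=2)
    ]
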