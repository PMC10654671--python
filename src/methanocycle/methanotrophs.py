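"""Methanotroph identification, pMMO/sMMO mode, and novel-family verification.

Aerobic (and intra-aerobic) methanotrophs are called from the presence of
*pmoA* and/or *mmoX*; MAGs in the ANME family *Methanoperedenaceae* are
called as anaerobic methanotrophs on taxonomy alone. Calls in families with
no prior record of methanotrophy must additionally show at least two
pMMO/sMMO-operon genes on scaffolds of >= 3 kbp each (per-scaffold
co-location is not required); calls failing that check are retained but
flagged unverified.

sMMO operon completeness is reported but never required — *mmoZ* is prone to
divergence and its absence does not disqualify an *mmoX*-based call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tables_io import (
    RuleThresholds,
    load_known_methanotroph_families,
    pathway_fractions,
)

ANME_FAMILY = "Methanoperedenaceae"
PMO_GENES = ("pmoA", "pmoB", "pmoC")
MMO_GENES = ("mmoX", "mmoY", "mmoZ")
MODES = ("PMO_ONLY", "MMO_ONLY", "BOTH", "ANME")


@dataclass
class MethanotrophFeatures:
    """Per-MAG pmo/mmo gene observations with their scaffold lengths."""

    mag_id: str
    family: str = ""
    known_methanotroph_family: bool = False
    # (gene_symbol, scaffold_id, scaffold_length) for pmo/mmo-operon genes
    marker_rows: list[tuple[str, str, int]] = field(default_factory=list)

    def has(self, gene: str) -> bool:
        return any(g == gene for g, _, _ in self.marker_rows)


@dataclass
class MethanotrophCall:
    mag_id: str
    mode: str
    verified: bool = True
    evidence: list[str] = field(default_factory=list)


def build_features(
    annotations: pd.DataFrame,
    taxonomy: pd.DataFrame,
    known_families: frozenset[str] | None = None,
) -> list[MethanotrophFeatures]:
    known = known_families if known_families is not None else load_known_methanotroph_families()
    family = dict(zip(taxonomy["mag_id"], taxonomy["family"].fillna("")))
    markers = annotations[annotations["gene_symbol"].isin(PMO_GENES + MMO_GENES)]
    rows_by_mag: dict[str, list[tuple[str, str, int]]] = {}
    for row in markers.itertuples():
        rows_by_mag.setdefault(str(row.mag_id), []).append(
            (row.gene_symbol, str(row.scaffold_id), int(row.scaffold_length))
        )
    mag_ids = sorted(set(annotations["mag_id"]) | set(taxonomy["mag_id"]))
    return [
        MethanotrophFeatures(
            mag_id=m,
            family=str(family.get(m, "") or ""),
            known_methanotroph_family=str(family.get(m, "") or "") in known,
            marker_rows=sorted(rows_by_mag.get(m, [])),
        )
        for m in mag_ids
    ]


def verify_novel_family(
    features: MethanotrophFeatures, thresholds: RuleThresholds | None = None
) -> bool:
    """Scaffold check for calls outside the known-methanotroph families.

    True iff at least ``min_verify_gene_count`` pmo/mmo-operon gene
    observations sit on scaffolds each at least ``min_verify_scaffold_bp``
    long; the qualifying genes may be spread over several scaffolds.
    """
    t = thresholds or RuleThresholds()
    qualifying = sum(
        1 for _, _, length in features.marker_rows if length >= t.min_verify_scaffold_bp
    )
    return qualifying >= t.min_verify_gene_count


def identify_methanotrophs(
    features: list[MethanotrophFeatures],
    thresholds: RuleThresholds | None = None,
) -> list[MethanotrophCall]:
    """Call methanotroph MAGs and assign their pMMO/sMMO mode."""
    t = thresholds or RuleThresholds()
    calls = []
    for f in features:
        if f.family == ANME_FAMILY:
            calls.append(
                MethanotrophCall(f.mag_id, "ANME", evidence=["family_methanoperedenaceae"])
            )
            continue
        has_pmoA, has_mmoX = f.has("pmoA"), f.has("mmoX")
        if not has_pmoA and not has_mmoX:
            continue
        mode = "BOTH" if (has_pmoA and has_mmoX) else ("PMO_ONLY" if has_pmoA else "MMO_ONLY")
        evidence = [g for g, flag in (("pmoA", has_pmoA), ("mmoX", has_mmoX)) if flag]
        verified = True
        if not f.known_methanotroph_family:
            verified = verify_novel_family(f, t)
            evidence.append("novel_family_verified" if verified else "novel_family_unverified")
        calls.append(MethanotrophCall(f.mag_id, mode, verified=verified, evidence=evidence))
    return calls


def calls_to_frame(calls: list[MethanotrophCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.mag_id, c.mode, c.verified, ";".join(c.evidence)) for c in calls],
        columns=["mag_id", "mode", "verified", "evidence"],
    )


def mode_counts(calls: list[MethanotrophCall]) -> dict[str, int]:
    """Tally of calls per mode; ANME counted separately from the aerobic modes."""
    out = {m: 0 for m in MODES}
    for c in calls:
        out[c.mode] += 1
    out["aerobic_total"] = out["PMO_ONLY"] + out["MMO_ONLY"] + out["BOTH"]
    return out


def trait_tallies(
    calls: list[MethanotrophCall],
    annotations: pd.DataFrame,
    pathways: pd.DataFrame,
    thresholds: RuleThresholds | None = None,
) -> dict[str, int]:
    """Redox-trait prevalence among the aerobic methanotroph calls.

    Counts MAGs with nitrite-reduction genes (*nirK*/*nirS*) and with high
    completion (>= ``trait_completion_min``) of the high- and low-affinity
    complex IV modules.
    """
    t = thresholds or RuleThresholds()
    aerobic = [c.mag_id for c in calls if c.mode in ("PMO_ONLY", "MMO_ONLY", "BOTH")]
    genes = {
        str(m): set(sub["gene_symbol"]) for m, sub in annotations.groupby("mag_id")
    }
    fractions = pathway_fractions(pathways, aerobic)
    tallies = {
        "aerobic_total": len(aerobic),
        "nitrite_reduction": 0,
        "complex_iv_high": 0,
        "complex_iv_low": 0,
    }
    for mag in aerobic:
        g = genes.get(mag, set())
        f = fractions.get(mag, {})
        if "nirK" in g or "nirS" in g:
            tallies["nitrite_reduction"] += 1
        if f.get("COMPLEX_IV_HIGH", 0) >= t.trait_completion_min:
            tallies["complex_iv_high"] += 1
        if f.get("COMPLEX_IV_LOW", 0) >= t.trait_completion_min:
            tallies["complex_iv_low"] += 1
    return tallies
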