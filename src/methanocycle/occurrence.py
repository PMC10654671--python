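"""Cross-study taxon harmonization and occurrence counts.

Published landfill surveys report methanogen taxa under decades of shifting
nomenclature (legacy species, genus, and family names across Greengenes,
SILVA, and NCBI releases). A versioned, human-editable synonym table maps
each legacy name to its GTDB family; names without a rule resolve to
``UNRESOLVED`` and never silently create a family. Studies whose reported
taxa all fail to resolve to family level or deeper are discarded. Presence
is liberal: any report of a resolvable taxon marks its family present in
that study.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

UNRESOLVED = "UNRESOLVED"

STUDY_COLUMNS = ["study_id", "method", "taxon_name", "rank_claimed"]


@dataclass
class SynonymMap:
    """Function from normalized legacy name to GTDB family."""

    mapping: dict[str, str]  # normalized legacy name -> family
    families: frozenset[str]  # codomain, for idempotence on current names

    @staticmethod
    def normalize(name: str) -> str:
        return " ".join(name.split()).casefold()


def load_synonym_map(path: str | Path | None = None) -> SynonymMap:
    if path is None:
        source = (
            importlib.resources.files("methanocycle.data")
            / "methanogen_family_synonyms.tsv"
        )
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, str] = {}
    for row in df.itertuples():
        key = SynonymMap.normalize(row.legacy_name)
        if key in mapping and mapping[key] != row.gtdb_family:
            raise ValueError(f"ambiguous synonym key: {row.legacy_name!r}")
        mapping[key] = row.gtdb_family
    return SynonymMap(mapping=mapping, families=frozenset(df["gtdb_family"]))


def harmonize(name: str, synonyms: SynonymMap, rank_claimed: str | None = None) -> str:
    """GTDB family for a reported taxon name, or UNRESOLVED.

    Exact lookup after whitespace/case normalization; a name already equal to
    a GTDB family in the table's codomain returns itself (idempotence).
    """
    key = SynonymMap.normalize(name)
    if not key:
        return UNRESOLVED
    for family in synonyms.families:
        if SynonymMap.normalize(family) == key:
            return family
    return synonyms.mapping.get(key, UNRESOLVED)


def presence_matrix(reports: pd.DataFrame, synonyms: SynonymMap) -> pd.DataFrame:
    """Boolean family x study matrix over retained studies.

    A study is retained only if at least one of its reported taxa harmonizes
    to a family; column order follows first appearance in the input.
    """
    for col in ("study_id", "taxon_name"):
        if col not in reports.columns:
            raise ValueError(f"study report table missing column '{col}'")
    resolved = reports.assign(
        family=[harmonize(n, synonyms) for n in reports["taxon_name"]]
    )
    hits = resolved[resolved["family"] != UNRESOLVED]
    retained = [s for s in reports["study_id"].unique() if s in set(hits["study_id"])]
    if not retained:
        raise ValueError("no study retained after harmonization")
    families = sorted(hits["family"].unique())
    matrix = pd.DataFrame(False, index=families, columns=retained)
    for row in hits.itertuples():
        matrix.loc[row.family, row.study_id] = True
    matrix.index.name = "family"
    return matrix


def occurrence_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-family occurrence count with the retained-study denominator."""
    if matrix.empty:
        raise ValueError("empty presence matrix")
    counts = matrix.sum(axis=1).astype(int)
    out = pd.DataFrame(
        {"family": matrix.index, "count": counts.values, "n_studies": matrix.shape[1]}
    )
    return out.sort_values(["count", "family"], ascending=[False, True], kind="mergesort").reset_index(drop=True)


def study_report_from_calls(
    methanogen_calls: pd.DataFrame,
    taxonomy: pd.DataFrame,
    study_id: str = "this_study",
    method: str = "metagenomics",
) -> pd.DataFrame:
    """Turn this pipeline's guild calls into an ordinary study report.

    Methanogen families (labelled candidates) and the ANME family enter the
    meta-analysis on the same footing as literature reports.
    """
    family = dict(zip(taxonomy["mag_id"], taxonomy["family"].fillna("")))
    keep = methanogen_calls[methanogen_calls["label"] != "EXCLUDED_NO_MCR"]
    names = sorted({family.get(m, "") for m in keep["mag_id"]} - {""})
    return pd.DataFrame(
        {
            "study_id": study_id,
            "method": method,
            "taxon_name": names,
            "rank_claimed": "family",
        },
        columns=STUDY_COLUMNS,
    )
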