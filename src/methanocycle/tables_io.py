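"""Readers, writers and validation for the pipeline's tabular inputs.

All tables are tab-separated UTF-8 with a header row (CSV accepted via the
``sep`` argument). Missing values are written as empty fields; writers emit
rows sorted by ``mag_id`` so outputs are byte-stable across runs.

The gene vocabulary is an external, editable token file shipped with the
package: each row maps a token (canonical gene symbol or an annotation-tool
dialect label) to a canonical symbol and a functional category. Readers
normalize dialect labels to canonical symbols and report — never drop —
tokens outside the vocabulary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: default number of steps per scored pathway
DEFAULT_PATHWAY_STEPS = {
    "HYDROGENOTROPHIC_METHANOGENESIS": 8,
    "CODH_ACS": 2,
    "WOOD_LJUNGDAHL": 7,
    "COMPLEX_IV_HIGH": 4,
    "COMPLEX_IV_LOW": 4,
    "CALVIN": 11,
}

ANNOTATION_COLUMNS = ["mag_id", "gene_symbol", "scaffold_id", "scaffold_length"]
PATHWAY_COLUMNS = ["mag_id", "pathway_id", "steps_present", "steps_total"]
COVERAGE_COLUMNS = ["site_id", "mag_id", "scaffold_id", "coverage"]


class TableFormatError(ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class TableValidationError(ValueError):
    """A structurally sound table contains invalid values."""


@dataclass(frozen=True)
class RuleThresholds:
    """Tunable cut-offs for the guild classification rules.

    ``hydro_min`` is inclusive (6/8 steps counts as meeting the 75 % bar);
    ``codh_acs_min`` is exclusive (with a 2-step module only 2/2 exceeds
    50 %); ``hydro_low_max`` is the exclusive ceiling below which the
    hydrogenotrophic pathway is considered effectively absent.
    """

    hydro_min: Fraction = Fraction(3, 4)
    hydro_low_max: Fraction = Fraction(1, 2)
    codh_acs_min: Fraction = Fraction(1, 2)
    wl_min: Fraction = Fraction(6, 7)
    min_verify_scaffold_bp: int = 3000
    min_verify_gene_count: int = 2
    trait_completion_min: Fraction = Fraction(3, 4)

    def __post_init__(self) -> None:
        for name in ("hydro_min", "hydro_low_max", "codh_acs_min", "wl_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise TableValidationError(f"{name} must be in [0, 1], got {v}")
        if self.hydro_low_max > self.hydro_min:
            raise TableValidationError("hydro_low_max must not exceed hydro_min")


@dataclass(frozen=True)
class Taxonomy:
    """A seven-rank GTDB classification for one MAG; empty string = unclassified."""

    mag_id: str
    domain: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def rank(self, name: str) -> str:
        return getattr(self, "class_" if name == "class" else name)


@dataclass
class Vocabulary:
    """Controlled gene-symbol vocabulary with dialect aliases."""

    canonical: frozenset[str]
    alias_to_canonical: Mapping[str, str]
    categories: Mapping[str, str]

    def normalize(self, token: str) -> str | None:
        """Canonical symbol for ``token``, or None if unrecognized."""
        token = token.strip()
        if token in self.canonical:
            return token
        return self.alias_to_canonical.get(token)


@dataclass
class AnnotationTable:
    """Validated gene-annotation rows plus the unrecognized-token report."""

    frame: pd.DataFrame
    unrecognized: dict[str, int] = field(default_factory=dict)


def load_vocabulary(path: str | Path | None = None) -> Vocabulary:
    """Load the gene vocabulary (the packaged default when ``path`` is None)."""
    if path is None:
        source = importlib.resources.files("methanocycle.data") / "gene_vocabulary.tsv"
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("token", "canonical", "category"):
        if col not in df.columns:
            raise TableFormatError(f"vocabulary file missing column '{col}'")
    canonical = frozenset(df["canonical"])
    aliases = {
        row.token: row.canonical for row in df.itertuples() if row.token != row.canonical
    }
    categories = dict(zip(df["canonical"], df["category"]))
    return Vocabulary(canonical, aliases, categories)


def load_known_methanotroph_families(path: str | Path | None = None) -> frozenset[str]:
    if path is None:
        source = (
            importlib.resources.files("methanocycle.data")
            / "known_methanotroph_families.txt"
        )
        text = source.read_text()
    else:
        text = Path(path).read_text()
    names = [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return frozenset(names)


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{what} table missing column(s): {', '.join(missing)}")


def read_annotations(
    path: str | Path,
    vocabulary: Vocabulary | None = None,
    sep: str = "\t",
) -> AnnotationTable:
    """Read a per-gene annotation table.

    Tokens are normalized through the vocabulary's alias map. Unknown tokens
    are retained in the table and tallied in :attr:`AnnotationTable.unrecognized`.
    """
    vocabulary = vocabulary or load_vocabulary()
    df = pd.read_csv(path, sep=sep, dtype={"mag_id": str, "gene_symbol": str, "scaffold_id": str})
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    bad = df.index[df["scaffold_length"] < 0]
    if len(bad):
        raise TableValidationError(
            f"negative scaffold_length at row(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    unrecognized: dict[str, int] = {}
    normalized = []
    for tok in df["gene_symbol"]:
        canon = vocabulary.normalize(tok)
        if canon is None:
            unrecognized[tok] = unrecognized.get(tok, 0) + 1
            normalized.append(tok)
        else:
            normalized.append(canon)
    df = df.assign(gene_symbol=normalized)
    return AnnotationTable(df[ANNOTATION_COLUMNS].copy(), unrecognized)


def read_pathways(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read per-MAG pathway-completion rows and validate step counts."""
    df = pd.read_csv(path, sep=sep, dtype={"mag_id": str, "pathway_id": str})
    _require_columns(df, PATHWAY_COLUMNS, "pathway")
    validate_pathways(df)
    return df[PATHWAY_COLUMNS].copy()


def validate_pathways(df: pd.DataFrame) -> None:
    if (df["steps_total"] < 1).any():
        raise TableValidationError("steps_total must be >= 1")
    if (df["steps_present"] < 0).any():
        raise TableValidationError("steps_present must be >= 0")
    over = df["steps_present"] > df["steps_total"]
    if over.any():
        rows = [int(i) + 2 for i in df.index[over][:5]]
        raise TableValidationError(f"steps_present > steps_total at row(s) {rows}")


def read_coverage(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"site_id": str, "mag_id": str, "scaffold_id": str})
    _require_columns(df, COVERAGE_COLUMNS, "coverage")
    if (df["coverage"] < 0).any():
        raise TableValidationError("coverage must be >= 0")
    dups = df.duplicated(subset=["mag_id", "scaffold_id"])
    if dups.any():
        raise TableValidationError(
            f"duplicate scaffold id(s) within a MAG: "
            f"{df.loc[dups, ['mag_id', 'scaffold_id']].head().to_dict('records')}"
        )
    return df[COVERAGE_COLUMNS].copy()


def read_taxonomy(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a taxonomy table: either a ``classification`` lineage-string column
    or the seven rank columns alongside ``mag_id``."""
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "mag_id" not in df.columns:
        raise TableFormatError("taxonomy table missing column(s): mag_id")
    if "classification" in df.columns:
        parsed = [parse_gtdb_lineage(s) for s in df["classification"]]
        out = pd.DataFrame(
            {
                "mag_id": df["mag_id"].values,
                **{
                    rank: [t.rank(rank) for t in parsed]
                    for rank in GTDB_RANKS
                },
            }
        )
        return out
    _require_columns(df, ("mag_id", *GTDB_RANKS), "taxonomy")
    return df[["mag_id", *GTDB_RANKS]].copy()


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a table with header, sorted by mag_id when present (deterministic)."""
    out = df
    if "mag_id" in df.columns:
        by = ["mag_id"] + [c for c in ("scaffold_id", "gene_symbol", "pathway_id") if c in df.columns]
        out = df.sort_values(by, kind="mergesort")
    out.to_csv(path, sep=sep, index=False)


def parse_gtdb_lineage(lineage: str) -> Taxonomy:
    """Parse a semicolon-delimited GTDB lineage string.

    Accepts a prefix of the seven ranks (``d__`` through ``s__``) in order;
    anything else — unknown prefixes, out-of-order ranks — is rejected.
    """
    if not lineage or not lineage.strip():
        raise TableFormatError("empty lineage string")
    parts = [p.strip() for p in lineage.strip().split(";") if p.strip()]
    if len(parts) > 7:
        raise TableFormatError(f"lineage has more than 7 ranks: {lineage!r}")
    values = {}
    for i, part in enumerate(parts):
        prefix = _RANK_PREFIXES[i]
        if not part.startswith(prefix):
            raise TableFormatError(
                f"expected rank prefix '{prefix}' at position {i + 1}, got {part!r}"
            )
        values[GTDB_RANKS[i]] = part[len(prefix):].strip()
    # ranks below an unclassified rank must also be unclassified
    names = [values.get(r, "") for r in GTDB_RANKS]
    seen_empty = False
    for rank, name in zip(GTDB_RANKS, names):
        if seen_empty and name:
            raise TableValidationError(
                f"rank '{rank}' classified below an unclassified rank: {lineage!r}"
            )
        if not name:
            seen_empty = True
    return Taxonomy(
        mag_id="",
        domain=names[0],
        phylum=names[1],
        class_=names[2],
        order=names[3],
        family=names[4],
        genus=names[5],
        species=names[6],
    )


def completion_fraction(steps_present: int, steps_total: int) -> Fraction:
    """Exact pathway completion ``steps_present / steps_total``.

    Kept rational so threshold comparisons at the 6/8-vs-75 % boundary are
    decidable without floating-point ambiguity.
    """
    if steps_total < 1:
        raise TableValidationError("steps_total must be >= 1")
    if steps_present < 0:
        raise TableValidationError("steps_present must be >= 0")
    if steps_present > steps_total:
        raise TableValidationError(
            f"steps_present ({steps_present}) exceeds steps_total ({steps_total})"
        )
    return Fraction(steps_present, steps_total)


def pathway_fractions(
    pathways: pd.DataFrame, mag_ids: Iterable[str]
) -> dict[str, dict[str, Fraction]]:
    """Per-MAG mapping pathway_id -> exact completion fraction.

    MAGs absent from the table get an empty mapping; callers fall back to
    0 / default-steps for the pathways they score.
    """
    out: dict[str, dict[str, Fraction]] = {str(m): {} for m in mag_ids}
    for row in pathways.itertuples():
        out.setdefault(str(row.mag_id), {})[row.pathway_id] = completion_fraction(
            int(row.steps_present), int(row.steps_total)
        )
    return out
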