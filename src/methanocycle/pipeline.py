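"""End-to-end pipeline: abundance -> guild classification -> ordination ->
occurrence meta-analysis, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import aggregate_by_rank, profiles_to_frame, site_profiles
from .acetogens import classify_acetogens
from .community import bray_curtis, nmds
from .methanogens import classify_methanogens
from .methanotrophs import (
    build_features as build_methanotroph_features,
    calls_to_frame,
    identify_methanotrophs,
    mode_counts,
    trait_tallies,
)
from .occurrence import (
    load_synonym_map,
    occurrence_counts,
    presence_matrix,
    study_report_from_calls,
)
from .tables_io import (
    RuleThresholds,
    read_annotations,
    read_coverage,
    read_pathways,
    read_taxonomy,
    write_table,
)

log = logging.getLogger("methanocycle")


@dataclass
class PipelineResult:
    outdir: Path
    abundance: pd.DataFrame
    methanogen_calls: pd.DataFrame
    methanotroph_calls: pd.DataFrame
    acetogen_calls: pd.DataFrame
    guild_summary: pd.DataFrame
    stress: float
    methanotroph_modes: dict[str, int]
    methanotroph_traits: dict[str, int]
    occurrence: pd.DataFrame | None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    log.info("stage %s", name)
    return name


def run_pipeline(
    annotations_path: str | Path,
    pathways_path: str | Path,
    taxonomy_path: str | Path,
    coverage_path: str | Path,
    outdir: str | Path,
    study_reports_path: str | Path | None = None,
    thresholds: RuleThresholds | None = None,
    rank: str = "family",
    nmds_k: int = 2,
    nmds_restarts: int = 20,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on the given tables and write outputs + manifest.

    Any stage failure is re-raised annotated with the stage name.
    """
    thresholds = thresholds or RuleThresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "annotations": Path(annotations_path),
        "pathways": Path(pathways_path),
        "taxonomy": Path(taxonomy_path),
        "coverage": Path(coverage_path),
    }
    if study_reports_path is not None:
        inputs["study_reports"] = Path(study_reports_path)

    stage = "tables_io.read"
    try:
        ann = read_annotations(inputs["annotations"])
        if ann.unrecognized:
            log.warning("unrecognized gene tokens: %s", ann.unrecognized)
        annotations = ann.frame
        pathways = read_pathways(inputs["pathways"])
        taxonomy = read_taxonomy(inputs["taxonomy"])
        coverage = read_coverage(inputs["coverage"])

        stage = "abundance.profiles"
        profiles = site_profiles(coverage)

        stage = "abundance.aggregate"
        missing_tax = sorted(set(coverage["mag_id"]) - set(taxonomy["mag_id"]))
        if missing_tax:
            raise ValueError(f"missing taxonomy for MAG(s): {missing_tax[:10]}")
        rank_profiles = {
            s: aggregate_by_rank(p, taxonomy, rank) for s, p in profiles.items()
        }
        abundance_out = profiles_to_frame(
            list(profiles.values()) + list(rank_profiles.values())
        )
        write_table(abundance_out, outdir / "abundance.tsv")

        stage = "classify.methanogens"
        methanogen_calls = classify_methanogens(annotations, pathways, taxonomy, thresholds)
        write_table(methanogen_calls, outdir / "methanogen_calls.tsv")

        stage = "classify.methanotrophs"
        mt_features = build_methanotroph_features(annotations, taxonomy)
        mt_calls = identify_methanotrophs(mt_features, thresholds)
        methanotroph_calls = calls_to_frame(mt_calls)
        write_table(methanotroph_calls, outdir / "methanotroph_calls.tsv")
        modes = mode_counts(mt_calls)
        traits = trait_tallies(mt_calls, annotations, pathways, thresholds)

        stage = "classify.acetogens"
        acetogen_calls = classify_acetogens(annotations, pathways, thresholds)
        write_table(acetogen_calls, outdir / "acetogen_calls.tsv")

        stage = "summary"
        site_of = dict(zip(coverage["mag_id"], coverage["site_id"]))
        summary_rows = []
        for frame, col in ((methanogen_calls, "label"), (methanotroph_calls, "mode")):
            for row in frame.itertuples():
                summary_rows.append((site_of.get(row.mag_id, ""), getattr(row, col), row.mag_id))
        guild_summary = (
            pd.DataFrame(summary_rows, columns=["site_id", "guild", "mag_id"])
            .groupby(["site_id", "guild"])
            .size()
            .reset_index(name="n_mags")
            .sort_values(["site_id", "guild"], kind="mergesort")
            .reset_index(drop=True)
        )
        write_table(guild_summary, outdir / "guild_summary.tsv")
        for guild, n in guild_summary.groupby("guild")["n_mags"].sum().items():
            log.info("guild tally: %s = %d MAGs", guild, n)

        stage = "ordination"
        dmatrix = bray_curtis(sorted(rank_profiles.values(), key=lambda p: p.site_id))
        pd.DataFrame(dmatrix.values, index=dmatrix.ids, columns=dmatrix.ids).to_csv(
            outdir / "bray_curtis.tsv", sep="\t"
        )
        ordination = nmds(dmatrix, k=nmds_k, n_restarts=nmds_restarts, seed=seed)
        coords = pd.DataFrame(
            ordination.coordinates,
            index=ordination.ids,
            columns=[f"axis{i + 1}" for i in range(nmds_k)],
        )
        coords.index.name = "site_id"
        coords.to_csv(outdir / "nmds_coordinates.tsv", sep="\t")
        log.info("NMDS stress (k=%d, %d restarts): %.4f", nmds_k, nmds_restarts, ordination.stress)

        stage = "meta.occurrence"
        occurrence = None
        if study_reports_path is not None:
            reports = pd.read_csv(inputs["study_reports"], sep="\t", dtype=str)
            own = study_report_from_calls(methanogen_calls, taxonomy)
            reports = pd.concat([reports, own], ignore_index=True)
            synonyms = load_synonym_map()
            matrix = presence_matrix(reports, synonyms)
            matrix.to_csv(outdir / "presence_matrix.csv")
            occurrence = occurrence_counts(matrix)
            write_table(occurrence, outdir / "occurrence_counts.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "command": "run_pipeline",
        "version": __version__,
        "seed": seed,
        "rank": rank,
        "nmds": {"k": nmds_k, "n_restarts": nmds_restarts},
        "inputs": {k: _sha256(v) for k, v in inputs.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stress": ordination.stress,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        outdir=outdir,
        abundance=abundance_out,
        methanogen_calls=methanogen_calls,
        methanotroph_calls=methanotroph_calls,
        acetogen_calls=acetogen_calls,
        guild_summary=guild_summary,
        stress=ordination.stress,
        methanotroph_modes=modes,
        methanotroph_traits=traits,
        occurrence=occurrence,
    )
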