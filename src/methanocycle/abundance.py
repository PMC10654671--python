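"""Coverage-based relative abundance.

A MAG's mean coverage is the unweighted arithmetic mean of the per-scaffold
mean read depths reported for its unique scaffolds. Relative abundance at a
site is each MAG's mean coverage divided by the summed mean coverage of all
MAGs at that site, times 100. Rank aggregation sums MAG percentages within
each taxon name; MAGs unclassified at the requested rank pool under
``unclassified_<rank>`` so totals are conserved at 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .tables_io import GTDB_RANKS, TableValidationError


@dataclass
class AbundanceProfile:
    """Per-unit relative abundance (percent) at one site, at one rank."""

    site_id: str
    rank: str
    entries: dict[str, float]

    def total(self) -> float:
        return float(sum(self.entries.values()))


def mag_mean_coverage(coverages: Iterable[float], scaffold_ids: Iterable[str] | None = None) -> float:
    """Unweighted mean of per-scaffold coverages for one MAG."""
    values = np.asarray(list(coverages), dtype=float)
    if values.size == 0:
        raise TableValidationError("no scaffold rows for MAG")
    if (values < 0).any():
        raise TableValidationError("coverage must be >= 0")
    if scaffold_ids is not None:
        ids = list(scaffold_ids)
        if len(set(ids)) != len(ids):
            raise TableValidationError("duplicate scaffold ids within a MAG")
    return float(values.mean())


def site_mean_coverages(coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-MAG mean coverage with site attribution.

    Returns a frame with columns site_id, mag_id, mean_coverage.
    """
    dups = coverage.duplicated(subset=["mag_id", "scaffold_id"])
    if dups.any():
        raise TableValidationError("duplicate scaffold ids within a MAG")
    grouped = (
        coverage.groupby(["site_id", "mag_id"], sort=True)["coverage"]
        .mean()
        .reset_index()
        .rename(columns={"coverage": "mean_coverage"})
    )
    return grouped


def relative_abundance(mean_coverages: Mapping[str, float], site_id: str) -> AbundanceProfile:
    """MAG-level relative abundance profile (percent) for one site."""
    if not mean_coverages:
        raise TableValidationError(f"no MAGs for site {site_id}")
    total = float(sum(mean_coverages.values()))
    if total <= 0:
        raise TableValidationError(f"site {site_id} has zero total coverage")
    entries = {str(m): 100.0 * c / total for m, c in sorted(mean_coverages.items())}
    return AbundanceProfile(site_id=site_id, rank="mag", entries=entries)


def site_profiles(coverage: pd.DataFrame) -> dict[str, AbundanceProfile]:
    """MAG-level profiles for every site in a coverage table."""
    means = site_mean_coverages(coverage)
    out = {}
    for site_id, sub in means.groupby("site_id", sort=True):
        out[str(site_id)] = relative_abundance(
            dict(zip(sub["mag_id"], sub["mean_coverage"])), str(site_id)
        )
    return out


def aggregate_by_rank(
    profile: AbundanceProfile, taxonomy: pd.DataFrame, rank: str
) -> AbundanceProfile:
    """Sum a MAG-level profile into taxon bins at the given rank."""
    if profile.rank != "mag":
        raise TableValidationError("aggregate_by_rank expects a MAG-level profile")
    if rank not in GTDB_RANKS:
        raise TableValidationError(f"unknown rank '{rank}'")
    tax = taxonomy.set_index("mag_id")[rank].astype(str)
    missing = sorted(set(profile.entries) - set(tax.index))
    if missing:
        raise TableValidationError(
            f"missing taxonomy record(s) for MAG(s): {', '.join(missing[:10])}"
        )
    sentinel = f"unclassified_{rank}"
    entries: dict[str, float] = {}
    for mag_id, pct in profile.entries.items():
        name = tax.loc[mag_id].strip() or sentinel
        entries[name] = entries.get(name, 0.0) + pct
    entries = dict(sorted(entries.items()))
    return AbundanceProfile(site_id=profile.site_id, rank=rank, entries=entries)


def profiles_to_frame(profiles: Iterable[AbundanceProfile]) -> pd.DataFrame:
    """Long-format output table: site_id, rank, unit_id, relative_abundance_percent."""
    rows = [
        (p.site_id, p.rank, unit, pct)
        for p in profiles
        for unit, pct in p.entries.items()
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "rank", "unit_id", "relative_abundance_percent"]
    )
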