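"""Bray-Curtis NMDS of family-level community composition.

Ordinates the eight simulated sites in two dimensions and reports the
Kruskal stress-1 of the best restart. The older-site and newer-site groups,
which draw from different background family pools, separate along the first
axis.
"""

import argparse
from pathlib import Path

import pandas as pd

from methanocycle.abundance import aggregate_by_rank, site_profiles
from methanocycle.community import bray_curtis, nmds
from methanocycle.tables_io import read_coverage, read_taxonomy

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--restarts", type=int, default=20)
parser.add_argument("--out", type=Path, default=Path("results/nmds_coordinates.tsv"))
args = parser.parse_args()

coverage = read_coverage(args.bundle / "coverage.tsv")
taxonomy = read_taxonomy(args.bundle / "taxonomy.tsv")
profiles = [
    aggregate_by_rank(p, taxonomy, "family") for p in site_profiles(coverage).values()
]
matrix = bray_curtis(sorted(profiles, key=lambda p: p.site_id))
result = nmds(matrix, k=2, n_restarts=args.restarts, seed=args.seed)

coords = pd.DataFrame(result.coordinates, index=result.ids, columns=["axis1", "axis2"])
coords.index.name = "site_id"
coords.to_csv(args.out, sep="\t")
print(f"NMDS over {len(result.ids)} sites, {args.restarts} restarts")
print(f"stress = {result.stress:.4f} (best of {min(result.restart_stresses):.4f}..{max(result.restart_stresses):.4f})")
print(coords.round(3))
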