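"""Cross-study occurrence of methanogen families.

Harmonizes the synthetic literature compilation (including legacy names such
as Methanosaetaceae) to GTDB families, adds this pipeline's own methanogen
calls as a 21st study, and counts per-family occurrences.
"""

import argparse
from pathlib import Path

import pandas as pd

from methanocycle.occurrence import (
    load_synonym_map,
    occurrence_counts,
    presence_matrix,
    study_report_from_calls,
)
from methanocycle.tables_io import read_taxonomy, write_table

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/bundle"))
parser.add_argument("--calls", type=Path, default=Path("results/methanogen_calls.tsv"))
parser.add_argument("--out", type=Path, default=Path("results/occurrence_counts.tsv"))
args = parser.parse_args()

reports = pd.read_csv(args.bundle / "study_reports.tsv", sep="\t", dtype=str)
calls = pd.read_csv(args.calls, sep="\t")
taxonomy = read_taxonomy(args.bundle / "taxonomy.tsv")
own = study_report_from_calls(calls, taxonomy)
reports = pd.concat([reports, own], ignore_index=True)

synonyms = load_synonym_map()
matrix = presence_matrix(reports, synonyms)
matrix.to_csv(args.out.parent / "presence_matrix.csv")
counts = occurrence_counts(matrix)
write_table(counts, args.out)

n = matrix.shape[1]
print(f"{n} studies retained ({len(set(reports['study_id'])) - n} discarded above family level)")
for row in counts.itertuples():
    print(f"  {row.family:>26s}  {row.count}/{row.n_studies}")
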