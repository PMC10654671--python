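"""Synthetic annotation/pathway/taxonomy/coverage tables with planted truth.

The generator emulates the statistical structure the downstream analyses
assume: per-MAG presence/absence gene patterns, stepwise pathway completion,
heavy-tailed (lognormal) coverage with per-scaffold jitter, and site-level
community composition with an "older" and a "newer" site group drawing from
different family pools. Every MAG carries a planted guild class whose gene
and pathway template is, at zero noise, recovered exactly by the
classification rules at default thresholds.

Nothing here is real data: all tables, and the study-scale configuration
that mirrors a landfill survey's reported community structure, are
synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import acetogens as acetogen_mod
from . import methanogens as methanogen_mod
from . import methanotrophs as methanotroph_mod
from .tables_io import RuleThresholds, write_table

HYDRO = "HYDROGENOTROPHIC_METHANOGENESIS"
CODH = "CODH_ACS"
WL = "WOOD_LJUNGDAHL"
CIV_HIGH = "COMPLEX_IV_HIGH"
CIV_LOW = "COMPLEX_IV_LOW"


@dataclass(frozen=True)
class GuildTemplate:
    """Gene and pathway blueprint for one planted guild class."""

    genes: tuple[str, ...]
    pathways: dict[str, tuple[int, int]]
    families: tuple[str, ...]
    methanogen_label: str = ""
    methanotroph_mode: str = ""
    acetogen_primary: str = ""


GUILD_TEMPLATES: dict[str, GuildTemplate] = {
    "strict": GuildTemplate(
        genes=("mcrA", "mcrB", "mcrG"),
        pathways={HYDRO: (7, 8), CODH: (0, 2)},
        families=("Methanocorpusculaceae", "Methanofollaceae", "Methanomicrobiaceae"),
        methanogen_label="STRICT_HYDROGENOTROPH",
    ),
    "acetoclastic": GuildTemplate(
        genes=("mcrA", "mcrB", "acs"),
        pathways={HYDRO: (7, 8), CODH: (2, 2)},
        families=("Methanotrichaceae", "Methanocullaceae", "Methanoregulaceae"),
        methanogen_label="ACETOCLASTIC",
    ),
    "methylotrophic": GuildTemplate(
        genes=("mcrA", "mtaB"),
        pathways={HYDRO: (2, 8), CODH: (0, 2)},
        families=("Methanomethylophilaceae",),
        methanogen_label="METHYLOTROPHIC",
    ),
    "methylthiol": GuildTemplate(
        genes=("mcrA", "mtsA"),
        pathways={HYDRO: (2, 8), CODH: (0, 2)},
        families=("",),  # unclassified at family level (order-level lineage only)
        methanogen_label="METHYLOTROPHIC",
    ),
    "broad": GuildTemplate(
        genes=("mcrA", "acs", "mtaB", "mttB"),
        pathways={HYDRO: (8, 8), CODH: (2, 2)},
        families=("Methanosarcinaceae",),
        methanogen_label="BROAD_SUBSTRATE",
    ),
    "mcr_lacking": GuildTemplate(
        genes=(),
        pathways={HYDRO: (7, 8), CODH: (2, 2)},
        families=("UBA472",),
        methanogen_label="EXCLUDED_NO_MCR",
    ),
    "anme": GuildTemplate(
        genes=("mcrA", "mcrB"),
        pathways={HYDRO: (7, 8), CODH: (0, 2)},
        families=("Methanoperedenaceae",),
        methanogen_label="REROUTED_ANME",
        methanotroph_mode="ANME",
    ),
    "methanotroph_pmo": GuildTemplate(
        genes=("pmoA", "pmoB", "pmoC"),
        pathways={},
        families=("Methylomonadaceae", "Methylococcaceae", "Acetobacteraceae", "Nevskiaceae"),
        methanotroph_mode="PMO_ONLY",
    ),
    "methanotroph_mmo": GuildTemplate(
        genes=("mmoX", "mmoY"),
        pathways={},
        families=("Methylomonadaceae", "Methylacidiphilaceae", "Mycobacteriaceae"),
        methanotroph_mode="MMO_ONLY",
    ),
    "methanotroph_both": GuildTemplate(
        genes=("pmoA", "pmoB", "mmoX", "mmoY"),
        pathways={},
        families=("Methylomonadaceae", "Methylomirabilaceae", "UBA9628", "UBA5629"),
        methanotroph_mode="BOTH",
    ),
    "acetogen_I": GuildTemplate(
        genes=("pta", "ack"),
        pathways={WL: (6, 7), CODH: (1, 2)},
        families=("Cloacimonadaceae", "Dysgonomonadaceae"),
        acetogen_primary="I",
    ),
    "acetogen_II": GuildTemplate(
        genes=("pta", "ack"),
        pathways={WL: (2, 7), CODH: (2, 2)},
        families=("Dysgonomonadaceae", "Lachnospiraceae"),
        acetogen_primary="II",
    ),
    "acetogen_III": GuildTemplate(
        genes=(),
        pathways={WL: (6, 7), CODH: (0, 2)},
        families=("Anaerolineaceae",),
        acetogen_primary="III",
    ),
    "acetogen_IV": GuildTemplate(
        genes=("pta", "ack"),
        pathways={WL: (1, 7), CODH: (0, 2)},
        families=("Bacteroidaceae", "Ruminococcaceae"),
        acetogen_primary="IV",
    ),
    "background": GuildTemplate(genes=(), pathways={}, families=()),
}

#: family -> (domain, phylum, class, order); placeholder alphanumeric names
#: stand in for unnamed GTDB lineages.
FAMILY_LINEAGE: dict[str, tuple[str, str, str, str]] = {
    "Methanobacteriaceae": ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales"),
    "Methanocorpusculaceae": ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales"),
    "Methanocullaceae": ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales"),
    "Methanofollaceae": ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales"),
    "Methanomicrobiaceae": ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales"),
    "Methanoregulaceae": ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales"),
    "Methanospirillaceae": ("Archaea", "Halobacterota", "Methanomicrobia", "Methanomicrobiales"),
    "Methanotrichaceae": ("Archaea", "Halobacterota", "Methanosarcinia", "Methanosarcinales"),
    "Methanosarcinaceae": ("Archaea", "Halobacterota", "Methanosarcinia", "Methanosarcinales"),
    "Methanoperedenaceae": ("Archaea", "Halobacterota", "Methanosarcinia", "Methanosarcinales"),
    "Methanomethylophilaceae": ("Archaea", "Thermoplasmatota", "Thermoplasmata", "Methanomassiliicoccales"),
    "UBA472": ("Archaea", "Thermoplasmatota", "E2", "UBA9212"),
    "": ("Archaea", "Euryarchaeota", "Methanofastidiosa", "Methanofastidiosales"),
    "Methylomonadaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Methylococcales"),
    "Methylococcaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Methylococcales"),
    "Methylacidiphilaceae": ("Bacteria", "Verrucomicrobiota", "Verrucomicrobiae", "Methylacidiphilales"),
    "Methylomirabilaceae": ("Bacteria", "Methylomirabilota", "Methylomirabilia", "Methylomirabilales"),
    "Acetobacteraceae": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Acetobacterales"),
    "Nevskiaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Nevskiales"),
    "Mycobacteriaceae": ("Bacteria", "Actinobacteriota", "Actinomycetia", "Mycobacteriales"),
    "UBA9628": ("Bacteria", "Elusimicrobiota", "Elusimicrobia", "UBA9628"),
    "UBA5629": ("Bacteria", "Chloroflexota", "Anaerolineae", "UBA5629"),
    "Gallionellaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales"),
    "Sulfurimonadaceae": ("Bacteria", "Campylobacterota", "Campylobacteria", "Campylobacterales"),
    "Arcobacteraceae": ("Bacteria", "Campylobacterota", "Campylobacteria", "Campylobacterales"),
    "Sulfurovoraceae": ("Bacteria", "Campylobacterota", "Campylobacteria", "Campylobacterales"),
    "Dysgonomonadaceae": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Cloacimonadaceae": ("Bacteria", "Cloacimonadota", "Cloacimonadia", "Cloacimonadales"),
    "Anaerolineaceae": ("Bacteria", "Chloroflexota", "Anaerolineae", "Anaerolineales"),
    "Bacteroidaceae": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Paludibacteraceae": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Tannerellaceae": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Marinifilaceae": ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Flavobacteriaceae": ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales"),
    "Lachnospiraceae": ("Bacteria", "Firmicutes_A", "Clostridia", "Lachnospirales"),
    "Ruminococcaceae": ("Bacteria", "Firmicutes_A", "Clostridia", "Oscillospirales"),
    "Christensenellaceae": ("Bacteria", "Firmicutes_A", "Clostridia", "Christensenellales"),
    "UBA6257": ("Bacteria", "Patescibacteria", "Paceibacteria", "UBA6257"),
    "Spirochaetaceae": ("Bacteria", "Spirochaetota", "Spirochaetia", "Spirochaetales"),
    "Leptospiraceae": ("Bacteria", "Spirochaetota", "Leptospirae", "Leptospirales"),
    "Syntrophaceae": ("Bacteria", "Desulfobacterota", "Syntrophia", "Syntrophales"),
    "Geobacteraceae": ("Bacteria", "Desulfobacterota", "Desulfuromonadia", "Geobacterales"),
    "Desulfovibrionaceae": ("Bacteria", "Desulfobacterota", "Desulfovibrionia", "Desulfovibrionales"),
    "Rhodocyclaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales"),
    "Comamonadaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales"),
    "Pseudomonadaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales"),
    "Moraxellaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales"),
    "Xanthomonadaceae": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Xanthomonadales"),
    "Synergistaceae": ("Bacteria", "Synergistota", "Synergistia", "Synergistales"),
}

# background composition pools; "older" sites lean microaerophilic/autotrophic,
# "newer" sites lean fermentative/acetogenic
_OLD_POOL = [
    ("Gallionellaceae", 5.0), ("Sulfurimonadaceae", 4.0), ("Arcobacteraceae", 4.0),
    ("Sulfurovoraceae", 2.0), ("Rhodocyclaceae", 2.0), ("Comamonadaceae", 2.0),
    ("Pseudomonadaceae", 1.5), ("Moraxellaceae", 1.0), ("Xanthomonadaceae", 1.0),
    ("Flavobacteriaceae", 1.0), ("Geobacteraceae", 1.0), ("Leptospiraceae", 0.5),
    ("UBA6257", 1.0), ("Desulfovibrionaceae", 0.5),
]
_NEW_POOL = [
    ("Dysgonomonadaceae", 5.0), ("Cloacimonadaceae", 5.0), ("Anaerolineaceae", 3.0),
    ("Bacteroidaceae", 2.5), ("Paludibacteraceae", 2.0), ("Tannerellaceae", 1.5),
    ("Marinifilaceae", 1.0), ("Lachnospiraceae", 2.0), ("Ruminococcaceae", 1.5),
    ("Christensenellaceae", 1.0), ("Spirochaetaceae", 1.0), ("Syntrophaceae", 1.0),
    ("Synergistaceae", 1.0), ("UBA6257", 2.0),
]

#: spurious additions used by ``degrade`` and neutral background genes
_BACKGROUND_GENES = ("ureC", "nosZ", "narG", "napA", "norB", "nirK", "nirS", "coxA", "ccoN", "phsA")


@dataclass(frozen=True)
class SiteSpec:
    """One sampling site: id, MAG count, and its planted guild composition.

    ``guild_counts`` gives exact per-class counts (background fills the
    remainder); ``guild_mix`` gives proportions converted to counts by
    largest remainder. Exactly one of the two should be supplied.
    """

    site_id: str
    n_mags: int
    guild_counts: dict[str, int] | None = None
    guild_mix: dict[str, float] | None = None
    older: bool = False

    def counts(self) -> dict[str, int]:
        if self.guild_counts is not None:
            counts = dict(self.guild_counts)
        elif self.guild_mix is not None:
            counts = _largest_remainder(self.guild_mix, self.n_mags)
        else:
            counts = {}
        unknown = set(counts) - set(GUILD_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown guild class(es): {sorted(unknown)}")
        total = sum(counts.values())
        if total > self.n_mags or any(v < 0 for v in counts.values()):
            raise ValueError(
                f"infeasible guild composition for site {self.site_id}: "
                f"{total} planted MAGs > {self.n_mags}"
            )
        counts["background"] = counts.get("background", 0) + self.n_mags - total
        return counts


def _largest_remainder(mix: dict[str, float], n: int) -> dict[str, int]:
    keys = sorted(k for k in mix if k != "background")
    raw = {k: mix[k] * n for k in keys}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    target = int(round(sum(raw.values())))
    leftover = max(0, min(target - sum(counts.values()), n - sum(counts.values())))
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:leftover]:
        counts[k] += 1
    return counts


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    sites: tuple[SiteSpec, ...]
    coverage_mu: float = 2.0
    coverage_sigma: float = 1.0
    scaffold_jitter_sd: float = 0.2
    n_scaffolds: tuple[int, int] = (5, 30)
    scaffold_bp: tuple[int, int] = (2500, 50000)
    #: per-site lognormal tilt applied to the background family weights so
    #: sites within a group are similar but not interchangeable
    site_tilt_sd: float = 0.5
    noise: float = 0.0
    #: counts of aerobic methanotrophs (in mag_id order) carrying each trait;
    #: None plants every trait on every aerobic methanotroph
    trait_counts: dict[str, int] | None = None


DEFAULT_GUILD_MIX: dict[str, float] = {
    "strict": 0.04,
    "acetoclastic": 0.05,
    "methylotrophic": 0.02,
    "methylthiol": 0.01,
    "broad": 0.02,
    "mcr_lacking": 0.01,
    "anme": 0.01,
    "methanotroph_pmo": 0.03,
    "methanotroph_mmo": 0.02,
    "methanotroph_both": 0.02,
    "acetogen_I": 0.04,
    "acetogen_II": 0.03,
    "acetogen_III": 0.02,
    "acetogen_IV": 0.08,
}


def default_config(seed: int, n_sites: int = 8, n_mags: int = 150) -> SimulationConfig:
    """Evenly mixed community: every guild class planted at every site."""
    site_ids = ["A", "B", "C", "D1", "D2", "E", "F1", "F2", "G", "H"][:n_sites]
    sites = tuple(
        SiteSpec(site_id=s, n_mags=n_mags, guild_mix=dict(DEFAULT_GUILD_MIX), older=i < n_sites // 2)
        for i, s in enumerate(site_ids)
    )
    return SimulationConfig(seed=seed, sites=sites)


@dataclass
class Bundle:
    """The generated table set plus the planted ground truth."""

    annotations: pd.DataFrame
    pathways: pd.DataFrame
    taxonomy: pd.DataFrame
    coverage: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("annotations", "pathways", "taxonomy", "coverage", "truth"):
            write_table(getattr(self, name), outdir / f"{name}.tsv")


def _lineage_columns(family: str, genus: str = "") -> dict[str, str]:
    domain, phylum, class_, order = FAMILY_LINEAGE[family]
    return {
        "domain": domain,
        "phylum": phylum,
        "class": class_,
        "order": order,
        "family": family,
        "genus": genus,
        "species": "",
    }


def generate(config: SimulationConfig) -> Bundle:
    """Generate the full table bundle; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    ann_rows, path_rows, tax_rows, cov_rows, truth_rows = [], [], [], [], []
    aerobic_methanotroph_mags: list[str] = []

    for site in config.sites:
        counts = site.counts()
        classes: list[str] = []
        for guild in sorted(counts):
            classes.extend([guild] * counts[guild])
        rng.shuffle(classes)
        pool = _OLD_POOL if site.older else _NEW_POOL
        pool_names = [f for f, _ in pool]
        pool_w = np.array([w for _, w in pool])
        pool_w = pool_w * np.exp(rng.normal(0.0, config.site_tilt_sd, size=len(pool_w)))
        pool_w = pool_w / pool_w.sum()

        for idx, guild in enumerate(classes, start=1):
            mag_id = f"ST{site.site_id}_{idx}"
            template = GUILD_TEMPLATES[guild]
            if guild == "background":
                family = str(rng.choice(pool_names, p=pool_w))
            else:
                family = str(template.families[rng.integers(len(template.families))])
            tax_rows.append({"mag_id": mag_id, **_lineage_columns(family)})

            n_scaffolds = int(rng.integers(config.n_scaffolds[0], config.n_scaffolds[1] + 1))
            lengths = rng.integers(config.scaffold_bp[0], config.scaffold_bp[1] + 1, size=n_scaffolds)
            is_methanotroph = template.methanotroph_mode in ("PMO_ONLY", "MMO_ONLY", "BOTH")
            if is_methanotroph:
                # marker-bearing scaffolds must clear the ~3 kbp verification bar
                n_marker = min(len(template.genes), n_scaffolds)
                lengths[:n_marker] = rng.integers(3100, config.scaffold_bp[1] + 1, size=n_marker)
            scaffold_ids = [f"{mag_id}_c{j + 1}" for j in range(n_scaffolds)]

            mag_cov = rng.lognormal(config.coverage_mu, config.coverage_sigma)
            jitter = np.exp(rng.normal(0.0, config.scaffold_jitter_sd, size=n_scaffolds))
            for sid, length, cov in zip(scaffold_ids, lengths, mag_cov * jitter):
                cov_rows.append((site.site_id, mag_id, sid, round(float(cov), 4)))

            # guild genes: one copy each, markers on the longest/clamped scaffolds
            for g_idx, gene in enumerate(template.genes):
                s_idx = g_idx % n_scaffolds
                ann_rows.append((mag_id, gene, scaffold_ids[s_idx], int(lengths[s_idx])))
            # neutral background genes; trait genes stay out of methanotroph
            # MAGs so redox traits are planted by count only
            neutral = (
                tuple(g for g in _BACKGROUND_GENES if g not in ("nirK", "nirS"))
                if is_methanotroph
                else _BACKGROUND_GENES
            )
            n_extra = int(rng.integers(0, 4))
            for gene in rng.choice(neutral, size=n_extra, replace=False):
                s_idx = int(rng.integers(n_scaffolds))
                ann_rows.append((mag_id, str(gene), scaffold_ids[s_idx], int(lengths[s_idx])))

            for pathway_id, (present, total) in template.pathways.items():
                path_rows.append((mag_id, pathway_id, present, total))
            if guild == "background":
                # low, harmless pathway signal
                path_rows.append((mag_id, HYDRO, int(rng.integers(0, 3)), 8))
                path_rows.append((mag_id, "CALVIN", int(rng.integers(0, 12)), 11))
            if is_methanotroph:
                aerobic_methanotroph_mags.append(mag_id)

            truth_rows.append(
                (
                    mag_id,
                    site.site_id,
                    guild,
                    template.methanogen_label,
                    template.methanotroph_mode,
                    template.acetogen_primary,
                    family,
                )
            )

    # redox/complex-IV traits for aerobic methanotrophs, planted by count
    # in mag_id order (None = all carry every trait)
    ordered = sorted(aerobic_methanotroph_mags)
    n_aer = len(ordered)
    tc = config.trait_counts or {
        "nitrite_reduction": n_aer,
        "complex_iv_high": n_aer,
        "complex_iv_low": n_aer,
    }
    ann_by_mag_scaffold = {m: s for (_, m, s, _) in cov_rows}  # any scaffold will do
    scaffold_len = {s: length for (_, _, s, length) in ann_rows} if ann_rows else {}
    for i, mag in enumerate(ordered):
        if i < tc.get("nitrite_reduction", 0):
            sid = ann_by_mag_scaffold[mag]
            ann_rows.append((mag, "nirK", sid, scaffold_len.get(sid, 5000)))
        high = 4 if i < tc.get("complex_iv_high", 0) else 1
        low = 4 if i < tc.get("complex_iv_low", 0) else 1
        path_rows.append((mag, CIV_HIGH, high, 4))
        path_rows.append((mag, CIV_LOW, low, 4))

    bundle = Bundle(
        annotations=pd.DataFrame(
            ann_rows, columns=["mag_id", "gene_symbol", "scaffold_id", "scaffold_length"]
        ),
        pathways=pd.DataFrame(
            path_rows, columns=["mag_id", "pathway_id", "steps_present", "steps_total"]
        ),
        taxonomy=pd.DataFrame(tax_rows),
        coverage=pd.DataFrame(cov_rows, columns=["site_id", "mag_id", "scaffold_id", "coverage"]),
        truth=pd.DataFrame(
            truth_rows,
            columns=[
                "mag_id",
                "site_id",
                "guild",
                "methanogen_label",
                "methanotroph_mode",
                "acetogen_primary",
                "family",
            ],
        ),
    )
    if config.noise > 0:
        bundle = degrade(bundle, config.noise, seed=config.seed + 1)
    return bundle


def degrade(bundle: Bundle, noise: float, seed: int, add_rate: float = 0.0) -> Bundle:
    """Drop each annotation row independently with probability ``noise``.

    ``add_rate`` optionally plants one spurious background gene per MAG with
    the given probability. Pathway, taxonomy and coverage tables are left
    untouched, so recovery under drop-only noise has a closed form per guild.
    """
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ann = bundle.annotations
    keep = rng.random(len(ann)) >= noise
    degraded = ann[keep].reset_index(drop=True)
    if add_rate > 0:
        extra = []
        for mag in bundle.truth["mag_id"]:
            if rng.random() < add_rate:
                gene = str(rng.choice(_BACKGROUND_GENES))
                extra.append((mag, gene, f"{mag}_spurious", 5000))
        if extra:
            degraded = pd.concat(
                [degraded, pd.DataFrame(extra, columns=ann.columns)], ignore_index=True
            )
    return Bundle(
        annotations=degraded,
        pathways=bundle.pathways,
        taxonomy=bundle.taxonomy,
        coverage=bundle.coverage,
        truth=bundle.truth,
    )


# ---------------------------------------------------------------------------
# recovery measurement and its analytic expectation


def measure_recovery(
    bundle: Bundle, thresholds: RuleThresholds | None = None
) -> tuple[float, dict[str, float]]:
    """Fraction of MAGs whose planted class the rule engine recovers.

    Methanogen classes are scored on the guild label, methanotroph classes on
    the pMMO/sMMO mode, acetogen classes on the primary category, background
    on remaining uncalled; ANME must be both rerouted and called ANME.
    """
    thresholds = thresholds or RuleThresholds()
    meth = methanogen_mod.classify_methanogens(
        bundle.annotations, bundle.pathways, bundle.taxonomy, thresholds
    )
    meth_label = dict(zip(meth["mag_id"], meth["label"]))
    calls = methanotroph_mod.identify_methanotrophs(
        methanotroph_mod.build_features(bundle.annotations, bundle.taxonomy), thresholds
    )
    mode = {c.mag_id: c.mode for c in calls}
    aceto = acetogen_mod.classify_acetogens(bundle.annotations, bundle.pathways, thresholds)
    aceto_primary = dict(zip(aceto["mag_id"], aceto["primary"]))

    per_class_hits: dict[str, list[bool]] = {}
    for row in bundle.truth.itertuples():
        guild = row.guild
        if guild == "background":
            ok = (
                row.mag_id not in meth_label
                and row.mag_id not in mode
                and row.mag_id not in aceto_primary
            )
        elif guild == "anme":
            ok = meth_label.get(row.mag_id) == "REROUTED_ANME" and mode.get(row.mag_id) == "ANME"
        elif row.methanogen_label:
            ok = meth_label.get(row.mag_id, "") == row.methanogen_label
        elif row.methanotroph_mode:
            ok = mode.get(row.mag_id, "") == row.methanotroph_mode
        else:
            ok = aceto_primary.get(row.mag_id, "") == row.acetogen_primary
        per_class_hits.setdefault(guild, []).append(bool(ok))
    per_class = {g: float(np.mean(h)) for g, h in sorted(per_class_hits.items())}
    overall = float(np.mean([v for h in per_class_hits.values() for v in h]))
    return overall, per_class


def class_recovery_probability(
    guild: str, drop_p: float, thresholds: RuleThresholds | None = None
) -> float:
    """Exact recovery probability for one guild class under drop-only noise.

    Enumerates every survival pattern of the class template's genes, reruns
    the classification rules on each, and sums the probabilities of the
    patterns that still yield the planted label.
    """
    thresholds = thresholds or RuleThresholds()
    template = GUILD_TEMPLATES[guild]
    genes = template.genes
    total = 0.0
    for pattern in product((False, True), repeat=len(genes)):
        prob = 1.0
        for kept in pattern:
            prob *= (1 - drop_p) if kept else drop_p
        surviving = frozenset(g for g, kept in zip(genes, pattern) if kept)
        if _recovers(guild, surviving, thresholds):
            total += prob
    return total


def _recovers(guild: str, genes: frozenset[str], t: RuleThresholds) -> bool:
    template = GUILD_TEMPLATES[guild]
    if guild == "background":
        return True
    family = template.families[0]
    if template.methanogen_label:
        f = methanogen_mod.MethanogenFeatures(
            mag_id="x",
            has_mcrA="mcrA" in genes,
            has_mcrB="mcrB" in genes,
            has_mcrC="mcrC" in genes,
            has_mcrD="mcrD" in genes,
            has_mcrG="mcrG" in genes,
            hydro=Fraction(*template.pathways.get(HYDRO, (0, 8))),
            codh_acs=Fraction(*template.pathways.get(CODH, (0, 2))),
            has_acs="acs" in genes,
            has_ack_and_acyltx="ack" in genes and ("act" in genes or "pta" in genes),
            methyl_substrates=frozenset(
                s for g, s in methanogen_mod.METHYL_GENE_SUBSTRATE.items() if g in genes
            ),
            has_mtsA="mtsA" in genes,
            has_mtaA="mtaA" in genes,
            family=family,
        )
        partition = methanogen_mod.identify_putative_methanogens([f], t)
        status = partition.get("x", "")
        if status == "candidate":
            label = methanogen_mod.classify_guild(f, t).label
        else:
            label = status
        return label == template.methanogen_label
    if template.methanotroph_mode:
        has_pmoA, has_mmoX = "pmoA" in genes, "mmoX" in genes
        if has_pmoA and has_mmoX:
            observed = "BOTH"
        elif has_pmoA:
            observed = "PMO_ONLY"
        elif has_mmoX:
            observed = "MMO_ONLY"
        else:
            observed = ""
        return observed == template.methanotroph_mode
    f = acetogen_mod.AcetogenFeatures(
        mag_id="x",
        wl=Fraction(*template.pathways.get(WL, (0, 7))),
        codh_acs=Fraction(*template.pathways.get(CODH, (0, 2))),
        has_pta="pta" in genes,
        has_ack="ack" in genes,
    )
    _, primary = acetogen_mod.classify_acetogen(f, t)
    return (primary or "") == template.acetogen_primary


def expected_recovery(config: SimulationConfig, drop_p: float) -> float:
    """Community-level expected recovery: class probabilities weighted by
    planted class sizes."""
    weights: dict[str, int] = {}
    for site in config.sites:
        for guild, n in site.counts().items():
            weights[guild] = weights.get(guild, 0) + n
    n_total = sum(weights.values())
    return sum(
        n * class_recovery_probability(guild, drop_p) for guild, n in weights.items()
    ) / n_total


# ---------------------------------------------------------------------------
# study-scale emulation (synthetic stand-in for a real landfill survey)

#: per-family occurrence counts (of 21 retained studies) used to plant the
#: synthetic literature compilation
DEFAULT_OCCURRENCE_COUNTS: dict[str, int] = {
    "Methanosarcinaceae": 17,
    "Methanotrichaceae": 15,
    "Methanocullaceae": 13,
    "Methanobacteriaceae": 13,
    "Methanofollaceae": 8,
    "Methanoregulaceae": 6,
    "Methanospirillaceae": 5,
    "Methanocorpusculaceae": 4,
    "Methanomethylophilaceae": 4,
    "Methanomicrobiaceae": 3,
    "Methanofastidiosaceae": 1,
}

#: legacy spellings some synthetic studies use; the harmonizer must map them
_LEGACY_ALIASES: dict[str, tuple[str, ...]] = {
    "Methanotrichaceae": ("Methanosaetaceae", "Methanosaeta", "Methanothrix soehngenii"),
    "Methanocullaceae": ("Methanoculleus", "Methanoculleus bourgensis"),
    "Methanobacteriaceae": ("Methanobacterium", "Methanobrevibacter"),
    "Methanofollaceae": ("Methanofollis",),
    "Methanosarcinaceae": ("Methanosarcina", "Methanosarcina barkeri"),
    "Methanocorpusculaceae": ("Methanocorpusculum",),
    "Methanospirillaceae": ("Methanospirillum hungatei",),
    "Methanoregulaceae": ("Methanoregula", "Methanolinea"),
    "Methanomethylophilaceae": ("Methanomethylophilus",),
    "Methanofastidiosaceae": ("Methanofastidiosum",),
}

_STUDY_METHODS = ("16S", "mcrA", "metagenomics", "FISH", "RFLP", "qPCR", "microarray")


def study_scale_config(seed: int) -> SimulationConfig:
    """Synthetic eight-site landfill with the community structure a decadal
    leachate survey reported: per-site MAG totals, per-site methanogen guild
    composition, a 15/5/11 pMMO/sMMO/both methanotroph split concentrated in
    the older sites, two ANME MAGs at one location, and redox-trait counts of
    27/24/26 of 31 aerobic methanotrophs."""
    sites = (
        SiteSpec("A", 93, guild_counts={"acetoclastic": 2, "methanotroph_pmo": 2, "methanotroph_mmo": 1, "methanotroph_both": 1, "acetogen_IV": 4}, older=True),
        SiteSpec("B", 188, guild_counts={"acetoclastic": 3, "methanotroph_pmo": 6, "methanotroph_mmo": 2, "methanotroph_both": 4, "acetogen_IV": 6}, older=True),
        SiteSpec("C", 134, guild_counts={"strict": 2, "acetoclastic": 3, "methylotrophic": 2, "methanotroph_pmo": 4, "methanotroph_mmo": 1, "methanotroph_both": 4, "acetogen_IV": 5}, older=True),
        SiteSpec("D1", 220, guild_counts={"acetoclastic": 6, "anme": 2, "methanotroph_pmo": 2, "methanotroph_mmo": 1, "methanotroph_both": 2, "acetogen_I": 3, "acetogen_IV": 6}, older=True),
        SiteSpec("D2", 269, guild_counts={"strict": 6, "acetoclastic": 6, "methylotrophic": 2, "broad": 3, "acetogen_I": 4, "acetogen_II": 2, "acetogen_IV": 10}),
        SiteSpec("E", 210, guild_counts={"strict": 3, "acetoclastic": 4, "methanotroph_pmo": 1, "mcr_lacking": 1, "acetogen_I": 3, "acetogen_IV": 8}),
        SiteSpec("F1", 294, guild_counts={"strict": 5, "acetoclastic": 7, "methylotrophic": 3, "methylthiol": 1, "broad": 4, "acetogen_I": 5, "acetogen_II": 3, "acetogen_III": 2, "acetogen_IV": 12}),
        SiteSpec("F2", 239, guild_counts={"strict": 5, "acetoclastic": 6, "methylotrophic": 3, "broad": 3, "acetogen_I": 4, "acetogen_II": 2, "acetogen_IV": 10}),
    )
    return SimulationConfig(
        seed=seed,
        sites=sites,
        trait_counts={"nitrite_reduction": 27, "complex_iv_high": 24, "complex_iv_low": 26},
    )


def synthetic_study_reports(
    seed: int,
    this_study: pd.DataFrame | None = None,
    this_study_families: set[str] | None = None,
    occurrence_counts: dict[str, int] | None = None,
    n_external: int = 20,
    n_discarded: int = 2,
) -> pd.DataFrame:
    """Synthetic literature compilation for the occurrence meta-analysis.

    Plants per-family occurrence counts over ``n_external`` retained external
    studies plus this pipeline's own report; some studies use legacy names so
    the synonym harmonization is exercised. ``n_discarded`` extra studies
    report only above-family names and must be dropped. The own report is
    appended when passed as ``this_study``; pass ``this_study_families``
    instead to discount its families from the planted counts while leaving
    the report to be appended downstream.
    """
    rng = np.random.default_rng(seed)
    counts = dict(occurrence_counts or DEFAULT_OCCURRENCE_COUNTS)
    this_families: set[str] = set(this_study_families or ())
    if this_study is not None:
        this_families |= set(this_study["taxon_name"])
    external_ids = [f"study_{i + 1:02d}" for i in range(n_external)]
    methods = {s: str(rng.choice(_STUDY_METHODS)) for s in external_ids}
    uncovered = set(external_ids)
    rows = []
    for family in sorted(counts, key=lambda f: (-counts[f], f)):
        k = counts[family] - (1 if family in this_families else 0)
        if k > n_external:
            raise ValueError(f"occurrence count for {family} exceeds study pool")
        take_uncovered = sorted(uncovered)[: min(k, len(uncovered))]
        remaining = sorted(set(external_ids) - set(take_uncovered))
        fill = list(rng.choice(remaining, size=k - len(take_uncovered), replace=False)) if k > len(take_uncovered) else []
        chosen = take_uncovered + [str(s) for s in fill]
        uncovered -= set(chosen)
        for study in chosen:
            aliases = (family,) + _LEGACY_ALIASES.get(family, ())
            name = str(aliases[rng.integers(len(aliases))])
            rank = "family" if name.endswith("aceae") else ("species" if " " in name else "genus")
            rows.append((study, methods[study], name, rank))
    if uncovered:
        raise ValueError(
            f"planted counts leave studies empty (would change the denominator): {sorted(uncovered)}"
        )
    for i in range(n_discarded):
        study = f"discarded_{i + 1}"
        rows.append((study, "16S", "Methanomicrobiales", "order"))
        rows.append((study, "16S", "Euryarchaeota", "phylum"))
    reports = pd.DataFrame(rows, columns=["study_id", "method", "taxon_name", "rank_claimed"])
    reports = reports.sort_values(["study_id", "taxon_name"], kind="mergesort").reset_index(drop=True)
    if this_study is not None:
        reports = pd.concat([reports, this_study], ignore_index=True)
    return reports
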