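"""Synthetic fecal-metabarcoding and nest-survey datasets with known truth.

The generator emulates a one-month breeding-season survey in a temperate
urban forest: ~107 fecal samples from ~13 host bird species dominated by
two families, a highly skewed dietary plant community of ~210 genera, a
~150-nest survey on ~18 substrate species, and a vegetation-community
table. Two keystone plant genera are *planted*: their base abundance is
boosted by a configurable factor for a configurable fraction of the bird
community, and two genera carry planted early/late-month abundance
shifts. Ground truth records what was planted so pipeline recovery can
be scored.

Everything is generated at classified-count level (no sequences); the
writers emit exactly the TSV/CSV dialects the ingest module reads.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from statistics import NormalDist

import numpy as np

from .ingest import (
    ARTIFICIAL,
    UNIDENTIFIED,
    CommunityTable,
    Lineage,
    NestRecord,
    OtuTable,
    SampleMeta,
    write_community_table,
    write_nest_records,
    write_otu_table,
    write_sample_meta,
)

import pandas as pd

# ---------------------------------------------------------------------------
# default study structure

# (species, family, order, sampling weight); two families carry ~75% of samples
DEFAULT_HOST_POOL: tuple[tuple[str, str, str, float], ...] = (
    ("Pica pica", "Corvidae", "Passeriformes", 0.28),
    ("Cyanopica cyanus", "Corvidae", "Passeriformes", 0.14),
    ("Urocissa erythroryncha", "Corvidae", "Passeriformes", 0.05),
    ("Turdus mandarinus", "Turdidae", "Passeriformes", 0.20),
    ("Turdus merula", "Turdidae", "Passeriformes", 0.08),
    ("Garrulax davidi", "Leiothrichidae", "Passeriformes", 0.05),
    ("Passer montanus", "Passeridae", "Passeriformes", 0.05),
    ("Dendrocopos major", "Picidae", "Piciformes", 0.04),
    ("Picus canus", "Picidae", "Piciformes", 0.03),
    ("Streptopelia orientalis", "Columbidae", "Columbiformes", 0.03),
    ("Spilopelia chinensis", "Columbidae", "Columbiformes", 0.02),
    ("Hirundo rustica", "Hirundinidae", "Passeriformes", 0.02),
    ("Apus pacificus", "Apodidae", "Apodiformes", 0.01),
)

# Leading dietary plant genera in descending base abundance; the keystone
# genera (Morus, Prunus) sit mid-pack at base ranks 5 and 8 so that their
# dominance in generated diets is created by the planted boost, not by the
# base profile. The list is padded with Genus_### names up to n_plant_genera.
_NAMED_GENERA = (
    "Rosa", "Cynoglossum", "Carya", "Syringa", "Morus", "Iris", "Ulmus",
    "Prunus", "Pteroceltis", "Koelreuteria", "Styphnolobium", "Carex",
    "Viola", "Lonicera", "Liriope", "Dianthus", "Castanea", "Pyrus",
    "Ailanthus", "Digitaria", "Rhamnus", "Amorpha", "Triticum", "Quercus",
    "Acer", "Platycladus", "Pinus", "Cotinus", "Robinia", "Vitex", "Celtis",
    "Forsythia", "Grewia", "Spiraea", "Diospyros", "Pertya",
)

# prey taxa: (taxon name, phylum, class, order, family, weight)
DEFAULT_PREY: tuple[tuple[str, str, str, str, str, float], ...] = (
    ("Aegosoma sinicum", "Arthropoda", "Insecta", "Coleoptera", "Cerambycidae", 0.060),
    ("Holotrichia oblita", "Arthropoda", "Insecta", "Coleoptera", "Scarabaeidae", 0.050),
    ("Anomala corpulenta", "Arthropoda", "Insecta", "Coleoptera", "Scarabaeidae", 0.030),
    ("Apolygus lucorum", "Arthropoda", "Insecta", "Hemiptera", "Miridae", 0.050),
    ("Erthesina fullo", "Arthropoda", "Insecta", "Hemiptera", "Pentatomidae", 0.025),
    ("Camponotus japonicus", "Arthropoda", "Insecta", "Hymenoptera", "Formicidae", 0.040),
    ("Vespula flaviceps", "Arthropoda", "Insecta", "Hymenoptera", "Vespidae", 0.020),
    ("Hyphantria cunea", "Arthropoda", "Insecta", "Lepidoptera", "Erebidae", 0.035),
    ("Lymantria dispar", "Arthropoda", "Insecta", "Lepidoptera", "Erebidae", 0.020),
    ("Musca domestica", "Arthropoda", "Insecta", "Diptera", "Muscidae", 0.030),
    ("Chironomus plumosus", "Arthropoda", "Insecta", "Diptera", "Chironomidae", 0.020),
    ("Blattella asahinai", "Arthropoda", "Insecta", "Blattodea", "Ectobiidae", 0.008),
    ("Teleogryllus emma", "Arthropoda", "Insecta", "Orthoptera", "Gryllidae", 0.007),
    ("Aceria sp.", "Arthropoda", "Arachnida", "Trombidiformes", "Eriophyidae", 0.030),
    ("Araneus ventricosus", "Arthropoda", "Arachnida", "Araneae", "Araneidae", 0.020),
    ("Armadillidium vulgare", "Arthropoda", "Malacostraca", "Isopoda", "Armadillidiidae", 0.025),
    ("Amynthas corticis", "Annelida", "Clitellata", "Crassiclitellata", "Megascolecidae", 0.110),
    ("Eisenia fetida", "Annelida", "Clitellata", "Crassiclitellata", "Lumbricidae", 0.070),
    ("Bradybaena ravida", "Mollusca", "Gastropoda", "Stylommatophora", "Camaenidae", 0.015),
    ("Nematoda sp.", "Nematoda", "", "", "", 0.010),
    ("Garrulax davidi", "Chordata", "Aves", "Passeriformes", "Leiothrichidae", 0.050),
    ("Passer montanus", "Chordata", "Aves", "Passeriformes", "Passeridae", 0.030),
    ("Cyanopica cyanus", "Chordata", "Aves", "Passeriformes", "Corvidae", 0.020),
    ("Homo sapiens", "Chordata", "Mammalia", "Primates", "Hominidae", 0.015),
    ("Apodemus agrarius", "Chordata", "Mammalia", "Rodentia", "Muridae", 0.015),
    ("Bufo gargarizans", "Chordata", "Amphibia", "Anura", "Bufonidae", 0.010),
)

# nest survey: (bird species, weight) over vegetation nests
DEFAULT_NEST_BIRDS: tuple[tuple[str, float], ...] = (
    ("Pica pica", 0.5888),
    ("Pycnonotus sinensis", 0.1308),
    ("Sinosuthora webbiana", 0.055),
    ("Garrulax davidi", 0.040),
    ("Chloris sinica", 0.030),
    ("Turdus mandarinus", 0.028),
    ("Cyanopica cyanus", 0.028),
    ("Streptopelia orientalis", 0.020),
    ("Spodiopsar cineraceus", 0.018),
    ("Urocissa erythroryncha", 0.016),
    ("Parus minor", 0.015),
    ("Dendrocopos major", 0.012),
    ("Hirundo rustica", 0.005),
    ("Upupa epops", 0.004),
)

# (substrate species, growth form, weight); deciduous ~0.785, coniferous
# ~0.075, shrub ~0.14, mirroring a broadleaf-dominated temperate park
DEFAULT_NEST_SUBSTRATES: tuple[tuple[str, str, float], ...] = (
    ("Robinia pseudoacacia", "deciduous_tree", 0.370),
    ("Quercus variabilis", "deciduous_tree", 0.160),
    ("Acer truncatum", "deciduous_tree", 0.095),
    ("Styphnolobium japonicum", "deciduous_tree", 0.045),
    ("Ulmus pumila", "deciduous_tree", 0.035),
    ("Koelreuteria paniculata", "deciduous_tree", 0.027),
    ("Diospyros lotus", "deciduous_tree", 0.025),
    ("Ailanthus altissima", "deciduous_tree", 0.015),
    ("Celtis bungeana", "deciduous_tree", 0.013),
    ("Platycladus orientalis", "coniferous_tree", 0.050),
    ("Pinus tabuliformis", "coniferous_tree", 0.025),
    ("Vitex negundo", "shrub", 0.050),
    ("Cotinus coggygria", "shrub", 0.030),
    ("Rhamnus parvifolia", "shrub", 0.015),
    ("Lonicera maackii", "shrub", 0.012),
    ("Syringa oblata", "shrub", 0.010),
    ("Spiraea trilobata", "shrub", 0.008),
    ("Grewia biloba", "shrub", 0.015),
)

# fixed community abundances: park canopy dominants plus modest presence for
# the leading dietary genera (a genus that birds eat heavily is generally at
# least present in the community); the remaining mass is spread over all
# other diet genera with a geometric tail
DEFAULT_COMMUNITY_DOMINANTS: dict[str, float] = {
    "Platycladus": 0.13, "Pinus": 0.10, "Quercus": 0.12, "Acer": 0.09,
    "Robinia": 0.11, "Cotinus": 0.06, "Ulmus": 0.03, "Koelreuteria": 0.03,
    "Vitex": 0.04, "Ailanthus": 0.02, "Celtis": 0.02, "Forsythia": 0.02,
    "Morus": 0.045, "Prunus": 0.030,
    "Rosa": 0.022, "Carya": 0.013, "Syringa": 0.013, "Cynoglossum": 0.009,
    "Iris": 0.009, "Styphnolobium": 0.012, "Rhamnus": 0.008,
}


@dataclass
class KeystonePlan:
    genus: str
    boost: float = 20.0
    coverage: float = 0.6  # fraction of the bird community (by sampling weight)


@dataclass
class TemporalPlan:
    genus: str
    early: float = 1.0
    mid: float = 1.0
    late: float = 1.0


@dataclass
class NestPlan:
    n_nests: int = 147
    p_unidentified: float = 31 / 147
    p_artificial: float = 9 / 116  # among identified nests
    bird_weights: tuple = DEFAULT_NEST_BIRDS
    substrates: tuple = DEFAULT_NEST_SUBSTRATES


@dataclass
class SimConfig:
    """Full parameterization of one synthetic survey; the seed fixes everything."""

    seed: int = 1
    n_samples: int = 107
    n_plant_genera: int = 210
    host_pool: tuple = DEFAULT_HOST_POOL
    abundance_model: str = "lognormal"  # or "log_series"
    sigma: float = 1.7  # lognormal shape; tuned for top-15 cumulative ~0.7
    log_series_theta: float = 0.97
    keystones: tuple[KeystonePlan, ...] = (
        KeystonePlan("Morus", 20.0, 0.6),
        KeystonePlan("Prunus", 20.0, 0.6),
    )
    temporal: tuple[TemporalPlan, ...] = (
        TemporalPlan("Morus", early=3.0, mid=1.0, late=1 / 3),
        TemporalPlan("Prunus", early=1 / 3, mid=1.0, late=3.0),
    )
    depth_mean: float = 2e4  # reads per sample per marker
    depth_dispersion: float = 2.0  # negative-binomial size parameter
    host_self_fraction: float = 0.65  # of a sample's COI reads
    prey: tuple = DEFAULT_PREY
    nest: NestPlan = field(default_factory=NestPlan)
    community_dominants: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMMUNITY_DOMINANTS)
    )
    survey_start: datetime.date = datetime.date(2024, 6, 4)
    survey_end: datetime.date = datetime.date(2024, 6, 25)


@dataclass
class GroundTruth:
    """What was planted, for scoring pipeline recovery."""

    keystone_genera: list[str]
    keystone_boosts: dict[str, float]
    keystone_coverage: dict[str, float]
    covered_hosts: dict[str, list[str]]
    temporal_effects: dict[str, dict[str, float]]
    host_family_weights: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def default_paper_like_config(seed: int = 1) -> SimConfig:
    """Default survey conditions: ~107 samples, 13 hosts in which two families
    dominate, ~210 plant genera with top-15 cumulative share around 0.7, two
    keystones planted at 20x boost and 0.6 community coverage, ~107
    vegetation nests over 18 substrate species."""
    return SimConfig(seed=seed)


# ---------------------------------------------------------------------------


def genus_names(n: int) -> list[str]:
    names = list(_NAMED_GENERA[:n])
    names += [f"Genus_{i:03d}" for i in range(len(names) + 1, n + 1)]
    return names


def _rank_abundance(cfg: SimConfig) -> np.ndarray:
    n = cfg.n_plant_genera
    if cfg.abundance_model == "lognormal":
        z = np.array([NormalDist().inv_cdf((i + 0.5) / n) for i in range(n)])
        w = np.exp(cfg.sigma * z)[::-1]
    elif cfg.abundance_model == "log_series":
        i = np.arange(1, n + 1)
        w = cfg.log_series_theta ** i / i
    else:
        raise ValueError(f"unknown abundance model {cfg.abundance_model!r}")
    return w / w.sum()


def _covered_hosts(cfg: SimConfig, plan: KeystonePlan, rng: np.random.Generator) -> list[str]:
    """Host species with access to the keystone: a weighted random permutation
    of the pool is consumed until the covered sampling-weight mass reaches the
    coverage fraction, so coverage means 'fraction of the bird community'."""
    species = [h[0] for h in cfg.host_pool]
    weights = np.array([h[3] for h in cfg.host_pool], dtype=float)
    weights = weights / weights.sum()
    order = rng.choice(len(species), size=len(species), replace=False, p=weights)
    covered, mass = [], 0.0
    for idx in order:
        if mass >= plan.coverage:
            break
        covered.append(species[idx])
        mass += weights[idx]
    return sorted(covered)


def _temporal_label(date: datetime.date) -> str:
    return "early" if date.day <= 10 else ("mid" if date.day <= 20 else "late")


def _draw_depth(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    r = cfg.depth_dispersion
    p = r / (r + cfg.depth_mean)
    return rng.negative_binomial(r, p, size=size) + 1  # avoid empty samples


def generate_dataset(cfg: SimConfig):
    """Generate one synthetic survey.

    Returns ``(coi, rbcl, samples, nests, community, truth)`` where the OTU
    tables, sample metadata, nest records and community table carry exactly
    the structure the ingest module consumes and ``truth`` records the
    planted effects.
    """
    rng = np.random.default_rng(cfg.seed)
    genera = genus_names(cfg.n_plant_genera)
    genus_idx = {g: i for i, g in enumerate(genera)}
    for plan in cfg.keystones:
        if plan.genus not in genus_idx:
            raise ValueError(f"keystone genus {plan.genus!r} not among the plant genera")
        if plan.boost < 1:
            raise ValueError("keystone boost factors must be >= 1")
    for plan in cfg.temporal:
        if plan.genus not in genus_idx:
            raise ValueError(f"temporal genus {plan.genus!r} not among the plant genera")

    base = _rank_abundance(cfg)
    species = [h[0] for h in cfg.host_pool]
    host_weights = np.array([h[3] for h in cfg.host_pool], dtype=float)
    host_weights = host_weights / host_weights.sum()

    covered = {plan.genus: _covered_hosts(cfg, plan, rng) for plan in cfg.keystones}

    # per (host, temporal bin) genus profile
    def profile(host: str, bin_label: str) -> np.ndarray:
        w = base.copy()
        for plan in cfg.keystones:
            if host in covered[plan.genus]:
                w[genus_idx[plan.genus]] *= plan.boost
        for plan in cfg.temporal:
            w[genus_idx[plan.genus]] *= getattr(plan, bin_label)
        return w / w.sum()

    # samples: host, date
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    hosts = [species[i] for i in rng.choice(len(species), size=n, p=host_weights)]
    span = (cfg.survey_end - cfg.survey_start).days
    dates = [
        cfg.survey_start + datetime.timedelta(days=int(d))
        for d in rng.integers(0, span + 1, size=n)
    ]
    samples = [SampleMeta(sample_id=s, collection_date=d) for s, d in zip(sample_ids, dates)]

    # rbcL counts: genus x sample, then split a couple of genera into 2 OTUs
    depths = _draw_depth(cfg, rng, n)
    genus_counts = np.zeros((cfg.n_plant_genera, n), dtype=np.int64)
    prof_cache: dict[tuple[str, str], np.ndarray] = {}
    for j in range(n):
        key = (hosts[j], _temporal_label(dates[j]))
        if key not in prof_cache:
            prof_cache[key] = profile(*key)
        genus_counts[:, j] = rng.multinomial(depths[j], prof_cache[key])

    split_genera = {g for g in ("Morus", "Rosa") if g in genus_idx}
    rbcl_rows: dict[str, np.ndarray] = {}
    rbcl_lineages: dict[str, Lineage] = {}
    otu_no = 0
    for g in genera:
        lineage = Lineage(["Viridiplantae", "Streptophyta", "Magnoliopsida", "", "", g, ""])
        row = genus_counts[genus_idx[g]]
        if g in split_genera:
            first = rng.binomial(row, 0.7)
            for part in (first, row - first):
                otu_no += 1
                oid = f"rbcL_OTU{otu_no:04d}"
                rbcl_rows[oid] = part
                rbcl_lineages[oid] = lineage
        else:
            otu_no += 1
            oid = f"rbcL_OTU{otu_no:04d}"
            rbcl_rows[oid] = row
            rbcl_lineages[oid] = lineage
    rbcl = OtuTable(
        marker="rbcL",
        counts=pd.DataFrame.from_dict(rbcl_rows, orient="index", columns=sample_ids),
        lineages=rbcl_lineages,
    )
    rbcl.counts.index.name = "otu_id"

    # COI counts: host self-reads plus a prey community
    prey = list(cfg.prey)
    prey_w = np.array([p[5] for p in prey], dtype=float)
    prey_w = prey_w / prey_w.sum()
    coi_depths = _draw_depth(cfg, rng, n)
    n_prey = len(prey)
    prey_counts = np.zeros((n_prey, n), dtype=np.int64)
    self_counts = np.zeros((len(species), n), dtype=np.int64)
    sp_idx = {s: i for i, s in enumerate(species)}
    for j in range(n):
        self_reads = int(round(cfg.host_self_fraction * coi_depths[j]))
        self_counts[sp_idx[hosts[j]], j] = self_reads
        prey_counts[:, j] = rng.multinomial(coi_depths[j] - self_reads, prey_w)

    coi_rows: dict[str, np.ndarray] = {}
    coi_lineages: dict[str, Lineage] = {}
    for i, (sp, fam, order, _) in enumerate(cfg.host_pool):
        oid = f"COI_host{i + 1:03d}"
        coi_rows[oid] = self_counts[i]
        coi_lineages[oid] = Lineage(
            ["Animalia", "Chordata", "Aves", order, fam, sp.split()[0], sp]
        )
    for i, (name, phylum, klass, order, family, _) in enumerate(prey):
        oid = f"COI_prey{i + 1:03d}"
        coi_rows[oid] = prey_counts[i]
        genus = name.split()[0] if not name.endswith("sp.") else ""
        coi_lineages[oid] = Lineage(
            ["Animalia", phylum, klass, order, family, genus, name]
        )
    coi = OtuTable(
        marker="COI",
        counts=pd.DataFrame.from_dict(coi_rows, orient="index", columns=sample_ids),
        lineages=coi_lineages,
    )
    coi.counts.index.name = "otu_id"

    nests = _generate_nests(cfg, rng)
    community = _generate_community(cfg, genera)
    truth = GroundTruth(
        keystone_genera=[p.genus for p in cfg.keystones],
        keystone_boosts={p.genus: p.boost for p in cfg.keystones},
        keystone_coverage={p.genus: p.coverage for p in cfg.keystones},
        covered_hosts=covered,
        temporal_effects={
            p.genus: {"early": p.early, "mid": p.mid, "late": p.late} for p in cfg.temporal
        },
        host_family_weights=_family_weights(cfg),
    )
    return coi, rbcl, samples, nests, community, truth


def _family_weights(cfg: SimConfig) -> dict[str, float]:
    out: dict[str, float] = {}
    total = sum(h[3] for h in cfg.host_pool)
    for _, fam, _, w in cfg.host_pool:
        out[fam] = out.get(fam, 0.0) + w / total
    return out


def _generate_nests(cfg: SimConfig, rng: np.random.Generator) -> list[NestRecord]:
    plan = cfg.nest
    birds = [b for b, _ in plan.bird_weights]
    bw = np.array([w for _, w in plan.bird_weights], dtype=float)
    bw = bw / bw.sum()
    subs = [(s, gf) for s, gf, _ in plan.substrates]
    sw = np.array([w for _, _, w in plan.substrates], dtype=float)
    sw = sw / sw.sum()
    nests: list[NestRecord] = []
    for i in range(plan.n_nests):
        nest_id = f"N{i + 1:03d}"
        bird = (
            UNIDENTIFIED
            if rng.random() < plan.p_unidentified
            else birds[rng.choice(len(birds), p=bw)]
        )
        if bird != UNIDENTIFIED and rng.random() < plan.p_artificial:
            nests.append(NestRecord(nest_id, bird, ARTIFICIAL, "non_plant"))
            continue
        substrate, gf = subs[rng.choice(len(subs), p=sw)]
        nests.append(NestRecord(nest_id, bird, substrate, gf))
    return nests


def _generate_community(cfg: SimConfig, genera: list[str]) -> CommunityTable:
    dominants = dict(cfg.community_dominants)
    unknown = set(dominants) - set(genera)
    if unknown:
        raise ValueError(f"community dominants not among plant genera: {sorted(unknown)}")
    rest = [g for g in genera if g not in dominants]
    remaining = 1.0 - sum(dominants.values())
    if remaining <= 0:
        raise ValueError("community dominants already exceed total abundance")
    # spread the remaining mass in proportion to the diet base profile, so
    # rarely-eaten genera are also rare in the community (near-neutral tail)
    base = _rank_abundance(cfg)
    gidx = {g: i for i, g in enumerate(genera)}
    tail = np.array([base[gidx[g]] for g in rest])
    tail = tail / tail.sum() * remaining
    fractions = dict(dominants)
    fractions.update({g: float(t) for g, t in zip(rest, tail)})
    total = sum(fractions.values())
    return CommunityTable({g: v / total for g, v in fractions.items()})


def nest_growth_form_map(cfg: SimConfig | None = None) -> dict[str, str]:
    """Substrate species -> growth form lookup used by the nest generator."""
    plan = (cfg or SimConfig()).nest
    return {s: gf for s, gf, _ in plan.substrates}


def write_dataset(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a full dataset in the ingest module's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coi, rbcl, samples, nests, community, truth = generate_dataset(cfg)
    paths = {
        "coi": outdir / "otu_coi.tsv",
        "rbcl": outdir / "otu_rbcl.tsv",
        "samples": outdir / "samples.csv",
        "nests": outdir / "nests.csv",
        "community": outdir / "community.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_otu_table(coi, paths["coi"])
    write_otu_table(rbcl, paths["rbcl"])
    write_sample_meta(samples, paths["samples"])
    write_nest_records(nests, paths["nests"])
    write_community_table(community, paths["community"])
    truth.to_json(paths["ground_truth"])
    return paths
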