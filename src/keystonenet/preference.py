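"""Food-preference (FP) and nesting-preference (NP) indices.

Both are selection-ratio-style electivity measures: the ratio of a plant
genus's relative abundance in what birds use (dietary plant reads, or
nest substrates) to its relative abundance in the local vegetation
community. An index above 1 means the genus is used more than its
availability would predict.
"""

from __future__ import annotations

import csv
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .ingest import (
    ARTIFICIAL,
    UNASSIGNED,
    CommunityTable,
    NestRecord,
    OtuTable,
    SampleMeta,
)


@dataclass(frozen=True)
class PreferenceResult:
    taxon: str
    usage_fraction: float
    community_fraction: float
    index: float  # NaN when flagged undefined
    kind: str  # "FP" or "NP"
    flag: str = ""  # "" or "undefined_community"


def diet_relative_abundance(
    otu: OtuTable,
    samples: Sequence[SampleMeta],
    level: str = "per_pool",
    rank: str = "genus",
) -> dict[str, float]:
    """Relative abundance of each plant taxon in the birds' diet.

    ``per_pool`` pools reads over all host-assigned samples before taking
    fractions ("relative abundance in all dietary plants"); the
    ``per_sample_mean`` convention takes within-sample fractions and averages
    them over samples with at least one plant read ("average relative
    abundance"). Either way the returned fractions sum to 1.
    """
    sids = [
        s.sample_id
        for s in samples
        if s.host_species != UNASSIGNED and s.sample_id in otu.counts.columns
    ]
    agg = otu.aggregate(rank)
    if agg.empty or not sids:
        raise ValueError("no classified plant reads in the host-assigned samples")
    agg = agg[sids]
    if level == "per_pool":
        totals = agg.sum(axis=1)
        grand = totals.sum()
        if grand <= 0:
            raise ValueError("no plant reads in the host-assigned samples")
        return {t: float(v) / grand for t, v in totals.items() if v > 0}
    if level == "per_sample_mean":
        col_sums = agg.sum(axis=0)
        informative = col_sums.index[col_sums > 0]
        if len(informative) == 0:
            raise ValueError("no plant reads in the host-assigned samples")
        fractions = agg[informative] / col_sums[informative]
        mean = fractions.mean(axis=1)
        return {t: float(v) for t, v in mean.items() if v > 0}
    raise ValueError(f"unknown level {level!r}")


def nest_relative_abundance(
    nests: Sequence[NestRecord], rank: str = "genus"
) -> dict[str, float]:
    """Relative abundance of each plant taxon among nest substrates.

    Artificial substrates are excluded; substrate species aggregate to genus
    (first name token) when ``rank="genus"``.
    """
    counts: Counter[str] = Counter()
    for n in nests:
        if n.substrate == ARTIFICIAL:
            continue
        taxon = n.substrate.split()[0] if rank == "genus" else n.substrate
        counts[taxon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no vegetation nests")
    return {t: c / total for t, c in counts.items()}


def preference_index(
    usage: Mapping[str, float],
    community: CommunityTable,
    kind: str = "FP",
) -> list[PreferenceResult]:
    """usage/community abundance ratio per genus.

    Community taxa are matched case-insensitively at genus rank (species
    entries summed to genus). Genera present in the community but absent from
    usage get index 0; genera used but absent from the community cannot be
    ratioed and are flagged ``undefined_community`` and listed after the
    ranked results. Results are sorted descending by index.
    """
    if kind not in ("FP", "NP"):
        raise ValueError(f"unknown preference kind {kind!r}")
    if not community.fractions:
        raise ValueError("empty community table")
    comm = community.at_genus()
    usage_by_genus: dict[str, float] = defaultdict(float)
    display: dict[str, str] = {}
    for taxon, frac in usage.items():
        key = taxon.split()[0].strip().lower()
        usage_by_genus[key] += frac
        display.setdefault(key, taxon.split()[0].strip())
    ranked: list[PreferenceResult] = []
    undefined: list[PreferenceResult] = []
    for key in sorted(set(comm) | set(usage_by_genus)):
        u = usage_by_genus.get(key, 0.0)
        c = comm.get(key)
        name = display.get(key, key.capitalize())
        if c is None or c <= 0:
            undefined.append(
                PreferenceResult(name, u, 0.0, math.nan, kind, flag="undefined_community")
            )
        else:
            ranked.append(PreferenceResult(name, u, c, u / c, kind))
    ranked.sort(key=lambda r: (-r.index, r.taxon))
    return ranked + sorted(undefined, key=lambda r: (-r.usage_fraction, r.taxon))


def preference_to_csv(results: Sequence[PreferenceResult], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["taxon", "usage_fraction", "community_fraction", "index", "kind", "flag"])
        for r in results:
            writer.writerow(
                [
                    r.taxon,
                    f"{r.usage_fraction:.10g}",
                    f"{r.community_fraction:.10g}",
                    "NA" if math.isnan(r.index) else f"{r.index:.10g}",
                    r.kind,
                    r.flag,
                ]
            )
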