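"""Descriptive outputs: composition tables, dietary overlap, temporal
bins and nest-substrate shares.

These reproduce the survey-style summaries a field study reports around
the network analysis: how skewed the diet is, which genera dominate, how
nests distribute over growth forms, and the grouped abundance tables an
ordination or differential-abundance tool would consume downstream.
"""

from __future__ import annotations

import datetime
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import (
    ARTIFICIAL,
    UNASSIGNED,
    UNIDENTIFIED,
    NestRecord,
    OtuTable,
    SampleMeta,
)
from .network import BipartiteNetwork
from .preference import diet_relative_abundance

TEMPORAL_LABELS = ("early", "mid", "late")


@dataclass
class CompositionTable:
    """Per-taxon mean relative abundance, sorted descending, with cumulative
    shares and an optional growth-form partition over the taxa above a
    threshold fraction."""

    table: pd.DataFrame  # columns: taxon, mean_relative_abundance, cumulative_share, growth_form
    partition: dict[str, dict] = field(default_factory=dict)
    partition_threshold: float = 0.0

    def top_cumulative_share(self, n: int) -> float:
        return float(self.table["mean_relative_abundance"].head(n).sum())


@dataclass
class OverlapResult:
    """Exact UpSet-style overlap of per-bird resource presence sets.

    ``exclusive_counts`` maps each observed membership pattern (a sorted
    tuple of bird names) to the number of resources used by exactly those
    birds; ``pairwise`` counts shared resources for every bird pair.
    """

    presence: dict[str, frozenset[str]]
    exclusive_counts: dict[tuple[str, ...], int]
    pairwise: pd.DataFrame


@dataclass
class TemporalBins:
    """Early/mid/late grouping of samples with per-bin abundance tables."""

    scheme: str
    bins: dict[str, list[str]]  # label -> sample ids
    abundance: pd.DataFrame | None = None  # taxon x bin relative abundances


def composition(
    otu: OtuTable,
    samples: Sequence[SampleMeta],
    rank: str = "genus",
    growth_forms: Mapping[str, str] | None = None,
    partition_threshold: float = 0.001,
    level: str = "per_sample_mean",
) -> CompositionTable:
    """Composition summary of the diet at ``rank``.

    Mean relative abundance follows the per-sample-mean convention by
    default; the partition sums group taxa above ``partition_threshold``
    (default 0.1%) by their growth-form label (e.g. woody vs herbaceous),
    reporting genus counts and cumulative shares within the classified
    subset.
    """
    fractions = diet_relative_abundance(otu, samples, level=level, rank=rank)
    rows = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
    gf = dict(growth_forms or {})
    table = pd.DataFrame(
        {
            "taxon": [t for t, _ in rows],
            "mean_relative_abundance": [v for _, v in rows],
        }
    )
    table["cumulative_share"] = table["mean_relative_abundance"].cumsum()
    table["growth_form"] = [gf.get(t, "NA") for t in table["taxon"]]

    partition: dict[str, dict] = {}
    above = table[table["mean_relative_abundance"] > partition_threshold]
    classified = above[above["growth_form"] != "NA"]
    total = classified["mean_relative_abundance"].sum()
    for label, group in classified.groupby("growth_form"):
        share = group["mean_relative_abundance"].sum()
        partition[str(label)] = {
            "n_taxa": int(len(group)),
            "cumulative_share": float(share / total) if total > 0 else 0.0,
        }
    return CompositionTable(table=table, partition=partition, partition_threshold=partition_threshold)


def presence_sets(net: BipartiteNetwork) -> dict[str, frozenset[str]]:
    """Post-filter resource set per bird node."""
    out: dict[str, set[str]] = {b: set() for b in net.bird_nodes}
    for bird, resource, _ in net.edges:
        out[bird].add(resource)
    return {b: frozenset(s) for b, s in out.items()}


def overlap_counts(presence: Mapping[str, frozenset[str] | set[str]]) -> OverlapResult:
    """Exact exclusive-intersection cardinalities over the presence sets.

    UpSet semantics: each resource is counted once, under the exact set of
    birds that use it; the sum of all exclusive counts therefore equals the
    size of the union. A pairwise (plain, non-exclusive) overlap matrix is
    also emitted; with fewer than two birds it is empty.
    """
    presence = {b: frozenset(s) for b, s in presence.items()}
    pattern_of: dict[str, tuple[str, ...]] = {}
    for resource in set().union(*presence.values()) if presence else set():
        members = tuple(sorted(b for b, s in presence.items() if resource in s))
        pattern_of[resource] = members
    exclusive = Counter(pattern_of.values())
    birds = sorted(presence)
    if len(birds) >= 2:
        pairwise = pd.DataFrame(0, index=birds, columns=birds, dtype="int64")
        for a, b in combinations(birds, 2):
            n = len(presence[a] & presence[b])
            pairwise.loc[a, b] = pairwise.loc[b, a] = n
        for b in birds:
            pairwise.loc[b, b] = len(presence[b])
    else:
        pairwise = pd.DataFrame(dtype="int64")
    return OverlapResult(
        presence=presence,
        exclusive_counts=dict(sorted(exclusive.items())),
        pairwise=pairwise,
    )


def overlap_to_tsv(result: OverlapResult, path: str | Path) -> None:
    """Membership-pattern TSV consumable by UpSet plotting tools."""
    with Path(path).open("w") as fh:
        fh.write("members\tcount\n")
        for members, count in result.exclusive_counts.items():
            fh.write("&".join(members) + f"\t{count}\n")


def temporal_bins(
    samples: Sequence[SampleMeta],
    scheme: str = "calendar_thirds",
    otu: OtuTable | None = None,
    rank: str = "genus",
    level: str = "per_pool",
) -> TemporalBins:
    """Partition samples into early/mid/late sampling-time groups.

    ``calendar_thirds`` maps day-of-month 1-10/11-20/21-31 to
    early/mid/late; ``tercile`` splits the samples into three equal-count
    groups by date. When an OTU table is given, a taxon x bin relative-
    abundance table is attached — the grouped input a differential-abundance
    analysis would consume.
    """
    bins: dict[str, list[str]] = {label: [] for label in TEMPORAL_LABELS}
    if scheme == "calendar_thirds":
        for s in samples:
            day = s.collection_date.day
            label = "early" if day <= 10 else ("mid" if day <= 20 else "late")
            bins[label].append(s.sample_id)
    elif scheme == "tercile":
        ordered = sorted(samples, key=lambda s: (s.collection_date, s.sample_id))
        for label, chunk in zip(TEMPORAL_LABELS, np.array_split(np.array([s.sample_id for s in ordered], dtype=object), 3)):
            bins[label] = list(chunk)
    else:
        raise ValueError(f"unknown temporal scheme {scheme!r}")
    if sum(bool(v) for v in bins.values()) <= 1:
        import logging

        logging.getLogger(__name__).warning(
            "all samples fall in a single temporal bin; differential contrasts are empty"
        )

    abundance = None
    if otu is not None:
        agg = otu.aggregate(rank)
        cols = {}
        for label, sids in bins.items():
            use = [s for s in sids if s in agg.columns]
            if not use:
                cols[label] = pd.Series(0.0, index=agg.index)
                continue
            if level == "per_pool":
                totals = agg[use].sum(axis=1)
                grand = totals.sum()
                cols[label] = totals / grand if grand > 0 else totals.astype(float)
            elif level == "per_sample_mean":
                col_sums = agg[use].sum(axis=0)
                keep = col_sums.index[col_sums > 0]
                cols[label] = (
                    (agg[keep] / col_sums[keep]).mean(axis=1)
                    if len(keep)
                    else pd.Series(0.0, index=agg.index)
                )
            else:
                raise ValueError(f"unknown level {level!r}")
        abundance = pd.DataFrame(cols)[list(TEMPORAL_LABELS)]
    return TemporalBins(scheme=scheme, bins=bins, abundance=abundance)


@dataclass
class NestSummary:
    n_total: int
    n_identified: int
    n_artificial: int  # artificial-substrate nests among identified ones
    n_vegetation: int  # identified nests on plant substrates
    growth_form_fractions: dict[str, float]
    substrate_counts: dict[str, int]
    bird_counts: dict[str, int]


def nest_shares(nests: Sequence[NestRecord]) -> NestSummary:
    """Summarize a nest survey.

    Vegetation nests are those with an identified bird on a plant substrate;
    artificial-substrate nests are counted separately and excluded from the
    growth-form fractions, which sum to 1 over vegetation nests.
    """
    identified = [n for n in nests if n.bird_species != UNIDENTIFIED]
    artificial = [n for n in identified if n.substrate == ARTIFICIAL]
    vegetation = [n for n in identified if n.substrate != ARTIFICIAL]
    if not vegetation:
        raise ValueError("no vegetation nests with identified birds")
    gf = Counter(n.growth_form for n in vegetation)
    total = sum(gf.values())
    return NestSummary(
        n_total=len(nests),
        n_identified=len(identified),
        n_artificial=len(artificial),
        n_vegetation=len(vegetation),
        growth_form_fractions={k: v / total for k, v in sorted(gf.items())},
        substrate_counts=dict(sorted(Counter(n.substrate for n in vegetation).items())),
        bird_counts=dict(sorted(Counter(n.bird_species for n in vegetation).items())),
    )
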