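# Methods

## Scope and model

keystonenet operationalizes "keystone resource" as the top-ranked
resource node of a weighted bipartite bird–resource network, ranked by
degree and by abundance-weighted mean degree (wMD). Three networks are
built from a breeding-season survey:

| kind | birds side | resource side | edge weight |
|---|---|---|---|
| `diet_animal` | host species called from COI | animal taxon groups | summed COI reads |
| `diet_plant` | host species called from COI | plant genera | summed rbcL reads |
| `nest_plant` | nest-owner species | substrate plant species | nest counts |

The analysis assumes the upstream steps (read QC, 97%-similarity OTU
clustering, BLAST taxonomy) were done by their standard published tools;
inputs are classified read-count tables. Read counts are treated as
relative usage intensity — a standard but strong metabarcoding
assumption (amplification bias, secondary ingestion and gut-passage
differences are not modeled).

### Host assignment

The host of a fecal sample is the avian species-level taxon with the
most COI reads in that sample. Ties are broken lexicographically with a
logged warning (determinism over an arbitrary choice); samples whose top
avian taxon holds under half of the sample's avian reads are assigned
but flagged `low_confidence`. Samples with no avian reads stay
`UNASSIGNED` and are excluded from every diet computation.

After assignment, each sample's reads classified to its *own* host
species are removed before composition and network steps
(`remove_host_reads`, on by default in the pipeline): host DNA in a
fecal sample is not diet. Reads of *other* bird species are kept — birds
occur as prey. Reads in family Hominidae (human contamination, which
fecal metabarcoding routinely detects) are excluded from prey networks
by default but reportable separately; both behaviors are toggleable.

### Abundance filters

Both filters are strict inequalities: an OTU is retained only if its
total reads across samples **exceed** `min_otu_reads` (default 100), and
a diet edge only if its weight **exceeds** `edge_min` (default 100
reads). "Absolute abundance" is read as the per-OTU total; a per-sample
variant (zeroing cells at or below the threshold) is available via
`filter_otus(scope="per_sample")`. Nest networks default to
`edge_min=0`: nest counts live on a ~100-nest scale where a threshold of
100 would erase the network, and single-nest links are real
observations, not sequencing noise.

### Node importance

For a node with incident edge abundances `s₁..sₙ` and absolute abundance
`b` (total reads, or total nests),

    wMD = (Σᵢ b·sᵢ) / (Σᵢ b).

The formula is evaluated term by term even though `b` cancels (literal
wMD equals the mean incident edge weight — an equivalence the tests
assert against an independent mean-of-weights oracle on 1000 random
networks). Whether `b` was meant to vary across the sum is genuinely
ambiguous; a `partner_weighted` variant that substitutes the partner
bird's abundance `bᵢ` is therefore implemented as a one-symbol change
and exposed everywhere (`variant=`). The default is the literal reading.
Degree-0 nodes get wMD 0 with a warning; rankings break ties by the
other statistic, then alphabetically. `rank_keystones(by="both")`
reports the intersection of the two top-k sets (k default 10).

Node abundances are totals over all observations, so a node's abundance
may exceed the sum of its surviving (post-filter) edge weights. Isolated
nodes are dropped from networks but kept in composition summaries.

### Animal resource aggregation

Animal OTUs aggregate to mixed-rank groups via a YAML rule file shipped
with the package: Insecta splits into its five dominant orders
(Coleoptera, Hemiptera, Hymenoptera, Lepidoptera, Diptera) plus "other
insects"; Aves, Rodentia, Amphibia, Arachnida, Annelida, Mollusca and
Hominidae are kept as named groups; the rest fall back to "other
Arthropoda" / "other vertebrates" / "other invertebrates". Users supply
their own file for other faunas.

### Preference indices

FP (food) and NP (nesting) are selection ratios: usage fraction over
community fraction per plant genus. Usage defaults to the **pooled**
convention (genus reads / all plant reads; nest counts / all vegetation
nests) because the indices describe "relative abundance in all dietary
plants"; composition summaries default to the **per-sample-mean**
convention ("average relative abundance"), which weights each sample
equally. Both conventions are exposed everywhere and agree for a single
sample. Community matching is case-insensitive at genus rank;
species-level community entries sum to their genus. Genera used but
absent from the community cannot be ratioed — they are flagged
`undefined_community` and listed after the ranked results rather than
silently dropped or given a pseudo-count. No "preference" cutoff is
applied by default (published FP values below 1 have been described as
preferences, so any cutoff would be a guess); `--preference-cutoff`
filters the report if the user wants one.

### Summaries

* Composition: per-genus mean relative abundance (per-sample-mean),
  cumulative shares, and a growth-form partition (woody vs herbaceous
  counts and shares) over genera above a threshold fraction — default
  0.1%, configurable. The growth-form lookup is a user-supplied CSV; a
  default for common North-China urban-forest genera ships with the
  package.
* Overlap: exact UpSet semantics — every resource is counted once under
  the exact set of birds using it, so exclusive counts sum to the union
  size; a plain pairwise overlap matrix is also emitted.
* Temporal bins: `calendar_thirds` (days 1–10/11–20/21–31 →
  early/mid/late; the default, matching beginning/mid/end-of-month
  phrasing) or `tercile` (three equal-count groups by date). Per-bin
  genus abundance tables are the grouped input a differential-abundance
  tool (e.g. LEfSe) would consume; the differential test itself is out
  of scope.
* Nest shares: vegetation nests are those with an identified owner on a
  plant substrate; artificial-structure nests and unidentified-owner
  nests are counted separately. Growth-form fractions are over
  vegetation nests only.

## Synthetic-data generator

Real surveys of this kind are typically available only on request, so
the generator is first-class, tested code that emulates the survey
conditions the pipeline targets:

* **Scale**: 107 fecal samples over a 4–25 June window; 13 host species
  whose two dominant families (Corvidae, Turdidae) carry ~75% of the
  sampling weight; 210 dietary plant genera; ~26 animal prey taxa; 147
  nests (~21% unidentified owners, ~8% of identified ones on artificial
  structures → ≈107 vegetation nests) over 18 substrate species with
  deciduous/coniferous/shrub weights ≈ 0.785/0.075/0.14.
* **Abundance model**: deterministic lognormal rank-abundance profile
  (quantile-spaced, shape σ = 1.7; log-series optional) — the standard
  species-abundance family, with σ chosen so the realized top-15
  cumulative diet share lands near 0.7 once keystone boosts are applied.
* **Planted keystones**: *Morus* and *Prunus* sit at base ranks 5 and 8
  (≈3.7% and 2.5%); their profile weight is multiplied by `boost`
  (default 20×) for the covered hosts, which makes them the top diet
  genera for covered birds. Dominance is thus *created by the planted
  effect*, not by the base profile, so top-3 recovery is a real signal.
  `coverage` (default 0.6) is the fraction of the bird community with
  access to the keystone: a weighted random permutation of host species
  is consumed until the covered sampling-weight mass reaches the
  coverage fraction. Ground truth records the covered species.
* **Planted phenology**: *Morus* ×3 early / ×⅓ late, *Prunus* mirrored,
  applied by the sample's calendar third.
* **Read depth**: negative binomial per sample per marker (mean 2×10⁴,
  dispersion 2) — overdispersed as real libraries are; configurable.
* **COI structure**: 65% of each sample's COI reads are the host's own
  (exercising host calling and host-read removal); the rest draw from a
  fixed prey community spanning the aggregation groups, including other
  birds and a small human fraction.
* **Community table**: fixed park-dominant canopy shares (Platycladus,
  Pinus, Quercus, Acer, Robinia, ...), modest presence for the leading
  diet genera, and the remaining mass spread proportionally to the diet
  base profile (a near-neutral tail, so deep-tail preference indices
  hover near 1 instead of exploding on mismatched tail shapes).
  Keystone community shares (0.045, 0.030) put their FP near 5.

The generator works at classified-count level; it does not emulate
sequencing error, chimeras, PCR bias, OTU mis-assignment or taxonomy
gaps. Passing recovery tests therefore show that the *statistics* find
planted structure under realistic skew and sampling noise — not that the
wet-lab and bioinformatic upstream would deliver unbiased counts.

## Verification design and problem sizes

Deterministic identities use handmade toy fixtures with hand-computed
expectations. Stochastic properties run at the default survey scale:
keystone recovery is scored over 100 seeded surveys (planted keystones
in the wMD top-3 in ≥95, observed 100/100), with monotonicity checked
across boosts {2, 5, 20} at 100 seeds each; temporal-effect direction is
checked the same way. Network accumulation is verified against a
brute-force per-cell oracle on 10-sample surveys, and literal wMD
against the mean-incident-weight oracle on 1000 random bipartite
networks of up to 30 nodes. `scripts/acceptance.py` reruns the survey
arithmetic and the 100-survey recovery measurements from scratch at
whatever seed is supplied.

## Known limitations

* Host calling trusts the dominant avian taxon; cross-contamination
  between samples or nest predation of other birds can in principle
  misassign a sample, and only the <50% flag surfaces it.
* Read counts are used as abundance without copy-number or biomass
  correction; wMD on diet networks is therefore a read-flux statistic.
* FP/NP inherit the community table's measurement basis (stem counts,
  cover, or basal area give different denominators); the package
  normalizes whatever basis it is given and leaves the choice to the
  user.
* Edge thresholds are absolute read counts, not rarefied or
  depth-normalized; heavily unequal sequencing depths between host
  species will shift which edges survive.
* The temporal binning supports one survey month; multi-season phenology
  is out of scope.
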