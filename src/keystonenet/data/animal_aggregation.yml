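# Default aggregation scheme for animal-diet resource nodes.
#
# Insecta is split into its five dominant orders plus an "other insects"
# bucket; remaining taxa are grouped at class/order/phylum level with
# "other Arthropoda" / "other vertebrates" / "other invertebrates"
# fallbacks. Rules are applied top to bottom; the first match wins.
class_splits:
  Insecta:
    orders: [Coleoptera, Hemiptera, Hymenoptera, Lepidoptera, Diptera]
    other: other insects
groups:
  - {rank: family, name: Hominidae, label: Hominidae}
  - {rank: class, name: Aves, label: Aves}
  - {rank: order, name: Rodentia, label: Rodentia}
  - {rank: class, name: Amphibia, label: Amphibia}
  - {rank: class, name: Arachnida, label: Arachnida}
  - {rank: phylum, name: Annelida, label: Annelida}
  - {rank: phylum, name: Mollusca, label: Mollusca}
fallbacks:
  - {rank: phylum, name: Arthropoda, label: other Arthropoda}
  - {rank: phylum, name: Chordata, label: other vertebrates}
default: other invertebrates
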