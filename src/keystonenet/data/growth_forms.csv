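taxon,growth_form
Rosa,woody
Carya,woody
Syringa,woody
Morus,woody
Ulmus,woody
Prunus,woody
Pteroceltis,woody
Koelreuteria,woody
Styphnolobium,woody
Lonicera,woody
Castanea,woody
Pyrus,woody
Ailanthus,woody
Rhamnus,woody
Amorpha,woody
Quercus,woody
Acer,woody
Platycladus,woody
Pinus,woody
Cotinus,woody
Robinia,woody
Vitex,woody
Celtis,woody
Forsythia,woody
Grewia,woody
Spiraea,woody
Diospyros,woody
Pertya,woody
Cynoglossum,herbaceous
Iris,herbaceous
Carex,herbaceous
Viola,herbaceous
Liriope,herbaceous
Dianthus,herbaceous
Digitaria,herbaceous
Triticum,herbaceous
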