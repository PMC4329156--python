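region,leasing_eur_per_ha,establishment_eur_per_ha
Götalands södra slättbygder,702,17
Götalands mellanbygder,445,17
Götalands norra slättbygder,330,17
Svealands slättbygder,217,17
Götalands skogsbygder,217,17
Mellersta Sveriges skogdbygder,131,17
Nedre Norrland,97,17
Övre Norrland,78,17
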