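# Standard-test-species whitelist (Latin names, one per line).
# Seeded with OECD/ISO standard acute test species; the exact membership used
# for the published tables is not printed anywhere, so edit as needed.
# Crustaceans
Daphnia magna
Daphnia pulex
Ceriodaphnia dubia
Americamysis bahia
Artemia salina
Gammarus pulex
Hyalella azteca
Palaemonetes pugio
# Fish
Danio rerio
Pimephales promelas
Oncorhynchus mykiss
Lepomis macrochirus
Cyprinus carpio
Carassius auratus
Oryzias latipes
Poecilia reticulata
Gasterosteus aculeatus
Ictalurus punctatus
Cyprinodon variegatus
Menidia beryllina
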