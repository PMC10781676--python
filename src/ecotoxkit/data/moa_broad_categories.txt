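# Controlled vocabulary: broad mode-of-action categories (32 entries).
# Seeded with every category named in the catalog narrative plus
# field-standard system-level categories; editable configuration — the full
# published vocabulary lives in the catalog's own column dictionary.
Neuroactive
Neuromuscular system
Endocrine
Cardiovascular system
Nucleic acid damage
Antibiotic
Synthetic auxin
Photosynthesis inhibition
Respiration inhibition
Cell division inhibition
Cell membrane disruption
Cell wall synthesis inhibition
Chitin synthesis inhibition
Lipid biosynthesis inhibition
Amino acid biosynthesis inhibition
Pigment biosynthesis inhibition
Protein synthesis inhibition
Growth regulation
Oxidative stress
Reactive
Narcosis
Immune system
Digestive system
Respiratory system
Renal system
Musculoskeletal system
Reproductive system
Metabolism
Antiparasitic
Antiviral
Antifungal
Multiple mechanisms
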